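"""Sequencing QC arithmetic and a window-Poisson peak caller.

The caller is a deliberately simplified MACS-style procedure for paired
treatment/input tracks that are already binned at a fixed step:

1. the control track is linearly scaled to the treatment sequencing depth
   (factor total_reads_treatment / total_reads_control);
2. the per-bin Poisson rate is the maximum of the scaled control mean over
   a 1-kb window, a 10-kb window, and the genome-wide scaled control mean
   (the local-rate idea of MACS; the genome-wide floor avoids a zero rate
   in unsequenced regions);
3. a bin is significant when the upper-tail Poisson probability
   P(X >= k; lambda) of its treatment count k falls at or below the
   p-value threshold (1e-5 by default, the published cutoff);
4. significant bins are merged across gaps of at most ``merge_gap`` bins
   and stretches shorter than ``min_peak_length`` are discarded;
5. each peak gets summit (most enriched significant bin), amplitude
   (maximum treatment pileup in the peak) and score -10*log10(p at the
   summit), capped when p underflows double precision.

The fragment-model estimation of MACS is not reproduced: the fragment
extension is configuration (300 bp in the study), and the mfold bounds are
accepted and used only to warn when no candidate region reaches the lower
bound, which on real data would indicate that MACS could not have built a
fragment model either.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, stats

from .coverage import CoverageTrack, DEFAULT_STEP
from .errors import ConfigError, DataError, FormatError
from .peaks import Peak, PeakSet, SCORE_CAP

logger = logging.getLogger(__name__)

LOG10 = math.log(10.0)


# ---------------------------------------------------------------------------
# QC arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCStats:
    """Read-filtering and mapping summary for one library.

    Rates are percentages reported to two decimals:
    clean_rate  = 100 * total_reads / raw_reads
    mapped_rate = 100 * mapped_reads / total_reads
    unique_mapped_rate = 100 * unique_mapped_reads / total_reads
    """

    raw_reads: int
    low_quality: int
    total_reads: int
    mapped_reads: int
    unique_mapped_reads: int
    clean_rate: float
    mapped_rate: float
    unique_mapped_rate: float


def compute_qc_stats(raw_reads: int, low_quality: int, mapped_reads: int,
                     unique_mapped_reads: int) -> QCStats:
    if min(raw_reads, low_quality, mapped_reads, unique_mapped_reads) < 0:
        raise DataError("read counts must be non-negative")
    if low_quality > raw_reads:
        raise DataError("low_quality exceeds raw_reads")
    total = raw_reads - low_quality
    if mapped_reads > total:
        raise DataError(
            f"mapped_reads ({mapped_reads}) exceeds total reads after "
            f"filtering ({total})")
    if unique_mapped_reads > mapped_reads:
        raise DataError("unique_mapped_reads exceeds mapped_reads")
    if raw_reads == 0 or total == 0:
        raise DataError("cannot compute rates over zero reads")
    return QCStats(
        raw_reads=raw_reads,
        low_quality=low_quality,
        total_reads=total,
        mapped_reads=mapped_reads,
        unique_mapped_reads=unique_mapped_reads,
        clean_rate=round(100.0 * total / raw_reads, 2),
        mapped_rate=round(100.0 * mapped_reads / total, 2),
        unique_mapped_rate=round(100.0 * unique_mapped_reads / total, 2),
    )


# ---------------------------------------------------------------------------
# Poisson window caller
# ---------------------------------------------------------------------------

@dataclass
class PeakCallParams:
    p_threshold: float = 1e-5
    mfold_low: float = 10.0
    mfold_high: float = 30.0
    bin_step: int = DEFAULT_STEP
    min_peak_length: int = 300          # = fragment extension
    merge_gap: int = 1                  # bins
    small_window: int = 1000            # bp
    large_window: int = 10000           # bp
    bandwidth: int | None = None        # accepted, logged, unused
    score_cap: float = SCORE_CAP

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigError("p_threshold must lie in (0, 1)")
        if not self.mfold_low < self.mfold_high:
            raise ConfigError("mfold_low must be < mfold_high")
        if self.bandwidth is not None:
            logger.info("bandwidth=%d accepted but unused by the window "
                        "Poisson caller", self.bandwidth)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sliding_mean(values: np.ndarray, window_bins: int) -> np.ndarray:
    w = max(1, window_bins)
    return ndimage.uniform_filter1d(values, size=w, mode="nearest")


def poisson_bin_pvalues(treatment: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Upper-tail Poisson probability P(X >= k; lambda) per bin.

    Non-integer treatment values are rounded up: a bin with fractional
    pileup k is at least as surprising as ceil(k) - 1 events are common.
    """
    k = np.ceil(treatment).astype(np.int64)
    return stats.poisson.sf(k - 1, lam)


def local_lambda(control_scaled: np.ndarray, step: int, small_window: int,
                 large_window: int, genome_mean: float) -> np.ndarray:
    lam_small = _sliding_mean(control_scaled, round(small_window / step))
    lam_large = _sliding_mean(control_scaled, round(large_window / step))
    return np.maximum(np.maximum(lam_small, lam_large), genome_mean)


def _runs_with_gaps(idx: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Group sorted significant-bin indices, bridging gaps <= merge_gap bins."""
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev <= merge_gap + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def call_peaks(treatment: CoverageTrack, control: CoverageTrack,
               params: PeakCallParams | None = None) -> PeakSet:
    """Call enrichment peaks on a treatment track against its input control."""
    params = params or PeakCallParams()
    if treatment.step != control.step:
        raise FormatError(
            f"step mismatch: treatment {treatment.step} vs control {control.step}")
    if treatment.step != params.bin_step:
        raise FormatError(
            f"params.bin_step {params.bin_step} != track step {treatment.step}")
    if set(treatment.chroms) != set(control.chroms):
        raise FormatError("treatment and control cover different chromosomes")
    if control.total_reads <= 0:
        raise ConfigError("control track has no reads (total_reads == 0)")

    scale = treatment.total_reads / control.total_reads
    step = treatment.step
    genome_mean = control.genome_mean() * scale
    if genome_mean <= 0:
        raise ConfigError("control track is empty: genome-wide mean is zero")

    peaks: list[Peak] = []
    max_enrichment = 0.0
    counter = 0
    for chrom in treatment.chroms:
        t = treatment.values[chrom]
        c = control.values.get(chrom, np.zeros_like(t)) * scale
        if t.size == 0:
            continue
        if c.size != t.size:
            raise FormatError(f"bin count mismatch on {chrom}")
        lam = local_lambda(c, step, params.small_window, params.large_window,
                           genome_mean)
        pvals = poisson_bin_pvalues(t, lam)
        with np.errstate(divide="ignore"):
            max_enrichment = max(max_enrichment, float(np.max(t / np.maximum(lam, 1e-300))))
        sig = np.flatnonzero(pvals <= params.p_threshold)
        if sig.size == 0:
            continue
        offset = treatment.starts.get(chrom, 0)
        for first, last in _runs_with_gaps(sig, params.merge_gap):
            length = (last - first + 1) * step
            if length < params.min_peak_length:
                continue
            window = slice(first, last + 1)
            sig_in = sig[(sig >= first) & (sig <= last)]
            # summit: middle of the tied maximal significant bins, so a
            # flat-topped peak gets a centred, strand-unbiased summit
            tied = sig_in[t[sig_in] == t[sig_in].max()]
            summit_bin = int(tied[tied.size // 2])
            k = int(np.ceil(t[summit_bin]))
            logp = stats.poisson.logsf(k - 1, lam[summit_bin])
            score = params.score_cap if not np.isfinite(logp) else min(
                params.score_cap, -10.0 * logp / LOG10)
            p_summit = float(np.exp(logp)) if np.isfinite(logp) else 0.0
            peaks.append(Peak(
                chrom=chrom,
                start=offset + first * step,
                end=offset + (last + 1) * step,
                name=f"peak_{counter}",
                summit=offset + summit_bin * step + step // 2,
                amplitude=float(np.max(t[window])),
                p_value=p_summit,
                score=float(score),
            ))
            counter += 1
    if max_enrichment < params.mfold_low:
        logger.warning(
            "no region exceeds mfold_low=%g (max treatment/lambda ratio %.2f); "
            "a fragment-model caller would fail on this input",
            params.mfold_low, max_enrichment)
    return PeakSet(peaks)


def write_run_log(params: PeakCallParams, path, extra: dict | None = None) -> None:
    """Echo all caller parameters (plus run facts) into a JSON run log."""
    payload = asdict(params)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
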