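"""Gene calling and two-tier differential H3K4Me3 enrichment.

A gene is "called" (H3K4Me3-enriched) when a peak interval comes within
1 kb of its TSS, boundaries inclusive. Differences between two genotypes
are reported in two disjoint tiers:

* unique enrichment — the gene is called in one genotype and completely
  absent from the other genotype's call set (presence/absence);
* preferential enrichment — the gene is called in both genotypes, with a
  matched peak pair whose amplitude ratio is at least ``fold_min`` (2 by
  default, inclusive) and whose larger amplitude is at least ``amp_min``
  (10), the pair lying within ``gene_window`` (1 kb) of the annotated gene
  interval (note: the gene body, not the TSS — a deliberately looser rule
  than gene calling).

Unique status takes precedence over preferential, so the five statuses
partition the union of call sets. Distances are measured between covered
bases, so a peak ending exactly 1 kb from a TSS still calls the gene.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .annotation import GenomeAnnotation, interval_gap, point_interval_distance
from .errors import DataError, UndefinedStatisticError
from .peaks import Peak, PeakSet

STATUSES = ("unique_wt", "unique_ko", "preferential_wt", "preferential_ko",
            "unchanged")


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    peak_name: str
    distance: int  # bp from nearest supporting peak to the TSS


@dataclass(frozen=True)
class DifferentialCall:
    gene_id: str
    status: str
    amp_wt: float
    amp_ko: float

    @property
    def ratio(self) -> float:
        lo = min(self.amp_wt, self.amp_ko)
        hi = max(self.amp_wt, self.amp_ko)
        if lo == 0.0:
            return float("inf")
        return hi / lo


def round_half_up_pct(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage 100*n/d rounded half-up, the convention of printed tables."""
    if denominator == 0:
        raise UndefinedStatisticError("percentage over a zero denominator")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-digits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# gene calling
# ---------------------------------------------------------------------------

def call_genes(peaks: PeakSet, annotation: GenomeAnnotation,
               window: int = 1000) -> dict[str, GeneCall]:
    """Genes with >= 1 peak interval within ``window`` bp of the TSS.

    Returns a mapping gene_id -> GeneCall recording the nearest such peak.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    calls: dict[str, GeneCall] = {}
    for g in annotation.genes.itertuples():
        best: tuple[int, str] | None = None
        for p in by_chrom.get(g.chrom, ()):  # peaks are sparse; linear scan per chrom
            d = point_interval_distance(g.tss, p.start, p.end)
            if d <= window and (best is None or d < best[0]):
                best = (d, p.name)
        if best is not None:
            calls[g.gene_id] = GeneCall(g.gene_id, best[1], best[0])
    return calls


def unique_genes(calls_wt: dict[str, GeneCall], calls_ko: dict[str, GeneCall],
                 ) -> tuple[set[str], set[str], set[str]]:
    """(unique_wt, unique_ko, shared) by strict set difference/intersection."""
    wt, ko = set(calls_wt), set(calls_ko)
    return wt - ko, ko - wt, wt & ko


# ---------------------------------------------------------------------------
# preferential enrichment
# ---------------------------------------------------------------------------

def _match_peaks(peaks_wt: list[Peak], peaks_ko: list[Peak], bin_step: int,
                 ) -> list[tuple[Peak, Peak]]:
    """Cross-genotype peak pairs: overlapping intervals or summits within one bin."""
    pairs = []
    for a in peaks_wt:
        for b in peaks_ko:
            overlap = a.start < b.end and b.start < a.end
            close = abs(a.summit - b.summit) <= bin_step
            if overlap or close:
                pairs.append((a, b))
    return pairs


def preferential_enrichment(peaks_wt: PeakSet, peaks_ko: PeakSet,
                            annotation: GenomeAnnotation,
                            fold_min: float = 2.0, amp_min: float = 10.0,
                            gene_window: int = 1000, bin_step: int = 50,
                            call_window: int = 1000,
                            ) -> dict[str, DifferentialCall]:
    """Full differential call set over the union of called genes."""
    for ps, label in ((peaks_wt, "wt"), (peaks_ko, "ko")):
        for p in ps:
            if p.amplitude is None or not np.isfinite(p.amplitude):
                raise DataError(f"peak {p.name} ({label}) has no amplitude")
    calls_wt = call_genes(peaks_wt, annotation, window=call_window)
    calls_ko = call_genes(peaks_ko, annotation, window=call_window)
    uniq_wt, uniq_ko, shared = unique_genes(calls_wt, calls_ko)

    wt_by_chrom: dict[str, list[Peak]] = {}
    for p in peaks_wt:
        wt_by_chrom.setdefault(p.chrom, []).append(p)
    ko_by_chrom: dict[str, list[Peak]] = {}
    for p in peaks_ko:
        ko_by_chrom.setdefault(p.chrom, []).append(p)
    pairs_by_chrom = {
        c: _match_peaks(wt_by_chrom.get(c, []), ko_by_chrom.get(c, []), bin_step)
        for c in set(wt_by_chrom) | set(ko_by_chrom)
    }

    out: dict[str, DifferentialCall] = {}
    peak_amp = {("wt", p.name): p.amplitude for p in peaks_wt}
    peak_amp.update({("ko", p.name): p.amplitude for p in peaks_ko})
    for gid in uniq_wt:
        out[gid] = DifferentialCall(gid, "unique_wt",
                                    amp_wt=peak_amp[("wt", calls_wt[gid].peak_name)],
                                    amp_ko=0.0)
    for gid in uniq_ko:
        out[gid] = DifferentialCall(gid, "unique_ko", amp_wt=0.0,
                                    amp_ko=peak_amp[("ko", calls_ko[gid].peak_name)])

    genes = annotation.genes.set_index("gene_id")
    for gid in shared:
        g = genes.loc[gid]
        best_passing: tuple[float, Peak, Peak] | None = None  # by max amplitude
        best_any: tuple[float, Peak, Peak] | None = None
        for a, b in pairs_by_chrom.get(g["chrom"], ()):  # pairs near the gene body
            lo = min(a.start, b.start)
            hi = max(a.end, b.end)
            if interval_gap(lo, hi, int(g["start"]), int(g["end"])) > gene_window:
                continue
            hi_amp = max(a.amplitude, b.amplitude)
            lo_amp = min(a.amplitude, b.amplitude)
            if best_any is None or hi_amp > best_any[0]:
                best_any = (hi_amp, a, b)
            passes = (hi_amp >= amp_min
                      and (lo_amp == 0.0 or hi_amp / lo_amp >= fold_min))
            if passes and (best_passing is None or hi_amp > best_passing[0]):
                best_passing = (hi_amp, a, b)
        # a gene is preferential when ANY matched pair near it passes the
        # fold/amplitude rule, even if a taller unchanged pair also sits there
        if best_passing is not None:
            _, a, b = best_passing
            status = ("preferential_wt" if a.amplitude > b.amplitude
                      else "preferential_ko")
            out[gid] = DifferentialCall(gid, status, amp_wt=a.amplitude,
                                        amp_ko=b.amplitude)
        elif best_any is not None:
            _, a, b = best_any
            out[gid] = DifferentialCall(gid, "unchanged", amp_wt=a.amplitude,
                                        amp_ko=b.amplitude)
        else:
            out[gid] = DifferentialCall(gid, "unchanged", amp_wt=0.0, amp_ko=0.0)
    return out


# ---------------------------------------------------------------------------
# summary arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialSummary:
    """Counts plus the derived one-decimal percentages of a two-genotype run.

    Percentages follow the printed convention: unique and preferential
    percentages are over the genotype's own called-gene total; the
    expanded tier (unique + preferential) is reported the same way;
    called-gene and peak-count differences are percentages of the first
    (wild-type) total.
    """

    called_wt: int
    called_ko: int
    unique_wt: int
    unique_ko: int
    expanded_wt: int        # unique + preferential, per genotype
    expanded_ko: int
    peaks_wt: int | None = None
    peaks_ko: int | None = None

    @property
    def unique_pct_wt(self) -> float:
        return round_half_up_pct(self.unique_wt, self.called_wt)

    @property
    def unique_pct_ko(self) -> float:
        return round_half_up_pct(self.unique_ko, self.called_ko)

    @property
    def expanded_pct_wt(self) -> float:
        return round_half_up_pct(self.expanded_wt, self.called_wt)

    @property
    def expanded_pct_ko(self) -> float:
        return round_half_up_pct(self.expanded_ko, self.called_ko)

    @property
    def called_difference_pct(self) -> float:
        return round_half_up_pct(self.called_wt - self.called_ko, self.called_wt)

    @property
    def peak_decrease_pct(self) -> float:
        if self.peaks_wt is None or self.peaks_ko is None:
            raise UndefinedStatisticError("peak counts were not supplied")
        return round_half_up_pct(self.peaks_wt - self.peaks_ko, self.peaks_wt)

    def to_dict(self) -> dict:
        d = dict(called_wt=self.called_wt, called_ko=self.called_ko,
                 unique_wt=self.unique_wt, unique_ko=self.unique_ko,
                 expanded_wt=self.expanded_wt, expanded_ko=self.expanded_ko,
                 unique_pct_wt=self.unique_pct_wt,
                 unique_pct_ko=self.unique_pct_ko,
                 expanded_pct_wt=self.expanded_pct_wt,
                 expanded_pct_ko=self.expanded_pct_ko,
                 called_difference_pct=self.called_difference_pct)
        if self.peaks_wt is not None and self.peaks_ko is not None:
            d.update(peaks_wt=self.peaks_wt, peaks_ko=self.peaks_ko,
                     peak_decrease_pct=self.peak_decrease_pct)
        return d


def summarize_differential(calls_wt: dict[str, GeneCall],
                           calls_ko: dict[str, GeneCall],
                           differential: dict[str, DifferentialCall],
                           peaks_wt: int | None = None,
                           peaks_ko: int | None = None) -> DifferentialSummary:
    by_status: dict[str, int] = {s: 0 for s in STATUSES}
    for c in differential.values():
        if c.status not in by_status:
            raise DataError(f"unknown status {c.status}")
        by_status[c.status] += 1
    return DifferentialSummary(
        called_wt=len(calls_wt), called_ko=len(calls_ko),
        unique_wt=by_status["unique_wt"], unique_ko=by_status["unique_ko"],
        expanded_wt=by_status["unique_wt"] + by_status["preferential_wt"],
        expanded_ko=by_status["unique_ko"] + by_status["preferential_ko"],
        peaks_wt=peaks_wt, peaks_ko=peaks_ko,
    )


def audit_summary(counts: dict) -> DifferentialSummary:
    """Build a summary from externally supplied published counts.

    Expected keys: called_wt, called_ko, unique_wt, unique_ko, expanded_wt,
    expanded_ko, and optionally peaks_wt / peaks_ko. Used to recompute
    printed percentages from printed counts.
    """
    required = ["called_wt", "called_ko", "unique_wt", "unique_ko",
                "expanded_wt", "expanded_ko"]
    missing = [k for k in required if k not in counts]
    if missing:
        raise DataError(f"audit counts missing keys: {missing}")
    return DifferentialSummary(
        **{k: counts[k] for k in required},
        peaks_wt=counts.get("peaks_wt"), peaks_ko=counts.get("peaks_ko"),
    )
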