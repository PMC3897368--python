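"""Genomic-context annotation of peaks.

Peaks are classified into exactly one of four categories relative to the
gene annotation — upstream (summit within 2 kb 5' of a TSS, strand-aware),
intragenic (summit inside a gene body), downstream (summit within 2 kb 3'
of a TES), intergenic (peak interval at least 2 kb from every annotated
gene) — with priority upstream > intragenic > downstream > intergenic, so
a peak near a short gene whose windows overlap is counted with the TSS.

Classification uses the summit, because the summit is the "location" of a
peak in a browser view, and it makes the categories mutually exclusive.
Intergenic distance is measured from the whole peak interval to gene
intervals. A peak whose summit escapes every 2-kb window while its body
still comes within 2 kb of a gene (possible only for peaks much wider than
2 kb) is assigned to the flank of its nearest gene rather than called
intergenic, keeping the partition total.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation, point_interval_distance
from .coverage import CoverageTrack
from .errors import ConfigError, DataError, MappingError, UndefinedStatisticError
from .peaks import Peak, PeakSet

logger = logging.getLogger(__name__)

CATEGORIES = ("upstream", "intragenic", "downstream", "intergenic")


@dataclass
class AnnotationParams:
    upstream_window: int = 2000
    downstream_window: int = 2000
    intergenic_min_distance: int = 2000

    def __post_init__(self) -> None:
        if min(self.upstream_window, self.downstream_window,
               self.intergenic_min_distance) <= 0:
            raise ConfigError("annotation windows must be positive")


def _classify_summit(peak: Peak, genes, params: AnnotationParams) -> str:
    """Priority rule for one peak against the gene records of its chromosome.

    ``genes`` is an iterable of objects with start/end/tss/tes/strand.
    """
    s = peak.summit
    in_upstream = in_gene = in_downstream = False
    min_interval_gap = None
    nearest_side = None
    nearest_dist = None
    for g in genes:
        if g.strand == "+":
            up_lo, up_hi = g.tss - params.upstream_window, g.tss - 1
            dn_lo, dn_hi = g.tes + 1, g.tes + params.downstream_window
        else:
            up_lo, up_hi = g.tss + 1, g.tss + params.upstream_window
            dn_lo, dn_hi = g.tes - params.downstream_window, g.tes - 1
        if up_lo <= s <= up_hi:
            in_upstream = True
        if g.start <= s < g.end:
            in_gene = True
        if dn_lo <= s <= dn_hi:
            in_downstream = True
        # interval-to-gene distance for the intergenic rule
        if peak.start < g.end and g.start < peak.end:
            gap = 0
        elif peak.end <= g.start:
            gap = g.start - (peak.end - 1)
        else:
            gap = peak.start - (g.end - 1)
        if min_interval_gap is None or gap < min_interval_gap:
            min_interval_gap = gap
        d = point_interval_distance(s, g.start, g.end)
        if nearest_dist is None or d < nearest_dist:
            nearest_dist = d
            if g.start <= s < g.end:
                nearest_side = "intragenic"
            elif (s < g.start) == (g.strand == "+"):
                nearest_side = "upstream"
            else:
                nearest_side = "downstream"
    if in_upstream:
        return "upstream"
    if in_gene:
        return "intragenic"
    if in_downstream:
        return "downstream"
    if min_interval_gap is None or min_interval_gap >= params.intergenic_min_distance:
        return "intergenic"
    # wide peak: body proximal, summit distal — count it with the nearest flank
    return nearest_side if nearest_side != "intragenic" else "intragenic"


def classify_peaks(peaks: PeakSet, annotation: GenomeAnnotation,
                   params: AnnotationParams | None = None,
                   ) -> tuple[PeakSet, dict[str, float]]:
    """Assign one category per peak; return the annotated set and fractions."""
    params = params or AnnotationParams()
    unknown = sorted(set(peaks.chroms) - set(annotation.chrom_lengths))
    if unknown:
        raise MappingError(f"peaks on chromosomes absent from annotation: {unknown}")
    by_chrom = {c: list(annotation.genes_on(c).itertuples())
                for c in set(peaks.chroms)}
    out = []
    counts = dict.fromkeys(CATEGORIES, 0)
    for p in peaks:
        cat = _classify_summit(p, by_chrom[p.chrom], params)
        counts[cat] += 1
        out.append(p.with_category(cat))
    n = len(out)
    fractions = {c: (counts[c] / n if n else 0.0) for c in CATEGORIES}
    return PeakSet(out), fractions


def cpg_association(peaks: PeakSet, islands, category_filter: str | None = None,
                    ) -> float:
    """Percent of peaks overlapping at least one CpG island by >= 1 bp.

    ``islands`` is a DataFrame with chrom/start/end. With a category
    filter, only peaks of that category enter the denominator; an empty
    denominator raises UndefinedStatisticError rather than reporting 0.
    Reported to one decimal, e.g. 74.1.
    """
    if category_filter is not None and category_filter not in CATEGORIES:
        raise DataError(f"unknown category: {category_filter}")
    trees: dict[str, IntervalTree] = {}
    for r in islands.itertuples():
        if r.end > r.start:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    selected = [p for p in peaks
                if category_filter is None or p.category == category_filter]
    if not selected:
        raise UndefinedStatisticError(
            "no peaks in the selected category; CpG fraction is undefined")
    hits = sum(1 for p in selected
               if p.chrom in trees and trees[p.chrom].overlap(p.start, p.end))
    return round(100.0 * hits / len(selected), 1)


def chromosome_distribution(peaks: PeakSet, chrom_lengths: dict[str, int],
                            ) -> dict[str, float]:
    """Peaks per megabase for every chromosome (zero-count ones included)."""
    missing = sorted(set(peaks.chroms) - set(chrom_lengths))
    if missing:
        raise MappingError(f"no length for chromosomes: {missing}")
    counts = dict.fromkeys(chrom_lengths, 0)
    for p in peaks:
        counts[p.chrom] += 1
    return {c: counts[c] / (chrom_lengths[c] / 1e6) for c in chrom_lengths}


@dataclass
class MetageneProfile:
    """Signal averaged over genes around TSS/TES.

    upstream: flank 5' of the TSS at track resolution (transcription
    orientation, TSS-distal first); body: gene body rescaled to
    n_body_bins; downstream: flank 3' of the TES. n_genes is the number of
    genes aggregated.
    """

    flank: int
    n_body_bins: int
    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes: int

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def metagene_profile(signal: CoverageTrack, annotation: GenomeAnnotation,
                     flank: int = 5000, n_body_bins: int = 300,
                     ) -> MetageneProfile:
    """Average signal over [TSS-flank, TSS), the rescaled body, and (TES, TES+flank].

    Minus-strand genes are reversed so the profile always reads in
    transcription orientation. Genes longer than n_body_bins*step, or whose
    flanks fall outside the chromosome, are excluded (counts logged).
    """
    if flank <= 0:
        raise ConfigError("flank must be positive")
    step = signal.step
    n_flank = flank // step
    up_rows, body_rows, down_rows = [], [], []
    n_too_long = n_out = 0
    for g in annotation.genes.itertuples():
        length = g.end - g.start
        if length > n_body_bins * step:
            n_too_long += 1
            continue
        vals = signal.values.get(g.chrom)
        if vals is None:
            n_out += 1
            continue
        lo_bin = (g.start - flank) // step
        hi_bin = (g.end - 1 + flank) // step
        if lo_bin < 0 or hi_bin >= vals.size:
            n_out += 1
            continue
        left = vals[lo_bin:lo_bin + n_flank]                      # 5' genomic flank
        right = vals[hi_bin - n_flank + 1:hi_bin + 1]             # 3' genomic flank
        body_bins = vals[g.start // step:(g.end - 1) // step + 1]
        # rescale body to n_body_bins by linear interpolation
        x = np.linspace(0.0, 1.0, body_bins.size) if body_bins.size > 1 else np.array([0.0])
        xi = np.linspace(0.0, 1.0, n_body_bins)
        body = np.interp(xi, x, body_bins)
        if g.strand == "-":
            left, right = right[::-1], left[::-1]
            body = body[::-1]
        up_rows.append(left)
        body_rows.append(body)
        down_rows.append(right)
    if not up_rows:
        raise DataError("no eligible genes for the metagene profile")
    if n_too_long or n_out:
        logger.info("metagene: excluded %d genes longer than %d bp and %d "
                    "without full flanks in the track", n_too_long,
                    n_body_bins * step, n_out)
    return MetageneProfile(
        flank=flank, n_body_bins=n_body_bins,
        upstream=np.mean(up_rows, axis=0),
        body=np.mean(body_rows, axis=0),
        downstream=np.mean(down_rows, axis=0),
        n_genes=len(up_rows),
    )
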