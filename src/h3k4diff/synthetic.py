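"""Seeded two-genotype ChIP-seq landscape simulator.

The generator emulates the statistical structure the downstream analysis
assumes: a genome of well-separated genes, CpG islands at most TSSs plus
scattered intergenic islands, an H3K4Me3 peak landscape whose category mix
matches the published genome-wide proportions, planted unique and
preferential differences between a wild-type and a knockout genotype, read
pileup tracks for a Poisson peak caller, and a partially concordant
expression table. Every output is a pure function of the configuration
(including its seed); per-component random streams are derived from the
seed with fixed offsets so adding a generator never perturbs earlier ones.

Design notes (see docs/methods.md for rationale):

* Genes are placed non-overlapping with >= 5 kb gaps so every peak has
  exactly one defensible category and a 1-kb gene-calling window is
  unambiguous.
* Peak amplitudes are log-normal (median ~30) with a detectability floor,
  so planted truth is recoverable by construction — the simulator
  deliberately avoids marginal peaks, which would make exact ground-truth
  recovery ill-posed.
* Signal fragments are stacked exactly at the summit, giving each peak a
  rectangular footprint of extension + step bp whose height equals the
  planted amplitude; background reads supply the Poisson texture.
* ``reads_per_condition`` is the total sequencing depth of each track:
  the control is uniform background at full depth, the treatment spends
  its depth on planted signal first and uniform background for the rest.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GENE_COLUMNS, GenomeAnnotation, ISLAND_COLUMNS
from .coverage import CoverageTrack
from .errors import (CapacityError, ConfigError, DataError, EmptyTrackError,
                     PlacementError)
from .peaks import Peak, PeakSet, score_from_p

CATEGORY_ORDER = ("upstream", "intragenic", "downstream", "intergenic")
MIN_GENE_GAP = 5000          # bp between consecutive gene intervals
TSS_ISLAND_HALF = 500        # CpG island = TSS +/- 500 bp
INTERGENIC_ISLAND_HALF = 400
DEEP_INTERGENIC_MARGIN = 2800  # bp clearance for "intergenic" placements
ENRICHMENT_STATUSES = ("both", "unique_wt", "unique_ko", "preferential_wt",
                       "preferential_ko", "neither")

_STREAMS = {"genome": 0, "landscape": 1, "coverage_wt": 2, "coverage_ko": 3,
            "expression": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    offset = _STREAMS.get(stream)
    if offset is None:
        offset = 16 + (zlib.crc32(stream.encode()) % (2 ** 20))
    return np.random.default_rng([seed, offset])


@dataclass
class SimConfig:
    """All knobs of the simulator; the seed fully determines the outputs."""

    n_chromosomes: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2000, 15000)
    cpg_at_tss_fraction: float = 0.94
    intergenic_cpg_fraction: float = 0.401
    category_mix: dict[str, float] = field(default_factory=lambda: {
        "upstream": 0.741, "intragenic": 0.063,
        "downstream": 0.083, "intergenic": 0.113})
    amplitude_distribution: tuple[float, float] = (30.0, 0.4)  # (median, sigma)
    min_amplitude: float = 18.0
    n_unique_wt: int = 10
    n_unique_ko: int = 10
    n_preferential_wt: int = 15
    n_preferential_ko: int = 15
    n_silent_genes: int = 0
    preferential_fold: float = 3.0
    amplitude_jitter: float = 0.10
    de_concordance: float = 0.11
    reads_per_condition: int = 30_000
    fragment_extension: int = 300
    bin_step: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cpg_at_tss_fraction", "intergenic_cpg_fraction",
                     "de_concordance", "amplitude_jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if set(self.category_mix) != set(CATEGORY_ORDER):
            raise ConfigError(f"category_mix must cover {CATEGORY_ORDER}")
        if any(v < 0 for v in self.category_mix.values()):
            raise ConfigError("category_mix proportions must be >= 0")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("category_mix must sum to 1 within 1e-9")
        planted = (self.n_unique_wt + self.n_unique_ko + self.n_preferential_wt
                   + self.n_preferential_ko + self.n_silent_genes)
        if planted > self.n_genes:
            raise ConfigError(
                f"planted gene counts ({planted}) exceed n_genes ({self.n_genes})")
        if self.preferential_fold < 2.0:
            raise ConfigError("preferential_fold must be >= 2")
        if self.min_amplitude < 1.0:
            raise ConfigError("min_amplitude must be >= 1")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ConfigError("invalid gene_length_range")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ConfigError("need >= 1 chromosome of positive length")
        if not 0 <= self.seed < 2 ** 31:
            raise ConfigError("seed must lie in [0, 2**31)")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length
                for i in range(self.n_chromosomes)}

    @property
    def peak_half_width(self) -> int:
        return (self.fragment_extension + self.bin_step) // 2

    # -- flat key=value serialization --------------------------------------

    def to_file(self, path) -> None:
        lines = []
        for key, value in self.__dict__.items():
            if key == "category_mix":
                for cat in CATEGORY_ORDER:
                    lines.append(f"category_mix.{cat}={value[cat]!r}")
            elif isinstance(value, tuple):
                lines.append(f"{key}={','.join(repr(v) for v in value)}")
            else:
                lines.append(f"{key}={value!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        kwargs: dict = {}
        mix: dict[str, float] = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected key=value")
            key, value = line.split("=", 1)
            key = key.strip()
            value = value.strip()
            if key.startswith("category_mix."):
                mix[key.split(".", 1)[1]] = float(value)
            elif key in ("gene_length_range", "amplitude_distribution"):
                parts = value.split(",")
                caster = int if key == "gene_length_range" else float
                kwargs[key] = tuple(caster(float(p)) for p in parts)
            elif key in ("cpg_at_tss_fraction", "intergenic_cpg_fraction",
                         "preferential_fold", "amplitude_jitter",
                         "de_concordance", "min_amplitude"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
        if mix:
            kwargs["category_mix"] = mix
        return cls(**kwargs)


@dataclass
class TruthTable:
    """Planted ground truth for recovery testing.

    genes: gene_id, status (enrichment), de_status (up_wt/up_ko/null).
    peaks: one row per landscape location with per-genotype amplitudes
    (0 where the peak is absent), planted category and CpG flag.
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame

    def gene_set(self, status: str) -> set[str]:
        if status not in ENRICHMENT_STATUSES:
            raise DataError(f"unknown enrichment status {status!r}")
        return set(self.genes.loc[self.genes["status"] == status, "gene_id"])

    def de_set(self, de_status: str) -> set[str]:
        return set(self.genes.loc[self.genes["de_status"] == de_status, "gene_id"])

    def status_counts(self) -> dict[str, int]:
        return self.genes["status"].value_counts().to_dict()


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig) -> GenomeAnnotation:
    """Place non-overlapping genes with >= 5 kb gaps plus CpG islands."""
    rng = _rng(config.seed, "genome")
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1

    gene_rows = []
    island_rows = []
    gid = 0
    lo, hi = config.gene_length_range
    for ci, chrom in enumerate(config.chrom_lengths):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        needed = int(lengths.sum()) + (n + 1) * MIN_GENE_GAP
        if needed > config.chrom_length:
            raise CapacityError(
                f"{chrom}: {n} genes need {needed} bp but chrom_length is "
                f"{config.chrom_length}; reduce n_genes or gene_length_range, "
                f"or raise chrom_length")
        slack = config.chrom_length - needed
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i in range(n):
            pos += MIN_GENE_GAP + int(extra[i])
            start = pos
            end = start + int(lengths[i])
            pos = end
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(dict(gene_id=f"gene_{gid:04d}", chrom=chrom,
                                  strand=strand, start=start, end=end))
            gid += 1

    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)
    annotation = GenomeAnnotation(chrom_lengths=config.chrom_lengths,
                                  genes=genes,
                                  cpg_islands=pd.DataFrame(columns=ISLAND_COLUMNS))

    # CpG islands over a fraction of TSSs
    has_island = rng.random(len(annotation.genes)) < config.cpg_at_tss_fraction
    for flag, g in zip(has_island, annotation.genes.itertuples()):
        if flag:
            start = max(0, g.tss - TSS_ISLAND_HALF)
            end = min(config.chrom_length, g.tss + TSS_ISLAND_HALF)
            island_rows.append(dict(chrom=g.chrom, start=start, end=end))
    annotation.genes["tss_island"] = list(has_island)

    # additional intergenic islands in deep-intergenic zones
    n_intergenic_islands = max(8, round(config.n_genes / 8))
    zones = _deep_intergenic_zones(annotation, config)
    if zones:
        placed: list[tuple[str, int]] = []
        widths = np.array([z[2] - z[1] for z in zones], dtype=float)
        probs = widths / widths.sum()
        tries = 0
        while len(placed) < n_intergenic_islands and tries < 50 * n_intergenic_islands:
            tries += 1
            zi = int(rng.choice(len(zones), p=probs))
            chrom, zlo, zhi = zones[zi]
            if zhi - zlo < 2 * INTERGENIC_ISLAND_HALF:
                continue
            center = int(rng.integers(zlo + INTERGENIC_ISLAND_HALF,
                                      zhi - INTERGENIC_ISLAND_HALF + 1))
            if any(c == chrom and abs(center - p) < 2500 for c, p in placed):
                continue
            placed.append((chrom, center))
            island_rows.append(dict(chrom=chrom,
                                    start=center - INTERGENIC_ISLAND_HALF,
                                    end=center + INTERGENIC_ISLAND_HALF))

    islands = pd.DataFrame(island_rows, columns=ISLAND_COLUMNS)
    islands = islands.sort_values(["chrom", "start"], kind="stable",
                                  ignore_index=True)
    annotation.cpg_islands = islands
    return annotation


def _deep_intergenic_zones(annotation: GenomeAnnotation, config: SimConfig,
                           ) -> list[tuple[str, int, int]]:
    """Intervals at least DEEP_INTERGENIC_MARGIN bp away from every gene."""
    zones = []
    for chrom, length in annotation.chrom_lengths.items():
        g = annotation.genes_on(chrom).sort_values("start")
        edges = [0]
        for r in g.itertuples():
            edges.extend([r.start, r.end])
        edges.append(length)
        for i in range(0, len(edges), 2):
            lo = edges[i] + DEEP_INTERGENIC_MARGIN
            hi = edges[i + 1] - DEEP_INTERGENIC_MARGIN
            if hi - lo > 0:
                zones.append((chrom, lo, hi))
    return zones


# ---------------------------------------------------------------------------
# peak landscapes
# ---------------------------------------------------------------------------

def _amp_draw(rng: np.random.Generator, config: SimConfig) -> float:
    median, sigma = config.amplitude_distribution
    return float(max(config.min_amplitude,
                     math.exp(rng.normal(math.log(median), sigma))))


def _jitter(rng: np.random.Generator, config: SimConfig) -> float:
    j = config.amplitude_jitter
    if j == 0.0:
        return 1.0
    return float(math.exp(rng.uniform(math.log(1.0 - j), math.log(1.0 + j))))


def _planted_peak(chrom: str, summit: int, name: str, amplitude: float,
                  config: SimConfig) -> Peak:
    half = config.peak_half_width
    # nominal significance vs a unit-rate background; planted peaks carry a
    # plausible score, the caller recomputes real ones
    from scipy.stats import poisson
    p = float(poisson.sf(max(1, round(amplitude)) - 1, 1.0))
    return Peak(chrom=chrom, start=summit - half, end=summit + half,
                name=name, summit=summit, amplitude=float(amplitude),
                p_value=p, score=score_from_p(p))


def generate_peak_landscapes(annotation: GenomeAnnotation, config: SimConfig,
                             ) -> tuple[PeakSet, PeakSet, TruthTable]:
    """Plant the two-genotype peak landscape and its ground truth."""
    rng = _rng(config.seed, "landscape")
    genes = annotation.genes
    n_genes = len(genes)
    if n_genes != config.n_genes:
        raise DataError("annotation does not match config.n_genes")

    # -- gene statuses ------------------------------------------------------
    order = rng.permutation(n_genes)
    statuses = np.array(["both"] * n_genes, dtype=object)
    cursor = 0
    for status, count in (("unique_wt", config.n_unique_wt),
                          ("unique_ko", config.n_unique_ko),
                          ("preferential_wt", config.n_preferential_wt),
                          ("preferential_ko", config.n_preferential_ko),
                          ("neither", config.n_silent_genes)):
        statuses[order[cursor:cursor + count]] = status
        cursor += count

    mix = config.category_mix
    n_enriched = n_genes - config.n_silent_genes
    if mix["upstream"] <= 0:
        raise PlacementError("category_mix.upstream must be positive: every "
                             "enriched gene carries a TSS-proximal peak")
    n_total = max(n_enriched, round(n_enriched / mix["upstream"]))
    n_intra = round(n_total * mix["intragenic"])
    n_down = round(n_total * mix["downstream"])
    n_inter = round(n_total * mix["intergenic"])

    peak_rows = []  # dicts feeding TruthTable.peaks

    # -- TSS-proximal (upstream) peaks, one per enriched gene ---------------
    for gi, g in enumerate(genes.itertuples()):
        status = statuses[gi]
        if status == "neither":
            continue
        offset = int(rng.integers(100, 501))
        summit = g.tss - offset if g.strand == "+" else g.tss + offset
        if status == "both":
            base = _amp_draw(rng, config)
            amp_wt = base * _jitter(rng, config)
            amp_ko = base * _jitter(rng, config)
        elif status == "unique_wt":
            amp_wt, amp_ko = _amp_draw(rng, config), 0.0
        elif status == "unique_ko":
            amp_wt, amp_ko = 0.0, _amp_draw(rng, config)
        else:  # preferential
            low = max(_amp_draw(rng, config), 10.0 / config.preferential_fold)
            high = config.preferential_fold * low
            if status == "preferential_wt":
                amp_wt = high * _jitter(rng, config)
                amp_ko = low * _jitter(rng, config)
            else:
                amp_wt = low * _jitter(rng, config)
                amp_ko = high * _jitter(rng, config)
        peak_rows.append(dict(
            name=f"up_{g.gene_id}", chrom=g.chrom, summit=summit,
            category="upstream", gene_id=g.gene_id,
            cpg_flag=bool(g.tss_island), amp_wt=amp_wt, amp_ko=amp_ko))

    # -- intragenic peaks ---------------------------------------------------
    body_margin = 1300
    pool = [g for g in genes.itertuples()
            if g.end - g.start > 2 * body_margin + 200]
    if len(pool) < n_intra:
        raise PlacementError(
            f"category_mix requests {n_intra} intragenic peaks but only "
            f"{len(pool)} genes are long enough to host one")
    chosen = rng.choice(len(pool), size=n_intra, replace=False)
    for i, pi in enumerate(chosen):
        g = pool[int(pi)]
        summit = int(rng.integers(g.start + body_margin, g.end - body_margin))
        base = _amp_draw(rng, config)
        peak_rows.append(dict(
            name=f"intra_{i:03d}", chrom=g.chrom, summit=summit,
            category="intragenic", gene_id=g.gene_id, cpg_flag=False,
            amp_wt=base * _jitter(rng, config),
            amp_ko=base * _jitter(rng, config)))

    # -- downstream peaks ---------------------------------------------------
    if n_down > n_genes:
        raise PlacementError("category_mix requests more downstream peaks "
                             "than genes")
    chosen = rng.choice(n_genes, size=n_down, replace=False)
    for i, gi in enumerate(chosen):
        g = genes.iloc[int(gi)]
        offset = int(rng.integers(300, 1801))
        summit = int(g["tes"] + offset if g["strand"] == "+" else g["tes"] - offset)
        base = _amp_draw(rng, config)
        peak_rows.append(dict(
            name=f"dn_{i:03d}", chrom=g["chrom"], summit=summit,
            category="downstream", gene_id=g["gene_id"], cpg_flag=False,
            amp_wt=base * _jitter(rng, config),
            amp_ko=base * _jitter(rng, config)))

    # -- intergenic peaks ---------------------------------------------------
    zones = _deep_intergenic_zones(annotation, config)
    if not zones and n_inter > 0:
        raise PlacementError("no intergenic space >= 2.8 kb from genes; "
                             "category_mix is incompatible with the annotation")
    islands = annotation.cpg_islands
    gene_islands = set()
    for g in annotation.genes.itertuples():  # islands glued to TSSs
        if g.tss_island:
            gene_islands.add((g.chrom, max(0, g.tss - TSS_ISLAND_HALF)))
    free_islands = [r for r in islands.itertuples()
                    if (r.chrom, r.start) not in gene_islands]
    n_on_island = int(round(n_inter * config.intergenic_cpg_fraction))
    if n_on_island > len(free_islands):
        raise PlacementError(
            f"{n_on_island} island-associated intergenic peaks requested but "
            f"only {len(free_islands)} intergenic CpG islands exist")
    widths = np.array([z[2] - z[1] for z in zones], dtype=float)
    probs = widths / widths.sum() if len(zones) else None
    taken = rng.choice(len(free_islands), size=n_on_island, replace=False) \
        if n_on_island else np.empty(0, dtype=int)
    placed_pos: list[tuple[str, int]] = []
    for i, ii in enumerate(taken):
        isl = free_islands[int(ii)]
        center = (isl.start + isl.end) // 2
        summit = center + int(rng.integers(-100, 101))
        placed_pos.append((isl.chrom, summit))
        base = _amp_draw(rng, config)
        peak_rows.append(dict(
            name=f"ig_{i:03d}", chrom=isl.chrom, summit=summit,
            category="intergenic", gene_id=None, cpg_flag=True,
            amp_wt=base * _jitter(rng, config),
            amp_ko=base * _jitter(rng, config)))
    island_pos = [(r.chrom, (r.start + r.end) // 2) for r in islands.itertuples()]
    i = n_on_island
    tries = 0
    while i < n_inter and tries < 200 * n_inter:
        tries += 1
        zi = int(rng.choice(len(zones), p=probs))
        chrom, zlo, zhi = zones[zi]
        if zhi <= zlo:
            continue
        summit = int(rng.integers(zlo, zhi))
        if any(c == chrom and abs(summit - p) < 1200 for c, p in island_pos):
            continue
        if any(c == chrom and abs(summit - p) < 800 for c, p in placed_pos):
            continue
        placed_pos.append((chrom, summit))
        base = _amp_draw(rng, config)
        peak_rows.append(dict(
            name=f"ig_{i:03d}", chrom=chrom, summit=summit,
            category="intergenic", gene_id=None, cpg_flag=False,
            amp_wt=base * _jitter(rng, config),
            amp_ko=base * _jitter(rng, config)))
        i += 1
    if i < n_inter:
        raise PlacementError("could not place all intergenic peaks away from "
                             "islands; annotation too crowded")

    # -- assemble -----------------------------------------------------------
    truth_peaks = pd.DataFrame(peak_rows)
    half = config.peak_half_width
    truth_peaks["start"] = truth_peaks["summit"] - half
    truth_peaks["end"] = truth_peaks["summit"] + half
    if (truth_peaks["start"] < 0).any() or any(
            truth_peaks.loc[truth_peaks["chrom"] == c, "end"].gt(length).any()
            for c, length in config.chrom_lengths.items()):
        raise PlacementError("planted peak escapes chromosome bounds")
    truth_peaks = truth_peaks.sort_values(["chrom", "start"], kind="stable",
                                          ignore_index=True)

    def build(side: str) -> PeakSet:
        col = f"amp_{side}"
        return PeakSet([
            _planted_peak(r.chrom, int(r.summit), r.name, getattr(r, col), config)
            for r in truth_peaks.itertuples() if getattr(r, col) > 0.0
        ])

    truth_genes = pd.DataFrame(dict(
        gene_id=genes["gene_id"], status=statuses,
        de_status=["null"] * n_genes))
    truth = TruthTable(genes=truth_genes, peaks=truth_peaks)
    return build("wt"), build("ko"), truth


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def _add_fragments(diff: np.ndarray, starts: np.ndarray, ext: int, step: int,
                   n_bins: int) -> None:
    """Accumulate fragment pileup via a difference array (per chromosome)."""
    b0 = np.clip(starts // step, 0, n_bins - 1)
    b1 = np.clip((starts + ext - 1) // step, 0, n_bins - 1)
    np.add.at(diff, b0, np.ones(starts.size))
    np.add.at(diff, b1 + 1, -np.ones(starts.size))


def generate_coverage_tracks(peaks: PeakSet, config: SimConfig,
                             genotype: str = "wt",
                             ) -> tuple[CoverageTrack, CoverageTrack]:
    """Treatment and input tracks for one genotype's planted landscape.

    Signal fragments (one per amplitude unit, stacked at the summit) are
    laid down first; uniform background fills the track up to
    ``reads_per_condition`` total reads. The control is uniform background
    at full depth.
    """
    if config.reads_per_condition == 0:
        raise EmptyTrackError("reads_per_condition is 0: tracks would be empty")
    rng = _rng(config.seed, f"coverage_{genotype}")
    step = config.bin_step
    ext = config.fragment_extension
    lengths = config.chrom_lengths
    n_bins = {c: int(np.ceil(length / step)) for c, length in lengths.items()}

    t_diff = {c: np.zeros(n + 1) for c, n in n_bins.items()}
    c_diff = {c: np.zeros(n + 1) for c, n in n_bins.items()}

    signal_reads = 0
    for p in peaks:
        n = int(round(p.amplitude))
        if n <= 0:
            continue
        start = np.full(n, p.summit - ext // 2)
        _add_fragments(t_diff[p.chrom], start, ext, step, n_bins[p.chrom])
        signal_reads += n

    bg_treatment = config.reads_per_condition - signal_reads
    if bg_treatment < 0:
        raise ConfigError(
            f"planted signal ({signal_reads} reads) exceeds "
            f"reads_per_condition ({config.reads_per_condition})")

    total_len = sum(lengths.values())
    props = np.array([lengths[c] / total_len for c in lengths])
    chroms = list(lengths)

    def scatter(diff: dict[str, np.ndarray], n_reads: int) -> None:
        counts = rng.multinomial(n_reads, props)
        for c, k in zip(chroms, counts):
            if k == 0:
                continue
            hi = max(1, lengths[c] - ext)
            starts = rng.integers(0, hi, size=k)
            _add_fragments(diff[c], starts, ext, step, n_bins[c])

    scatter(t_diff, bg_treatment)
    scatter(c_diff, config.reads_per_condition)

    def finalize(diff: dict[str, np.ndarray], total: int) -> CoverageTrack:
        return CoverageTrack(
            values={c: np.cumsum(d[:-1]) for c, d in diff.items()},
            step=step, total_reads=total, tag_size=49, extension=ext)

    return (finalize(t_diff, config.reads_per_condition),
            finalize(c_diff, config.reads_per_condition))


# ---------------------------------------------------------------------------
# expression table
# ---------------------------------------------------------------------------

def generate_expression_table(truth: TruthTable, config: SimConfig,
                              ) -> pd.DataFrame:
    """Partially concordant expression table; updates truth.genes.de_status.

    A ``de_concordance`` fraction of differentially enriched genes receive
    fold >= 1.5 with p < 0.01 in the direction of their enrichment; every
    other gene is null (fold ~ 1, uniform p).
    """
    rng = _rng(config.seed, "expression")
    rows = []
    de_status = []
    for r in truth.genes.itertuples():
        enriched_dir = None
        if r.status in ("unique_wt", "preferential_wt"):
            enriched_dir = "wt"
        elif r.status in ("unique_ko", "preferential_ko"):
            enriched_dir = "ko"
        if enriched_dir is not None and rng.random() < config.de_concordance:
            fold = float(math.exp(rng.uniform(math.log(1.5), math.log(4.0))))
            p = float(10.0 ** rng.uniform(-6.0, math.log10(0.0099)))
            rows.append(dict(gene=r.gene_id, fold_change=fold,
                             direction=enriched_dir, p_value=p))
            de_status.append(f"up_{enriched_dir}")
        else:
            fold = float(math.exp(abs(rng.normal(0.0, 0.05))))
            direction = "wt" if rng.random() < 0.5 else "ko"
            rows.append(dict(gene=r.gene_id, fold_change=fold,
                             direction=direction, p_value=float(rng.uniform())))
            de_status.append("null")
    truth.genes["de_status"] = de_status
    return pd.DataFrame(rows, columns=["gene", "fold_change", "direction",
                                       "p_value"])


def write_expression_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth_table(truth: TruthTable, gene_path, peak_path) -> None:
    truth.genes.to_csv(gene_path, sep="\t", index=False)
    truth.peaks.to_csv(peak_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# one-call simulation
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    config: SimConfig
    annotation: GenomeAnnotation
    peaks_wt: PeakSet
    peaks_ko: PeakSet
    truth: TruthTable
    expression: pd.DataFrame
    tracks: dict[str, tuple[CoverageTrack, CoverageTrack]] = field(
        default_factory=dict)


def simulate(config: SimConfig, with_coverage: bool = True) -> Simulation:
    """Run every generator in order and bundle the outputs."""
    annotation = generate_genome(config)
    peaks_wt, peaks_ko, truth = generate_peak_landscapes(annotation, config)
    expression = generate_expression_table(truth, config)
    tracks = {}
    if with_coverage:
        tracks["wt"] = generate_coverage_tracks(peaks_wt, config, genotype="wt")
        tracks["ko"] = generate_coverage_tracks(peaks_ko, config, genotype="ko")
    return Simulation(config=config, annotation=annotation, peaks_wt=peaks_wt,
                      peaks_ko=peaks_ko, truth=truth, expression=expression,
                      tracks=tracks)
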