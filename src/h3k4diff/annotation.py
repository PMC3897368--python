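"""Genome annotation container: chromosomes, genes, CpG islands.

The annotation is the coordinate frame for every classification rule in the
pipeline. Genes are strand-aware: the transcription start site (TSS) of a
plus-strand gene is its leftmost base, of a minus-strand gene its rightmost
base (0-based). All intervals are 0-based, half-open, BED-style.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

GENE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end"]
ISLAND_COLUMNS = ["chrom", "start", "end"]


def tss_tes(start: int, end: int, strand: str) -> tuple[int, int]:
    """Strand-aware (TSS, TES) base positions for a half-open gene interval."""
    if strand == "+":
        return start, end - 1
    return end - 1, start


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus gene and CpG-island tables.

    genes: DataFrame with columns gene_id, chrom, strand, start, end
           (tss/tes columns are derived on construction).
    cpg_islands: DataFrame with columns chrom, start, end.
    """

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    cpg_islands: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ISLAND_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise DataError(f"gene table missing columns: {missing}")
        g = self.genes.reset_index(drop=True).copy()
        if not g.empty:
            bad = g[~g["chrom"].isin(self.chrom_lengths)]
            if len(bad):
                raise DataError(
                    f"genes on unknown chromosomes: {sorted(bad['chrom'].unique())}"
                )
            if (g["start"] >= g["end"]).any():
                raise DataError("gene with start >= end")
            tss, tes = zip(*(tss_tes(s, e, st) for s, e, st in
                             zip(g["start"], g["end"], g["strand"])))
            g["tss"] = list(tss)
            g["tes"] = list(tes)
        else:
            g["tss"] = pd.Series(dtype=int)
            g["tes"] = pd.Series(dtype=int)
        self.genes = g
        self.cpg_islands = self.cpg_islands.reset_index(drop=True).copy()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == chrom]

    # -- BED serialization (genes as BED6, islands as BED3/BED6) ------------

    def genes_bed(self) -> str:
        lines = [
            f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}"
            for r in self.genes.itertuples()
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    def islands_bed(self) -> str:
        lines = [
            f"{r.chrom}\t{r.start}\t{r.end}\tCpG_{i}\t0\t."
            for i, r in enumerate(self.cpg_islands.itertuples())
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    def write_genes_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.genes_bed())

    def write_islands_bed(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.islands_bed())


def read_genes_bed(path, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Read a BED6 gene table (name column = gene id)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{ln}: expected >=6 BED columns")
            rows.append(
                dict(gene_id=parts[3], chrom=parts[0], strand=parts[5],
                     start=int(parts[1]), end=int(parts[2]))
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def read_intervals_bed(path) -> pd.DataFrame:
    """Read a BED file down to chrom/start/end (e.g. CpG islands)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            rows.append(dict(chrom=parts[0], start=int(parts[1]), end=int(parts[2])))
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Base-resolution distance between two half-open intervals.

    0 when they overlap; otherwise the number of bases separating the
    closest covered bases plus... precisely: distance between nearest
    covered base positions. Adjacent intervals ([0,10),[10,20)) are 1 apart.
    """
    if a_start < b_end and b_start < a_end:
        return 0
    if a_end <= b_start:
        return b_start - (a_end - 1)
    return a_start - (b_end - 1)


def point_interval_distance(p: int, start: int, end: int) -> int:
    """Distance from base position p to the nearest covered base of [start, end)."""
    if start <= p < end:
        return 0
    if p < start:
        return start - p
    return p - (end - 1)


def genome_chrom_array(chrom_lengths: dict[str, int], step: int) -> dict[str, int]:
    """Number of fixed-step bins fully or partly covering each chromosome."""
    return {c: int(np.ceil(length / step)) for c, length in chrom_lengths.items()}
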