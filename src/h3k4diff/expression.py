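"""Integration of differential H3K4Me3 enrichment with expression data.

The expression input is a precomputed per-gene table of fold change
(ratio > 0), direction (which genotype is higher) and p-value, e.g. from a
published microarray contrast. A gene is differentially expressed (DE)
toward a genotype when fold_change >= 1.5 (inclusive) and p < 0.01
(strict). DE sets are then intersected with the enrichment sets per
genotype, direction-matched: a gene counts only when its
higher-expression genotype equals its enrichment genotype.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .differential import DifferentialCall, round_half_up_pct
from .errors import DataError, UndefinedStatisticError

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["gene", "fold_change", "direction", "p_value"]
GENOTYPES = ("wt", "ko")


def read_expression_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"expression table missing columns: {missing}")
    return table


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    dupes = table["gene"][table["gene"].duplicated()].unique().tolist()
    if dupes:
        raise DataError(f"duplicate gene ids in expression table: {dupes}")
    if (table["fold_change"] <= 0).any():
        raise DataError("fold_change must be a positive ratio")
    if ((table["p_value"] < 0) | (table["p_value"] > 1)).any():
        raise DataError("p_value outside [0, 1]")
    bad_dir = set(table["direction"]) - set(GENOTYPES)
    if bad_dir:
        raise DataError(f"unknown direction labels: {sorted(bad_dir)}")
    return table


def call_differential_expression(table: pd.DataFrame, fold_min: float = 1.5,
                                 p_max: float = 0.01,
                                 ) -> tuple[set[str], set[str]]:
    """(DE_wt, DE_ko): genes passing fold >= fold_min and p < p_max."""
    table = validate_expression_table(table)
    passing = table[(table["fold_change"] >= fold_min)
                    & (table["p_value"] < p_max)]
    de_wt = set(passing.loc[passing["direction"] == "wt", "gene"])
    de_ko = set(passing.loc[passing["direction"] == "ko", "gene"])
    return de_wt, de_ko


@dataclass(frozen=True)
class OverlapReport:
    """DE / enrichment overlap per genotype at one tier."""

    tier: str
    de_wt: int
    de_ko: int
    enriched_wt: int
    enriched_ko: int
    overlap_wt: int
    overlap_ko: int

    @property
    def overlap_pct_wt(self) -> float:
        return round_half_up_pct(self.overlap_wt, self.de_wt)

    @property
    def overlap_pct_ko(self) -> float:
        return round_half_up_pct(self.overlap_ko, self.de_ko)

    def to_dict(self) -> dict:
        return dict(tier=self.tier, de_wt=self.de_wt, de_ko=self.de_ko,
                    enriched_wt=self.enriched_wt, enriched_ko=self.enriched_ko,
                    overlap_wt=self.overlap_wt, overlap_ko=self.overlap_ko,
                    overlap_pct_wt=self.overlap_pct_wt,
                    overlap_pct_ko=self.overlap_pct_ko)


def enrichment_sets(differential: dict[str, DifferentialCall], tier: str,
                    ) -> tuple[set[str], set[str]]:
    """Per-genotype gene sets at a tier: unique_only or unique_plus_preferential."""
    if tier not in ("unique_only", "unique_plus_preferential"):
        raise DataError(f"unknown tier: {tier}")
    statuses_wt = {"unique_wt"}
    statuses_ko = {"unique_ko"}
    if tier == "unique_plus_preferential":
        statuses_wt.add("preferential_wt")
        statuses_ko.add("preferential_ko")
    wt = {g for g, c in differential.items() if c.status in statuses_wt}
    ko = {g for g, c in differential.items() if c.status in statuses_ko}
    return wt, ko


def intersect_enrichment_expression(de_sets: tuple[set[str], set[str]],
                                    differential: dict[str, DifferentialCall],
                                    tier: str = "unique_plus_preferential",
                                    ) -> OverlapReport:
    de_wt, de_ko = de_sets
    if not de_wt or not de_ko:
        raise UndefinedStatisticError("empty DE set: overlap percentage undefined")
    enr_wt, enr_ko = enrichment_sets(differential, tier)
    only_expr = (de_wt | de_ko) - set(differential)
    if only_expr:
        logger.info("%d DE genes absent from the enrichment universe",
                    len(only_expr))
    return OverlapReport(
        tier=tier, de_wt=len(de_wt), de_ko=len(de_ko),
        enriched_wt=len(enr_wt), enriched_ko=len(enr_ko),
        overlap_wt=len(de_wt & enr_wt), overlap_ko=len(de_ko & enr_ko),
    )


def audit_overlap(overlap: int, de_total: int) -> float:
    """Recompute a printed overlap percentage from printed counts."""
    return round_half_up_pct(overlap, de_total)


def export_gene_lists(differential: dict[str, DifferentialCall],
                      de_sets: tuple[set[str], set[str]], outdir) -> dict:
    """Write one sorted, deduplicated gene list per category plus a manifest.

    Replaces proprietary pathway-tool input preparation with plain text.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lists: dict[str, set[str]] = {
        "unique_wt": set(), "unique_ko": set(),
        "preferential_wt": set(), "preferential_ko": set(),
    }
    for gid, call in differential.items():
        if call.status in lists:
            lists[call.status].add(gid)
    de_wt, de_ko = de_sets
    lists["de_wt"] = set(de_wt)
    lists["de_ko"] = set(de_ko)
    manifest = {}
    for name, genes in lists.items():
        path = outdir / f"{name}.txt"
        with open(path, "w") as fh:
            for g in sorted(genes):
                fh.write(f"{g}\n")
        manifest[name] = len(genes)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
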