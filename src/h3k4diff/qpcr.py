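"""Bench-validation arithmetic: ChIP-qPCR percent of input, qRT-PCR
relative expression (delta-delta-Ct), and two-group comparisons with
Bonferroni correction.

Percent of input corrects the input Ct for the chromatin dilution used as
input before comparing against the ChIP (or IgG) Ct:

    adjusted_input_Ct = mean(Ct_input) - log_E(1 / input_fraction)
    percent          = 100 * E ** (adjusted_input_Ct - mean(Ct_chip))

with E the per-cycle amplification efficiency (2.0 = perfect doubling).
The input fraction is a mandatory, explicit parameter: defaulting it to 1
would silently inflate every recovery by the dilution factor.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError, DegenerateDataError

EXACT_MW_MAX_N = 12  # combined sample size up to which the exact permutation
                     # null is enumerated; the normal approximation is used above


@dataclass
class QPCRMeasurement:
    """Replicate Ct values for one target in one condition."""

    target: str
    condition: str
    ct_chip: Sequence[float]
    ct_input: Sequence[float]
    ct_igg: Sequence[float] = field(default_factory=list)
    input_fraction: float | None = None
    amplification_efficiency: float = 2.0

    def __post_init__(self) -> None:
        for name, cts in (("chip", self.ct_chip), ("input", self.ct_input),
                          ("igg", self.ct_igg)):
            if any(c <= 0 for c in cts):
                raise DataError(f"non-positive Ct in {name} channel")
        if not self.ct_chip or not self.ct_input:
            raise DataError("need >= 1 replicate per channel")
        if not 1.0 < self.amplification_efficiency <= 2.2:
            raise ConfigError("amplification efficiency must lie in (1, 2.2]")


def percent_of_input(m: QPCRMeasurement) -> dict[str, float]:
    """Percent of input for the ChIP channel and, when present, IgG.

    IgG is reported alongside the ChIP signal, never subtracted from it.
    """
    if m.input_fraction is None:
        raise ConfigError(
            "input_fraction is required: the percent-of-input correction "
            "cannot silently assume undiluted input")
    if not 0.0 < m.input_fraction <= 1.0:
        raise ConfigError("input_fraction must lie in (0, 1]")
    eff = m.amplification_efficiency
    adjusted_input = float(np.mean(m.ct_input)) - math.log(1.0 / m.input_fraction,
                                                           eff)
    out = {"chip": 100.0 * eff ** (adjusted_input - float(np.mean(m.ct_chip)))}
    if m.ct_igg:
        out["igg"] = 100.0 * eff ** (adjusted_input - float(np.mean(m.ct_igg)))
    return out


def relative_expression(ct_target: dict[str, Sequence[float]],
                        ct_reference: dict[str, Sequence[float]],
                        calibrator: str, efficiency: float = 2.0,
                        ) -> dict[str, float]:
    """Delta-delta-Ct fold changes per sample against a calibrator sample.

    ct_target / ct_reference map sample label -> replicate Cts for the
    gene of interest and the reference gene. The calibrator's fold change
    is 1 by construction.
    """
    if calibrator not in ct_target:
        raise DataError(f"calibrator sample {calibrator!r} missing from targets")
    missing = [s for s in ct_target if s not in ct_reference]
    if missing:
        raise DataError(f"reference gene Cts missing for samples: {missing}")
    dct = {s: float(np.mean(ct_target[s])) - float(np.mean(ct_reference[s]))
           for s in ct_target}
    dct_cal = dct[calibrator]
    return {s: efficiency ** (dct_cal - d) for s, d in dct.items()}


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def bonferroni(p: float, n_comparisons: int) -> float:
    if n_comparisons < 1:
        raise ConfigError("n_comparisons must be >= 1")
    return min(1.0, p * n_comparisons)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with the tie convention (0.5 per tie)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact permutation p-value of the Mann-Whitney U statistic.

    All C(n1+n2, n1) relabelings are enumerated, so the p-value is exact
    under the permutation null even in the presence of ties. The two-sided
    p is the permutation fraction with |U - n1*n2/2| at least as large as
    observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both groups need >= 1 observation for the rank test")
    pooled = np.concatenate([x, y])
    n1 = x.size
    mu = n1 * y.size / 2.0
    observed = abs(_u_statistic(x, y) - mu)
    total = hits = 0
    idx = range(pooled.size)
    for combo in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(combo)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mu) >= observed - 1e-12:
            hits += 1
    return hits / total


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact permutation p for small samples, normal approximation above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size + y.size <= EXACT_MW_MAX_N:
        return mann_whitney_exact(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic")
    return float(res.pvalue)


def welch_t(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("t tests need >= 2 observations per group")
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        raise DegenerateDataError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


TESTS = {
    "mann_whitney": mann_whitney,
    # both published t-test labels resolve to the two-tailed unpaired Welch test
    "t_two_tailed": welch_t,
    "t_unpaired": welch_t,
}


@dataclass
class GroupComparison:
    group_a: Sequence[float]
    group_b: Sequence[float]
    test: str = "mann_whitney"
    n_comparisons: int = 1

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ConfigError(f"unknown test {self.test!r}; "
                              f"choose from {sorted(TESTS)}")
        if self.n_comparisons < 1:
            raise ConfigError("n_comparisons must be >= 1")


def compare_groups(c: GroupComparison) -> tuple[float, float]:
    """(raw p, Bonferroni-adjusted p) for one comparison."""
    raw = TESTS[c.test](c.group_a, c.group_b)
    return raw, bonferroni(raw, c.n_comparisons)
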