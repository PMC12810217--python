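"""Group statistics and the dynapenia decomposition.

Summary-statistic group comparisons (pooled-SD Cohen's d, two-sample
t-tests from means/SDs/ns, Bonferroni correction), peak-power versus
muscle-volume regression with an ANCOVA-style between-age slope test, and
the decomposition of the age-related power decline (dynapenia) into

* sarcopenia    — power lost with the missing muscle volume,
* myosteatosis  — power lost to the extra intramuscular lipid volume,
* sarcosthenia  — the volume-invariant remainder (intrinsic weakness),

using a power-per-volume slope in W/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    """Degenerate input to a statistical routine."""


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD summary of one variable in one group."""

    variable: str
    group: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise StatsError("negative SD")
        if self.n < 2:
            raise StatsError("group size must be >= 2")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of peak power (kW) on muscle volume (ml)."""

    intercept_kw: float
    slope_w_per_ml: float
    pearson_r: float
    n: int
    residual_sd_kw: float
    p_value: float

    def __post_init__(self):
        if abs(self.pearson_r) > 1 + 1e-12:
            raise StatsError("|r| > 1")
        if self.n < 3:
            raise StatsError("regression needs n >= 3")


@dataclass(frozen=True)
class CompositeMeans:
    """Group means of the jumping-muscle composite needed for decomposition."""

    volume_ml: float
    lean_volume_ml: float
    peak_power_kw: float

    def __post_init__(self):
        if self.lean_volume_ml > self.volume_ml + 1e-9:
            raise StatsError("lean volume exceeds volume")

    @property
    def lipid_volume_ml(self) -> float:
        return self.volume_ml - self.lean_volume_ml


@dataclass(frozen=True)
class DynapeniaDecomposition:
    """Additive split of the age-related power decline (W).

    sarcopenia_w + myosteatosis_w + sarcosthenia_w == total_decline_w by
    construction (sarcosthenia is the remainder; equality is exact up to
    floating-point re-association).
    """

    sarcopenia_w: float
    myosteatosis_w: float
    sarcosthenia_w: float
    total_decline_w: float
    volume_deficit_ml: float
    lipid_increase_ml: float
    pct_explained_sarcopenia_myosteatosis: float
    pct_sarcosthenia: float
    negative_total: bool = False

    def as_dict(self) -> dict:
        return {
            "sarcopenia_w": self.sarcopenia_w,
            "myosteatosis_w": self.myosteatosis_w,
            "sarcosthenia_w": self.sarcosthenia_w,
            "total_decline_w": self.total_decline_w,
            "volume_deficit_ml": self.volume_deficit_ml,
            "lipid_increase_ml": self.lipid_increase_ml,
            "pct_explained_sarcopenia_myosteatosis": self.pct_explained_sarcopenia_myosteatosis,
            "pct_sarcosthenia": self.pct_sarcosthenia,
            "negative_total": self.negative_total,
        }


def pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    """Common standard deviation of two groups (pooled, df-weighted)."""
    num = (a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2
    return math.sqrt(num / (a.n + b.n - 2))


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Effect size: difference in averages over the common (pooled) SD.

    No small-sample (Hedges) correction is applied.
    """
    sp = pooled_sd(a, b)
    if sp == 0:
        raise StatsError("pooled SD is zero")
    return (a.mean - b.mean) / sp


def two_sample_test(
    a: GroupSummary, b: GroupSummary, pooled: bool = True
) -> tuple[float, float]:
    """Two-sided t-test from summary statistics; returns (t, p).

    ``pooled=True`` assumes equal variances (Student); ``False`` uses Welch.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, 1.0
        raise StatsError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled
    )
    return float(t), float(p)


def bonferroni(p_values: Sequence[float] | float, m: int | None = None) -> np.ndarray | float:
    """Bonferroni adjustment p_adj = min(1, m * p).

    ``m`` defaults to the number of p-values supplied; it must be at least
    that number.
    """
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p < 0) | (p > 1)).any():
        raise StatsError("p-values outside [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise StatsError("m smaller than the number of p-values")
    adj = np.minimum(1.0, m * p)
    return float(adj[0]) if scalar else adj


def power_volume_regression(
    volumes_ml: Sequence[float], powers_kw: Sequence[float]
) -> RegressionFit:
    """OLS of jump peak power (kW) on summed jumping-muscle volume (ml).

    The slope is reported in W/ml (kW/ml x 1000) with Pearson's r attached.
    """
    v = np.asarray(volumes_ml, dtype=float)
    p = np.asarray(powers_kw, dtype=float)
    if len(v) != len(p):
        raise StatsError("volume and power lengths differ")
    if len(v) < 3:
        raise StatsError("regression needs n >= 3")
    if (v <= 0).any():
        raise StatsError("volumes must be positive")
    if np.ptp(v) == 0:
        raise StatsError("zero volume variance")
    res = sps.linregress(v, p)
    resid = p - (res.intercept + res.slope * v)
    ddof = min(2, len(v) - 1)
    return RegressionFit(
        intercept_kw=float(res.intercept),
        slope_w_per_ml=float(res.slope * 1000.0),
        pearson_r=float(res.rvalue),
        n=len(v),
        residual_sd_kw=float(np.sqrt((resid**2).sum() / (len(v) - ddof))),
        p_value=float(res.pvalue),
    )


def slope_difference_test(
    volumes_young: Sequence[float],
    powers_young: Sequence[float],
    volumes_old: Sequence[float],
    powers_old: Sequence[float],
) -> tuple[float, float]:
    """ANCOVA-style test of unequal power-volume slopes between age groups.

    Fits the combined linear model with group intercepts and compares the
    common-slope model against the separate-slopes model (group x volume
    interaction) with an F-test; returns (F, p).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    vy, py = np.asarray(volumes_young, float), np.asarray(powers_young, float)
    vo, po = np.asarray(volumes_old, float), np.asarray(powers_old, float)
    if len(vy) < 3 or len(vo) < 3:
        raise StatsError("each group needs n >= 3")
    if np.ptp(vy) == 0 or np.ptp(vo) == 0:
        raise StatsError("degenerate design: zero volume variance in a group")
    df = pd.DataFrame(
        {
            "volume": np.concatenate([vy, vo]),
            "power": np.concatenate([py, po]),
            "age": ["young"] * len(vy) + ["old"] * len(vo),
        }
    )
    reduced = smf.ols("power ~ volume + C(age)", data=df).fit()
    full = smf.ols("power ~ volume * C(age)", data=df).fit()
    tab = anova_lm(reduced, full)
    return float(tab["F"].iloc[1]), float(tab["Pr(>F)"].iloc[1])


def dynapenia_decomposition(
    young: CompositeMeans, old: CompositeMeans, slope_w_per_ml: float
) -> DynapeniaDecomposition:
    """Split the old-vs-young power decline into its three components.

    * sarcopenia   = (V_young - V_old) x slope          [volume deficit]
    * myosteatosis = (lipid_old - lipid_young) x slope  [extra lipid volume]
    * sarcosthenia = total decline - sarcopenia - myosteatosis

    with total decline = (P_young - P_old) x 1000 W and lipid volume =
    volume - lean volume per age group.  A negative total is computed as-is
    but flagged.
    """
    if slope_w_per_ml <= 0:
        raise StatsError("slope must be positive")
    volume_deficit = young.volume_ml - old.volume_ml
    lipid_increase = old.lipid_volume_ml - young.lipid_volume_ml
    sarcopenia = volume_deficit * slope_w_per_ml
    myosteatosis = lipid_increase * slope_w_per_ml
    total = (young.peak_power_kw - old.peak_power_kw) * 1000.0
    sarcosthenia = total - sarcopenia - myosteatosis
    if total != 0:
        pct_explained = 100.0 * (sarcopenia + myosteatosis) / total
        pct_sarcosthenia = 100.0 * sarcosthenia / total
    else:
        pct_explained = float("nan")
        pct_sarcosthenia = float("nan")
    return DynapeniaDecomposition(
        sarcopenia_w=sarcopenia,
        myosteatosis_w=myosteatosis,
        sarcosthenia_w=sarcosthenia,
        total_decline_w=total,
        volume_deficit_ml=volume_deficit,
        lipid_increase_ml=lipid_increase,
        pct_explained_sarcopenia_myosteatosis=pct_explained,
        pct_sarcosthenia=pct_sarcosthenia,
        negative_total=bool(total < 0),
    )


def percent_difference(value: float, reference: float) -> float:
    """Percent difference of ``value`` relative to an explicit basis group."""
    if reference == 0:
        raise StatsError("zero reference for percent difference")
    return 100.0 * (value - reference) / reference
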