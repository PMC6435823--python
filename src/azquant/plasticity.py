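"""Homeostatic-plasticity analyses of per-AZ channel intensities.

Paired before/after single-AZ analysis for acute potentiation: vehicle
correction (ratio of vehicle-group after/before means), a normality-gated
paired test, discrimination between additive (y = x + c) and multiplicative
(y = m*x) scaling of channel content by residual sum of squares, and a
tercile analysis of where non-increases concentrate. Population (unpaired)
comparisons of per-NMJ mean intensities cover the chronic paradigms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import is_normal, unpaired_test

__all__ = [
    "CorrectedTable",
    "ScalingFit",
    "TercileReport",
    "PopulationComparison",
    "vehicle_correct",
    "paired_change_test",
    "fit_scaling_models",
    "tercile_change_analysis",
    "population_compare",
    "ecdf",
]


@dataclass(frozen=True)
class CorrectedTable:
    """Vehicle-corrected paired intensities.

    ``table`` columns: ``punctum_id, baseline, after_raw, after_corrected,
    delta`` with ``delta = after_corrected - baseline``.
    """

    table: pd.DataFrame
    vehicle_factor: float


@dataclass(frozen=True)
class ScalingFit:
    """Additive-vs-multiplicative scaling discrimination.

    Both candidate models have one free parameter, so the lower residual
    sum of squares selects the model directly; AIC is reported for
    transparency. ``selected_model`` is ``indistinguishable`` when the RSS
    difference is within ``rel_tol`` of the smaller RSS.
    """

    free_slope: float
    free_intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    additive_c: float
    rss_add: float
    multiplicative_m: float
    rss_mult: float
    selected_model: str
    aic_add: float
    aic_mult: float
    n: int

    def to_dict(self) -> dict:
        return {
            "free_slope": self.free_slope,
            "free_intercept": self.free_intercept,
            "r_squared": self.r_squared,
            "slope_ci": list(self.slope_ci),
            "additive_c": self.additive_c,
            "rss_add": self.rss_add,
            "multiplicative_m": self.multiplicative_m,
            "rss_mult": self.rss_mult,
            "selected_model": self.selected_model,
            "aic_add": self.aic_add,
            "aic_mult": self.aic_mult,
            "n": self.n,
        }


@dataclass(frozen=True)
class TercileReport:
    """Change frequency by baseline tercile.

    ``table`` columns: ``tercile, n, n_le0, prop_le0`` for the bottom,
    middle, and top thirds of baseline intensity; ``pvalues`` holds the
    three pairwise two-sided Fisher exact p-values on (<=0 vs >0) counts.
    """

    table: pd.DataFrame
    pvalues: dict


@dataclass(frozen=True)
class PopulationComparison:
    """Normalized group summaries and pairwise tests against a control."""

    summary: pd.DataFrame  # group, n, mean_norm, sem_norm
    tests: pd.DataFrame  # group, test_name, statistic, p
    control: str
    control_mean: float


def vehicle_correct(treated: pd.DataFrame, vehicle: pd.DataFrame) -> CorrectedTable:
    """Correct treated after-values for vehicle-only effects.

    The correction factor is the mean over vehicle puncta of
    ``after_raw / baseline``; treated ``after_corrected = after_raw / f``.
    """
    if len(vehicle) == 0:
        raise ValueError("vehicle table is empty")
    vb = vehicle["baseline"].to_numpy(float)
    if np.any(vb <= 0):
        raise ValueError("vehicle baselines must be > 0")
    f = float(np.mean(vehicle["after_raw"].to_numpy(float) / vb))
    out = treated.copy()
    out["after_corrected"] = out["after_raw"] / f
    out["delta"] = out["after_corrected"] - out["baseline"]
    return CorrectedTable(table=out, vehicle_factor=f)


def _deltas(table: pd.DataFrame) -> np.ndarray:
    if "delta" in table.columns:
        return table["delta"].to_numpy(float)
    y = table["after_corrected"] if "after_corrected" in table.columns else table["after_raw"]
    return (y - table["baseline"]).to_numpy(float)


def paired_change_test(
    table: pd.DataFrame,
    normality_alpha: float = 0.05,
) -> dict:
    """Paired test of the before/after change.

    A D'Agostino-Pearson normality gate on the deltas selects a paired t
    test (normal) or the Wilcoxon signed-rank test (non-normal); both
    two-sided. All-zero deltas return the degenerate ``p = 1`` path.
    """
    d = _deltas(table)
    if len(d) < 6:
        raise ValueError("paired test requires at least 6 pairs")
    if np.all(d == 0):
        return {"test_name": "degenerate", "statistic": float("nan"), "p": 1.0}
    if is_normal(d, normality_alpha):
        y = table["after_corrected"] if "after_corrected" in table.columns else table["after_raw"]
        t, p = stats.ttest_rel(y.to_numpy(float), table["baseline"].to_numpy(float))
        return {"test_name": "paired_t", "statistic": float(t), "p": float(p)}
    w, p = stats.wilcoxon(d)
    return {"test_name": "wilcoxon", "statistic": float(w), "p": float(p)}


def fit_scaling_models(
    table: pd.DataFrame,
    rel_tol: float = 0.05,
    use_corrected: bool = True,
) -> ScalingFit:
    """Fit and compare additive and multiplicative scaling models.

    Given baselines x and after-values y: the unconstrained OLS line gives
    ``free_slope/free_intercept/r_squared``; the additive model ``y = x + c``
    has the closed form ``c = mean(y - x)``; the multiplicative model
    ``y = m*x`` has ``m = sum(xy)/sum(x^2)``. Both have one parameter, so
    the smaller RSS selects the model; within ``rel_tol`` relative
    difference (or both zero) the result is ``indistinguishable``.
    """
    x = table["baseline"].to_numpy(float)
    ycol = "after_corrected" if use_corrected and "after_corrected" in table.columns else "after_raw"
    y = table[ycol].to_numpy(float)
    n = len(x)
    if n < 3:
        raise ValueError("scaling fit requires at least 3 puncta")
    if np.std(x) == 0:
        raise ValueError("zero baseline variance")

    res = stats.linregress(x, y)
    free_slope, free_intercept = float(res.slope), float(res.intercept)
    r_squared = float(res.rvalue**2)

    # 95% CI on the free slope with an HC3 heteroscedasticity-robust SE:
    # fluorescence noise scales with intensity, so homoscedastic OLS errors
    # would understate the slope variance
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    resid = y - (free_slope * x + free_intercept)
    h = 1.0 / n + xc**2 / sxx
    se_slope = float(np.sqrt(np.sum((xc * resid / (1.0 - h)) ** 2)) / sxx)
    tcrit = float(stats.t.ppf(0.975, n - 2))
    slope_ci = (free_slope - tcrit * se_slope, free_slope + tcrit * se_slope)

    c = float(np.mean(y - x))
    rss_add = float(np.sum((y - (x + c)) ** 2))
    m = float(np.sum(x * y) / np.sum(x * x))
    rss_mult = float(np.sum((y - m * x) ** 2))

    def _aic(rss: float) -> float:
        # Gaussian log-likelihood up to a constant; k = 1 parameter
        if rss <= 0:
            return float("-inf")
        return n * np.log(rss / n) + 2.0

    if rss_add == 0 and rss_mult == 0:
        selected = "indistinguishable"
    elif abs(rss_add - rss_mult) <= rel_tol * min(rss_add, rss_mult):
        selected = "indistinguishable"
    else:
        selected = "additive" if rss_add < rss_mult else "multiplicative"

    return ScalingFit(
        free_slope=free_slope,
        free_intercept=free_intercept,
        r_squared=r_squared,
        slope_ci=slope_ci,
        additive_c=c,
        rss_add=rss_add,
        multiplicative_m=m,
        rss_mult=rss_mult,
        selected_model=selected,
        aic_add=_aic(rss_add),
        aic_mult=_aic(rss_mult),
        n=n,
    )


def tercile_change_analysis(table: pd.DataFrame) -> TercileReport:
    """Frequency of no-change-or-decrease (delta <= 0) by baseline tercile.

    Puncta are ranked by baseline (stable sort, ties keep input order) and
    split into three rank groups whose sizes differ by at most one. All
    three pairwise comparisons use two-sided Fisher exact tests on the
    2x2 (<=0 vs >0) count tables.
    """
    n = len(table)
    if n < 9:
        raise ValueError("tercile analysis requires at least 9 puncta")
    d = _deltas(table)
    order = np.argsort(table["baseline"].to_numpy(float), kind="stable")
    groups = np.array_split(order, 3)
    names = ["bottom", "middle", "top"]
    rows = []
    le0 = []
    for name, idx in zip(names, groups):
        k = int(np.sum(d[idx] <= 0))
        rows.append({"tercile": name, "n": len(idx), "n_le0": k, "prop_le0": k / len(idx)})
        le0.append((k, len(idx)))
    pvalues = {}
    for i in range(3):
        for j in range(i + 1, 3):
            (k1, n1), (k2, n2) = le0[i], le0[j]
            _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
            pvalues[(names[i], names[j])] = float(p)
    return TercileReport(table=pd.DataFrame(rows), pvalues=pvalues)


def population_compare(
    groups: Mapping[str, np.ndarray],
    normalize_to: str,
    alpha: float = 0.05,
) -> PopulationComparison:
    """Compare named groups of per-NMJ mean punctum intensities.

    Every value is divided by the control group's mean; each non-control
    group is tested against control with the normality/variance-gated
    Student / Welch / Mann-Whitney choice. Groups must hold >= 3 NMJs.
    """
    if normalize_to not in groups:
        raise ValueError(f"unknown normalize_to group: {normalize_to!r}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(np.asarray(vals)) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 NMJs")
    control = np.asarray(groups[normalize_to], dtype=float)
    cmean = float(control.mean())
    if cmean == 0:
        raise ValueError("control mean is zero")
    srows, trows = [], []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float) / cmean
        srows.append(
            {
                "group": name,
                "n": len(v),
                "mean_norm": float(v.mean()),
                "sem_norm": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan"),
            }
        )
        if name != normalize_to:
            test, statistic, p = unpaired_test(np.asarray(vals, float), control, alpha)
            trows.append({"group": name, "test_name": test, "statistic": statistic, "p": p})
    return PopulationComparison(
        summary=pd.DataFrame(srows),
        tests=pd.DataFrame(trows, columns=["group", "test_name", "statistic", "p"]),
        control=normalize_to,
        control_mean=cmean,
    )


def ecdf(values: np.ndarray) -> pd.DataFrame:
    """Empirical cumulative distribution, for per-AZ intensity plots."""
    x = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"value": x, "cumulative_prob": np.arange(1, len(x) + 1) / len(x)})
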