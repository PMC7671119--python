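"""Method-evaluation statistics for external-marker strain tracking.

External (skin-mounted) marker strain is validated against a reference
method that tracks markers inside the muscle (fluoromicrometry).  For each
paired trial, external strain is regressed on internal strain by ordinary
least squares; the slope against the ideal slope of 1 measures accuracy
(skin slip attenuates external strain multiplicatively, so slopes below 1
mean underestimation), and the RMSE of the residuals measures precision on
the strain scale.  Per-trial statistics are pooled as means with standard
errors, individuals are compared with a one-way ANOVA, and peak kinematic
excursions are correlated against neurocranial elevation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .strain import StrainSeries

__all__ = [
    "RegressionResult",
    "ValidationReport",
    "GroupSummary",
    "compare_strain_methods",
    "pool_mean_of_means",
    "pool_validation_trials",
    "anova_oneway",
    "correlate_peaks",
]


@dataclass
class RegressionResult:
    """OLS of external strain on internal strain for one paired trial."""

    slope: float
    intercept: float
    rmse_pct: float  # residual RMSE on the strain scale (% strain)
    accuracy: float  # slope / ideal slope of 1
    n_frames: int


@dataclass
class ValidationReport:
    """Pooled accuracy/precision of the external-marker method."""

    per_trial: pd.DataFrame  # columns: slope, intercept, rmse_pct, accuracy
    mean_accuracy: float
    sem_accuracy: float
    mean_rmse_pct: float
    sem_rmse_pct: float
    underestimation_margin_pct: float  # 100 * (1 - mean accuracy)
    n_trials: int


@dataclass
class GroupSummary:
    """Per-group means with a mean-of-means grand summary and ANOVA."""

    group_means: np.ndarray
    group_sems: np.ndarray
    group_ns: np.ndarray
    grand_mean: float  # unweighted mean of group means
    grand_sem: float  # SEM across group means (NaN for a single group)
    pooled_mean: float  # mean across all values, groups merged
    pooled_sem: float
    anova_F: float
    anova_p: float


def _series_values(s: StrainSeries | np.ndarray) -> np.ndarray:
    return s.strain_pct if isinstance(s, StrainSeries) else np.asarray(s, dtype=float)


def compare_strain_methods(
    external: StrainSeries | np.ndarray,
    internal: StrainSeries | np.ndarray,
    fit_intercept: bool = True,
) -> RegressionResult:
    """Regress external on internal strain for one frame-aligned trial.

    Both series must cover the same frames (no time warping or lag
    estimation — the methods are synchronized by the shared video clock).
    Requires >= 10 jointly finite frames and non-degenerate internal
    variance.
    """
    ext = _series_values(external)
    ref = _series_values(internal)
    if ext.shape != ref.shape:
        raise ValueError("external and internal series must share frames")
    ok = np.isfinite(ext) & np.isfinite(ref)
    if ok.sum() < 10:
        raise ValueError("need >= 10 jointly finite frames for regression")
    x, y = ref[ok], ext[ok]
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ValueError("internal strain has zero variance; slope undefined")
    if fit_intercept:
        slope, intercept = np.polyfit(x, y, 1)
    else:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    resid = y - (slope * x + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        rmse_pct=rmse,
        accuracy=float(slope) / 1.0,
        n_frames=int(ok.sum()),
    )


def pool_validation_trials(results: Sequence[RegressionResult]) -> ValidationReport:
    """Pool per-trial regressions into mean accuracy and precision +/- SEM.

    Accuracy is pooled as the mean of per-trial slope ratios (not one
    regression over concatenated trials), matching how method accuracy is
    conventionally reported for repeated strikes.
    """
    if len(results) < 1:
        raise ValueError("need at least one paired trial")
    df = pd.DataFrame(
        {
            "slope": [r.slope for r in results],
            "intercept": [r.intercept for r in results],
            "rmse_pct": [r.rmse_pct for r in results],
            "accuracy": [r.accuracy for r in results],
            "n_frames": [r.n_frames for r in results],
        }
    )
    n = len(df)
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    mean_acc = float(df["accuracy"].mean())
    return ValidationReport(
        per_trial=df,
        mean_accuracy=mean_acc,
        sem_accuracy=sem(df["accuracy"]),
        mean_rmse_pct=float(df["rmse_pct"].mean()),
        sem_rmse_pct=sem(df["rmse_pct"]),
        underestimation_margin_pct=100.0 * (1.0 - mean_acc),
        n_trials=n,
    )


def pool_mean_of_means(
    values_by_group: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> GroupSummary:
    """Summarize per-individual values, robust to individual differences.

    When individuals differ significantly, per-trial values cannot simply
    be pooled; the grand mean is then the unweighted mean of per-individual
    means with its SEM taken across individuals ("mean of means").  The
    plain pooled-across-trials mean +/- SEM is also returned for the
    homogeneous case.  A one-way ANOVA across groups (when every group has
    >= 2 values) accompanies the summary to guide which pooling applies.
    """
    if isinstance(values_by_group, Mapping):
        groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_group]
    groups = [g for g in groups if g.size > 0]
    if not groups:
        raise ValueError("no group values supplied")
    means = np.array([g.mean() for g in groups])
    sems = np.array(
        [g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else np.nan for g in groups]
    )
    ns = np.array([len(g) for g in groups])
    k = len(groups)
    grand_mean = float(means.mean())
    grand_sem = float(means.std(ddof=1) / np.sqrt(k)) if k > 1 else float("nan")
    allv = np.concatenate(groups)
    pooled_mean = float(allv.mean())
    pooled_sem = (
        float(allv.std(ddof=1) / np.sqrt(len(allv))) if len(allv) > 1 else float("nan")
    )
    if k >= 2 and all(len(g) >= 2 for g in groups):
        F, p = anova_oneway(groups)
    else:
        F, p = float("nan"), float("nan")
    return GroupSummary(
        group_means=means,
        group_sems=sems,
        group_ns=ns,
        grand_mean=grand_mean,
        grand_sem=grand_sem,
        pooled_mean=pooled_mean,
        pooled_sem=pooled_sem,
        anova_F=F,
        anova_p=p,
    )


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: F statistic and upper-tail p.

    Requires >= 2 groups with >= 2 values each (so the error degrees of
    freedom are positive).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in arrs):
        raise ValueError("every group needs >= 2 values")
    n_total = sum(len(g) for g in arrs)
    if n_total - len(arrs) < 1:
        raise ValueError("degenerate error degrees of freedom")
    F, p = stats.f_oneway(*arrs)
    return float(F), float(p)


def correlate_peaks(
    elevation_peaks: Sequence[float],
    excursion_peaks: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Pearson correlation of each peak-excursion variable vs elevation.

    One row per excursion variable with r and the two-sided p value;
    requires >= 3 paired trials and non-zero variance in both variables.
    """
    elev = np.asarray(elevation_peaks, dtype=float)
    if len(elev) < 3:
        raise ValueError("need >= 3 paired trials")
    rows = []
    for name, vals in excursion_peaks.items():
        y = np.asarray(vals, dtype=float)
        if y.shape != elev.shape:
            raise ValueError(f"{name!r}: peak count mismatch")
        if np.var(elev) == 0 or np.var(y) == 0:
            raise ValueError(f"{name!r}: zero variance; correlation undefined")
        r, p = stats.pearsonr(elev, y)
        rows.append((name, float(r), float(p), len(elev)))
    return pd.DataFrame(rows, columns=["variable", "r", "p", "n"])
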