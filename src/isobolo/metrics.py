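"""Time-course reduction: trapezoidal AUC, %MPE scoring, group comparisons.

%MPE (per cent maximal possible effect) anchors each treated animal's AUC
between the injured-vehicle group (0%) and the sham-operated group (100%):

    %MPE = (AUC_post - AUC_vehicle) / (AUC_sham - AUC_vehicle) * 100

Per-animal %MPE uses the *group-mean* vehicle and sham AUCs as references,
so per-animal values (and their SEMs) are interpretable; values above 100
are not truncated.  Group time-course comparisons use one-way ANOVA with
Dunnett's many-to-one post hoc test against the vehicle control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TIMEPOINTS, AnimalRecord

__all__ = [
    "AUCResult",
    "MPEResult",
    "DunnettComparison",
    "DunnettResult",
    "auc_trapezoid",
    "percent_mpe",
    "anova_dunnett",
    "cohort_metrics",
    "group_summary",
]


@dataclass(frozen=True)
class AUCResult:
    value: float  # g*h
    t_start: float
    t_end: float


@dataclass(frozen=True)
class MPEResult:
    percent: float
    auc_post: float
    auc_vehicle: float
    auc_sham: float


def auc_trapezoid(times, thresholds) -> AUCResult:
    """Area under the threshold time course by the trapezoidal rule."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two timepoints")
    if t.size != y.size:
        raise ValueError("times and thresholds must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    value = float(np.trapezoid(y, t))
    return AUCResult(value=value, t_start=float(t[0]), t_end=float(t[-1]))


def percent_mpe(auc_post: float, auc_vehicle: float, auc_sham: float) -> MPEResult:
    """Normalise a post-drug AUC to the vehicle (0%) / sham (100%) anchors."""
    denom = auc_sham - auc_vehicle
    if denom == 0:
        raise ValueError("degenerate controls: sham and vehicle AUCs are equal")
    pct = (auc_post - auc_vehicle) / denom * 100.0
    return MPEResult(percent=float(pct), auc_post=float(auc_post),
                     auc_vehicle=float(auc_vehicle), auc_sham=float(auc_sham))


@dataclass(frozen=True)
class DunnettComparison:
    label: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float


@dataclass(frozen=True)
class DunnettResult:
    f_stat: float
    p_anova: float
    df_between: int
    df_within: int
    comparisons: tuple[DunnettComparison, ...]


def anova_dunnett(
    groups: dict[str, np.ndarray],
    control_label: str,
    seed: int = 0,
) -> DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons against control.

    Dunnett familywise-adjusted p-values come from the equicorrelated
    multivariate-t distribution (seeded quasi-Monte-Carlo integration, so
    results are reproducible to ~1e-4); each adjusted p is floored at the
    corresponding pooled-variance unadjusted p, which it can never honestly
    undercut.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs n >= 2")
    if all(np.var(a) == 0 for a in arrays.values()) and len(
        {a.mean() for a in arrays.values()}
    ) == 1:
        raise ValueError("all observations identical: F undefined")

    f_stat, p_anova = stats.f_oneway(*arrays.values())
    if np.isnan(f_stat):  # zero within-group variance with equal means
        f_stat, p_anova = 0.0, 1.0

    control = arrays[control_label]
    others = {k: v for k, v in arrays.items() if k != control_label}
    n_total = sum(a.size for a in arrays.values())
    k_groups = len(arrays)
    df_within = n_total - k_groups
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_within

    res = stats.dunnett(
        *others.values(), control=control, rng=np.random.default_rng(seed)
    )
    comparisons = []
    for i, (label, a) in enumerate(others.items()):
        t_i = float(res.statistic[i])
        if mse > 0:
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / control.size))
            t_plain = (a.mean() - control.mean()) / se
            p_unadj = float(2 * stats.t.sf(abs(t_plain), df_within))
        else:
            p_unadj = 1.0 if a.mean() == control.mean() else 0.0
        p_adj = float(min(1.0, max(res.pvalue[i], p_unadj)))
        comparisons.append(
            DunnettComparison(label=label, statistic=t_i,
                              p_unadjusted=p_unadj, p_adjusted=p_adj)
        )
    return DunnettResult(
        f_stat=float(f_stat),
        p_anova=float(p_anova),
        df_between=k_groups - 1,
        df_within=df_within,
        comparisons=tuple(comparisons),
    )


def _animal_auc(rec: AnimalRecord, window: tuple[float, float]) -> float:
    """AUC over the window, including the t = 0 baseline point."""
    times = [0.0, *TIMEPOINTS]
    values = [rec.baseline_g] + [rec.thresholds[t] for t in TIMEPOINTS]
    lo, hi = window
    sel = [(t, v) for t, v in zip(times, values) if lo <= t <= hi]
    return auc_trapezoid([t for t, _ in sel], [v for _, v in sel]).value


def cohort_metrics(
    cohort: list[AnimalRecord],
    window: tuple[float, float] = (0.0, 8.0),
    vehicle_label: str = "vehicle",
    sham_label: str = "sham",
) -> pd.DataFrame:
    """Per-animal AUC and %MPE table.

    References are the group-mean AUCs of the named vehicle and sham arms.
    Columns: animal_id, arm_label, dose_a_mgkg, dose_b_mgkg, total_dose_mgkg,
    auc_gh, mpe_percent.
    """
    labels = {rec.arm.label for rec in cohort}
    for need in (vehicle_label, sham_label):
        if need not in labels:
            raise ValueError(f"cohort lacks required arm {need!r}")
    aucs = {rec.animal_id: _animal_auc(rec, window) for rec in cohort}
    veh = float(np.mean([aucs[r.animal_id] for r in cohort if r.arm.label == vehicle_label]))
    sham = float(np.mean([aucs[r.animal_id] for r in cohort if r.arm.label == sham_label]))
    rows = []
    for rec in cohort:
        a = aucs[rec.animal_id]
        rows.append(
            {
                "animal_id": rec.animal_id,
                "arm_label": rec.arm.label,
                "dose_a_mgkg": rec.arm.dose_a,
                "dose_b_mgkg": rec.arm.dose_b,
                "total_dose_mgkg": rec.arm.dose_a + rec.arm.dose_b,
                "auc_gh": a,
                "mpe_percent": percent_mpe(a, veh, sham).percent,
            }
        )
    return pd.DataFrame(rows)


def group_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Arm-level mean, SEM and n for AUC and %MPE."""
    def sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    out = (
        metrics.groupby("arm_label", sort=True)
        .agg(
            n=("animal_id", "size"),
            dose_a_mgkg=("dose_a_mgkg", "first"),
            dose_b_mgkg=("dose_b_mgkg", "first"),
            auc_mean=("auc_gh", "mean"),
            auc_sem=("auc_gh", sem),
            mpe_mean=("mpe_percent", "mean"),
            mpe_sem=("mpe_percent", sem),
        )
        .reset_index()
    )
    return out
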