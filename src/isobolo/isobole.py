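"""Tallarida fixed-ratio isobolographic additivity analysis.

For a mixture dosed in fixed ED50-fraction proportions rho_a + rho_b = 1,
Loewe additivity predicts a combination ED50 (in total mass dose)

    Z_add = rho_a * ED50_a + rho_b * ED50_b,
    SEM(Z_add) = sqrt(rho_a^2 SEM_a^2 + rho_b^2 SEM_b^2),

and the interaction index compares the experimentally fitted combination
ED50 with this prediction:

    gamma = ED50_exp / Z_add    (< 1 synergy, = 1 additivity, > 1 antagonism).

The gamma confidence interval uses the delta method on log(gamma), which
keeps it positive and asymmetric; the additivity test is a Student t on
the ED50 difference (a log-dose variant is also provided).  Geometry
helpers express everything in component-mass coordinates for isobolograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

from scipy import stats

__all__ = [
    "Ed50Estimate",
    "MixtureDesign",
    "AdditivePrediction",
    "InteractionResult",
    "IsobologramGeometry",
    "mixture_design",
    "additive_ed50",
    "interaction_index",
    "additivity_ttest",
    "isobologram_geometry",
]


class _HasEd50(Protocol):
    ed50: float
    ed50_sem: float
    df: int


@dataclass(frozen=True)
class Ed50Estimate:
    """A bare ED50 +/- SEM, for analysis-only use without raw data."""

    ed50: float
    ed50_sem: float
    df: int = 10

    def __post_init__(self) -> None:
        if self.ed50 <= 0:
            raise ValueError("ed50 must be positive")
        if self.ed50_sem < 0:
            raise ValueError("ed50_sem must be non-negative")


@dataclass(frozen=True)
class MixtureDesign:
    """Fixed-ratio design: potency fractions and the implied mass split."""

    rho_a: float
    rho_b: float
    mass_ratio_a: float  # dose_a / (dose_a + dose_b) at any total dose


@dataclass(frozen=True)
class AdditivePrediction:
    z_add: float  # mg/kg, total mass dose
    sem: float
    df: int


@dataclass(frozen=True)
class InteractionResult:
    gamma: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    verdict: str  # synergistic | additive | antagonistic
    level: float
    alpha: float


def mixture_design(ed50_a: float, ed50_b: float, rho_a: float = 0.5) -> MixtureDesign:
    """Fixed-ratio design from component ED50s and the potency fraction rho_a.

    A 1:1 (rho_a = 0.5) ED50-ratio design doses each component in proportion
    to its own ED50, so both contribute equally in potency units; the mass
    split is rho_a*ED50_a : rho_b*ED50_b.
    """
    if ed50_a <= 0 or ed50_b <= 0:
        raise ValueError("ED50s must be positive")
    if not (0 < rho_a < 1):
        raise ValueError("rho_a must be in (0, 1)")
    rho_b = 1.0 - rho_a
    mass_a = rho_a * ed50_a
    return MixtureDesign(
        rho_a=rho_a, rho_b=rho_b, mass_ratio_a=mass_a / (mass_a + rho_b * ed50_b)
    )


def _as_estimate(x) -> Ed50Estimate:
    if isinstance(x, Ed50Estimate):
        return x
    return Ed50Estimate(ed50=x.ed50, ed50_sem=x.ed50_sem, df=x.df)


def additive_ed50(
    fit_a: _HasEd50, fit_b: _HasEd50, design: MixtureDesign, df: int | None = None
) -> AdditivePrediction:
    """Theoretical additive ED50 of the mixture with composite SEM.

    Variances propagate with the squared potency fractions (the two
    monotherapy estimates are independent).  ``df`` defaults to the sum of
    the component dfs; pass the animal-based value (e.g. 2*(n-1)) to match
    designs where per-group ns, not regression dfs, set the comparison.
    """
    a, b = _as_estimate(fit_a), _as_estimate(fit_b)
    z = design.rho_a * a.ed50 + design.rho_b * b.ed50
    sem = math.sqrt((design.rho_a * a.ed50_sem) ** 2 + (design.rho_b * b.ed50_sem) ** 2)
    return AdditivePrediction(z_add=z, sem=sem, df=df if df is not None else a.df + b.df)


def additivity_ttest(
    ed50_exp: float,
    sem_exp: float,
    add: AdditivePrediction,
    df: int | None = None,
    log_scale: bool = False,
) -> tuple[float, float]:
    """Student t-test of the experimental vs theoretical additive ED50.

    Returns (t, two-sided p); t > 0 means the experimental ED50 falls below
    the additive prediction.  ``log_scale=True`` tests the difference of
    log ED50s with delta-method SEs instead of the plain dose-scale
    difference.  If both SEs are zero, p is 0 when the means differ
    (degenerate, infinitely precise inputs) and 1 when they coincide.
    """
    if ed50_exp <= 0 or sem_exp < 0:
        raise ValueError("ed50_exp must be positive and sem_exp non-negative")
    if add.z_add <= 0:
        raise ValueError("additive ED50 must be positive")
    nu = df if df is not None else add.df
    if log_scale:
        diff = math.log(add.z_add) - math.log(ed50_exp)
        se = math.hypot(sem_exp / ed50_exp, add.sem / add.z_add)
    else:
        diff = add.z_add - ed50_exp
        se = math.hypot(sem_exp, add.sem)
    if se == 0:
        return (0.0, 1.0) if diff == 0 else (math.inf, 0.0)
    t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), nu))
    return (float(t), p)


def interaction_index(
    ed50_exp: float,
    sem_exp: float,
    add: AdditivePrediction,
    level: float = 0.95,
    alpha: float = 0.05,
    df: int | None = None,
    log_scale_test: bool = False,
) -> InteractionResult:
    """Interaction index gamma with CI and the additivity significance test.

    CI: delta method on log(gamma) -- SE(log gamma) =
    sqrt((SEM_exp/ED50_exp)^2 + (SEM_add/Z_add)^2) -- back-transformed with
    a t quantile at ``df``.  Verdict: synergistic when gamma < 1 and the
    additivity t-test rejects at ``alpha``; antagonistic when gamma > 1 and
    it rejects; additive otherwise.
    """
    if not (0 < level < 1) or not (0 < alpha < 1):
        raise ValueError("level and alpha must be in (0, 1)")
    if ed50_exp <= 0 or add.z_add <= 0:
        raise ValueError("ED50s must be positive")
    nu = df if df is not None else add.df
    gamma = ed50_exp / add.z_add
    se_log = math.hypot(sem_exp / ed50_exp, add.sem / add.z_add)
    if se_log == 0:
        lo = hi = gamma
    else:
        q = stats.t.ppf(0.5 + level / 2.0, nu)
        lo, hi = gamma * math.exp(-q * se_log), gamma * math.exp(q * se_log)
    t, p = additivity_ttest(ed50_exp, sem_exp, add, df=nu, log_scale=log_scale_test)
    if p < alpha and gamma < 1:
        verdict = "synergistic"
    elif p < alpha and gamma > 1:
        verdict = "antagonistic"
    else:
        verdict = "additive"
    return InteractionResult(
        gamma=float(gamma), ci_low=float(lo), ci_high=float(hi),
        t_stat=t, p_value=p, verdict=verdict, level=level, alpha=alpha,
    )


@dataclass(frozen=True)
class IsobologramGeometry:
    """Isobologram in component-mass coordinates (drug A on x, B on y)."""

    intercept_a: tuple[float, float]  # (ED50_a, 0)
    intercept_b: tuple[float, float]  # (0, ED50_b)
    additive_point: tuple[float, float]
    experimental_point: tuple[float, float]
    below_line: bool
    line_position: float  # x/ED50_a + y/ED50_b at the experimental point


def isobologram_geometry(
    fit_a: _HasEd50, fit_b: _HasEd50, design: MixtureDesign, ed50_exp: float
) -> IsobologramGeometry:
    """Additivity-line intercepts plus the additive and experimental points.

    The additive point is the mass split of Z_add (it lies exactly on the
    segment joining the intercepts); the experimental point splits the
    fitted combination ED50 by the design mass ratio.  ``below_line`` is
    the sign test for synergy: x/ED50_a + y/ED50_b < 1.
    """
    a, b = _as_estimate(fit_a), _as_estimate(fit_b)
    if ed50_exp <= 0:
        raise ValueError("ed50_exp must be positive")
    z = additive_ed50(a, b, design).z_add
    add_pt = (design.mass_ratio_a * z, (1.0 - design.mass_ratio_a) * z)
    exp_pt = (design.mass_ratio_a * ed50_exp, (1.0 - design.mass_ratio_a) * ed50_exp)
    pos = exp_pt[0] / a.ed50 + exp_pt[1] / b.ed50
    return IsobologramGeometry(
        intercept_a=(a.ed50, 0.0),
        intercept_b=(0.0, b.ed50),
        additive_point=add_pt,
        experimental_point=exp_pt,
        below_line=pos < 1.0,
        line_position=float(pos),
    )
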