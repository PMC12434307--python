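"""Hill dose-response fitting of %MPE data: ED50 +/- SEM, Emax, R^2.

The model is a three-parameter Hill curve with the floor fixed at zero
(%MPE is constructed so vehicle defines 0%):

    E(D) = Emax * D**h / (D**h + ED50**h)

ED50 is fitted on the natural-log scale (which keeps it positive and makes
its sampling distribution closer to normal); its SEM on the dose scale
comes from the delta method.  The optimiser is Levenberg-Marquardt-style
least squares with multi-start initialisation over a log-spaced ED50 grid,
so a single bad start cannot silently return a local optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponsePoint",
    "HillFit",
    "ConvergenceError",
    "fit_hill",
    "ed50_interval",
    "hill_curve",
]


class ConvergenceError(RuntimeError):
    """The non-linear fit failed to converge from every start point."""


@dataclass(frozen=True)
class DoseResponsePoint:
    dose: float  # mg/kg; for mixtures the summed mass dose
    mpe: float  # %
    weight: float = 1.0  # optional replicate count

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not math.isfinite(self.mpe):
            raise ValueError("mpe must be finite")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with covariance on the internal scale.

    ``covariance`` is ordered (emax, log_ed50, hill); for a fixed-hill fit
    the hill row/column is zero.  ``ed50_sem`` is on the mg/kg scale via
    the delta method.
    """

    ed50: float
    ed50_sem: float
    emax: float
    emax_sem: float
    hill: float
    covariance: np.ndarray
    r2: float
    df: int
    n_points: int
    hill_fixed: bool = False

    def predict(self, dose) -> np.ndarray:
        return hill_curve(np.asarray(dose, dtype=float), self.emax, self.ed50, self.hill)


def hill_curve(dose: np.ndarray, emax: float, ed50: float, hill: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    out = np.zeros_like(dose)
    pos = dose > 0
    r = (dose[pos] / ed50) ** hill
    out[pos] = emax * r / (1.0 + r)
    return out


def fit_hill(
    points: list[DoseResponsePoint],
    fix_hill: float | None = None,
    emax_max: float | None = None,
) -> HillFit:
    """Least-squares Hill fit of %MPE against dose.

    Requires at least 3 distinct positive doses (4 when the Hill slope is
    free).  Residuals are weighted by sqrt(weight).  ``emax_max`` bounds the
    fitted plateau; on %MPE data a cap slightly above the 100% sham
    reference keeps Emax and ED50 jointly identified when the tested doses
    do not reach the plateau.  Raises :class:`ConvergenceError` if no start
    converges.
    """
    doses = np.array([p.dose for p in points], dtype=float)
    y = np.array([p.mpe for p in points], dtype=float)
    w = np.sqrt(np.array([p.weight for p in points], dtype=float))
    distinct = np.unique(doses[doses > 0])
    n_free = 2 if fix_hill is not None else 3
    if distinct.size < n_free + 1:
        raise ValueError(
            f"need at least {n_free + 1} distinct positive doses for a "
            f"{n_free}-parameter fit, got {distinct.size}"
        )
    if np.ptp(y) == 0:
        raise ValueError("all responses equal: total sum of squares is zero")

    emax0 = float(np.max(y))
    if emax0 <= 0:
        emax0 = 1.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        emax, log_ed50 = theta[0], theta[1]
        hill = fix_hill if fix_hill is not None else theta[2]
        return w * (hill_curve(doses, emax, math.exp(log_ed50), hill) - y)

    starts = np.log(np.geomspace(distinct.min(), distinct.max(), 5))
    best = None
    best_ss = np.inf
    e_hi = emax_max if emax_max is not None else np.inf
    for s in starts:
        theta0 = [min(emax0, e_hi), s] if fix_hill is not None else [min(emax0, e_hi), s, 1.0]
        lower = [-np.inf, -np.inf] if fix_hill is not None else [-np.inf, -np.inf, 1e-3]
        upper = [e_hi, np.inf] if fix_hill is not None else [e_hi, np.inf, np.inf]
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lower, upper),
                xtol=1e-12, ftol=1e-10, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        ss = 2.0 * sol.cost
        if ss < best_ss:
            best, best_ss = sol, ss
    if best is None:
        raise ConvergenceError("Hill fit did not converge from any start point")

    theta = best.x
    emax = float(theta[0])
    log_ed50 = float(theta[1])
    hill = float(fix_hill) if fix_hill is not None else float(theta[2])
    ed50 = math.exp(log_ed50)

    n = doses.size
    df = n - len(theta)
    ss_res = float(np.sum(best.fun**2))
    ybar = float(np.average(y, weights=w**2))
    ss_tot = float(np.sum((w * (y - ybar)) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    # covariance of the free parameters: s^2 (J^T J)^{-1}
    J = best.jac
    s2 = ss_res / df if df > 0 else 0.0
    jtj = J.T @ J
    cov_free = s2 * np.linalg.pinv(jtj)
    # embed into the full (emax, log_ed50, hill) ordering
    cov = np.zeros((3, 3))
    if fix_hill is not None:
        cov[:2, :2] = cov_free
    else:
        cov = cov_free
    ed50_sem = ed50 * math.sqrt(max(cov[1, 1], 0.0))
    emax_sem = math.sqrt(max(cov[0, 0], 0.0))

    return HillFit(
        ed50=ed50,
        ed50_sem=ed50_sem,
        emax=emax,
        emax_sem=emax_sem,
        hill=hill,
        covariance=cov,
        r2=float(r2),
        df=df,
        n_points=n,
        hill_fixed=fix_hill is not None,
    )


def ed50_interval(fit: HillFit, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for ED50, built on the log scale.

    Back-transforming keeps the lower bound positive and makes the interval
    asymmetric on the dose scale, as ED50 sampling distributions are.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if fit.ed50_sem == 0:
        return (fit.ed50, fit.ed50)
    se_log = fit.ed50_sem / fit.ed50
    q = stats.t.ppf(0.5 + level / 2.0, fit.df) if fit.df > 0 else stats.norm.ppf(0.5 + level / 2.0)
    half = q * se_log
    return (fit.ed50 * math.exp(-half), fit.ed50 * math.exp(half))
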