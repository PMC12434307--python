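"""Synthetic cohorts for a spinal-nerve-ligation von Frey study.

Emulates the arm structure of a two-drug fixed-ratio combination experiment
in the rat L5-L6 spinal nerve ligation (SNL) model: sham and vehicle control
groups, monotherapy dose arms for a pregabalin-like drug A and a
thioctic-acid-like drug B, and 1:1 ED50-ratio mixture arms.  Ground truth is
a Hill pharmacodynamic model expressed in Loewe "additivity units"
(dose_a/ED50_a + dose_b/ED50_b), in which the mixture ED50 is scaled by a
potency multiplier ``gamma_true`` -- so the simulator's truth and the
downstream interaction-index estimand coincide by construction
(``gamma_true = 1`` is exact Loewe additivity, ``< 1`` synergy).

Each latent threshold is observed through a simulated up-down staircase and
the Dixon estimator, reproducing the discreteness and censoring of real
von Frey data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .updown import (
    DEFAULT_PSYCHOMETRIC_SLOPE,
    FilamentLadder,
    build_ladder,
    dixon_threshold,
    simulate_updown,
)

__all__ = [
    "TreatmentArm",
    "PDParams",
    "AnimalRecord",
    "effect_fraction",
    "latent_timecourse",
    "simulate_study",
    "default_arms",
    "cohort_to_frame",
    "frame_to_cohort",
    "TIMEPOINTS",
]

#: Post-dose sampling grid in hours (baseline t = 0 is recorded separately).
TIMEPOINTS: tuple[float, ...] = (0.5, 1, 2, 3, 4, 5, 6, 7, 8)


@dataclass(frozen=True)
class TreatmentArm:
    label: str
    dose_a: float = 0.0  # mg/kg of the pregabalin-like component
    dose_b: float = 0.0  # mg/kg of the thioctic-acid-like component
    n_animals: int = 6
    sham: bool = False

    def __post_init__(self) -> None:
        if self.dose_a < 0 or self.dose_b < 0:
            raise ValueError("doses must be non-negative")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.sham and (self.dose_a or self.dose_b):
            raise ValueError("sham arms carry no drug")


@dataclass(frozen=True)
class PDParams:
    """Ground-truth pharmacodynamic parameters of the simulator.

    Thresholds in grams; ED50s in mg/kg; ``emax_*`` as fraction of the
    sham-vehicle gap recoverable; ``sigma`` is the SD of the lognormal
    between-animal sensitivity factor applied to individual ED50s.
    """

    t_sham: float = 8.94  # one filament log-step below the 15 g ceiling
    t_vehicle: float = 3.0  # allodynic level, below the 4 g reference line
    ed50_a: float = 2.45
    ed50_b: float = 57.49
    hill_a: float = 1.5
    hill_b: float = 1.5
    emax_a: float = 1.082
    emax_b: float = 0.913
    t_peak: float = 3.0  # h; peak drug effect
    gamma_true: float = 0.524  # the emulated study's estimated interaction index
    sigma: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.t_vehicle < self.t_sham <= 15):
            raise ValueError("need 0 < t_vehicle < t_sham <= 15")
        if self.ed50_a <= 0 or self.ed50_b <= 0:
            raise ValueError("ED50s must be positive")
        if not (0 < self.emax_a <= 1.1 and 0 < self.emax_b <= 1.1):
            raise ValueError("emax must be in (0, 1.1]")
        if self.hill_a <= 0 or self.hill_b <= 0:
            raise ValueError("Hill slopes must be positive")
        if self.gamma_true <= 0:
            raise ValueError("gamma_true must be positive")
        if not (min(TIMEPOINTS) <= self.t_peak <= max(TIMEPOINTS)):
            raise ValueError("t_peak must lie within the sampling window")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    arm: TreatmentArm
    baseline_g: float
    thresholds: dict[float, float] = field(compare=False)

    def __post_init__(self) -> None:
        bad = set(self.thresholds) - set(TIMEPOINTS)
        if bad:
            raise ValueError(f"timepoints outside the sampling grid: {sorted(bad)}")
        vals = [self.baseline_g, *self.thresholds.values()]
        if any(not (0 < v <= 15) for v in vals):
            raise ValueError("thresholds must lie in (0, 15] g")


def effect_fraction(dose: float, ed50: float, hill: float) -> float:
    """Hill effect fraction ``dose**h / (dose**h + ed50**h)`` in [0, 1)."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if ed50 <= 0 or hill <= 0:
        raise ValueError("ed50 and hill must be positive")
    if dose == 0:
        return 0.0
    r = (dose / ed50) ** hill
    return r / (1.0 + r)


def _time_profile(t: float, t_peak: float) -> float:
    """One-parameter rise-and-decay shape, normalised so g(t_peak) = 1."""
    if t <= 0:
        return 0.0
    x = t / t_peak
    return x * math.exp(1.0 - x)


def _total_effect(arm: TreatmentArm, p: PDParams, sensitivity: float = 1.0) -> float:
    """Peak-time effect fraction for an arm under the Loewe additive model.

    Doses are pooled in additivity units u = dA/ED50_a + dB/ED50_b and
    passed through one Hill curve whose half-effect point is ``gamma_true``
    potency units for genuine mixtures (1 for monotherapy, so the
    single-drug limits reduce exactly to each drug's own Hill curve).
    Emax and Hill slope are potency-weighted blends of the components.
    """
    ea, eb = p.ed50_a * sensitivity, p.ed50_b * sensitivity
    ua, ub = arm.dose_a / ea, arm.dose_b / eb
    u = ua + ub
    if u == 0:
        return 0.0
    wa = ua / u
    emax = wa * p.emax_a + (1 - wa) * p.emax_b
    hill = wa * p.hill_a + (1 - wa) * p.hill_b
    gamma = p.gamma_true if (arm.dose_a > 0 and arm.dose_b > 0) else 1.0
    r = (u / gamma) ** hill
    return emax * r / (1.0 + r)


def latent_timecourse(
    arm: TreatmentArm,
    params: PDParams,
    timepoints: tuple[float, ...] = TIMEPOINTS,
    sensitivity: float = 1.0,
) -> dict[float, float]:
    """Noise-free threshold (g) at each timepoint for one animal.

    latent(t) = base + gap * E_total * g(t) with base = t_vehicle
    (t_sham for sham arms), gap = t_sham - t_vehicle and the rise-and-decay
    profile g peaking at t_peak.
    """
    bad = set(timepoints) - set(TIMEPOINTS) - {0.0, 0}
    if bad:
        raise ValueError(f"timepoints outside the sampling grid: {sorted(bad)}")
    base = params.t_sham if arm.sham else params.t_vehicle
    gap = params.t_sham - params.t_vehicle
    effect = _total_effect(arm, params, sensitivity)
    return {
        float(t): base + gap * effect * _time_profile(float(t), params.t_peak)
        for t in timepoints
    }


def default_arms(params: PDParams | None = None, n_animals: int = 6) -> list[TreatmentArm]:
    """The study's arm layout: controls, two monotherapy ladders, mixtures.

    Monotherapy doses span 0.3-30 mg/kg (drug A) and 10-300 mg/kg (drug B);
    mixture arms give total doses 3.75-30 mg/kg split in the 1:1 ED50-ratio
    mass proportion implied by the design ED50s.
    """
    p = params or PDParams()
    arms = [
        TreatmentArm("sham", n_animals=n_animals, sham=True),
        TreatmentArm("vehicle", n_animals=n_animals),
    ]
    for d in (0.3, 1.0, 3.0, 10.0, 30.0):
        arms.append(TreatmentArm(f"drugA_{d:g}", dose_a=d, n_animals=n_animals))
    for d in (10.0, 30.0, 100.0, 300.0):
        arms.append(TreatmentArm(f"drugB_{d:g}", dose_b=d, n_animals=n_animals))
    mass_ratio_a = p.ed50_a / (p.ed50_a + p.ed50_b)
    for total in (3.75, 7.5, 15.0, 30.0):
        arms.append(
            TreatmentArm(
                f"mix_{total:g}",
                dose_a=total * mass_ratio_a,
                dose_b=total * (1 - mass_ratio_a),
                n_animals=n_animals,
            )
        )
    return arms


def simulate_study(
    arms: list[TreatmentArm],
    params: PDParams,
    seed: int,
    ladder: FilamentLadder | None = None,
    psychometric_slope: float = DEFAULT_PSYCHOMETRIC_SLOPE,
    timepoints: tuple[float, ...] = TIMEPOINTS,
) -> list[AnimalRecord]:
    """Simulate one full cohort; fully reproducible from ``seed``.

    Requires at least one sham and one vehicle arm (the %MPE references).
    Each animal draws a lognormal sensitivity factor (scale ``sigma``)
    multiplying its ED50s; every latent threshold (including the t = 0
    baseline) is then observed through a simulated up-down staircase and
    the Dixon estimator.  Per-animal random streams are derived from
    ``(seed, arm index, animal index)`` so adding arms does not perturb
    existing ones.
    """
    labels = [a.label for a in arms]
    if len(set(labels)) != len(labels):
        raise ValueError("arm labels must be unique")
    if not any(a.sham for a in arms):
        raise ValueError("a sham arm is required (100% reference for %MPE)")
    if not any((not a.sham) and a.dose_a == 0 and a.dose_b == 0 for a in arms):
        raise ValueError("a vehicle arm is required (0% reference for %MPE)")
    lad = ladder or build_ladder()

    cohort: list[AnimalRecord] = []
    for ai, arm in enumerate(arms):
        for j in range(arm.n_animals):
            rng = np.random.default_rng(np.random.SeedSequence([seed, ai, j]))
            sens = float(np.exp(rng.normal(0.0, params.sigma))) if params.sigma else 1.0
            latent = latent_timecourse(arm, params, timepoints, sensitivity=sens)
            base_latent = params.t_sham if arm.sham else params.t_vehicle

            def observe(value: float) -> float:
                seq = simulate_updown(value, psychometric_slope, lad, rng)
                return dixon_threshold(seq, lad).grams

            baseline = observe(base_latent)
            observed = {t: observe(v) for t, v in latent.items()}
            cohort.append(
                AnimalRecord(
                    animal_id=f"{arm.label}_{j + 1:02d}",
                    arm=arm,
                    baseline_g=baseline,
                    thresholds=observed,
                )
            )
    return cohort


_TIME_COLS = ["t0"] + [f"t{t:g}" for t in TIMEPOINTS]


def cohort_to_frame(cohort: list[AnimalRecord]) -> pd.DataFrame:
    """Cohort as a flat table: one row per animal, one column per timepoint."""
    rows = []
    for rec in cohort:
        row: dict[str, object] = {
            "animal_id": rec.animal_id,
            "arm_label": rec.arm.label,
            "dose_a_mgkg": rec.arm.dose_a,
            "dose_b_mgkg": rec.arm.dose_b,
            "t0": rec.baseline_g,
        }
        for t in TIMEPOINTS:
            row[f"t{t:g}"] = rec.thresholds[t]
        rows.append(row)
    return pd.DataFrame(rows, columns=["animal_id", "arm_label", "dose_a_mgkg", "dose_b_mgkg", *_TIME_COLS])


def frame_to_cohort(frame: pd.DataFrame) -> list[AnimalRecord]:
    """Inverse of :func:`cohort_to_frame`; arm sizes recomputed per label."""
    counts = frame["arm_label"].value_counts().to_dict()
    cohort = []
    for _, row in frame.iterrows():
        label = str(row["arm_label"])
        da, db = float(row["dose_a_mgkg"]), float(row["dose_b_mgkg"])
        arm = TreatmentArm(
            label,
            dose_a=da,
            dose_b=db,
            n_animals=int(counts[label]),
            sham=(label == "sham"),
        )
        cohort.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                arm=arm,
                baseline_g=float(row["t0"]),
                thresholds={t: float(row[f"t{t:g}"]) for t in TIMEPOINTS},
            )
        )
    return cohort
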