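"""End-to-end orchestration: simulate -> metrics -> fits -> isobolography.

The pipeline turns a cohort (simulated or loaded from CSV) into per-animal
metrics, three Hill fits (two monotherapies and the fixed-ratio mixture on
its total-mass dose axis), the Tallarida additive prediction and the
interaction-index report.  All outputs are plain CSV/JSON and byte-stable
under a fixed configuration and seed; logs go to stderr and never mix with
results.

An analysis-only "paper twin" entry point reproduces the isobolographic
arithmetic directly from published ED50 +/- SEM values, with no raw data
or simulation involved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .doseresponse import ConvergenceError, DoseResponsePoint, HillFit, ed50_interval, fit_hill
from .isobole import (
    AdditivePrediction,
    Ed50Estimate,
    InteractionResult,
    additive_ed50,
    interaction_index,
    isobologram_geometry,
    mixture_design,
)
from .metrics import anova_dunnett, cohort_metrics, group_summary
from .simulate import TIMEPOINTS, AnimalRecord, PDParams, default_arms, frame_to_cohort, simulate_study, cohort_to_frame

__all__ = [
    "RunConfig",
    "StudyReport",
    "ValidationError",
    "run_pipeline",
    "analyze_cohort",
    "read_cohort",
    "write_cohort",
    "paper_twin",
    "replicate_studies",
    "fit_cohort_curves",
]

log = logging.getLogger("isobolo")


class ValidationError(ValueError):
    """Invalid input data or configuration (CLI exit code 2)."""


def _version() -> str:
    try:
        return metadata.version("isobolo")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    ``df_rule``: "regression" (default) sums the two monotherapy fit
    residual dfs for the additivity t-test and gamma CI -- the honest count
    when fits are per-animal; "animal" uses the conservative per-group
    2*(n-1) convention (n = animals per group), appropriate when only
    published ED50 +/- SEM values are available.

    ``fix_hill``: the analysis fixes the Hill slope at the package's
    canonical 1.5 (free-slope fits are unidentifiable on 4-dose designs
    that do not reach the plateau); set to None to fit it.

    ``emax_max``: upper bound on fitted %MPE plateaus, slightly above the
    100% sham reference; keeps Emax/ED50 identified on partial curves.
    """

    seed: int = 1
    n_animals: int = 6
    params: PDParams = field(default_factory=PDParams)
    rho_a: float = 0.5
    alpha: float = 0.05
    ci_level: float = 0.95
    df_rule: str = "regression"
    auc_window: tuple[float, float] = (0.0, 8.0)
    fix_hill: float | None = 1.5
    emax_max: float | None = 120.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.ci_level < 1):
            raise ValidationError("alpha and ci_level must be in (0, 1)")
        if self.df_rule not in ("animal", "regression"):
            raise ValidationError("df_rule must be 'animal' or 'regression'")
        if self.n_animals < 1:
            raise ValidationError("n_animals must be >= 1")

    def ttest_df(self, fit_a: HillFit, fit_b: HillFit) -> int:
        if self.df_rule == "animal":
            return 2 * (self.n_animals - 1)
        return fit_a.df + fit_b.df

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["auc_window"] = list(self.auc_window)
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat ``key = value`` config file; PDParams fields are top-level keys."""
        pd_fields = {f.name: f.type for f in dataclasses.fields(PDParams)}
        cfg_fields = {"seed", "n_animals", "rho_a", "alpha", "ci_level",
                      "df_rule", "auc_window", "fix_hill", "emax_max"}
        kw: dict = {}
        pd_kw: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in pd_fields:
                pd_kw[key] = float(val)
            elif key == "seed" or key == "n_animals":
                kw[key] = int(val)
            elif key == "df_rule":
                kw[key] = val
            elif key == "auc_window":
                lo, hi = (float(x) for x in val.split(","))
                kw[key] = (lo, hi)
            elif key in ("fix_hill", "emax_max"):
                kw[key] = None if val.lower() in ("none", "") else float(val)
            elif key in cfg_fields:
                kw[key] = float(val)
            else:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
        kw["params"] = PDParams(**pd_kw)
        return cls(**kw)


@dataclass(frozen=True)
class StudyReport:
    summary: pd.DataFrame
    fits: dict[str, HillFit]
    additive: AdditivePrediction
    interaction: InteractionResult
    dunnett_auc: object
    provenance: dict

    def to_dict(self) -> dict:
        def fit_dict(f: HillFit) -> dict:
            lo, hi = ed50_interval(f, 0.95)
            return {
                "ed50": f.ed50, "ed50_sem": f.ed50_sem,
                "ed50_ci95": [lo, hi],
                "emax": f.emax, "emax_sem": f.emax_sem, "hill": f.hill,
                "hill_fixed": f.hill_fixed, "r2": f.r2, "df": f.df,
                "n_points": f.n_points,
                "covariance": [[float(x) for x in row] for row in f.covariance],
            }

        d = self.dunnett_auc
        return {
            "provenance": self.provenance,
            "arms": self.summary.to_dict(orient="records"),
            "fits": {k: fit_dict(v) for k, v in self.fits.items()},
            "additive": dataclasses.asdict(self.additive),
            "interaction": dataclasses.asdict(self.interaction),
            "dunnett_auc": {
                "f_stat": d.f_stat, "p_anova": d.p_anova,
                "df_between": d.df_between, "df_within": d.df_within,
                "comparisons": [dataclasses.asdict(c) for c in d.comparisons],
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"


# ---------------------------------------------------------------------------
# cohort I/O

_REQUIRED_COLS = ["animal_id", "arm_label", "dose_a_mgkg", "dose_b_mgkg"]
_TIME_COLS = ["t0"] + [f"t{t:g}" for t in TIMEPOINTS]


def write_cohort(cohort: list[AnimalRecord], path: str | Path) -> None:
    frame = cohort_to_frame(cohort).copy()
    # shortest round-tripping decimal form, so read_cohort restores the
    # records bit-exactly
    for col in frame.columns:
        if frame[col].dtype.kind == "f":
            frame[col] = frame[col].map(lambda v: repr(float(v)))
    frame.to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[AnimalRecord]:
    """Read and validate a cohort CSV (see :func:`write_cohort` for layout).

    Rejects unknown timepoint columns (the grid is t0, t0.5 ... t8),
    duplicate animal ids, non-numeric doses/thresholds and thresholds
    outside (0, 15] g, naming the offending file row.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ValidationError(f"unparseable CSV {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLS + _TIME_COLS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    extra_t = [c for c in frame.columns
               if c.startswith("t") and c[1:].replace(".", "", 1).isdigit()
               and c not in _TIME_COLS]
    if extra_t:
        raise ValidationError(
            f"{path}: timepoint columns {extra_t} outside the grid t0, t0.5 ... t8"
        )
    dup = frame["animal_id"][frame["animal_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"{path}: duplicate animal ids {sorted(set(dup))}")
    for col in _TIME_COLS + ["dose_a_mgkg", "dose_b_mgkg"]:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric {col} at row {int(bad[0]) + 2}"
            )
        frame[col] = vals
    for col in _TIME_COLS:
        bad = frame.index[(frame[col] <= 0) | (frame[col] > 15)]
        if len(bad):
            raise ValidationError(
                f"{path}: {col} outside (0, 15] g at row {int(bad[0]) + 2}"
            )
    return frame_to_cohort(frame)


# ---------------------------------------------------------------------------
# analysis

def fit_cohort_curves(
    metrics: pd.DataFrame,
    fix_hill: float | None = 1.5,
    emax_max: float | None = 120.0,
) -> dict[str, HillFit]:
    """Hill fits for drug A, drug B and the mixture from per-animal %MPE.

    Points are per-animal (honest residual dfs); the mixture dose axis is
    the summed mass dose.  Arms are classified by their dose pattern.
    """
    def points(mask) -> list[DoseResponsePoint]:
        sub = metrics[mask]
        return [
            DoseResponsePoint(dose=row.total_dose_mgkg, mpe=row.mpe_percent)
            for row in sub.itertuples()
        ]

    is_a = (metrics["dose_a_mgkg"] > 0) & (metrics["dose_b_mgkg"] == 0)
    is_b = (metrics["dose_b_mgkg"] > 0) & (metrics["dose_a_mgkg"] == 0)
    is_mix = (metrics["dose_a_mgkg"] > 0) & (metrics["dose_b_mgkg"] > 0)
    fits = {}
    for name, mask in (("drugA", is_a), ("drugB", is_b), ("mixture", is_mix)):
        pts = points(mask)
        if not pts:
            raise ValidationError(f"no dose arms found for {name}")
        fits[name] = fit_hill(pts, fix_hill=fix_hill, emax_max=emax_max)
    return fits


def analyze_cohort(cohort: list[AnimalRecord], config: RunConfig) -> StudyReport:
    """Metrics, fits and isobolographic analysis of one cohort."""
    metrics = cohort_metrics(cohort, window=config.auc_window)
    summary = group_summary(metrics)
    fits = fit_cohort_curves(metrics, fix_hill=config.fix_hill, emax_max=config.emax_max)
    df_t = config.ttest_df(fits["drugA"], fits["drugB"])
    design = mixture_design(fits["drugA"].ed50, fits["drugB"].ed50, config.rho_a)
    add = additive_ed50(fits["drugA"], fits["drugB"], design, df=df_t)
    inter = interaction_index(
        fits["mixture"].ed50, fits["mixture"].ed50_sem, add,
        level=config.ci_level, alpha=config.alpha, df=df_t,
    )
    auc_groups = {
        label: sub["auc_gh"].to_numpy()
        for label, sub in metrics.groupby("arm_label")
    }
    dun = anova_dunnett(auc_groups, control_label="vehicle", seed=config.seed)
    provenance = {
        "package": "isobolo",
        "version": _version(),
        "seed": config.seed,
        "config_sha256": config.sha256(),
    }
    return StudyReport(
        summary=summary, fits=fits, additive=add, interaction=inter,
        dunnett_auc=dun, provenance=provenance,
    )


def _geometry_frame(report: StudyReport, config: RunConfig) -> pd.DataFrame:
    design = mixture_design(
        report.fits["drugA"].ed50, report.fits["drugB"].ed50, config.rho_a
    )
    geo = isobologram_geometry(
        report.fits["drugA"], report.fits["drugB"], design,
        report.fits["mixture"].ed50,
    )
    mix_sem = report.fits["mixture"].ed50_sem
    rows = [
        ("intercept_a", *geo.intercept_a, 0.0, 0.0),
        ("intercept_b", *geo.intercept_b, 0.0, 0.0),
        ("additive", *geo.additive_point,
         design.mass_ratio_a * report.additive.sem,
         (1 - design.mass_ratio_a) * report.additive.sem),
        ("experimental", *geo.experimental_point,
         design.mass_ratio_a * mix_sem, (1 - design.mass_ratio_a) * mix_sem),
    ]
    return pd.DataFrame(
        rows, columns=["point", "dose_a_mgkg", "dose_b_mgkg", "sem_a", "sem_b"]
    )


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    cohort: list[AnimalRecord] | None = None,
) -> StudyReport:
    """Run all stages and write the full output bundle to ``outdir``.

    Files written: cohort.csv, metrics.csv, summary.csv, fit_<curve>.json,
    interaction.json, isobologram.csv, report.json.  With an unchanged
    (config, seed) the bundle is byte-identical across runs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    if cohort is None:
        arms = default_arms(config.params, n_animals=config.n_animals)
        cohort = simulate_study(arms, config.params, seed=config.seed)
        log.info("simulate: %d animals in %d arms (seed %d)",
                 len(cohort), len(arms), config.seed)
    write_cohort(cohort, out / "cohort.csv")

    metrics = cohort_metrics(cohort, window=config.auc_window)
    metrics.to_csv(out / "metrics.csv", index=False)
    report = analyze_cohort(cohort, config)
    report.summary.to_csv(out / "summary.csv", index=False)
    for name, f in report.fits.items():
        payload = {k: v for k, v in report.to_dict()["fits"][name].items()}
        (out / f"fit_{name}.json").write_text(
            json.dumps(payload, sort_keys=True, indent=2) + "\n"
        )
    (out / "interaction.json").write_text(
        json.dumps(
            {
                "additive": dataclasses.asdict(report.additive),
                "interaction": dataclasses.asdict(report.interaction),
            },
            sort_keys=True, indent=2,
        ) + "\n"
    )
    _geometry_frame(report, config).to_csv(out / "isobologram.csv", index=False)
    (out / "report.json").write_text(report.to_json())
    log.info("pipeline done in %.2f s -> %s", time.perf_counter() - t0, out)
    return report


# ---------------------------------------------------------------------------
# analysis-only paper twin

def paper_twin(
    ed50_a: float = 2.45,
    sem_a: float = 0.23,
    ed50_b: float = 57.49,
    sem_b: float = 5.59,
    ed50_exp: float = 15.69,
    sem_exp: float = 1.03,
    rho_a: float = 0.5,
    df: int = 10,
    level: float = 0.95,
    alpha: float = 0.05,
) -> dict:
    """Isobolographic arithmetic from published ED50 +/- SEM values alone.

    Defaults are the monotherapy and 1:1 combination estimates of the
    pregabalin / thioctic acid SNL study this package models; no raw data
    or simulation is touched.  Returns the additive prediction, interaction
    index with CI, t-test and isobologram geometry as one JSON-ready dict.
    """
    a = Ed50Estimate(ed50_a, sem_a, df)
    b = Ed50Estimate(ed50_b, sem_b, df)
    design = mixture_design(ed50_a, ed50_b, rho_a)
    add = additive_ed50(a, b, design, df=df)
    inter = interaction_index(ed50_exp, sem_exp, add, level=level, alpha=alpha, df=df)
    geo = isobologram_geometry(a, b, design, ed50_exp)
    return {
        "inputs": {
            "ed50_a": ed50_a, "sem_a": sem_a, "ed50_b": ed50_b, "sem_b": sem_b,
            "ed50_exp": ed50_exp, "sem_exp": sem_exp, "rho_a": rho_a, "df": df,
        },
        "design": dataclasses.asdict(design),
        "additive": dataclasses.asdict(add),
        "interaction": dataclasses.asdict(inter),
        "isobologram": {
            "intercept_a": list(geo.intercept_a),
            "intercept_b": list(geo.intercept_b),
            "additive_point": list(geo.additive_point),
            "experimental_point": list(geo.experimental_point),
            "below_line": geo.below_line,
            "line_position": geo.line_position,
        },
    }


# ---------------------------------------------------------------------------
# replicate mode

def replicate_studies(n_reps: int, config: RunConfig) -> pd.DataFrame:
    """Simulate and analyse ``n_reps`` independent studies.

    Per-replicate seeds derive from (config.seed, replicate index), so the
    set is reproducible and grows stably.  Rows with non-convergent fits
    carry NaNs and count against rejection rates.
    """
    rows = []
    for rep in range(n_reps):
        sub = int(np.random.SeedSequence([config.seed, rep]).generate_state(1)[0]
                  % (2**31 - 1))
        rep_cfg = dataclasses.replace(config, seed=sub)
        arms = default_arms(rep_cfg.params, n_animals=rep_cfg.n_animals)
        cohort = simulate_study(arms, rep_cfg.params, seed=rep_cfg.seed)
        try:
            metrics = cohort_metrics(cohort, window=rep_cfg.auc_window)
            fits = fit_cohort_curves(metrics, fix_hill=rep_cfg.fix_hill,
                                     emax_max=rep_cfg.emax_max)
            df_t = rep_cfg.ttest_df(fits["drugA"], fits["drugB"])
            design = mixture_design(fits["drugA"].ed50, fits["drugB"].ed50,
                                    rep_cfg.rho_a)
            add = additive_ed50(fits["drugA"], fits["drugB"], design, df=df_t)
            inter = interaction_index(
                fits["mixture"].ed50, fits["mixture"].ed50_sem, add,
                level=rep_cfg.ci_level, alpha=rep_cfg.alpha, df=df_t,
            )
            rows.append({
                "rep": rep, "seed": sub,
                "ed50_a": fits["drugA"].ed50, "ed50_b": fits["drugB"].ed50,
                "ed50_mix": fits["mixture"].ed50,
                "z_add": add.z_add, "gamma": inter.gamma,
                "t_stat": inter.t_stat, "p_value": inter.p_value,
                "verdict": inter.verdict,
            })
        except ConvergenceError:
            rows.append({
                "rep": rep, "seed": sub, "ed50_a": np.nan, "ed50_b": np.nan,
                "ed50_mix": np.nan, "z_add": np.nan, "gamma": np.nan,
                "t_stat": np.nan, "p_value": np.nan, "verdict": "failed",
            })
    return pd.DataFrame(rows)
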