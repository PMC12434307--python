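"""Dixon up-down estimation of 50% von Frey withdrawal thresholds.

The up-down (staircase) procedure presents calibrated filaments to the paw:
after a withdrawal the next filament is one step weaker, after no withdrawal
one step stronger.  Testing continues until four presentations after the
first direction change, or until the staircase runs off the end of the
ladder.  The 50% threshold is ``10**(log10(F_final) + k*delta)`` where ``k``
is Dixon's tabulated coefficient for the terminal response pattern and
``delta`` the mean log10 spacing of the filament ladder.

This module provides the ladder/sequence containers, the threshold
estimator with its bundled coefficient table, and a staircase simulator
driven by a logistic psychometric function in log10 force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
import numpy as np

__all__ = [
    "FilamentLadder",
    "UpDownSequence",
    "ThresholdEstimate",
    "build_ladder",
    "dixon_threshold",
    "simulate_updown",
    "load_k_table",
    "sequence_to_rows",
    "DEFAULT_PSYCHOMETRIC_SLOPE",
]

#: Logistic slope (per log10 g) of the simulated psychometric function:
#: misclassification ~1% one standard log-step away from threshold (~9% at a
#: half step; delta ~ 0.2249 for the 0.4-15 g, 8-filament ladder), i.e.
#: slope = ln(99)/delta.  Together with the between-animal variability
#: default this reproduces the assay precision reported for the kind of
#: SNL study the simulator emulates (per-group %MPE SEMs of a few percent,
#: fitted ED50 SEMs ~7-10% of the estimate).
DEFAULT_PSYCHOMETRIC_SLOPE = math.log(99.0) / ((math.log10(15.0) - math.log10(0.4)) / 7)

_MAX_PATTERN_LEN = 8


class UpDownError(ValueError):
    """A sequence violates the up-down transition rule or the k-table."""


@dataclass(frozen=True)
class FilamentLadder:
    """Ordered set of von Frey filament forces (grams)."""

    forces: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.forces) < 3:
            raise ValueError("ladder needs at least 3 filaments")
        if any(f <= 0 for f in self.forces):
            raise ValueError("filament forces must be positive")
        if any(b <= a for a, b in zip(self.forces, self.forces[1:])):
            raise ValueError("filament forces must be strictly increasing")

    @property
    def log_forces(self) -> np.ndarray:
        return np.log10(np.asarray(self.forces))

    @property
    def delta(self) -> float:
        """Mean successive spacing of log10 forces (dimensionless)."""
        lf = self.log_forces
        return float(np.mean(np.diff(lf)))

    def nearest_index(self, force: float) -> int:
        """Index of the filament closest to ``force`` in log10 distance."""
        return int(np.argmin(np.abs(self.log_forces - math.log10(force))))

    def __len__(self) -> int:
        return len(self.forces)


@dataclass(frozen=True)
class UpDownSequence:
    """One staircase test: filament indices and binary withdrawal responses."""

    filament_indices: tuple[int, ...]
    responses: tuple[bool, ...]
    start_index: int

    def validate(self, ladder: FilamentLadder) -> None:
        idx, resp = self.filament_indices, self.responses
        if len(idx) != len(resp) or not idx:
            raise UpDownError("indices and responses must be non-empty and equal length")
        if idx[0] != self.start_index:
            raise UpDownError("sequence must begin at start_index")
        n = len(ladder)
        if any(i < 0 or i >= n for i in idx):
            raise UpDownError("filament index outside ladder bounds")
        for t in range(len(idx) - 1):
            expect = idx[t] - 1 if resp[t] else idx[t] + 1
            if idx[t + 1] != expect:
                raise UpDownError(
                    f"trial {t + 1}: up-down rule violated "
                    f"(index {idx[t]} with response {resp[t]} must be followed by {expect})"
                )


@dataclass(frozen=True)
class ThresholdEstimate:
    """50% withdrawal threshold in grams, flagged if boundary-assigned."""

    grams: float
    censored: bool


def build_ladder(
    min_force: float = 0.4, max_force: float = 15.0, n_filaments: int = 8
) -> FilamentLadder:
    """Log-spaced filament ladder between ``min_force`` and ``max_force`` g.

    The default reproduces the conventional 0.4-15 g clinical/behavioural
    range with 8 filaments (log step ~0.225).
    """
    if min_force <= 0 or max_force <= min_force:
        raise ValueError("need 0 < min_force < max_force")
    if n_filaments < 3:
        raise ValueError("need at least 3 filaments")
    forces = np.logspace(math.log10(min_force), math.log10(max_force), n_filaments)
    # pin endpoints exactly to the requested bounds
    forces[0], forces[-1] = min_force, max_force
    return FilamentLadder(tuple(float(f) for f in forces))


def load_k_table() -> dict[str, float]:
    """Bundled Dixon coefficient table: terminal O/X pattern -> k."""
    table: dict[str, float] = {}
    text = resources.files("isobolo.data").joinpath("dixon_k.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pattern"):
            continue
        pat, k = line.split("\t")
        table[pat] = float(k)
    return table


_K_TABLE: dict[str, float] | None = None


def _k_table() -> dict[str, float]:
    global _K_TABLE
    if _K_TABLE is None:
        _K_TABLE = load_k_table()
    return _K_TABLE


def dixon_threshold(seq: UpDownSequence, ladder: FilamentLadder) -> ThresholdEstimate:
    """Estimate the 50% withdrawal threshold from a staircase sequence.

    All-negative sequences are assigned the ceiling (top filament force) and
    all-positive sequences the floor (bottom filament force), both censored.
    Otherwise the terminal pattern -- from the trial preceding the first
    direction change onward -- is looked up in the bundled Dixon k-table and
    the estimate is ``10**(log10(F_final) + k*delta)``, clamped to the ladder
    range (a clamped value is reported censored).
    """
    seq.validate(ladder)
    resp = seq.responses
    if all(resp):
        return ThresholdEstimate(grams=ladder.forces[0], censored=True)
    if not any(resp):
        return ThresholdEstimate(grams=ladder.forces[-1], censored=True)

    first_change = next(i for i in range(1, len(resp)) if resp[i] != resp[i - 1])
    pattern = "".join("X" if r else "O" for r in resp[first_change - 1 :])
    if len(pattern) > _MAX_PATTERN_LEN:
        raise UpDownError(
            f"terminal pattern {pattern!r} longer than the bundled k-table covers"
        )
    try:
        k = _k_table()[pattern]
    except KeyError:
        raise UpDownError(f"pattern {pattern!r} absent from k-table") from None

    x_f = math.log10(ladder.forces[seq.filament_indices[-1]])
    grams = 10.0 ** (x_f + k * ladder.delta)
    lo, hi = ladder.forces[0], ladder.forces[-1]
    if grams >= hi:
        return ThresholdEstimate(grams=hi, censored=True)
    if grams <= lo:
        return ThresholdEstimate(grams=lo, censored=True)
    return ThresholdEstimate(grams=grams, censored=False)


def _p_withdraw(force: float, latent_threshold: float, slope: float) -> float:
    """Logistic psychometric function in log10 force."""
    x = math.log10(force) - math.log10(latent_threshold)
    if x == 0.0:
        return 0.5
    z = slope * x
    if z > 700.0:
        return 1.0
    if z < -700.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))


def simulate_updown(
    latent_threshold: float,
    psychometric_slope: float,
    ladder: FilamentLadder,
    rng: np.random.Generator | int,
    start_force: float = 2.0,
) -> UpDownSequence:
    """Simulate one staircase from a latent threshold.

    Responses are Bernoulli with withdrawal probability logistic in
    ``log10(force)`` centred at ``log10(latent_threshold)`` with the given
    slope (``slope = inf`` gives a deterministic step function).  The
    staircase starts at the filament nearest ``start_force`` (2 g by
    convention), stops four presentations after the first direction change,
    or earlier if it runs off either end of the ladder.
    """
    if latent_threshold <= 0:
        raise ValueError("latent_threshold must be positive")
    if psychometric_slope <= 0:
        raise ValueError("psychometric_slope must be positive")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    start = ladder.nearest_index(start_force)
    idx = start
    indices: list[int] = []
    responses: list[bool] = []
    first_change: int | None = None
    while True:
        p = _p_withdraw(ladder.forces[idx], latent_threshold, psychometric_slope)
        r = bool(gen.random() < p)
        indices.append(idx)
        responses.append(r)
        t = len(responses) - 1
        if first_change is None and t >= 1 and responses[t] != responses[t - 1]:
            first_change = t
        if first_change is not None and t >= first_change + 4:
            break
        nxt = idx - 1 if r else idx + 1
        if nxt < 0 or nxt >= len(ladder):
            break  # staircase ran off the ladder; estimator handles censoring
        idx = nxt
    return UpDownSequence(
        filament_indices=tuple(indices), responses=tuple(responses), start_index=start
    )


def sequence_to_rows(
    seq: UpDownSequence, ladder: FilamentLadder
) -> list[tuple[int, float, int]]:
    """Serialize a sequence to (trial, force_g, response) rows for CSV export."""
    return [
        (t + 1, ladder.forces[i], int(r))
        for t, (i, r) in enumerate(zip(seq.filament_indices, seq.responses))
    ]
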