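"""Up-down staircase: ladder construction, Dixon estimator, simulator."""

import csv
import math
from importlib import resources

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isobolo.updown import (
    DEFAULT_PSYCHOMETRIC_SLOPE,
    FilamentLadder,
    UpDownSequence,
    UpDownError,
    build_ladder,
    dixon_threshold,
    load_k_table,
    simulate_updown,
)

DELTA_8 = (math.log10(15) - math.log10(0.4)) / 7  # standard 8-filament spacing


def make_sequence(ladder, start_force, responses):
    """Build a valid sequence by walking the up-down rule from the start."""
    idx = ladder.nearest_index(start_force)
    indices = [idx]
    for r in responses[:-1]:
        idx = idx - 1 if r else idx + 1
        indices.append(idx)
    return UpDownSequence(
        filament_indices=tuple(indices),
        responses=tuple(responses),
        start_index=indices[0],
    )


class TestBuildLadder:
    def test_standard_range(self):
        lad = build_ladder(0.4, 15, 8)
        assert len(lad) == 8
        assert lad.forces[0] == pytest.approx(0.4)
        assert lad.forces[-1] == pytest.approx(15.0)
        assert lad.delta == pytest.approx(DELTA_8, abs=1e-12)

    def test_exact_log_spacing(self):
        lad = build_ladder(1, 10, 3)
        assert np.allclose(lad.log_forces, [0.0, 0.5, 1.0])
        assert lad.delta == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "args", [(0, 10, 5), (-1, 10, 5), (10, 1, 5), (1, 10, 2)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            build_ladder(*args)

    def test_forces_must_increase(self):
        with pytest.raises(ValueError):
            FilamentLadder((1.0, 1.0, 2.0))


class TestKTable:
    def test_classic_two_trial_anchors(self):
        # closed-form symmetry of the normal-ogive MLE: the two-trial
        # staircases estimate the midpoint between the tested levels
        table = load_k_table()
        assert table["OX"] == pytest.approx(-0.5, abs=1e-3)
        assert table["XO"] == pytest.approx(0.5, abs=1e-3)

    def test_mirror_antisymmetry(self):
        # swapping withdrawals and non-withdrawals mirrors the staircase,
        # so the coefficient flips sign for every pattern
        table = load_k_table()
        swap = str.maketrans("OX", "XO")
        for pat, k in table.items():
            assert table[pat.translate(swap)] == pytest.approx(-k, abs=2e-3)


class TestDixonThreshold:
    def test_all_negative_hits_ceiling(self, ladder):
        seq = make_sequence(ladder, 2.0, [False] * 5)  # climbs to 15 g
        est = dixon_threshold(seq, ladder)
        assert est.grams == 15.0
        assert est.censored

    def test_all_positive_hits_floor(self, ladder):
        seq = make_sequence(ladder, 2.0, [True] * 4)  # descends to 0.4 g
        est = dixon_threshold(seq, ladder)
        assert est.grams == pytest.approx(0.4)
        assert est.censored

    def test_matches_independent_table_lookup(self, ladder):
        """A fixed 6-trial sequence must equal 10**(Xf + k*delta) with k
        read straight from the bundled data file, bypassing the package
        loader and estimator logic."""
        responses = [False, False, True, False, True, False]
        seq = make_sequence(ladder, 2.0, responses)
        est = dixon_threshold(seq, ladder)

        raw = {}
        text = resources.files("isobolo.data").joinpath("dixon_k.tsv").read_text()
        for row in csv.reader(
            (l for l in text.splitlines() if l and not l.startswith("#")),
            delimiter="\t",
        ):
            if row[0] != "pattern":
                raw[row[0]] = float(row[1])
        # first reversal is at trial 3 (O -> X); the counted pattern starts
        # one trial earlier, giving OXOXO
        k = raw["OXOXO"]
        final_force = ladder.forces[seq.filament_indices[-1]]
        expected = 10 ** (math.log10(final_force) + k * ladder.delta)
        assert est.grams == pytest.approx(expected, rel=1e-12)
        assert not est.censored

    @pytest.mark.parametrize("pat", ["OXOXX", "XOXOO", "OXX", "XOO", "OXOXOX"])
    def test_estimate_follows_k_formula(self, ladder, pat):
        """For any terminal pattern beginning at the reversal, the estimate
        is exactly 10**(log10(F_final) + k*delta); for near-zero k (e.g.
        OXOXX, k = 0.0835) it sits essentially on the final filament."""
        table = load_k_table()
        responses = [c == "X" for c in pat]
        seq = make_sequence(ladder, 3.0, responses)
        est = dixon_threshold(seq, ladder)
        final_force = ladder.forces[seq.filament_indices[-1]]
        assert est.grams == pytest.approx(
            final_force * 10 ** (table[pat] * ladder.delta), rel=1e-12
        )

    def test_rejects_rule_violation(self, ladder):
        seq = UpDownSequence((3, 5), (True, False), 3)
        with pytest.raises(UpDownError):
            dixon_threshold(seq, ladder)

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, c):
        """Multiplying every filament force by c multiplies the estimate by c."""
        base = build_ladder(0.4, 15, 8)
        scaled = FilamentLadder(tuple(f * c for f in base.forces))
        responses = [False, True, False, True, True, False]
        s1 = make_sequence(base, 2.0, responses)
        s2 = UpDownSequence(s1.filament_indices, s1.responses, s1.start_index)
        e1 = dixon_threshold(s1, base)
        e2 = dixon_threshold(s2, scaled)
        assert e2.grams == pytest.approx(c * e1.grams, rel=1e-9)


class TestSimulateUpdown:
    def test_step_function_limit_is_deterministic(self, ladder):
        """With an infinitely steep psychometric function the animal
        withdraws exactly when the force exceeds the latent threshold."""
        seq = simulate_updown(2.0, math.inf, ladder, rng=0)
        for i, r in zip(seq.filament_indices, seq.responses):
            assert r == (ladder.forces[i] >= 2.0)

    def test_latent_far_above_ceiling_censors(self, ladder):
        seq = simulate_updown(100.0, DEFAULT_PSYCHOMETRIC_SLOPE, ladder, rng=3)
        est = dixon_threshold(seq, ladder)
        assert est.grams == 15.0
        assert est.censored

    def test_same_seed_same_sequence(self, ladder):
        a = simulate_updown(4.0, DEFAULT_PSYCHOMETRIC_SLOPE, ladder, rng=11)
        b = simulate_updown(4.0, DEFAULT_PSYCHOMETRIC_SLOPE, ladder, rng=11)
        assert a == b

    def test_sequences_are_valid(self, ladder, rng):
        for _ in range(200):
            latent = float(rng.uniform(0.5, 14.0))
            seq = simulate_updown(latent, DEFAULT_PSYCHOMETRIC_SLOPE, ladder, rng)
            seq.validate(ladder)  # up-down rule and bounds hold
            dixon_threshold(seq, ladder)  # every pattern resolvable

    def test_round_trip_median_within_one_step(self, ladder):
        """Estimator calibration: the median estimate over many staircases
        stays within one log-step of the latent threshold."""
        rng = np.random.default_rng(7)
        for latent in (1.5, 4.0, 6.0):
            est = [
                dixon_threshold(
                    simulate_updown(latent, DEFAULT_PSYCHOMETRIC_SLOPE, ladder, rng),
                    ladder,
                ).grams
                for _ in range(1000)
            ]
            err = abs(math.log10(np.median(est)) - math.log10(latent))
            assert err < ladder.delta

    def test_censoring_monotone_in_latent(self, ladder):
        """Raising the latent threshold never lowers the mean estimate."""
        means = []
        for latent in (1.0, 2.0, 4.0, 8.0, 14.0):
            rng = np.random.default_rng(5)
            est = [
                dixon_threshold(
                    simulate_updown(latent, DEFAULT_PSYCHOMETRIC_SLOPE, ladder, rng),
                    ladder,
                ).grams
                for _ in range(400)
            ]
            means.append(np.mean(est))
        assert all(b >= a for a, b in zip(means, means[1:]))

    @pytest.mark.parametrize("bad", [(-1.0, 5.0), (2.0, 0.0)])
    def test_invalid_parameters(self, ladder, bad):
        latent, slope = bad
        with pytest.raises(ValueError):
            simulate_updown(latent, slope, ladder, rng=0)
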