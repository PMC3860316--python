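"""Synthetic observers: psychometric layer, undersampling observer, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdksim.observers import (
    EXP1_GROUP_CALIBRATION,
    EXP2_GROUP_CALIBRATION,
    LEVITT_3DOWN1UP,
    CohortSpec,
    GroupCalibration,
    MechanisticParams,
    ObserverParameterError,
    ObserverParams,
    PrimeShifts,
    apply_prime_shift,
    count_motion_votes,
    draw_cohort,
    mechanistic_respond,
    p_correct,
    respond,
)
from rdksim.stimulus import RDKParams, generate_trial


class TestPsychometricFunction:
    def test_threshold_anchor(self):
        obs = ObserverParams(alpha_pct=30.0, beta=3.0, lapse=0.0)
        assert p_correct(30.0, obs) == pytest.approx(LEVITT_3DOWN1UP, abs=1e-9)
        assert p_correct(30.0, obs) == pytest.approx(0.794, abs=1e-3)

    def test_guess_floor_and_lapse_ceiling(self):
        obs = ObserverParams(alpha_pct=30.0, lapse=0.02)
        assert p_correct(0.0, obs) == pytest.approx(0.5)
        assert p_correct(100.0, obs) >= 0.96
        assert p_correct(100.0, obs) <= 1.0 - obs.lapse + 1e-12

    def test_out_of_range_coherence_rejected(self):
        obs = ObserverParams(alpha_pct=30.0)
        with pytest.raises(ObserverParameterError):
            p_correct(120.0, obs)
        with pytest.raises(ObserverParameterError):
            p_correct(-1.0, obs)

    @settings(derandomize=True, max_examples=60)
    @given(
        alpha=st.floats(1.0, 99.0),
        beta=st.floats(0.5, 8.0),
        lapse=st.floats(0.0, 0.06),
    )
    def test_monotone_in_coherence(self, alpha, beta, lapse):
        obs = ObserverParams(alpha_pct=alpha, beta=beta, lapse=lapse)
        grid = np.linspace(0.0, 100.0, 201)
        p = p_correct(grid, obs)
        assert np.all(np.diff(p) >= -1e-12)


class TestRespond:
    def test_saturated_always_correct(self, rng):
        obs = ObserverParams(alpha_pct=1.0, beta=3.0, lapse=0.0)
        assert all(
            respond(100.0, d, obs, rng) == d
            for d in ("left", "right")
            for _ in range(100)
        )

    @pytest.mark.parametrize("bias,expected", [(0.5, 0.5), (0.46, 0.46)])
    def test_zero_coherence_guessing_follows_bias(self, bias, expected, rng):
        obs = ObserverParams(alpha_pct=30.0, bias_left=bias)
        n = 10_000
        left = sum(
            respond(0.0, "left" if rng.random() < 0.5 else "right", obs, rng) == "left"
            for _ in range(n)
        )
        se = np.sqrt(expected * (1 - expected) / n)
        assert left / n == pytest.approx(expected, abs=3 * se)

    def test_empirical_accuracy_matches_p_correct(self, rng):
        obs = ObserverParams(alpha_pct=30.0, beta=3.0, lapse=0.01)
        for coherence in (15.0, 30.0, 60.0):
            p = p_correct(coherence, obs)
            n = 10_000
            hits = 0
            for _ in range(n):
                d = "left" if rng.random() < 0.5 else "right"
                hits += respond(coherence, d, obs, rng) == d
            se = np.sqrt(p * (1 - p) / n)
            assert hits / n == pytest.approx(p, abs=3 * se)


class TestMechanisticObserver:
    def test_full_coherence_full_sampling_always_correct(self):
        mech = MechanisticParams(p_sample=1.0, internal_noise_sd=0.0)
        for direction in ("left", "right"):
            params = RDKParams(n_dots=50, coherence_pct=100.0, direction=direction,
                               n_frames=5, seed=3)
            for rep in range(20):
                rng = np.random.default_rng(rep)
                frames = generate_trial(params, rng)
                assert mechanistic_respond(frames, mech, rng) == direction

    def test_zero_coherence_near_chance(self):
        mech = MechanisticParams(p_sample=1.0, internal_noise_sd=0.0)
        params = RDKParams(n_dots=40, coherence_pct=0.0, n_frames=5)
        rng = np.random.default_rng(11)
        n = 400
        hits = sum(
            mechanistic_respond(generate_trial(params, rng), mech, rng) == "right"
            for _ in range(n)
        )
        assert hits / n == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n))

    def test_vote_total_matches_brute_force(self, rng):
        """With p_sample = 1 and no internal noise the observer is a pure
        vote counter: the total equals a hand count of displacement signs."""
        params = RDKParams(n_dots=20, coherence_pct=60.0, n_frames=6, seed=5)
        frames = generate_trial(params)
        expected = 0.0
        w = params.aperture.width_deg
        for prev, cur in zip(frames, frames[1:]):
            for d in range(cur.n_dots):
                if cur.age[d] > 0:
                    dx = cur.x[d] - prev.x[d]
                    dx = dx - w * round(dx / w)
                    expected += np.sign(dx)
        mech = MechanisticParams(p_sample=1.0, internal_noise_sd=0.0)
        assert count_motion_votes(frames, mech, rng) == pytest.approx(expected)

    def test_accuracy_monotone_in_p_sample_and_integration(self):
        """Monte-Carlo sweep: more sampling and more pooled transitions can
        only help direction discrimination."""
        def accuracy(p_sample, integration, seed):
            mech = MechanisticParams(p_sample=p_sample, internal_noise_sd=8.0,
                                     integration_frames=integration)
            params = RDKParams(n_dots=100, coherence_pct=40.0, direction="right",
                               n_frames=8)
            rng = np.random.default_rng(seed)
            n = 300
            return sum(
                mechanistic_respond(generate_trial(params, rng), mech, rng) == "right"
                for _ in range(n)
            ) / n

        a_low, a_mid, a_high = (accuracy(p, None, 21) for p in (0.05, 0.3, 1.0))
        assert a_low <= a_mid + 0.05 <= a_high + 0.10
        a_short, a_long = (accuracy(0.3, k, 22) for k in (2, 7))
        assert a_short <= a_long + 0.05

    def test_too_few_frames_rejected(self, rng):
        frames = generate_trial(RDKParams(n_dots=10, n_frames=1, seed=0))
        with pytest.raises(ObserverParameterError):
            mechanistic_respond(frames, MechanisticParams(), rng)


class TestPrimeShifts:
    def test_additive_shift_examples(self):
        obs = ObserverParams(alpha_pct=20.0)
        dys = EXP2_GROUP_CALIBRATION["dyslexia"].prime_shifts
        ctl = EXP2_GROUP_CALIBRATION["control"].prime_shifts
        assert apply_prime_shift(obs, dys, "same").alpha_pct == pytest.approx(32.63)
        assert apply_prime_shift(obs, ctl, "opposite").alpha_pct == pytest.approx(17.97)
        assert apply_prime_shift(obs, dys, "static").alpha_pct == pytest.approx(20.0)

    def test_shift_ordering_same_static_opposite(self):
        for group in ("control", "dyslexia"):
            shifts = EXP2_GROUP_CALIBRATION[group].prime_shifts
            obs = ObserverParams(alpha_pct=20.0)
            a = {c: apply_prime_shift(obs, shifts, c).alpha_pct
                 for c in ("same", "static", "opposite")}
            assert a["same"] > a["static"] > a["opposite"]

    def test_shift_clamped_into_range(self):
        obs = ObserverParams(alpha_pct=1.0)
        shifts = PrimeShifts(delta_same_pct=150.0, delta_opposite_pct=-50.0)
        assert apply_prime_shift(obs, shifts, "same").alpha_pct == 100.0
        assert apply_prime_shift(obs, shifts, "opposite").alpha_pct > 0.0


class TestCohort:
    def test_zero_sd_collapses_to_mean(self):
        groups = {
            "control": GroupCalibration(32.74, 0.0, PrimeShifts(7.87, -2.03)),
            "dyslexia": GroupCalibration(47.09, 0.0, PrimeShifts(12.63, -2.76)),
        }
        cohort = draw_cohort(CohortSpec(n_per_group=5, groups=groups, seed=1))
        by_group = {g: [o.alpha_pct for o in cohort if o.group == g]
                    for g in ("control", "dyslexia")}
        assert by_group["control"] == pytest.approx([32.74] * 5)
        assert by_group["dyslexia"] == pytest.approx([47.09] * 5)

    def test_sample_mean_recovers_group_mean(self):
        spec = CohortSpec(n_per_group=10_000, groups=EXP1_GROUP_CALIBRATION, seed=2)
        cohort = draw_cohort(spec)
        for group in ("control", "dyslexia"):
            target = EXP1_GROUP_CALIBRATION[group].alpha_mean_pct
            mean = np.mean([o.alpha_pct for o in cohort if o.group == group])
            assert mean == pytest.approx(target, rel=0.01)

    def test_reproducible_under_seed(self):
        spec = CohortSpec(n_per_group=6, seed=9)
        a = [o.alpha_pct for o in draw_cohort(spec)]
        b = [o.alpha_pct for o in draw_cohort(spec)]
        assert a == b
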