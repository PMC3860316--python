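"""Adaptive staircase: update rule, reversal logging, estimation, catch trials."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from rdksim.observers import ObserverParams, PsychometricObserver
from rdksim.staircase import (
    EstimationError,
    StaircaseConfig,
    StaircaseState,
    TrialRecord,
    combine_blocks,
    estimate_from_blocks,
    estimate_threshold,
    response_bias,
    run_block,
    update,
)


class _FixedObserver:
    """Deterministic observer: always correct or always incorrect."""

    def __init__(self, correct: bool):
        self.correct = correct

    def respond_trial(self, coherence_pct, direction, stim_params, rng):
        if self.correct:
            return direction
        return "left" if direction == "right" else "right"


class TestUpdateRule:
    def test_third_correct_halves(self):
        cfg = StaircaseConfig()
        state = StaircaseState(current_coherence_pct=50.0, consecutive_correct=2)
        update(state, True, cfg)
        assert state.current_coherence_pct == 25.0
        assert state.consecutive_correct == 0

    def test_incorrect_doubles(self):
        cfg = StaircaseConfig()
        state = StaircaseState(current_coherence_pct=25.0)
        update(state, False, cfg)
        assert state.current_coherence_pct == 50.0

    def test_doubling_clamped_at_cap(self):
        cfg = StaircaseConfig()
        state = StaircaseState(current_coherence_pct=60.0)
        update(state, False, cfg)
        assert state.current_coherence_pct == 100.0

    def test_halving_clamped_at_floor(self):
        cfg = StaircaseConfig(coherence_floor_pct=0.1)
        state = StaircaseState(current_coherence_pct=0.15, consecutive_correct=2)
        update(state, True, cfg)
        assert state.current_coherence_pct == 0.1

    def test_reversal_logged_at_prestep_value(self):
        """Descend 50 -> 25 -> 12.5, then an error flips direction: the
        reversal records 12.5, the coherence at which the flip occurred."""
        cfg = StaircaseConfig()
        state = StaircaseState(current_coherence_pct=50.0)
        for _ in range(6):
            update(state, True, cfg)
        assert state.current_coherence_pct == 12.5
        assert state.reversals == []
        update(state, False, cfg)
        assert state.reversals == [12.5]
        assert state.current_coherence_pct == 25.0
        for _ in range(3):
            update(state, True, cfg)
        assert state.reversals == [12.5, 25.0]


class TestEstimation:
    def test_geometric_mean_of_reversals(self):
        assert estimate_threshold([40, 20, 40, 20, 40, 20, 40, 20]) == pytest.approx(
            28.28, abs=0.005
        )

    def test_idempotent_on_constant_reversals(self):
        assert estimate_threshold([17.5] * 6) == pytest.approx(17.5)

    def test_block_combination(self):
        assert combine_blocks([30.0, 40.0]) == pytest.approx(34.64, abs=0.005)

    def test_discard_first_k(self):
        assert estimate_threshold([100.0, 20.0, 20.0], discard_first_k=1) == pytest.approx(20.0)

    def test_empty_reversals_error(self):
        with pytest.raises(EstimationError):
            estimate_threshold([])


class TestResponseBias:
    def test_percentage_arithmetic(self):
        trials = [
            TrialRecord(i, 1.0, "right", "left" if i < 23 else "right", False, True)
            for i in range(50)
        ]
        assert response_bias(trials) == pytest.approx(46.0)
        all_right = [TrialRecord(i, 1.0, "right", "right", True, True) for i in range(50)]
        assert response_bias(all_right) == 0.0

    def test_no_catch_trials_error(self):
        with pytest.raises(EstimationError):
            response_bias([TrialRecord(0, 50.0, "left", "left", True, False)])

    def test_unbiased_observer_near_fifty(self, rng):
        obs = PsychometricObserver(ObserverParams(alpha_pct=30.0, bias_left=0.5))
        cfg = StaircaseConfig()
        trials = []
        for _ in range(60):
            _, block = run_block(obs, None, cfg, rng)
            trials.extend(block.trials)
        n_catch = sum(t.is_catch for t in trials)
        assert n_catch >= 200
        assert response_bias(trials) == pytest.approx(50.0, abs=4.0)


class TestRunBlock:
    def test_perfect_observer_descends_to_floor(self, rng):
        cfg = StaircaseConfig(max_trials=120)
        _, block = run_block(_FixedObserver(True), None, cfg, rng)
        assert not block.converged  # never a direction flip
        coherences = [t.coherence_pct for t in block.trials if not t.is_catch]
        assert min(coherences) == cfg.coherence_floor_pct
        non_increasing = all(b <= a for a, b in zip(coherences, coherences[1:]))
        assert non_increasing

    def test_always_incorrect_pinned_at_cap(self, rng):
        cfg = StaircaseConfig(max_trials=60)
        _, block = run_block(_FixedObserver(False), None, cfg, rng)
        coherences = [t.coherence_pct for t in block.trials if not t.is_catch]
        assert coherences[-1] == cfg.coherence_cap_pct
        assert not block.converged

    def test_catch_cadence_every_five_trials(self, rng):
        obs = PsychometricObserver(ObserverParams(alpha_pct=30.0))
        cfg = StaircaseConfig()
        for _ in range(40):
            _, block = run_block(obs, None, cfg, rng)
            flags = [t.is_catch for t in block.trials]
            for s in range(0, len(flags) - 4):
                assert any(flags[s : s + 5]), "5 consecutive trials without a catch"

    def test_catch_trials_never_touch_staircase(self, rng):
        """Replaying only the non-catch outcomes through the update rule
        reproduces the staircase coherence sequence exactly."""
        obs = PsychometricObserver(ObserverParams(alpha_pct=25.0))
        cfg = StaircaseConfig()
        for _ in range(10):
            _, block = run_block(obs, None, cfg, rng)
            replay = StaircaseState(current_coherence_pct=cfg.start_coherence_pct)
            for t in block.trials:
                if t.is_catch:
                    assert t.coherence_pct == cfg.catch_coherence_pct
                    continue
                assert t.coherence_pct == replay.current_coherence_pct
                update(replay, t.correct, cfg)
            assert replay.reversals == block.reversals

    @pytest.mark.parametrize("beta", [1.5, 3.0, 5.0])
    def test_convergence_accuracy_near_79pct(self, beta):
        """Long-run accuracy at convergence sits in [0.76, 0.82] across
        psychometric slopes: the three-down/one-up equilibrium."""
        obs = PsychometricObserver(ObserverParams(alpha_pct=30.0, beta=beta, lapse=0.01))
        cfg = StaircaseConfig()
        rng = np.random.default_rng(int(beta * 10))
        accs = []
        for _ in range(150):
            _, block = run_block(obs, None, cfg, rng)
            tail = [t.correct for t in block.trials if not t.is_catch][-20:]
            accs.append(np.mean(tail))
        assert 0.76 <= np.mean(accs) <= 0.82

    def test_larger_alpha_larger_estimates(self, rng):
        alphas = rng.uniform(10, 70, 30)
        ests = []
        cfg = StaircaseConfig()
        for a in alphas:
            obs = PsychometricObserver(ObserverParams(alpha_pct=float(a)))
            blocks = [run_block(obs, None, cfg, rng)[1] for _ in range(2)]
            ests.append(estimate_from_blocks(blocks).combined_pct)
        assert spearmanr(alphas, ests).statistic > 0.0
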