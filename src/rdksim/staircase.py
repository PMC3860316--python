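"""Three-down/one-up adaptive coherence staircase.

Coherence is halved after three consecutive correct responses and doubled
after each error, clamped to [floor, cap].  With symmetric logarithmic
steps this rule converges where p³ = 1/2, i.e. at ~79.4% correct.  A
*reversal* is a trial at which the step direction flips; the staircase
terminates after a configured number of reversals and the threshold is the
geometric mean of the reversal coherences (the pre-step value at each
flip).  Catch trials at 1% coherence are interleaved at least once every
five trials to estimate response bias; they never touch the staircase
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .stimulus import RDKParams

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "BlockResult",
    "ThresholdEstimate",
    "EstimationError",
    "update",
    "run_block",
    "estimate_threshold",
    "combine_blocks",
    "response_bias",
    "estimate_from_blocks",
    "trial_frame",
]


class EstimationError(ValueError):
    """Raised when a threshold cannot be estimated (e.g. no reversals)."""


@dataclass(frozen=True)
class StaircaseConfig:
    start_coherence_pct: float = 50.0
    n_reversals: int = 8
    n_down: int = 3
    step_down_factor: float = 0.5
    step_up_factor: float = 2.0
    coherence_cap_pct: float = 100.0
    coherence_floor_pct: float = 0.1
    catch_coherence_pct: float = 1.0
    catch_window: int = 5
    max_trials: int = 400
    discard_first_k_reversals: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.start_coherence_pct <= self.coherence_cap_pct):
            raise ValueError("start coherence must lie in (0, cap]")
        if self.n_reversals < 2:
            raise ValueError("n_reversals must be >= 2")
        if not (0.0 < self.coherence_floor_pct < self.coherence_cap_pct):
            raise ValueError("floor must lie in (0, cap)")
        if not (0.0 < self.step_down_factor < 1.0 < self.step_up_factor):
            raise ValueError("need step_down_factor < 1 < step_up_factor")
        if self.catch_window < 1:
            raise ValueError("catch_window must be >= 1")


@dataclass
class StaircaseState:
    """Mutable adaptive track."""

    current_coherence_pct: float
    consecutive_correct: int = 0
    last_direction: str = "none"  # {"down", "up", "none"}
    reversals: list[float] = field(default_factory=list)
    n_updates: int = 0


@dataclass(frozen=True)
class TrialRecord:
    index: int
    coherence_pct: float
    direction: str
    response: str
    correct: bool
    is_catch: bool


def update(state: StaircaseState, correct: bool, cfg: StaircaseConfig) -> StaircaseState:
    """Apply one (non-catch) trial outcome to the staircase, in place.

    A reversal is logged whenever the step direction flips, recording the
    coherence at which the flip occurred (the pre-step value).
    """

    def _step(direction: str) -> None:
        pre = state.current_coherence_pct
        if state.last_direction != "none" and state.last_direction != direction:
            state.reversals.append(pre)
        factor = cfg.step_down_factor if direction == "down" else cfg.step_up_factor
        new = pre * factor
        state.current_coherence_pct = min(
            max(new, cfg.coherence_floor_pct), cfg.coherence_cap_pct
        )
        state.last_direction = direction
        state.consecutive_correct = 0

    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= cfg.n_down:
            _step("down")
    else:
        _step("up")
    state.n_updates += 1
    return state


def estimate_threshold(reversals: Sequence[float], discard_first_k: int = 0) -> float:
    """Geometric mean of the (optionally trimmed) reversal coherences."""
    vals = list(reversals)[discard_first_k:]
    if not vals:
        raise EstimationError("no reversal values to estimate a threshold from")
    return float(gmean(vals))


def combine_blocks(block_thresholds: Sequence[float]) -> float:
    """Combine per-block thresholds by their geometric mean."""
    if not list(block_thresholds):
        raise EstimationError("no block thresholds to combine")
    return float(gmean(list(block_thresholds)))


def response_bias(trials: Sequence[TrialRecord]) -> float:
    """Percentage of "left" responses on catch trials."""
    catch = [t for t in trials if t.is_catch]
    if not catch:
        raise EstimationError("no catch trials in the log")
    n_left = sum(t.response == "left" for t in catch)
    return 100.0 * n_left / len(catch)


@dataclass(frozen=True)
class BlockResult:
    threshold_pct: float
    reversals: list[float]
    trials: list[TrialRecord]
    converged: bool

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class ThresholdEstimate:
    block_thresholds: list[float]
    combined_pct: float
    response_bias_pct: float


def estimate_from_blocks(blocks: Sequence[BlockResult]) -> ThresholdEstimate:
    """Combine blocks: geometric mean of block thresholds; bias pooled over
    all catch trials of all blocks."""
    thresholds = [b.threshold_pct for b in blocks]
    all_trials = [t for b in blocks for t in b.trials]
    return ThresholdEstimate(
        block_thresholds=thresholds,
        combined_pct=combine_blocks(thresholds),
        response_bias_pct=response_bias(all_trials),
    )


def run_block(
    observer,
    stim_params: RDKParams | None,
    cfg: StaircaseConfig,
    rng: np.random.Generator,
) -> tuple[StaircaseState, BlockResult]:
    """Run one staircase block to ``cfg.n_reversals`` reversals.

    ``observer`` must expose ``respond_trial(coherence_pct, direction,
    stim_params, rng) -> "left" | "right"``.  Stimulus direction is drawn
    uniformly per trial.  Catch trials (at ``catch_coherence_pct``) occupy
    one uniformly drawn slot per five-trial window, constrained so that any
    five consecutive trials contain at least one; their responses are
    logged but never update the staircase.  Blocks that fail to reach the
    reversal count within ``max_trials`` are flagged, not raised.
    """
    state = StaircaseState(current_coherence_pct=cfg.start_coherence_pct)
    trials: list[TrialRecord] = []
    w = cfg.catch_window
    catch_slot = -1
    last_catch = -1

    trial = 0
    while len(state.reversals) < cfg.n_reversals and trial < cfg.max_trials:
        if trial % w == 0:
            # draw this window's catch slot; keep consecutive catch indices
            # no more than one window apart so every w consecutive trials
            # contain a catch trial
            lo = trial
            hi = min(trial + w - 1, last_catch + w) if last_catch >= 0 else trial + w - 1
            catch_slot = int(rng.integers(lo, hi + 1))
        is_catch = trial == catch_slot
        direction = "left" if rng.random() < 0.5 else "right"
        coherence = cfg.catch_coherence_pct if is_catch else state.current_coherence_pct
        response = observer.respond_trial(coherence, direction, stim_params, rng)
        correct = response == direction
        trials.append(TrialRecord(trial, coherence, direction, response, correct, is_catch))
        if is_catch:
            last_catch = trial
        else:
            update(state, correct, cfg)
        trial += 1

    converged = len(state.reversals) >= cfg.n_reversals
    if converged:
        threshold = estimate_threshold(state.reversals, cfg.discard_first_k_reversals)
    else:
        # pathological observer: report the last coherence level rather than hang
        threshold = (
            estimate_threshold(state.reversals, 0)
            if state.reversals
            else state.current_coherence_pct
        )
    return state, BlockResult(threshold, list(state.reversals), trials, converged)


def trial_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial log as a tidy DataFrame."""
    return pd.DataFrame(
        {
            "trial": [t.index for t in trials],
            "coherence_pct": [t.coherence_pct for t in trials],
            "direction": [t.direction for t in trials],
            "response": [t.response for t in trials],
            "correct": [t.correct for t in trials],
            "is_catch": [t.is_catch for t in trials],
        }
    )
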