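"""Experiment drivers and summary statistics.

Two simulated study designs are assembled from the stimulus engine, the
synthetic observers and the adaptive staircase:

* **Experiment 1** — 2 dot densities (400 vs 100 dots in a 6° × 6°
  aperture) × 2 animation-frame counts (5 vs 8) × 2 reader groups; two
  staircase blocks per condition starting at 50% coherence, 8 reversals.
  The derived summary of interest is *temporal recruitment*: the drop in
  coherence threshold from 5-frame to 8-frame presentations, per density.
* **Experiment 2** — coherent prime (same/opposite direction) vs
  stationary prime × 2 groups; 300 dots in a 13.35° × 13.35° aperture,
  three-frame dot lifetime, 10-frame (160 ms) test preceded by a 96 ms
  prime and a 32 ms blank; staircases start at 25% coherence, 6 reversals.
  The derived summary is the per-participant *difference score* of each
  primed threshold against the static-prime baseline.

Descriptive statistics only (means, SDs, t-based 95% CIs); exported tables
are structured so inferential analyses can be run externally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .observers import (
    EXP1_GROUP_CALIBRATION,
    EXP2_GROUP_CALIBRATION,
    MECHANISTIC_DEFAULTS,
    CohortSpec,
    MechanisticObserver,
    MechanisticParams,
    ObserverParams,
    PsychometricObserver,
    apply_prime_shift,
    draw_cohort,
)
from .staircase import StaircaseConfig, estimate_from_blocks, run_block
from .stimulus import Aperture, PrimeSpec, RDKParams, prime_params

__all__ = [
    "ConditionSpec",
    "ExperimentResult",
    "SummaryTable",
    "EXP1_STAIRCASE",
    "EXP2_STAIRCASE",
    "EXP2_TEST_PARAMS",
    "EXP1_CONDITIONS",
    "EXP2_CONDITIONS",
    "exp1_stim_params",
    "exp1_condition_offsets",
    "exp1_cohort_spec",
    "exp2_cohort_spec",
    "run_experiment1",
    "run_experiment2",
    "summarize",
    "prime_difference_scores",
    "recruitment_reduction",
    "plot_thresholds",
]

EXP1_STAIRCASE = StaircaseConfig(start_coherence_pct=50.0, n_reversals=8)
EXP2_STAIRCASE = StaircaseConfig(start_coherence_pct=25.0, n_reversals=6)

#: Test stimulus of the priming experiment.  Total timings (96/32/160 ms
#: with 6/2/10 frames) imply a nominal 16 ms frame; the simulation uses
#: nominal milliseconds throughout.
EXP2_TEST_PARAMS = RDKParams(
    n_dots=300,
    aperture=Aperture(13.35, 13.35),
    frame_duration_ms=16.0,
    n_frames=10,
    dot_lifetime_frames=3,
    coherence_pct=25.0,
)

EXP2_PRIME_SPECS: Mapping[str, PrimeSpec] = {
    "same": PrimeSpec("coherent_same", 96.0, 32.0),
    "opposite": PrimeSpec("coherent_opposite", 96.0, 32.0),
    "static": PrimeSpec("stationary", 96.0, 32.0),
}

EXP1_CONDITIONS = (("high", 5), ("high", 8), ("low", 5), ("low", 8))
EXP2_CONDITIONS = ("same", "opposite", "static")

#: Recruitment calibration: drop in threshold (coherence points) from 5 to
#: 8 frames at high density, per group; zero at low density.
EXP1_RECRUITMENT_PTS: Mapping[str, float] = {"control": 6.1, "dyslexia": 7.5}

#: Half the density main effect (points); low-density conditions sit this
#: far above the group marginal mean and high-density ones this far below.
EXP1_DENSITY_SPLIT_PTS = 5.0


def exp1_stim_params(density: str, n_frames: int) -> RDKParams:
    """Stimulus recipe of one density × frames cell (400 or 100 dots)."""
    if density not in ("high", "low"):
        raise ValueError("density must be 'high' or 'low'")
    return RDKParams(n_dots=400 if density == "high" else 100, n_frames=n_frames)


def exp1_condition_offsets(group: str) -> dict[tuple[str, int], float]:
    """Additive per-condition threshold offsets around the group mean.

    Chosen so that the cell means average to the group marginal mean, the
    high-density 5→8-frame drop equals the calibrated recruitment value,
    the low-density cells show no recruitment, and the density main effect
    splits symmetrically.
    """
    r = EXP1_RECRUITMENT_PTS[group]
    d = EXP1_DENSITY_SPLIT_PTS
    return {
        ("low", 5): +d,
        ("low", 8): +d,
        ("high", 5): -d + r / 2.0,
        ("high", 8): -d - r / 2.0,
    }


def exp1_cohort_spec(n_per_group: int = 20, seed: int | None = None) -> CohortSpec:
    return CohortSpec(n_per_group=n_per_group, groups=EXP1_GROUP_CALIBRATION, seed=seed)


def exp2_cohort_spec(n_per_group: int = 10, seed: int | None = None) -> CohortSpec:
    return CohortSpec(n_per_group=n_per_group, groups=EXP2_GROUP_CALIBRATION, seed=seed)


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of a design: its factors, stimulus and staircase recipes."""

    experiment: str  # {"exp1", "exp2"}
    label: str
    stim_params: RDKParams
    staircase_cfg: StaircaseConfig
    density: str | None = None
    n_frames: int | None = None
    prime: str | None = None

    def __post_init__(self) -> None:
        if self.experiment == "exp1":
            if self.density not in ("high", "low") or self.n_frames not in (5, 8):
                raise ValueError("exp1 condition requires density in {high, low}, frames in {5, 8}")
        elif self.experiment == "exp2":
            if self.prime not in EXP2_CONDITIONS:
                raise ValueError(f"exp2 condition requires prime in {EXP2_CONDITIONS}")
        else:
            raise ValueError("experiment must be 'exp1' or 'exp2'")


@dataclass
class ExperimentResult:
    """Tidy per-participant × condition threshold table plus trial logs."""

    experiment: str
    thresholds: pd.DataFrame
    trials: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def _latin_square_order(i: int, conditions: Sequence) -> list:
    """Cyclic Latin square: participant i starts at condition i mod k."""
    k = len(conditions)
    shift = i % k
    return list(conditions[shift:]) + list(conditions[:shift])


def _clamped_alpha(alpha: float) -> float:
    return min(max(alpha, 1e-3), 100.0)


def _run_participant_condition(
    observer,
    stim_params: RDKParams | None,
    cfg: StaircaseConfig,
    rng: np.random.Generator,
    n_blocks: int = 2,
):
    blocks = []
    seeds = []
    for _ in range(n_blocks):
        block_seed = int(rng.integers(0, 2**31))
        seeds.append(block_seed)
        _, block = run_block(observer, stim_params, cfg, np.random.default_rng(block_seed))
        blocks.append(block)
    return blocks, seeds


def _collect_trials(rows: list[dict], blocks, participant, group, label) -> None:
    from .staircase import trial_frame

    for b_idx, block in enumerate(blocks, start=1):
        df = trial_frame(block.trials)
        df.insert(0, "participant", participant)
        df.insert(1, "group", group)
        df.insert(2, "condition", label)
        df.insert(3, "block", b_idx)
        rows.append(df)


def run_experiment1(
    cohort: CohortSpec | None = None,
    rng: np.random.Generator | None = None,
    *,
    observer_kind: str = "psychometric",
    mech_by_group: Mapping[str, MechanisticParams] | None = None,
    n_blocks: int = 2,
    keep_trials: bool = False,
) -> ExperimentResult:
    """Simulate the density × animation-frames design.

    Each participant completes ``n_blocks`` staircase blocks in each of the
    four conditions; condition order is counterbalanced with a cyclic Latin
    square across participants.  With the psychometric observer, each
    condition's effective threshold is the participant's baseline alpha
    plus the calibrated condition offset; with the mechanistic observer the
    condition differences emerge from the dot stimuli themselves.
    """
    if cohort is None:
        cohort = exp1_cohort_spec()
    if rng is None:
        rng = np.random.default_rng(cohort.seed)
    if observer_kind not in ("psychometric", "mechanistic"):
        raise ValueError("observer_kind must be 'psychometric' or 'mechanistic'")
    mech_by_group = mech_by_group or MECHANISTIC_DEFAULTS

    participants = draw_cohort(cohort, rng)
    rows = []
    trial_rows: list[pd.DataFrame] = []
    for i, obs in enumerate(participants):
        order = _latin_square_order(i, EXP1_CONDITIONS)
        per_condition = {}
        for density, n_frames in order:
            stim = exp1_stim_params(density, n_frames)
            if observer_kind == "psychometric":
                offset = exp1_condition_offsets(obs.group)[(density, n_frames)]
                eff = replace(obs, alpha_pct=_clamped_alpha(obs.alpha_pct + offset))
                runner = PsychometricObserver(eff)
            else:
                runner = MechanisticObserver(mech_by_group[obs.group])
            blocks, seeds = _run_participant_condition(
                runner, stim, EXP1_STAIRCASE, rng, n_blocks
            )
            per_condition[(density, n_frames)] = (blocks, seeds)
        for density, n_frames in EXP1_CONDITIONS:
            blocks, seeds = per_condition[(density, n_frames)]
            est = estimate_from_blocks(blocks)
            label = f"{density}_{n_frames}f"
            rows.append(
                {
                    "participant": i,
                    "group": obs.group,
                    "condition": label,
                    "density": density,
                    "n_frames": n_frames,
                    "block1_threshold_pct": est.block_thresholds[0],
                    "block2_threshold_pct": est.block_thresholds[-1],
                    "combined_threshold_pct": est.combined_pct,
                    "response_bias_pct": est.response_bias_pct,
                    "converged": all(b.converged for b in blocks),
                    "block_seeds": ";".join(str(s) for s in seeds),
                    "true_alpha_pct": obs.alpha_pct,
                }
            )
            if keep_trials:
                _collect_trials(trial_rows, blocks, i, obs.group, label)
    thresholds = pd.DataFrame(rows)
    trials = pd.concat(trial_rows, ignore_index=True) if trial_rows else None
    return ExperimentResult("exp1", thresholds, trials, {"observer": observer_kind})


def exp2_trial_composition(condition: str) -> dict:
    """Stimulus composition of one priming-experiment trial: the prime
    recipe, the blank ISI frame count and the test recipe.  This is what a
    frame-reading (mechanistic) observer would be shown."""
    spec = EXP2_PRIME_SPECS[condition]
    return {
        "prime_spec": spec,
        "prime_params": prime_params(spec, EXP2_TEST_PARAMS),
        "isi_frames": int(round(spec.isi_ms / EXP2_TEST_PARAMS.frame_duration_ms)),
        "test_params": EXP2_TEST_PARAMS,
    }


def run_experiment2(
    cohort: CohortSpec | None = None,
    rng: np.random.Generator | None = None,
    *,
    n_blocks: int = 2,
    keep_trials: bool = False,
) -> ExperimentResult:
    """Simulate the coherent-prime contrast design.

    Each participant completes ``n_blocks`` blocks in each prime condition
    (same / opposite / static), in a per-participant random order.  The
    effective threshold per condition is the baseline alpha shifted by the
    group's calibrated prime shift (static = baseline by definition).
    """
    if cohort is None:
        cohort = exp2_cohort_spec()
    if rng is None:
        rng = np.random.default_rng(cohort.seed)
    participants = draw_cohort(cohort, rng)
    rows = []
    trial_rows: list[pd.DataFrame] = []
    for i, obs in enumerate(participants):
        order = [EXP2_CONDITIONS[j] for j in rng.permutation(len(EXP2_CONDITIONS))]
        per_condition = {}
        for condition in order:
            shifts = cohort.groups[obs.group].prime_shifts
            eff = apply_prime_shift(obs, shifts, condition)
            runner = PsychometricObserver(eff)
            blocks, seeds = _run_participant_condition(
                runner, EXP2_TEST_PARAMS, EXP2_STAIRCASE, rng, n_blocks
            )
            per_condition[condition] = (blocks, seeds)
        for condition in EXP2_CONDITIONS:
            blocks, seeds = per_condition[condition]
            est = estimate_from_blocks(blocks)
            rows.append(
                {
                    "participant": i,
                    "group": obs.group,
                    "condition": condition,
                    "block1_threshold_pct": est.block_thresholds[0],
                    "block2_threshold_pct": est.block_thresholds[-1],
                    "combined_threshold_pct": est.combined_pct,
                    "response_bias_pct": est.response_bias_pct,
                    "converged": all(b.converged for b in blocks),
                    "block_seeds": ";".join(str(s) for s in seeds),
                    "true_alpha_pct": obs.alpha_pct,
                }
            )
            if keep_trials:
                _collect_trials(trial_rows, blocks, i, obs.group, condition)
    thresholds = pd.DataFrame(rows)
    trials = pd.concat(trial_rows, ignore_index=True) if trial_rows else None
    metadata = {"composition": {c: exp2_trial_composition(c) for c in EXP2_CONDITIONS}}
    return ExperimentResult("exp2", thresholds, trials, metadata)


# ---------------------------------------------------------------------------
# summaries

@dataclass
class SummaryTable:
    """Descriptive summaries: cell statistics plus design-specific derived
    quantities (recruitment reductions or prime difference scores)."""

    cell_stats: pd.DataFrame
    recruitment: pd.DataFrame | None = None
    prime_effects: pd.DataFrame | None = None


def _cell_stats(thresholds: pd.DataFrame) -> pd.DataFrame:
    recs = []
    for (group, condition), cell in thresholds.groupby(["group", "condition"]):
        vals = cell["combined_threshold_pct"].to_numpy()
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n > 1 else float("nan")
        if n > 1 and math.isfinite(sd):
            half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        else:
            half = float("nan")
        recs.append(
            {
                "group": group,
                "condition": condition,
                "n": n,
                "mean_pct": mean,
                "sd_pct": sd,
                "ci95_low_pct": mean - half,
                "ci95_high_pct": mean + half,
            }
        )
    return pd.DataFrame(recs)


def recruitment_reduction(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Temporal recruitment per group × density: mean 5-frame threshold
    minus mean 8-frame threshold, in coherence points."""
    recs = []
    for (group, density), cell in thresholds.groupby(["group", "density"]):
        m5 = cell.loc[cell["n_frames"] == 5, "combined_threshold_pct"].mean()
        m8 = cell.loc[cell["n_frames"] == 8, "combined_threshold_pct"].mean()
        recs.append(
            {
                "group": group,
                "density": density,
                "mean_5f_pct": float(m5),
                "mean_8f_pct": float(m8),
                "reduction_pts": float(m5 - m8),
            }
        )
    return pd.DataFrame(recs)


def prime_difference_scores(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Per-participant primed-minus-static difference scores (points)."""
    wide = thresholds.pivot_table(
        index=["participant", "group"], columns="condition", values="combined_threshold_pct"
    ).reset_index()
    wide["diff_same_pts"] = wide["same"] - wide["static"]
    wide["diff_opposite_pts"] = wide["opposite"] - wide["static"]
    return wide[["participant", "group", "diff_same_pts", "diff_opposite_pts"]]


def summarize(result: ExperimentResult) -> SummaryTable:
    """Descriptive summary of an experiment run.

    Requires at least 2 participants per group for SDs/CIs to be defined.
    """
    thresholds = result.thresholds
    cell = _cell_stats(thresholds)
    recruitment = prime_effects = None
    if result.experiment == "exp1":
        recruitment = recruitment_reduction(thresholds)
    else:
        diffs = prime_difference_scores(thresholds)
        recs = []
        for group, g in diffs.groupby("group"):
            for col, label in (("diff_same_pts", "same"), ("diff_opposite_pts", "opposite")):
                vals = g[col].to_numpy()
                recs.append(
                    {
                        "group": group,
                        "prime": label,
                        "mean_diff_pts": float(np.mean(vals)),
                        "sd_diff_pts": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                        "n": len(vals),
                    }
                )
        prime_effects = pd.DataFrame(recs)
    return SummaryTable(cell, recruitment, prime_effects)


def plot_thresholds(summary: SummaryTable, path: str) -> None:
    """Bar chart of mean thresholds by condition and group, with 95% CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cell = summary.cell_stats
    conditions = sorted(cell["condition"].unique())
    groups = sorted(cell["group"].unique())
    x = np.arange(len(conditions))
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    for gi, group in enumerate(groups):
        sub = cell[cell["group"] == group].set_index("condition").reindex(conditions)
        err = (sub["ci95_high_pct"] - sub["mean_pct"]).to_numpy()
        ax.bar(
            x + gi * width,
            sub["mean_pct"].to_numpy(),
            width,
            yerr=np.where(np.isfinite(err), err, 0.0),
            capsize=3,
            label=group,
        )
    ax.set_xticks(x + width * (len(groups) - 1) / 2)
    ax.set_xticklabels(conditions, rotation=30, ha="right")
    ax.set_ylabel("coherence threshold (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
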