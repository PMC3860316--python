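"""Configuration, named parameter sets, and file export.

Run configurations are plain YAML; unknown keys are rejected with the
offending key path so typos never silently fall back to defaults.  Result
tables are CSV (the auditable psychophysics convention) with a short
comment header embedding the master seed, a config hash and the package
version; existing files are never appended to or overwritten — a version
suffix is added instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pipeline import EXP1_STAIRCASE, EXP2_STAIRCASE, ExperimentResult, SummaryTable
from .staircase import StaircaseConfig
from .stimulus import Aperture, DotField, RDKParams

__all__ = [
    "ConfigError",
    "RunConfig",
    "PARAM_SETS",
    "load_config",
    "resolve_staircase_config",
    "write_results",
    "read_table",
    "export_frames_csv",
    "export_frames_png",
]


class ConfigError(ValueError):
    """Raised for unparsable configs, unknown keys, or invariant violations."""


#: Named stimulus parameter sets transcribed from the two study designs.
PARAM_SETS: dict[str, RDKParams] = {
    "exp1_high_density": RDKParams(n_dots=400),
    "exp1_low_density": RDKParams(n_dots=100),
    "exp2_test": RDKParams(
        n_dots=300,
        aperture=Aperture(13.35, 13.35),
        frame_duration_ms=16.0,
        n_frames=10,
        dot_lifetime_frames=3,
        coherence_pct=25.0,
    ),
    "exp2_prime_same": RDKParams(
        n_dots=300,
        aperture=Aperture(13.35, 13.35),
        frame_duration_ms=16.0,
        n_frames=6,
        dot_lifetime_frames=3,
        coherence_pct=100.0,
        direction="right",
    ),
    "exp2_prime_opposite": RDKParams(
        n_dots=300,
        aperture=Aperture(13.35, 13.35),
        frame_duration_ms=16.0,
        n_frames=6,
        dot_lifetime_frames=3,
        coherence_pct=100.0,
        direction="left",
    ),
    "exp2_prime_static": RDKParams(
        n_dots=300,
        aperture=Aperture(13.35, 13.35),
        frame_duration_ms=16.0,
        n_frames=6,
        dot_lifetime_frames=3,
        coherence_pct=0.0,
        direction="static",
    ),
}


@dataclass
class RunConfig:
    """Resolved run configuration with paper-derived defaults."""

    experiment: str = "exp1"
    observer: str = "psychometric"
    n_per_group: int = 10
    seed: int = 0
    out_dir: str = "results"
    stimulus_set: str = "exp1_high_density"
    stimulus: dict = field(default_factory=dict)
    staircase: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ConfigError("experiment: must be 'exp1' or 'exp2'")
        if self.observer not in ("psychometric", "mechanistic"):
            raise ConfigError("observer: must be 'psychometric' or 'mechanistic'")
        if self.stimulus_set not in PARAM_SETS:
            raise ConfigError(
                f"stimulus_set: unknown parameter set {self.stimulus_set!r}; "
                f"known sets: {sorted(PARAM_SETS)}"
            )


_STIM_KEYS = {f.name for f in dataclasses.fields(RDKParams)} - {"aperture"} | {
    "aperture_width_deg",
    "aperture_height_deg",
    "aperture_shape",
}
_STAIR_KEYS = {f.name for f in dataclasses.fields(StaircaseConfig)}
_COHORT_KEYS = {
    "n_per_group",
    "beta",
    "lapse",
    "bias_left",
    "control_alpha_mean",
    "control_alpha_sd",
    "dyslexia_alpha_mean",
    "dyslexia_alpha_sd",
}
_TOP_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def _check_keys(mapping: dict, allowed: set[str], prefix: str = "") -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown config key: {prefix}{key}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; missing keys fall back to defaults
    (Experiment 1, high-density 8-frame stimulus)."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS)
    for sub, allowed in (("stimulus", _STIM_KEYS), ("staircase", _STAIR_KEYS), ("cohort", _COHORT_KEYS)):
        if sub in raw:
            if not isinstance(raw[sub], dict):
                raise ConfigError(f"{sub}: must be a mapping")
            _check_keys(raw[sub], allowed, prefix=f"{sub}.")
    return RunConfig(**raw)


def resolve_staircase_config(cfg: RunConfig) -> StaircaseConfig:
    """Staircase configuration for a run: per-experiment defaults (50%/8
    reversals or 25%/6 reversals) with explicit overrides applied."""
    base = EXP1_STAIRCASE if cfg.experiment == "exp1" else EXP2_STAIRCASE
    return dataclasses.replace(base, **cfg.staircase)


def resolve_stim_params(cfg: RunConfig) -> RDKParams:
    base = PARAM_SETS[cfg.stimulus_set]
    over = dict(cfg.stimulus)
    ap_kwargs = {}
    for k, apk in (
        ("aperture_width_deg", "width_deg"),
        ("aperture_height_deg", "height_deg"),
        ("aperture_shape", "shape"),
    ):
        if k in over:
            ap_kwargs[apk] = over.pop(k)
    if ap_kwargs:
        ap = dataclasses.replace(base.aperture, **ap_kwargs)
        over["aperture"] = ap
    return dataclasses.replace(base, **over)


# ---------------------------------------------------------------------------
# result files

def config_hash(obj) -> str:
    """Short stable hash of a config-like object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _versioned(path: Path) -> Path:
    if not path.exists():
        return path
    k = 1
    while True:
        candidate = path.with_name(f"{path.stem}_r{k}{path.suffix}")
        if not candidate.exists():
            return candidate
        k += 1


def _write_csv(df: pd.DataFrame, path: Path, seed, cfg_hash: str) -> Path:
    path = _versioned(path)
    with open(path, "w") as fh:
        fh.write(f"# rdksim v{__version__}\n")
        fh.write(f"# seed: {seed}\n")
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, index=False)
    return path


def write_results(
    result: ExperimentResult,
    summary: SummaryTable | None,
    out_dir: str | Path,
    seed=None,
    config=None,
) -> dict[str, Path]:
    """Write thresholds.csv, summary tables and (if logged) trials.csv.

    Files carry a comment header with seed, config hash and version and are
    version-suffixed rather than overwritten.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(config if config is not None else result.metadata)
    paths = {"thresholds": _write_csv(result.thresholds, out / "thresholds.csv", seed, h)}
    if result.trials is not None:
        paths["trials"] = _write_csv(result.trials, out / "trials.csv", seed, h)
    if summary is not None:
        paths["summary"] = _write_csv(summary.cell_stats, out / "summary.csv", seed, h)
        if summary.recruitment is not None:
            paths["recruitment"] = _write_csv(
                summary.recruitment, out / "recruitment.csv", seed, h
            )
        if summary.prime_effects is not None:
            paths["prime_effects"] = _write_csv(
                summary.prime_effects, out / "prime_effects.csv", seed, h
            )
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_results` (header comments
    stripped), reproducing the original frame exactly — including floats,
    hence the round-trip parser."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# stimulus export

def export_frames_csv(frames: list[DotField], path: str | Path) -> Path:
    """Write a per-dot manifest: frame index, dot id, position, flags, age."""
    recs = []
    for f_idx, f in enumerate(frames):
        for d in range(f.n_dots):
            recs.append(
                {
                    "frame": f_idx,
                    "dot": d,
                    "x_deg": f.x[d],
                    "y_deg": f.y[d],
                    "is_signal": bool(f.is_signal[d]),
                    "age_frames": int(f.age[d]),
                }
            )
    df = pd.DataFrame(recs)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def export_frames_png(
    frames: list[DotField], out_dir: str | Path, px_per_deg: int = 20
) -> list[Path]:
    """Rasterise frames to PNG, one file per frame, 1 dot = 1 pixel (white
    on black) — visualisation only; the simulation itself is geometric."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for f_idx, f in enumerate(frames):
        ap = f.aperture or Aperture()
        w = int(round(ap.width_deg * px_per_deg))
        h = int(round(ap.height_deg * px_per_deg))
        img = np.zeros((h, w), dtype=np.uint8)
        col = np.clip(((f.x + ap.width_deg / 2) * px_per_deg).astype(int), 0, w - 1)
        row = np.clip(((ap.height_deg / 2 - f.y) * px_per_deg).astype(int), 0, h - 1)
        img[row, col] = 255
        p = out / f"frame_{f_idx:03d}.png"
        Image.fromarray(img, mode="L").save(p)
        paths.append(p)
    return paths
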