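"""Random-dot kinematogram (RDK) stimulus engine.

An RDK is an apparent-motion display built from a rapid sequence of dot
frames.  On every frame a fixed fraction of the dots — the *signal* dots,
set by the coherence level — is displaced rigidly in a single direction,
while the remaining *noise* dots move randomly.  Each dot lives for a fixed
number of frames before being regenerated at a random location, so no
single dot can be tracked across the whole animation.

Geometry is continuous, in degrees of visual angle, with the origin at the
aperture centre and +x pointing rightward.  Signal dots wrap around the
aperture edge; noise dots are kept inside by reflection (random-walk rule)
or by uniform repositioning.  The simulation is purely geometric: dots are
points, and luminance/rendering properties are carried only as metadata by
the export helpers in :mod:`rdksim.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Aperture",
    "RDKParams",
    "DotField",
    "PrimeSpec",
    "StimulusParameterError",
    "make_dot_field",
    "advance_frame",
    "generate_trial",
    "make_prime_sequence",
    "compute_density",
    "total_duration_ms",
]

DIRECTIONS = ("left", "right", "static")
SIGNAL_RULES = ("random_per_lifetime", "fixed_identity")
NOISE_RULES = ("random_walk", "random_reposition")
APERTURE_SHAPES = ("square", "circle")
DENSITY_CONVENTIONS = ("circular_effective", "literal_area")


class StimulusParameterError(ValueError):
    """Raised when a stimulus parameter is out of its valid range."""


def _require_finite_positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise StimulusParameterError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class Aperture:
    """Borderless display region, centred on the origin.

    For a circular aperture ``width_deg`` doubles as the diameter and must
    equal ``height_deg``.
    """

    width_deg: float = 6.0
    height_deg: float = 6.0
    shape: str = "square"

    def __post_init__(self) -> None:
        if self.shape not in APERTURE_SHAPES:
            raise StimulusParameterError(f"aperture shape must be one of {APERTURE_SHAPES}")
        _require_finite_positive("width_deg", self.width_deg)
        _require_finite_positive("height_deg", self.height_deg)
        if self.shape == "circle" and self.width_deg != self.height_deg:
            raise StimulusParameterError("circular aperture requires width_deg == height_deg")

    @property
    def diameter_deg(self) -> float:
        """Diameter of a circular aperture (equals ``width_deg``)."""
        return self.width_deg

    @property
    def area_deg2(self) -> float:
        if self.shape == "circle":
            return math.pi * (self.diameter_deg / 2.0) ** 2
        return self.width_deg * self.height_deg

    def contains(self, x: np.ndarray, y: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.shape == "circle":
            r = np.hypot(x, y)
            return r <= self.diameter_deg / 2.0 + atol
        return (np.abs(x) <= self.width_deg / 2.0 + atol) & (
            np.abs(y) <= self.height_deg / 2.0 + atol
        )


def _round_half_away_from_zero(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class RDKParams:
    """Complete recipe for one RDK animation.

    Defaults reproduce the high-density test stimulus of the first study
    condition set: 400 dots in a 6° × 6° square aperture, 10.5°/s dot speed,
    16.67 ms frames, two-frame dot lifetime, eight frames.
    """

    n_dots: int = 400
    aperture: Aperture = field(default_factory=Aperture)
    coherence_pct: float = 50.0
    direction: str = "right"
    speed_deg_per_s: float = 10.5
    frame_duration_ms: float = 16.67
    n_frames: int = 8
    dot_lifetime_frames: int = 2
    signal_rule: str = "random_per_lifetime"
    noise_rule: str = "random_walk"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.n_dots, (int, np.integer)) or self.n_dots < 0:
            raise StimulusParameterError(f"n_dots must be a non-negative int, got {self.n_dots!r}")
        if not (math.isfinite(self.coherence_pct) and 0.0 <= self.coherence_pct <= 100.0):
            raise StimulusParameterError(
                f"coherence_pct must lie in [0, 100], got {self.coherence_pct!r}"
            )
        if self.direction not in DIRECTIONS:
            raise StimulusParameterError(f"direction must be one of {DIRECTIONS}")
        if not (math.isfinite(self.speed_deg_per_s) and self.speed_deg_per_s >= 0):
            raise StimulusParameterError("speed_deg_per_s must be finite and >= 0")
        _require_finite_positive("frame_duration_ms", self.frame_duration_ms)
        if self.n_frames < 1:
            raise StimulusParameterError("n_frames must be >= 1")
        if self.dot_lifetime_frames < 1:
            raise StimulusParameterError("dot_lifetime_frames must be >= 1")
        if self.signal_rule not in SIGNAL_RULES:
            raise StimulusParameterError(f"signal_rule must be one of {SIGNAL_RULES}")
        if self.noise_rule not in NOISE_RULES:
            raise StimulusParameterError(f"noise_rule must be one of {NOISE_RULES}")

    @property
    def step_deg(self) -> float:
        """Per-frame displacement of a signal dot, speed × frame duration."""
        return self.speed_deg_per_s * self.frame_duration_ms / 1000.0

    @property
    def n_signal(self) -> int:
        """Signal-dot count: round-half-away-from-zero of n_dots × coherence/100."""
        return _round_half_away_from_zero(self.n_dots * self.coherence_pct / 100.0)


def total_duration_ms(params: RDKParams) -> int:
    """Nominal animation duration, rounded to the nearest millisecond."""
    return int(round(params.n_frames * params.frame_duration_ms))


@dataclass
class DotField:
    """One animation frame: dot positions, signal flags and ages.

    ``age`` counts frames since a dot was (re)generated; it never reaches
    the dot lifetime, because a dot whose age has hit ``lifetime − 1`` is
    regenerated on the next transition.
    """

    x: np.ndarray
    y: np.ndarray
    is_signal: np.ndarray
    age: np.ndarray
    aperture: Aperture | None = None

    @property
    def n_dots(self) -> int:
        return self.x.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """(n_dots, 2) array of (x, y) positions in degrees."""
        return np.column_stack([self.x, self.y])

    def copy(self) -> "DotField":
        return DotField(
            self.x.copy(), self.y.copy(), self.is_signal.copy(), self.age.copy(), self.aperture
        )


PRIME_KINDS = ("coherent_same", "coherent_opposite", "stationary")


@dataclass(frozen=True)
class PrimeSpec:
    """Prime stimulus recipe: a fully coherent or stationary RDK shown
    briefly before the test, separated from it by a blank inter-stimulus
    interval (ISI)."""

    kind: str = "stationary"
    duration_ms: float = 96.0
    isi_ms: float = 32.0

    def __post_init__(self) -> None:
        if self.kind not in PRIME_KINDS:
            raise StimulusParameterError(f"prime kind must be one of {PRIME_KINDS}")
        if not (math.isfinite(self.duration_ms) and self.duration_ms >= 0):
            raise StimulusParameterError("duration_ms must be finite and >= 0")
        if not (math.isfinite(self.isi_ms) and self.isi_ms >= 0):
            raise StimulusParameterError("isi_ms must be finite and >= 0")


# ---------------------------------------------------------------------------
# geometry helpers

def _uniform_positions(aperture: Aperture, k: int, rng: np.random.Generator):
    if aperture.shape == "circle":
        radius = aperture.diameter_deg / 2.0
        r = radius * np.sqrt(rng.random(k))
        theta = rng.uniform(0.0, 2.0 * math.pi, k)
        return r * np.cos(theta), r * np.sin(theta)
    x = rng.uniform(-aperture.width_deg / 2.0, aperture.width_deg / 2.0, k)
    y = rng.uniform(-aperture.height_deg / 2.0, aperture.height_deg / 2.0, k)
    return x, y


def _wrap(v: np.ndarray, half: float) -> np.ndarray:
    """Modular wrap into [-half, half)."""
    return (v + half) % (2.0 * half) - half


def _reflect(v: np.ndarray, half: float) -> np.ndarray:
    """Triangular fold into [-half, half] (mirror at the edges)."""
    p = (v + half) % (4.0 * half)
    p = np.where(p > 2.0 * half, 4.0 * half - p, p)
    return p - half


def _wrap_circle(x: np.ndarray, y: np.ndarray, radius: float):
    """Carry dots that left a circular aperture to the diametrically
    opposite edge, continuing along their heading."""
    r = np.hypot(x, y)
    out = r > radius
    if np.any(out):
        scale = 1.0 - 2.0 * radius / r[out]
        x = x.copy()
        y = y.copy()
        x[out] *= scale
        y[out] *= scale
    return x, y


def _reflect_circle(x: np.ndarray, y: np.ndarray, radius: float):
    r = np.hypot(x, y)
    out = r > radius
    if np.any(out):
        scale = (2.0 * radius - r[out]) / r[out]
        x = x.copy()
        y = y.copy()
        x[out] *= scale
        y[out] *= scale
    return x, y


# ---------------------------------------------------------------------------
# core operations

def make_dot_field(params: RDKParams, rng: np.random.Generator) -> DotField:
    """Build the initial frame of an RDK.

    Positions are uniform over the aperture, signal flags are assigned at
    random (``params.n_signal`` of them), and ages are staggered uniformly
    over ``{0, …, lifetime − 1}`` so that dot expiries are spread across
    transitions from the first frame on (steady state).
    """
    n = params.n_dots
    x, y = _uniform_positions(params.aperture, n, rng)
    is_signal = np.zeros(n, dtype=bool)
    k = params.n_signal
    if k > 0:
        is_signal[rng.choice(n, size=k, replace=False)] = True
    age = rng.integers(0, params.dot_lifetime_frames, size=n)
    return DotField(x, y, is_signal, age.astype(np.int64), params.aperture)


def advance_frame(field: DotField, params: RDKParams, rng: np.random.Generator) -> DotField:
    """Produce the next animation frame.

    Signal dots translate by ``step_deg`` along ``params.direction`` and
    wrap at the aperture edge; noise dots take a random-direction step of
    the same magnitude (``random_walk``, reflected at the edge) or are
    repositioned uniformly (``random_reposition``).  Dots whose age has
    reached ``lifetime − 1`` are regenerated at a uniform random location
    with age 0; under ``random_per_lifetime`` the signal flags of the
    regenerated dots are re-drawn so the total signal count is conserved.

    A ``static`` direction freezes the display entirely (stationary prime):
    the returned frame is an identical copy, ages included.
    """
    if params.direction == "static":
        return field.copy()

    n = params.n_dots
    ap = params.aperture
    step = params.step_deg
    sgn = 1.0 if params.direction == "right" else -1.0

    new_age = field.age + 1
    regen = new_age >= params.dot_lifetime_frames
    x = field.x.copy()
    y = field.y.copy()
    is_signal = field.is_signal.copy()

    move_signal = is_signal & ~regen
    if np.any(move_signal):
        if ap.shape == "circle":
            xs = x[move_signal] + sgn * step
            xs, ys = _wrap_circle(xs, y[move_signal], ap.diameter_deg / 2.0)
            x[move_signal] = xs
            y[move_signal] = ys
        else:
            x[move_signal] = _wrap(x[move_signal] + sgn * step, ap.width_deg / 2.0)

    move_noise = ~is_signal & ~regen
    m = int(move_noise.sum())
    if m > 0:
        if params.noise_rule == "random_walk":
            theta = rng.uniform(0.0, 2.0 * math.pi, m)
            xn = x[move_noise] + step * np.cos(theta)
            yn = y[move_noise] + step * np.sin(theta)
            if ap.shape == "circle":
                xn, yn = _reflect_circle(xn, yn, ap.diameter_deg / 2.0)
            else:
                xn = _reflect(xn, ap.width_deg / 2.0)
                yn = _reflect(yn, ap.height_deg / 2.0)
        else:  # random_reposition
            xn, yn = _uniform_positions(ap, m, rng)
        x[move_noise] = xn
        y[move_noise] = yn

    k_regen = int(regen.sum())
    if k_regen > 0:
        xr, yr = _uniform_positions(ap, k_regen, rng)
        x[regen] = xr
        y[regen] = yr
        if params.signal_rule == "random_per_lifetime":
            kept = int(field.is_signal[~regen].sum())
            need = params.n_signal - kept
            flags = np.zeros(k_regen, dtype=bool)
            if need > 0:
                flags[rng.choice(k_regen, size=need, replace=False)] = True
            is_signal[regen] = flags
        new_age = new_age.copy()
        new_age[regen] = 0

    return DotField(x, y, is_signal, new_age, ap)


def generate_trial(params: RDKParams, rng: np.random.Generator | None = None) -> list[DotField]:
    """Generate the full frame sequence of one trial.

    When ``rng`` is omitted a generator is built from ``params.seed``, so
    identical (params, seed) pairs yield bit-identical sequences.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    frames = [make_dot_field(params, rng)]
    for _ in range(params.n_frames - 1):
        frames.append(advance_frame(frames[-1], params, rng))
    return frames


def prime_params(spec: PrimeSpec, test_params: RDKParams) -> RDKParams:
    """Stimulus parameters for the prime implied by ``spec``.

    Coherent primes are 100%-coherent copies of the test stimulus moving in
    the same or opposite direction; the stationary prime has direction
    ``static`` (zero displacement) and carries no signal dots.
    """
    if spec.duration_ms < test_params.frame_duration_ms:
        raise StimulusParameterError(
            "prime duration is smaller than one animation frame "
            f"({spec.duration_ms} < {test_params.frame_duration_ms} ms)"
        )
    n_frames = int(round(spec.duration_ms / test_params.frame_duration_ms))
    if spec.kind == "stationary":
        return replace(test_params, coherence_pct=0.0, direction="static", n_frames=n_frames)
    if test_params.direction == "static":
        raise StimulusParameterError("coherent prime requires a moving test stimulus")
    if spec.kind == "coherent_same":
        direction = test_params.direction
    else:
        direction = "left" if test_params.direction == "right" else "right"
    return replace(test_params, coherence_pct=100.0, direction=direction, n_frames=n_frames)


def make_prime_sequence(
    spec: PrimeSpec, test_params: RDKParams, rng: np.random.Generator | None = None
) -> list[DotField]:
    """Generate the prime frame sequence preceding a test stimulus."""
    return generate_trial(prime_params(spec, test_params), rng)


def compute_density(
    n_dots: int, aperture: Aperture, convention: str = "circular_effective"
) -> float:
    """Dot density in dots/deg².

    ``circular_effective`` divides by the area of a circle whose diameter is
    the aperture width — the convention under which the reported densities
    for 400 and 100 dots in a 6° aperture (14.15 and 3.54 dots/deg²) are
    exact.  ``literal_area`` divides by the aperture's actual area.
    """
    if convention not in DENSITY_CONVENTIONS:
        raise StimulusParameterError(f"convention must be one of {DENSITY_CONVENTIONS}")
    if n_dots < 0:
        raise StimulusParameterError("n_dots must be >= 0")
    if convention == "circular_effective":
        area = math.pi * (aperture.width_deg / 2.0) ** 2
    else:
        area = aperture.area_deg2
    if area <= 0:
        raise StimulusParameterError("aperture area must be > 0")
    return n_dots / area
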