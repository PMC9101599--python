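"""Synthetic trajectory-following trials with graded motor impairment.

The clinical recordings behind this kind of study (a haptic device sampling
the end-effector position while a subject traces a displayed curve) are not
publicly available, so this module generates surrogate data with the same
protocol structure: 3 shapes x 3 resistive-force modes per subject, patients
tested with one hand and controls with both, giving 9 or 18 trials per
subject.

Impairment is encoded by a clinician-style score on a 0-28 scale (14 items,
0-2 points each; 28 = unimpaired).  A score maps deterministically, with
seeded between-subject jitter, to distortion parameters:

* band-limited tremor (two sinusoids in the 4-8 Hz band plus white noise),
* a slow radial drift away from the reference curve,
* time-warp slowing with occasional pauses.

All distortions vanish at score 28, so a ceiling-score trajectory lies
exactly on the reference polyline.  Severity grows monotonically as the
score drops, which is what gives the extracted kinematic features their
strong monotone relationship with the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import TaskCurve, WORKSPACE_HALF_CM, default_curves
from .errors import InvalidParameterError

#: Resistive force-feedback modes (N) used in the protocol.
FORCE_MODES = (0.0, 1.5, 5.0)

#: Ceiling of the clinician scale (14 items x 2 points).
SCORE_MAX = 28

#: Empirical patient score pool (clinician scale scores of the 25 recruited
#: patients); used as the default patient score distribution.
PATIENT_SCORE_POOL = (
    5, 11, 19, 17, 13, 24, 20, 22, 7, 14, 16, 18, 21,
    16, 14, 13, 19, 17, 22, 11, 9, 14, 15, 10, 18,
)

#: Control subjects score at or near the scale ceiling.
CONTROL_SCORE_POOL = (26, 27, 28)

#: Default simulator sampling rate (Hz).  The device samples at 1 kHz; the
#: features are rate-invariant after smoothing, so a lower default keeps
#: synthetic cohorts cheap.  Pass ``sample_rate=1000`` for device-rate data.
DEFAULT_SAMPLE_RATE_HZ = 200.0

#: Nominal unimpaired task duration (s) for one lap of the curve.
DEFAULT_DURATION_HINT_S = 10.0

_SHAPE_CODE = {"square": 1, "triangle": 2, "circle": 3}
_HAND_CODE = {"right": 0, "left": 1}


@dataclass(frozen=True)
class TrajectoryRecording:
    """One trial: the sampled end-effector path plus protocol metadata."""

    subject_id: str
    hand: str
    shape_id: str
    force_mode: float
    times: np.ndarray = field(repr=False)
    xs: np.ndarray = field(repr=False)
    ys: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if not (len(times) == len(xs) == len(ys)):
            raise InvalidParameterError("times, xs, ys must have equal length")
        if len(times) < 3:
            raise InvalidParameterError("a recording needs at least 3 samples")
        if np.any(np.diff(times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if max(np.max(np.abs(xs)), np.max(np.abs(ys))) > WORKSPACE_HALF_CM + 1e-9:
            raise InvalidParameterError("positions outside the device workspace")
        if self.hand not in _HAND_CODE:
            raise InvalidParameterError(f"unknown hand {self.hand!r}")
        if not any(np.isclose(self.force_mode, f) for f in FORCE_MODES):
            raise InvalidParameterError(
                f"force_mode must be one of {FORCE_MODES}, got {self.force_mode}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def positions(self) -> np.ndarray:
        """``(n, 2)`` position array in cm."""
        return np.column_stack([self.xs, self.ys])

    @property
    def task_time(self) -> float:
        """Task execution time T (s): last minus first timestamp."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class ImpairmentProfile:
    """Distortion parameters derived from a ground-truth scale score."""

    true_score: int
    tremor_amp: float  # cm
    tremor_freq: float  # Hz
    drift_bias: float  # cm
    speed_scale: float  # (0, 1]; 1 = unimpaired pace
    pause_prob: float
    seed: int

    @property
    def severity(self) -> float:
        """Normalized impairment in [0, 1]: 0 at score 28, 1 at score 0."""
        return (SCORE_MAX - self.true_score) / SCORE_MAX


def profile_from_score(true_score: int, seed: int) -> ImpairmentProfile:
    """Map a 0-28 scale score to seeded distortion parameters.

    The mapping is deterministic in ``(true_score, seed)``.  The jitter
    factor depends on the seed only, so at a fixed seed the parameters are
    exactly monotone in the score: tremor and drift non-increasing, speed
    non-decreasing.  Score 28 yields zero distortion.
    """
    score = int(true_score)
    if score != true_score or not 0 <= score <= SCORE_MAX:
        raise InvalidParameterError(
            f"true_score must be an integer in [0, {SCORE_MAX}], got {true_score!r}"
        )
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(0.85, 1.15)  # between-subject variability
    tremor_freq = rng.uniform(4.0, 8.0)
    severity = (SCORE_MAX - score) / SCORE_MAX
    return ImpairmentProfile(
        true_score=score,
        tremor_amp=0.5 * jitter * severity**1.1,
        tremor_freq=tremor_freq,
        drift_bias=0.8 * jitter * severity,
        speed_scale=1.0 / (1.0 + 2.0 * jitter * severity),
        pause_prob=0.08 * severity,
        seed=int(seed),
    )


def _curve_interpolator(curve: TaskCurve):
    """Return a function mapping arc length along the closed curve to (x, y)."""
    closed = np.vstack([curve.vertices, curve.vertices[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    def interp(s: np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, cum[-1])
        return np.column_stack(
            [np.interp(s, cum, closed[:, 0]), np.interp(s, cum, closed[:, 1])]
        )

    return interp, cum[-1]


def simulate_trajectory(
    curve: TaskCurve,
    profile: ImpairmentProfile,
    force_mode: float,
    duration_hint: float = DEFAULT_DURATION_HINT_S,
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ,
    subject_id: str = "sim",
    hand: str = "right",
) -> TrajectoryRecording:
    """Simulate one clockwise lap of ``curve`` under an impairment profile.

    The path is the reference curve traversed once, time-warped by the
    profile's slowing and pauses, and perturbed by radial drift plus
    band-limited tremor.  Output is bit-identical for identical inputs.

    Notes
    -----
    All fixed-shape random draws happen before any draw whose size depends
    on profile parameters, so profiles differing only in severity share the
    same underlying noise waveforms — severity then scales the distortion
    amplitudes monotonically.
    """
    if not duration_hint > 0:
        raise InvalidParameterError("duration_hint must be positive")
    if not sample_rate > 0:
        raise InvalidParameterError("sample_rate must be positive")
    if not any(np.isclose(force_mode, f) for f in FORCE_MODES):
        raise InvalidParameterError(f"force_mode must be one of {FORCE_MODES}")

    severity = profile.severity
    rng = np.random.default_rng(
        [profile.seed, _SHAPE_CODE[curve.shape_id], int(force_mode * 10),
         _HAND_CODE[hand]]
    )

    # Fixed-shape draws (independent of severity) — see Notes.
    f_mod = rng.uniform(0.1, 0.3)
    phi_mod = rng.uniform(0, 2 * np.pi)
    pause_gate = rng.uniform(size=3)
    pause_start_frac = rng.uniform(0.1, 0.9, size=3)
    pause_len_s = rng.uniform(0.3, 1.0, size=3)
    n_drift_cycles = rng.integers(1, 3)
    phi_drift = rng.uniform(0, 2 * np.pi)
    tremor_dirs = rng.normal(size=(2, 2))
    tremor_dirs /= np.linalg.norm(tremor_dirs, axis=1, keepdims=True)
    tremor_phases = rng.uniform(0, 2 * np.pi, size=2)

    # Resistive force mildly prolongs the task for impaired subjects.
    duration = duration_hint / profile.speed_scale * (1.0 + 0.01 * force_mode * severity)
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate

    # Monotone phase: modulated progress rate, zeroed inside pause windows.
    # Even unimpaired movement has a small smooth pace variation (5%);
    # impairment deepens it.  The path itself stays on the curve.
    rate = 1.0 + (0.05 + 0.25 * severity) * np.sin(2 * np.pi * f_mod * t + phi_mod)
    rate = np.clip(rate, 0.05, None)
    for gate, start_frac, length in zip(pause_gate, pause_start_frac, pause_len_s):
        if gate < profile.pause_prob:
            start = start_frac * duration
            rate[(t >= start) & (t < start + length)] = 0.0
    u = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]))])
    if u[-1] <= 0:  # pathological: everything paused
        u = t.copy()
    u /= u[-1]

    interp, total_len = _curve_interpolator(curve)
    base = interp(u * total_len)

    # Radial drift: slow signed offset along the outward direction.
    radial_vec = base - curve.centroid
    radial_norm = np.linalg.norm(radial_vec, axis=1, keepdims=True)
    radial_unit = radial_vec / np.where(radial_norm > 1e-12, radial_norm, 1.0)
    drift = profile.drift_bias * np.sin(2 * np.pi * n_drift_cycles * u + phi_drift)

    # Band-limited tremor: two sinusoids in the 4-8 Hz band + white noise.
    f1 = profile.tremor_freq
    f2 = min(1.37 * f1, 8.0)
    tremor = 0.5 * profile.tremor_amp * (
        np.sin(2 * np.pi * f1 * t + tremor_phases[0])[:, None] * tremor_dirs[0]
        + np.sin(2 * np.pi * f2 * t + tremor_phases[1])[:, None] * tremor_dirs[1]
    )
    if profile.tremor_amp > 0:
        noise = rng.normal(0.0, 0.04 * profile.tremor_amp, size=(n, 2))
    else:
        noise = np.zeros((n, 2))

    pos = base + drift[:, None] * radial_unit + tremor + noise
    np.clip(pos, -(WORKSPACE_HALF_CM - 1e-3), WORKSPACE_HALF_CM - 1e-3, out=pos)

    return TrajectoryRecording(
        subject_id=subject_id,
        hand=hand,
        shape_id=curve.shape_id,
        force_mode=float(force_mode),
        times=t,
        xs=pos[:, 0],
        ys=pos[:, 1],
    )


def _resolve_sampler(score_sampler, pool):
    """Turn a distribution spec into a callable(rng) -> int score."""
    if score_sampler is None or score_sampler == "empirical":
        values = np.asarray(pool, dtype=int)
        return lambda rng: int(rng.choice(values))
    if score_sampler == "uniform":
        return lambda rng: int(rng.integers(0, SCORE_MAX + 1))
    if callable(score_sampler):
        return lambda rng: int(score_sampler(rng))
    values = np.asarray(list(score_sampler), dtype=int)
    if values.size == 0:
        raise InvalidParameterError("empty score pool")
    return lambda rng: int(rng.choice(values))


def make_cohort(
    n_patients: int = 25,
    n_controls: int = 10,
    score_sampler=None,
    seed: int = 0,
    curves: dict[str, TaskCurve] | None = None,
    duration_hint: float = DEFAULT_DURATION_HINT_S,
    sample_rate: float = DEFAULT_SAMPLE_RATE_HZ,
    control_scores=CONTROL_SCORE_POOL,
) -> list[tuple[TrajectoryRecording, int]]:
    """Generate a full study cohort of recordings with ground-truth scores.

    Each patient performs the 9 protocol trials (3 shapes x 3 force modes)
    with one hand; each control performs all 9 with both hands (18 trials).
    Cohort size is therefore ``9*n_patients + 18*n_controls`` — the default
    25 patients + 10 controls reproduce the protocol's 405 trials.

    Parameters
    ----------
    score_sampler
        ``None``/``"empirical"`` draws patient scores from the recruited
        patients' score pool (5-24); ``"uniform"`` draws uniformly on 0-28;
        a sequence is used as a pool; a callable receives the cohort RNG.
    control_scores
        Pool for control-subject scores (defaults to the 26-28 ceiling).

    Returns
    -------
    list of (TrajectoryRecording, true_score), ordering reproducible from
    ``seed``.
    """
    if n_patients < 0 or n_controls < 0:
        raise InvalidParameterError("subject counts must be non-negative")
    if curves is None:
        curves = default_curves()
    rng = np.random.default_rng(seed)
    patient_sampler = _resolve_sampler(score_sampler, PATIENT_SCORE_POOL)
    control_sampler = _resolve_sampler(None, control_scores)

    cohort: list[tuple[TrajectoryRecording, int]] = []

    def run_trials(subject_id, hand, score, subject_seed):
        profile = profile_from_score(score, subject_seed)
        for shape in ("square", "triangle", "circle"):
            for force in FORCE_MODES:
                rec = simulate_trajectory(
                    curves[shape], profile, force,
                    duration_hint=duration_hint, sample_rate=sample_rate,
                    subject_id=subject_id, hand=hand,
                )
                cohort.append((rec, score))

    for p in range(n_patients):
        score = patient_sampler(rng)
        hand = "right" if rng.uniform() < 0.5 else "left"
        run_trials(f"P{p + 1:03d}", hand, score, int(rng.integers(2**31)))
    for c in range(n_controls):
        score = control_sampler(rng)
        for hand in ("right", "left"):
            run_trials(f"C{c + 1:03d}", hand, score, int(rng.integers(2**31)))
    return cohort


__all__ = [
    "FORCE_MODES",
    "SCORE_MAX",
    "PATIENT_SCORE_POOL",
    "CONTROL_SCORE_POOL",
    "TrajectoryRecording",
    "ImpairmentProfile",
    "profile_from_score",
    "simulate_trajectory",
    "make_cohort",
]
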