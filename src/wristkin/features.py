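"""The seven kinematic features of the trajectory-following task.

From one recording and its reference curve the extractor computes:

======  =========================================================  =======
symbol  definition                                                 unit
======  =========================================================  =======
NPV     number of peak-velocity points: velocity-curve points       count
        exceeding the average speed (two interpretations, below)
V       average instantaneous speed, (1/N) sum V_i                  cm/s
A       average acceleration magnitude, (1/N) sum A_i               cm/s^2
D       average trajectory deviation: mean nearest distance from    cm
        each sample to the reference polyline
C       trajectory coincidence: percentage of the traced path       %
        length lying within ``epsilon`` of the reference curve
S       intersection area: total area of the pockets enclosed       cm^2
        between the (closed) traced path and the reference curve,
        i.e. the symmetric-difference area of the two regions
T       task execution time                                         s
======  =========================================================  =======

NPV is ambiguous as usually stated ("points where the instantaneous
velocity is larger than the average velocity"): read literally it counts
samples and is therefore sampling-rate dependent.  The default here counts
strict local maxima of the speed curve above the mean speed, the
sub-movement reading used in the motor-performance literature; the literal
per-sample count is available as ``npv_mode="literal"``.

Velocities are computed from positions smoothed by a centered moving
average (default 50 ms window), then central differences; acceleration is
the magnitude of the derivative of the velocity *vector* (a signed scalar
dV/dt would average to ~0 over a closed loop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from shapely.validation import make_valid

from .curves import TaskCurve
from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidParameterError,
)
from .simulate import TrajectoryRecording

#: Canonical feature order used throughout the package.
FEATURE_NAMES = ("NPV", "V", "A", "D", "C", "S", "T")


@dataclass(frozen=True)
class VelocityProfile:
    """Per-sample speed and acceleration magnitude of one recording."""

    times: np.ndarray = field(repr=False)
    speeds: np.ndarray = field(repr=False)  # cm/s, non-negative
    accel_mags: np.ndarray = field(repr=False)  # cm/s^2, non-negative

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.speeds) == len(self.accel_mags)):
            raise InvalidParameterError("profile arrays must share a length")

    @property
    def n(self) -> int:
        return len(self.speeds)


@dataclass(frozen=True)
class FeatureVector:
    """The seven features extracted from one trial."""

    NPV: int
    V: float
    A: float
    D: float
    C: float
    S: float
    T: float

    def __post_init__(self) -> None:
        if self.NPV < 0 or int(self.NPV) != self.NPV:
            raise InvalidParameterError("NPV must be a non-negative integer")
        for name in ("V", "A", "D", "S", "T"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if not 0.0 <= self.C <= 100.0:
            raise InvalidParameterError("C must lie in [0, 100] percent")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable settings of the feature extractor."""

    smooth_window: float = 0.05  # s; centered moving-average width
    epsilon: float = 0.25  # cm; coincidence tolerance band
    npv_mode: str = "peaks"  # "peaks" | "literal"


def compute_velocity_profile(
    rec: TrajectoryRecording, smooth_window: float = 0.05
) -> VelocityProfile:
    """Speed and acceleration-magnitude series from a recording.

    Positions are smoothed with a centered moving average of width
    ``smooth_window`` seconds (0 disables smoothing) before differencing.
    Central differences are used at interior samples and one-sided
    differences at the endpoints (via :func:`numpy.gradient`).
    """
    if rec.n_samples < 3:
        raise InsufficientDataError("need at least 3 samples for differentiation")
    t = rec.times
    xs, ys = rec.xs, rec.ys
    if smooth_window > 0:
        dt = float(np.median(np.diff(t)))
        w = max(1, int(round(smooth_window / dt)))
        if w > 1:
            xs = uniform_filter1d(xs, size=w, mode="nearest")
            ys = uniform_filter1d(ys, size=w, mode="nearest")
    vx, vy = np.gradient(xs, t), np.gradient(ys, t)
    ax, ay = np.gradient(vx, t), np.gradient(vy, t)
    return VelocityProfile(
        times=t, speeds=np.hypot(vx, vy), accel_mags=np.hypot(ax, ay)
    )


def count_peak_velocity_points(profile: VelocityProfile, mode: str = "peaks") -> int:
    """NPV: velocity-curve points above the mean speed.

    ``mode="peaks"`` counts strict interior local maxima of the speed curve
    whose value exceeds the mean speed; ``mode="literal"`` counts every
    sample above the mean speed.
    """
    if profile.n < 1:
        raise InsufficientDataError("empty velocity profile")
    mean_speed = float(np.mean(profile.speeds))
    if mode == "literal":
        return int(np.sum(profile.speeds > mean_speed))
    if mode == "peaks":
        peaks, _ = find_peaks(profile.speeds)
        return int(np.sum(profile.speeds[peaks] > mean_speed))
    raise InvalidParameterError(f"unknown NPV mode {mode!r}")


def average_velocity(profile: VelocityProfile) -> float:
    """Mean instantaneous speed V = (1/N) sum V_i, in cm/s."""
    if profile.n < 1:
        raise InsufficientDataError("empty velocity profile")
    return float(np.mean(profile.speeds))


def average_acceleration(profile: VelocityProfile) -> float:
    """Mean acceleration magnitude A = (1/N) sum A_i, in cm/s^2."""
    if profile.n < 1:
        raise InsufficientDataError("empty velocity profile")
    return float(np.mean(profile.accel_mags))


def _distances_to_curve(rec: TrajectoryRecording, curve: TaskCurve) -> np.ndarray:
    """Nearest (segment-projected) distance from each sample to the curve."""
    points = shapely.points(rec.positions)
    return shapely.distance(points, curve.ring)


def trajectory_deviation(rec: TrajectoryRecording, curve: TaskCurve) -> float:
    """Average trajectory deviation D, in cm.

    Each sample's deviation is its Euclidean distance to the nearest point
    of the reference polyline (projection onto segments, not vertex-only);
    D is the mean of these distances.
    """
    return float(np.mean(_distances_to_curve(rec, curve)))


def trajectory_coincidence(
    rec: TrajectoryRecording, curve: TaskCurve, epsilon: float = 0.25
) -> float:
    """Trajectory coincidence C = 100 * Lc / Lr, in percent.

    Lr is the traced path length; Lc is the length of the path segments
    whose *both* endpoints lie within ``epsilon`` of the reference curve.
    """
    if rec.n_samples < 2:
        raise InsufficientDataError("need at least 2 samples for a path length")
    if not epsilon > 0:
        raise InvalidParameterError("epsilon must be positive")
    dists = _distances_to_curve(rec, curve)
    seg_len = np.linalg.norm(np.diff(rec.positions, axis=0), axis=1)
    total = float(np.sum(seg_len))
    if total <= 0:
        raise DegenerateInputError("zero-length trajectory has undefined coincidence")
    within = (dists[:-1] <= epsilon) & (dists[1:] <= epsilon)
    # roundoff guard: the ratio is mathematically in [0, 1]
    return float(np.clip(100.0 * np.sum(seg_len[within]) / total, 0.0, 100.0))


def _polygonal_part(geom) -> shapely.Geometry:
    """Union of the polygonal components of a (possibly mixed) geometry."""
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        if polys:
            return shapely.union_all(polys)
    return shapely.Polygon()


def intersection_area(rec: TrajectoryRecording, curve: TaskCurve) -> float:
    """Intersection area S: summed pocket areas between path and curve, cm^2.

    The traced path is closed (last sample joined to the first) and cleaned
    of self-intersections; S is the area of the symmetric difference
    between the region it encloses and the region enclosed by the reference
    curve.  Two identical regions give 0.  A degenerate path enclosing no
    area counts as a full miss: the curve's own area is returned with a
    warning.
    """
    if rec.n_samples < 3:
        raise InsufficientDataError("need at least 3 samples to enclose an area")
    raw = shapely.Polygon(rec.positions)
    region = _polygonal_part(raw if raw.is_valid else make_valid(raw))
    curve_poly = curve.polygon
    if region.area < 1e-9:
        warnings.warn(
            "trajectory encloses no area; intersection area falls back to "
            "the full curve area",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(curve_poly.area)
    return float(curve_poly.symmetric_difference(region).area)


def extract_features(
    rec: TrajectoryRecording,
    curve: TaskCurve,
    params: ExtractionParams | None = None,
) -> FeatureVector:
    """Compute the full seven-feature vector for one trial."""
    params = params or ExtractionParams()
    profile = compute_velocity_profile(rec, params.smooth_window)
    return FeatureVector(
        NPV=count_peak_velocity_points(profile, params.npv_mode),
        V=average_velocity(profile),
        A=average_acceleration(profile),
        D=trajectory_deviation(rec, curve),
        C=trajectory_coincidence(rec, curve, params.epsilon),
        S=intersection_area(rec, curve),
        T=rec.task_time,
    )


def build_feature_table(
    cohort: list[tuple[TrajectoryRecording, int]],
    curves: dict[str, TaskCurve],
    params: ExtractionParams | None = None,
) -> pd.DataFrame:
    """Feature table for a whole cohort: metadata + 7 features + score."""
    rows = []
    for rec, score in cohort:
        fv = extract_features(rec, curves[rec.shape_id], params)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "hand": rec.hand,
                "shape_id": rec.shape_id,
                "force_n": rec.force_mode,
                **{name: getattr(fv, name) for name in FEATURE_NAMES},
                "score": score,
            }
        )
    return pd.DataFrame(rows)
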