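"""Closed planar reference curves for the trajectory-following task.

The task presents one of three closed shapes — square, triangle, circle —
inside the haptic device's roughly 10 x 10 cm planar workspace, and the
subject traces it clockwise with the end-effector handle.  Curves are
represented as closed polylines resampled to (approximately) arc-length
uniform vertices, which keeps nearest-point queries well conditioned.

Conventions, fixed for reproducibility:

* curves are centered on the workspace origin;
* the square is axis-aligned, the triangle equilateral with one vertex up;
* for square and triangle ``size`` is the side length, for the circle it is
  the diameter;
* vertex order is clockwise (negative shoelace area), matching the tracing
  instruction given to subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import InvalidParameterError, WorkspaceViolationError

#: Workspace half-extent in cm: positions must stay within [-5, 5] x [-5, 5].
WORKSPACE_HALF_CM = 5.0

#: Shapes used in the protocol.
SHAPE_IDS = ("square", "triangle", "circle")

#: Default physical scale (cm) of the displayed curves.
DEFAULT_SIZE_CM = 8.0

#: Default number of polyline vertices after resampling.
DEFAULT_N_POINTS = 400


def _closed(vertices: np.ndarray) -> np.ndarray:
    """Return the polyline with the first vertex appended at the end."""
    return np.vstack([vertices, vertices[:1]])


def _signed_area(vertices: np.ndarray) -> float:
    """Shoelace signed area of the closed polygon (negative = clockwise)."""
    closed = _closed(vertices)
    x, y = closed[:, 0], closed[:, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def _perimeter(vertices: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(_closed(vertices), axis=0), axis=1)))


@dataclass(frozen=True)
class TaskCurve:
    """A closed, clockwise, simple reference polyline in the X-Y plane.

    Parameters
    ----------
    shape_id
        One of ``"square"``, ``"triangle"``, ``"circle"``.
    vertices
        ``(n, 2)`` array of vertex coordinates in cm.  The polyline is
        implicitly closed (the first vertex is *not* repeated at the end).
    size_cm
        Nominal scale: side length for square/triangle, diameter for circle.
    """

    shape_id: str
    vertices: np.ndarray = field(repr=False)
    size_cm: float

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise InvalidParameterError("vertices must be an (n>=3, 2) array")
        object.__setattr__(self, "vertices", verts)
        if self.shape_id not in SHAPE_IDS:
            raise InvalidParameterError(f"unknown shape_id {self.shape_id!r}")
        if np.max(np.abs(verts)) > WORKSPACE_HALF_CM + 1e-9:
            raise WorkspaceViolationError(
                "curve extends beyond the 10 x 10 cm device workspace"
            )
        if self.perimeter <= 0:
            raise InvalidParameterError("curve has zero perimeter")
        if _signed_area(verts) >= 0:
            raise InvalidParameterError("curve must be clockwise oriented")
        if not self.ring.is_simple:
            raise InvalidParameterError("curve polyline must be non-self-intersecting")

    @property
    def ring(self) -> shapely.LinearRing:
        """The curve as a shapely ring (boundary geometry)."""
        return shapely.LinearRing(self.vertices)

    @property
    def polygon(self) -> shapely.Polygon:
        """The region enclosed by the curve."""
        return shapely.Polygon(self.vertices)

    @property
    def perimeter(self) -> float:
        """Closed polyline length in cm."""
        return _perimeter(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the enclosed region, in cm."""
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape_id": self.shape_id,
                "size_cm": self.size_cm,
                "points": self.vertices.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TaskCurve":
        obj = json.loads(text)
        return cls(
            shape_id=obj["shape_id"],
            vertices=np.asarray(obj["points"], dtype=float),
            size_cm=float(obj["size_cm"]),
        )


def _resample_closed(vertices: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polyline to ``n_points`` arc-length-uniform vertices."""
    closed = _closed(vertices)
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return np.column_stack([x, y])


def make_task_curve(
    shape_id: str,
    size: float = DEFAULT_SIZE_CM,
    n_points: int = DEFAULT_N_POINTS,
) -> TaskCurve:
    """Construct a clockwise task curve centered on the workspace origin.

    Parameters
    ----------
    shape_id
        ``"square"``, ``"triangle"`` or ``"circle"``.
    size
        Side length (square, triangle) or diameter (circle), in cm.
        Must be positive and fit the 10 cm workspace.
    n_points
        Number of vertices after arc-length-uniform resampling (>= 3;
        >= 64 recommended for the circle).

    Returns
    -------
    TaskCurve
    """
    if shape_id not in SHAPE_IDS:
        raise InvalidParameterError(f"unknown shape_id {shape_id!r}")
    if not size > 0:
        raise InvalidParameterError("size must be positive")
    if size > 2 * WORKSPACE_HALF_CM:
        raise WorkspaceViolationError("size exceeds the 10 cm workspace")
    if n_points < 3:
        raise InvalidParameterError("n_points must be >= 3")

    if shape_id == "square":
        h = size / 2.0
        base = np.array([[h, h], [h, -h], [-h, -h], [-h, h]])
    elif shape_id == "triangle":
        # Equilateral, one vertex up, centered on its centroid; clockwise.
        radius = size / np.sqrt(3.0)
        angles = np.deg2rad([90.0, -30.0, -150.0])
        base = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    else:  # circle
        radius = size / 2.0
        # Decreasing angle = clockwise; regular n-gon is already uniform.
        theta = np.pi / 2 - 2 * np.pi * np.arange(n_points) / n_points
        base = radius * np.column_stack([np.cos(theta), np.sin(theta)])

    verts = _resample_closed(base, n_points)
    # re-center: resampling can shift the area centroid by a hair when the
    # vertex count does not divide evenly among the sides
    verts -= np.array(shapely.Polygon(verts).centroid.coords[0])
    if np.max(np.abs(verts)) > WORKSPACE_HALF_CM:
        raise WorkspaceViolationError(
            f"{shape_id} of size {size} cm does not fit the 10 x 10 cm workspace"
        )
    return TaskCurve(shape_id=shape_id, vertices=verts, size_cm=float(size))


def default_curves(
    size: float = DEFAULT_SIZE_CM, n_points: int = DEFAULT_N_POINTS
) -> dict[str, TaskCurve]:
    """The three protocol curves keyed by shape id."""
    return {shape: make_task_curve(shape, size, n_points) for shape in SHAPE_IDS}
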