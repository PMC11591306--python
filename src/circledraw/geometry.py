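"""Trajectory geometry for drawn circles.

A trial's pen trajectory (time-stamped 2D samples, cm) is reduced to the
geometric quantities the analysis runs on:

* **center** — midpoint of the horizontal and vertical extremes of the
  drawing (mean of min and max per axis);
* **radius** — the trajectory is resampled to 50 points equally spaced in
  arc length (so the speed profile cannot bias the estimate) and the radius
  is the mean Euclidean distance from those points to the center;
* **aspect ratio** — the ratio of the two perpendicular projected extents
  of the resampled drawing that deviates most from one, found by a 1°
  rotation scan;
* **circularity gate** — a drawing counts as non-circular when its aspect
  ratio falls outside [0.1, 10] or its path length is shorter than twice
  the start-to-end distance (an open arc rather than a closed loop).

All coordinates are in cm; time stamps in seconds at the tablet's native
rate (60 Hz for the recorded data, but nothing here assumes a rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_RESAMPLE",
    "ASPECT_RATIO_BOUNDS",
    "DegenerateTrajectoryError",
    "RawTrajectory",
    "ResampledTrajectory",
    "TrialGeometry",
    "compute_center",
    "path_length",
    "start_end_distance",
    "resample_spatial",
    "compute_radius",
    "compute_aspect_ratio",
    "classify_circular",
    "trial_geometry",
]

#: Number of arc-length-equidistant points a trajectory is resampled to.
N_RESAMPLE = 50

#: Aspect-ratio interval outside which a drawing is non-circular.
ASPECT_RATIO_BOUNDS = (0.1, 10.0)

#: Angular step (degrees) of the rotation scan for the aspect ratio.
ASPECT_SCAN_STEP_DEG = 1.0

#: Path length must be at least this multiple of the start-to-end distance.
CLOSURE_FACTOR = 2.0


class DegenerateTrajectoryError(ValueError):
    """The trajectory has no spatial extent (all samples coincide)."""


@dataclass(frozen=True)
class RawTrajectory:
    """Time-stamped pen samples of a single trial.

    Parameters
    ----------
    t : array-like
        Sample times in seconds, monotone nondecreasing.
    x, y : array-like
        Pen position in cm, same length as ``t`` (>= 2 samples).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1):
            raise ValueError("t, x, y must be one-dimensional")
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) < 2:
            raise ValueError("a trajectory needs at least two samples")
        if not (np.isfinite(t).all() and np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("trajectory contains non-finite values")
        if np.any(np.diff(t) < 0):
            raise ValueError("time stamps must be monotone nondecreasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def points(self) -> np.ndarray:
        """Sample positions as an (n, 2) array."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class ResampledTrajectory:
    """A trajectory resampled to points equally spaced in arc length."""

    points: np.ndarray  # (n, 2) in cm

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TrialGeometry:
    """Per-trial geometric quantities of one drawn circle."""

    center: tuple[float, float]
    radius: float
    aspect_ratio: float
    path_length: float
    start_end_distance: float
    is_circular: bool


def _require_nondegenerate(traj: RawTrajectory) -> None:
    if np.ptp(traj.x) == 0.0 and np.ptp(traj.y) == 0.0:
        raise DegenerateTrajectoryError("all trajectory samples coincide")


def compute_center(traj: RawTrajectory) -> tuple[float, float]:
    """Center of a drawing: mean of the min and max position per axis."""
    _require_nondegenerate(traj)
    cx = 0.5 * (traj.x.min() + traj.x.max())
    cy = 0.5 * (traj.y.min() + traj.y.max())
    return float(cx), float(cy)


def path_length(traj: RawTrajectory) -> float:
    """Total length of the sampled polyline, in cm."""
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def start_end_distance(traj: RawTrajectory) -> float:
    """Euclidean distance between the first and last sample, in cm."""
    return float(np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))


def resample_spatial(traj: RawTrajectory, n: int = N_RESAMPLE) -> ResampledTrajectory:
    """Resample a trajectory to ``n`` points equally spaced in arc length.

    Points sit at arc lengths ``s_i = i * L / n`` for ``i = 0..n-1``
    (half-open parameterization: a closed curve's coincident start/end
    point is not represented twice), obtained by linear interpolation
    along the sampled polyline.  The result depends only on the path, not
    on the speed profile with which it was drawn.

    Raises
    ------
    DegenerateTrajectoryError
        If the path has zero length.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seg = np.hypot(np.diff(traj.x), np.diff(traj.y))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0.0:
        raise DegenerateTrajectoryError("trajectory has zero path length")
    si = np.arange(n) * (total / n)
    xi = np.interp(si, s, traj.x)
    yi = np.interp(si, s, traj.y)
    return ResampledTrajectory(np.column_stack([xi, yi]))


def compute_radius(traj: RawTrajectory, n: int = N_RESAMPLE) -> float:
    """Mean distance of the arc-length-resampled points to the center."""
    cx, cy = compute_center(traj)
    pts = resample_spatial(traj, n).points
    return float(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy).mean())


def compute_aspect_ratio(
    traj: RawTrajectory,
    n: int = N_RESAMPLE,
    step_deg: float = ASPECT_SCAN_STEP_DEG,
) -> float:
    """Worst perpendicular-extent ratio of the resampled drawing.

    For each orientation on a grid over [0°, 90°) the drawing's resampled
    points are projected on that direction and its perpendicular; the
    extent is max minus min of the projections.  Returned is the ratio
    ``extent(theta) / extent(theta + 90°)`` whose deviation from one
    (|log ratio|) is largest.  A perfect circle gives 1; an elongated
    drawing gives a value far from 1 (possibly 0 or inf for a segment).
    """
    _require_nondegenerate(traj)
    pts = resample_spatial(traj, n).points
    theta = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    dirs = np.stack([np.cos(theta), np.sin(theta)])          # (2, k)
    perp = np.stack([-np.sin(theta), np.cos(theta)])         # (2, k)
    ext_a = np.ptp(pts @ dirs, axis=0)
    ext_b = np.ptp(pts @ perp, axis=0)
    with np.errstate(divide="ignore"):
        ratio = np.where(ext_b > 0.0, ext_a / np.where(ext_b > 0, ext_b, 1.0), np.inf)
        ratio = np.where((ext_a == 0.0) & (ext_b > 0.0), 0.0, ratio)
        score = np.abs(np.log(np.where(ratio > 0.0, ratio, np.finfo(float).tiny)))
        score = np.where(np.isinf(ratio), np.inf, score)
    return float(ratio[int(np.argmax(score))])


def classify_circular(g: TrialGeometry) -> bool:
    """Apply the circularity gate to a trial's geometry.

    Non-circular when the aspect ratio is below 0.1 or above 10, or when
    the path length is shorter than twice the start-to-end distance.
    """
    return _circular_from_scalars(g.aspect_ratio, g.path_length, g.start_end_distance)


def _circular_from_scalars(aspect_ratio: float, plen: float, closure: float) -> bool:
    lo, hi = ASPECT_RATIO_BOUNDS
    if not np.isfinite(aspect_ratio):
        return False
    if aspect_ratio < lo or aspect_ratio > hi:
        return False
    if plen < CLOSURE_FACTOR * closure:
        return False
    return True


def trial_geometry(traj: RawTrajectory, n: int = N_RESAMPLE) -> TrialGeometry:
    """Compute all per-trial geometric quantities for one trajectory.

    Raises :class:`DegenerateTrajectoryError` for a trajectory without
    spatial extent; callers analysing whole sessions should catch it and
    record the trial as non-circular rather than aborting.
    """
    center = compute_center(traj)
    pts = resample_spatial(traj, n).points
    radius = float(np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]).mean())
    aspect = compute_aspect_ratio(traj, n)
    plen = path_length(traj)
    closure = start_end_distance(traj)
    return TrialGeometry(
        center=center,
        radius=radius,
        aspect_ratio=aspect,
        path_length=plen,
        start_end_distance=closure,
        is_circular=_circular_from_scalars(aspect, plen, closure),
    )
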