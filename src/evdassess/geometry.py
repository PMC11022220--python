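"""Trajectory-versus-target geometry for ventricular targeting trials.

The ventricular target is approximated as a sphere of radius ``R`` (mm).  A
trainee's catheter path is a straight segment defined by an entry point on the
skull, a unit direction vector, and a depth of insertion.  From these we derive
the standard targeting measures:

* **engagement** ``E`` — the length of the path's intersection with the target
  ball (the chord length, for a through-and-through pass);
* **closest approach** ``d`` — the minimum distance from the target centre to
  the (clamped) path segment;
* the **distance metric** ``D = R − sqrt(R² − d²)`` — zero for a dead-centre
  pass, rising steeply to ``R`` at the wall, and continued past the wall as a
  complex number whose non-zero imaginary part flags a miss.  The magnitude
  ``|D|`` equals ``d`` for every ``d ≥ R`` and is continuous and monotone
  non-decreasing in ``d``;
* **angulation** — the unsigned angles between the actual and ideal directions
  after projection into the sagittal and coronal planes;
* **MDM** — the signed distance from the catheter tip to the nearest point of
  the ventricle wall (negative inside the target).

Geometric quantities are in millimetres, angles in degrees, times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateProjectionError, InvalidInputError

__all__ = [
    "Trajectory",
    "TargetSphere",
    "FlaggedDistance",
    "AnatomicalFrame",
    "RAS",
    "TargetingMeasures",
    "closest_approach",
    "line_distance",
    "engagement",
    "metric_D",
    "angulation",
    "mdm",
    "measure_trial",
]

UNIT_TOL = 1e-9
#: angle (degrees) below which a projected direction is treated as zero-length
PROJECTION_TOL = 1e-12


def _as_vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise InvalidInputError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite, got {arr}")
    return arr


@dataclass(frozen=True)
class Trajectory:
    """A planned catheter path: entry point, unit direction, depth of insertion.

    Parameters
    ----------
    entry : (3,) array_like, mm
    direction : (3,) array_like, unit norm within 1e-9
    depth : float, mm, strictly positive
    """

    entry: np.ndarray
    direction: np.ndarray
    depth: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry", _as_vec3(self.entry, "entry"))
        direction = _as_vec3(self.direction, "direction")
        norm = float(np.linalg.norm(direction))
        if abs(norm - 1.0) > UNIT_TOL:
            raise InvalidInputError(
                f"direction must be unit-norm within {UNIT_TOL:g}; got ‖v‖ = {norm!r}"
            )
        object.__setattr__(self, "direction", direction)
        depth = float(self.depth)
        if not math.isfinite(depth) or depth <= 0:
            raise InvalidInputError(f"depth must be a positive finite length, got {depth!r}")
        object.__setattr__(self, "depth", depth)

    @property
    def tip(self) -> np.ndarray:
        """Catheter tip position, ``entry + depth * direction`` (mm)."""
        return self.entry + self.depth * self.direction


@dataclass(frozen=True)
class TargetSphere:
    """Spherical approximation of the ventricular target volume."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))
        radius = float(self.radius)
        if not math.isfinite(radius) or radius <= 0:
            raise InvalidInputError(f"radius must be a positive finite length, got {radius!r}")
        object.__setattr__(self, "radius", radius)


@dataclass(frozen=True)
class FlaggedDistance:
    """The complex-valued distance metric, stored component-wise.

    ``outside`` is true exactly when the imaginary part is non-zero, i.e. when
    the closest approach exceeded the target radius.  The magnitude is the
    complex modulus ``sqrt(real² + imag²)``.
    """

    real_part: float
    imag_part: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.real_part, self.imag_part)

    @property
    def outside(self) -> bool:
        return self.imag_part != 0.0

    @property
    def as_complex(self) -> complex:
        return complex(self.real_part, self.imag_part)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Anatomical coordinate convention used for plane projections.

    The default is RAS: x = right, y = anterior, z = superior.  The sagittal
    plane has normal x; the coronal plane has normal y.
    """

    sagittal_normal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    coronal_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        for name in ("sagittal_normal", "coronal_normal"):
            vec = _as_vec3(getattr(self, name), name)
            norm = float(np.linalg.norm(vec))
            if norm == 0:
                raise InvalidInputError(f"{name} must be non-zero")
            object.__setattr__(self, name, vec / norm)


#: default right/anterior/superior frame
RAS = AnatomicalFrame()


@dataclass(frozen=True)
class TargetingMeasures:
    """All per-trial geometric outcomes for one targeting attempt."""

    engagement: float
    closest_distance: float
    metric: FlaggedDistance
    sagittal_angle: float
    coronal_angle: float
    mdm: float
    task_time: float

    def __post_init__(self) -> None:
        if self.engagement < 0 or self.closest_distance < 0:
            raise InvalidInputError("engagement and closest_distance must be non-negative")
        if not self.task_time > 0:
            raise InvalidInputError(f"task_time must be positive, got {self.task_time!r}")


def closest_approach(traj: Trajectory, target: TargetSphere) -> float:
    """Minimum distance (mm) from the target centre to the closed path segment.

    The segment is ``entry + t * depth * direction`` for ``t`` in [0, 1]; a
    drain that stops short of the target is scored by its tip, not by the
    infinite line through it.
    """
    rel = target.center - traj.entry
    t = float(np.clip(np.dot(rel, traj.direction), 0.0, traj.depth))
    return float(np.linalg.norm(rel - t * traj.direction))


def line_distance(traj: Trajectory, target: TargetSphere) -> float:
    """Distance (mm) from the target centre to the infinite line through the path."""
    rel = target.center - traj.entry
    t = float(np.dot(rel, traj.direction))
    return float(np.linalg.norm(rel - t * traj.direction))


def engagement(traj: Trajectory, target: TargetSphere) -> float:
    """Length (mm) of the path segment's intersection with the closed target ball.

    For a segment long enough to contain the full chord this is
    ``2 * sqrt(R² − d_line²)``; it is zero when the line misses the ball, and
    is truncated when the segment enters but does not traverse it.
    """
    rel = target.center - traj.entry
    m = float(np.dot(rel, traj.direction))  # arclength of the foot of the perpendicular
    disc = target.radius**2 - (float(np.dot(rel, rel)) - m * m)
    if disc <= 0.0:
        return 0.0
    half = math.sqrt(disc)
    lo = max(m - half, 0.0)
    hi = min(m + half, traj.depth)
    return max(hi - lo, 0.0)


def metric_D(d: float, R: float) -> FlaggedDistance:
    """The targeting distance metric ``D = R − sqrt(R² − d²)``, continued past the wall.

    Inside the target (``d ≤ R``) D is real: 0 at the centre, R at the wall,
    with the Lorentz-form identity ``1 − D/R = sqrt(1 − d²/R²)``.  Outside,
    the square root goes imaginary and D is continued on the principal branch
    as ``R − i*sqrt(d² − R²)``; the non-zero imaginary part flags the miss and
    the magnitude equals the Euclidean miss distance ``d`` for every ``d ≥ R``.
    """
    d = float(d)
    R = float(R)
    if not (math.isfinite(d) and d >= 0):
        raise InvalidInputError(f"d must be a finite non-negative length, got {d!r}")
    if not (math.isfinite(R) and R > 0):
        raise InvalidInputError(f"R must be a positive finite length, got {R!r}")
    if d <= R:
        return FlaggedDistance(real_part=R - math.sqrt(R * R - d * d), imag_part=0.0)
    return FlaggedDistance(real_part=R, imag_part=-math.sqrt(d * d - R * R))


def _project_unit(direction: np.ndarray, normal: np.ndarray, label: str) -> np.ndarray:
    proj = direction - np.dot(direction, normal) * normal
    norm = float(np.linalg.norm(proj))
    if norm <= PROJECTION_TOL:
        raise DegenerateProjectionError(
            f"direction {direction} is orthogonal to the {label} plane; "
            "its in-plane angle is undefined"
        )
    return proj / norm


def angulation(
    traj: Trajectory, ideal: Trajectory, frame: AnatomicalFrame = RAS
) -> tuple[float, float]:
    """Unsigned sagittal- and coronal-plane angles (degrees) between actual and
    ideal directions.

    Each direction is projected onto the named plane and the angle between the
    projections is returned, in [0, 180].  A direction orthogonal to a plane
    has no defined in-plane heading and raises
    :class:`~evdassess.exceptions.DegenerateProjectionError`.
    """
    angles = []
    for normal, label in ((frame.sagittal_normal, "sagittal"), (frame.coronal_normal, "coronal")):
        a = _project_unit(traj.direction, normal, label)
        b = _project_unit(ideal.direction, normal, label)
        cosang = float(np.clip(np.dot(a, b), -1.0, 1.0))
        angles.append(math.degrees(math.acos(cosang)))
    return angles[0], angles[1]


def mdm(tip, target: TargetSphere) -> float:
    """Signed distance (mm) from a point to the closest ventricle wall.

    Negative inside the target, zero on the wall, positive outside.
    """
    tip = _as_vec3(tip, "tip")
    return float(np.linalg.norm(tip - target.center)) - target.radius


def measure_trial(
    traj: Trajectory,
    target: TargetSphere,
    ideal: Trajectory,
    task_time: float,
    frame: AnatomicalFrame = RAS,
) -> TargetingMeasures:
    """Compute the full set of targeting measures for one trial."""
    d = closest_approach(traj, target)
    sag, cor = angulation(traj, ideal, frame)
    return TargetingMeasures(
        engagement=engagement(traj, target),
        closest_distance=d,
        metric=metric_D(d, target.radius),
        sagittal_angle=sag,
        coronal_angle=cor,
        mdm=mdm(traj.tip, target),
        task_time=float(task_time),
    )
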