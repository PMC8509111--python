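"""Frame, localizer and scan-plane geometry.

Coordinate conventions
----------------------
Frame coordinates (x, y, z), all in millimetres:

* origin at the centre of the frame base,
* +y anterior, +z superior, +x completing a right-handed system
  (the patient's left when facing anteriorly),
* localizers are attached tangentially to a circle of given radius
  around the frame's vertical axis.

Image coordinates (u, v) are physical millimetres in the scan plane
with origin at the point where the frame's vertical axis pierces the
plane.  The chart is an isometry: distances measured between (u, v)
points equal the 3D distances between the corresponding plane points,
which is what makes inter-fiducial image distances usable as 3D
distances.

An anteroposterior tilt ``theta`` rotates the scan plane about the
left-right (x) axis; positive ``theta`` raises the anterior side, so
the plane height is greater anteriorly than posteriorly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    DegenerateGeometryError,
    OffPlaneError,
    OutOfExtentError,
)

__all__ = [
    "RodLine",
    "SPLocalizerGeom",
    "NLocalizerGeom",
    "ScanPlanePose",
    "make_plane",
    "intersect",
    "to_image",
    "to_frame",
    "build_frame",
    "min_valid_height",
]

_UNIT_TOL = 1e-12

#: Outward horizontal unit vectors of the four frame aspects.
ASPECT_DIRECTIONS = {
    "anterior": np.array([0.0, 1.0, 0.0]),
    "posterior": np.array([0.0, -1.0, 0.0]),
    "left": np.array([-1.0, 0.0, 0.0]),
    "right": np.array([1.0, 0.0, 0.0]),
}


def _as_unit(vec, name):
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be a unit vector, |{name}| = {n!r}")
    return v


@dataclass(frozen=True)
class RodLine:
    """A rod's cylindrical axis: ``base + t * direction`` for t in [0, length]."""

    base: np.ndarray
    direction: np.ndarray
    length: float
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "base", np.asarray(self.base, dtype=float))
        object.__setattr__(self, "direction", _as_unit(self.direction, "direction"))
        if not np.all(np.isfinite(self.base)):
            raise ValueError("rod base must be finite")
        if not self.length > 0:
            raise ValueError(f"rod length must be positive, got {self.length}")

    def point_at(self, t):
        return self.base + t * self.direction

    @property
    def end(self):
        return self.point_at(self.length)


@dataclass(frozen=True)
class SPLocalizerGeom:
    """A Sturm-Pastyr localizer: a V of two diagonal rods around a vertical rod.

    All three rod axes lie in a vertical plane spanned by ``in_plane_axis``
    (horizontal) and ``up_axis`` (vertical) through the shared ``apex``.
    At local height h above the apex, the diagonal rods A and C sit at
    horizontal offsets -h*tan(alpha) and +h*tan(alpha), so for an untilted
    slice the fiducial spacings are d_AB = d_BC = h*tan(alpha) and
    d_AC = 2*h*tan(alpha).

    Parameters
    ----------
    apex : (3,) array
        Shared inferior meeting point of the V and base of the vertical rod.
    in_plane_axis, up_axis : (3,) unit vectors
        Orthonormal horizontal/vertical directions of the localizer plane.
    alpha : float
        Half-angle of the V in radians, in (0, pi/2).
    extent : float
        Vertical span of the rods in mm (rod A/C axis length is
        ``extent / cos(alpha)``).
    localizer_id : str
        Aspect name or other identifier.
    """

    apex: np.ndarray
    in_plane_axis: np.ndarray
    up_axis: np.ndarray
    alpha: float
    extent: float
    localizer_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float))
        object.__setattr__(
            self, "in_plane_axis", _as_unit(self.in_plane_axis, "in_plane_axis")
        )
        object.__setattr__(self, "up_axis", _as_unit(self.up_axis, "up_axis"))
        if abs(float(self.in_plane_axis @ self.up_axis)) > _UNIT_TOL:
            raise ValueError("in_plane_axis and up_axis must be orthogonal")
        if not 0.0 < self.alpha < math.pi / 2:
            raise ConfigError(f"half-angle alpha must be in (0, pi/2), got {self.alpha}")
        if not self.extent > 0:
            raise ConfigError(f"extent must be positive, got {self.extent}")

    @property
    def tan_alpha(self) -> float:
        return math.tan(self.alpha)

    def point_at_height(self, h, rod):
        """Frame point on rod 'A', 'B' or 'C' at local height ``h`` above the apex."""
        t = self.tan_alpha
        offset = {"A": -t, "B": 0.0, "C": t}[rod]
        return self.apex + h * (self.up_axis + offset * self.in_plane_axis)

    def rods(self):
        """The three rod axes as :class:`RodLine` (A diagonal, B vertical, C diagonal)."""
        t = self.tan_alpha
        diag_len = self.extent * math.hypot(1.0, t)
        out = []
        for label, off in (("A", -t), ("B", 0.0), ("C", t)):
            d = self.up_axis + off * self.in_plane_axis
            d = d / np.linalg.norm(d)
            length = self.extent if label == "B" else diag_len
            out.append(
                RodLine(self.apex, d, length, label=f"{self.localizer_id}:{label}")
            )
        return tuple(out)


@dataclass(frozen=True)
class NLocalizerGeom:
    """An N-localizer: two vertical rods joined by a diagonal in an N shape.

    The vertical rods stand at horizontal offsets ``-width/2`` and
    ``+width/2`` along ``in_plane_axis`` from ``center``; the diagonal
    runs from the top of the first vertical rod (the 'A' side) to the
    bottom of the second (the 'C' side).  All three axes are coplanar.
    """

    center: np.ndarray
    in_plane_axis: np.ndarray
    up_axis: np.ndarray
    width: float
    height: float
    localizer_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(
            self, "in_plane_axis", _as_unit(self.in_plane_axis, "in_plane_axis")
        )
        object.__setattr__(self, "up_axis", _as_unit(self.up_axis, "up_axis"))
        if abs(float(self.in_plane_axis @ self.up_axis)) > _UNIT_TOL:
            raise ValueError("in_plane_axis and up_axis must be orthogonal")
        if not (self.width > 0 and self.height > 0):
            raise ConfigError("N-localizer width and height must be positive")

    def rods(self):
        """Rod axes (vertical A, diagonal B, vertical C)."""
        half = 0.5 * self.width
        base_a = self.center - half * self.in_plane_axis
        base_c = self.center + half * self.in_plane_axis
        rod_a = RodLine(base_a, self.up_axis, self.height, label=f"{self.localizer_id}:A")
        rod_c = RodLine(base_c, self.up_axis, self.height, label=f"{self.localizer_id}:C")
        top_a = rod_a.end
        diag = base_c - top_a
        diag_len = float(np.linalg.norm(diag))
        rod_b = RodLine(top_a, diag / diag_len, diag_len, label=f"{self.localizer_id}:B")
        return rod_a, rod_b, rod_c

    @property
    def diagonal_top(self):
        """Top-of-rod-A end of the diagonal."""
        return self.rods()[1].base

    @property
    def diagonal_bottom(self):
        """Bottom-of-rod-C end of the diagonal."""
        r = self.rods()[1]
        return r.end


@dataclass(frozen=True)
class ScanPlanePose:
    """A CT slice: plane through (0, 0, z0) satisfying z = z0 + y*tan(theta).

    ``e_u`` (frame +x) and ``e_v`` form an orthonormal in-plane chart with
    origin at (0, 0, z0); the chart is an isometry between image (u, v)
    millimetres and 3D plane points.
    """

    z0: float
    theta: float
    origin: np.ndarray = field(init=False)
    e_u: np.ndarray = field(init=False)
    e_v: np.ndarray = field(init=False)
    normal: np.ndarray = field(init=False)

    def __post_init__(self):
        if not abs(self.theta) < math.pi / 2:
            raise ConfigError(f"|theta| must be < pi/2, got {self.theta}")
        c, s = math.cos(self.theta), math.sin(self.theta)
        object.__setattr__(self, "origin", np.array([0.0, 0.0, float(self.z0)]))
        object.__setattr__(self, "e_u", np.array([1.0, 0.0, 0.0]))
        object.__setattr__(self, "e_v", np.array([0.0, c, s]))
        object.__setattr__(self, "normal", np.array([0.0, -s, c]))


def make_plane(z0, theta=0.0):
    """Scan plane at central height ``z0`` (mm) with anteroposterior tilt ``theta`` (rad)."""
    return ScanPlanePose(float(z0), float(theta))


def intersect(line: RodLine, plane: ScanPlanePose, tol=1e-9):
    """Intersection point of a rod axis with a scan plane.

    Raises
    ------
    DegenerateGeometryError
        If the rod is (numerically) parallel to the plane.
    OutOfExtentError
        If the intersection lies beyond the rod's ends, i.e. the slice
        misses the physical rod.
    """
    denom = float(plane.normal @ line.direction)
    if abs(denom) < 1e-12:
        raise DegenerateGeometryError(
            f"rod {line.label!r} is parallel to the scan plane"
        )
    t = float(plane.normal @ (plane.origin - line.base)) / denom
    if t < -tol or t > line.length + tol:
        raise OutOfExtentError(
            f"plane misses rod {line.label!r}: axis parameter {t:.3f} "
            f"outside [0, {line.length:.3f}]"
        )
    return line.point_at(t)


def to_image(p, plane: ScanPlanePose, tol=1e-6):
    """Chart an on-plane 3D point into image (u, v) millimetres."""
    p = np.asarray(p, dtype=float)
    rel = p - plane.origin
    dist = abs(float(rel @ plane.normal))
    if dist > tol:
        raise OffPlaneError(f"point {p} is {dist:.3g} mm off the scan plane")
    return np.array([float(rel @ plane.e_u), float(rel @ plane.e_v)])


def to_frame(q, plane: ScanPlanePose):
    """Inverse chart: image (u, v) to the 3D frame point on the plane."""
    q = np.asarray(q, dtype=float)
    return plane.origin + q[0] * plane.e_u + q[1] * plane.e_v


def min_valid_height(radius, theta):
    """Smallest slice height whose plane clears the frame base.

    A tilted plane dips below its central height on the low side; it must
    not intersect the frame base (z = 0) anywhere within the placement
    radius.
    """
    return abs(radius * math.tan(theta))


def plane_is_valid(plane: ScanPlanePose, radius) -> bool:
    """Whether the plane clears the frame base within the placement radius."""
    return plane.z0 >= min_valid_height(radius, plane.theta) - 1e-12


def _tangent_axis(outward):
    """Horizontal in-plane axis for a localizer facing ``outward``: z-hat x outward."""
    return np.cross(np.array([0.0, 0.0, 1.0]), outward)


def build_frame(config):
    """Build the localizer geometries for a frame configuration.

    Parameters
    ----------
    config : FrameConfig
        Localizer kind ('sp' or 'n'), aspect list, placement radius and
        per-kind dimensions (see :class:`spframe.config.FrameConfig`).

    Returns
    -------
    dict
        Mapping aspect name -> :class:`SPLocalizerGeom` or
        :class:`NLocalizerGeom`, in the configured aspect order.
    """
    geoms = {}
    for aspect in config.aspects:
        if aspect not in ASPECT_DIRECTIONS:
            raise ConfigError(
                f"unknown aspect {aspect!r}; expected one of {sorted(ASPECT_DIRECTIONS)}"
            )
        outward = ASPECT_DIRECTIONS[aspect]
        attach = config.radius * outward
        axis = _tangent_axis(outward)
        up = np.array([0.0, 0.0, 1.0])
        if config.kind == "sp":
            geoms[aspect] = SPLocalizerGeom(
                apex=attach,
                in_plane_axis=axis,
                up_axis=up,
                alpha=config.alpha,
                extent=config.extent,
                localizer_id=aspect,
            )
        elif config.kind == "n":
            geoms[aspect] = NLocalizerGeom(
                center=attach,
                in_plane_axis=axis,
                up_axis=up,
                width=config.n_width,
                height=config.n_height,
                localizer_id=aspect,
            )
        else:
            raise ConfigError(f"unknown localizer kind {config.kind!r}")
    return geoms
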