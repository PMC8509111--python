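"""N-localizer forward model and inverse.

The N-localizer's two vertical rods and one diagonal rod are cut by a
scan plane in three collinear points (two planes intersect in a line).
The fraction ``f = d_AB / d_AC`` at which the diagonal fiducial B
divides the segment between the vertical-rod fiducials A and C equals
the fraction at which the plane crosses the diagonal rod, so

    p_B = top_of_rod_A_end + f * (bottom_of_rod_C_end - top_of_rod_A_end)

recovers the 3D crossing point exactly at any tilt angle — the
N-localizer's accuracy is insensitive to tilt, unlike the Sturm-Pastyr
V whose fiducial spacing shrinks when the slice drops toward the apex.

Each diagonal rod yields one full (u,v) <-> (x,y,z) correspondence; each
vertical rod yields an (x, y)-only correspondence (its frame-horizontal
position is constant at every height), improving accuracy in x and y
but not in z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, OutOfExtentError
from .geometry import NLocalizerGeom, ScanPlanePose, intersect, to_image
from .registration import Correspondence
from .sp import FiducialSet

__all__ = ["NSolution", "n_forward", "n_solve", "n_correspondences"]


@dataclass(frozen=True)
class NSolution:
    """Result of the N-localizer inverse for one localizer."""

    p_b: np.ndarray
    xy_a: np.ndarray
    xy_c: np.ndarray
    fraction: float


def n_forward(geom: NLocalizerGeom, plane: ScanPlanePose) -> FiducialSet:
    """Noise-free fiducial centres (vertical A, diagonal B, vertical C)."""
    uvs = [to_image(intersect(rod, plane), plane) for rod in geom.rods()]
    return FiducialSet(geom.localizer_id, *uvs)


def n_solve(fid: FiducialSet, geom: NLocalizerGeom, tol=1e-9) -> NSolution:
    """Invert one N-localizer's fiducials.

    The solved point is constrained to the diagonal rod axis by
    construction, so it remains on the rod under noisy input.

    Raises
    ------
    DegenerateInputError
        If ``d_AC`` is not positive.
    OutOfExtentError
        If the interpolation fraction falls outside [0, 1] beyond
        tolerance (the slice misses the diagonal rod).
    """
    d_ac = fid.d_ac
    if d_ac <= 0:
        raise DegenerateInputError("d_AC must be positive for the N solve")
    f = fid.d_ab / d_ac
    if f < -tol or f > 1 + tol:
        raise OutOfExtentError(
            f"diagonal fraction {f:.4f} outside [0, 1]: slice beyond the N extent"
        )
    f = min(max(f, 0.0), 1.0)
    rod_a, rod_b, rod_c = geom.rods()
    top = rod_b.base      # top of vertical rod A
    bottom = rod_b.end    # bottom of vertical rod C
    p_b = top + f * (bottom - top)
    return NSolution(
        p_b=p_b,
        xy_a=rod_a.base[:2].copy(),
        xy_c=rod_c.base[:2].copy(),
        fraction=f,
    )


def n_correspondences(sol: NSolution, fid: FiducialSet):
    """One full pair from the diagonal plus two xy-only pairs per localizer."""
    return [
        Correspondence(uv=fid.uv_b, xyz=sol.p_b),
        Correspondence(uv=fid.uv_a, xy=sol.xy_a),
        Correspondence(uv=fid.uv_c, xy=sol.xy_c),
    ]
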