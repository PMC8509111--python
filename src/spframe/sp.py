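"""Sturm-Pastyr forward model and inverse solves.

A Sturm-Pastyr (SP) localizer is a coplanar V of two diagonal rods (A, C)
around a central vertical rod (B).  A CT slice cuts the three rod axes in
three points whose image centres ("fiducials") are collinear in the
absence of noise, so the three inter-fiducial distances satisfy
``d_AC = d_AB + d_BC`` and carry two independent pieces of information.
Image noise breaks collinearity, making all three distances linearly
independent; the three-point solve below exploits this to recover one
point per rod axis instead of the single point of the classic solve.

Inverse problem
---------------
Let ``t = tan(alpha)`` and parameterize points on the three rod axes by
their local heights ``h_A, h_B, h_C`` above the apex.  In localizer-plane
coordinates these are ``P_A = (-h_A t, h_A)``, ``P_B = (0, h_B)``,
``P_C = (h_C t, h_C)``.  The three-point solve finds heights whose
pairwise distances match the measured ``d_AB, d_BC, d_AC``.

With ``k = 1 + t**2``, ``s = h_A + h_C``, ``p = h_A - h_C`` and squared
distances normalized by ``d_AC**2`` the system reduces algebraically to a
single quadratic in ``S = s**2``::

    (f1**2 + 4 t**6 D**2) S**2 + (2 f1 f0 - 4 t**4 D**2) S + f0**2 = 0

where ``D = (d_AB**2 - d_BC**2)/d_AC**2``, ``Sg = (d_AB**2 + d_BC**2)/d_AC**2``,
``f1 = t**2 (2 Sg - k)`` and ``f0 = k - 2 Sg + D**2``.  Each real root
yields one candidate via ``p = sign(F D) sqrt(P)``, ``h_B = (k s - q)/2``
with ``P = 1 - t**2 S``, ``F = f1 S + f0`` and ``q = 2 t**2 s D**2 / F``.

Collinear (noise-free) input is exactly the tangency of this quadratic —
the same degeneracy as the linear dependence of the three distances — and
there the two roots merge into the well-conditioned midpoint ``-B/2A``,
for which the cancellation-free forms::

    P* = t**4 D**2 (2 Sg - (1 - t**2)) / A
    F* = 2 t**6 D**2 (f0 + D**2) / A        (so q -> A s / (t**4 (f0 + D**2)))

follow from the identity ``f1 + t**2 f0 == t**2 D**2`` (normalized units).
All quadratic algebra runs in extended precision (``np.longdouble``) so
that the tangency test cleanly separates noise-free roundoff from genuine
near-collinear noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .errors import DegenerateInputError, SolverFailureError
from .geometry import ScanPlanePose, SPLocalizerGeom, intersect, to_image

__all__ = [
    "FiducialSet",
    "SPSolution",
    "forward",
    "solve_classic",
    "classic_height",
    "solve_three_point",
    "solve_heights_batch",
    "correspondences",
]

_L = np.longdouble

#: Relative discriminant below which input is treated as exactly collinear
#: (tangency).  Noise-free float64 pipelines measure |disc_rel| <= ~3e-19;
#: genuinely noisy input almost never falls below ~1e-15.
TANGENCY_THRESHOLD = 1e-17

#: Relative discriminant below which the system is declared infeasible
#: (no real solution; the perturbed distances violate the reachable set).
INFEASIBLE_THRESHOLD = -1e-9

#: d_AC below this is a slice essentially at the apex; the solve degenerates.
MIN_DAC = 1.0

# status codes of the batch solver
OK, DEGENERATE, INFEASIBLE, NO_BRANCH = 0, 1, 2, 3
STATUS_LABELS = {OK: "ok", DEGENERATE: "degenerate", INFEASIBLE: "infeasible",
                 NO_BRANCH: "no_branch"}


@dataclass(frozen=True)
class FiducialSet:
    """Measured (u, v) centres of fiducials A, B, C for one localizer.

    Distances are always recomputed from the stored centres, never cached,
    so the ``d_XY == |uv_X - uv_Y|`` invariant holds by construction.
    """

    localizer_id: str
    uv_a: np.ndarray
    uv_b: np.ndarray
    uv_c: np.ndarray

    def __post_init__(self):
        for name in ("uv_a", "uv_b", "uv_c"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (2,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite (2,) array")
            object.__setattr__(self, name, v)

    @property
    def d_ab(self) -> float:
        return float(np.linalg.norm(self.uv_a - self.uv_b))

    @property
    def d_bc(self) -> float:
        return float(np.linalg.norm(self.uv_b - self.uv_c))

    @property
    def d_ac(self) -> float:
        return float(np.linalg.norm(self.uv_a - self.uv_c))

    @property
    def collinearity_residual(self) -> float:
        """d_AC - (d_AB + d_BC): zero for collinear (noise-free) centres."""
        return self.d_ac - self.d_ab - self.d_bc

    def squared_distances(self):
        """(d_AB^2, d_BC^2, d_AC^2) accumulated in extended precision."""
        a = self.uv_a.astype(_L)
        b = self.uv_b.astype(_L)
        c = self.uv_c.astype(_L)
        return (
            np.sum((a - b) ** 2),
            np.sum((b - c) ** 2),
            np.sum((a - c) ** 2),
        )

    def perturbed(self, offsets):
        """New set with the three centres displaced by ``offsets`` (3, 2)."""
        off = np.asarray(offsets, dtype=float)
        return FiducialSet(
            self.localizer_id,
            self.uv_a + off[0],
            self.uv_b + off[1],
            self.uv_c + off[2],
        )


@dataclass(frozen=True)
class SPSolution:
    """Result of the three-point solve: one frame point per rod axis."""

    p_a: np.ndarray
    p_b: np.ndarray
    p_c: np.ndarray
    heights: np.ndarray
    collinearity_residual: float
    branch: dict = field(default_factory=dict)

    @property
    def points(self):
        return self.p_a, self.p_b, self.p_c


def forward(geom: SPLocalizerGeom, plane: ScanPlanePose) -> FiducialSet:
    """Noise-free fiducial centres of one SP localizer in a scan plane.

    Intersects the plane with the three rod axes and charts the
    intersection points into image coordinates.  Raises
    :class:`~spframe.errors.OutOfExtentError` if the slice misses a rod
    and :class:`~spframe.errors.DegenerateGeometryError` if a rod is
    parallel to the plane.
    """
    uvs = []
    for rod in geom.rods():
        p = intersect(rod, plane)
        uvs.append(to_image(p, plane))
    return FiducialSet(geom.localizer_id, *uvs)


def classic_height(fid: FiducialSet, geom: SPLocalizerGeom) -> float:
    """Local height of the classic one-point estimate.

    The classic method assumes the three fiducial centres are collinear
    (exactly true without noise): the scan line through the localizer
    plane is parameterized by the rod-B height ``h_B`` and its local
    slope ``m``, for which ``d_AB = h_A t sqrt(1+m^2)`` and
    ``d_BC = h_C t sqrt(1+m^2)`` with ``h_A = h_B/(1+tm)``,
    ``h_C = h_B/(1-tm)``.  Inverting,

        m   = (d_BC - d_AB) / (t (d_AB + d_BC))
        h_B = (d_AB + d_BC) (1 - t^2 m^2) / (2 t sqrt(1 + m^2))

    which is exact for noise-free input at any tilt.  The slope estimate
    divides by the inter-fiducial spacing, so its noise amplification —
    and with it the classic method's error — grows sharply as the slice
    approaches the apex, and worsens under tilt.
    """
    d_ab, d_bc = fid.d_ab, fid.d_bc
    if fid.d_ac < MIN_DAC or d_ab + d_bc <= 0:
        raise DegenerateInputError(
            f"d_AC = {fid.d_ac:.3f} mm below the {MIN_DAC} mm degeneracy "
            "threshold (slice at the localizer apex)"
        )
    t = geom.tan_alpha
    m = (d_bc - d_ab) / (t * (d_ab + d_bc))
    if abs(t * m) >= 1.0:
        raise SolverFailureError(
            f"classic solve: estimated scan-line slope {m:.3f} outside the "
            "V opening (perturbed fiducials inconsistent with the geometry)"
        )
    return (d_ab + d_bc) * (1.0 - t * t * m * m) / (2.0 * t * math.hypot(1.0, m))


def classic_anchor(fid: FiducialSet, geom: SPLocalizerGeom):
    """Classic collinear-model height triple (h_A, h_B, h_C), used as the
    branch anchor of the three-point solve; falls back to the symmetric
    estimate when the classic solve fails."""
    t = geom.tan_alpha
    try:
        h_b = classic_height(fid, geom)
        m = (fid.d_bc - fid.d_ab) / (t * (fid.d_ab + fid.d_bc))
        return np.array([h_b / (1 + t * m), h_b, h_b / (1 - t * m)])
    except SolverFailureError:
        h = fid.d_ac / (2.0 * t)
        return np.array([h, h, h])


def solve_classic(fid: FiducialSet, geom: SPLocalizerGeom, clamp=False):
    """Classic Sturm-Pastyr inverse: one point, on the vertical rod B.

    See :func:`classic_height` for the collinear scan-line model.  The
    returned frame point pairs with fiducial B (the circle fiducial on
    the vertical rod) in the registration.
    """
    h = classic_height(fid, geom)
    if h > geom.extent:
        if not clamp:
            raise SolverFailureError(
                f"classic height {h:.2f} mm beyond rod extent {geom.extent:.2f} mm"
            )
        h = geom.extent
    return geom.point_at_height(h, "B")


def _fwd_heights_ld(h, t):
    """Pairwise distances of the three axis points at longdouble heights."""
    ha, hb, hc = h
    k = 1 + t * t
    return np.array(
        [
            np.sqrt(k * ha * ha - 2 * ha * hb + hb * hb),
            np.sqrt(k * hc * hc - 2 * hc * hb + hb * hb),
            np.sqrt(t * t * (ha + hc) ** 2 + (ha - hc) ** 2),
        ]
    )


def _polish_ld(h, d_ld, t, iters=14):
    """Damped Newton refinement of one height triple, in longdouble.

    ``np.linalg`` has no longdouble support, so the 3x3 system is solved
    by Cramer's rule.  Near-tangent roots make the Jacobian almost
    singular; step halving keeps the iteration monotone.
    """
    k = 1 + t * t
    best = h.copy()
    bres = np.max(np.abs(_fwd_heights_ld(h, t) - d_ld))
    floor = _L(1e-16) * max(d_ld[2], _L(1.0))
    for _ in range(iters):
        if bres < floor:
            break
        ha, hb, hc = h
        dd = _fwd_heights_ld(h, t)
        r = dd - d_ld
        dab, dbc, dac = (max(x, _L(1e-12)) for x in dd)
        j00 = (k * ha - hb) / dab
        j01 = (hb - ha) / dab
        j11 = (hb - hc) / dbc
        j12 = (k * hc - hb) / dbc
        j20 = (k * ha + (t * t - 1) * hc) / dac
        j22 = (k * hc + (t * t - 1) * ha) / dac
        # Cramer's rule on the sparse Jacobian
        # | j00 j01  0  |   [sx]   [r0]
        # |  0  j11 j12 | * [sy] = [r1]
        # | j20  0  j22 |   [sz]   [r2]
        det = j00 * j11 * j22 + j01 * j12 * j20
        if det == 0:
            break
        r0, r1, r2 = -r
        sx = (r0 * j11 * j22 - j01 * (r1 * j22 - j12 * r2)) / det
        sy = (j00 * (r1 * j22 - j12 * r2) + r0 * j12 * j20) / det
        sz = (j00 * j11 * r2 + j01 * r1 * j20 - r0 * j11 * j20) / det
        step = np.array([sx, sy, sz])
        fac = _L(1.0)
        improved = False
        for _ in range(6):
            h2 = h + fac * step
            res2 = np.max(np.abs(_fwd_heights_ld(h2, t) - d_ld))
            if res2 < bres:
                h, bres = h2, res2
                best = h2.copy()
                improved = True
                break
            fac /= 2
        if not improved:
            break
    return best, bres


def solve_heights_batch(
    dab2,
    dbc2,
    dac2,
    tan_alpha,
    extent,
    h_init,
    *,
    residual_tol=1e-6,
    min_dac=MIN_DAC,
):
    """Vectorized closed-form three-point solve on squared distances.

    Parameters
    ----------
    dab2, dbc2, dac2 : (N,) arrays (any float dtype; promoted to longdouble)
        Squared inter-fiducial distances.
    tan_alpha : float
        V half-angle tangent of the localizer.
    extent : float
        Vertical rod extent in mm; admissible heights lie in [0, extent].
    h_init : (N,) or (N, 3) array
        Branch anchor, normally the classic collinear-model estimate
        (h_A, h_B, h_C); among admissible real solutions the one nearest
        in summed squared height difference to the anchor is returned.
        A 1-D anchor h is broadcast to (h, h, h).
    residual_tol : float
        Relative distance-residual admission tolerance.  The default 1e-6
        suits the unpolished Monte Carlo path; the scalar API tightens it
        after Newton polish.

    Returns
    -------
    heights : (N, 3) float64
        Recovered (h_A, h_B, h_C); zeros where not ok.
    status : (N,) int8
        0 ok, 1 degenerate (d_AC < min_dac), 2 infeasible (no real
        solution), 3 no admissible branch within [0, extent].
    diag : dict of arrays
        'disc_rel' and 'tangent' per element.
    """
    t = _L(tan_alpha)
    k = 1 + t * t
    ab2 = np.asarray(dab2, dtype=_L)
    bc2 = np.asarray(dbc2, dtype=_L)
    ac2 = np.asarray(dac2, dtype=_L)
    n = ac2.shape[0]
    h_init = np.asarray(h_init, dtype=float)
    if h_init.ndim == 1:
        h_init = h_init[:, None].repeat(3, axis=1)

    status = np.full(n, NO_BRANCH, dtype=np.int8)
    heights = np.zeros((n, 3), dtype=float)

    scale = np.sqrt(ac2.astype(float))
    degenerate = ~(scale >= min_dac)
    status[degenerate] = DEGENERATE
    live = ~degenerate

    with np.errstate(divide="ignore", invalid="ignore"):
        a2 = np.where(live, ab2 / np.where(ac2 > 0, ac2, 1), 0)
        b2 = np.where(live, bc2 / np.where(ac2 > 0, ac2, 1), 0)
        D = a2 - b2
        Sg = a2 + b2
        f1 = t * t * (2 * Sg - k)
        f0 = k - 2 * Sg + D * D
        A = f1 * f1 + 4 * t**6 * D * D
        B = 2 * f1 * f0 - 4 * t**4 * D * D
        disc = B * B - 4 * A * f0 * f0
        sc2 = np.maximum(B * B, 4 * A * f0 * f0)
        sc2 = np.maximum(sc2, _L(1e-300))
        disc_rel = (disc / sc2).astype(float)

        infeasible = live & (disc_rel < INFEASIBLE_THRESHOLD)
        status[infeasible] = INFEASIBLE
        live = live & ~infeasible

        tangent = live & (disc_rel <= TANGENCY_THRESHOLD)
        delta = np.sqrt(np.maximum(disc, 0)) / (2 * A)
        delta = np.where(tangent, _L(0), delta)

        s_star = -B / (2 * A)
        p_star = t**4 * D * D * (2 * Sg - (1 - t * t)) / A
        f_star = 2 * t**6 * D * D * (f0 + D * D) / A

        # two candidate roots per element (they coincide at the tangency)
        S = np.stack([s_star + delta, s_star - delta], axis=1)
        P = np.stack([p_star - t * t * delta, p_star + t * t * delta], axis=1)
        F = np.stack([f_star + f1 * delta, f_star - f1 * delta], axis=1)

        D2 = D[:, None]
        valid = (S >= 0) & (P >= -_L(1e-9)) & live[:, None]
        S = np.maximum(S, 0)
        P = np.maximum(P, 0)
        s = np.sqrt(S)

        sym = D2 == 0
        denom_sym = (t**4 * (f0 + D * D))[:, None]
        q_sym = np.where(denom_sym != 0, A[:, None] * s / np.where(denom_sym != 0, denom_sym, 1), np.inf)
        q_gen = np.where(F != 0, 2 * t * t * s * D2 * D2 / np.where(F != 0, F, 1), np.inf)
        q = np.where(sym, q_sym, q_gen)
        valid &= np.isfinite(q.astype(float))

        p = np.where(sym, _L(0), np.sign(F) * np.sign(D2) * np.sqrt(P))

        sc = np.asarray(scale, dtype=_L)[:, None]
        h_a = ((s + p) / 2 * sc).astype(float)
        h_b = ((k * s - q) / 2 * sc).astype(float)
        h_c = ((s - p) / 2 * sc).astype(float)

    cand = np.stack([h_a, h_b, h_c], axis=2)  # (n, 2, 3)

    # admission: distance residual and extent
    d_model = _pairwise_distances(cand, float(tan_alpha))  # (n, 2, 3)
    d_meas = np.sqrt(np.stack([ab2, bc2, ac2], axis=1).astype(float))  # (n, 3)
    res = np.max(np.abs(d_model - d_meas[:, None, :]), axis=2)
    tol = residual_tol * np.maximum(scale, 1.0)
    admissible = (
        valid
        & (res <= tol[:, None])
        & np.all(cand >= -1e-9, axis=2)
        & np.all(cand <= extent + 1e-9, axis=2)
    )

    d2 = np.sum((cand - h_init[:, None, :]) ** 2, axis=2)
    d2 = np.where(admissible, d2, np.inf)
    # near-tie between the two branches: prefer the larger h_B, deterministically
    both = np.all(admissible, axis=1)
    gap = np.abs(np.where(both, d2[:, 0], 0.0) - np.where(both, d2[:, 1], 0.0))
    near_tie = both & (
        gap <= 1e-7 * np.maximum(np.where(both, np.max(d2, axis=1), 0.0), 1e-30)
    )
    pick = np.argmin(d2, axis=1)
    pick = np.where(near_tie, np.argmax(cand[:, :, 1], axis=1), pick)
    got = np.take_along_axis(d2, pick[:, None], axis=1)[:, 0]
    okmask = np.isfinite(got)
    chosen = np.take_along_axis(cand, pick[:, None, None], axis=1)[:, 0, :]
    heights[okmask] = chosen[okmask]
    status[okmask] = OK
    return heights, status, {"disc_rel": disc_rel, "tangent": tangent}


def _pairwise_distances(h, t):
    """Distances (d_AB, d_BC, d_AC) for height triples h (..., 3), float64."""
    k = 1 + t * t
    ha, hb, hc = h[..., 0], h[..., 1], h[..., 2]
    dab = np.sqrt(np.maximum(k * ha * ha - 2 * ha * hb + hb * hb, 0))
    dbc = np.sqrt(np.maximum(k * hc * hc - 2 * hc * hb + hb * hb, 0))
    dac = np.sqrt(np.maximum(t * t * (ha + hc) ** 2 + (ha - hc) ** 2, 0))
    return np.stack([dab, dbc, dac], axis=-1)


def solve_three_point(fid: FiducialSet, geom: SPLocalizerGeom) -> SPSolution:
    """Three-point Sturm-Pastyr inverse: one frame point per rod axis.

    Uses the closed-form quadratic (module docstring) with extended
    precision and a damped-Newton polish; the branch nearest to the
    classic estimate among real in-extent solutions is returned.

    Raises
    ------
    DegenerateInputError
        If ``d_AC < 1`` mm (slice at the apex).
    SolverFailureError
        If the perturbed distances admit no real solution, or none with
        all three heights within the rod extent.
    """
    t = geom.tan_alpha
    dab2, dbc2, dac2 = fid.squared_distances()
    if float(np.sqrt(dac2)) < MIN_DAC:
        raise DegenerateInputError(
            f"d_AC = {float(np.sqrt(dac2)):.3f} mm below the {MIN_DAC} mm "
            "degeneracy threshold (slice at the localizer apex)"
        )
    anchor = classic_anchor(fid, geom)
    heights, status, diag = solve_heights_batch(
        np.array([dab2]), np.array([dbc2]), np.array([dac2]),
        t, geom.extent, anchor[None, :], residual_tol=1e-6,
    )
    if status[0] == INFEASIBLE:
        raise SolverFailureError(
            "no real solution: perturbed distances are infeasible for the rod "
            f"geometry (disc_rel = {diag['disc_rel'][0]:.3e})",
            residuals=None,
        )
    if status[0] != OK:
        raise SolverFailureError(
            "no admissible solution branch within the rod extent",
            residuals=None,
        )

    # polish in longdouble unless the input was classified as collinear
    d_ld = np.array([np.sqrt(dab2), np.sqrt(dbc2), np.sqrt(dac2)], dtype=_L)
    h_ld = heights[0].astype(_L)
    if not diag["tangent"][0]:
        h_ld, _ = _polish_ld(h_ld, d_ld, _L(t))
    h = h_ld.astype(float)

    d_model = _pairwise_distances(h[None, :], t)[0]
    d_meas = np.array([fid.d_ab, fid.d_bc, fid.d_ac])
    resid = d_model - d_meas
    tol = 1e-9 * max(fid.d_ac, 1.0)
    if np.max(np.abs(resid)) > tol:
        raise SolverFailureError(
            "three-point solve did not converge to tolerance",
            residuals=resid,
        )
    p_a = geom.point_at_height(h[0], "A")
    p_b = geom.point_at_height(h[1], "B")
    p_c = geom.point_at_height(h[2], "C")
    return SPSolution(
        p_a=p_a,
        p_b=p_b,
        p_c=p_c,
        heights=h,
        collinearity_residual=fid.collinearity_residual,
        branch={
            "disc_rel": float(diag["disc_rel"][0]),
            "tangent": bool(diag["tangent"][0]),
            "classic_anchor": anchor,
            "distance_residuals": resid,
        },
    )


def correspondences(solution, fid: FiducialSet):
    """Pair measured (u, v) centres with solved frame points.

    ``solution`` may be an :class:`SPSolution` (three-point mode: three
    full pairs) or a single frame point (classic mode: one pair anchored
    at fiducial B, the circle fiducial on the vertical rod).
    """
    from .registration import Correspondence

    if isinstance(solution, SPSolution):
        return [
            Correspondence(uv=fid.uv_a, xyz=solution.p_a),
            Correspondence(uv=fid.uv_b, xyz=solution.p_b),
            Correspondence(uv=fid.uv_c, xyz=solution.p_c),
        ]
    point = np.asarray(solution, dtype=float)
    if point.shape != (3,):
        raise ValueError("classic solution must be a single (3,) frame point")
    return [Correspondence(uv=fid.uv_b, xyz=point)]


def scan_line_heights(geom: SPLocalizerGeom, plane: ScanPlanePose):
    """True per-rod intersection heights of a plane, for reference/oracles."""
    out = []
    for rod, label in zip(geom.rods(), "ABC"):
        p = geometry.intersect(rod, plane)
        h = float((p - geom.apex) @ geom.up_axis)
        out.append(h)
    return np.array(out)
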