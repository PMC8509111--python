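"""Monte Carlo estimation of registration accuracy (RMSe).

Protocol, per scenario and slice height z:

1. forward-model every localizer to get exact fiducial centres,
2. fit the unperturbed image-to-frame matrix M (residual ~ 0),
3. per iteration, displace every fiducial centre by an independent
   random vector of Euclidean norm <= the noise bound (1.0 mm by
   default), re-solve every localizer and refit the perturbed matrix,
4. map the six target points with both matrices and accumulate the
   squared 3D distance between the two images of each target,
5. after n iterations report, per target,

       RMSe = sqrt( (1/n) * sum_i [ (x_i - x^_i)^2 + (y_i - y^_i)^2
                                    + (z_i - z^_i)^2 ] ).

Iterations in which any localizer's solve fails (near the apex the
perturbed distances can be infeasible for the rod geometry) are counted
and excluded; the tables carry ``n_used``/``n_failed`` per cell.

Randomness is reproducible and order-independent: each (seed, scenario,
height) cell gets its own counter-based Philox stream, so re-running a
single height or re-ordering a sweep gives bit-identical numbers.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sp
from .config import ScenarioConfig
from .errors import ConfigError, OutOfExtentError, SpframeError
from .geometry import build_frame, make_plane, plane_is_valid
from .registration import fit_transform

logger = logging.getLogger(__name__)

__all__ = ["NoiseModel", "perturb", "run_height", "sweep", "RMSE_COLUMNS"]

RMSE_COLUMNS = [
    "scenario_id", "mode", "theta_deg", "target", "z_mm",
    "rmse_mm", "se_mm", "n_used", "n_failed",
]

_CHUNK = 1 << 15


@dataclass(frozen=True)
class NoiseModel:
    """Bounded random displacement of fiducial centres.

    ``disk`` (default) draws uniformly from the closed disk of radius
    ``max_magnitude`` — the natural reading of a "maximum magnitude"
    bound on the displacement vector.  ``square`` draws each component
    uniformly from [-m/sqrt(2), +m/sqrt(2)] so the norm bound still
    holds.  ``gaussian`` is an isotropic normal (sigma = m/2) with
    rejection outside the disk.  Every variant guarantees
    ``|offset| <= max_magnitude``.
    """

    max_magnitude: float = 1.0
    distribution: str = "disk"

    def __post_init__(self):
        if self.max_magnitude < 0:
            raise ConfigError("max_magnitude must be >= 0")
        if self.distribution not in ("disk", "square", "gaussian"):
            raise ConfigError(f"unknown noise distribution {self.distribution!r}")

    def sample(self, rng, shape):
        """Offsets of shape ``shape + (2,)`` with norm <= max_magnitude."""
        m = self.max_magnitude
        if m == 0:
            return np.zeros(tuple(shape) + (2,))
        if self.distribution == "disk":
            r = m * np.sqrt(rng.random(shape))
            ang = rng.uniform(0, 2 * np.pi, shape)
            return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=-1)
        if self.distribution == "square":
            half = m / np.sqrt(2.0)
            return rng.uniform(-half, half, tuple(shape) + (2,))
        # truncated gaussian
        out = rng.normal(0.0, m / 2.0, tuple(shape) + (2,))
        norm = np.linalg.norm(out, axis=-1, keepdims=True)
        bad = norm[..., 0] > m
        while np.any(bad):
            out[bad] = rng.normal(0.0, m / 2.0, (int(bad.sum()), 2))
            norm = np.linalg.norm(out, axis=-1, keepdims=True)
            bad = norm[..., 0] > m
        return out


def perturb(fid: sp.FiducialSet, noise: NoiseModel, rng) -> sp.FiducialSet:
    """One noisy copy of a fiducial set (distances recomputed, not stored)."""
    return fid.perturbed(noise.sample(rng, (3,)))


def _cell_stream(seed, scenario_id, z_index):
    """Independent Philox stream for one (seed, scenario, height) cell."""
    key = zlib.crc32(scenario_id.encode())
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                spawn_key=(key, int(z_index)))
    return np.random.Generator(np.random.Philox(ss))


def _exact_fiducials(scenario, plane):
    """Exact fiducial sets per localizer; raises OutOfExtentError if missed."""
    geoms = build_frame(scenario.frame)
    out = []
    for aspect, geom in geoms.items():
        if scenario.mode == "n_localizer":
            from .nloc import n_forward
            out.append((geom, n_forward(geom, plane)))
        else:
            out.append((geom, sp.forward(geom, plane)))
    return out


def _unperturbed_matrix(scenario, plane, loc_fids):
    """Fit M from the exact (noise-free) correspondences."""
    from .nloc import n_correspondences, n_solve

    records = []
    for geom, fid in loc_fids:
        if scenario.mode == "classic":
            records += sp.correspondences(sp.solve_classic(fid, geom), fid)
        elif scenario.mode == "three_point":
            records += sp.correspondences(sp.solve_three_point(fid, geom), fid)
        else:
            records += n_correspondences(n_solve(fid, geom), fid)
    return fit_transform(records)


def _classic_heights_batch(uv_hat, geom):
    """Vectorized collinear-model classic estimate; see sp.classic_height."""
    t = geom.tan_alpha
    d_ab = np.linalg.norm(uv_hat[:, 0, :] - uv_hat[:, 1, :], axis=1)
    d_bc = np.linalg.norm(uv_hat[:, 1, :] - uv_hat[:, 2, :], axis=1)
    d_ac = np.linalg.norm(uv_hat[:, 0, :] - uv_hat[:, 2, :], axis=1)
    ok = (d_ac >= sp.MIN_DAC) & (d_ab + d_bc > 0)
    denom = np.where(ok, d_ab + d_bc, 1.0)
    m = (d_bc - d_ab) / (t * denom)
    ok &= np.abs(t * m) < 1.0
    h = (d_ab + d_bc) * (1.0 - t * t * m * m) / (2.0 * t * np.hypot(1.0, m))
    return np.where(ok, h, 0.0), np.where(ok, m, 0.0), ok


def _batch_solve_sp_three_point(uv_hat, geom):
    """Per-iteration rod points from perturbed centres, (n, 3, 2) -> (n, 3, 3)."""
    a = uv_hat[:, 0, :].astype(np.longdouble)
    b = uv_hat[:, 1, :].astype(np.longdouble)
    c = uv_hat[:, 2, :].astype(np.longdouble)
    dab2 = np.sum((a - b) ** 2, axis=1)
    dbc2 = np.sum((b - c) ** 2, axis=1)
    dac2 = np.sum((a - c) ** 2, axis=1)
    t = geom.tan_alpha
    h_cl, m_cl, cl_ok = _classic_heights_batch(uv_hat, geom)
    # anchor = classic collinear triple; symmetric fallback where classic fails
    h_sym = np.sqrt(dac2.astype(float)) / (2.0 * t)
    anchor = np.empty((uv_hat.shape[0], 3))
    anchor[:, 0] = np.where(cl_ok, h_cl / (1 + t * m_cl), h_sym)
    anchor[:, 1] = np.where(cl_ok, h_cl, h_sym)
    anchor[:, 2] = np.where(cl_ok, h_cl / (1 - t * m_cl), h_sym)
    heights, status, _ = sp.solve_heights_batch(
        dab2, dbc2, dac2, t, geom.extent, anchor
    )
    ok = status == sp.OK
    e = geom.in_plane_axis
    u = geom.up_axis
    dirs = np.stack([u - t * e, u, u + t * e])  # (3, 3): rod A, B, C
    pts = geom.apex[None, None, :] + heights[:, :, None] * dirs[None, :, :]
    return pts, ok


def _batch_solve_sp_classic(uv_hat, geom):
    """Classic per-iteration point on rod B, (n, 3, 2) -> (n, 1, 3)."""
    h, _, ok = _classic_heights_batch(uv_hat, geom)
    ok &= h <= geom.extent
    pts = geom.apex[None, None, :] + h[:, None, None] * geom.up_axis[None, None, :]
    return pts, ok


def _batch_solve_n(uv_hat, geom):
    """N-localizer per-iteration diagonal point, (n, 3, 2) -> (n, 1, 3)."""
    d_ab = np.linalg.norm(uv_hat[:, 0, :] - uv_hat[:, 1, :], axis=1)
    d_ac = np.linalg.norm(uv_hat[:, 0, :] - uv_hat[:, 2, :], axis=1)
    ok = d_ac > 0
    f = np.where(ok, d_ab / np.where(d_ac > 0, d_ac, 1.0), 0.0)
    ok &= (f >= -1e-9) & (f <= 1 + 1e-9)
    f = np.clip(f, 0.0, 1.0)
    _, rod_b, _ = geom.rods()
    top, bottom = rod_b.base, rod_b.end
    pts = top[None, None, :] + f[:, None, None] * (bottom - top)[None, None, :]
    return pts, ok


def _fit_batch(design, rhs, z_rows):
    """Batched per-iteration least-squares fit of the 3x3 matrices.

    design : (n, m, 3) rows [u, v, 1];  rhs : (n, m, 3) frame coords
    (z entries of xy-only rows are ignored);  z_rows : (m,) bool mask of
    rows that constrain the z column.
    """
    gram = np.einsum("nmi,nmj->nij", design, design)
    atb_xy = np.einsum("nmi,nmk->nik", design, rhs[:, :, :2])
    m_xy = np.linalg.solve(gram, atb_xy)  # (n, 3, 2)
    if z_rows.all():
        gram_z = gram
        atb_z = np.einsum("nmi,nm->ni", design, rhs[:, :, 2])
    else:
        dz = design[:, z_rows, :]
        gram_z = np.einsum("nmi,nmj->nij", dz, dz)
        atb_z = np.einsum("nmi,nm->ni", dz, rhs[:, z_rows, 2])
    m_z = np.linalg.solve(gram_z, atb_z[:, :, None])  # (n, 3, 1)
    return np.concatenate([m_xy, m_z], axis=2)  # (n, 3, 3)


def run_height(scenario: ScenarioConfig, z0: float, seed: int,
               n_iterations=None, z_index=None):
    """RMSe rows (one per target) for a single slice height.

    Returns a list of dicts with :data:`RMSE_COLUMNS`; an empty list if
    the height is invalid for the scenario (plane hits the frame base or
    misses a rod), with the reason logged.
    """
    n_total = int(n_iterations if n_iterations is not None else scenario.n_iterations)
    if z_index is None:
        z_index = int(round((z0 - scenario.z_start) / scenario.z_step))
    plane = make_plane(z0, scenario.theta)
    if not plane_is_valid(plane, scenario.frame.radius):
        logger.info("skip %s z=%.1f: plane intersects the frame base",
                    scenario.scenario_id, z0)
        return []
    try:
        loc_fids = _exact_fiducials(scenario, plane)
    except (OutOfExtentError, SpframeError) as exc:
        logger.info("skip %s z=%.1f: %s", scenario.scenario_id, z0, exc)
        return []

    uv0 = np.stack([np.stack([f.uv_a, f.uv_b, f.uv_c]) for _, f in loc_fids])
    n_loc = len(loc_fids)

    if scenario.mode == "three_point":
        rows_per_loc, z_row_mask = 3, [True, True, True]
    elif scenario.mode == "classic":
        rows_per_loc, z_row_mask = 1, [True]
    else:
        rows_per_loc, z_row_mask = 3, [True, False, False]
    z_rows = np.array(z_row_mask * n_loc)

    def solve_and_design(uv_hat):
        """Per-iteration design/rhs/valid-mask for perturbed centres."""
        n = uv_hat.shape[0]
        design = np.empty((n, rows_per_loc * n_loc, 3))
        rhs = np.empty((n, rows_per_loc * n_loc, 3))
        ok = np.ones(n, dtype=bool)
        for i, (geom, _) in enumerate(loc_fids):
            uv_i = uv_hat[:, i, :, :]
            if scenario.mode == "three_point":
                pts, ok_i = _batch_solve_sp_three_point(uv_i, geom)
                duv = uv_i  # all three fiducials enter the design
            elif scenario.mode == "classic":
                pts, ok_i = _batch_solve_sp_classic(uv_i, geom)
                duv = uv_i[:, 1:2, :]  # fiducial B only
            else:
                pts_b, ok_i = _batch_solve_n(uv_i, geom)
                rod_a, _, rod_c = geom.rods()
                pts = np.empty((n, 3, 3))
                pts[:, 0, :] = pts_b[:, 0, :]
                pts[:, 1, :2] = rod_a.base[:2]
                pts[:, 2, :2] = rod_c.base[:2]
                pts[:, 1:, 2] = 0.0  # unused: xy-only rows
                duv = uv_i[:, [1, 0, 2], :]  # diagonal first, then verticals
            sl = slice(i * rows_per_loc, (i + 1) * rows_per_loc)
            design[:, sl, 0:2] = duv
            design[:, sl, 2] = 1.0
            rhs[:, sl, :] = pts
            ok &= ok_i
        return design, rhs, ok

    # unperturbed matrix through the same batch path, so that a zero-noise
    # run is bit-identical and RMSe degenerates to exactly zero
    d0, r0, ok0 = solve_and_design(uv0[None, :, :, :])
    if not ok0[0]:
        logger.info("skip %s z=%.1f: unperturbed solve failed",
                    scenario.scenario_id, z0)
        return []
    m0 = _fit_batch(d0, r0, z_rows)[0]
    fit_resid = np.abs(
        np.einsum("mi,ij->mj", d0[0], m0)[:, :2] - r0[0][:, :2]
    ).max()
    if fit_resid > 1e-6:
        logger.warning("%s z=%.1f: unperturbed fit residual %.2e",
                       scenario.scenario_id, z0, fit_resid)

    labels, target_uv = scenario.target_array()
    tdesign = np.hstack([target_uv, np.ones((len(labels), 1))])  # (T, 3)
    t0 = tdesign @ m0  # unperturbed target coordinates

    noise = NoiseModel(scenario.noise_mm, scenario.noise_distribution)
    rng = _cell_stream(seed, scenario.scenario_id, z_index)

    sumsq = np.zeros(len(labels))
    sumsq2 = np.zeros(len(labels))
    n_used = 0
    n_failed = 0
    done = 0
    while done < n_total:
        n = min(_CHUNK, n_total - done)
        done += n
        offsets = noise.sample(rng, (n, n_loc, 3))
        uv_hat = uv0[None, :, :, :] + offsets  # (n, n_loc, 3, 2)
        design, rhs, ok = solve_and_design(uv_hat)

        n_failed += int(n - ok.sum())
        if not np.any(ok):
            continue
        m_hat = _fit_batch(design[ok], rhs[ok], z_rows)
        t_hat = np.einsum("ti,nij->ntj", tdesign, m_hat)
        sq = np.sum((t_hat - t0[None, :, :]) ** 2, axis=2)  # (n_ok, T)
        sumsq += sq.sum(axis=0)
        sumsq2 += (sq**2).sum(axis=0)
        n_used += int(ok.sum())

    rows = []
    for j, label in enumerate(labels):
        if n_used == 0:
            rmse = np.nan
            se = np.nan
        else:
            mean_sq = sumsq[j] / n_used
            rmse = float(np.sqrt(mean_sq))
            var_sq = max(sumsq2[j] / n_used - mean_sq**2, 0.0)
            se_mean = np.sqrt(var_sq / n_used)
            se = float(se_mean / (2 * rmse)) if rmse > 0 else 0.0
        rows.append(
            dict(
                scenario_id=scenario.scenario_id,
                mode=scenario.mode,
                theta_deg=scenario.theta_deg,
                target=label,
                z_mm=float(z0),
                rmse_mm=rmse,
                se_mm=se,
                n_used=n_used,
                n_failed=n_failed,
            )
        )
    return rows


def sweep(scenarios, seed: int, n_iterations=None) -> pd.DataFrame:
    """Full RMSe table over scenarios x heights x targets.

    Invalid heights are skipped (logged), never aborting the sweep.
    ``n_iterations`` overrides every scenario's iteration count (the
    published protocol's 2^21 is impractical for routine runs).
    """
    rows = []
    for scenario in scenarios:
        for idx, z0 in enumerate(scenario.heights()):
            rows += run_height(scenario, float(z0), seed,
                               n_iterations=n_iterations, z_index=idx)
    return pd.DataFrame(rows, columns=RMSE_COLUMNS)
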