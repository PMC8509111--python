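"""Overdetermined least-squares image-to-frame registration.

The mapping from image to frame coordinates of one scan plane is affine:
``[x, y, z] = [u, v, 1] @ M`` with a 3x3 matrix ``M`` whose rows are the
images of the chart axes and origin.  Given fiducial correspondences
(measured (u, v) centre <-> solved (x, y, z) frame point) the matrix is
fitted column-by-column by ordinary (unweighted) linear least squares.

Vertical N-localizer rods contribute partial correspondences that pin
down (x, y) but say nothing about z; such ``xy_only`` records enter the
x and y column fits but never the z column.

The model/results split follows the statsmodels convention:
``PlaneRegistration(records).fit()`` returns a
:class:`PlaneRegistrationResults` carrying the matrix, per-record
residuals and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "Correspondence",
    "PlaneRegistration",
    "PlaneRegistrationResults",
    "fit_transform",
    "apply_transform",
]


@dataclass(frozen=True)
class Correspondence:
    """One fiducial pairing.

    ``kind='full'`` pairs (u, v) with a 3D frame point; ``kind='xy_only'``
    pairs it with a fixed horizontal position (vertical rods have constant
    (x, y) at every height).
    """

    uv: np.ndarray
    xyz: np.ndarray = None
    xy: np.ndarray = None

    def __post_init__(self):
        object.__setattr__(self, "uv", np.asarray(self.uv, dtype=float))
        if self.uv.shape != (2,):
            raise ValueError("uv must be a (2,) array")
        if (self.xyz is None) == (self.xy is None):
            raise ValueError("provide exactly one of xyz (full) or xy (xy_only)")
        if self.xyz is not None:
            object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))
            if self.xyz.shape != (3,):
                raise ValueError("xyz must be a (3,) array")
        else:
            object.__setattr__(self, "xy", np.asarray(self.xy, dtype=float))
            if self.xy.shape != (2,):
                raise ValueError("xy must be a (2,) array")

    @property
    def kind(self) -> str:
        return "full" if self.xyz is not None else "xy_only"


def _design(records):
    full = [r for r in records if r.kind == "full"]
    part = [r for r in records if r.kind == "xy_only"]
    if len(full) < 3:
        raise ConfigError(
            f"need at least 3 full correspondences to resolve z, got {len(full)}"
        )
    a_full = np.array([[r.uv[0], r.uv[1], 1.0] for r in full])
    b_full = np.array([r.xyz for r in full])
    if part:
        a_part = np.array([[r.uv[0], r.uv[1], 1.0] for r in part])
        b_part = np.array([r.xy for r in part])
        a_xy = np.vstack([a_full, a_part])
        b_xy = np.vstack([b_full[:, :2], b_part])
    else:
        a_xy = a_full
        b_xy = b_full[:, :2]
    return a_full, b_full, a_xy, b_xy


def _check_rank(a, what):
    if np.linalg.matrix_rank(a, tol=1e-8 * max(np.abs(a).max(), 1.0)) < 3:
        raise ConfigError(
            f"degenerate fit: the (u, v) fiducial centres of the {what} records "
            "are collinear"
        )


def fit_transform(records):
    """Least-squares 3x3 transform from a correspondence list.

    x and y columns are fitted on all records; the z column on full
    records only.  Raises :class:`~spframe.errors.ConfigError` for fewer
    than three full records or collinear (u, v) designs.
    """
    a_full, b_full, a_xy, b_xy = _design(records)
    _check_rank(a_full, "full")
    _check_rank(a_xy, "combined")
    m = np.empty((3, 3))
    m[:, :2], *_ = np.linalg.lstsq(a_xy, b_xy, rcond=None)
    m[:, 2], *_ = np.linalg.lstsq(a_full, b_full[:, 2], rcond=None)
    return m


def apply_transform(m, uv):
    """Map image (u, v) (single point or (N, 2)) to frame coordinates."""
    uv = np.asarray(uv, dtype=float)
    single = uv.ndim == 1
    pts = np.atleast_2d(uv)
    out = np.hstack([pts, np.ones((len(pts), 1))]) @ m
    return out[0] if single else out


class PlaneRegistration:
    """Image-to-frame registration model for one scan plane.

    Parameters
    ----------
    records : sequence of Correspondence
        Full and xy-only fiducial pairings from any mix of localizers.

    Examples
    --------
    >>> res = PlaneRegistration(records).fit()
    >>> res.transform            # the 3x3 matrix
    >>> res.predict([0.0, 0.0])  # frame coordinates of the image centre
    """

    def __init__(self, records):
        self.records = list(records)
        if not self.records:
            raise ConfigError("no correspondences given")

    @classmethod
    def from_dataframe(cls, df):
        """Build from a DataFrame with columns u_mm, v_mm, x_mm, y_mm, z_mm.

        Rows with missing/NaN ``z_mm`` become xy-only records.
        """
        records = []
        for _, row in df.iterrows():
            uv = [row["u_mm"], row["v_mm"]]
            if "z_mm" in df.columns and np.isfinite(row["z_mm"]):
                records.append(
                    Correspondence(uv=uv, xyz=[row["x_mm"], row["y_mm"], row["z_mm"]])
                )
            else:
                records.append(Correspondence(uv=uv, xy=[row["x_mm"], row["y_mm"]]))
        return cls(records)

    @property
    def n_full(self):
        return sum(r.kind == "full" for r in self.records)

    @property
    def n_xy_only(self):
        return sum(r.kind == "xy_only" for r in self.records)

    def fit(self):
        m = fit_transform(self.records)
        return PlaneRegistrationResults(self, m)


class PlaneRegistrationResults:
    """Fitted registration: matrix, residuals and diagnostics."""

    def __init__(self, model, transform):
        self.model = model
        self.transform = transform
        resid = []
        for r in model.records:
            mapped = apply_transform(transform, r.uv)
            if r.kind == "full":
                resid.append(mapped - r.xyz)
            else:
                resid.append(np.array([*(mapped[:2] - r.xy), np.nan]))
        self.resid = np.array(resid)

    @property
    def rmse(self) -> float:
        """Root mean square residual over all fitted components."""
        sq = np.square(self.resid)
        return float(np.sqrt(np.nanmean(np.where(np.isnan(sq), np.nan, sq))))

    @property
    def max_abs_resid(self) -> float:
        return float(np.nanmax(np.abs(self.resid)))

    def predict(self, uv):
        """Frame coordinates of image points under the fitted transform."""
        return apply_transform(self.transform, uv)

    def summary(self) -> str:
        model = self.model
        lines = [
            "Image-to-frame registration (ordinary least squares)",
            "=" * 56,
            f"records: {len(model.records)}  "
            f"(full: {model.n_full}, xy-only: {model.n_xy_only})",
            f"rmse: {self.rmse:.6g} mm   max |resid|: {self.max_abs_resid:.6g} mm",
            "",
            "transform [u v 1] -> [x y z]:",
        ]
        for row in self.transform:
            lines.append("  [{: 12.6f} {: 12.6f} {: 12.6f}]".format(*row))
        lines.append("")
        lines.append(f"{'u_mm':>10} {'v_mm':>10} {'kind':>8} {'resid_mm':>12}")
        for r, e in zip(model.records, self.resid):
            norm = np.sqrt(np.nansum(np.square(e)))
            lines.append(
                f"{r.uv[0]:>10.3f} {r.uv[1]:>10.3f} {r.kind:>8} {norm:>12.3e}"
            )
        return "\n".join(lines)
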