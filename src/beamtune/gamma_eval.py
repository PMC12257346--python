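"""Gamma-index comparison of dose distributions.

The gamma index combines a dose-difference criterion (in percent, local or
global normalization) with a distance-to-agreement criterion (in mm): for a
reference point r with dose D_r,

    gamma(r) = min over evaluated positions p of
               sqrt( ((D_e(p) - D_r) / dD)^2 + (|p - r| / dd)^2 )

where dd is the distance criterion and dD is ``dose_crit`` percent of the
local reference dose (local normalization) or of the reference maximum
(global). Points below a low-dose threshold (percent of the reference
maximum) are excluded. A pass rate (GPR) is the percentage of evaluated
reference points with gamma <= 1.

The evaluated distribution is linearly interpolated and searched in two
stages: a shared coarse sub-grid (default one tenth of the distance
criterion) inside a capped radius bounds gamma per point, then an
exhaustive fine-grid pass (default one hundredth of the distance
criterion) inside each point's proven search radius resolves the narrow
dose-level-set valleys that a coarse grid alone would miss, so that sharp
gradients do not produce discretization false positives. The reference is
never interpolated. For 1D profiles the minimum over the interpolated
polyline is solved exactly, segment by segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import BeamtuneError, SchemaError


@dataclass(frozen=True)
class DoseImage:
    """2D dose grid with pixel spacing and origin.

    ``values[i, j]`` is the dose at position ``origin + (i*spacing[0],
    j*spacing[1])`` in (y, x) mm. Dose units are whatever the producer used
    (Gy or percent); gamma only needs both images on the same scale.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise BeamtuneError("DoseImage values must be 2D")
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise BeamtuneError("spacing must be positive")
        if not np.all(np.isfinite(v)):
            raise BeamtuneError("DoseImage contains non-finite values")

    @property
    def ys(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.values.shape[0])

    @property
    def xs(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.values.shape[1])

    def interpolator(self) -> Callable[[np.ndarray], np.ndarray]:
        """Linear interpolator over (y, x) points; NaN outside the grid."""
        return RegularGridInterpolator(
            (self.ys, self.xs), self.values, method="linear",
            bounds_error=False, fill_value=np.nan,
        )


@dataclass(frozen=True)
class GammaParams:
    """Gamma-evaluation criteria and search controls."""

    dose_crit: float = 1.0          # [% of normalization dose]
    dist_crit: float = 1.0          # [mm]
    normalization: str = "local"    # "local" or "global"
    threshold: float = 10.0         # low-dose cutoff [% of reference max]
    search_step_fraction: float = 0.1   # coarse sub-grid step / dist_crit
    search_radius_factor: float = 3.0   # search radius / dist_crit
    fine_step_fraction: float = 0.01    # exhaustive refinement step / dist_crit

    def __post_init__(self) -> None:
        if self.dose_crit <= 0 or self.dist_crit <= 0:
            raise BeamtuneError("dose and distance criteria must be positive")
        if not 0 <= self.threshold < 100:
            raise BeamtuneError("threshold must be in [0, 100)")
        if self.normalization not in ("local", "global"):
            raise BeamtuneError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class GammaResult:
    """Gamma map aligned to the reference grid (NaN below threshold)."""

    gamma: np.ndarray
    n_evaluated: int

    @property
    def gpr(self) -> float:
        """Gamma pass rate [%]; gamma == 1 counts as passing."""
        g = self.gamma[np.isfinite(self.gamma)]
        if g.size == 0:
            raise BeamtuneError("no evaluated points")
        return 100.0 * float(np.count_nonzero(g <= 1.0 + 1e-12)) / g.size


def gpr(result: GammaResult) -> float:
    """Percentage of evaluated points with gamma <= 1."""
    return result.gpr


# ---------------------------------------------------------------------------
# Core minimization, dimension-agnostic
# ---------------------------------------------------------------------------

def _ball_offsets(ndim: int, step: float, radius: float) -> np.ndarray:
    """All offsets on a step-grid within ``radius``, sorted by distance."""
    n = int(np.floor(radius / step + 1e-9))
    axes = [step * np.arange(-n, n + 1)] * ndim
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    r2 = (pts ** 2).sum(axis=1)
    keep = r2 <= radius ** 2 + 1e-12
    pts, r2 = pts[keep], r2[keep]
    order = np.argsort(r2, kind="stable")
    return pts[order]


def _coarse_pass(
    ref_pts: np.ndarray,
    ref_dose: np.ndarray,
    eval_interp: Callable[[np.ndarray], np.ndarray],
    delta_dose: np.ndarray,
    gp: GammaParams,
) -> np.ndarray:
    """Upper-bound gamma^2 per point from a shared coarse offset sweep.

    Offsets are processed by increasing distance; a point is dropped once
    its running minimum is below the pure-distance term of every remaining
    offset.
    """
    n, ndim = ref_pts.shape
    dd2 = gp.dist_crit ** 2
    radius = gp.search_radius_factor * gp.dist_crit
    step = gp.search_step_fraction * gp.dist_crit

    gamma2 = np.full(n, np.inf)
    offsets = _ball_offsets(ndim, step, radius)
    active = np.arange(n)
    for off in offsets:
        r2 = float((off ** 2).sum())
        active = active[gamma2[active] > r2 / dd2]
        if active.size == 0:
            break
        de = eval_interp(ref_pts[active] + off)
        g2 = ((de - ref_dose[active]) / delta_dose[active]) ** 2 + r2 / dd2
        g2 = np.where(np.isnan(de), np.inf, g2)
        np.minimum.at(gamma2, active, g2)
    return gamma2


_CHUNK = 4_000_000  # max interpolation points per vectorized call


def _fine_pass(
    ref_pts: np.ndarray,
    ref_dose: np.ndarray,
    eval_interp: Callable[[np.ndarray], np.ndarray],
    delta_dose: np.ndarray,
    gamma2: np.ndarray,
    gp: GammaParams,
) -> np.ndarray:
    """Exhaustive fine-grid search within each point's proven bound.

    If gamma at a point is bounded by g, its minimizer lies within
    ``dist_crit * g`` of the point (beyond that the distance term alone
    exceeds g). Points are bucketed by bound so each bucket shares one
    fine offset template.
    """
    dd = gp.dist_crit
    dd2 = dd * dd
    fine = gp.fine_step_fraction * dd
    radius_cap = gp.search_radius_factor * dd
    bound = np.minimum(np.sqrt(gamma2) * dd + fine, radius_cap)

    order = np.argsort(bound)
    out = gamma2.copy()
    i = 0
    while i < order.size:
        r_lo = bound[order[i]]
        if r_lo <= fine:  # already (near-)exact match at zero offset
            j = int(np.searchsorted(bound[order], fine, side="right"))
            i = max(j, i + 1)
            continue
        r_hi = min(2.0 * r_lo, radius_cap)
        j = int(np.searchsorted(bound[order], r_hi, side="right"))
        j = max(j, i + 1)
        idx = order[i:j]
        offs = _ball_offsets(ref_pts.shape[1], fine, r_hi)
        # chunk points so each vectorized call stays bounded in memory
        per = max(1, _CHUNK // offs.shape[0])
        for k in range(0, idx.size, per):
            sel = idx[k:k + per]
            pts = ref_pts[sel][:, None, :] + offs[None, :, :]
            de = eval_interp(pts.reshape(-1, ref_pts.shape[1]))
            de = de.reshape(sel.size, offs.shape[0])
            r2 = (offs ** 2).sum(axis=1)[None, :]
            g2 = ((de - ref_dose[sel, None]) / delta_dose[sel, None]) ** 2 + r2 / dd2
            g2 = np.where(np.isnan(de), np.inf, g2)
            out[sel] = np.minimum(out[sel], g2.min(axis=1))
        i = j
    return out


def _gamma_points_tracked(
    ref_pts: np.ndarray,
    ref_dose: np.ndarray,
    eval_interp: Callable[[np.ndarray], np.ndarray],
    delta_dose: np.ndarray,
    gp: GammaParams,
) -> np.ndarray:
    """Minimum gamma for reference points of shape (N, ndim).

    ``delta_dose`` is the per-point dose criterion in absolute dose units.
    Evaluated samples outside the grid (NaN) are ignored. A coarse shared
    sweep bounds gamma per point; an exhaustive fine pass inside each
    point's proven search radius then resolves narrow dose-level-set
    valleys that a coarse grid alone would miss (discretization false
    positives).
    """
    gamma2 = _coarse_pass(ref_pts, ref_dose, eval_interp, delta_dose, gp)
    gamma2 = _fine_pass(ref_pts, ref_dose, eval_interp, delta_dose, gamma2, gp)
    return np.sqrt(gamma2)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def gamma_map(reference: DoseImage, evaluated: DoseImage, gp: GammaParams) -> GammaResult:
    """2D gamma of ``evaluated`` against ``reference``.

    The reference grid points at or above the low-dose threshold are
    compared against the linearly interpolated evaluated distribution.
    """
    ref_max = float(reference.values.max())
    if ref_max <= 0:
        raise BeamtuneError("reference maximum dose must be positive")
    # require spatial overlap of the two grids
    if (
        reference.ys[-1] < evaluated.ys[0] or evaluated.ys[-1] < reference.ys[0]
        or reference.xs[-1] < evaluated.xs[0] or evaluated.xs[-1] < reference.xs[0]
    ):
        raise BeamtuneError("reference and evaluated grids do not overlap")

    mask = reference.values >= gp.threshold / 100.0 * ref_max
    if not mask.any():
        raise BeamtuneError("no reference points above the dose threshold")
    yy, xx = np.meshgrid(reference.ys, reference.xs, indexing="ij")
    pts = np.stack([yy[mask], xx[mask]], axis=-1)
    dose = reference.values[mask]
    if gp.normalization == "local":
        delta = gp.dose_crit / 100.0 * dose
    else:
        delta = np.full(dose.shape, gp.dose_crit / 100.0 * ref_max)

    g = _gamma_points_tracked(pts, dose, evaluated.interpolator(), delta, gp)
    out = np.full(reference.values.shape, np.nan)
    out[mask] = g
    return GammaResult(gamma=out, n_evaluated=int(mask.sum()))


def gamma_profile(
    ref_positions: np.ndarray,
    ref_dose: np.ndarray,
    eval_positions: np.ndarray,
    eval_dose: np.ndarray,
    gp: GammaParams,
) -> GammaResult:
    """1D gamma of an evaluated profile against a reference profile.

    In one dimension the minimum over the linearly interpolated evaluated
    polyline is solved exactly: on each segment gamma^2 is a quadratic in
    the segment parameter, so the vertex (clipped to the segment) gives the
    per-segment minimum without any search discretization. The search
    parameters of :class:`GammaParams` are therefore not used here.
    """
    ref_positions = np.asarray(ref_positions, dtype=float)
    ref_dose = np.asarray(ref_dose, dtype=float)
    xe = np.asarray(eval_positions, dtype=float)
    de = np.asarray(eval_dose, dtype=float)
    ref_max = float(ref_dose.max())
    if ref_max <= 0:
        raise BeamtuneError("reference maximum dose must be positive")
    mask = ref_dose >= gp.threshold / 100.0 * ref_max
    if not mask.any():
        raise BeamtuneError("no reference points above the dose threshold")

    x0, x1 = xe[:-1], xe[1:]
    d0, d1 = de[:-1], de[1:]
    dx, dd_seg = x1 - x0, d1 - d0
    out = np.full(ref_dose.shape, np.nan)
    for i in np.nonzero(mask)[0]:
        dr = ref_dose[i]
        delta = gp.dose_crit / 100.0 * (dr if gp.normalization == "local" else ref_max)
        # gamma^2(t) = ((d0 + t*dd - dr)/delta)^2 + ((x0 + t*dx - xr)/dc)^2
        a = (dd_seg / delta) ** 2 + (dx / gp.dist_crit) ** 2
        b = (d0 - dr) * dd_seg / delta ** 2 + (x0 - ref_positions[i]) * dx / gp.dist_crit ** 2
        c = ((d0 - dr) / delta) ** 2 + ((x0 - ref_positions[i]) / gp.dist_crit) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.clip(np.where(a > 0, -b / a, 0.0), 0.0, 1.0)
        g2 = a * t ** 2 + 2 * b * t + c
        out[i] = np.sqrt(g2.min())
    return GammaResult(gamma=out, n_evaluated=int(mask.sum()))


# ---------------------------------------------------------------------------
# Plane I/O — a diff-able text grid with spacing/origin headers
# ---------------------------------------------------------------------------

def write_plane_text(path: str | Path, img: DoseImage) -> None:
    """Write a dose plane as text: header lines then CSV rows."""
    with open(path, "w") as fh:
        fh.write(f"#spacing_mm: {img.spacing[0]:g},{img.spacing[1]:g}\n")
        fh.write(f"#origin_mm: {img.origin[0]:g},{img.origin[1]:g}\n")
        np.savetxt(fh, img.values, fmt="%.6g", delimiter=",")


def read_plane_text(path: str | Path) -> DoseImage:
    """Read a dose plane written by :func:`write_plane_text`."""
    path = Path(path)
    spacing = origin = None
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#spacing_mm:"):
            spacing = tuple(float(v) for v in line.split(":", 1)[1].split(","))
        elif line.startswith("#origin_mm:"):
            origin = tuple(float(v) for v in line.split(":", 1)[1].split(","))
        elif line.startswith("#"):
            raise SchemaError(f"{path}: unknown header {line!r}")
        else:
            rows.append([float(v) for v in line.split(",")])
    if spacing is None:
        raise SchemaError(f"{path}: missing #spacing_mm header")
    return DoseImage(values=np.array(rows), spacing=spacing, origin=origin or (0.0, 0.0))


def read_dicom_dose(path: str | Path) -> DoseImage:
    """Read a planar DICOM RT Dose file into a :class:`DoseImage`."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    values = ds.pixel_array.astype(float) * float(getattr(ds, "DoseGridScaling", 1.0))
    if values.ndim == 3:
        if values.shape[0] != 1:
            raise SchemaError("only single-plane RT Dose volumes are supported")
        values = values[0]
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(ipp[1]), float(ipp[0]))
    return DoseImage(values=values, spacing=spacing, origin=origin)
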