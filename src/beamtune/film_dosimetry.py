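"""Radiochromic-film processing chain.

Implements the computational side of EBT3-style film dosimetry:

* net optical density, ``netOD = log10(I_unexposed / I_exposed)`` per colour
  channel of a 48-bit transmission scan;
* a rational calibration through the origin per channel,
  ``D(x) = b*x / (c - x)`` with x the netOD, fitted by least squares;
* triple-channel dose reconstruction: a common relative thickness/scan
  perturbation ``delta`` multiplies all three channel netODs; per pixel the
  value of delta (bounded to ±10%) minimizing the variance of the three
  channel-dose estimates is found, and the corrected dose is their mean.
  Separating the common-mode perturbation from dose is what makes the
  multichannel method outperform a single channel;
* box smoothing with a kernel sized to 1% of the scan diagonal;
* rigid registration of the modelled plane to the measurement by maximizing
  the Pearson correlation coefficient over translations and rotation;
* a synthetic film-scan generator inverting the calibration, for offline
  round-trip testing of the whole chain.

No lateral-response-artifact correction is applied; films are assumed
centred on the scanner window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import curve_fit

from .errors import BeamtuneError, CalibrationError, RegistrationError
from .gamma_eval import DoseImage

DELTA_BOUND = 0.10  # |thickness perturbation| limit for triple-channel solve


@dataclass(frozen=True)
class FilmScan:
    """RGB transmission scan: 16-bit intensities plus the unexposed reference."""

    pixels: np.ndarray               # (H, W, 3) uint16
    unexposed_ref: np.ndarray        # (3,) per-channel unexposed intensity
    dpi: float = 250.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        ref = np.asarray(self.unexposed_ref, dtype=float)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "unexposed_ref", ref)
        if px.ndim != 3 or px.shape[2] != 3:
            raise BeamtuneError("film scan must be (H, W, 3)")
        if self.dpi <= 0:
            raise BeamtuneError("dpi must be positive")
        if np.any(ref <= 0):
            raise BeamtuneError("unexposed reference intensities must be positive")

    @property
    def pixel_mm(self) -> float:
        return 25.4 / self.dpi


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-channel rational dose response D(x) = b*x/(c - x), x = netOD."""

    b: np.ndarray            # (3,)
    c: np.ndarray            # (3,)
    x_max: np.ndarray        # (3,) netOD fit-range upper end
    max_dose: float          # [Gy] highest calibrated dose
    rms_residual: np.ndarray | None = None   # (3,) per-channel RMS dose residual

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        c = np.asarray(self.c, dtype=float)
        xm = np.asarray(self.x_max, dtype=float)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "x_max", xm)
        if np.any(c <= xm):
            raise CalibrationError("pole c must lie above the netOD fit range")
        if np.any(b <= 0):
            raise CalibrationError("calibration slope b must be positive")

    def dose(self, netod: np.ndarray, channel: int) -> np.ndarray:
        """Dose [Gy] from netOD on one channel (clipped to the fit range)."""
        x = np.clip(netod, 0.0, self.x_max[channel])
        return self.b[channel] * x / (self.c[channel] - x)

    def netod(self, dose: np.ndarray, channel: int) -> np.ndarray:
        """Inverse response: netOD producing the given dose on one channel."""
        d = np.asarray(dose, dtype=float)
        return self.c[channel] * d / (self.b[channel] + d)


# ---------------------------------------------------------------------------
# netOD and calibration
# ---------------------------------------------------------------------------

def net_optical_density(scan: FilmScan) -> np.ndarray:
    """Per-channel netOD map, shape (H, W, 3), clipped below at 0."""
    px = scan.pixels.astype(float)
    if np.any(px <= 0):
        raise BeamtuneError("scan contains zero pixel intensities")
    netod = np.log10(scan.unexposed_ref[None, None, :] / px)
    return np.clip(netod, 0.0, None)


def fit_calibration(
    doses: Sequence[float],
    netods: np.ndarray,
) -> CalibrationCurve:
    """Least-squares fit of the rational calibration per channel.

    Parameters
    ----------
    doses:
        Calibration dose levels [Gy]; at least 4 including 0.
    netods:
        Array (n_levels, 3) of the per-channel netOD at each level.
    """
    d = np.asarray(doses, dtype=float)
    x = np.asarray(netods, dtype=float)
    if d.size < 4 or 0.0 not in d:
        raise CalibrationError("need >= 4 dose levels including 0 Gy")
    if x.shape != (d.size, 3):
        raise CalibrationError("netods must be (n_levels, 3)")
    order = np.argsort(d)
    d, x = d[order], x[order]
    if np.any(np.diff(x, axis=0) <= 0):
        raise CalibrationError("netOD must increase monotonically with dose")

    def model(xv: np.ndarray, b: float, c: float) -> np.ndarray:
        return b * xv / (c - xv)

    bs, cs, rms = [], [], []
    for k in range(3):
        xk = x[:, k]
        c0 = 1.5 * xk.max()
        b0 = d[-1] * (c0 - xk[-1]) / xk[-1]
        (b, c), _ = curve_fit(model, xk, d, p0=(b0, c0), maxfev=20000)
        if c <= xk.max():
            raise CalibrationError(f"channel {k}: fitted pole inside the data range")
        bs.append(b)
        cs.append(c)
        rms.append(float(np.sqrt(np.mean((model(xk, b, c) - d) ** 2))))
    return CalibrationCurve(
        b=np.array(bs), c=np.array(cs), x_max=x.max(axis=0),
        max_dose=float(d.max()), rms_residual=np.array(rms),
    )


# ---------------------------------------------------------------------------
# Triple-channel reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TripleChannelResult:
    dose: DoseImage
    delta: np.ndarray          # per-pixel thickness perturbation estimate
    fallback: np.ndarray       # pixels where delta=0 was kept


def triple_channel_dose(
    netods: np.ndarray,
    cal: CalibrationCurve,
    pixel_mm: float = 25.4 / 250.0,
    delta_step: float = 0.002,
    origin: tuple[float, float] = (0.0, 0.0),
) -> TripleChannelResult:
    """Triple-channel dose reconstruction from per-channel netOD maps.

    The physical disturbance (active-layer thickness, scanner response) is
    modelled as a common multiplicative factor on the netOD of all three
    channels: ``netOD_k = (1 + delta) * f_k(D)``. Per pixel, delta in
    [-10%, +10%] is found by a dense scan (step ``delta_step``) minimizing
    the variance of the three corrected channel doses, refined by a
    parabolic step; the output dose is the mean of the corrected estimates.
    Pixels where no delta beats the uncorrected variance keep delta = 0 and
    are flagged.
    """
    nod = np.asarray(netods, dtype=float)
    if nod.ndim != 3 or nod.shape[2] != 3:
        raise BeamtuneError("netods must be (H, W, 3)")
    h, wdt, _ = nod.shape
    flat = nod.reshape(-1, 3)

    def channel_doses(delta: np.ndarray) -> np.ndarray:
        # corrected netOD = netOD / (1 + delta); delta broadcast over pixels
        out = np.empty_like(flat)
        for k in range(3):
            out[:, k] = cal.dose(flat[:, k] / (1.0 + delta), k)
        return out

    def variance(delta: np.ndarray) -> np.ndarray:
        return channel_doses(delta).var(axis=1)

    deltas = np.arange(-DELTA_BOUND, DELTA_BOUND + delta_step / 2, delta_step)
    best_var = np.full(flat.shape[0], np.inf)
    best_delta = np.zeros(flat.shape[0])
    for dv in deltas:
        v = variance(np.full(1, dv))
        better = v < best_var
        best_var[better] = v[better]
        best_delta[better] = dv

    # parabolic refinement around the best grid value
    v0 = variance(best_delta)
    vm = variance(best_delta - delta_step)
    vp = variance(best_delta + delta_step)
    denom = vm - 2 * v0 + vp
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (vm - vp) / np.where(denom == 0, 1, denom), 0.0)
    refined = np.clip(best_delta + shift * delta_step, -DELTA_BOUND, DELTA_BOUND)
    v_ref = variance(refined)
    take = v_ref <= v0
    best_delta = np.where(take, refined, best_delta)
    best_var = np.where(take, v_ref, v0)

    var_unperturbed = variance(np.zeros(1))
    fallback = best_var > var_unperturbed + 1e-30
    best_delta = np.where(fallback, 0.0, best_delta)

    dose = channel_doses(best_delta).mean(axis=1).reshape(h, wdt)
    return TripleChannelResult(
        dose=DoseImage(values=dose, spacing=(pixel_mm, pixel_mm), origin=origin),
        delta=best_delta.reshape(h, wdt),
        fallback=fallback.reshape(h, wdt),
    )


def single_channel_dose(
    netods: np.ndarray, cal: CalibrationCurve, channel: int = 0,
    pixel_mm: float = 25.4 / 250.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> DoseImage:
    """Uncorrected single-channel dose (baseline for the triple-channel gain)."""
    nod = np.asarray(netods, dtype=float)
    return DoseImage(values=cal.dose(nod[:, :, channel], channel),
                     spacing=(pixel_mm, pixel_mm), origin=origin)


# ---------------------------------------------------------------------------
# Smoothing and registration
# ---------------------------------------------------------------------------

def smoothing_kernel_size(shape: tuple[int, int], fraction: float = 0.01) -> int:
    """Odd box-kernel side: ``fraction`` of the image diagonal, minimum 3 px."""
    diag = math.hypot(shape[0], shape[1])
    k = round(fraction * diag)
    if k % 2 == 0:
        k += 1
    return max(k, 3)


def smooth_dose(img: DoseImage, fraction: float = 0.01) -> DoseImage:
    """Box-filter smoothing with a kernel sized to 1% of the diagonal.

    Reflection edge handling keeps the image mean exactly unchanged.
    """
    if img.values.shape[0] < 3 or img.values.shape[1] < 3:
        raise BeamtuneError("image must be at least 3x3")
    k = smoothing_kernel_size(img.values.shape, fraction)
    smoothed = ndimage.uniform_filter(img.values, size=k, mode="reflect")
    return DoseImage(values=smoothed, spacing=img.spacing, origin=img.origin)


@dataclass(frozen=True)
class RegistrationResult:
    dx: float               # [mm] translation applied to the model
    dy: float               # [mm]
    theta: float            # [deg] rotation about the measurement centre
    correlation: float
    registered: DoseImage   # model resampled onto the measurement grid


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        raise RegistrationError("flat (zero-variance) image in registration")
    return float(np.corrcoef(a, b)[0, 1])


def register_rigid(
    measurement: DoseImage,
    model: DoseImage,
    rotate: bool = True,
    coarse_range: float = 5.0,
    coarse_step: float = 0.5,
    fine_step: float = 0.1,
    theta_range: float = 3.0,
    theta_step: float = 0.1,
) -> RegistrationResult:
    """Rigidly register ``model`` onto ``measurement`` by correlation.

    The aligned model is ``A(p) = model(R(-theta) @ (p - c) + c - t)`` with c
    the measurement-grid centre and t = (dy, dx) the reported translation.
    The search is staged: a coarse translation grid (±``coarse_range`` mm at
    ``coarse_step``), a rotation scan at the best translation (±3° at 0.1°),
    then a fine translation grid at ``fine_step`` around the optimum. The
    model is resampled with linear interpolation; overlap of at least 50% of
    the measurement area is required.
    """
    interp = RegularGridInterpolator(
        (model.ys, model.xs), model.values, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    yy, xx = np.meshgrid(measurement.ys, measurement.xs, indexing="ij")
    cy = 0.5 * (measurement.ys[0] + measurement.ys[-1])
    cx = 0.5 * (measurement.xs[0] + measurement.xs[-1])
    meas_flat = measurement.values.ravel()

    def sample(dy: float, dx: float, theta_deg: float) -> np.ndarray:
        th = math.radians(theta_deg)
        y0, x0 = yy - cy, xx - cx
        ry = math.cos(th) * y0 - math.sin(th) * x0 + cy - dy
        rx = math.sin(th) * y0 + math.cos(th) * x0 + cx - dx
        return interp(np.stack([ry.ravel(), rx.ravel()], axis=-1))

    def score(dy: float, dx: float, theta_deg: float) -> float:
        vals = sample(dy, dx, theta_deg)
        ok = np.isfinite(vals)
        if ok.sum() < 0.5 * meas_flat.size:
            return -np.inf
        return _pearson(vals[ok], meas_flat[ok])

    def grid_search(dys, dxs, thetas, best):
        for th in thetas:
            for dy in dys:
                for dx in dxs:
                    s = score(dy, dx, th)
                    if s > best[3]:
                        best = (dy, dx, th, s)
        return best

    steps = np.arange(-coarse_range, coarse_range + coarse_step / 2, coarse_step)
    best = grid_search(steps, steps, [0.0], (0.0, 0.0, 0.0, -np.inf))
    if not np.isfinite(best[3]):
        raise RegistrationError("insufficient overlap between model and measurement")
    if rotate:
        thetas = np.arange(-theta_range, theta_range + theta_step / 2, theta_step)
        best = grid_search([best[0]], [best[1]], thetas, best)
    fine = np.arange(-coarse_step, coarse_step + fine_step / 2, fine_step)
    best = grid_search(best[0] + fine, best[1] + fine, [best[2]], best)

    dy, dx, th, corr = best
    vals = sample(dy, dx, th)
    registered = DoseImage(
        values=np.where(np.isfinite(vals), vals, 0.0).reshape(measurement.values.shape),
        spacing=measurement.spacing, origin=measurement.origin,
    )
    return RegistrationResult(dx=float(dx), dy=float(dy), theta=float(th),
                              correlation=float(corr), registered=registered)


# ---------------------------------------------------------------------------
# Synthetic film scans and TIFF I/O
# ---------------------------------------------------------------------------

def simulate_film_scan(
    dose: DoseImage,
    cal: CalibrationCurve,
    noise_sd: float = 0.0,
    delta_field: np.ndarray | None = None,
    seed: int = 0,
    unexposed_ref: Sequence[float] = (42000.0, 40000.0, 36000.0),
) -> FilmScan:
    """Forward-model a film scan from a dose plane [synthetic stand-in].

    Inverts the calibration per channel, applies the common-mode thickness
    perturbation ``delta_field`` (netOD -> netOD*(1+delta)), multiplies by
    lognormal-free Gaussian intensity noise of relative sd ``noise_sd``, and
    quantizes to 16 bits.
    """
    d = dose.values
    if np.any(d < 0):
        raise CalibrationError("negative dose cannot be exposed on film")
    if d.max() > cal.max_dose:
        raise CalibrationError(
            f"dose {d.max():g} Gy exceeds the calibration range ({cal.max_dose:g} Gy)"
        )
    ref = np.asarray(unexposed_ref, dtype=float)
    rng = np.random.default_rng(seed)
    h, w = d.shape
    out = np.empty((h, w, 3), dtype=np.uint16)
    for k in range(3):
        x = cal.netod(d, k)
        if delta_field is not None:
            x = x * (1.0 + np.asarray(delta_field, dtype=float))
        intensity = ref[k] * 10.0 ** (-x)
        if noise_sd > 0:
            intensity = intensity * (1.0 + rng.normal(0.0, noise_sd, size=intensity.shape))
        out[:, :, k] = np.clip(np.round(intensity), 1, 65535).astype(np.uint16)
    dpi = 25.4 / dose.spacing[0]
    return FilmScan(pixels=out, unexposed_ref=ref, dpi=dpi)


def write_film_tiff(path: str | Path, scan: FilmScan) -> None:
    """Write a 48-bit RGB TIFF with the scan resolution."""
    import tifffile

    tifffile.imwrite(
        str(path), scan.pixels, photometric="rgb",
        resolution=(scan.dpi, scan.dpi), resolutionunit="INCH",
    )


def read_film_tiff(
    path: str | Path, unexposed_ref: Sequence[float], dpi: float | None = None
) -> FilmScan:
    """Read a 48-bit RGB TIFF film scan."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        pixels = page.asarray()
        if dpi is None:
            xres = page.tags.get("XResolution")
            if xres is not None:
                num, den = xres.value
                dpi = num / den
            else:
                dpi = 250.0
    return FilmScan(pixels=pixels, unexposed_ref=np.asarray(unexposed_ref, float),
                    dpi=float(dpi))
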