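"""Shared fixtures and independent oracles for the beamtune test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import norm

import beamtune as bt

Z80 = float(norm.ppf(0.8))  # standard-normal quantile at 0.8


# ---------------------------------------------------------------------------
# Analytic profile builders
# ---------------------------------------------------------------------------

def erf_profile(
    half_width: float = 15.0,
    sigma: float = 2.0,
    step: float = 0.1,
    extent: float = 45.0,
    axis: str = "crossline",
    field_size: float = 3.0,
    depth: float = 10.0,
    oit: float = 0.0,
) -> bt.Profile:
    """Ideal double-erf field: 100*(Phi((x+h)/s) - Phi((x-h)/s))."""
    x = step * np.arange(-round(extent / step), round(extent / step) + 1)
    d = 100.0 * (ndtr((x + half_width) / sigma) - ndtr((x - half_width) / sigma))
    return bt.Profile(axis=axis, positions=x, dose=d, depth=depth,
                      field_size=field_size, oit=oit)


def step_profile(half_width: float = 15.0, step: float = 0.1,
                 extent: float = 45.0) -> bt.Profile:
    """Ideal step field; edges sit exactly halfway between samples."""
    x = step * np.arange(-round(extent / step), round(extent / step) + 1) + step / 2
    d = np.where(np.abs(x) < half_width, 100.0, 0.0)
    return bt.Profile(axis="crossline", positions=x, dose=d, depth=10.0, field_size=3.0)


@pytest.fixture
def default_params() -> bt.BeamModelParams:
    return bt.BeamModelParams(essx=0.5, essy=0.0, dlg=0.9, mlc_transmission=0.015)


@pytest.fixture
def calibration() -> bt.CalibrationCurve:
    """A plausible EBT3-like rational calibration (red most sensitive)."""
    return bt.CalibrationCurve(
        b=np.array([10.0, 14.0, 30.0]),
        c=np.array([0.8, 1.0, 1.6]),
        x_max=np.array([0.78, 0.9, 1.3]),
        max_dose=19.0,
    )


# ---------------------------------------------------------------------------
# Gamma oracles: exhaustive fine-grid search, independent of the engine
# ---------------------------------------------------------------------------

def gamma_oracle_1d(
    ref_positions, ref_dose, eval_positions, eval_dose, gp: bt.GammaParams,
    step: float = 1e-4,
) -> np.ndarray:
    """Brute-force gamma along the dense evaluated polyline."""
    ref_positions = np.asarray(ref_positions, float)
    ref_dose = np.asarray(ref_dose, float)
    xs = np.arange(eval_positions[0], eval_positions[-1] + step / 2, step)
    ds = np.interp(xs, eval_positions, eval_dose)
    ref_max = ref_dose.max()
    out = np.full(ref_dose.shape, np.nan)
    radius = gp.search_radius_factor * gp.dist_crit
    for i, (x, d) in enumerate(zip(ref_positions, ref_dose)):
        if d < gp.threshold / 100.0 * ref_max:
            continue
        delta = gp.dose_crit / 100.0 * (d if gp.normalization == "local" else ref_max)
        sel = np.abs(xs - x) <= radius
        g2 = ((ds[sel] - d) / delta) ** 2 + ((xs[sel] - x) / gp.dist_crit) ** 2
        out[i] = np.sqrt(g2.min())
    return out


def _dense_bilinear(img: bt.DoseImage, step: float) -> tuple[np.ndarray, float]:
    """Bilinear upsampling of a square-spacing image to ``step`` mm (float32).

    Requires the original spacing to be an integer multiple of ``step`` so
    that every original grid node lands exactly on the dense grid.
    """
    s = img.spacing[0]
    assert img.spacing[0] == img.spacing[1]
    ratio = s / step
    assert abs(ratio - round(ratio)) < 1e-9
    h, w = img.values.shape
    ty = np.arange((h - 1) * round(ratio) + 1) * step / s  # in index units
    i0 = np.minimum(ty.astype(int), h - 2)
    fy = (ty - i0).astype(np.float32)
    a = img.values.astype(np.float32)
    rows = a[i0] * (1 - fy)[:, None] + a[i0 + 1] * fy[:, None]
    tx = np.arange((w - 1) * round(ratio) + 1) * step / s
    j0 = np.minimum(tx.astype(int), w - 2)
    fx = (tx - j0).astype(np.float32)
    dense = rows[:, j0] * (1 - fx)[None, :] + rows[:, j0 + 1] * fx[None, :]
    return dense, step


def gamma_oracle_2d(
    reference: bt.DoseImage, evaluated: bt.DoseImage, gp: bt.GammaParams,
    step: float = 0.01,
) -> np.ndarray:
    """Exhaustive fine-grid gamma for aligned square-grid images.

    The evaluated image is bilinearly upsampled to ``step`` mm; for each
    reference point the search window is bounded by the zero-offset gamma
    (the distance term alone exceeds it further out), capped at the engine's
    nominal search radius.
    """
    assert reference.spacing == evaluated.spacing
    assert reference.origin == evaluated.origin
    dense, _ = _dense_bilinear(evaluated, step)
    s = reference.spacing[0]
    ratio = round(s / step)
    ref = reference.values
    ref_max = ref.max()
    radius_cap = gp.search_radius_factor * gp.dist_crit
    out = np.full(ref.shape, np.nan)
    templates: dict[int, np.ndarray] = {}
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            d = ref[i, j]
            if d < gp.threshold / 100.0 * ref_max:
                continue
            delta = gp.dose_crit / 100.0 * (d if gp.normalization == "local" else ref_max)
            ci, cj = i * ratio, j * ratio
            g0 = abs(float(dense[ci, cj]) - d) / delta
            radius = min(g0 * gp.dist_crit, radius_cap)
            k = int(np.ceil(radius / step))
            lo_i, hi_i = max(ci - k, 0), min(ci + k, dense.shape[0] - 1)
            lo_j, hi_j = max(cj - k, 0), min(cj + k, dense.shape[1] - 1)
            win = dense[lo_i:hi_i + 1, lo_j:hi_j + 1].astype(float)
            key = (lo_i - ci, hi_i - ci, lo_j - cj, hi_j - cj)
            if key not in templates:
                dy = step * np.arange(key[0], key[1] + 1)
                dx = step * np.arange(key[2], key[3] + 1)
                templates[key] = (dy[:, None] ** 2 + dx[None, :] ** 2) / gp.dist_crit ** 2
            g2 = ((win - d) / delta) ** 2 + templates[key]
            out[i, j] = np.sqrt(g2.min())
    return out
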