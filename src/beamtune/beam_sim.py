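"""Synthetic MLC-aperture beam simulator.

A minimal fluence-convolution model with the same user-facing parameters as
a clinical TPS beam model: the dosimetric leaf gap (DLG) enlarges the
modelled leaf-tip gap, so each crossline field edge is pushed outward by
DLG/2; the effective spot size (ESS) is the standard deviation of a Gaussian
source blur, applied per axis on top of a depth-dependent intrinsic blur
(phantom scatter and detector response lumped together); a single MLC
transmission fraction floors the out-of-field dose.

It is emphatically *not* a dose engine: there is no head-scatter source
model, no rounded-tip ray tracing, and no tongue-and-groove. Its purpose is
to provide paired "measured" (reference parameters, optional noise) and
"modelled" (candidate parameters) profiles and dose planes with the correct
qualitative structure — leaf-pitch-periodic FWHM and penumbra modulation
versus the off-axis inline translation (OIT), DLG-shifted edges, a
transmission floor, and a DLG-dependent leakage ridge from leaves parked at
the central axis — so the whole parameter-tuning protocol can be exercised
and tested offline.

Dose profiles are built as

    D(x) = 100 * [T + (1 - T) * (Phi((x - xL)/s) - Phi((x - xR)/s))] / norm

with Phi the standard-normal CDF, T the MLC transmission and
s = sqrt(ESS_axis^2 + sigma_depth^2), renormalized so the CAX sample is 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr

from .errors import BeamtuneError, GeometryError
from .gamma_eval import DoseImage
from .profiles import Profile


@dataclass(frozen=True)
class BeamModelParams:
    """The user-configurable beam-model parameters under optimization.

    essx, essy:
        Effective spot size [mm], crossline / inline Gaussian sigma.
        Physically the correction for a finite source, so bounded below by 0.
    dlg:
        Dosimetric leaf gap [mm]; each modelled crossline leaf tip retracts
        by dlg/2, enlarging the gap by the full parameter value.
    mlc_transmission:
        Average MLC transmission as a fraction of the open-field dose.
    """

    essx: float
    essy: float
    dlg: float
    mlc_transmission: float = 0.015

    def __post_init__(self) -> None:
        if self.essx < 0 or self.essy < 0:
            raise BeamtuneError("effective spot size has a lower bound of 0 mm")
        if self.dlg < 0:
            raise BeamtuneError("dlg must be >= 0")
        if not 0 <= self.mlc_transmission < 0.1:
            raise BeamtuneError("mlc_transmission must be in [0, 0.1)")


def _default_sigma() -> dict[float, float]:
    return {5.0: 2.4, 10.0: 2.8, 20.0: 3.4}


@dataclass(frozen=True)
class SimConfig:
    """Simulator geometry, leaf-structure amplitudes and noise.

    leaf_pitch:
        Central MLC leaf width [mm] (5 mm for Millennium central leaves).
    fwhm_modulation_amp:
        Amplitude a [mm] of the cosine edge modulation versus OIT: each
        crossline edge moves by ``a*cos(2*pi*OIT/pitch)``, so the FWHM is
        largest between leaves (OIT = 0, +/-5 mm) and smallest under a leaf.
    penumbra_modulation_amp:
        Relative cosine modulation of the crossline edge blur versus OIT
        (same period and phase), emulating the higher transmission near
        leaf junctions widening the penumbra.
    junction_leak_amp:
        Amplitude [% of open dose] of a leaf-pitch-periodic ripple on inline
        profiles from interleaf junctions.
    intrinsic_sigma:
        Depth [cm] -> intrinsic Gaussian blur sigma [mm].
    closed_leaf_ridge:
        Leaves outside the field-defining pairs park abutting at the central
        axis; an inline scan runs along that abutment line, so it sees a
        DLG-proportional leakage floor outside the field edges. Enabling
        this makes the inline direction DLG-sensitive.
    ridge_gain:
        Leakage per mm of DLG (fraction of open dose) for the ridge.
    noise_sd:
        Gaussian measurement noise sd [% dose] added before renormalization.
    seed:
        Governs all randomness of a profile set.
    oit:
        OIT [mm] at which crossline optimization profiles are acquired.
    grid_step:
        Simulation grid spacing [mm].
    margin:
        Scan extent beyond the nominal field edge [mm].
    """

    leaf_pitch: float = 5.0
    fwhm_modulation_amp: float = 0.15
    penumbra_modulation_amp: float = 0.05
    junction_leak_amp: float = 0.0
    intrinsic_sigma: Mapping[float, float] = field(default_factory=_default_sigma)
    closed_leaf_ridge: bool = True
    ridge_gain: float = 0.02
    noise_sd: float = 0.0
    seed: int = 0
    oit: float = 1.2
    grid_step: float = 0.2
    margin: float = 30.0
    ssd: float = 90.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.intrinsic_sigma.values()):
            raise BeamtuneError("intrinsic sigma values must be positive")
        if self.noise_sd < 0:
            raise BeamtuneError("noise_sd must be >= 0")
        if self.leaf_pitch <= 0 or self.grid_step <= 0:
            raise BeamtuneError("leaf_pitch and grid_step must be positive")

    def sigma_at(self, depth: float) -> float:
        try:
            return float(self.intrinsic_sigma[depth])
        except KeyError:
            raise GeometryError(
                f"no intrinsic blur configured for depth {depth:g} cm "
                f"(configured: {sorted(self.intrinsic_sigma)})"
            ) from None


def edge_positions(
    params: BeamModelParams, field_size: float, oit: float, cfg: SimConfig
) -> tuple[float, float]:
    """Crossline field-edge positions [mm] for a symmetric MLC aperture.

    The half-width is the nominal half aperture plus half the DLG (each leaf
    tip retracts by dlg/2) plus the leaf-structure cosine modulation.
    """
    if field_size <= 0:
        raise GeometryError("field_size must be positive")
    half = (
        field_size * 10.0 / 2.0
        + params.dlg / 2.0
        + cfg.fwhm_modulation_amp * math.cos(2.0 * math.pi * oit / cfg.leaf_pitch)
    )
    return (-half, half)


def _rng_for(cfg: SimConfig, field_size: float, depth: float, axis: str, oit: float):
    """Deterministic per-profile generator derived from the set seed."""
    key = [
        int(cfg.seed),
        int(round(field_size * 10)),
        int(round(depth * 10)),
        0 if axis == "crossline" else 1,
        int(round((oit + 1000.0) * 1000)),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_profile(
    params: BeamModelParams,
    field_size: float,
    depth: float,
    axis: str,
    oit: float,
    cfg: SimConfig,
) -> Profile:
    """Simulate one line scan for the given geometry and parameters."""
    sigma_d = cfg.sigma_at(depth)
    half_nominal = field_size * 10.0 / 2.0
    extent = half_nominal + cfg.margin
    n = int(round(extent / cfg.grid_step))
    x = cfg.grid_step * np.arange(-n, n + 1)

    t = params.mlc_transmission
    phase = math.cos(2.0 * math.pi * oit / cfg.leaf_pitch)
    if axis == "crossline":
        xl, xr = edge_positions(params, field_size, oit, cfg)
        sigma = math.hypot(params.essx, sigma_d) * (
            1.0 + cfg.penumbra_modulation_amp * phase
        )
        window = ndtr((x - xl) / sigma) - ndtr((x - xr) / sigma)
        dose = t + (1.0 - t) * window
    elif axis == "inline":
        yl, yr = -half_nominal, half_nominal
        sigma = math.hypot(params.essy, sigma_d)
        window = ndtr((x - yl) / sigma) - ndtr((x - yr) / sigma)
        dose = t + (1.0 - t) * window
        if cfg.junction_leak_amp:
            dose = dose + cfg.junction_leak_amp / 100.0 * np.cos(
                2.0 * math.pi * x / cfg.leaf_pitch
            ) * window
        if cfg.closed_leaf_ridge:
            dose = dose + cfg.ridge_gain * params.dlg * (1.0 - window)
    else:
        raise GeometryError(f"unknown axis {axis!r}")

    dose = 100.0 * dose
    if cfg.noise_sd > 0:
        rng = _rng_for(cfg, field_size, depth, axis, oit)
        dose = dose + rng.normal(0.0, cfg.noise_sd, size=dose.shape)
    cax = dose[n]
    if cax <= 0:
        raise BeamtuneError("simulated CAX dose is not positive")
    dose = dose * (100.0 / cax)
    return Profile(
        axis=axis, positions=x, dose=dose, depth=depth, ssd=cfg.ssd,
        field_size=field_size, oit=oit if axis == "crossline" else 0.0,
        collimation="mlc",
    )


def simulate_profile_set(
    params: BeamModelParams,
    cfg: SimConfig,
    field_sizes: Sequence[float] = (2.0, 3.0, 4.0, 5.0),
    crossline_depths: Sequence[float] = (5.0, 10.0, 20.0),
    inline_depths: Sequence[float] = (10.0,),
) -> list[Profile]:
    """The optimization-profile set: crossline scans at each depth for each
    field size (at the configured OIT) plus inline scans at 10 cm.

    Defaults give 16 profiles: {2,3,4,5} cm x (3 crossline depths + 1 inline).
    """
    out: list[Profile] = []
    for w in field_sizes:
        for d in crossline_depths:
            out.append(simulate_profile(params, w, d, "crossline", cfg.oit, cfg))
        for d in inline_depths:
            out.append(simulate_profile(params, w, d, "inline", 0.0, cfg))
    return out


def simulate_oit_sweep(
    params: BeamModelParams,
    cfg: SimConfig,
    field_size: float = 3.0,
    depth: float = 10.0,
    oit_min: float = -10.0,
    oit_max: float = 10.0,
    oit_step: float = 0.5,
) -> list[Profile]:
    """Crossline profiles of one field at OITs spanning two leaf widths."""
    n = int(round((oit_max - oit_min) / oit_step))
    oits = oit_min + oit_step * np.arange(n + 1)
    return [simulate_profile(params, field_size, depth, "crossline", float(o), cfg)
            for o in oits]


# ---------------------------------------------------------------------------
# 2D dose planes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Aperture:
    """A rectangular MLC aperture contributing to a composite plan."""

    width_x: float          # crossline side [cm]
    width_y: float          # inline side [cm]
    weight: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)  # (y, x) offset [mm]


@dataclass(frozen=True)
class PlanSpec:
    """Weighted sum of apertures with a prescription normalization."""

    apertures: Sequence[Aperture]
    prescription: float = 100.0
    depth: float = 5.0

    def __post_init__(self) -> None:
        if len(self.apertures) == 0:
            raise BeamtuneError("plan_spec must list at least one aperture")


def simulate_dose_plane(
    params: BeamModelParams,
    plan_spec: PlanSpec,
    cfg: SimConfig,
    pixel_mm: float = 0.1,
) -> DoseImage:
    """2D dose plane as a weighted sum of separable blurred apertures.

    Each aperture contributes T + (1-T) * fx(x) * fy(y) with DLG-widened
    crossline edges; the plane is normalized so its maximum equals the plan
    prescription. Leaf-structure modulation is not modelled in 2D (the plane
    represents an arc-averaged delivery).
    """
    sigma_d = cfg.sigma_at(plan_spec.depth)
    sx = math.hypot(params.essx, sigma_d)
    sy = math.hypot(params.essy, sigma_d)
    t = params.mlc_transmission

    half_max = max(
        max(a.width_x, a.width_y) * 10.0 / 2.0 + max(abs(c) for c in (a.center + (0.0,)))
        for a in plan_spec.apertures
    )
    extent = half_max + cfg.margin
    n = int(round(extent / pixel_mm))
    coords = pixel_mm * np.arange(-n, n + 1)
    total = np.zeros((coords.size, coords.size))
    wsum = 0.0
    for a in plan_spec.apertures:
        hx = a.width_x * 10.0 / 2.0 + params.dlg / 2.0
        hy = a.width_y * 10.0 / 2.0
        cy, cx = a.center
        fx = ndtr((coords - (cx - hx)) / sx) - ndtr((coords - (cx + hx)) / sx)
        fy = ndtr((coords - (cy - hy)) / sy) - ndtr((coords - (cy + hy)) / sy)
        total += a.weight * np.outer(fy, fx)
        wsum += a.weight
    if wsum <= 0:
        raise BeamtuneError("plan_spec apertures have zero total weight")
    dose = t + (1.0 - t) * total / wsum
    dose = plan_spec.prescription * dose / dose.max()
    return DoseImage(values=dose, spacing=(pixel_mm, pixel_mm),
                     origin=(float(coords[0]), float(coords[0])))
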