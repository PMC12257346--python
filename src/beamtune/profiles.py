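"""1D dose-profile data model, I/O, metrics and off-axis sweep analysis.

A :class:`Profile` is a single water-phantom line scan: off-axis positions in
mm against relative dose in percent of the central-axis (CAX) value, tagged
with its acquisition geometry (scan axis, depth, SSD, nominal field size and —
for crossline scans — the off-axis inline translation, OIT).

The metrics here follow the conventions used when commissioning MLC beam
models for small stereotactic fields: the dosimetric field size is the full
width at half maximum (FWHM) of the normalized profile, and the penumbra is
the lateral distance between the 80% and 20% absolute dose levels on each
side. Level crossings are located on the outermost bracketing sample pair
(scanning from the tails inward) with linear interpolation, which is robust
to noise-induced multiple crossings near a level.

The OIT sweep analysis identifies the measurement position that is most
representative of the average profile over the width of several MLC leaves:
FWHM and mean penumbra oscillate with the leaf-pitch period as the scan line
moves from a leaf centre to a leaf junction, and the representative OIT is
the one whose metrics sit closest to the sweep average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateProfileError,
    GeometryError,
    MetricUndefinedError,
    ProfileValidationError,
    SchemaError,
)

AXES = ("crossline", "inline")
COLLIMATIONS = ("mlc", "jaw")

#: header keys required by the profile CSV dialect, mapped to Profile fields
_HEADER_KEYS = {
    "axis": "axis",
    "depth_cm": "depth",
    "ssd_cm": "ssd",
    "field_size_cm": "field_size",
    "oit_mm": "oit",
    "collimation": "collimation",
}


@dataclass(frozen=True)
class Profile:
    """One measured or modelled line scan.

    Parameters
    ----------
    axis:
        ``"crossline"`` (parallel to leaf motion, X) or ``"inline"``
        (perpendicular, Y).
    positions:
        Strictly increasing off-axis offsets from the CAX [mm].
    dose:
        Relative dose [% of CAX dose], same length as ``positions``.
    depth:
        Measurement depth [cm].
    ssd:
        Source-to-surface distance [cm].
    field_size:
        Nominal square field side [cm].
    oit:
        Off-axis inline translation of a crossline scan [mm]; 0 for inline.
    collimation:
        ``"mlc"`` for MLC-defined fields, ``"jaw"`` otherwise.
    """

    axis: str
    positions: np.ndarray
    dose: np.ndarray
    depth: float
    field_size: float
    ssd: float = 90.0
    oit: float = 0.0
    collimation: str = "mlc"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "dose", dose)
        if self.axis not in AXES:
            raise ProfileValidationError(f"unknown axis {self.axis!r}")
        if self.collimation not in COLLIMATIONS:
            raise ProfileValidationError(f"unknown collimation {self.collimation!r}")
        if pos.ndim != 1 or dose.ndim != 1 or pos.size != dose.size:
            raise ProfileValidationError("positions and dose must be 1D of equal length")
        if pos.size < 3:
            raise ProfileValidationError("a profile needs at least 3 samples")
        d = np.diff(pos)
        if np.any(d <= 0):
            row = int(np.argmax(d <= 0)) + 1
            raise ProfileValidationError(
                f"positions not strictly increasing at sample {row} (x={pos[row]:g} mm)"
            )
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(dose))):
            raise ProfileValidationError("non-finite sample in profile")

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def geometry(self) -> tuple:
        """Hashable acquisition-geometry key (axis, field, depth, ssd, oit)."""
        return (self.axis, self.field_size, self.depth, self.ssd, self.oit)


@dataclass(frozen=True)
class ProfileMetrics:
    """FWHM and per-side 80–20% penumbra widths of one profile [mm]."""

    fwhm: float
    penumbra_left: float
    penumbra_right: float

    @property
    def penumbra_mean(self) -> float:
        return 0.5 * (self.penumbra_left + self.penumbra_right)


@dataclass(frozen=True)
class PenumbraRegion:
    """Position interval between the 80% and 20% crossings of one side."""

    side: str
    lo: float
    hi: float

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass(frozen=True)
class OITSweep:
    """Per-OIT FWHM and mean penumbra of a crossline sweep.

    ``fwhm_norm`` and ``penumbra_norm`` are each metric divided by its sweep
    average, the convention used to visualize leaf-pitch-periodic modulation.
    """

    oit: np.ndarray
    fwhm: np.ndarray
    penumbra_mean: np.ndarray
    leaf_pitch: float = 5.0

    def __post_init__(self) -> None:
        o = np.asarray(self.oit, dtype=float)
        f = np.asarray(self.fwhm, dtype=float)
        p = np.asarray(self.penumbra_mean, dtype=float)
        order = np.argsort(o)
        object.__setattr__(self, "oit", o[order])
        object.__setattr__(self, "fwhm", f[order])
        object.__setattr__(self, "penumbra_mean", p[order])
        if self.leaf_pitch <= 0:
            raise GeometryError("leaf_pitch must be positive")
        if o.size == 0:
            raise GeometryError("empty OIT sweep")
        if np.unique(o).size != o.size:
            raise GeometryError("OIT values must be unique")

    @property
    def fwhm_norm(self) -> np.ndarray:
        return self.fwhm / self.fwhm.mean()

    @property
    def penumbra_norm(self) -> np.ndarray:
        return self.penumbra_mean / self.penumbra_mean.mean()


# ---------------------------------------------------------------------------
# I/O — `#key: value` header lines followed by `position_mm,dose` rows.
# ---------------------------------------------------------------------------

def write_profile(path: str | Path, profile: Profile) -> None:
    """Write one profile in the beamtune CSV dialect."""
    lines = [
        f"#axis: {profile.axis}",
        f"#depth_cm: {profile.depth:g}",
        f"#ssd_cm: {profile.ssd:g}",
        f"#field_size_cm: {profile.field_size:g}",
        f"#oit_mm: {profile.oit:g}",
        f"#collimation: {profile.collimation}",
        "position_mm,dose",
    ]
    lines += [f"{x:.6f},{d:.6f}" for x, d in zip(profile.positions, profile.dose)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_profiles(path: str | Path) -> list[Profile]:
    """Read profiles from a beamtune CSV file.

    A file holds one or more blocks; each block starts with ``#key: value``
    header lines, followed by a ``position_mm,dose`` column line and numeric
    rows. Malformed numeric rows raise, naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    profiles: list[Profile] = []
    meta: dict[str, str] = {}
    xs: list[float] = []
    ds: list[float] = []
    in_data = False

    def flush(lineno: int) -> None:
        nonlocal meta, xs, ds, in_data
        if not meta and not xs:
            return
        missing = [k for k in _HEADER_KEYS if k not in meta]
        if missing:
            raise SchemaError(f"{path}: missing metadata {missing} (block ending line {lineno})")
        try:
            profiles.append(
                Profile(
                    axis=meta["axis"],
                    positions=np.array(xs),
                    dose=np.array(ds),
                    depth=float(meta["depth_cm"]),
                    ssd=float(meta["ssd_cm"]),
                    field_size=float(meta["field_size_cm"]),
                    oit=float(meta["oit_mm"]),
                    collimation=meta["collimation"],
                )
            )
        except ValueError as exc:  # bad numeric metadata
            raise SchemaError(f"{path}: {exc}") from exc
        meta, xs, ds = {}, [], []
        in_data = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if in_data:  # a new header after data starts the next block
                flush(lineno)
            key, _, value = line[1:].partition(":")
            key = key.strip()
            if key not in _HEADER_KEYS:
                raise SchemaError(f"{path}:{lineno}: unknown metadata key {key!r}")
            meta[key] = value.strip()
            continue
        if line.lower().replace(" ", "") == "position_mm,dose":
            in_data = True
            continue
        if not in_data:
            raise SchemaError(f"{path}:{lineno}: data row before 'position_mm,dose' header")
        parts = line.split(",")
        try:
            x, d = float(parts[0]), float(parts[1])
        except (ValueError, IndexError) as exc:
            raise ProfileValidationError(f"{path}:{lineno}: malformed data row {line!r}") from exc
        if xs and x <= xs[-1]:
            raise ProfileValidationError(
                f"{path}:{lineno}: position {x:g} not increasing (previous {xs[-1]:g})"
            )
        xs.append(x)
        ds.append(d)
    flush(lineno=-1)
    if not profiles:
        raise SchemaError(f"{path}: no profile blocks found")
    return profiles


def read_profile_dir(directory: str | Path, pattern: str = "*.csv") -> list[Profile]:
    """Read every profile CSV in a directory (sorted by name)."""
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files in {directory}")
    out: list[Profile] = []
    for f in files:
        out.extend(read_profiles(f))
    return out


# ---------------------------------------------------------------------------
# Normalization and resampling
# ---------------------------------------------------------------------------

def normalize_to_cax(p: Profile, window: float = 0.5) -> Profile:
    """Scale dose so the sample nearest the CAX (position 0) equals 100.

    The CAX value is the single sample nearest x=0 (within ``window`` mm),
    matching a point-like detector reading rather than a plateau average.
    """
    i = int(np.argmin(np.abs(p.positions)))
    if abs(p.positions[i]) > window:
        raise DegenerateProfileError(
            f"no sample within ±{window} mm of the CAX (nearest at {p.positions[i]:g} mm)"
        )
    cax = p.dose[i]
    if cax <= 0:
        raise DegenerateProfileError(f"CAX dose {cax:g} is not positive")
    return replace(p, dose=p.dose * (100.0 / cax))


def resample_linear(p: Profile, step: float = 0.1) -> Profile:
    """Linearly resample onto an arithmetic grid of spacing ``step`` mm.

    The grid spans [min, max] of the original positions; if the span is not
    an exact multiple of ``step`` the original right endpoint is appended so
    endpoints are always preserved.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = float(p.positions[0]), float(p.positions[-1])
    if step > hi - lo:
        raise ValueError(f"step {step} mm exceeds the profile span {hi - lo:g} mm")
    n = int(math.floor((hi - lo) / step + 1e-9))
    x = lo + step * np.arange(n + 1)
    if hi - x[-1] > 1e-9:
        x = np.append(x, hi)
    x[-1] = hi
    d = np.interp(x, p.positions, p.dose)
    return replace(p, positions=x, dose=d)


# ---------------------------------------------------------------------------
# Level crossings and metrics
# ---------------------------------------------------------------------------

def _crossing(p: Profile, level: float, side: str) -> float:
    """Outermost position where the dose crosses ``level`` on one side.

    For the right side this is the last sample pair (k, k+1) with
    dose[k] >= level > dose[k+1]; for the left side the mirror. Linear
    interpolation between the bracketing samples.
    """
    dose, pos = p.dose, p.positions
    above = dose >= level
    if not above.any():
        raise MetricUndefinedError(f"profile never reaches the {level:g}% level")
    if side == "right":
        k = int(np.max(np.nonzero(above)))
        if k == len(dose) - 1:
            raise MetricUndefinedError(f"no {level:g}% crossing on the right side")
        k2 = k + 1
    elif side == "left":
        k = int(np.min(np.nonzero(above)))
        if k == 0:
            raise MetricUndefinedError(f"no {level:g}% crossing on the left side")
        k2 = k - 1
    else:
        raise ValueError("side must be 'left' or 'right'")
    d0, d1 = dose[k], dose[k2]
    if d1 == d0:  # flat bracketing pair; crossing at the inner sample
        return float(pos[k])
    t = (level - d0) / (d1 - d0)
    return float(pos[k] + t * (pos[k2] - pos[k]))


def fwhm(p: Profile) -> float:
    """Dosimetric field size: distance between the outermost 50% crossings.

    The profile is expected on the normalized percent scale (CAX = 100).
    """
    return _crossing(p, 50.0, "right") - _crossing(p, 50.0, "left")


def penumbra_region(p: Profile, side: str) -> PenumbraRegion:
    """Interval between the 80% and 20% absolute-level crossings of one side."""
    x80 = _crossing(p, 80.0, side)
    x20 = _crossing(p, 20.0, side)
    lo, hi = (min(x80, x20), max(x80, x20))
    return PenumbraRegion(side=side, lo=lo, hi=hi)


def penumbra_width(p: Profile, side: str) -> float:
    """80–20% penumbra width on the given side [mm]."""
    return penumbra_region(p, side).width


def profile_metrics(p: Profile) -> ProfileMetrics:
    """FWHM and both penumbra widths of a normalized profile."""
    return ProfileMetrics(
        fwhm=fwhm(p),
        penumbra_left=penumbra_width(p, "left"),
        penumbra_right=penumbra_width(p, "right"),
    )


# ---------------------------------------------------------------------------
# OIT sweep
# ---------------------------------------------------------------------------

def oit_sweep_metrics(
    profiles: Sequence[Profile],
    leaf_pitch: float = 5.0,
    resample_step: float = 0.1,
) -> OITSweep:
    """Per-OIT FWHM and mean penumbra for a crossline sweep.

    All profiles must be crossline scans of the same field size and depth,
    differing only in OIT. Each is normalized to the CAX and resampled to
    ``resample_step`` mm before the metrics are taken.
    """
    if len(profiles) < 3:
        raise GeometryError("an OIT sweep needs at least 3 profiles")
    ref = profiles[0]
    oits, fwhms, pens = [], [], []
    for p in profiles:
        if p.axis != "crossline":
            raise GeometryError(f"sweep profile at OIT {p.oit:g} mm is not crossline")
        if (p.field_size, p.depth) != (ref.field_size, ref.depth):
            raise GeometryError(
                f"heterogeneous sweep geometry: {p.field_size}x{p.field_size} cm @ "
                f"{p.depth} cm vs {ref.field_size}x{ref.field_size} cm @ {ref.depth} cm"
            )
        q = resample_linear(normalize_to_cax(p), resample_step)
        m = profile_metrics(q)
        oits.append(p.oit)
        fwhms.append(m.fwhm)
        pens.append(m.penumbra_mean)
    if len(set(oits)) < 3:
        raise GeometryError("an OIT sweep needs at least 3 distinct OIT values")
    return OITSweep(
        oit=np.array(oits), fwhm=np.array(fwhms), penumbra_mean=np.array(pens),
        leaf_pitch=leaf_pitch,
    )


def representative_oit(sweep: OITSweep, tie_rel_tol: float = 0.02) -> float:
    """OIT whose metrics are closest to the sweep average.

    Minimizes ``|FWHM_norm - 1| + |penumbra_norm - 1|`` (equal weights). In a
    leaf-pitch-periodic sweep the quarter-pitch positions are degenerate
    minima, so objective values within ``tie_rel_tol`` of the minimum
    (relative to the sweep's objective range) are treated as tied; ties are
    broken by the smallest |OIT|, then the positive sign — the measurement
    position closest to the CAX, where beam divergence is negligible.
    """
    obj = np.abs(sweep.fwhm_norm - 1.0) + np.abs(sweep.penumbra_norm - 1.0)
    lo, span = obj.min(), obj.max() - obj.min()
    tied = obj <= lo + tie_rel_tol * span
    candidates = sweep.oit[tied]
    order = np.lexsort((-np.sign(candidates), np.abs(candidates)))
    return float(candidates[order[0]])
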