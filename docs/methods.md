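# Methods

This note documents the models, conventions and numerical choices behind
`beamtune`, in the order the protocol uses them.

## Profile model and metrics

A profile is a 1D scan of relative dose (percent of the central-axis value)
versus off-axis position in mm, with geometry metadata: scan axis
(crossline = leaf-motion direction X, inline = Y), depth [cm], SSD [cm]
(default 90), nominal square field size [cm], and — for crossline scans —
the off-axis inline translation (OIT) [mm]. Positions are strictly
increasing; all intervals are closed.

*Normalization.* The CAX dose is the single sample nearest position 0
(within ±0.5 mm), matching a point-like detector reading; a plateau average
would wash out exactly the leaf-structure effects the protocol measures.
Dose is scaled so this sample equals 100.

*Crossings.* FWHM is the distance between the outermost 50% crossings; the
penumbra on each side is the interval between the outermost 80% and 20%
absolute-level crossings (not levels relative to a local shoulder). The
"outermost" rule — last bracketing sample pair scanning from the tails
inward, linear interpolation within the pair — makes the metrics robust to
noise-induced multiple crossings near a level. Profiles are resampled to a
0.1 mm grid (linear interpolation, endpoints preserved) before metrics are
taken or profiles are compared.

*Representative OIT.* A sweep of crossline scans over ±2 leaf widths gives
FWHM and mean penumbra versus OIT; each is normalized to its sweep average.
The representative OIT minimizes the unweighted L1 sum
`|FWHM_norm − 1| + |penumbra_norm − 1|`; the two criteria get equal weight
and the mean of the left/right penumbra widths is used, the simplest
symmetric choices. In a leaf-pitch-periodic sweep all quarter-pitch
positions are degenerate minima of the cosine model, so objective values
within 2% of the minimum (relative to the sweep's objective range) are
treated as tied before tie-breaking by smallest |OIT|, then positive sign —
the position nearest the CAX, where beam divergence is negligible. Without
the tolerance, the pick among exact-tie candidates would be decided by
interpolation noise at the 1e-4 level.

## Beam simulator

The simulator is a minimal fluence-convolution model with the same
user-facing parameters as a clinical TPS beam model; it is not a dose
engine (no head-scatter sources, rounded-tip ray tracing or
tongue-and-groove). Its role is to provide paired "measured" (reference
parameters + noise) and "modelled" (candidate parameters) data with the
right qualitative structure for protocol testing.

A crossline profile is

    D(x) ∝ T + (1 − T) · [Φ((x − xL)/σ) − Φ((x − xR)/σ)],

renormalized to CAX = 100, with T the MLC transmission,
σ = sqrt(ESS_axis² + σ_depth²) the quadrature sum of the spot blur and a
depth-dependent intrinsic blur, and the edges at

    xR = −xL = 5·W + DLG/2 + a·cos(2π·OIT/pitch)

for nominal field side W [cm]: the DLG retracts each modelled leaf tip by
half the parameter, and the cosine term (amplitude a, default 0.15 mm)
models the leaf-structure FWHM modulation — widest between leaves, as a
small detector sees it. A same-phase relative modulation of σ (default 5%)
reproduces the observed penumbra widening near leaf junctions. Inline
edges sit at ±5·W (leaf sides are flat; no DLG). Because the
field-defining leaves park abutting at the central axis, an inline scan
runs along the closed-leaf abutment and sees a DLG-proportional leakage
floor outside the field (gain 0.02 per mm DLG, times the complement of the
blurred aperture window); this makes the inline direction DLG-sensitive
and is what distinguishes otherwise near-equivalent (ESSy, DLG)
combinations. It can be disabled to emulate leaves parked at the carriage.

Defaults: leaf pitch 5 mm (central Millennium leaves); intrinsic
σ = 2.4/2.8/3.4 mm at depths 5/10/20 cm, chosen to give 80–20% penumbras
of 4–6 mm — plausible for a 6 MV FFF beam measured with a small diode —
and configuration, not claims; transmission 1.5%; grid step 0.2 mm over
the field plus a 30 mm margin (0.05 mm for OIT sweeps, where quarter-pitch
degeneracy makes the selection sensitive to crossing-interpolation phase
noise at coarser grids); additive Gaussian noise on relative dose, off by
default, with one seed governing a whole profile set and each profile's
stream derived deterministically from (seed, geometry).

2D dose planes are weighted sums of separable blurred rectangular
apertures with DLG-widened crossline edges, normalized to a prescription;
leaf-structure modulation is deliberately absent in 2D (planes represent
arc-averaged deliveries).

What the simulator does **not** emulate — interleaf leakage spectra,
rounded-tip transmission tails, detector volume averaging, scanner lateral
response — bounds what passing tests show: they validate the *protocol*
(selection, metric, search, verification chain), not any dose engine.

## AID objective and grid search

The absolute integrated difference between a measured and a modelled
profile is the area between the curves over the measured profile's
penumbra regions, trapezoidally integrated on the 0.1 mm grid (region
endpoints included exactly), in %·mm. Regions always come from the
measured (reference) profile so every candidate parameter set is scored on
identical intervals; with "area between curves" and a monotone penumbra
this equals the absolute difference of the areas under the curves. Both
profiles must already be on the percent scale (a CAX sample outside
100 ± 10 is rejected rather than silently renormalized, which would
rescale genuine dose discrepancies).

Per-direction objective: mean over that direction's depths within each
field size, then a weighted sum over field sizes (defaults 10/30/30/30%
for 2/3/4/5 cm, the clinical field-size frequencies); the inline direction
has a single depth, so its average is the value itself. The total
objective sums the crossline and inline components with equal weight; both
components are retained per cell for inspection.

The optimization is an exhaustive evaluation over candidate values of
(ESSx, ESSy, DLG) — by design, since TPS beam configuration is a discrete
re-calculation per candidate, and the grid doubles as documentation of
what was tried. Default spacings 0.1 mm (ESS) and 0.05 mm (DLG); sparse
candidate lists are supported, and unevaluated or failed cells stay NaN.
The optimum is the argmin over finite cells. Cells within 1% (relative) of
the minimum are statistically indistinguishable — measured AID values
carry a few-percent reproducibility uncertainty while the metric's own
integration error is below 0.1% — and resolve toward the least
aggressive correction: smallest DLG, then smallest ESSx + ESSy. This also
implements the physical-lower-bound argument: when the modelled penumbra
with an ESS component at 0 is already at least as wide as measured, the
component stays at 0. With noise-free input the minimum is exactly 0 and
the band is empty, so recovery is exact. Diagnostics report the AID margin
to the runner-up as a relative difference in percent.

## Gamma evaluation

γ(r) over the evaluated distribution combines the dose difference (against
`dose_crit` percent of the local reference dose, or of the reference
maximum for global normalization) with the distance to agreement (against
`dist_crit`), reference points below a threshold (default 10% of the
reference maximum) excluded; γ = 1 counts as passing. The reference is
never interpolated; the evaluated distribution is bilinear.

Search: a shared coarse offset sweep (step `dist_crit`/10, radius capped
at 3×`dist_crit`, beyond which the distance term alone is uninteresting)
bounds γ per point, pruning points whose running minimum already beats the
distance term of all remaining offsets. Because a bound g confines the
minimizer to within `dist_crit`·g of the point, a second exhaustive pass
at `dist_crit`/100 inside that per-point radius then resolves the narrow
valleys along dose level sets that a coarse grid misses — the
discretization false positives that interpolation is meant to suppress.
For 1D profiles no search grid is used at all: γ² is quadratic on each
segment of the evaluated polyline and is minimized exactly. Degenerate
inputs (zero reference maximum, disjoint grids, nothing above threshold)
raise.

## Film chain

Net optical density is `log10(I_unexposed/I_exposed)` per channel, clipped
below at 0; the unexposed reference is a per-channel scalar (film-base and
fog are not subtracted separately). Calibration fixes the two-parameter
rational form `D(x) = b·x/(c − x)` through the origin per channel, fitted
by least squares on netOD–dose pairs (≥ 4 levels including 0 Gy, netOD
monotone in dose enforced); the pole c must exceed the netOD range.
Doses above the calibrated maximum are refused rather than extrapolated.

Triple-channel reconstruction models the physical disturbance
(active-layer thickness, scanner response) as one multiplicative factor on
the netOD of all three channels. Per pixel, the disturbance Δ ∈ ±10% that
minimizes the variance of the three corrected channel doses is found by a
dense scan (step 0.002) with one parabolic refinement; the dose is the
mean of the corrected estimates, and pixels where no Δ beats the
uncorrected variance keep Δ = 0 with a flag. In unexposed regions Δ is
unidentifiable and its map is noise there; the dose remains accurate.
Published multichannel formulations parameterize a scan-value disturbance
instead; to first order in Δ the two act identically on the channel doses,
which is the equivalence assumed here.

Smoothing is a uniform box filter whose side is 1% of the image diagonal
in pixels, rounded, forced odd, minimum 3; reflection padding makes the
filter doubly stochastic, so the image mean is preserved exactly.
Registration maximizes the Pearson correlation (invariant to dose
rescaling) of the model resampled on the measurement grid over a staged
rigid search: translations ±5 mm at 0.5 mm, rotation ±3° at 0.1° about the
grid centre (rotation can be disabled), then translation refinement at
0.1 mm; at least 50% of the measurement area must stay covered. No
lateral-response-artifact correction is applied anywhere — films are
assumed centred on the scanner window.

The synthetic scan generator inverts the calibration per channel, applies
the Δ field and multiplicative Gaussian intensity noise, and quantizes to
16 bits; one seed makes scans bit-reproducible. It exists so the whole
chain (dose → scan → dose) can be round-trip tested: noiseless round-trip
error is below 0.5% of the maximum dose (quantization only).

## Verification statistics

Per-plan records carry the gamma pass rate of each beam model against the
plan's measured film dose. Mean GPRs are arithmetic means over matching
plans, reported to 0.1. Improvements over a baseline model are means of
per-plan GPR *ratios* (not ratios of means, and not mean differences),
expressed as percentages; this is the convention under which the packaged
15-plan fixture reproduces its published per-technique aggregates, except
the DCAT Acuros figure, where the fixture supports 3.9% against a printed
3.8% under every convention tried — that aggregate is reported as computed
and excluded from assertions.

## Problem sizes in tests

Tests and the acceptance script use the study's own geometry throughout
(16-profile optimization sets, ±10 mm OIT sweeps at 0.25 mm, a 135-cell
candidate grid, 5 noise seeds); gamma-oracle cross-checks run on 64×64
planes at 1 mm spacing against an exhaustive 0.01 mm search, and film
round trips on ~50×50 planes — sizes at which every oracle is itself
re-computable in seconds.
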