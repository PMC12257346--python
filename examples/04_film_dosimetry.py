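"""Radiochromic-film processing chain on a synthetic scan.

A known dose plane is forward-modelled into a 48-bit RGB film scan
(rational calibration per channel, a spatially varying active-layer
thickness perturbation, scanner noise), then reconstructed with
triple-channel dosimetry, box-smoothed, and rigidly registered against the
modelled plane it came from. The common-mode thickness perturbation is
separated from dose — the point of using all three channels.
"""

import numpy as np

import beamtune as bt

# plausible EBT3-like calibration, red channel most sensitive
cal = bt.CalibrationCurve(
    b=np.array([10.0, 14.0, 30.0]),
    c=np.array([0.8, 1.0, 1.6]),
    x_max=np.array([0.78, 0.9, 1.3]),
    max_dose=19.0,
)

# ground-truth dose: 15 Gy Gaussian spot, 0.4 mm pixels
n, spacing = 60, 0.4
c0 = spacing * (n - 1) / 2
y = spacing * np.arange(n) - c0
dose = bt.DoseImage(15.0 * np.exp(-(y[:, None] ** 2 + y[None, :] ** 2) / 80.0),
                    (spacing, spacing), (-c0, -c0))

# film exposure + scan: +/-3% thickness ripple, 0.3% scanner noise
delta = 0.03 * np.sin(np.linspace(0, 4 * np.pi, n))[:, None] * np.ones((n, n))
scan = bt.simulate_film_scan(dose, cal, noise_sd=0.003, delta_field=delta, seed=1)

netod = bt.net_optical_density(scan)
triple = bt.triple_channel_dose(netod, cal, pixel_mm=spacing, origin=dose.origin)
single = bt.single_channel_dose(netod, cal, channel=0, pixel_mm=spacing,
                                origin=dose.origin)

err3 = np.abs(triple.dose.values - dose.values).mean()
err1 = np.abs(single.values - dose.values).mean()
print(f"mean |dose error|: single channel {err1:.3f} Gy, "
      f"triple channel {err3:.3f} Gy")
# the per-pixel delta is noisy; its median over each ripple phase tracks it
exposed = dose.values > 5.0
hi, lo = exposed & (delta > 0.02), exposed & (delta < -0.02)
print(f"median recovered thickness perturbation: "
      f"{np.median(triple.delta[hi]):+.3f} on the +3% ripple crests, "
      f"{np.median(triple.delta[lo]):+.3f} in the -3% troughs")

smoothed = bt.smooth_dose(triple.dose)
shifted_model = bt.DoseImage(dose.values, dose.spacing,
                             origin=(dose.origin[0] + 0.8, dose.origin[1] - 1.2))
reg = bt.register_rigid(smoothed, shifted_model, rotate=False)
print(f"registration recovered shift: ({reg.dx:+.1f}, {reg.dy:+.1f}) mm "
      f"(applied: (+1.2, -0.8) mm), correlation {reg.correlation:.4f}")
print("\nTriple-channel reconstruction removes the common-mode thickness")
print("signal that a single channel misreads as dose.")
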