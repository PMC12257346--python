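"""Gamma-verify beam models against a film-like measured dose plane.

A 3x3 cm plan computed with reference parameters (DLG 0.9 mm) is turned
into a noisy film measurement (scan noise, thickness ripple, triple-channel
reconstruction, box smoothing). Two modelled planes are then gamma-compared
against it under the strict local 1%/1 mm criterion with a 10% low-dose
threshold: one using the matching parameters and one with DLG mis-set to
1.6 mm — a value tuned on large fields that overshoots small apertures.
"""

import numpy as np

import beamtune as bt

cal = bt.CalibrationCurve(
    b=np.array([10.0, 14.0, 30.0]), c=np.array([0.8, 1.0, 1.6]),
    x_max=np.array([0.78, 0.9, 1.3]), max_dose=19.0,
)

cfg = bt.SimConfig(fwhm_modulation_amp=0.0, penumbra_modulation_amp=0.0)
plan = bt.PlanSpec([bt.Aperture(3, 3)], prescription=15.0, depth=5.0)
truth = bt.simulate_dose_plane(
    bt.BeamModelParams(essx=0.5, essy=0.0, dlg=0.9), plan, cfg, pixel_mm=1.0)

# film measurement of the delivered plan: scan noise + thickness ripple
ripple = 0.02 * np.sin(np.arange(truth.values.shape[0]) / 4.0)[:, None] \
    * np.ones_like(truth.values)
scan = bt.simulate_film_scan(truth, cal, noise_sd=0.004, delta_field=ripple, seed=3)
rec = bt.triple_channel_dose(bt.net_optical_density(scan), cal,
                             pixel_mm=1.0, origin=truth.origin)
measured = bt.smooth_dose(rec.dose)

gp = bt.GammaParams(dose_crit=1.0, dist_crit=1.0, normalization="local",
                    threshold=10.0)
for label, dlg in (("matched model (DLG 0.9 mm)", 0.9),
                   ("mis-set model (DLG 1.6 mm)", 1.6)):
    model = bt.simulate_dose_plane(
        bt.BeamModelParams(essx=0.5, essy=0.0, dlg=dlg), plan, cfg, pixel_mm=1.0)
    res = bt.gamma_map(measured, model, gp)
    print(f"{label}: GPR = {res.gpr:6.2f}%  "
          f"(mean gamma {np.nanmean(res.gamma):.2f}, "
          f"{res.n_evaluated} points evaluated)")

print("\nThe 0.7 mm DLG excess widens each field edge by 0.35 mm; on top of")
print("the film noise this pushes penumbra points past the local 1%/1 mm")
print("criterion, while the matched model stays near the noise floor.")
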