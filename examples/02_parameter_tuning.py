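"""Tune DLG and effective spot size against measured small-field profiles.

A "measured" 16-profile optimization set (field sizes 2-5 cm; crossline at
depths 5/10/20 cm at OIT 1.2 mm, inline at 10 cm) is generated with
reference parameters ESS = (0.5, 0) mm, DLG = 0.9 mm plus 0.3% measurement
noise. The weighted AID objective is then evaluated over a 3D candidate
grid and its minimum recovers the generating parameters.
"""

import numpy as np

import beamtune as bt

truth = bt.BeamModelParams(essx=0.5, essy=0.0, dlg=0.9)
measured = bt.simulate_profile_set(truth, bt.SimConfig(noise_sd=0.3, seed=2))

grid = bt.build_aid_grid(
    measured,
    essx_values=np.round(np.arange(0.3, 0.701, 0.1), 2),
    essy_values=[0.0, 0.1, 0.2],
    dlg_values=np.round(np.arange(0.7, 1.101, 0.05), 3),
    provider=bt.sim_provider(bt.SimConfig()),
    w=bt.FieldWeights(),   # 10% for 2x2 cm^2, 30% each for 3-5 cm^2
)
best, diag = bt.optimal_params(grid)

print(f"candidate grid: {diag.n_evaluated} parameter combinations")
print(f"optimum: ESS(x, y) = ({best.essx:g}, {best.essy:g}) mm, DLG = {best.dlg:g} mm")
print(f"weighted AID at optimum: {diag.best_aid:.2f} %mm "
      f"(noise floor of the absolute-difference integral)")
if diag.margin_pct is not None:
    print(f"margin to second-best cell: {diag.margin_pct:.1f}%")
print("\nThe argmin of the field-size-weighted, depth-averaged AID recovers")
print("the parameters that generated the measurements.")
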