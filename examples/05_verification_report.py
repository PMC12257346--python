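"""Aggregate verification-plan gamma pass rates by technique and model.

The packaged fixture holds 15 lung SBRT verification plans (11 DCAT,
4 VMAT), each with the local 1%/1 mm gamma pass rate of its film
measurement against three beam models: the clinically commissioned AAA
model and the small-field-optimized AAA and Acuros XB models.
"""

import beamtune as bt

records = bt.table1_fixture()
print(bt.summary_table(records, baseline="clin_aaa").to_string(index=False))

dcat = bt.improvement_stats(records, "opt_aaa", "clin_aaa", technique="DCAT")
vmat = bt.improvement_stats(records, "opt_aaa", "clin_aaa", technique="VMAT")
print(f"\noptimized AAA vs clinical AAA, mean per-plan GPR ratio improvement:")
print(f"  DCAT: {dcat.mean_rounded:+.1f}%   VMAT: {vmat.mean_rounded:+.1f}%")
print("\nThe tuned model mainly helps DCAT deliveries, whose static apertures")
print("match the small-field profiles used for the tuning; heavily modulated")
print("VMAT plans are less sensitive to the penumbra-focused correction.")
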