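"""The closed-form assay readouts: vesicle calcium influx, LDH cytotoxicity,
and delta-delta-Ct relative expression.
"""

import numpy as np
import pandas as pd

from tauagg import assays, synth

# vesicle influx: synthetic fields for the three tau species
for name, frac in (("WT fibrils", 0.12), ("g-tau", 0.21), ("s-tau", 0.28)):
    field = synth.gen_vesicle_frames(40, [frac], noise_sd=5.0, seed=11)
    out = assays.influx_from_frame(field)
    usable = out[~out["excluded"]]
    print(f"{name}: mean calcium influx "
          f"{usable['influx_pct'].mean():.1f} % over {len(usable)} vesicles")

# LDH cytotoxicity from 490/680 nm absorbance pairs
m = assays.LdhMeasurement(a490_sample=0.6, a680_sample=0.1,
                          a490_spontaneous=0.2, a680_spontaneous=0.1,
                          a490_maximum=1.1, a680_maximum=0.1)
print(f"\nLDH cytotoxicity: {assays.ldh_cytotoxicity(m):.1f} %")

# relative expression: Ct table built from known fold changes
rows = []
for sample, group, fc in [("PBS0", "PBS", 1.0), ("PBS1", "PBS", 1.0),
                          ("tau0", "tau", 8.0), ("tau1", "tau", 6.0)]:
    rows += [{"sample": sample, "group": group, "gene": "GAPDH", "ct": 20.0},
             {"sample": sample, "group": group, "gene": "18S", "ct": 10.0},
             {"sample": sample, "group": group, "gene": "TNF",
              "ct": 25.0 - np.log2(fc)}]
expr = assays.relative_expression(pd.DataFrame(rows))
print("\nrelative expression (fold change vs PBS control):")
print(expr[["sample", "gene", "fold_change"]].to_string(index=False))
print("\nAll three formulas cancel uniform gain (and offsets where both")
print("numerator and denominator are differences), so raw-signal scaling")
print("does not affect the reported percentages or fold changes.")
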