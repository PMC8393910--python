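"""Enumerate all pair and triple FA combinations and assign doses.

Pairs combine FAs at their single-FA peak doses; triples reduce every
component to one third of its peak dose (half-up integer rounding) to
limit the total lipid load. Writes results/mixture_designs.csv.
"""

import pandas as pd

from pparmix.mixtures import assign_doses, enumerate_mixtures

profiles = pd.read_csv("results/profiles.csv")
peaks = dict(zip(profiles["fa"], profiles["peak_dose"]))
panel = sorted(peaks)

rows = []
for k, scale in ((2, 1.0), (3, 1 / 3)):
    for m in enumerate_mixtures(panel, k):
        dosed = assign_doses(m, peaks, scale)
        rows.append(
            {
                "label": dosed.label,
                "k": k,
                "components": ";".join(f"{fa}:{d:g}" for fa, d in dosed.components),
                "total_dose": dosed.total_dose,
            }
        )
designs = pd.DataFrame(rows)
designs.to_csv("results/mixture_designs.csv", index=False)
print(f"designed {len(designs)} mixtures over {len(panel)} FAs")
print(designs.groupby("k").size().rename("count").to_string())
print("\ntriple component doses (one third of peak, rounded):")
print(designs[designs["k"] == 3].head(3).to_string(index=False))
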