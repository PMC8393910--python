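"""Normalize raw dual-reporter readings to fold-changes vs vehicle.

Each well's firefly/Renilla ratio is divided by its plate's mean vehicle
ratio; Renilla relative to the vehicle mean doubles as a viability proxy
(threshold 0.7). Writes results/normalized.csv.
"""

import pandas as pd

from pparmix.normalize import flag_viability, fold_changes
from pparmix.simulate import read_plate_csv

wells = read_plate_csv("results/plate_data.csv")
norm = flag_viability(fold_changes(wells), threshold=0.7)
norm.to_csv("results/normalized.csv", index=False, float_format="%.10g")

flagged = norm[norm["viability_flag"]]
print(f"normalized {len(norm)} of {len(wells)} wells")
print(f"viability-flagged wells: {len(flagged)}")
if len(flagged):
    totals = flagged["components"].str.count(":")
    print(
        "flagged wells are high-total-dose treatments "
        f"({flagged['treatment'].nunique()} treatments)"
    )
veh = norm[norm["treatment"] == "vehicle"].groupby("plate_id")["fold_change"].mean()
print("vehicle mean fold per plate (should be 1):")
print(veh.to_string())
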