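"""Pairwise treatment comparisons on the mixtures plate.

All-pairwise Tukey HSD over single-FA and mixture treatments with a
compact letter display, plus per-FA grids testing each mixture against the
single FA it contains. Writes results/comparisons.csv, results/letters.csv
and results/mixture_vs_component_grid.csv.
"""

import pandas as pd

from pparmix.mixtures import MixtureDesign
from pparmix.simulate import parse_components
from pparmix.stats import letter_display, mixture_vs_component_grid, pairwise_compare

norm = pd.read_csv("results/normalized.csv", keep_default_na=False)
plate = norm[norm["plate_id"] == "P2"]

groups = {
    t: g["fold_change"].to_numpy()
    for t, g in plate.groupby("treatment")
    if t != "vehicle"
}
comps = pairwise_compare(groups, alpha=0.05)
pd.DataFrame(
    [
        {"group_a": c.group_a, "group_b": c.group_b, "estimate": c.estimate,
         "p_value": c.p_value, "significant": c.significant}
        for c in comps
    ]
).to_csv("results/comparisons.csv", index=False, float_format="%.10g")

letters = letter_display(comps)
pd.DataFrame(
    [{"treatment": t, "letters": "".join(ls)} for t, ls in sorted(letters.items())]
).to_csv("results/letters.csv", index=False)

designs, singles = [], {}
for comp_str in plate["components"].unique():
    parsed = parse_components(comp_str)
    if len(parsed) >= 2:
        designs.append(MixtureDesign(parsed))
    elif len(parsed) == 1:
        fa, dose = parsed[0]
        singles[fa] = f"{fa}@{dose:g}"
grid = mixture_vs_component_grid(sorted(designs, key=lambda m: m.label),
                                 singles, groups, alpha=0.05)
grid.map(lambda v: "" if v is pd.NA else int(v)).to_csv(
    "results/mixture_vs_component_grid.csv"
)

n_sig = sum(c.significant for c in comps)
print(f"pairwise comparisons: {len(comps)} pairs, {n_sig} significant at 0.05")
print(f"letter groups: {len(set(letters.values()))}")
cells = grid.to_numpy().ravel()
filled = sum(v is not pd.NA for v in cells)
hits = sum(v is True for v in cells)
print(f"mixture-vs-component grid: {hits} of {filled} cells significant")
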