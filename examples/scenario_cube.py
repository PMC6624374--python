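"""Map fish B1 status over a small fish x nutrient x attenuation cube.

A desk-scale 2 x 3 x 3 version of the scenario grid: enough to see the
two B1-poor regions (high fish with high nutrients, and strong
background attenuation) and the B1-rich corner at low fish abundance
in clear water.
"""

from b1web import classify, run_scenario, scenario_grid, summarize
from b1web.metrics import cube_report

classifications, summaries = [], []
for scenario in scenario_grid(2, 3, 3):
    result = run_scenario(scenario)
    classifications.append(classify(result))
    summaries.append(summarize(result))

cube = cube_report(classifications, summaries)
symbol = {"b1_poor": "P", "b1_rich": ".", "intermediate": "o"}

for fish in sorted(cube.fish_abundance.unique()):
    block = cube[cube.fish_abundance == fish]
    ks = sorted(block.k_bg.unique())
    print(f"fish = {fish:.4f} ind/m^3        k_bg: "
          + "  ".join(f"{k:.2f}" for k in ks))
    for N in sorted(block.total_N.unique()):
        row = [symbol[block[(block.total_N == N) & (block.k_bg == k)]
                      .label.iloc[0]] for k in ks]
        print(f"  total N = {N:5.2f} mmol/m^3:    " + "     ".join(row))
    print()

n_poor = int((cube.label == "b1_poor").sum())
print(f"{n_poor} of {len(cube)} scenarios leave planktivorous fish B1-poor "
      "(P = poor, . = rich, o = intermediate).")
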