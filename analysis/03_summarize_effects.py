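"""Summarize the scenario runs: percent-change boxes, effect sizes, headline numbers.

Reads results/scenario_results.csv, writes per-scenario summaries and
defaunation-vs-control effect sizes, and prints the carbon headline: median
percent change per removal level in each preset, the share of declining runs,
and a back-of-envelope biome-scale release using the animal-dominated 50%
scenario.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from defaunation_carbon.summarize import biome_release_estimate

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
table = pd.read_csv(OUT / "scenario_results.csv")

rows = []
for (site, pct, scenario, response), grp in table.groupby(
    ["site_id", "removal_pct", "scenario", "response"]
):
    finite = grp["pct_change"].dropna().to_numpy()
    if finite.size == 0:
        continue
    q25, med, q75 = np.percentile(finite, [25, 50, 75])
    rows.append(
        {
            "site_id": site,
            "removal_pct": pct,
            "scenario": scenario,
            "response": response,
            "median_pct": med,
            "q25_pct": q25,
            "q75_pct": q75,
            "pct_runs_declining": 100.0 * float(np.mean(finite < 0)),
            "n_iterations": int(finite.size),
            "consistent": bool(q25 > 0 or q75 < 0),
        }
    )
summary = pd.DataFrame(rows)
summary.to_csv(OUT / "scenario_summaries.csv", index=False)

# Effect sizes: defaunation minus each control, per site/level/response.
wide = summary.pivot_table(
    index=["site_id", "removal_pct", "response"], columns="scenario", values="median_pct"
).reset_index()
wide["effect_vs_individual_control"] = wide["defaunation"] - wide["individual_control"]
wide["effect_vs_species_control"] = wide["defaunation"] - wide["species_control"]
wide.to_csv(OUT / "effect_sizes.csv", index=False)

carbon = summary.query("response == 'carbon' and scenario == 'defaunation'")
print("Median carbon change (%) by removal level:")
print(
    carbon.pivot_table(index="removal_pct", columns="site_id", values="median_pct")
    .round(2)
    .to_string()
)
print("\nShare of runs with declining carbon (%), defaunation scenario:")
print(
    carbon.pivot_table(index="removal_pct", columns="site_id", values="pct_runs_declining")
    .round(1)
    .to_string()
)
seed_size = summary.query("response == 'cw_seed_size' and scenario == 'defaunation'")
print("\nMedian community-weighted seed-size change (%):")
print(
    seed_size.pivot_table(index="removal_pct", columns="site_id", values="median_pct")
    .round(1)
    .to_string()
)

loss_50 = -carbon.query("site_id == 'animal_dominated' and removal_pct == 50")["median_pct"].iloc[0]
release = biome_release_estimate(124.0, loss_50 / 100.0)
print(
    f"\nIf forests like the animal-dominated preset lost {loss_50:.1f}% of a 124 Pg stock "
    f"(the 50% extirpation median), that would release ~{release:.1f} Pg C."
)
print("wrote", OUT / "scenario_summaries.csv", "and", OUT / "effect_sizes.csv")
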