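# defaunation-carbon

Simulation pipeline for asking how the loss of large-bodied seed dispersers —
and with them the large-seeded, animal-dispersed tree species they maintain —
changes aboveground carbon storage in tropical forest communities.

It is aimed at community ecologists and ecosystem modellers who work with
stem-inventory tables (one row per tree ≥ 10 cm DBH) plus species trait tables
(dispersal mode, seed length, wood density, adult stature), and who want a
reproducible, null-model-controlled extirpation experiment rather than a
forest dynamics model.

## The method

Per-stem aboveground biomass follows the moist-forest allometry of Chave et
al. (2005), which needs only wood density *W* (g cm⁻³) and diameter *D* (cm):

```
AGB (kg) = W · exp(−1.499 + 2.148 ln D + 0.207 (ln D)² − 0.0281 (ln D)³)
```

Its multiplicative structure factors stand carbon into a **wood-density** term
and a DBH-driven **volume** term, so simulated shifts can be decomposed into
those two channels. Stand-level responses: carbon (Mg C ha⁻¹), a volume index
(Σ of the DBH term), basal-area-weighted stand wood density, the fraction of
large trees (≥ 70 cm DBH), and community-weighted seed size.

A simulated extirpation is a two-step draw, holding total basal area constant:

1. **Removal** — delete *N*<sub>Rem</sub> = 25/50/75/100% of the individuals
   of large-seeded animal-dispersed species (those above the 75th-percentile
   seed length among the community's animal-dispersed species, or a fixed
   regional cutoff), recording lost basal area BA<sub>Loss</sub> and
   incidental species loss *S*<sub>Loss</sub>.
2. **Recovery** — repopulate with clones of surviving stems drawn uniformly
   with replacement until total basal area is back within ±1% of the
   original. Because basal area, not stem count, is the target,
   *N*<sub>Rec</sub> ≠ *N*<sub>Rem</sub> in general.

Every iteration is paired with two matched null controls: an
**individual-based** control removing the same *N*<sub>Rem</sub> stems at
random (isolating the pure remove-and-replace artefact) and a
**species-based** control removing *S*<sub>Loss</sub> random species
(isolating species loss per se). Responses are summarized as percent change
from the original community — medians, 25–75% boxes, the share of declining
runs, and median-difference effect sizes versus the controls (no p-values,
which would be arbitrary in a simulation of chosen size).

Missing traits are filled by a taxonomic fallback chain — seed length from a
genus-wise fruit-length regression (fitted where ≥ 3 species have both
measurements), then the genus mean; wood density from genus then family
means — with every imputed value tagged by source.

A synthetic-community generator reproduces the structure this analysis relies
on (right-skewed DBH distributions with a 10 cm floor, lognormal seed lengths,
and the dispersal–seed size–adult size linkage in which large-seeded
animal-dispersed species are larger as adults than small-seeded ones but
smaller than abiotic dispersers, which have the lowest wood densities), so the
whole pipeline is testable without plot data.

## Worked example

```python
from defaunation_carbon import (
    ScenarioSpec, generate_site, impute_community, run_scenario, summarize_scenario,
)

_, community = generate_site("animal_dominated", seed=0)   # 2000 stems, 90% animal-dispersed
community = impute_community(community)
run = run_scenario(community, ScenarioSpec(removal_fraction=1.0, iterations=500, rng_seed=0))
for scenario in ("defaunation", "individual_control", "species_control"):
    s = summarize_scenario(run.results, "carbon", scenario=scenario)
    print(f"{scenario:>18}: median {s.median_pct:+.2f}%  IQR [{s.q25_pct:+.2f}, {s.q75_pct:+.2f}]  "
          f"declining {s.pct_runs_declining:.0f}%")
```

prints

```
       defaunation: median -0.93%  IQR [-1.22, -0.66]  declining 98%
individual_control: median +0.01%  IQR [-0.39, +0.41]  declining 48%
   species_control: median +0.04%  IQR [-0.56, +0.61]  declining 49%
```

Complete extirpation of large-seeded animal-dispersed species from this
animal-dominated community consistently lowers carbon storage (median −0.93%,
98% of runs declining, inter-quantile box excluding zero), while both matched
controls sit at zero — the loss is attributable to *which* species were
removed, not to the removal/replacement machinery. The same run shows
community-weighted seed size dropping by 37%. On the `abiotic_rich` preset
(abundant, very large abiotically dispersed species) the carbon median stays
within about ±1%: the contrasting regional responses arise from floristics.

The numbered scripts under `analysis/` run the full narrative — community
generation, all removal levels with controls, effect-size summaries, the
cross-site volume-vs-wood-density mechanism check, and trait-group
contrasts — writing tables under `results/`. The `defaunation-carbon` CLI
(`generate` / `simulate` / `summarize`) does the same from the shell for
user-supplied stem and trait tables.

## Layout

- `src/defaunation_carbon/` — library: `data_io`, `traits`, `carbon`,
  `simulation`, `summarize`, `synthetic_data`, `config`, `cli`.
- `analysis/` — numbered narrative drivers writing to `results/`.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — model assumptions, parameter choices and limitations.
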