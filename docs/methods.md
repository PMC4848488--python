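# Methods

## Scope and model

The package implements an equilibrium-composition thought experiment: what
would a tropical forest stand's aboveground carbon stock be if the individuals
of large-seeded animal-dispersed tree species declined and the lost basal area
were taken up by the remaining community? There is no demographic dynamics —
no growth, recruitment or mortality through time — because the time frame of
defaunation-driven compositional change is unknown; the simulation compares
compositional end states at constant basal area.

Aboveground biomass per stem uses the Chave et al. (2005) moist-forest
allometry, AGB = W·g(D) with
g(D) = exp(a₀ + a₁ ln D + a₂ (ln D)² + a₃ (ln D)³) and default coefficients
(−1.499, 2.148, 0.207, −0.0281). Height is implicit in g(D). The model is
known to overestimate absolute biomass; all analysis is on percent changes,
which a common multiplicative bias cannot affect. Stand carbon is
carbon_fraction × Σᵢ Wᵢ g(Dᵢ) / area. The carbon fraction (Mg C per Mg
biomass) is not part of the source allometry; it defaults to 0.5 and is
configurable. Percent-change outputs are provably insensitive to it (it
cancels), which the test suite asserts end to end.

Responses tracked per simulated community: carbon (Mg C ha⁻¹); a volume index
Σ g(Dᵢ), the non-wood-density factor of stand biomass; stand wood density as
the species-level average weighted by per-species basal area (equal to the
stem-BA-weighted mean when wood density is constant within species, as it is
after imputation); the fraction of stems ≥ 70 cm DBH; and the stem-weighted
mean seed length of animal-dispersed individuals (basal-area weighting is
available as an option; the weighting used is declared in run metadata).

## Trait handling

Raw dispersal modes (animal, wind, unassisted, multiple) aggregate to
animal-dispersed = {animal, multiple} versus abiotic = {wind, unassisted};
unmapped labels are an error, never a silent default.

Imputation chain, in decreasing order of preference:

- **Seed length** — measured value; else a genus-wise OLS regression of seed
  length on fruit length, fitted only in genera where ≥ 3 species carry both
  measurements (non-positive predictions fall through with a warning; fit
  quality is reported per genus but never used as a gate); else the genus mean
  of measured seed lengths.
- **Wood density** — species value; else genus mean; else family mean.

Genus and family means are computed from measured/species-level values only,
so chains of imputations cannot form, and a measured value is never
overwritten. Every resolved value carries a source tag in the augmented trait
table.

Large-seeded classification: among the animal-dispersed species *present* in
a community, the cutoff is the 75th percentile of seed lengths — one value
per species, unweighted, using the linear-interpolation ("type 7") quantile —
and species strictly above it are large-seeded; ties fall to small-seeded.
The percentile, a stem-weighted variant, and fixed regional cutoffs in cm
(e.g. 1.5–2.0) are configurable, since cutoff placement shifts
classifications. Abiotic species are never classified large-seeded.

## Simulation engine

Each iteration applies removal then recovery:

- **Defaunation removal**: N_Rem = round(fraction × count) individuals of
  large-seeded species, drawn uniformly without replacement. Rounding is
  round-half-even; fraction 1.0 removes every such individual.
- **Recovery**: stems are drawn uniformly with replacement from the
  *post-removal survivor pool* and appended as clones (same species, same
  DBH — a drawn large tree re-enters at full size, with a fresh stem id)
  until total basal area reaches the original community's total. A draw that
  would overshoot the +tolerance bound (default ±1%) is rejected and redrawn;
  draws are capped (default 10⁵), and an iteration whose band cannot be
  reached fails explicitly, is dropped, and is reported — never silently
  retried. Termination uses a 10⁻⁹ relative epsilon on the deficit so that
  deficits equal to an exact multiple of a clone's basal area terminate
  despite floating-point rounding. The terminal total is therefore within
  (−10⁻⁹, +tolerance] of the original, and the ±tolerance contract is
  asserted on every emitted result.
- **Controls**: per iteration, an individual-based control removes the same
  N_Rem stems uniformly from the whole pool, and a species-based control
  removes S_Loss species drawn uniformly from the species list (unweighted by
  abundance — abundance weighting would just re-create the individual-based
  control). Both recover basal area the same way. The controls target the
  original total basal area, which is numerically identical to recovering the
  post-removal deficit.

Reproducibility: one root seed spawns an independent `numpy` SeedSequence
child per (iteration, scenario) pair, so any single iteration can be replayed
in isolation and a fixed seed yields bit-identical results tables.

Percent changes with an undefined baseline (e.g. a community with no ≥ 70 cm
tree) are recorded as NaN and excluded from summaries with a count, rather
than raising mid-run.

## Synthetic communities

The generator emulates the statistical features the analysis depends on, not
any particular site:

- **Dispersal mix** — each species is animal-dispersed with probability
  `animal_fraction`; abundance ranks are assigned independently of traits, so
  the stem-level fraction tracks the species-level target in expectation.
- **Abundances** — geometric rank-abundance series (decay 0.03), the
  simplest one-parameter dominance model.
- **Seed lengths** — lognormal (median 1 cm, log-sd 0.8) for animal-dispersed
  species; abiotic seeds one log-unit smaller.
- **Size linkage** — species maximum DBH is a group multiplier
  (small-seeded animal 1.0, large-seeded animal 1.24, abiotic 1.44; the
  multipliers encode the observed ~+24% and ~−14% adult-diameter contrasts)
  times a base of 60 cm with 0.08 lognormal noise. Maximum height is a
  power-law function of maximum DBH and is reported as an adult-stature
  index only.
- **Stem diameters** — per-species truncated exponential on
  [10 cm, max DBH] with scale 0.30 × max DBH, giving right-skewed
  distributions with far more small than large trees; sampled area is set so
  stem density is 500 ha⁻¹.
- **Wood density** — normal within dispersal class (animal 0.60, abiotic
  0.55, sd 0.08) truncated to (0.1, 1.2), making abiotic dispersers the
  least dense on average.
- **Missingness** — configurable fractions of species have seed length
  blanked with fruit length retained (10%), both blanked (5%), wood density
  blanked (10%) or whole genera blanked (≈5% of genera), so every branch of
  the imputation chain is exercised downstream.

The free parameters above (base max DBH, DBH-scale fraction, max-DBH noise,
pool richness, abundance decay) were fixed once by checking that the two
preset regimes show their qualitative signatures robustly across replicate
community draws, and are not tuned per analysis. Within-group variances have
no empirical anchor and are documented as free parameters.

Presets: `animal_dominated` (animal fraction 0.90; abiotic species rare but
individually large) and `abiotic_rich` (animal fraction 0.60 with an abiotic
size multiplier of 1.60 — abundant, Dipterocarp-like emergents). At full
extirpation the first loses carbon consistently (median < 0, inter-quantile
box excluding zero) while the second stays within about ±1%. Because the
community-to-community spread of the abiotic-rich median is of the same order
as that ±1% band (sd ≈ 0.75 percentage points across pool draws), the ±1%
check is evaluated on the mean of per-community medians over three replicate
communities rather than on a single draw.

The cross-site mechanism analysis uses a 12-site gradient in animal-dispersal
prevalence (stem fractions 0.50–0.95) with richer sites (300 species, 3,000
stems each): at the preset scale, species-pool sampling noise in per-site
medians is comparable to the gradient signal and obscures the correlation
structure; at the gradient scale the site-median carbon change correlates
strongly with the volume-index change (r ≈ 0.85–0.93) and much more weakly
with the wood-density change, reproducing the volume-driven mechanism.

What passing these synthetic tests does *not* show: agreement with any real
site's absolute carbon stocks, seed-size reductions, or regional percentages;
real inventories have spatial structure, measurement error, taxonomic
uncertainty and trait covariances the generator does not emulate.

## Numerical and design choices

- Quantiles everywhere are numpy's linear-interpolation ("type 7") method;
  the summary box is the 25th–75th percentile range, flagged "consistent"
  when it excludes zero.
- Effect sizes are differences in median percent change (defaunation minus
  matched control); no p-values are produced for simulation contrasts, since
  significance is an artefact of the chosen iteration count.
- Cross-site correlations are Pearson coefficients over per-site medians at
  the 100% removal level by default (other levels are an option).
- Group contrasts report normal-approximation 95% CIs (mean ± 1.96 SE);
  singleton groups report a mean with the CI flagged unavailable.
- DBH ≥ 10 cm is enforced at ingest (configurable); conifers, lianas and
  stems unidentified to genus are always excluded, palms excluded by default
  with an opt-in flag that applies the same allometry to palm stems.
  Genus-level stems are retained and matched to an explicit genus-proxy trait
  record rather than to a guessed congener.
- Analysis-scale choices: the shipped drivers and end-to-end tests use 100–500
  iterations per scenario level and 2,000–3,000-stem communities, sizes at
  which the summary statistics of interest are stable to well within their
  assertion margins.

## Known limitations

- Single-census snapshots only; no multi-census or temporal dynamics.
- No taxonomy resolution against external name resolvers; trait tables must
  already be keyed consistently with the stem table.
- The allometric coefficients are global constants per run (moist-forest
  default; dry/wet variants can be swapped via configuration but are not
  mixed within a community).
- The recovery rule never stops short of the target from below; in degenerate
  pools where every surviving stem overshoots the band, the iteration fails
  explicitly rather than accepting a shortfall.
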