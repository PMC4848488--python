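"""Percent-change summaries, effect sizes versus matched controls, and contrasts.

Every response is analysed as the percent change from the original community's
value.  Per scenario we report the median, the 25th–75th percentile box, and
the share of runs that declined; an effect is "consistent" when that
inter-quantile box excludes zero.  Defaunation effect sizes are differences in
median percent change between the defaunation scenario and its matched
control — no p-values are attached, since the number of iterations is an
arbitrary choice that would make any effect "significant".

Cross-site mechanism checks correlate per-site median changes in carbon with
median changes in stand volume and stand wood density (Pearson).  Trait-group
contrasts compare adult stature and wood density across large-seeded animal,
small-seeded animal and abiotically dispersed species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulation import IterationResult, RESPONSES
from .traits import DispersalClass, SpeciesTraits

__all__ = [
    "SummaryError",
    "ScenarioSummary",
    "EffectSize",
    "TraitGroupContrasts",
    "percent_change",
    "summarize_scenario",
    "summaries_frame",
    "effect_vs_control",
    "cross_site_correlation",
    "trait_group_contrasts",
    "biome_release_estimate",
]

TRAIT_GROUPS = ("large_animal", "small_animal", "abiotic")
CONTRAST_PAIRS = (("large_animal", "small_animal"), ("large_animal", "abiotic"))
CONTRAST_TRAITS = ("max_dbh_cm", "max_height_m", "wood_density")


class SummaryError(ValueError):
    """A summary precondition is violated (zero baseline, empty input, ...)."""


def percent_change(original: float, new: float) -> float:
    """100 * (new - original) / original; undefined for a zero baseline."""
    if original == 0:
        raise SummaryError("percent change undefined for a zero baseline")
    return 100.0 * (new - original) / original


@dataclass(frozen=True)
class ScenarioSummary:
    """Distribution summary of percent changes for one scenario and response."""

    scenario: str
    response: str
    median_pct: float
    q25_pct: float
    q75_pct: float
    pct_runs_declining: float
    n_iterations: int
    n_failed: int
    consistent: bool


def summarize_scenario(
    results: Iterable[IterationResult],
    response: str,
    scenario: str | None = None,
    n_failed: int = 0,
    quantile_box: tuple[float, float] = (25.0, 75.0),
) -> ScenarioSummary:
    """Summarize percent changes of ``response`` across iterations.

    ``scenario`` filters the (possibly mixed) result collection; iterations
    where the response is undefined (NaN) are excluded and counted into
    ``n_failed``.  The "consistent" flag marks an inter-quantile box that
    excludes zero.
    """
    results = list(results)
    if scenario is not None:
        results = [r for r in results if r.scenario == scenario]
    changes = np.array([r.pct_change[response] for r in results], dtype=float)
    finite = changes[np.isfinite(changes)]
    n_failed = n_failed + int(changes.size - finite.size)
    if finite.size == 0:
        raise SummaryError(f"no successful iterations for response {response!r}")
    q25, med, q75 = np.percentile(finite, [quantile_box[0], 50.0, quantile_box[1]])
    return ScenarioSummary(
        scenario=scenario if scenario is not None else (results[0].scenario if results else ""),
        response=response,
        median_pct=float(med),
        q25_pct=float(q25),
        q75_pct=float(q75),
        pct_runs_declining=float(100.0 * np.mean(finite < 0)),
        n_iterations=int(finite.size),
        n_failed=n_failed,
        consistent=bool(q25 > 0 or q75 < 0),
    )


def summaries_frame(
    results: Iterable[IterationResult],
    scenarios: Sequence[str] | None = None,
    responses: Sequence[str] = RESPONSES,
) -> pd.DataFrame:
    """Tidy table of :func:`summarize_scenario` over scenarios x responses."""
    results = list(results)
    if scenarios is None:
        scenarios = sorted({r.scenario for r in results})
    rows = []
    for scenario in scenarios:
        for response in responses:
            try:
                s = summarize_scenario(results, response, scenario=scenario)
            except SummaryError:
                continue
            rows.append(s.__dict__)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectSize:
    """Median-difference effect of defaunation relative to a matched control."""

    response: str
    defaunation_median_pct: float
    control_median_pct: float

    @property
    def effect_pct(self) -> float:
        return self.defaunation_median_pct - self.control_median_pct


def effect_vs_control(defaun: ScenarioSummary, control: ScenarioSummary) -> EffectSize:
    """Difference in median percent change, defaunation minus control."""
    if defaun.response != control.response:
        raise SummaryError(
            f"response mismatch: {defaun.response!r} vs {control.response!r}"
        )
    return EffectSize(
        response=defaun.response,
        defaunation_median_pct=defaun.median_pct,
        control_median_pct=control.median_pct,
    )


def cross_site_correlation(site_medians: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation across sites of two per-site median changes."""
    if len(site_medians) < 3:
        raise SummaryError("need at least 3 sites for a cross-site correlation")
    x = np.array([p[0] for p in site_medians], dtype=float)
    y = np.array([p[1] for p in site_medians], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise SummaryError("non-finite site medians")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SummaryError("zero variance in one margin; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class TraitGroupContrasts:
    """Group means with 95% CIs and the pairwise percent differences."""

    group_stats: pd.DataFrame  # columns: trait, group, n, mean, ci_low, ci_high
    contrasts: pd.DataFrame  # columns: trait, group_a, group_b, pct_difference


def _group_of(sp: SpeciesTraits, large_seeded: set[str]) -> str:
    if sp.dispersal_class is DispersalClass.ABIOTIC:
        return "abiotic"
    return "large_animal" if sp.species_id in large_seeded else "small_animal"


def trait_group_contrasts(
    traits: Iterable[SpeciesTraits],
    large_seeded: set[str],
    trait_names: Sequence[str] = CONTRAST_TRAITS,
) -> TraitGroupContrasts:
    """Compare adult stature and wood density across dispersal/seed-size groups.

    For each trait and group: mean and normal-approximation 95% CI
    (mean ± 1.96·SE; CI unavailable for singleton groups).  Contrasts report
    100·(mean_A − mean_B)/mean_B for large- vs small-seeded animal-dispersed
    species and large-seeded animal vs abiotically dispersed species.
    """
    traits = list(traits)
    stat_rows = []
    means: dict[tuple[str, str], float] = {}
    for trait in trait_names:
        for group in TRAIT_GROUPS:
            values = np.array(
                [
                    getattr(sp, trait)
                    for sp in traits
                    if _group_of(sp, large_seeded) == group and getattr(sp, trait) is not None
                ],
                dtype=float,
            )
            n = values.size
            mean = float(values.mean()) if n else float("nan")
            if n >= 2:
                se = float(values.std(ddof=1) / np.sqrt(n))
                ci = (mean - 1.96 * se, mean + 1.96 * se)
            else:
                ci = (float("nan"), float("nan"))
            means[(trait, group)] = mean
            stat_rows.append(
                {
                    "trait": trait,
                    "group": group,
                    "n": n,
                    "mean": mean,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                }
            )
    contrast_rows = []
    for trait in trait_names:
        for group_a, group_b in CONTRAST_PAIRS:
            mean_a, mean_b = means[(trait, group_a)], means[(trait, group_b)]
            pct = (
                100.0 * (mean_a - mean_b) / mean_b
                if np.isfinite(mean_a) and np.isfinite(mean_b) and mean_b != 0
                else float("nan")
            )
            contrast_rows.append(
                {"trait": trait, "group_a": group_a, "group_b": group_b, "pct_difference": pct}
            )
    return TraitGroupContrasts(
        group_stats=pd.DataFrame(stat_rows), contrasts=pd.DataFrame(contrast_rows)
    )


def biome_release_estimate(stock_pg: float, loss_fraction: float) -> float:
    """Back-of-envelope carbon release (Pg C): biome stock times fractional loss."""
    if not (stock_pg > 0):
        raise SummaryError("stock_pg must be positive")
    if not (0 <= loss_fraction <= 1):
        raise SummaryError("loss_fraction must lie in [0, 1]")
    return stock_pg * loss_fraction
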