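"""Dispersal classification, trait imputation and large-seeded species identification.

Tree species are classified by seed dispersal mode into four raw categories
(animal, wind, unassisted, multiple), aggregated into two classes: animal-dispersed
(animal, multiple) versus abiotically dispersed (wind, unassisted).  Missing seed
lengths and wood densities are filled by a taxonomic-fallback chain:

* seed length — measured value, else a genus-wise linear model of seed length on
  fruit length (fitted only in genera with at least three species carrying both
  measurements), else the genus mean of measured seed lengths;
* wood density — species value, else genus mean, else family mean.

Genus and family means are computed from species-level measurements only, never
from previously imputed values, so no imputation chains occur.

"Large-seeded" animal-dispersed species are those whose seed length strictly
exceeds a cutoff: by default the 75th percentile of seed lengths across the
animal-dispersed species of the community (one value per species, unweighted,
linear-interpolation quantile), or alternatively a fixed regional cutoff in cm.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, TYPE_CHECKING

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, type hints only
    from .data_io import Community

log = logging.getLogger(__name__)

__all__ = [
    "DispersalMode",
    "DispersalClass",
    "SeedLengthSource",
    "WoodDensitySource",
    "SpeciesTraits",
    "FruitSeedModel",
    "LargeSeededRule",
    "ClassificationError",
    "TraitError",
    "classify_dispersal",
    "fit_fruit_seed_models",
    "genus_seed_means",
    "genus_wood_density_means",
    "family_wood_density_means",
    "impute_seed_length",
    "impute_wood_density",
    "impute_all",
    "impute_community",
    "classify_large_seeded",
    "community_weighted_seed_size",
]


class ClassificationError(ValueError):
    """An unmapped raw dispersal-mode label was encountered."""


class TraitError(ValueError):
    """A trait-level precondition was violated (e.g. no classifiable species)."""


class DispersalMode(str, Enum):
    ANIMAL = "animal"
    WIND = "wind"
    UNASSISTED = "unassisted"
    MULTIPLE = "multiple"


class DispersalClass(str, Enum):
    ANIMAL = "animal"
    ABIOTIC = "abiotic"


class SeedLengthSource(str, Enum):
    MEASURED = "measured"
    FRUIT_MODEL = "fruit_model"
    GENUS_MEAN = "genus_mean"
    MISSING = "missing"


class WoodDensitySource(str, Enum):
    SPECIES = "species"
    GENUS = "genus"
    FAMILY = "family"
    MISSING = "missing"


def classify_dispersal(mode: DispersalMode | str) -> DispersalClass:
    """Aggregate the four raw dispersal modes into animal vs abiotic.

    ``animal`` and ``multiple`` (animal combined with an abiotic vector) count
    as animal-dispersed; ``wind`` and ``unassisted`` as abiotically dispersed.
    Unmapped labels raise :class:`ClassificationError` rather than silently
    defaulting.
    """
    try:
        mode = DispersalMode(mode)
    except ValueError:
        raise ClassificationError(f"unknown dispersal mode: {mode!r}") from None
    if mode in (DispersalMode.ANIMAL, DispersalMode.MULTIPLE):
        return DispersalClass.ANIMAL
    return DispersalClass.ABIOTIC


@dataclass
class SpeciesTraits:
    """Per-species functional traits used by the simulation.

    Lengths are in cm, wood density in g cm^-3, maximum height in m.  Optional
    fields are ``None`` when unknown; ``*_source`` fields record where the
    working value came from.
    """

    species_id: str
    genus: str
    family: str
    dispersal_mode: DispersalMode
    seed_length_cm: float | None = None
    seed_length_source: SeedLengthSource = SeedLengthSource.MISSING
    fruit_length_cm: float | None = None
    wood_density: float | None = None
    wood_density_source: WoodDensitySource = WoodDensitySource.MISSING
    max_height_m: float | None = None
    max_dbh_cm: float | None = None

    def __post_init__(self) -> None:
        self.dispersal_mode = DispersalMode(self.dispersal_mode)
        if self.seed_length_cm is not None:
            if not (self.seed_length_cm > 0):
                raise TraitError(
                    f"{self.species_id}: seed_length_cm must be positive, "
                    f"got {self.seed_length_cm}"
                )
            if self.seed_length_source == SeedLengthSource.MISSING:
                self.seed_length_source = SeedLengthSource.MEASURED
        if self.wood_density is not None:
            if not (0 < self.wood_density <= 1.5):
                raise TraitError(
                    f"{self.species_id}: wood_density must lie in (0, 1.5], "
                    f"got {self.wood_density}"
                )
            if self.wood_density_source == WoodDensitySource.MISSING:
                self.wood_density_source = WoodDensitySource.SPECIES

    @property
    def dispersal_class(self) -> DispersalClass:
        return classify_dispersal(self.dispersal_mode)


@dataclass(frozen=True)
class FruitSeedModel:
    """Genus-level OLS model predicting seed length (cm) from fruit length (cm)."""

    genus: str
    slope: float
    intercept: float
    n_species: int
    r_squared: float

    def predict(self, fruit_length_cm: float) -> float:
        return self.slope * fruit_length_cm + self.intercept


def fit_fruit_seed_models(
    traits: Iterable[SpeciesTraits], min_species: int = 3
) -> dict[str, FruitSeedModel]:
    """Fit per-genus OLS models of seed length on fruit length.

    Only species carrying both measurements contribute; genera with fewer than
    ``min_species`` complete species, or with zero variance in fruit length,
    are omitted (the latter with a warning).
    """
    by_genus: dict[str, list[tuple[float, float]]] = defaultdict(list)
    for sp in traits:
        if (
            sp.seed_length_cm is not None
            and sp.seed_length_source == SeedLengthSource.MEASURED
            and sp.fruit_length_cm is not None
        ):
            by_genus[sp.genus].append((sp.fruit_length_cm, sp.seed_length_cm))

    models: dict[str, FruitSeedModel] = {}
    for genus, pairs in by_genus.items():
        if len(pairs) < min_species:
            continue
        fruit = np.array([p[0] for p in pairs])
        seed = np.array([p[1] for p in pairs])
        if np.ptp(fruit) == 0:
            log.warning("genus %s: zero variance in fruit length; model omitted", genus)
            continue
        fit = stats.linregress(fruit, seed)
        models[genus] = FruitSeedModel(
            genus=genus,
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            n_species=len(pairs),
            r_squared=float(fit.rvalue**2),
        )
    return models


def genus_seed_means(traits: Iterable[SpeciesTraits]) -> dict[str, float]:
    """Genus means of *measured* seed lengths (imputed values never contribute)."""
    acc: dict[str, list[float]] = defaultdict(list)
    for sp in traits:
        if sp.seed_length_cm is not None and sp.seed_length_source == SeedLengthSource.MEASURED:
            acc[sp.genus].append(sp.seed_length_cm)
    return {g: float(np.mean(v)) for g, v in acc.items()}


def genus_wood_density_means(traits: Iterable[SpeciesTraits]) -> dict[str, float]:
    """Genus means of species-level wood densities."""
    acc: dict[str, list[float]] = defaultdict(list)
    for sp in traits:
        if sp.wood_density is not None and sp.wood_density_source == WoodDensitySource.SPECIES:
            acc[sp.genus].append(sp.wood_density)
    return {g: float(np.mean(v)) for g, v in acc.items()}


def family_wood_density_means(traits: Iterable[SpeciesTraits]) -> dict[str, float]:
    """Family means of species-level wood densities."""
    acc: dict[str, list[float]] = defaultdict(list)
    for sp in traits:
        if sp.wood_density is not None and sp.wood_density_source == WoodDensitySource.SPECIES:
            acc[sp.family].append(sp.wood_density)
    return {f: float(np.mean(v)) for f, v in acc.items()}


def impute_seed_length(
    sp: SpeciesTraits,
    models: Mapping[str, FruitSeedModel],
    genus_means: Mapping[str, float],
) -> tuple[float | None, SeedLengthSource]:
    """Resolve a working seed length, in decreasing order of preference.

    Measured value, else genus fruit-length model applied to the species'
    fruit length, else genus mean of measured seed lengths, else missing.
    A non-positive model prediction falls through to the next source.
    """
    if sp.seed_length_cm is not None and sp.seed_length_source == SeedLengthSource.MEASURED:
        return sp.seed_length_cm, SeedLengthSource.MEASURED
    model = models.get(sp.genus)
    if model is not None and sp.fruit_length_cm is not None:
        pred = model.predict(sp.fruit_length_cm)
        if pred > 0:
            return float(pred), SeedLengthSource.FRUIT_MODEL
        log.warning(
            "%s: fruit-length model for genus %s predicted %.3g cm; falling back",
            sp.species_id,
            sp.genus,
            pred,
        )
    if sp.genus in genus_means:
        return genus_means[sp.genus], SeedLengthSource.GENUS_MEAN
    return None, SeedLengthSource.MISSING


def impute_wood_density(
    sp: SpeciesTraits,
    genus_means: Mapping[str, float],
    family_means: Mapping[str, float],
) -> tuple[float | None, WoodDensitySource]:
    """Species value, else genus mean, else family mean, else missing."""
    if sp.wood_density is not None and sp.wood_density_source == WoodDensitySource.SPECIES:
        return sp.wood_density, WoodDensitySource.SPECIES
    if sp.genus in genus_means:
        return genus_means[sp.genus], WoodDensitySource.GENUS
    if sp.family in family_means:
        return family_means[sp.family], WoodDensitySource.FAMILY
    return None, WoodDensitySource.MISSING


def impute_all(traits: Iterable[SpeciesTraits]) -> list[SpeciesTraits]:
    """Apply the full imputation chain to a trait table.

    Returns new records; measured values are never overwritten (imputation is
    source-monotone).
    """
    traits = list(traits)
    models = fit_fruit_seed_models(traits)
    seed_means = genus_seed_means(traits)
    wd_genus = genus_wood_density_means(traits)
    wd_family = family_wood_density_means(traits)
    out = []
    for sp in traits:
        seed, seed_src = impute_seed_length(sp, models, seed_means)
        wd, wd_src = impute_wood_density(sp, wd_genus, wd_family)
        out.append(
            replace(
                sp,
                seed_length_cm=seed,
                seed_length_source=seed_src,
                wood_density=wd,
                wood_density_source=wd_src,
            )
        )
    return out


def impute_community(community: "Community") -> "Community":
    """Return a copy of ``community`` with its trait table fully imputed."""
    from .data_io import Community  # local import to avoid cycle

    imputed = {sp.species_id: sp for sp in impute_all(community.traits.values())}
    return Community(
        site_id=community.site_id,
        stems=community.stems,
        traits=imputed,
        area_ha=community.area_ha,
    )


@dataclass(frozen=True)
class LargeSeededRule:
    """How to place the large-seeded cutoff among animal-dispersed species.

    Exactly one of ``percentile`` (default 75, linear-interpolation quantile)
    or ``fixed_cutoff_cm`` applies; ``fixed_cutoff_cm`` wins when set.  With
    ``basis='species'`` the percentile is taken over one value per species;
    ``basis='stems'`` weights species by stem abundance (sensitivity option).
    Species exactly at the cutoff fall to small-seeded (strict inequality).
    """

    percentile: float = 75.0
    fixed_cutoff_cm: float | None = None
    basis: str = "species"

    def __post_init__(self) -> None:
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must lie in (0, 100)")
        if self.basis not in ("species", "stems"):
            raise ValueError("basis must be 'species' or 'stems'")
        if self.fixed_cutoff_cm is not None and not (self.fixed_cutoff_cm > 0):
            raise ValueError("fixed_cutoff_cm must be positive")


def classify_large_seeded(
    community: "Community", rule: LargeSeededRule = LargeSeededRule()
) -> set[str]:
    """Identify the large-seeded animal-dispersed species of a community.

    Considers only species actually present in the stem table.  Animal-dispersed
    species lacking a seed length after imputation are excluded with a warning.
    Abiotic species are never returned.  Raises :class:`TraitError` when no
    animal-dispersed species with seed lengths exist.
    """
    counts: dict[str, int] = defaultdict(int)
    for stem in community.stems:
        counts[stem.species_id] += 1

    lengths: dict[str, float] = {}
    missing: list[str] = []
    for sid in counts:
        sp = community.traits[sid]
        if sp.dispersal_class is not DispersalClass.ANIMAL:
            continue
        if sp.seed_length_cm is None:
            missing.append(sid)
        else:
            lengths[sid] = sp.seed_length_cm
    if missing:
        log.warning(
            "%d animal-dispersed species lack seed lengths and are excluded "
            "from large-seeded classification: %s",
            len(missing),
            ", ".join(sorted(missing)[:10]),
        )
    if not lengths:
        raise TraitError(
            f"community {community.site_id}: no animal-dispersed species with seed lengths"
        )

    if rule.fixed_cutoff_cm is not None:
        cutoff = rule.fixed_cutoff_cm
    else:
        if rule.basis == "species":
            values = np.array(list(lengths.values()))
        else:
            values = np.array([lengths[sid] for sid in lengths for _ in range(counts[sid])])
        cutoff = float(np.percentile(values, rule.percentile))
    return {sid for sid, length in lengths.items() if length > cutoff}


def community_weighted_seed_size(community: "Community", weighting: str = "stems") -> float:
    """Abundance-weighted mean seed length (cm) over animal-dispersed individuals.

    ``weighting='stems'`` weights each stem equally (the default, declared in
    output metadata); ``'basal_area'`` weights stems by basal area.  Raises
    :class:`TraitError` when the community holds no animal-dispersed stems with
    seed lengths.
    """
    from .carbon import basal_area_cm2

    if weighting not in ("stems", "basal_area"):
        raise ValueError("weighting must be 'stems' or 'basal_area'")
    total_w = 0.0
    total = 0.0
    for stem in community.stems:
        sp = community.traits[stem.species_id]
        if sp.dispersal_class is not DispersalClass.ANIMAL or sp.seed_length_cm is None:
            continue
        w = 1.0 if weighting == "stems" else basal_area_cm2(stem.dbh_cm)
        total_w += w
        total += w * sp.seed_length_cm
    if total_w == 0:
        raise TraitError(
            f"community {community.site_id}: no animal-dispersed stems with seed lengths"
        )
    return total / total_w
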