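"""Shared fixtures: hand-built toy communities and preset synthetic sites."""

from __future__ import annotations

import numpy as np
import pytest

from defaunation_carbon import (
    Community,
    DispersalMode,
    SpeciesTraits,
    StemRecord,
)
from defaunation_carbon.synthetic_data import generate_site
from defaunation_carbon.traits import impute_community


def make_species(
    species_id: str,
    mode: str = "animal",
    seed: float | None = 1.0,
    wd: float | None = 0.6,
    genus: str | None = None,
    family: str = "Fam01",
    **kwargs,
) -> SpeciesTraits:
    return SpeciesTraits(
        species_id=species_id,
        genus=genus or f"G_{species_id}",
        family=family,
        dispersal_mode=DispersalMode(mode),
        seed_length_cm=seed,
        wood_density=wd,
        **kwargs,
    )


def make_stem(species_id: str, dbh: float, k: int = 0, site: str = "toy") -> StemRecord:
    return StemRecord(
        stem_id=f"{site}-{species_id}-{k}",
        species_id=species_id,
        dbh_cm=dbh,
        plot_id=f"{site}-p0",
        site_id=site,
    )


def make_community(stems, traits, area_ha: float = 1.0) -> Community:
    return Community(
        site_id=stems[0].site_id,
        stems=list(stems),
        traits={sp.species_id: sp for sp in traits},
        area_ha=area_ha,
    )


@pytest.fixture
def toy_community() -> Community:
    """Three species (two animal-dispersed, one wind), six stems, 1 ha."""
    traits = [
        make_species("A", "animal", seed=3.0, wd=0.6),
        make_species("B", "animal", seed=1.0, wd=0.5),
        make_species("C", "wind", seed=0.4, wd=0.55),
    ]
    stems = [
        make_stem("A", 40.0, 0),
        make_stem("A", 25.0, 1),
        make_stem("B", 15.0, 0),
        make_stem("B", 12.0, 1),
        make_stem("B", 18.0, 2),
        make_stem("C", 30.0, 0),
    ]
    return make_community(stems, traits)


@pytest.fixture(scope="session")
def animal_dominated_community() -> Community:
    """An imputed 2000-stem animal-dominated preset community (fixed seed)."""
    _, community = generate_site("animal_dominated", seed=0)
    return impute_community(community)


@pytest.fixture(scope="session")
def abiotic_rich_community() -> Community:
    _, community = generate_site("abiotic_rich", seed=0)
    return impute_community(community)
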