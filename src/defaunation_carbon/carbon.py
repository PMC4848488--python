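"""Allometric aboveground biomass and the stand-level response variables.

Per-stem aboveground biomass (AGB, kg) follows the pan-tropical moist-forest
model of Chave et al. (2005), which needs only wood density W (g cm^-3) and
DBH D (cm):

    AGB = W * exp(a0 + a1*ln D + a2*(ln D)^2 + a3*(ln D)^3)

with default coefficients (-1.499, 2.148, 0.207, -0.0281).  The multiplicative
structure factors stand biomass into a wood-density term and a DBH-driven
volume term g(D) = exp(...), so stand-level shifts in carbon can be decomposed
into shifts in stand volume (sum of g(D) over stems, the "volume index") and
in basal-area-weighted stand wood density.

Stand-level responses:

* carbon (Mg C ha^-1) = carbon_fraction * sum_i W_i g(D_i) / area;
* volume index = sum_i g(D_i) (model units);
* basal-area-weighted wood density = sum_s WD_s BA_s / sum_s BA_s over species;
* large-tree fraction = share of stems with DBH >= 70 cm.

The model is known to overestimate absolute AGB; responses are analysed as
percent changes, which are unaffected by a common multiplicative bias and by
the carbon fraction.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import Community

__all__ = [
    "AllometricCoefficients",
    "CHAVE_2005_MOIST",
    "StandState",
    "agb_kg",
    "volume_term",
    "basal_area_cm2",
    "stand_state",
    "KG_PER_MG",
]

KG_PER_MG = 1000.0


@dataclass(frozen=True)
class AllometricCoefficients:
    """Coefficients of ln-AGB polynomial in ln DBH, plus the carbon fraction."""

    a0: float = -1.499
    a1: float = 2.148
    a2: float = 0.207
    a3: float = -0.0281
    carbon_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.carbon_fraction <= 1):
            raise ValueError("carbon_fraction must lie in (0, 1]")
        if not np.isfinite(self.volume_term(10.0)) or self.volume_term(10.0) <= 0:
            raise ValueError("volume term must be positive and finite at D = 10 cm")

    def volume_term(self, dbh_cm):
        """g(D) = exp(a0 + a1 lnD + a2 (lnD)^2 + a3 (lnD)^3); vectorized."""
        ln_d = np.log(dbh_cm)
        return np.exp(self.a0 + self.a1 * ln_d + self.a2 * ln_d**2 + self.a3 * ln_d**3)


#: Moist-forest DBH+wood-density model (Chave et al. 2005), the default.
CHAVE_2005_MOIST = AllometricCoefficients()


def volume_term(dbh_cm, coefficients: AllometricCoefficients = CHAVE_2005_MOIST):
    """The DBH-driven factor g(D) of the biomass model (vectorized)."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh_cm <= 0):
        raise ValueError("DBH must be positive")
    return coefficients.volume_term(dbh_cm)


def agb_kg(
    wood_density,
    dbh_cm,
    coefficients: AllometricCoefficients = CHAVE_2005_MOIST,
):
    """Aboveground biomass (kg) of a stem: W * g(D).  Vectorized.

    Strictly increasing in both W and D over the valid domain.  DBH below the
    10 cm sampling floor is permitted (the model extrapolates) but the inputs
    must be positive.
    """
    wood_density = np.asarray(wood_density, dtype=float)
    if np.any(wood_density <= 0):
        raise ValueError("wood density must be positive")
    return wood_density * volume_term(dbh_cm, coefficients)


def basal_area_cm2(dbh_cm):
    """Cross-sectional stem area at breast height, pi (D/2)^2, cm^2.  Vectorized."""
    dbh_cm = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh_cm <= 0):
        raise ValueError("DBH must be positive")
    return np.pi * (dbh_cm / 2.0) ** 2


@dataclass(frozen=True)
class StandState:
    """The stand-level response variables of one (possibly simulated) community."""

    carbon_mg_ha: float
    volume_index: float
    ba_weighted_wd: float
    large_tree_frac: float
    basal_area_cm2: float
    n_stems: int
    n_species: int


def stand_state(
    community: "Community",
    coefficients: AllometricCoefficients = CHAVE_2005_MOIST,
    large_tree_threshold_cm: float = 70.0,
) -> StandState:
    """Compute the stand-level responses of a community.

    Requires every stem's species to carry a (possibly imputed) wood density;
    offenders are listed in the raised ``ValueError``.  Stand wood density is
    the species-level average weighted by per-species basal area, which for
    species-constant wood densities equals the stem-BA-weighted mean.
    """
    missing = sorted(
        {s.species_id for s in community.stems if community.traits[s.species_id].wood_density is None}
    )
    if missing:
        raise ValueError(
            f"{community.site_id}: {len(missing)} species lack wood density "
            "(run imputation first): " + ", ".join(missing[:10])
        )

    dbh = np.array([s.dbh_cm for s in community.stems])
    wd = np.array([community.traits[s.species_id].wood_density for s in community.stems])
    g = volume_term(dbh, coefficients)
    ba = basal_area_cm2(dbh)

    ba_by_species: dict[str, float] = defaultdict(float)
    for stem, b in zip(community.stems, ba):
        ba_by_species[stem.species_id] += float(b)
    ba_total = sum(ba_by_species.values())
    wd_weighted = (
        sum(community.traits[sid].wood_density * b for sid, b in ba_by_species.items()) / ba_total
    )

    agb_total_kg = float(np.sum(wd * g))
    return StandState(
        carbon_mg_ha=coefficients.carbon_fraction * agb_total_kg / KG_PER_MG / community.area_ha,
        volume_index=float(np.sum(g)),
        ba_weighted_wd=float(wd_weighted),
        large_tree_frac=float(np.mean(dbh >= large_tree_threshold_cm)),
        basal_area_cm2=float(np.sum(ba)),
        n_stems=len(community.stems),
        n_species=len(ba_by_species),
    )
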