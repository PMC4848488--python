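"""Read, validate, filter and pool stem and trait tables into site communities.

Stem inventories arrive as delimited text with one row per measured tree
(>= 10 cm DBH).  Column names vary across source datasets and are remapped via a
small configuration mapping.  Ingest applies the DBH floor, exclusion filters
drop growth forms the allometry does not cover (conifers, lianas, and palms
unless explicitly included) plus stems not identified at least to genus, and
plots within a site are pooled into a single :class:`Community`.

Nothing is dropped silently: every rejected row is counted by reason and the
counts are logged and returned.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import (
    DispersalMode,
    SeedLengthSource,
    SpeciesTraits,
    WoodDensitySource,
)

log = logging.getLogger(__name__)

__all__ = [
    "GrowthForm",
    "IdLevel",
    "StemRecord",
    "Community",
    "IngestReport",
    "ConfigurationError",
    "InputError",
    "ValidationError",
    "DEFAULT_COLUMN_MAP",
    "read_stem_table",
    "write_stem_table",
    "apply_exclusion_filters",
    "pool_site",
    "read_trait_table",
    "write_trait_table",
]


class ConfigurationError(ValueError):
    """The column mapping does not cover a required field."""


class InputError(ValueError):
    """The input file is unusable (e.g. empty)."""


class ValidationError(ValueError):
    """A community invariant is violated."""


class GrowthForm(str, Enum):
    TREE = "tree"
    PALM = "palm"
    LIANA = "liana"
    CONIFER = "conifer"
    UNKNOWN = "unknown"


class IdLevel(str, Enum):
    SPECIES = "species"
    GENUS = "genus"
    NONE = "none"


@dataclass(frozen=True)
class StemRecord:
    """One measured tree: taxon link, DBH (cm) and plot/site membership."""

    stem_id: str
    species_id: str
    dbh_cm: float
    plot_id: str
    site_id: str
    growth_form: GrowthForm = GrowthForm.TREE
    id_level: IdLevel = IdLevel.SPECIES


#: Default logical-field -> column-name mapping for stem tables.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "site": "site_id",
    "plot": "plot_id",
    "stem": "stem_id",
    "taxon": "species_id",
    "dbh": "dbh_cm",
    "growth_form": "growth_form",
    "id_level": "id_level",
}

_REQUIRED_FIELDS = ("site", "plot", "taxon", "dbh")


@dataclass
class IngestReport:
    """Row bookkeeping for one stem-table read: counts sum to rows parsed."""

    n_rows: int = 0
    n_kept: int = 0
    n_below_dbh_min: int = 0
    n_unparseable_dbh: int = 0

    @property
    def n_excluded(self) -> int:
        return self.n_below_dbh_min + self.n_unparseable_dbh


def _parse_growth_form(value: object) -> GrowthForm:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return GrowthForm.TREE
    try:
        return GrowthForm(str(value).strip().lower())
    except ValueError:
        log.warning("unrecognized growth form %r; treating as unknown", value)
        return GrowthForm.UNKNOWN


def _parse_id_level(value: object) -> IdLevel:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return IdLevel.SPECIES
    try:
        return IdLevel(str(value).strip().lower())
    except ValueError:
        log.warning("unrecognized id level %r; treating as species", value)
        return IdLevel.SPECIES


def read_stem_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    dbh_min_cm: float = 10.0,
    sep: str | None = None,
) -> tuple[list[StemRecord], IngestReport]:
    """Read a delimited stem table into :class:`StemRecord` objects.

    ``column_map`` maps the logical fields (site, plot, taxon, dbh, and
    optionally stem, growth_form, id_level) to the file's column names;
    unmapped optional fields fall back to defaults (row-index stem ids,
    growth form ``tree``, id level ``species``).  Rows whose DBH does not
    parse or falls below ``dbh_min_cm`` are rejected and counted, never
    silently dropped.  ``sep`` is inferred from the extension when omitted
    (``.tsv`` -> tab, else comma).
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","

    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.empty:
        raise InputError(f"{path}: no data rows")
    for field_name in _REQUIRED_FIELDS:
        if cmap[field_name] not in frame.columns:
            raise ConfigurationError(
                f"{path}: required column {cmap[field_name]!r} (field {field_name!r}) missing; "
                f"available: {list(frame.columns)}"
            )

    dbh = pd.to_numeric(frame[cmap["dbh"]], errors="coerce")
    report = IngestReport(n_rows=len(frame))
    stems: list[StemRecord] = []
    has_stem = cmap["stem"] in frame.columns
    has_gf = cmap["growth_form"] in frame.columns
    has_il = cmap["id_level"] in frame.columns
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        d = dbh.iloc[i]
        if pd.isna(d):
            report.n_unparseable_dbh += 1
            continue
        if d < dbh_min_cm:
            report.n_below_dbh_min += 1
            continue
        stems.append(
            StemRecord(
                stem_id=str(row[cmap["stem"]]) if has_stem else f"row{i}",
                species_id=str(row[cmap["taxon"]]).strip(),
                dbh_cm=float(d),
                plot_id=str(row[cmap["plot"]]).strip(),
                site_id=str(row[cmap["site"]]).strip(),
                growth_form=_parse_growth_form(row[cmap["growth_form"]]) if has_gf else GrowthForm.TREE,
                id_level=_parse_id_level(row[cmap["id_level"]]) if has_il else IdLevel.SPECIES,
            )
        )
    report.n_kept = len(stems)
    if report.n_excluded:
        log.info(
            "%s: kept %d of %d rows (%d below %.4g cm DBH, %d unparseable DBH)",
            path,
            report.n_kept,
            report.n_rows,
            report.n_below_dbh_min,
            report.n_unparseable_dbh,
            )
    return stems, report


def write_stem_table(stems: Iterable[StemRecord], path: str | Path) -> None:
    """Write stems as a CSV using the default column names."""
    frame = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "plot_id": s.plot_id,
                "stem_id": s.stem_id,
                "species_id": s.species_id,
                "dbh_cm": s.dbh_cm,
                "growth_form": s.growth_form.value,
                "id_level": s.id_level.value,
            }
            for s in stems
        ]
    )
    frame.to_csv(path, index=False)


def apply_exclusion_filters(
    stems: Sequence[StemRecord], include_palms: bool = False
) -> tuple[list[StemRecord], dict[str, int]]:
    """Drop growth forms outside the allometry's domain and unidentified stems.

    Conifers, lianas and stems not identified to at least genus level are
    always removed; palms are removed unless ``include_palms`` is set (the
    inclusion variant applies the same biomass equation to palm stems).  The
    returned report counts removals by reason and sums to input minus output.
    The operation is idempotent.
    """
    kept: list[StemRecord] = []
    report = {"conifer": 0, "liana": 0, "palm": 0, "unidentified": 0}
    for stem in stems:
        if stem.id_level is IdLevel.NONE:
            report["unidentified"] += 1
        elif stem.growth_form is GrowthForm.CONIFER:
            report["conifer"] += 1
        elif stem.growth_form is GrowthForm.LIANA:
            report["liana"] += 1
        elif stem.growth_form is GrowthForm.PALM and not include_palms:
            report["palm"] += 1
        else:
            kept.append(stem)
    dropped = sum(report.values())
    if dropped:
        log.info("exclusion filters removed %d stems: %s", dropped, report)
    return kept, report


@dataclass
class Community:
    """A pooled site-level stem set with its trait table and sampled area.

    The unit the simulator mutates.  Validation enforces a positive sampled
    area and total basal area, trait coverage for every stem's species, and
    stem-id uniqueness within the site.
    """

    site_id: str
    stems: list[StemRecord]
    traits: dict[str, SpeciesTraits]
    area_ha: float

    def __post_init__(self) -> None:
        if not (self.area_ha > 0):
            raise ValidationError(f"{self.site_id}: area_ha must be positive, got {self.area_ha}")
        if not self.stems:
            raise ValidationError(f"{self.site_id}: community has no stems")
        missing = sorted({s.species_id for s in self.stems} - set(self.traits))
        if missing:
            raise ValidationError(
                f"{self.site_id}: {len(missing)} species without trait records: "
                + ", ".join(missing[:10])
            )
        ids = Counter(s.stem_id for s in self.stems)
        dupes = [i for i, n in ids.items() if n > 1]
        if dupes:
            raise ValidationError(
                f"{self.site_id}: duplicate stem ids within site: {dupes[:5]}"
            )
        if not (self.total_basal_area_cm2 > 0):
            raise ValidationError(f"{self.site_id}: total basal area must be positive")

    @property
    def total_basal_area_cm2(self) -> float:
        from .carbon import basal_area_cm2

        return float(sum(basal_area_cm2(s.dbh_cm) for s in self.stems))

    @property
    def n_stems(self) -> int:
        return len(self.stems)

    @property
    def species_present(self) -> set[str]:
        return {s.species_id for s in self.stems}


def pool_site(
    stems: Sequence[StemRecord],
    traits: Mapping[str, SpeciesTraits],
    area_ha: float,
) -> Community:
    """Pool plot-level stems into a single validated site community."""
    if not stems:
        raise ValidationError("cannot pool an empty stem collection")
    sites = {s.site_id for s in stems}
    if len(sites) != 1:
        raise ValidationError(f"stems span multiple sites: {sorted(sites)}")
    return Community(
        site_id=next(iter(sites)),
        stems=list(stems),
        traits=dict(traits),
        area_ha=float(area_ha),
    )


_TRAIT_COLUMNS = [
    "species_id",
    "genus",
    "family",
    "dispersal_mode",
    "seed_length_cm",
    "seed_length_source",
    "fruit_length_cm",
    "wood_density",
    "wood_density_source",
    "max_height_m",
    "max_dbh_cm",
]


def _opt_float(value: object) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_trait_table(path: str | Path, sep: str | None = None) -> dict[str, SpeciesTraits]:
    """Read a species trait table keyed by species_id.

    Expected columns: species_id, genus, family, dispersal_mode, and optionally
    seed_length_cm, fruit_length_cm, wood_density, max_height_m, max_dbh_cm and
    the ``*_source`` columns; missing values as empty cells.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    if frame.empty:
        raise InputError(f"{path}: no data rows")
    for col in ("species_id", "genus", "family", "dispersal_mode"):
        if col not in frame.columns:
            raise ConfigurationError(f"{path}: required trait column {col!r} missing")
    traits: dict[str, SpeciesTraits] = {}
    for row in frame.to_dict("records"):
        sp = SpeciesTraits(
            species_id=str(row["species_id"]),
            genus=str(row["genus"]),
            family=str(row["family"]),
            dispersal_mode=DispersalMode(str(row["dispersal_mode"]).strip().lower()),
            seed_length_cm=_opt_float(row.get("seed_length_cm")),
            fruit_length_cm=_opt_float(row.get("fruit_length_cm")),
            wood_density=_opt_float(row.get("wood_density")),
            max_height_m=_opt_float(row.get("max_height_m")),
            max_dbh_cm=_opt_float(row.get("max_dbh_cm")),
        )
        src = row.get("seed_length_source")
        if isinstance(src, str) and src:
            sp.seed_length_source = SeedLengthSource(src)
        src = row.get("wood_density_source")
        if isinstance(src, str) and src:
            sp.wood_density_source = WoodDensitySource(src)
        traits[sp.species_id] = sp
    return traits


def write_trait_table(
    traits: Mapping[str, SpeciesTraits],
    path: str | Path,
    large_seeded: set[str] | None = None,
) -> None:
    """Write an augmented trait table with source columns and optional flag."""
    rows = []
    for sp in traits.values():
        row = {
            "species_id": sp.species_id,
            "genus": sp.genus,
            "family": sp.family,
            "dispersal_mode": sp.dispersal_mode.value,
            "dispersal_class": sp.dispersal_class.value,
            "seed_length_cm": sp.seed_length_cm,
            "seed_length_source": sp.seed_length_source.value,
            "fruit_length_cm": sp.fruit_length_cm,
            "wood_density": sp.wood_density,
            "wood_density_source": sp.wood_density_source.value,
            "max_height_m": sp.max_height_m,
            "max_dbh_cm": sp.max_dbh_cm,
        }
        if large_seeded is not None:
            row["large_seeded"] = sp.species_id in large_seeded
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
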