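"""Two-step removal/recovery simulations of defaunation and matched null controls.

Each iteration of a scenario removes a set of stems from the pooled community
and then recovers the lost basal area (to a relative tolerance, default 1%) by
repopulating the community with clones of surviving stems, drawn uniformly with
replacement; a recovered stem keeps its source's species identity and DBH.
Because the target is basal area, not stem density, the number removed (N_Rem)
and the number recovered (N_Rec) generally differ.

Three scenario families are paired per iteration:

* defaunation — remove a fraction (25/50/75/100%) of the individuals of
  large-seeded animal-dispersed species, drawn uniformly;
* individual-based control — remove the same number of individuals (matched
  N_Rem) drawn from the whole pool irrespective of dispersal, isolating the
  numerical effect of replacing large stems with several small ones;
* species-based control — remove as many randomly chosen species (matched
  S_Loss, unweighted by abundance) as were incidentally lost in the paired
  defaunation iteration, isolating the effect of species loss per se.

Reproducibility: one root seed spawns an independent RNG stream per
(iteration, scenario) pair, so any iteration can be replayed in isolation and
two runs with the same seed produce bit-identical results tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .carbon import (
    CHAVE_2005_MOIST,
    AllometricCoefficients,
    KG_PER_MG,
    StandState,
    basal_area_cm2,
    volume_term,
)
from .traits import DispersalClass, LargeSeededRule, classify_large_seeded

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import Community, StemRecord

log = logging.getLogger(__name__)

__all__ = [
    "DEFAUNATION",
    "INDIVIDUAL_CONTROL",
    "SPECIES_CONTROL",
    "SCENARIOS",
    "RESPONSES",
    "REMOVAL_FRACTIONS",
    "ScenarioSpec",
    "IterationResult",
    "RecoveryFailure",
    "ScenarioRun",
    "ScenarioError",
    "RecoveryError",
    "remove_defaunation",
    "remove_individual_control",
    "remove_species_control",
    "recover_basal_area",
    "run_scenario",
    "results_to_frame",
]

DEFAUNATION = "defaunation"
INDIVIDUAL_CONTROL = "individual_control"
SPECIES_CONTROL = "species_control"
SCENARIOS = (DEFAUNATION, INDIVIDUAL_CONTROL, SPECIES_CONTROL)

#: Response variables tracked per iteration (percent change from original).
RESPONSES = ("carbon", "volume_index", "ba_weighted_wd", "large_tree_frac", "cw_seed_size")

#: The four defaunation levels simulated by default.
REMOVAL_FRACTIONS = (0.25, 0.50, 0.75, 1.00)

_DRAW_BUFFER = 512


class ScenarioError(ValueError):
    """A scenario precondition is violated (e.g. no large-seeded species)."""


class RecoveryError(RuntimeError):
    """Basal-area recovery could not reach the tolerance band."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one simulation run at a single removal level."""

    removal_fraction: float
    iterations: int = 1000
    ba_tolerance: float = 0.01
    rng_seed: int = 0
    max_draw_attempts: int = 100_000
    large_seeded_rule: LargeSeededRule = field(default_factory=LargeSeededRule)
    large_tree_threshold_cm: float = 70.0
    coefficients: AllometricCoefficients = CHAVE_2005_MOIST

    def __post_init__(self) -> None:
        if not (0 < self.removal_fraction <= 1):
            raise ValueError("removal_fraction must lie in (0, 1]")
        if not (self.ba_tolerance > 0):
            raise ValueError("ba_tolerance must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class IterationResult:
    """Bookkeeping for one scenario draw within one iteration."""

    iteration: int
    scenario: str
    n_rem: int
    n_rec: int
    ba_loss_cm2: float
    s_loss: int
    before: StandState
    after: StandState
    pct_change: dict[str, float]


@dataclass(frozen=True)
class RecoveryFailure:
    iteration: int
    scenario: str
    message: str


@dataclass(frozen=True)
class ScenarioRun:
    """All successful iteration results of one run, plus dropped failures."""

    site_id: str
    spec: ScenarioSpec
    large_seeded: frozenset[str]
    before: StandState
    results: tuple[IterationResult, ...]
    failures: tuple[RecoveryFailure, ...]

    def to_frame(self) -> pd.DataFrame:
        return results_to_frame(self.results)


class _SimContext:
    """Precomputed per-stem arrays; iterations only manipulate index multisets."""

    def __init__(
        self,
        community: "Community",
        coefficients: AllometricCoefficients,
        large_tree_threshold_cm: float,
        large_seeded: set[str],
    ) -> None:
        stems = community.stems
        self.community = community
        self.species_ids = sorted(community.species_present)
        index = {sid: i for i, sid in enumerate(self.species_ids)}
        self.n_species = len(self.species_ids)
        self.sp = np.array([index[s.species_id] for s in stems], dtype=np.int64)
        self.dbh = np.array([s.dbh_cm for s in stems])
        self.ba = basal_area_cm2(self.dbh)
        self.g = volume_term(self.dbh, coefficients)

        missing = sorted(
            sid for sid in self.species_ids if community.traits[sid].wood_density is None
        )
        if missing:
            raise ScenarioError(
                f"{community.site_id}: species lack wood density (impute first): "
                + ", ".join(missing[:10])
            )
        wd_species = np.array([community.traits[sid].wood_density for sid in self.species_ids])
        self.wd = wd_species[self.sp]
        self.wg = self.wd * self.g

        seed_species = np.array(
            [
                community.traits[sid].seed_length_cm
                if (
                    community.traits[sid].dispersal_class is DispersalClass.ANIMAL
                    and community.traits[sid].seed_length_cm is not None
                )
                else np.nan
                for sid in self.species_ids
            ]
        )
        self.seed = seed_species[self.sp]
        self.animal_seed_mask = np.isfinite(self.seed)

        large_idx = {index[sid] for sid in large_seeded if sid in index}
        self.large_mask = np.isin(self.sp, list(large_idx)) if large_idx else np.zeros(len(stems), bool)

        self.total_counts = np.bincount(self.sp, minlength=self.n_species)
        self.area_ha = community.area_ha
        self.coefficients = coefficients
        self.threshold = large_tree_threshold_cm
        self.all_idx = np.arange(len(stems), dtype=np.int64)

    # -- responses ---------------------------------------------------------

    def state(self, idx: np.ndarray) -> StandState:
        ba = self.ba[idx]
        ba_total = float(ba.sum())
        g_total = float(self.g[idx].sum())
        agb_kg = float(self.wg[idx].sum())
        counts = np.bincount(self.sp[idx], minlength=self.n_species)
        return StandState(
            carbon_mg_ha=self.coefficients.carbon_fraction * agb_kg / KG_PER_MG / self.area_ha,
            volume_index=g_total,
            ba_weighted_wd=float(np.dot(self.wd[idx], ba) / ba_total),
            large_tree_frac=float(np.mean(self.dbh[idx] >= self.threshold)),
            basal_area_cm2=ba_total,
            n_stems=int(idx.size),
            n_species=int(np.count_nonzero(counts)),
        )

    def cw_seed_size(self, idx: np.ndarray) -> float:
        mask = self.animal_seed_mask[idx]
        if not mask.any():
            return float("nan")
        return float(np.mean(self.seed[idx][mask]))

    def responses(self, state: StandState, idx: np.ndarray) -> dict[str, float]:
        return {
            "carbon": state.carbon_mg_ha,
            "volume_index": state.volume_index,
            "ba_weighted_wd": state.ba_weighted_wd,
            "large_tree_frac": state.large_tree_frac,
            "cw_seed_size": self.cw_seed_size(idx),
        }

    # -- removals ----------------------------------------------------------

    def removal_defaunation(
        self, fraction: float, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        pool = np.flatnonzero(self.large_mask)
        if pool.size == 0:
            raise ScenarioError("no individuals of large-seeded species to remove")
        n_rem = int(round(fraction * pool.size))  # round-half-even
        removed = rng.choice(pool, size=n_rem, replace=False) if n_rem else np.empty(0, np.int64)
        return self._split(removed)

    def removal_individuals(
        self, n_rem: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        if n_rem > self.all_idx.size:
            raise ScenarioError(f"n_rem={n_rem} exceeds pool size {self.all_idx.size}")
        removed = (
            rng.choice(self.all_idx, size=n_rem, replace=False) if n_rem else np.empty(0, np.int64)
        )
        return self._split(removed)

    def removal_species(
        self, s_loss: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        present = np.flatnonzero(self.total_counts > 0)
        if s_loss > present.size - 1:
            raise ScenarioError(
                f"s_loss={s_loss} too large for a {present.size}-species community"
            )
        if s_loss == 0:
            return self.all_idx.copy(), np.empty(0, np.int64)
        drop = rng.choice(present, size=s_loss, replace=False)
        mask = np.isin(self.sp, drop)
        return self.all_idx[~mask], self.all_idx[mask]

    def _split(self, removed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mask = np.zeros(self.all_idx.size, dtype=bool)
        mask[removed] = True
        return self.all_idx[~mask], self.all_idx[mask]

    def species_lost(self, survivor_idx: np.ndarray) -> int:
        counts = np.bincount(self.sp[survivor_idx], minlength=self.n_species)
        return int(np.sum((self.total_counts > 0) & (counts == 0)))


def _draw_recovery(
    ba: np.ndarray,
    pool: np.ndarray,
    current_ba: float,
    target_ba: float,
    tolerance: float,
    rng: np.random.Generator,
    max_draw_attempts: int,
) -> list[int]:
    """Append stems drawn uniformly with replacement from ``pool`` until the
    running basal area reaches ``target_ba``.

    A draw that would push the total beyond ``target_ba * (1 + tolerance)`` is
    rejected and redrawn (counted against ``max_draw_attempts``); the terminal
    total therefore lies in [target, target*(1+tolerance)], i.e. within the
    tolerance band.  Raises :class:`RecoveryError` when the band cannot be
    reached within the attempt budget.
    """
    # a relative epsilon keeps exact-multiple deficits from spinning on rounding noise
    eps = 1e-9 * target_ba
    if current_ba >= target_ba - eps:
        return []
    if pool.size == 0:
        raise RecoveryError("empty survivor pool; cannot recover basal area")
    upper = target_ba * (1.0 + tolerance)
    recovered: list[int] = []
    attempts = 0
    buf = np.empty(0, dtype=np.int64)
    pos = 0
    while current_ba < target_ba - eps:
        if pos == buf.size:
            buf = rng.integers(0, pool.size, size=_DRAW_BUFFER)
            pos = 0
        attempts += 1
        if attempts > max_draw_attempts:
            raise RecoveryError(
                f"recovery did not reach the ±{tolerance:.2%} band within "
                f"{max_draw_attempts} draws (deficit {target_ba - current_ba:.1f} cm²)"
            )
        j = int(pool[buf[pos]])
        pos += 1
        b = float(ba[j])
        if current_ba + b <= upper:
            recovered.append(j)
            current_ba += b
    return recovered


# ---------------------------------------------------------------------------
# Public, community-level wrappers


@dataclass(frozen=True)
class RemovalBookkeeping:
    n_rem: int
    ba_loss_cm2: float
    s_loss: int


def _require_rng(rng: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _wrap_removal(
    community: "Community",
    ctx: _SimContext,
    survivor_idx: np.ndarray,
    removed_idx: np.ndarray,
) -> tuple[list["StemRecord"], list["StemRecord"], RemovalBookkeeping]:
    survivors = [community.stems[i] for i in survivor_idx]
    removed = [community.stems[i] for i in removed_idx]
    book = RemovalBookkeeping(
        n_rem=len(removed),
        ba_loss_cm2=float(ctx.ba[removed_idx].sum()),
        s_loss=ctx.species_lost(survivor_idx),
    )
    return survivors, removed, book


def remove_defaunation(
    community: "Community",
    fraction: float,
    large_seeded_set: set[str],
    rng: np.random.Generator | int,
):
    """Remove ``round(fraction * N)`` individuals of large-seeded species.

    Returns ``(survivors, removed, bookkeeping)`` where bookkeeping records
    N_Rem, the basal area lost and the incidental species loss S_Loss.
    """
    if not large_seeded_set:
        raise ScenarioError("large_seeded_set is empty")
    ctx = _SimContext(community, CHAVE_2005_MOIST, 70.0, large_seeded_set)
    surv, rem = ctx.removal_defaunation(fraction, _require_rng(rng))
    return _wrap_removal(community, ctx, surv, rem)


def remove_individual_control(
    community: "Community", n_rem: int, rng: np.random.Generator | int
):
    """Remove ``n_rem`` individuals drawn uniformly from the whole pool."""
    ctx = _SimContext(community, CHAVE_2005_MOIST, 70.0, set())
    surv, rem = ctx.removal_individuals(n_rem, _require_rng(rng))
    return _wrap_removal(community, ctx, surv, rem)


def remove_species_control(
    community: "Community", s_loss: int, rng: np.random.Generator | int
):
    """Remove ``s_loss`` species drawn uniformly (unweighted by abundance)."""
    ctx = _SimContext(community, CHAVE_2005_MOIST, 70.0, set())
    surv, rem = ctx.removal_species(s_loss, _require_rng(rng))
    return _wrap_removal(community, ctx, surv, rem)


def recover_basal_area(
    survivors: "Community",
    ba_loss_cm2: float,
    tolerance: float = 0.01,
    rng: np.random.Generator | int = 0,
    max_draw_attempts: int = 100_000,
):
    """Recover lost basal area by cloning surviving stems.

    Draws stems uniformly with replacement from ``survivors`` until the total
    basal area is back within ``±tolerance`` of the pre-removal total
    (survivor BA + ``ba_loss_cm2``).  Returns ``(recovered_community, n_rec)``;
    clones keep their source species and DBH but get fresh stem ids.
    """
    from .data_io import Community

    if ba_loss_cm2 < 0:
        raise ValueError("ba_loss_cm2 must be >= 0")
    ba = basal_area_cm2(np.array([s.dbh_cm for s in survivors.stems]))
    current = float(ba.sum())
    target = current + float(ba_loss_cm2)
    picks = _draw_recovery(
        ba,
        np.arange(len(survivors.stems)),
        current,
        target,
        tolerance,
        _require_rng(rng),
        max_draw_attempts,
    )
    clones = [
        replace(survivors.stems[j], stem_id=f"{survivors.stems[j].stem_id}#r{k}")
        for k, j in enumerate(picks, start=1)
    ]
    recovered = Community(
        site_id=survivors.site_id,
        stems=list(survivors.stems) + clones,
        traits=survivors.traits,
        area_ha=survivors.area_ha,
    )
    return recovered, len(picks)


# ---------------------------------------------------------------------------
# Scenario runner


def _pct_changes(before: dict[str, float], after: dict[str, float]) -> dict[str, float]:
    out = {}
    for key, orig in before.items():
        new = after[key]
        if not np.isfinite(orig) or orig == 0 or not np.isfinite(new):
            out[key] = float("nan")
        else:
            out[key] = 100.0 * (new - orig) / orig
    return out


def _iteration_rng(seed: int, iteration: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(iteration, stream))
    )


def run_scenario(
    community: "Community",
    spec: ScenarioSpec,
    large_seeded: set[str] | None = None,
) -> ScenarioRun:
    """Run paired defaunation / individual-control / species-control iterations.

    Per iteration: a defaunation removal and recovery, then an individual-based
    control matched on N_Rem and a species-based control matched on S_Loss, all
    three with independent RNG streams.  Iterations whose recovery cannot reach
    the basal-area tolerance band are dropped and reported in ``failures``.
    """
    if large_seeded is None:
        large_seeded = classify_large_seeded(community, spec.large_seeded_rule)
    if not large_seeded:
        raise ScenarioError(
            f"{community.site_id}: no large-seeded animal-dispersed species under the given rule"
        )
    ctx = _SimContext(community, spec.coefficients, spec.large_tree_threshold_cm, large_seeded)
    before_state = ctx.state(ctx.all_idx)
    before_resp = ctx.responses(before_state, ctx.all_idx)
    target_ba = before_state.basal_area_cm2

    results: list[IterationResult] = []
    failures: list[RecoveryFailure] = []

    for i in range(spec.iterations):
        rng_def = _iteration_rng(spec.rng_seed, i, 0)
        surv_def, rem_def = ctx.removal_defaunation(spec.removal_fraction, rng_def)
        n_rem = rem_def.size
        s_loss = ctx.species_lost(surv_def)

        rng_ind = _iteration_rng(spec.rng_seed, i, 1)
        surv_ind, rem_ind = ctx.removal_individuals(n_rem, rng_ind)
        rng_spc = _iteration_rng(spec.rng_seed, i, 2)
        surv_spc, rem_spc = ctx.removal_species(s_loss, rng_spc)

        draws = (
            (DEFAUNATION, surv_def, rem_def, rng_def),
            (INDIVIDUAL_CONTROL, surv_ind, rem_ind, rng_ind),
            (SPECIES_CONTROL, surv_spc, rem_spc, rng_spc),
        )
        for name, surv, rem, rng in draws:
            ba_loss = float(ctx.ba[rem].sum())
            try:
                picks = _draw_recovery(
                    ctx.ba,
                    surv,
                    float(ctx.ba[surv].sum()),
                    target_ba,
                    spec.ba_tolerance,
                    rng,
                    spec.max_draw_attempts,
                )
            except RecoveryError as exc:
                failures.append(RecoveryFailure(iteration=i, scenario=name, message=str(exc)))
                log.warning("iteration %d %s dropped: %s", i, name, exc)
                continue
            idx = np.concatenate([surv, np.asarray(picks, dtype=np.int64)])
            after_state = ctx.state(idx)
            after_resp = ctx.responses(after_state, idx)
            results.append(
                IterationResult(
                    iteration=i,
                    scenario=name,
                    n_rem=int(rem.size),
                    n_rec=len(picks),
                    ba_loss_cm2=ba_loss,
                    s_loss=ctx.species_lost(surv),
                    before=before_state,
                    after=after_state,
                    pct_change=_pct_changes(before_resp, after_resp),
                )
            )

    return ScenarioRun(
        site_id=community.site_id,
        spec=spec,
        large_seeded=frozenset(large_seeded),
        before=before_state,
        results=tuple(results),
        failures=tuple(failures),
    )


def results_to_frame(results: Iterable[IterationResult]) -> pd.DataFrame:
    """Long-format results table: one row per iteration x scenario x response."""
    rows = []
    for r in results:
        for response, pct in r.pct_change.items():
            rows.append(
                {
                    "iteration": r.iteration,
                    "scenario": r.scenario,
                    "response": response,
                    "pct_change": pct,
                    "n_rem": r.n_rem,
                    "n_rec": r.n_rec,
                    "ba_loss_cm2": r.ba_loss_cm2,
                    "s_loss": r.s_loss,
                    "ba_after_cm2": r.after.basal_area_cm2,
                    "ba_before_cm2": r.before.basal_area_cm2,
                }
            )
    return pd.DataFrame(rows)
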