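"""Removal/recovery engine: bookkeeping, matched controls, reproducibility."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from defaunation_carbon.carbon import basal_area_cm2
from defaunation_carbon.simulation import (
    DEFAUNATION,
    INDIVIDUAL_CONTROL,
    SPECIES_CONTROL,
    RecoveryError,
    ScenarioError,
    ScenarioSpec,
    recover_basal_area,
    remove_defaunation,
    remove_individual_control,
    remove_species_control,
    run_scenario,
)

from conftest import make_community, make_species, make_stem


def uniform_community(counts: dict[str, int], dbh: float = 20.0, modes=None, seeds=None):
    """Community with ``counts[sid]`` stems of each species, all at ``dbh``."""
    modes = modes or {}
    seeds = seeds or {}
    traits = [
        make_species(sid, modes.get(sid, "animal"), seed=seeds.get(sid, 1.0), wd=0.6)
        for sid in counts
    ]
    stems = [make_stem(sid, dbh, k) for sid, n in counts.items() for k in range(n)]
    return make_community(stems, traits)


class TestRemoveDefaunation:
    def test_n_rem_is_rounded_fraction_of_large_seeded_stems(self):
        community = uniform_community({"big": 8, "small": 5}, seeds={"big": 3.0, "small": 1.0})
        _, removed, book = remove_defaunation(community, 0.5, {"big"}, rng=0)
        assert book.n_rem == len(removed) == 4
        assert all(s.species_id == "big" for s in removed)

    def test_round_half_even(self):
        community = uniform_community({"big": 6, "small": 5}, seeds={"big": 3.0})
        _, _, book = remove_defaunation(community, 0.25, {"big"}, rng=0)
        assert book.n_rem == 2  # 1.5 rounds to 2 under round-half-even

    def test_full_removal_extirpates_and_counts_species_loss(self):
        community = uniform_community(
            {"big1": 3, "big2": 2, "small": 4}, seeds={"big1": 3.0, "big2": 2.5}
        )
        survivors, removed, book = remove_defaunation(community, 1.0, {"big1", "big2"}, rng=1)
        assert book.n_rem == 5
        assert {s.species_id for s in survivors} == {"small"}
        assert book.s_loss == 2  # both exclusively large-seeded species lost
        assert book.ba_loss_cm2 == pytest.approx(5 * basal_area_cm2(20.0), rel=1e-12)

    def test_empty_large_seeded_set_is_scenario_error(self):
        community = uniform_community({"a": 3})
        with pytest.raises(ScenarioError):
            remove_defaunation(community, 0.5, set(), rng=0)


class TestRemoveIndividualControl:
    def test_zero_removals_leave_community_unchanged(self):
        community = uniform_community({"a": 4, "b": 2})
        survivors, removed, book = remove_individual_control(community, 0, rng=0)
        assert len(survivors) == 6 and removed == [] and book.n_rem == 0

    def test_removing_everything_leaves_empty_survivors(self):
        community = uniform_community({"a": 4})
        survivors, removed, _ = remove_individual_control(community, 4, rng=0)
        assert survivors == [] and len(removed) == 4

    def test_overdraw_rejected(self):
        community = uniform_community({"a": 4})
        with pytest.raises(ScenarioError):
            remove_individual_control(community, 5, rng=0)

    def test_removed_composition_tracks_pool_composition(self):
        # 30 animal / 30 abiotic stems; hypergeometric mean of animal removals
        # in a draw of 20 is 10 (sd of the mean over 300 draws ~ 0.11).
        community = uniform_community(
            {"an": 30, "ab": 30}, modes={"ab": "wind"}, seeds={"an": 1.0, "ab": 0.5}
        )
        rng = np.random.default_rng(7)
        mean_animal = np.mean(
            [
                sum(1 for s in remove_individual_control(community, 20, rng)[1] if s.species_id == "an")
                for _ in range(300)
            ]
        )
        assert mean_animal == pytest.approx(10.0, abs=0.5)


class TestRemoveSpeciesControl:
    def test_zero_species_is_identity(self):
        community = uniform_community({"a": 3, "b": 3})
        survivors, removed, _ = remove_species_control(community, 0, rng=0)
        assert len(survivors) == 6 and removed == []

    def test_one_species_fully_absent(self):
        community = uniform_community({"a": 2, "b": 3, "c": 4})
        survivors, removed, book = remove_species_control(community, 1, rng=3)
        gone = {s.species_id for s in removed}
        assert len(gone) == 1
        assert gone.isdisjoint({s.species_id for s in survivors})
        assert book.n_rem == dict(a=2, b=3, c=4)[gone.pop()]
        assert book.s_loss == 1

    def test_cannot_remove_all_species(self):
        community = uniform_community({"a": 2, "b": 3})
        with pytest.raises(ScenarioError):
            remove_species_control(community, 2, rng=0)


class TestRecoverBasalArea:
    def test_zero_loss_is_identity(self):
        community = uniform_community({"a": 5})
        recovered, n_rec = recover_basal_area(community, 0.0, rng=0)
        assert n_rec == 0 and recovered.n_stems == 5

    def test_single_species_pool_adds_integer_multiples(self):
        # every clone has the same basal area b; recovery must add exactly
        # ceil(loss/b) clones when that lands inside the +1% band
        community = uniform_community({"a": 10}, dbh=10.0)
        b = float(basal_area_cm2(10.0))
        # deficit 2.95*b: three clones land at +0.05*b, inside the +1% band
        recovered, n_rec = recover_basal_area(community, 2.95 * b, tolerance=0.01, rng=0)
        assert n_rec == 3
        assert recovered.total_basal_area_cm2 == pytest.approx(13 * b, rel=1e-9)
        # deficit 2.5*b: any integer number of clones misses the band entirely
        with pytest.raises(RecoveryError):
            recover_basal_area(community, 2.5 * b, tolerance=0.01, rng=0, max_draw_attempts=500)

    def test_unreachable_band_raises(self):
        # one giant survivor, tiny deficit: any clone overshoots the band
        community = uniform_community({"a": 1}, dbh=60.0)
        with pytest.raises(RecoveryError):
            recover_basal_area(community, 5.0, tolerance=0.01, rng=0, max_draw_attempts=200)

    def test_clones_keep_species_and_dbh_with_fresh_ids(self):
        community = uniform_community({"a": 3}, dbh=15.0)
        recovered, n_rec = recover_basal_area(community, 2 * basal_area_cm2(15.0), rng=0)
        clones = recovered.stems[3:]
        assert n_rec == len(clones) == 2
        assert all(c.species_id == "a" and c.dbh_cm == 15.0 for c in clones)
        assert len({c.stem_id for c in recovered.stems}) == recovered.n_stems

    def test_recovered_distribution_matches_enumeration(self):
        """Exhaustive enumeration of the accept/reject draw chain on a 2-stem pool.

        Conditional on acceptance, each accepted draw is uniform over the stems
        that still fit under the overshoot cap, and states where nothing fits
        absorb into failure; the empirical terminal-state distribution over many
        seeded runs must match.
        """
        d_small, d_big = 15.0, 20.0
        b = [float(basal_area_cm2(d_small)), float(basal_area_cm2(d_big))]
        ba_loss, tol = 500.0, 0.25
        start = sum(b)
        target = start + ba_loss
        upper = target * (1 + tol)

        exact: Counter = Counter()

        def recurse(total, counts, prob):
            if total >= target:
                exact[counts] += prob
                return
            fits = [i for i in range(2) if total + b[i] <= upper]
            if not fits:
                exact["fail"] += prob
                return
            for i in fits:
                new = (counts[0] + (i == 0), counts[1] + (i == 1))
                recurse(total + b[i], new, prob / len(fits))

        recurse(start, (0, 0), 1.0)
        assert abs(sum(exact.values()) - 1.0) < 1e-12

        community = uniform_community({"s": 1, "t": 1})
        community.stems[0] = make_stem("s", d_small)
        community.stems[1] = make_stem("t", d_big)
        empirical: Counter = Counter()
        runs = 3000
        for k in range(runs):
            try:
                recovered, _ = recover_basal_area(
                    community, ba_loss, tolerance=tol, rng=k, max_draw_attempts=300
                )
            except RecoveryError:
                empirical["fail"] += 1
                continue
            clone_species = [c.species_id for c in recovered.stems[2:]]
            empirical[(clone_species.count("s"), clone_species.count("t"))] += 1

        keys = set(exact) | set(empirical)
        tv_distance = 0.5 * sum(
            abs(exact.get(k, 0.0) - empirical.get(k, 0) / runs) for k in keys
        )
        assert tv_distance < 0.05


@pytest.fixture(scope="module")
def run(animal_dominated_community):
    spec = ScenarioSpec(removal_fraction=0.5, iterations=20, rng_seed=3)
    return run_scenario(animal_dominated_community, spec)


class TestRunScenario:
    def test_yields_triples(self, run):
        assert len(run.results) + len(run.failures) == 60
        per_iter = Counter(r.iteration for r in run.results)
        assert all(v == 3 for v in per_iter.values())

    def test_controls_are_matched(self, run):
        by_iter = {}
        for r in run.results:
            by_iter.setdefault(r.iteration, {})[r.scenario] = r
        for triple in by_iter.values():
            assert triple[INDIVIDUAL_CONTROL].n_rem == triple[DEFAUNATION].n_rem
            assert triple[SPECIES_CONTROL].s_loss == triple[DEFAUNATION].s_loss

    def test_basal_area_conserved_in_every_result(self, run):
        for r in run.results:
            deviation = abs(r.after.basal_area_cm2 - r.before.basal_area_cm2)
            assert deviation <= run.spec.ba_tolerance * r.before.basal_area_cm2

    def test_same_seed_is_bit_identical(self, animal_dominated_community):
        spec = ScenarioSpec(removal_fraction=1.0, iterations=5, rng_seed=11)
        frame1 = run_scenario(animal_dominated_community, spec).to_frame()
        frame2 = run_scenario(animal_dominated_community, spec).to_frame()
        pd.testing.assert_frame_equal(frame1, frame2)

    def test_different_seeds_differ(self, animal_dominated_community):
        spec1 = ScenarioSpec(removal_fraction=1.0, iterations=5, rng_seed=11)
        spec2 = ScenarioSpec(removal_fraction=1.0, iterations=5, rng_seed=12)
        frame1 = run_scenario(animal_dominated_community, spec1).to_frame()
        frame2 = run_scenario(animal_dominated_community, spec2).to_frame()
        assert not frame1.equals(frame2)

    def test_full_removal_drops_cw_seed_size(self, run, animal_dominated_community):
        spec = ScenarioSpec(removal_fraction=1.0, iterations=5, rng_seed=2)
        full = run_scenario(animal_dominated_community, spec)
        for r in full.results:
            if r.scenario == DEFAUNATION:
                assert r.pct_change["cw_seed_size"] < 0
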