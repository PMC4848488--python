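"""Dispersal classification, imputation chain and large-seeded identification."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defaunation_carbon.traits import (
    ClassificationError,
    DispersalClass,
    LargeSeededRule,
    SeedLengthSource,
    TraitError,
    WoodDensitySource,
    classify_dispersal,
    classify_large_seeded,
    community_weighted_seed_size,
    fit_fruit_seed_models,
    genus_seed_means,
    impute_all,
    impute_seed_length,
    impute_wood_density,
)

from conftest import make_community, make_species, make_stem


class TestClassifyDispersal:
    @pytest.mark.parametrize(
        "mode,expected",
        [
            ("animal", DispersalClass.ANIMAL),
            ("multiple", DispersalClass.ANIMAL),
            ("wind", DispersalClass.ABIOTIC),
            ("unassisted", DispersalClass.ABIOTIC),
        ],
    )
    def test_aggregation_rule(self, mode, expected):
        assert classify_dispersal(mode) is expected

    def test_unmapped_label_raises(self):
        with pytest.raises(ClassificationError, match="bird"):
            classify_dispersal("bird")


class TestFruitSeedModels:
    def test_collinear_points_recover_exact_line(self):
        traits = [
            make_species(f"s{i}", seed=s, fruit_length_cm=f, genus="Ficus")
            for i, (f, s) in enumerate([(2.0, 1.0), (4.0, 2.0), (6.0, 3.0)])
        ]
        models = fit_fruit_seed_models(traits)
        model = models["Ficus"]
        assert model.slope == pytest.approx(0.5)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0)
        assert model.n_species == 3

    def test_genus_with_two_species_gets_no_model(self):
        traits = [
            make_species("s1", seed=1.0, fruit_length_cm=2.0, genus="Pauper"),
            make_species("s2", seed=2.0, fruit_length_cm=4.0, genus="Pauper"),
        ]
        assert fit_fruit_seed_models(traits) == {}

    def test_species_missing_either_measurement_do_not_contribute(self):
        traits = [
            make_species("s1", seed=1.0, fruit_length_cm=2.0, genus="G"),
            make_species("s2", seed=2.0, fruit_length_cm=None, genus="G"),
            make_species("s3", seed=None, fruit_length_cm=6.0, genus="G"),
            make_species("s4", seed=3.0, fruit_length_cm=6.0, genus="G"),
        ]
        models = fit_fruit_seed_models(traits)
        assert "G" not in models  # only 2 complete species

    def test_zero_variance_fruit_lengths_omitted(self):
        traits = [
            make_species(f"s{i}", seed=float(i + 1), fruit_length_cm=3.0, genus="Flat")
            for i in range(3)
        ]
        assert "Flat" not in fit_fruit_seed_models(traits)


class TestImputeSeedLength:
    def test_measured_value_wins(self):
        sp = make_species("s", seed=2.1, fruit_length_cm=8.0)
        value, source = impute_seed_length(sp, {}, {})
        assert (value, source) == (2.1, SeedLengthSource.MEASURED)

    def test_fruit_model_prediction(self):
        from defaunation_carbon.traits import FruitSeedModel

        sp = make_species("s", seed=None, fruit_length_cm=8.0, genus="Ficus")
        models = {"Ficus": FruitSeedModel("Ficus", slope=0.5, intercept=0.0, n_species=3, r_squared=1.0)}
        value, source = impute_seed_length(sp, models, {"Ficus": 1.3})
        assert (value, source) == (4.0, SeedLengthSource.FRUIT_MODEL)

    def test_genus_mean_fallback(self):
        sp = make_species("s", seed=None, fruit_length_cm=None, genus="Ficus")
        value, source = impute_seed_length(sp, {}, {"Ficus": 1.3})
        assert (value, source) == (1.3, SeedLengthSource.GENUS_MEAN)

    def test_negative_prediction_falls_through(self):
        from defaunation_carbon.traits import FruitSeedModel

        sp = make_species("s", seed=None, fruit_length_cm=1.0, genus="Odd")
        models = {"Odd": FruitSeedModel("Odd", slope=0.5, intercept=-2.0, n_species=3, r_squared=0.5)}
        value, source = impute_seed_length(sp, models, {"Odd": 0.9})
        assert (value, source) == (0.9, SeedLengthSource.GENUS_MEAN)

    def test_no_source_available(self):
        sp = make_species("s", seed=None, fruit_length_cm=None, genus="Lost")
        assert impute_seed_length(sp, {}, {}) == (None, SeedLengthSource.MISSING)


class TestImputeWoodDensity:
    def test_preference_order(self):
        genus_means = {"G": 0.55}
        family_means = {"Fam01": 0.58}
        sp = make_species("s", wd=0.62, genus="G")
        assert impute_wood_density(sp, genus_means, family_means) == (0.62, WoodDensitySource.SPECIES)
        sp = make_species("s", wd=None, genus="G")
        assert impute_wood_density(sp, genus_means, family_means) == (0.55, WoodDensitySource.GENUS)
        sp = make_species("s", wd=None, genus="H")
        assert impute_wood_density(sp, genus_means, family_means) == (0.58, WoodDensitySource.FAMILY)
        sp = make_species("s", wd=None, genus="H", family="FamX")
        assert impute_wood_density(sp, {}, {}) == (None, WoodDensitySource.MISSING)

    def test_means_use_species_level_values_only(self):
        traits = [
            make_species("s1", wd=0.5, genus="G"),
            make_species("s2", wd=None, genus="G"),
        ]
        imputed = impute_all(traits)
        by_id = {sp.species_id: sp for sp in imputed}
        assert by_id["s2"].wood_density == pytest.approx(0.5)  # not diluted by s2 itself
        assert by_id["s2"].wood_density_source is WoodDensitySource.GENUS


class TestImputeAllMonotone:
    def test_measured_values_never_overwritten(self):
        traits = [
            make_species("s1", seed=2.0, wd=0.7, fruit_length_cm=5.0, genus="G"),
            make_species("s2", seed=1.0, wd=0.5, fruit_length_cm=2.0, genus="G"),
            make_species("s3", seed=1.5, wd=0.6, fruit_length_cm=3.0, genus="G"),
            make_species("s4", seed=None, wd=None, fruit_length_cm=4.0, genus="G"),
        ]
        imputed = {sp.species_id: sp for sp in impute_all(traits)}
        for sid in ("s1", "s2", "s3"):
            original = next(t for t in traits if t.species_id == sid)
            assert imputed[sid].seed_length_cm == original.seed_length_cm
            assert imputed[sid].wood_density == original.wood_density
            assert imputed[sid].seed_length_source is SeedLengthSource.MEASURED
        assert imputed["s4"].seed_length_source is SeedLengthSource.FRUIT_MODEL
        assert imputed["s4"].wood_density_source is WoodDensitySource.GENUS


def animal_community(seed_lengths, extra_traits=(), stems_per_species=1):
    traits = [
        make_species(f"a{i}", "animal", seed=s) for i, s in enumerate(seed_lengths)
    ] + list(extra_traits)
    stems = [
        make_stem(t.species_id, 20.0, k)
        for t in traits
        for k in range(stems_per_species)
    ]
    return make_community(stems, traits)


class TestClassifyLargeSeeded:
    def test_percentile_cutoff_linear_interpolation(self):
        # seeds {1,2,3,4}: the 75th percentile is 3.25, so only the 4 cm species
        community = animal_community([1.0, 2.0, 3.0, 4.0])
        assert classify_large_seeded(community) == {"a3"}

    def test_fixed_regional_cutoff(self):
        community = animal_community([1.5, 2.0])
        rule = LargeSeededRule(fixed_cutoff_cm=1.8)
        assert classify_large_seeded(community, rule) == {"a1"}

    def test_tie_at_cutoff_falls_to_small_seeded(self):
        community = animal_community([1.0, 2.0])
        rule = LargeSeededRule(fixed_cutoff_cm=2.0)
        assert classify_large_seeded(community, rule) == set()

    def test_abiotic_species_never_returned(self):
        big_wind = make_species("wind_big", "wind", seed=50.0)
        community = animal_community([1.0, 2.0, 3.0, 4.0], extra_traits=[big_wind])
        assert "wind_big" not in classify_large_seeded(community)

    def test_all_abiotic_community_raises(self):
        traits = [make_species("w1", "wind", seed=1.0), make_species("w2", "wind", seed=2.0)]
        stems = [make_stem("w1", 20), make_stem("w2", 25)]
        with pytest.raises(TraitError):
            classify_large_seeded(make_community(stems, traits))

    def test_stem_weighted_basis_shifts_cutoff(self):
        # 10 stems of the 1 cm species drag the stem-weighted percentile down.
        traits = [
            make_species("common_small", "animal", seed=1.0),
            make_species("rare_mid", "animal", seed=2.0),
            make_species("rare_big", "animal", seed=3.0),
        ]
        stems = [make_stem("common_small", 20, k) for k in range(10)] + [
            make_stem("rare_mid", 20),
            make_stem("rare_big", 20),
        ]
        community = make_community(stems, traits)
        assert classify_large_seeded(community, LargeSeededRule(basis="stems")) == {
            "rare_mid",
            "rare_big",
        }

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=30.0, allow_nan=False),
            min_size=4,
            max_size=40,
            unique=True,
        )
    )
    def test_at_most_a_quarter_plus_one_flagged(self, seeds):
        community = animal_community(seeds)
        large = classify_large_seeded(community)
        assert len(large) <= len(seeds) // 4 + 1

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=30.0, allow_nan=False),
            min_size=4,
            max_size=40,
            unique=True,
        )
    )
    def test_partition_is_exhaustive_and_disjoint(self, seeds):
        abiotic = [make_species("w", "wind", seed=0.5), make_species("u", "unassisted", seed=0.5)]
        community = animal_community(seeds, extra_traits=abiotic)
        large = classify_large_seeded(community)
        animal = {f"a{i}" for i in range(len(seeds))}
        small = animal - large
        abiotic_ids = {"w", "u"}
        assert large | small | abiotic_ids == community.species_present
        assert large.isdisjoint(small) and large.isdisjoint(abiotic_ids)


class TestCommunityWeightedSeedSize:
    def test_stem_weighted_mean(self):
        traits = [
            make_species("small", "animal", seed=1.0),
            make_species("big", "animal", seed=3.0),
        ]
        stems = [make_stem("small", 20, k) for k in range(2)] + [
            make_stem("big", 20, k) for k in range(2)
        ]
        community = make_community(stems, traits)
        assert community_weighted_seed_size(community) == pytest.approx(2.0)

    def test_removal_of_large_seeded_stems_shrinks_mean(self):
        traits = [
            make_species("small", "animal", seed=1.0),
            make_species("big", "animal", seed=3.0),
        ]
        stems = [make_stem("small", 20, k) for k in range(2)]
        community = make_community(stems, traits)
        assert community_weighted_seed_size(community) == pytest.approx(1.0)  # -50% vs 2.0

    def test_single_species_community(self):
        community = animal_community([1.7])
        assert community_weighted_seed_size(community) == pytest.approx(1.7)

    def test_abiotic_only_signals_undefined(self):
        traits = [make_species("w", "wind", seed=1.0)]
        community = make_community([make_stem("w", 20)], traits)
        with pytest.raises(TraitError):
            community_weighted_seed_size(community)
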