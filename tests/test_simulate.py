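"""Synthetic study generator: demographics, truth, design and noise."""

import numpy as np
import pytest

import deepcompartment as dc
from deepcompartment.exceptions import DataError, InvalidParameterError
from deepcompartment.simulate import (
    DoseRule,
    true_curve,
    true_curves_matrix,
    typical_parameters,
)


class TestFatFreeMass:
    def test_adult_reference_value(self):
        # BMI = 70 / 1.76^2 = 22.60; maturation ~ 1 at age 30
        assert dc.fat_free_mass(70.0, 176.0, 30.0) == pytest.approx(56.13, abs=0.05)

    def test_maturation_floor_in_young_children(self):
        mass_term = 9270.0 * 10.0 / (6680.0 + 216.0 * (10.0 / 0.8**2))
        assert dc.fat_free_mass(10.0, 80.0, 1e-6) == pytest.approx(
            0.88 * mass_term, rel=1e-9
        )

    def test_maturation_midpoint_at_13_4_years(self):
        mass_term = 9270.0 * 50.0 / (6680.0 + 216.0 * (50.0 / 1.6**2))
        assert dc.fat_free_mass(50.0, 160.0, 13.4) == pytest.approx(
            0.94 * mass_term, rel=1e-9
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            dc.fat_free_mass(0.0, 176.0, 30.0)
        with pytest.raises(InvalidParameterError):
            dc.fat_free_mass(70.0, 176.0, -1.0)


class TestAssignDose:
    @pytest.mark.parametrize("weight,expected", [
        (70.0, 3500.0),   # exact multiple of 250
        (66.0, 3250.0),   # 3300 rounds down to nearest 250
        (62.5, 3250.0),   # 3125 is a tie; half rounds away from zero
    ])
    def test_weight_based_rounding(self, weight, expected):
        assert dc.assign_dose(weight, DoseRule(per_kg=50, quantum=250)) == expected


class TestObservationTimes:
    def test_component_means_recovered(self):
        rng = np.random.default_rng(5)
        draws = np.array([
            dc.sample_observation_times(rng=rng) for _ in range(10_000)
        ])
        means = draws.mean(axis=0)
        assert 3.8 < means[0] < 4.2
        assert 23.5 < means[1] < 24.5
        assert 47.5 < means[2] < 48.5

    def test_truncation_floor(self):
        rng = np.random.default_rng(6)
        draws = np.array([
            dc.sample_observation_times(rng=rng) for _ in range(5_000)
        ])
        assert draws.min() >= 0.25
        assert np.all(np.diff(draws, axis=1) >= 0)

    def test_seeded_determinism(self):
        a = dc.sample_observation_times(seed=42)
        b = dc.sample_observation_times(seed=42)
        assert np.array_equal(a, b)


class TestGenerateCovariates:
    def test_row_count_and_positivity(self):
        table = dc.generate_covariates(756, dc.PopulationConfig(), seed=1)
        assert len(table) == 756
        assert (table[["age", "height", "weight", "ffm"]] > 0).all().all()

    def test_seeded_determinism(self):
        a = dc.generate_covariates(50, dc.PopulationConfig(), seed=9)
        b = dc.generate_covariates(50, dc.PopulationConfig(), seed=9)
        assert a.equals(b)

    def test_adult_median_height_plausible(self):
        table = dc.generate_covariates(4000, dc.PopulationConfig(), seed=2)
        adults = table[table["age"] > 20]
        assert 160.0 < adults["height"].median() < 190.0


class TestSimulatePopulation:
    def test_observation_count_is_three_per_subject(self, small_study):
        assert sum(len(t) for t in small_study.obs_times) == 3 * small_study.n

    def test_ffm_column_consistent_with_formula(self, small_study):
        f = small_study.frame
        recomputed = dc.fat_free_mass(
            f["weight"].to_numpy(), f["height"].to_numpy(), f["age"].to_numpy()
        )
        assert np.max(np.abs(recomputed - f["ffm"].to_numpy())) < 1e-10

    def test_no_randomness_without_iiv_and_noise(self):
        cfg = dc.PopulationConfig(n=10, seed=4, sigma=0.0, omega_cl=0.0,
                                  omega_v1=0.0)
        study = dc.simulate_population(cfg)
        typ = typical_parameters(study.frame["ffm"].to_numpy(), cfg)
        assert np.allclose(study.true_params, typ)
        for obs, truth in zip(study.observations, study.true_obs):
            assert np.array_equal(obs, truth)

    def test_median_peak_concentration_scale(self, small_study):
        peaks = true_curves_matrix(
            small_study, np.arange(small_study.n), np.array([0.25])
        ).ravel()
        assert 50.0 < np.median(peaks) < 250.0

    def test_full_reproducibility_and_sigma_isolation(self):
        a = dc.simulate_population(dc.PopulationConfig(n=8, seed=77))
        b = dc.simulate_population(dc.PopulationConfig(n=8, seed=77))
        assert np.array_equal(a.true_params, b.true_params)
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.observations, b.observations))
        c = dc.simulate_population(dc.PopulationConfig(n=8, seed=77, sigma=1.0))
        assert np.array_equal(a.true_params, c.true_params)
        assert all(np.array_equal(x, y) for x, y in zip(a.true_obs, c.true_obs))
        assert not all(np.array_equal(x, y)
                       for x, y in zip(a.observations, c.observations))

    def test_log_parameter_variability_recovers_omega(self):
        cfg = dc.PopulationConfig(n=10_000, seed=13)
        study = dc.simulate_population(cfg)
        typ = typical_parameters(study.frame["ffm"].to_numpy(), cfg)
        sd = np.std(np.log(study.true_params[:, 0]) - np.log(typ[:, 0]))
        assert abs(sd - cfg.omega_cl) / cfg.omega_cl < 0.05


class TestNoiseCovariates:
    @pytest.fixture(scope="class")
    def big_augmented(self):
        study = dc.simulate_population(dc.PopulationConfig(n=10_000, seed=15))
        return dc.augment_noise_covariates(study, seed=16)

    def test_category_frequencies_near_uniform(self, big_augmented):
        freq = big_augmented.frame["noise_cat"].value_counts(normalize=True)
        assert set(freq.index) == {1, 2, 3, 4, 5}
        assert ((freq > 0.18) & (freq < 0.22)).all()

    def test_continuous_noise_in_unit_interval(self, big_augmented):
        for col in ("noise1", "noise2"):
            vals = big_augmented.frame[col]
            assert vals.between(0.0, 1.0).all()

    def test_independence_from_weight(self, big_augmented):
        f = big_augmented.frame
        for col in ("noise1", "noise2"):
            assert abs(np.corrcoef(f[col], f["weight"])[0, 1]) < 0.05

    def test_name_collision_rejected(self, big_augmented):
        with pytest.raises(DataError, match="collision"):
            dc.augment_noise_covariates(big_augmented, seed=1)


class TestTrueCurve:
    def test_unknown_subject_rejected(self, small_study):
        with pytest.raises(DataError):
            true_curve(small_study, "nope")
        with pytest.raises(DataError):
            true_curve(small_study, small_study.n + 3)

    def test_single_point_grid_at_dose_time(self, small_study):
        dose = small_study.regimens[0].events[0].amount
        v1 = small_study.true_params[0, 1]
        c = true_curve(small_study, 0, np.array([0.0]))
        assert np.isclose(c.values[0], dose / v1 / 10.0)

    def test_matches_analytic_oracle(self, small_study):
        grid = np.linspace(0.0, 72.0, 30)
        c = true_curve(small_study, 3, grid)
        pk = dc.PKParameters(*small_study.true_params[3])
        dose = small_study.regimens[3].events[0].amount
        assert np.allclose(c.values, dc.analytic_bolus_solution(pk, dose, grid),
                           rtol=1e-12)

    def test_matrix_path_matches_per_subject_path(self, small_study):
        grid = np.linspace(0.0, 72.0, 20)
        mat = true_curves_matrix(small_study, [0, 5, 7], grid)
        for row, idx in zip(mat, [0, 5, 7]):
            assert np.allclose(row, true_curve(small_study, idx, grid).values)
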