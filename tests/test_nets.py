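"""Architecture forward passes, constraints and effect-curve extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import deepcompartment as dc
from deepcompartment.exceptions import ConfigurationError, InvalidParameterError
from deepcompartment.nets import (
    BranchSpec,
    apply_boundary,
    build_model,
    softplus,
    softplus_inv,
)

COVS = ("weight", "height", "age")


def make_model(variant, **kwargs):
    spec = dc.ArchitectureSpec(variant=variant, covariates=COVS, **kwargs)
    model = build_model(spec, list(COVS))
    return spec, model


class TestNaiveForward:
    def test_zero_weights_give_softplus_of_bias(self):
        _, model = make_model("naive", hidden_size=4)
        p = model.init_params(np.random.default_rng(0))
        for key in ("W1", "b1", "W2"):
            p[key] = np.zeros_like(p[key])
        p["b2"] = np.array([0.1, 0.2, 0.3, 0.4])
        z = model.predict(p, np.random.default_rng(1).uniform(size=(5, 3)))
        assert np.allclose(z, softplus(p["b2"]))

    def test_zero_preactivation_maps_to_ln2(self):
        _, model = make_model("naive")
        p = model.init_params(np.random.default_rng(0))
        for key in p:
            p[key] = np.zeros_like(p[key])
        z = model.predict(p, np.zeros((2, 3)))
        assert np.allclose(z, np.log(2.0))

    def test_hand_evaluated_single_neuron(self):
        """softplus(swish(0.5)) with all unit weights and zero biases."""
        spec = dc.ArchitectureSpec(variant="naive", covariates=("x",),
                                   hidden_size=1)
        model = build_model(spec, ["x"])
        p = {
            "W1": np.array([[1.0]]), "b1": np.zeros(1),
            "W2": np.ones((1, 4)), "b2": np.zeros(4),
        }
        z = model.predict(p, np.array([[0.5]]))
        sw = 0.5 * expit(0.5)
        expected = np.log1p(np.exp(sw))
        assert np.allclose(z, expected, rtol=1e-12)
        assert np.isclose(expected, 0.8608, atol=5e-4)

    def test_nan_input_rejected(self):
        _, model = make_model("naive")
        p = model.init_params(np.random.default_rng(0))
        x = np.zeros((2, 3))
        x[1, 1] = np.nan
        with pytest.raises(InvalidParameterError, match="NaN"):
            model.predict(p, x)


class TestBoundary:
    def test_midpoint_at_zero_preactivation(self):
        assert np.isclose(apply_boundary(0.0, (0.3, 7.0)), 3.65)
        assert np.isclose(apply_boundary(0.0, (0.0, 0.5)), 0.25)

    def test_saturation_limits(self):
        assert np.isclose(apply_boundary(60.0, (0.3, 7.0)), 7.0)
        assert np.isclose(apply_boundary(-60.0, (0.3, 7.0)), 0.3)

    def test_invalid_bounds_rejected_at_spec_validation(self):
        with pytest.raises(ConfigurationError):
            dc.ArchitectureSpec(
                variant="boundary", covariates=COVS,
                bounds={"CL": (0.5, 0.1), "V1": (0.3, 7), "Q": (0.05, 0.5),
                        "V2": (0, 2)},
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_outputs_strictly_inside_default_bounds(self, seed):
        rng = np.random.default_rng(seed)
        spec, model = make_model("boundary")
        p = model.init_params(rng)
        for key in ("W1", "W2"):
            p[key] = p[key] * rng.uniform(0.1, 50.0)
        x = rng.uniform(-3.0, 3.0, size=(8, 3))
        z = model.predict(p, x)
        lb = np.array([spec.bounds[n][0] for n in dc.PARAM_ORDER])
        ub = np.array([spec.bounds[n][1] for n in dc.PARAM_ORDER])
        # strictly inside up to float saturation of the sigmoid
        assert np.all(z >= lb) and np.all(z <= ub)
        interior = model.predict(p, x * 1e-3)
        assert np.all(interior > lb) and np.all(interior < ub)

    def test_softsign_variant_respects_bounds(self):
        rng = np.random.default_rng(3)
        spec, model = make_model("boundary", use_softsign=True)
        p = model.init_params(rng)
        z = model.predict(p, rng.uniform(-5, 5, size=(10, 3)))
        lb = np.array([spec.bounds[n][0] for n in dc.PARAM_ORDER])
        ub = np.array([spec.bounds[n][1] for n in dc.PARAM_ORDER])
        assert np.all(z > lb) and np.all(z < ub)


class TestGlobal:
    def test_raw_zero_theta_gives_ln2(self):
        _, model = make_model("global", global_priors={})
        p = model.init_params(np.random.default_rng(0))
        z = model.predict(p, np.random.default_rng(1).uniform(size=(4, 3)))
        assert np.allclose(z[:, 2], np.log(2.0))
        assert np.allclose(z[:, 3], np.log(2.0))

    def test_global_columns_constant_across_batch(self):
        _, model = make_model("global")
        p = model.init_params(np.random.default_rng(0))
        z = model.predict(p, np.random.default_rng(1).uniform(size=(6, 3)))
        assert np.ptp(z[:, 2]) == 0.0 and np.ptp(z[:, 3]) == 0.0
        assert np.ptp(z[:, 0]) > 0.0  # network outputs differ across subjects

    def test_prior_initialization_on_pk_scale(self):
        _, model = make_model("global")
        p = model.init_params(np.random.default_rng(0))
        assert np.isclose(softplus(p["theta_Q"][0]), 0.2)
        assert np.isclose(softplus(p["theta_V2"][0]), 0.8)

    def test_all_params_global_rejected(self):
        with pytest.raises(ConfigurationError):
            dc.ArchitectureSpec(variant="global", covariates=COVS,
                                global_params=("CL", "V1", "Q", "V2"))

    def test_theta_gradient_flows(self):
        _, model = make_model("global")
        p = model.init_params(np.random.default_rng(0))
        x = np.random.default_rng(1).uniform(size=(3, 3))
        _, cache = model.forward(p, x)
        d_z = np.zeros((3, 4))
        d_z[:, 2] = 1.0
        grads = model.backward(p, cache, d_z)
        assert abs(grads["theta_Q"][0]) > 0


class TestMultiBranch:
    def spec(self):
        return dc.ArchitectureSpec(
            variant="multibranch", covariates=("ffm", "age"), hidden_size=4,
            branches=(
                BranchSpec(covariates=("ffm", "age"), targets=("CL",)),
                BranchSpec(covariates=("ffm",), targets=("V1",)),
            ),
            global_params=("Q", "V2"),
        )

    def test_single_branch_equals_branch_output(self):
        spec = self.spec()
        model = build_model(spec, ["ffm", "age"])
        p = model.init_params(np.random.default_rng(0))
        x = np.random.default_rng(1).uniform(size=(5, 2))
        z, _ = model.forward(p, x)
        f, _, _ = model.branch_output(p, 0, x[:, model.branch_cols[0]])
        assert np.allclose(z[:, 0], f[:, 0])

    def test_product_of_two_branches(self):
        spec = dc.ArchitectureSpec(
            variant="multibranch", covariates=("a", "b"), hidden_size=2,
            branches=(
                BranchSpec(covariates=("a",), targets=("V1",)),
                BranchSpec(covariates=("b",), targets=("V1",)),
                BranchSpec(covariates=("a",), targets=("CL",)),
            ),
            global_params=("Q", "V2"),
        )
        model = build_model(spec, ["a", "b"])
        p = model.init_params(np.random.default_rng(0))
        # constant branches: zero weights, bias chosen so factors are 2 and 0.5
        for j, val in ((0, 2.0), (1, 0.5)):
            p[f"br{j}_W1"] = np.zeros_like(p[f"br{j}_W1"])
            p[f"br{j}_b1"] = np.zeros_like(p[f"br{j}_b1"])
            p[f"br{j}_W2"] = np.zeros_like(p[f"br{j}_W2"])
            p[f"br{j}_b2"] = np.array([softplus_inv(val)])
        z = model.predict(p, np.random.default_rng(1).uniform(size=(4, 2)))
        assert np.allclose(z[:, 1], 1.0)

    def test_v1_bias_initialized_at_half(self):
        spec = self.spec()
        model = build_model(spec, ["ffm", "age"])
        p = model.init_params(np.random.default_rng(0))
        assert p["br1_b2"][0] == 0.5
        p["br1_W1"] = np.zeros_like(p["br1_W1"])
        p["br1_b1"] = np.zeros_like(p["br1_b1"])
        p["br1_W2"] = np.zeros_like(p["br1_W2"])
        z = model.predict(p, np.random.default_rng(1).uniform(size=(3, 2)))
        assert np.allclose(z[:, 1], softplus(0.5))
        assert np.isclose(softplus(0.5), 0.97408, atol=5e-6)

    def test_orphan_parameter_rejected(self):
        with pytest.raises(ConfigurationError, match="V1"):
            dc.ArchitectureSpec(
                variant="multibranch", covariates=("ffm",), hidden_size=2,
                branches=(BranchSpec(covariates=("ffm",), targets=("CL",)),),
                global_params=("Q", "V2"),
            )

    def test_log_factorization_is_exact(self):
        spec = dc.ArchitectureSpec(
            variant="multibranch", covariates=("a", "b"), hidden_size=3,
            branches=(
                BranchSpec(covariates=("a",), targets=("CL", "V1")),
                BranchSpec(covariates=("b",), targets=("CL", "V1")),
            ),
            global_params=("Q", "V2"),
        )
        model = build_model(spec, ["a", "b"])
        p = model.init_params(np.random.default_rng(7))
        x = np.random.default_rng(8).uniform(size=(6, 2))
        z, _ = model.forward(p, x)
        log_sum = np.zeros((6, 2))
        for j in range(2):
            f, _, _ = model.branch_output(p, j, x[:, model.branch_cols[j]])
            log_sum += np.log(f)
        assert np.max(np.abs(np.log(z[:, :2]) - log_sum)) < 1e-10


@pytest.mark.parametrize("variant,kwargs", [
    ("naive", {}),
    ("boundary", {}),
    ("global", {}),
    ("initialized", {"typical_values": dc.PKParameters(0.15, 3.0, 0.15, 0.6)}),
])
def test_positivity_and_permutation_invariance(variant, kwargs):
    spec, model = make_model(variant, **kwargs)
    rng = np.random.default_rng(11)
    p = model.init_params(rng)
    x = rng.uniform(-2.0, 2.0, size=(7, 3))
    z = model.predict(p, x)
    assert np.all(z > 0) and np.all(np.isfinite(z))
    perm = rng.permutation(7)
    assert np.allclose(model.predict(p, x[perm]), z[perm])


class TestInitTypical:
    def test_bias_is_softplus_inverse_of_typical(self):
        typical = dc.PKParameters(0.15, 3.0, 0.15, 0.6)
        spec = dc.ArchitectureSpec(variant="naive", covariates=COVS)
        p = dc.init_typical(spec, typical, list(COVS))
        expected = np.log(np.expm1(0.15))
        assert np.isclose(p["b2"][0], expected)
        assert np.isclose(softplus(p["b2"][1]), 3.0)

    def test_typical_value_ln2_gives_zero_bias(self):
        spec = dc.ArchitectureSpec(variant="naive", covariates=COVS)
        ln2 = float(np.log(2.0))
        p = dc.init_typical(spec, dc.PKParameters(ln2, ln2, ln2, ln2), list(COVS))
        assert np.allclose(p["b2"], 0.0, atol=1e-12)

    def test_untrained_prediction_spread_below_five_percent(self):
        typical = dc.PKParameters(0.15, 3.0, 0.15, 0.6)
        spec, model = make_model(
            "initialized", typical_values=typical, hidden_size=8
        )
        p = model.init_params(np.random.default_rng(0))
        x = np.random.default_rng(1).uniform(0.0, 1.0, size=(100, 3))
        z = model.predict(p, x)
        tv = typical.as_array()
        assert np.all(np.abs(z - tv) / tv < 0.05)

    def test_nonpositive_typical_rejected(self):
        with pytest.raises(InvalidParameterError):
            softplus_inv(0.0)


class TestEffectCurves:
    def fit_constant_branch(self):
        study = dc.simulate_population(dc.PopulationConfig(n=12, seed=3))
        ds = study.to_dataset(["ffm", "age"])
        spec = dc.ArchitectureSpec(
            variant="multibranch", covariates=("ffm", "age"), hidden_size=2,
            branches=(
                BranchSpec(covariates=("ffm", "age"), targets=("CL",)),
                BranchSpec(covariates=("ffm",), targets=("V1",)),
            ),
            global_params=("Q", "V2"),
        )
        return dc.train(ds, spec, dc.TrainingProtocol(epochs=1, seed=0)), ds

    def test_zero_weight_branch_is_flat_at_ln2(self):
        fit, _ = self.fit_constant_branch()
        for key in list(fit.params):
            if key.startswith("br0_"):
                fit.params[key] = np.zeros_like(fit.params[key])
        curves = dc.extract_effect_curves(fit)
        cl_curves = [c for c in curves if c.parameter == "CL"]
        for c in cl_curves:
            assert np.allclose(c.values, np.log(2.0))

    def test_curve_reproduces_subject_branch_factor(self):
        fit, ds = self.fit_constant_branch()
        subject = ds.subjects[0]
        grid = np.array([subject.covariates["ffm"]])
        curves = dc.extract_effect_curves(fit, grids={"ffm": grid})
        v1 = next(c for c in curves if c.parameter == "V1" and c.covariate == "ffm")
        x = fit.scaler.transform_value("ffm", grid)[:, None]
        f, _, _ = fit.model.branch_output(fit.params, 1, x)
        assert np.allclose(v1.values, f[:, 0])

    def test_extrapolation_is_flagged(self):
        fit, _ = self.fit_constant_branch()
        lo, hi = fit.scaler.range("ffm")
        curves = dc.extract_effect_curves(
            fit, grids={"ffm": np.array([lo - 5.0, (lo + hi) / 2, hi + 5.0])}
        )
        v1 = next(c for c in curves if c.parameter == "V1")
        assert list(v1.extrapolated) == [True, False, True]

    def test_non_multibranch_rejected(self):
        study = dc.simulate_population(dc.PopulationConfig(n=6, seed=3))
        fit = dc.train(
            study.to_dataset(["ffm", "age"]),
            dc.ArchitectureSpec(variant="naive", covariates=("ffm", "age")),
            dc.TrainingProtocol(epochs=1, seed=0),
        )
        with pytest.raises(ConfigurationError):
            dc.extract_effect_curves(fit)
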