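"""Multinomial model: score equations, oracles, metrics, drop-one ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

import vegmosaic as vm
from vegmosaic.features import DesignMatrix, FeatureSpec
from vegmosaic.landscape import PREDICTOR_NAMES
from vegmosaic.model import _nll_grad


def _intercept_design(n):
    return DesignMatrix(np.ones((n, 1)), ["intercept"], FeatureSpec(()))


def _plain_design(x, names):
    """Design matrix from raw columns (intercept + given columns, no scaling)."""
    spec = FeatureSpec(tuple(names), include_quadratic=False,
                       include_interactions=False,
                       means={n: 0.0 for n in names}, sds={n: 1.0 for n in names})
    vals = np.column_stack([np.ones(len(x))] + [x[:, i] for i in range(x.shape[1])])
    return DesignMatrix(vals, ["intercept"] + list(names), spec)


class TestFit:
    def test_intercept_only_recovers_class_frequencies(self):
        labels = np.array([0] * 50 + [1] * 30 + [2] * 20)
        model = vm.fit(_intercept_design(100), labels, vm.FitOptions(ridge=0.0))
        p = model.probabilities(_intercept_design(100))
        np.testing.assert_allclose(p, np.tile([0.5, 0.3, 0.2], (100, 1)), atol=1e-7)

    def test_two_by_two_table_log_odds(self):
        """Closed-form logistic MLE on counts (20,10 / 5,15): slope = ln 6."""
        x = np.array([0] * 30 + [1] * 20, dtype=float)[:, None]
        labels = np.array([0] * 20 + [1] * 10 + [0] * 5 + [1] * 15)
        design = _plain_design(x, ["x"])
        model = vm.fit(design, labels, vm.FitOptions(ridge=0.0))
        assert model.coefficients[0, 1] == pytest.approx(np.log(6.0), abs=1e-6)

    def test_column_sum_constraint_without_ridge(self, small_landscape):
        """Per-class probability sums equal observed counts with ridge = 0."""
        env, spec, vegmap = (small_landscape[k] for k in ("env", "spec", "vegmap"))
        design = vm.expand(spec, env.samples())
        labels = vegmap.labels.ravel()
        model = vm.fit(design, labels, vm.FitOptions(ridge=0.0))
        p = model.probabilities(design)
        counts = np.bincount(labels, minlength=vegmap.n_classes)
        assert np.abs(p.sum(axis=0) - counts).max() / len(labels) < 1e-6

    def test_probability_recovery_improves_with_sample_size(self):
        """Fitted-vs-true mean TV distance shrinks as the landscape grows."""
        tvs = {}
        for rows, cols in [(70, 70), (140, 140)]:
            cfg = vm.LandscapeConfig(grid_rows=rows, grid_cols=cols, n_types=4, seed=21)
            env = vm.generate_environment(cfg)
            spec = vm.build_spec(PREDICTOR_NAMES, env.samples())
            truth = vm.generate_true_model(4, spec, seed=21)
            veg = vm.sample_vegetation(env, truth, seed=21)
            design = vm.expand(spec, env.samples())
            model = vm.fit(design, veg.labels.ravel())
            tv = 0.5 * np.abs(truth.probabilities(design)
                              - model.probabilities(design)).sum(axis=1)
            tvs[rows * cols] = tv.mean()
        assert tvs[140 * 140] < tvs[70 * 70]
        assert tvs[140 * 140] < 0.05

    def test_likelihood_not_worse_than_null(self, fitted_small):
        design, model = fitted_small["design"], fitted_small["model"]
        labels = fitted_small["vegmap"].labels.ravel()
        k = model.n_classes
        onehot = np.zeros((design.n_rows, k))
        onehot[np.arange(design.n_rows), labels] = 1
        mask = np.ones((k - 1, design.n_columns))
        null_nll, _ = _nll_grad(np.zeros((k - 1) * design.n_columns),
                                design.values, onehot, 0.0, mask)
        assert -model.fit_metadata["log_likelihood"] < null_nll

    def test_complete_separation_without_ridge_raises(self):
        x = np.array([-1.0] * 20 + [1.0] * 20)[:, None]
        labels = np.array([0] * 20 + [1] * 20)
        design = _plain_design(x, ["x"])
        with pytest.raises(vm.FitError, match="ridge"):
            vm.fit(design, labels, vm.FitOptions(ridge=0.0))
        # a positive ridge makes the same problem well-posed
        model = vm.fit(design, labels, vm.FitOptions(ridge=1e-2))
        assert np.isfinite(model.coefficients).all()

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="every class"):
            vm.fit(_intercept_design(10), np.array([0] * 5 + [2] * 5))

    def test_fitted_loglik_matches_derivative_free_oracle(self):
        """On tiny instances the optimum matches Nelder-Mead within 1e-4."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(120, 2))
        logits = np.column_stack([np.zeros(120), x @ [1.0, -0.5], x @ [-0.5, 0.2]])
        labels = np.array([rng.choice(3, p=np.exp(r) / np.exp(r).sum()) for r in logits])
        design = _plain_design(x, ["a", "b"])
        model = vm.fit(design, labels, vm.FitOptions(ridge=0.0))

        k = 3
        onehot = np.zeros((120, k))
        onehot[np.arange(120), labels] = 1
        mask = np.ones((k - 1, 3))
        nm = optimize.minimize(
            lambda b: _nll_grad(b, design.values, onehot, 0.0, mask)[0],
            np.zeros((k - 1) * 3), method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10})
        ours = -model.fit_metadata["log_likelihood"]
        assert ours <= nm.fun + 1e-4
        assert abs(ours - nm.fun) < 1e-4

    def test_matches_sklearn_multinomial(self):
        """Independent cross-check: sklearn's unpenalized multinomial fit."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(8)
        x = rng.normal(size=(400, 3))
        eta = np.column_stack([np.zeros(400), x @ [1.2, -0.3, 0.5],
                               x @ [-0.6, 0.9, 0.1]])
        p = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        labels = np.array([rng.choice(3, p=row) for row in p])
        design = _plain_design(x, ["a", "b", "c"])
        ours = vm.fit(design, labels, vm.FitOptions(ridge=0.0))
        sk = LogisticRegression(C=np.inf, tol=1e-10, max_iter=5000).fit(x, labels)
        p_ours = ours.probabilities(design)
        p_sk = sk.predict_proba(x)
        assert np.abs(p_ours - p_sk).max() < 1e-4


class TestPredictEvaluate:
    def test_zero_coefficients_give_uniform_rows(self, small_landscape):
        spec = small_landscape["spec"]
        truth = vm.generate_true_model(5, spec, coefficient_scale=0.0)
        design = vm.expand(spec, small_landscape["env"].samples())
        field = vm.predict_probabilities(truth, design)
        np.testing.assert_allclose(field.values, 0.2, atol=1e-12)

    def test_saturated_logit_overflow_safe(self):
        spec = FeatureSpec(())
        coefs = np.array([[50.0], [0.0], [0.0]])  # class 1 logit +50
        model = vm.PVMModel(coefs, [f"c{i}" for i in range(4)], "c0", spec)
        p = model.probabilities(_intercept_design(5))
        assert np.all(p[:, 1] >= 1 - 1e-20)
        # logits up to +-1e3 stay finite and normalized
        coefs = np.array([[1000.0], [-1000.0], [0.0]])
        model = vm.PVMModel(coefs, [f"c{i}" for i in range(4)], "c0", spec)
        p = model.probabilities(_intercept_design(5))
        assert np.isfinite(p).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_row_sums_normalized_at_scale(self, small_landscape):
        spec = small_landscape["spec"]
        truth = vm.generate_true_model(8, spec, coefficient_scale=1.0, seed=2)
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {n: rng.normal(spec.means[n], spec.sds[n], size=100_000)
             for n in spec.predictor_names})
        design = vm.expand(spec, frame)
        field = vm.predict_probabilities(truth, design)
        assert np.abs(field.values.sum(axis=1) - 1.0).max() < 1e-9

    def test_evaluate_baselines_uniform(self, fitted_small):
        metrics = vm.evaluate(fitted_small["model"], fitted_small["design"],
                              fitted_small["vegmap"].labels.ravel())
        f = fitted_small["vegmap"].frequencies()
        assert metrics.baseline_random == pytest.approx(np.sum(f**2))
        assert metrics.baseline_majority == pytest.approx(f.max())
        assert metrics.baseline_majority >= metrics.baseline_random
        assert metrics.proportion_correct > metrics.baseline_random
        assert metrics.n_parameters == 3 * 36

    def test_uniform_frequencies_random_baseline(self):
        assert vm.random_assignment_baseline([0.25] * 4) == pytest.approx(0.25)
        assert vm.majority_baseline([0.25] * 4) == pytest.approx(0.25)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=30))
    def test_majority_dominates_random_baseline(self, weights):
        """max f >= sum f^2 for any frequency vector (Cauchy-Schwarz)."""
        assert vm.majority_baseline(weights) >= vm.random_assignment_baseline(weights) - 1e-12

    def test_model_json_roundtrip(self, fitted_small, tmp_path):
        model = fitted_small["model"]
        model.to_json(tmp_path / "m.json")
        back = vm.PVMModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.class_names == model.class_names
        p1 = model.probabilities(fitted_small["design"])
        p2 = back.probabilities(fitted_small["design"])
        np.testing.assert_array_equal(p1, p2)


class TestDropOne:
    def test_informative_predictor_outranks_null(self):
        """Removing a loaded predictor costs BIC; removing a null one pays."""
        cfg = vm.LandscapeConfig(grid_rows=80, grid_cols=80, n_types=3, seed=13,
                                 cross_correlation_targets=())
        env = vm.generate_environment(cfg)
        samples = env.samples(["jja", "wind"])
        spec = vm.build_spec(["jja", "wind"], samples)
        # truth loads on jja only; wind is pure noise
        coefs = np.zeros((2, spec.n_columns))
        coefs[0, 1] = 2.0
        coefs[1, 1] = -1.5
        truth = vm.PVMModel(coefs, ["a", "b", "c"], "a", spec)
        veg = vm.sample_vegetation(env, truth, seed=13)
        rows = vm.drop_one_importance(samples, veg.labels.ravel(), ["jja", "wind"])
        by_label = {r.model_label: r for r in rows}
        assert by_label["full"].delta_bic == 0.0
        assert by_label["-jja"].delta_bic > by_label["-wind"].delta_bic
        assert by_label["-wind"].delta_bic < 0

    def test_parameter_counts_follow_basis(self, small_landscape):
        env, vegmap = small_landscape["env"], small_landscape["vegmap"]
        rows = vm.drop_one_importance(
            env.samples(), vegmap.labels.ravel(), PREDICTOR_NAMES,
            vm.FitOptions(), climate_predictors=("jja", "djf", "ppt", "cwd"),
            fixed_predictors=("soil_depth", "wind", "march_radiation"))
        by_label = {r.model_label: r for r in rows}
        k1 = vegmap.n_classes - 1
        assert by_label["full"].n_parameters == 36 * k1
        for name in PREDICTOR_NAMES:
            assert by_label[f"-{name}"].n_parameters == 28 * k1
        assert by_label["climate only"].n_parameters == 15 * k1
        assert by_label["fixed only"].n_parameters == 10 * k1
        # rows between full and group rows are sorted by decreasing delta BIC
        dropped = [r.delta_bic for r in rows[1:8]]
        assert dropped == sorted(dropped, reverse=True)
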