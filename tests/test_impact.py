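"""Impact decomposition: Bray-Curtis, slopes, vulnerability, type responses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vegmosaic as vm
from vegmosaic.features import FeatureSpec
from vegmosaic.projection import ProbabilityField


def _field(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"c{i}" for i in range(values.shape[1])]
    return ProbabilityField(values=values, class_names=names)


class TestBrayCurtis:
    @pytest.mark.parametrize("x,y,expected", [
        ([0.3, 0.7], [0.3, 0.7], 0.0),
        ([1, 0], [0, 1], 1.0),
        ([0.5, 0.5], [1.0, 0.0], 0.5),
        ([0.5, 0.5], [0.9, 0.1], 0.4),
    ])
    def test_hand_cases(self, x, y, expected):
        assert vm.bray_curtis(x, y) == pytest.approx(expected)

    def test_degenerate_zero_vectors_warn(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert vm.bray_curtis([0, 0], [0, 0]) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            vm.bray_curtis([-0.1, 1.1], [0.5, 0.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=12),
           st.lists(st.floats(0, 10), min_size=2, max_size=12))
    def test_symmetry_and_bounds(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]) + 1e-6, np.array(y[:n]) + 1e-6
        d = vm.bray_curtis(x, y)
        assert d == pytest.approx(vm.bray_curtis(y, x))
        assert 0.0 <= d <= 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 10))
    def test_equals_half_l1_for_probability_vectors(self, seed, k):
        rng = np.random.default_rng(seed)
        p, q = rng.dirichlet(np.ones(k)), rng.dirichlet(np.ones(k))
        assert vm.bray_curtis(p, q) == pytest.approx(0.5 * np.abs(p - q).sum())


class TestPixelImpacts:
    def test_identity_and_disjoint(self):
        base = _field([[1, 0], [0, 1], [0.5, 0.5]])
        same = vm.pixel_impacts(base, [base])[0]
        np.testing.assert_allclose(same.values, 0.0)
        flipped = _field([[0, 1], [1, 0], [0.5, 0.5]])
        d = vm.pixel_impacts(base, [flipped])[0]
        np.testing.assert_allclose(d.values, [1.0, 1.0, 0.0])

    def test_rows_match_scalar_oracle(self):
        rng = np.random.default_rng(3)
        base = _field(rng.dirichlet(np.ones(5), size=30))
        fut = _field(rng.dirichlet(np.ones(5), size=30))
        d = vm.pixel_impacts(base, [fut])[0]
        expected = [vm.bray_curtis(base.values[i], fut.values[i]) for i in range(30)]
        np.testing.assert_allclose(d.values, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vm.pixel_impacts(_field(np.full((3, 2), 0.5)),
                             [_field(np.full((4, 2), 0.5))])


class TestSlopes:
    def test_exact_proportional_series(self):
        dt = np.array([1.0, 2.0, 3.0])
        fit = vm.sensitivity_slope(0.05 * dt, dt)
        assert fit.slope == pytest.approx(0.05)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_closed_form(self):
        fit = vm.sensitivity_slope([0.1, 0.3, 0.35], [1.0, 2.0, 4.0])
        assert fit.slope == pytest.approx(2.1 / 21)

    def test_zero_dissimilarity_gives_zero_slope(self):
        assert vm.sensitivity_slope([0, 0, 0], [1, 2, 3]).slope == 0.0

    def test_degenerate_warming_series_rejected(self):
        with pytest.raises(ValueError):
            vm.sensitivity_slope([0.1, 0.2], [0.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_grid_search_minimizer(self, seed):
        """Closed form agrees with brute-force least squares within 1e-6."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        dt = rng.uniform(0.5, 6, n)
        d = rng.uniform(0, 1, n)
        slope = vm.sensitivity_slope(d, dt).slope
        grid = np.linspace(-1, 1, 2001)
        for _ in range(3):
            sse = ((d[:, None] - grid[None, :] * dt[:, None]) ** 2).sum(axis=0)
            best = grid[np.argmin(sse)]
            width = grid[1] - grid[0]
            grid = np.linspace(best - width, best + width, 2001)
        assert abs(slope - best) < 1e-6

    def test_exposure_identity_and_scaling(self):
        reg = np.array([1.0, 2.0, 3.0])
        assert vm.exposure_slope(reg, reg).slope == pytest.approx(1.0)
        assert vm.exposure_slope(1.2 * reg, reg).slope == pytest.approx(1.2)


class TestVulnerability:
    def test_trivial_products(self):
        s = np.array([[0.2, 0.0], [0.1, 0.3]])
        np.testing.assert_array_equal(vm.vulnerability(s, np.ones_like(s)), s)
        np.testing.assert_array_equal(
            vm.vulnerability(np.zeros_like(s), s), np.zeros_like(s))
        assert vm.vulnerability(np.array([0.2]), np.array([1.1]))[0] == pytest.approx(0.22)

    def test_misaligned_rasters_rejected(self):
        with pytest.raises(ValueError):
            vm.vulnerability(np.ones((2, 2)), np.ones((3, 2)))


class TestDecomposition:
    def test_exposure_averages_to_one_and_spans_band(self, fitted_small, small_suite):
        model = fitted_small["model"]
        base = vm.project(model, fitted_small["env"])
        futures = [vm.project(model, s) for s in small_suite.scenarios]
        summary = vm.decompose_impacts(base, futures, small_suite)
        assert summary.exposure.mean() == pytest.approx(1.0, abs=1e-6)
        assert summary.exposure.min() >= 0.79 and summary.exposure.max() <= 1.21
        np.testing.assert_array_equal(summary.vulnerability,
                                      summary.sensitivity * summary.exposure)
        assert np.all(summary.sensitivity >= 0)

    def test_sensitivity_agrees_with_per_pixel_oracle(self, fitted_small, small_suite):
        model = fitted_small["model"]
        base = vm.project(model, fitted_small["env"])
        futures = [vm.project(model, s) for s in small_suite.scenarios]
        summary = vm.decompose_impacts(base, futures, small_suite)
        i = 1234  # arbitrary pixel
        d = [vm.bray_curtis(base.values[i], f.values[i]) for f in futures]
        dt = [vm.local_mat_change(small_suite.baseline, s).ravel()[i]
              for s in small_suite.scenarios]
        assert summary.sensitivity.ravel()[i] == pytest.approx(
            vm.sensitivity_slope(d, dt).slope)

    def test_regional_change_tracks_warming(self, fitted_small, small_suite):
        from scipy.stats import spearmanr

        model = fitted_small["model"]
        f0 = vm.frequency_vector(vm.project(model, fitted_small["env"]))
        changes = [vm.regional_change(f0, vm.frequency_vector(vm.project(model, s)))
                   for s in small_suite.scenarios]
        rho = spearmanr(changes, small_suite.delta_mat).statistic
        assert rho > 0.8

    def test_two_region_landscape_sensitivity_contrast(self):
        """Pixels at a steep class boundary are far more sensitive than
        pixels deep inside one class's climate envelope."""
        spec = FeatureSpec(("jja", "djf"), means={"jja": 16.0, "djf": 5.0},
                           sds={"jja": 2.0, "djf": 1.0})
        coefs = np.zeros((1, spec.n_columns))
        coefs[0, spec.column_names.index("jja")] = 8.0
        truth = vm.PVMModel(coefs, ["warm_shrub", "cool_forest"], "warm_shrub", spec)

        shape = (10, 20)
        jja = np.full(shape, 16.0)   # boundary region: logit 0
        jja[:, 10:] = 8.0            # stable region: logit -32
        base = vm.EnvironmentalStack(
            layers={"jja": jja, "djf": np.full(shape, 5.0)},
            elevation=np.zeros(shape), coast_distance=np.zeros(shape))
        scenarios = []
        for dt in [1.0, 2.0, 3.0, 4.0]:
            stack = vm.EnvironmentalStack(
                layers={"jja": jja + dt, "djf": np.full(shape, 5.0) + dt},
                elevation=base.elevation, coast_distance=base.coast_distance)
            scenarios.append(vm.ClimateScenario(
                label=f"+{dt}C", stack=stack, delta_mat=dt, delta_ppt_percent=0.0))
        suite = vm.ScenarioSuite(baseline=base, scenarios=scenarios,
                                 exposure_pattern=np.zeros(shape))
        base_field = vm.project(truth, base)
        futures = [vm.project(truth, s) for s in scenarios]
        summary = vm.decompose_impacts(base_field, futures, suite)
        flipping = summary.sensitivity[:, :10].mean()
        stable = summary.sensitivity[:, 10:].mean()
        assert flipping / stable > 3.0


class TestTypeResponse:
    def test_exact_linear_decline(self):
        t = np.linspace(0.69, 5.67, 20)
        p = np.zeros(20)
        resp = vm.type_response(0.3 - 0.02 * t, t, p, class_name="grass")
        assert resp.chosen_form == "linear"
        assert resp.direction == "decline"
        assert resp.coefficients["mat"] == pytest.approx(-0.02, abs=1e-10)

    def test_exponential_recovery_with_noise(self):
        rng = np.random.default_rng(17)
        t = np.linspace(0.69, 5.67, 54)
        p = rng.uniform(-23, 38, 54)
        f = 0.2 * np.exp(-0.9 * t) + rng.normal(0, 0.002, 54)
        resp = vm.type_response(np.clip(f, 0, None), t, p)
        assert resp.chosen_form == "exponential"
        assert resp.coefficients["b"] == pytest.approx(-0.9, abs=0.1)
        assert resp.direction == "decline"

    def test_interior_maximum_is_hump(self):
        t = np.linspace(0.69, 5.67, 30)
        f = 0.2 - 0.01 * (t - 2.0) ** 2
        resp = vm.type_response(f, t, np.zeros(30))
        assert resp.chosen_form == "quadratic"
        assert resp.direction == "hump"

    def test_constant_trajectory_is_flat(self):
        t = np.linspace(0.69, 5.67, 10)
        resp = vm.type_response(np.full(10, 0.125), t, np.zeros(10))
        assert resp.direction == "flat"

    def test_too_few_scenarios_rejected(self):
        with pytest.raises(ValueError):
            vm.type_response([0.1] * 4, [1, 2, 3, 4], [0, 0, 0, 0])


class TestWeightedLocation:
    def test_uniform_weights_give_plain_mean(self):
        field = _field(np.full((4, 2), 0.5))
        axis = np.array([10.0, 20.0, 30.0, 40.0])
        assert vm.weighted_location(field, axis, "c0") == pytest.approx(25.0)

    def test_point_mass_picks_single_pixel(self):
        vals = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        axis = np.array([7.0, 9.0, 11.0])
        assert vm.weighted_location(_field(vals), axis, "c0") == pytest.approx(7.0)

    def test_hand_weighted_mean(self):
        vals = np.column_stack([[0.2, 0.3, 0.5], [0.8, 0.7, 0.5]])
        axis = np.array([10.0, 20.0, 30.0])
        assert vm.weighted_location(_field(vals), axis, "c0") == pytest.approx(23.0)

    def test_zero_mass_class_rejected(self):
        vals = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="zero total probability"):
            vm.weighted_location(_field(vals), np.array([1.0, 2.0]), "c1")


class TestSensitivityCorrelates:
    def _predictors(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({k: rng.normal(size=n) for k in
                             ("djf", "ppt", "wind", "march_radiation")})

    def test_exact_linear_truth_recovered(self):
        x = self._predictors(500)
        y = 2.0 * x["djf"] - 1.0 * x["ppt"]
        report = vm.sensitivity_correlates(y.to_numpy(), x)
        assert report["r_squared"] == pytest.approx(1.0)
        assert report["coefficients"]["djf"] == pytest.approx(2.0, abs=1e-8)
        assert abs(report["coefficients"]["wind"]) < 1e-8

    def test_pure_noise_has_negligible_r2(self):
        x = self._predictors(10_000, seed=1)
        y = np.random.default_rng(2).normal(size=10_000)
        report = vm.sensitivity_correlates(y, x)
        assert report["r_squared"] < 0.01

    def test_dropping_null_predictor_barely_moves_r2(self):
        x = self._predictors(10_000, seed=3)
        rng = np.random.default_rng(4)
        y = 0.5 * x["djf"] + rng.normal(size=10_000)
        report = vm.sensitivity_correlates(y.to_numpy(), x, drop=["march_radiation"])
        assert abs(report["r_squared"] - report["r_squared_dropped"]) < 0.005

    def test_collinear_columns_named(self):
        x = self._predictors(100, seed=5)
        x["ppt"] = 2.0 * x["djf"]
        with pytest.raises(ValueError, match="collinear"):
            vm.sensitivity_correlates(np.ones(100), x)
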