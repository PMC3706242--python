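"""Objective function, pattern search, profile CIs and synthetic data."""

import numpy as np
import pytest
from scipy import stats

from celiacqsp import (
    CalibrationDataset,
    FitProblem,
    Observation,
    confidence_intervals,
    default_constraints,
    fit,
    hooke_jeeves,
    sse_objective,
    synth_observations,
)
from celiacqsp.calibration import evaluate_observations
from celiacqsp.parameters import Parameter, ParameterSet


# ---------------------------------------------------------------------------
# toy problems: free "parameters" drive a simple analytic predictor
# ---------------------------------------------------------------------------

def toy_problem(dataset, free, values, predictor, **settings):
    params = ParameterSet(
        [Parameter(n, v) for n, v in values.items()], expect_full=False)
    bounds = {n: (v / 100.0, v * 100.0) for n, v in values.items()}
    return FitProblem(dataset=dataset, params=params, free=free,
                      bounds=bounds, predictor=predictor, **settings)


def linear_predictor(xs):
    """y = a * x through the origin; 'a' is the free parameter."""

    def predict(p):
        return p["a"] * np.asarray(xs)

    return predict


class TestSseObjective:
    def test_single_observation_is_squared_residual(self):
        ds = CalibrationDataset([Observation("y", 3.0, weight=1.0)])
        prob = toy_problem(ds, ("a",), {"a": 5.0}, lambda p: [p["a"]])
        assert sse_objective(np.log10([5.0]), prob) == pytest.approx(4.0)

    def test_weighted_sum_matches_hand_computation(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0]
        ys = [1.1, 1.9, 3.2, 3.9, 5.3]
        ws = [1.0, 2.0, 1.0, 0.5, 1.0]
        ds = CalibrationDataset(
            [Observation("y", y, weight=w) for y, w in zip(ys, ws)])
        prob = toy_problem(ds, ("a",), {"a": 1.0}, linear_predictor(xs))
        expected = sum(w * (x - y) ** 2 for x, y, w in zip(xs, ys, ws))
        assert sse_objective(np.log10([1.0]), prob) == pytest.approx(
            expected, abs=1e-10)

    def test_zero_at_the_generating_parameters(self, params):
        design = [Observation("villous_area_pct", 0.0, diet="gluten"),
                  Observation("antibody_pct", 0.0, diet="gluten"),
                  Observation("IL15", 0.0, diet="gfd")]
        ds = synth_observations(params, design, noise_cv=0.0, seed=1)
        prob = FitProblem(dataset=ds, params=params, free=("k_deam",),
                          bounds={"k_deam": (1e-3, 1e3)})
        z0 = np.log10([params["k_deam"]])
        assert sse_objective(z0, prob) == pytest.approx(0.0, abs=1e-8)


class TestHookeJeeves:
    def test_quadratic_1d(self):
        x, f, n = hooke_jeeves(lambda z: (z[0] - 2.0) ** 2, np.array([0.0]),
                               step0=0.5, tol=1e-6)
        assert x[0] == pytest.approx(2.0, abs=1e-4)
        assert f < 1e-8

    def test_anisotropic_quadratic_2d(self):
        def f(z):
            return (z[0] - 1.0) ** 2 + 10.0 * (z[1] + 3.0) ** 2

        x, fv, _ = hooke_jeeves(f, np.array([0.0, 0.0]), step0=0.5, tol=1e-6)
        np.testing.assert_allclose(x, [1.0, -3.0], atol=1e-4)

    def test_rosenbrock_beats_random_search(self):
        def rosen(z):
            return (1 - z[0]) ** 2 + 100.0 * (z[1] - z[0] ** 2) ** 2

        lo, hi = np.array([-2.0, -1.0]), np.array([2.0, 3.0])
        x, f_hj, _ = hooke_jeeves(rosen, np.array([-1.2, 1.0]), step0=0.5,
                                  tol=1e-8, max_iter=5000, bounds=(lo, hi))
        rng = np.random.default_rng(0)
        samples = rng.uniform(lo, hi, size=(1_000_000, 2))
        f_rand = np.min((1 - samples[:, 0]) ** 2
                        + 100.0 * (samples[:, 1] - samples[:, 0] ** 2) ** 2)
        assert f_hj < f_rand

    def test_never_worse_than_start(self):
        rng = np.random.default_rng(5)

        def bumpy(z):
            return float(np.sum(z ** 2) + np.sin(5 * z).sum())

        for _ in range(5):
            x0 = rng.uniform(-2, 2, size=3)
            _, f_opt, _ = hooke_jeeves(bumpy, x0, step0=0.3, tol=1e-3,
                                       max_iter=200)
            assert f_opt <= bumpy(x0)

    def test_respects_bounds(self):
        lo, hi = np.array([0.5]), np.array([1.5])
        x, _, _ = hooke_jeeves(lambda z: (z[0] - 3.0) ** 2, np.array([1.0]),
                               step0=0.5, tol=1e-6, bounds=(lo, hi))
        assert x[0] == pytest.approx(1.5)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            hooke_jeeves(lambda z: 0.0, np.zeros(1), step0=-1.0)
        with pytest.raises(ValueError, match="finite"):
            hooke_jeeves(lambda z: np.nan, np.zeros(1))


class TestFit:
    def test_no_free_parameters_returns_initial(self, params):
        ds = default_constraints()
        prob = FitProblem(dataset=ds, params=params, free=(), bounds={})
        res = fit(prob)
        assert res.values == {}
        assert res.sse == res.sse_initial

    def test_recovers_perturbed_parameters_on_noiseless_data(self, params):
        """Self-consistency: data generated by the model, starts x1.5 off."""
        free = ("k_iec_death_if21", "k_il15_aiec")
        design = [
            Observation("villous_area_pct", 0.0, diet="gluten"),
            Observation("villous_area_pct", 0.0, diet="gfd"),
            Observation("IL15", 0.0, diet="gluten"),
            Observation("IF21", 0.0, diet="gluten"),
            Observation("antibody_pct", 0.0,
                        intervention=("il15_antibody", 1.0)),
        ]
        ds = synth_observations(params, design, noise_cv=0.0, seed=2)
        start = params.with_values(**{n: params[n] * 1.5 for n in free})
        prob = FitProblem(
            dataset=ds, params=start, free=free,
            bounds={n: (params[n] / 10, params[n] * 10) for n in free},
            step0=0.2, tol=1e-4, max_iter=60,
        )
        res = fit(prob)
        assert res.sse <= res.sse_initial
        for n in free:
            assert res.values[n] == pytest.approx(params[n], rel=0.05), n

    def test_constraint_set_is_satisfied_by_the_default_parameters(
            self, params):
        """The packaged set reproduces the calibration anchors (small SSE
        relative to the anchor magnitudes)."""
        ds = default_constraints()
        prob = FitProblem(dataset=ds, params=params, free=(), bounds={})
        res = fit(prob)
        assert res.sse < 200.0


class TestConfidenceIntervals:
    @staticmethod
    def _linear_fit_problem(n=10, sigma=0.5, seed=4):
        rng = np.random.default_rng(seed)
        xs = np.linspace(1.0, 5.0, n)
        a_true = 2.0
        ys = a_true * xs + sigma * rng.standard_normal(n)
        ds = CalibrationDataset([Observation("y", float(y)) for y in ys])
        prob = toy_problem(ds, ("a",), {"a": 1.0}, linear_predictor(xs),
                           tol=1e-7)
        return prob, xs, ys

    def test_matches_closed_form_linear_regression_ci(self):
        prob, xs, ys = self._linear_fit_problem()
        res = fit(prob)
        a_hat = res.values["a"]
        # closed form: a_hat = Sxy/Sxx, var = s^2/Sxx, t-based 95% CI
        sxx = np.sum(xs ** 2)
        assert a_hat == pytest.approx(np.sum(xs * ys) / sxx, rel=1e-4)
        dof = len(xs) - 1
        s2 = np.sum((ys - a_hat * xs) ** 2) / dof
        half = stats.t.ppf(0.975, dof) * np.sqrt(s2 / sxx)
        ci = confidence_intervals(prob, res)["a"]
        assert ci[0] == pytest.approx(a_hat - half, rel=0.05)
        assert ci[1] == pytest.approx(a_hat + half, rel=0.05)

    def test_zero_noise_interval_collapses(self):
        xs = np.linspace(1.0, 5.0, 10)
        ys = 2.0 * xs
        ds = CalibrationDataset([Observation("y", float(y)) for y in ys])
        prob = toy_problem(ds, ("a",), {"a": 1.5}, linear_predictor(xs),
                           tol=1e-9)
        res = fit(prob)
        lo, hi = confidence_intervals(prob, res, rtol=1e-6)["a"]
        assert (hi - lo) / res.values["a"] < 1e-3

    def test_uninfluential_parameter_spans_the_box(self):
        xs = np.linspace(1.0, 5.0, 8)
        ys = 2.0 * xs + 0.1

        def predict(p):
            return p["a"] * xs  # 'b' has no influence

        ds = CalibrationDataset([Observation("y", float(y)) for y in ys])
        prob = toy_problem(ds, ("a", "b"), {"a": 2.0, "b": 1.0}, predict)
        res = fit(prob)
        with pytest.warns(UserWarning, match="reached the search box"):
            ci = confidence_intervals(prob, res)
        lo, hi = ci["b"]
        assert lo == pytest.approx(prob.bounds["b"][0], rel=1e-6)
        assert hi == pytest.approx(prob.bounds["b"][1], rel=1e-6)

    def test_coverage_on_replicated_toy_problem(self):
        """95% profile CI should cover the truth in most replicates."""
        xs = np.linspace(1.0, 4.0, 12)
        a_true = 3.0
        rng = np.random.default_rng(99)
        covered = 0
        n_rep = 40
        for _ in range(n_rep):
            ys = a_true * xs * np.exp(
                np.sqrt(np.log(1 + 0.1 ** 2)) * rng.standard_normal(len(xs)))
            ds = CalibrationDataset([Observation("y", float(y)) for y in ys])
            prob = toy_problem(ds, ("a",), {"a": 1.0}, linear_predictor(xs),
                               tol=1e-6)
            res = fit(prob)
            lo, hi = confidence_intervals(prob, res)["a"]
            covered += lo <= a_true <= hi
        assert covered >= int(0.85 * n_rep)


class TestSynthObservations:
    def test_deterministic_per_seed(self, params):
        design = [Observation("antibody_pct", 0.0, diet="gluten"),
                  Observation("villous_area_pct", 0.0, diet="gfd")]
        a = synth_observations(params, design, noise_cv=0.2, seed=42)
        b = synth_observations(params, design, noise_cv=0.2, seed=42)
        assert [o.value for o in a] == [o.value for o in b]

    def test_noise_cv_matches_request(self, params):
        # 50 replicate measurements of one steady-state observable
        design = [Observation("villous_area_pct", 0.0, diet="gluten")] * 50
        ds = synth_observations(params, design, noise_cv=0.1, seed=7)
        values = np.array([o.value for o in ds])
        cv = values.std(ddof=1) / values.mean()
        assert 0.07 < cv < 0.13

    def test_negative_cv_rejected(self, params):
        with pytest.raises(ValueError):
            synth_observations(params, [], noise_cv=-0.1, seed=0)


class TestDatasetRoundTrip:
    def test_csv_frame_round_trip(self):
        ds = default_constraints(extended=True)
        df = ds.to_frame()
        back = CalibrationDataset.from_frame(df)
        assert back.to_frame().equals(df)

    def test_unresolvable_observable_is_reported(self, params):
        with pytest.raises(KeyError, match="no_such_readout"):
            evaluate_observations(
                params, [Observation("no_such_readout", 1.0)])
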