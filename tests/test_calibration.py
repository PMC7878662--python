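import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from prlstat5.calibrate import (
    CalibrationProblem,
    Chain,
    ExperimentalDataset,
    aic,
    default_fit_parameterization,
    default_timepoints,
    delta_aic,
    log_marginal_from_sse,
    mh_chain,
    run_fits,
    select_best,
)
from prlstat5.network import ConfigurationError, ModelStructure
from prlstat5.sensitivity import FitParameterization
from prlstat5.synth import generate_dataset

FULL = ModelStructure(True, True, True)


class TestDatasetLayout:
    def test_default_layout_has_37_points(self):
        df = default_timepoints()
        assert len(df) == 37
        counts = df["stream"].value_counts()
        assert counts["pJAK2"] == 6
        assert counts["pSTAT5A"] == 5  # 30-min anchor excluded
        assert counts["pSTAT5B"] == 5
        assert counts["ratioA"] == 5
        assert counts["ratioB"] == 9
        assert counts["bclxl"] == 7

    def test_unknown_stream_rejected(self):
        bad = pd.DataFrame({"stream": ["nope"], "time_min": [1.0], "value": [0.0]})
        with pytest.raises(ConfigurationError):
            ExperimentalDataset(bad)

    def test_csv_round_trip(self, tmp_path):
        df = default_timepoints()
        df["value"] = np.arange(len(df), dtype=float)
        ds = ExperimentalDataset(df)
        path = tmp_path / "obs.csv"
        ds.to_csv(path)
        back = ExperimentalDataset.read_csv(path)
        pd.testing.assert_frame_equal(ds.data, back.data)


@pytest.fixture(scope="module")
def toy_problem():
    """Full-structure problem on a noiseless synthetic dataset."""
    fit = default_fit_parameterization(FULL)
    synth = generate_dataset(fit.center_log10(), fit, FULL, noise=0.0, seed=0)
    return CalibrationProblem(synth.dataset, FULL, fit, alpha=1e-3, beta=1e-3), fit


class TestSSE:
    def test_zero_at_generating_parameters(self, toy_problem):
        prob, fit = toy_problem
        assert prob.sse(fit.center_log10()) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_shift_gives_n_c_squared(self, toy_problem):
        prob, fit = toy_problem
        shifted = prob.dataset.data.copy()
        shifted["value"] = shifted["value"] + 0.3
        prob2 = CalibrationProblem(
            ExperimentalDataset(shifted), FULL, fit, alpha=1e-3, beta=1e-3
        )
        assert prob2.sse(fit.center_log10()) == pytest.approx(37 * 0.3**2, rel=1e-9)

    def test_matches_residual_loop_oracle(self, toy_problem, rng):
        prob, fit = toy_problem
        theta = fit.center_log10() + rng.uniform(-0.2, 0.2, size=fit.k)
        pred = prob.predict(theta)
        manual = 0.0
        for i in range(prob.dataset.n):
            manual += (prob.dataset.values()[i] - pred[i]) ** 2
        assert prob.sse(theta) == pytest.approx(manual, rel=1e-12)

    def test_failed_integration_gives_infinite_sse(self, toy_problem):
        prob, fit = toy_problem
        assert prob.log_likelihood(float("inf")) == -math.inf


class TestMarginalLikelihood:
    def test_monotone_in_sse(self):
        assert log_marginal_from_sse(0.5, 37) > log_marginal_from_sse(0.8, 37)

    def test_symbolic_case(self):
        # alpha=1, beta=1, n=2: difference between SSE=0 and SSE=2 is -2*log(2)
        diff = log_marginal_from_sse(2.0, 2, 1.0, 1.0) - log_marginal_from_sse(0.0, 2, 1.0, 1.0)
        assert diff == pytest.approx(-2.0 * math.log(2.0), rel=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 40))
            sse = float(rng.uniform(0.01, 5.0))
            alpha = float(rng.uniform(0.5, 3.0))
            beta = float(rng.uniform(0.5, 3.0))
            u0 = math.log((beta + sse / 2) / (alpha + n / 2))
            u = np.linspace(u0 - 30, u0 + 30, 400001)
            s2 = np.exp(u)
            logf = (
                -(n / 2) * np.log(2 * np.pi * s2) - sse / (2 * s2)
                + alpha * math.log(beta) - math.lgamma(alpha)
                - (alpha + 1) * np.log(s2) - beta / s2 + u
            )
            val = np.trapezoid(np.exp(np.clip(logf, -700, None)), u)
            assert log_marginal_from_sse(sse, n, alpha, beta) == pytest.approx(
                math.log(val), abs=1e-8
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            log_marginal_from_sse(-1.0, 10)
        with pytest.raises(ConfigurationError):
            log_marginal_from_sse(1.0, 0)


class _AnalyticProblem:
    """Duck-typed 1-D stand-in with a closed-form SSE surface."""

    def __init__(self, sse_fn, lo=-2.0, hi=2.0, n=10, alpha=1.0, beta=1.0):
        self._sse = sse_fn
        self._lo, self._hi = np.array([lo]), np.array([hi])
        self.n, self.alpha, self.beta = n, alpha, beta
        self.d = 1

    def bounds(self):
        return self._lo, self._hi

    def in_support(self, theta):
        return bool(np.all(theta >= self._lo) and np.all(theta <= self._hi))

    def sample_prior(self, rng, n=1):
        out = rng.uniform(self._lo, self._hi, size=(n, 1))
        return out[0] if n == 1 else out

    def sse(self, theta):
        return float(self._sse(np.asarray(theta)))

    def log_likelihood(self, sse):
        return log_marginal_from_sse(sse, self.n, self.alpha, self.beta)


class TestMetropolisHastings:
    def test_flat_target_samples_prior_uniformly(self):
        prob = _AnalyticProblem(lambda th: 1.0)
        chain = mh_chain(prob, n_iter=6000, seed=11, step=0.6, n_retain=1000)
        draws = chain.retained()[:, 0]
        u = (draws + 2.0) / 4.0
        assert kstest(u[::5], "uniform").pvalue > 0.01

    def test_quadratic_toy_matches_grid_posterior(self):
        prob = _AnalyticProblem(lambda th: float(20.0 * (th[0] - 0.4) ** 2), n=20)
        chain = mh_chain(prob, n_iter=12000, seed=3, step=0.25, n_retain=2000)
        draws = chain.retained()[:, 0]
        edges = np.linspace(-2, 2, 41)
        grid = 0.5 * (edges[:-1] + edges[1:])
        logp = np.array([prob.log_likelihood(prob.sse([g])) for g in grid])
        p = np.exp(logp - logp.max())
        p /= p.sum()
        hist, _ = np.histogram(draws, bins=edges)
        q = hist / hist.sum()
        tv = 0.5 * np.abs(p - q).sum()
        assert tv < 0.1

    def test_fixed_seed_bit_identical(self):
        prob = _AnalyticProblem(lambda th: float(th[0] ** 2))
        a = mh_chain(prob, n_iter=300, seed=42, step=0.3)
        b = mh_chain(prob, n_iter=300, seed=42, step=0.3)
        assert np.array_equal(a.thetas, b.thetas)
        assert np.array_equal(a.accepted, b.accepted)

    def test_out_of_support_proposals_rejected(self):
        prob = _AnalyticProblem(lambda th: 0.0, lo=-0.05, hi=0.05)
        chain = mh_chain(prob, n_iter=500, seed=0, step=1.0)
        assert np.all(chain.thetas >= -0.05) and np.all(chain.thetas <= 0.05)


class TestRunFitsAndSelection:
    @staticmethod
    def _chain_with_sse(values, names=("x",)):
        n = len(values)
        return Chain(
            thetas=np.zeros((n, len(names))),
            sse=np.asarray(values, float),
            log_post=np.zeros(n),
            accepted=np.ones(n, bool),
            seed=0,
            names=list(names),
            n_retain=n,
        )

    def test_lowest_median_rule(self):
        chains = [self._chain_with_sse([m] * 10) for m in (0.7, 0.5, 0.9)]
        post = select_best(chains, FULL)
        assert post.median_sse() == pytest.approx(0.5)

    def test_second_lowest_rule(self):
        chains = [self._chain_with_sse([m] * 10) for m in (0.7, 0.5, 0.9)]
        post = select_best(chains, FULL, rule="second_lowest")
        assert post.median_sse() == pytest.approx(0.7)

    def test_single_chain_selects_itself(self):
        chains = [self._chain_with_sse([0.3] * 5)]
        assert select_best(chains, FULL).median_sse() == pytest.approx(0.3)

    def test_stability_screen_drops_drifting_chain(self):
        drifting = self._chain_with_sse(np.linspace(1.0, 0.0, 50))  # slope -0.02
        stable = self._chain_with_sse([0.6] * 50)
        post = select_best([drifting, stable], FULL, max_trend_slope=0.01)
        assert post.median_sse() == pytest.approx(0.6)

    def test_empty_chain_list_rejected(self):
        with pytest.raises(ConfigurationError):
            select_best([], FULL)

    def test_independent_chains_converge_on_toy(self):
        prob = _AnalyticProblem(lambda th: float(30.0 * (th[0] - 0.2) ** 2), n=20)
        chains = run_fits(prob, n_chains=2, n_iter=2000, seed=5, step=0.3)
        med = [np.median(c.retained()[:, 0]) for c in chains]
        assert abs(med[0] - med[1]) < 0.3
        again = run_fits(prob, n_chains=2, n_iter=2000, seed=5, step=0.3)
        assert np.array_equal(chains[0].thetas, again[0].thetas)


class TestAIC:
    def test_zero_when_sse_equals_n(self):
        assert aic(10.0, 10, 0) == pytest.approx(0.0)

    def test_parameter_penalty(self):
        assert aic(5.0, 37, 20) - aic(5.0, 37, 10) == pytest.approx(20.0)

    def test_delta_aic_from_published_values(self):
        # subtracting the minimum from {-79.85, -89.11, -81.25}
        deltas = delta_aic({"ab-": -79.85, "-bc": -89.11, "abc": -81.25})
        assert deltas["-bc"] == pytest.approx(0.0)
        assert deltas["ab-"] == pytest.approx(9.26, abs=1e-9)
        assert deltas["abc"] == pytest.approx(7.86, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            aic(0.0, 37, 33)
        with pytest.raises(ConfigurationError):
            aic(1.0, 0, 33)


class TestFitParameterization:
    def test_round_trip_exact(self):
        from prlstat5.network import default_parameters

        p = default_parameters(FULL).with_updates(k8B=0.123, k14B=0.456, k17B=0.007)
        factors = FitParameterization.rates_to_factors(p)
        rates = FitParameterization.factors_to_rates(factors, p)
        assert rates["k8B"] == pytest.approx(p["k8B"], rel=1e-15)
        assert rates["k14B"] == pytest.approx(p["k14B"], rel=1e-15)
        assert rates["k17B"] == pytest.approx(p["k17B"], rel=1e-15)

    def test_mult_expansion_uses_fitted_base_rate(self):
        from prlstat5.network import default_initial_values, default_parameters

        params = default_parameters(FULL)
        init = default_initial_values(FULL)
        fit = FitParameterization(
            ["k8A", "mult8B"], {"k8A": params["k8A"], "mult8B": 1.0}
        )
        new_p, _ = fit.to_model_values(np.array([0.01, 4.0]), params, init)
        assert new_p["k8B"] == pytest.approx(0.04)
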