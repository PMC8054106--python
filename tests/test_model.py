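"""Model core: noise model, densities vs dense oracles, sampler behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import multivariate_normal

from prevsmooth import (
    McmcConfig,
    ModelParams,
    RegionGraph,
    SpatioTemporalGPR,
    build_ar1_correlation,
    build_car_correlation,
    kron_covariance,
    log_likelihood,
    log_prior,
    noise_variance,
    predict_surface,
)
from prevsmooth.model import _car_factor, _ar1_factor, _field_logpdf_parts
from prevsmooth.survey import assemble_dataset

from conftest import random_connected_graph

LOG2PI = math.log(2 * math.pi)


def obs_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["survey_id", "region_id", "year", "q", "n_eff", "y_logit", "v_floor"],
    )


def params(**kw):
    base = dict(alpha=0.0, sigma2=1.0, rho_s=0.5, phi=0.5, tau2=1.0)
    base.update(kw)
    return ModelParams(**base)


class TestNoiseVariance:
    def test_log_e_units(self):
        assert noise_variance(math.e, 1.0) == pytest.approx(1.0)
        assert noise_variance(math.e**2, 2.0) == pytest.approx(1.0)

    def test_strictly_decreasing_in_n(self):
        assert noise_variance(1000, 2.0) < noise_variance(100, 2.0)

    @pytest.mark.parametrize("n", [0.5, 1.0])
    def test_domain_error(self, n):
        with pytest.raises(ValueError, match="n_eff"):
            noise_variance(n, 1.0)


class TestLogLikelihood:
    def graph(self):
        return RegionGraph.from_edge_list([("A", "B")])

    def test_standard_normal_at_mean(self):
        # y equals alpha + S exactly and unit noise variance
        g = self.graph()
        p = params(alpha=0.3, tau2=1.0)
        S = np.array([[0.7], [0.0]])
        data = assemble_dataset(
            obs_frame([("s", "A", 2000, 0.5, math.e, 1.0, False)]), g, [2000, 2000]
        )
        ll = log_likelihood(p, S, data)
        assert ll == pytest.approx(-0.5 * LOG2PI)

    def test_matches_dense_mvn_oracle_multiple_obs_per_cell(self):
        g = self.graph()
        p = params(alpha=-0.2, tau2=1.7)
        years = range(2000, 2003)
        rng = np.random.default_rng(5)
        S = rng.standard_normal((2, 3))
        rows = [
            ("s1", "A", 2001, 0.4, 50.0, -0.3, False),
            ("s2", "A", 2001, 0.5, 200.0, 0.1, False),
            ("s1", "B", 2002, 0.3, 80.0, -0.8, False),
        ]
        data = assemble_dataset(obs_frame(rows), g, years)
        ll = log_likelihood(p, S, data)
        # oracle: independent normals evaluated via a diagonal MVN
        mean = np.array(
            [p.alpha + S[0, 1], p.alpha + S[0, 1], p.alpha + S[1, 2]]
        )
        var = np.array(
            [noise_variance(n, p.tau2) for n in (50.0, 200.0, 80.0)]
        )
        oracle = multivariate_normal(mean=mean, cov=np.diag(var)).logpdf(
            [-0.3, 0.1, -0.8]
        )
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_empty_dataset_contributes_zero(self):
        g = self.graph()
        data = assemble_dataset(obs_frame([]), g, range(2000, 2003))
        assert log_likelihood(params(), np.zeros((2, 3)), data) == 0.0

    def test_dimension_mismatch_rejected(self):
        g = self.graph()
        data = assemble_dataset(obs_frame([]), g, range(2000, 2003))
        with pytest.raises(ValueError, match="field shape"):
            log_likelihood(params(), np.zeros((3, 2)), data)


class TestFieldPrior:
    def test_zero_field_reduces_to_normalising_constant(self):
        rng = np.random.default_rng(2)
        g = random_connected_graph(rng, 3)
        p = params(sigma2=2.0, rho_s=0.7, phi=0.3)
        T = 2
        Qs, ld_s = _car_factor(g, p.rho_s)
        Qt, ld_t = _ar1_factor(T, p.phi)
        got = _field_logpdf_parts(np.zeros((3, T)), Qs, ld_s, Qt, ld_t, p.sigma2)
        cov = kron_covariance(
            build_car_correlation(g, p.rho_s),
            build_ar1_correlation(T, p.phi),
            p.sigma2,
        )
        expected = -0.5 * (np.linalg.slogdet(cov)[1] + 6 * LOG2PI)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_kronecker_path_matches_dense_mvn_oracle(self):
        # random K, T with K*T <= 64; tolerance 1e-8
        rng = np.random.default_rng(9)
        for _ in range(50):
            K = int(rng.integers(2, 9))
            T = int(rng.integers(1, 64 // K + 1))
            g = random_connected_graph(rng, K)
            p = params(
                sigma2=float(rng.uniform(0.3, 3.0)),
                rho_s=float(rng.uniform(0.05, 0.95)),
                phi=float(rng.uniform(-0.9, 0.9)),
            )
            S = rng.standard_normal((K, T))
            Qs, ld_s = _car_factor(g, p.rho_s)
            Qt, ld_t = _ar1_factor(T, p.phi)
            got = _field_logpdf_parts(S, Qs, ld_s, Qt, ld_t, p.sigma2)
            cov = kron_covariance(
                build_car_correlation(g, p.rho_s),
                build_ar1_correlation(T, p.phi),
                p.sigma2,
            )
            oracle = multivariate_normal(
                mean=np.zeros(K * T), cov=cov
            ).logpdf(S.ravel())
            assert got == pytest.approx(oracle, abs=1e-8)

    def test_doubling_sigma2_shifts_zero_field_density(self):
        rng = np.random.default_rng(4)
        g = random_connected_graph(rng, 4)
        T = 3
        Qs, ld_s = _car_factor(g, 0.6)
        Qt, ld_t = _ar1_factor(T, 0.4)
        z = np.zeros((4, T))
        lp1 = _field_logpdf_parts(z, Qs, ld_s, Qt, ld_t, 1.0)
        lp2 = _field_logpdf_parts(z, Qs, ld_s, Qt, ld_t, 2.0)
        assert lp1 - lp2 == pytest.approx(0.5 * 4 * T * math.log(2.0))

    def test_log_prior_includes_finite_hyperprior_terms(self):
        rng = np.random.default_rng(6)
        g = random_connected_graph(rng, 3)
        lp = log_prior(params(), np.zeros((3, 4)), g, range(2000, 2004))
        assert np.isfinite(lp)


class TestMcmcConfig:
    def test_default_retains_ten_thousand(self):
        assert McmcConfig().n_retained == 10_000

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError, match="positive integer"):
            McmcConfig(n_iter=1005, burn_in=1000, thin=10)
        with pytest.raises(ValueError, match="positive integer"):
            McmcConfig(n_iter=1000, burn_in=1000, thin=10)


class TestSampler:
    def small_data(self, seed=0):
        g = RegionGraph.from_edge_list([("A", "B"), ("B", "C")])
        rng = np.random.default_rng(seed)
        rows = []
        for region in ("A", "B", "C"):
            for year in (2000, 2001, 2002):
                q = float(rng.uniform(0.2, 0.8))
                rows.append(
                    ("s", region, year, q, 200.0, math.log(q / (1 - q)), False)
                )
        return assemble_dataset(obs_frame(rows), g, range(2000, 2003))

    def fit(self, data, **kw):
        defaults = dict(n_iter=600, burn_in=100, thin=5, seed=3)
        defaults.update(kw)
        return SpatioTemporalGPR(**defaults).fit(data)

    def test_same_seed_identical_draws(self):
        data = self.small_data()
        a = self.fit(data).draws_
        b = self.fit(data).draws_
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])

    def test_retention_count(self):
        est = self.fit(self.small_data(), n_iter=700, burn_in=100, thin=3)
        assert est.draws_["alpha"].shape == (200,)
        assert est.draws_["field"].shape == (200, 3, 3)

    def test_prior_predictive_runs_on_empty_dataset(self):
        g = RegionGraph.from_edge_list([("A", "B")])
        data = assemble_dataset(obs_frame([]), g, range(2000, 2002))
        est = self.fit(data)
        s = est.surface_
        assert np.all((s.lo95 > 0) & (s.hi95 < 1))

    def test_unobserved_region_gets_finite_interval(self):
        g = RegionGraph.from_edge_list([("A", "B"), ("B", "C")])
        rows = [
            ("s", "A", 2000, 0.3, 300.0, math.log(0.3 / 0.7), False),
            ("s", "B", 2001, 0.4, 300.0, math.log(0.4 / 0.6), False),
        ]
        data = assemble_dataset(obs_frame(rows), g, range(2000, 2002))
        est = self.fit(data)
        m, lo, hi = est.surface_.at("C", 2001)
        assert 0.0 < lo <= m <= hi < 1.0

    def test_shrinkage_widens_interval_when_n_eff_drops(self):
        g = RegionGraph.from_edge_list([("A", "B"), ("B", "C")])
        fixed = ModelParams(alpha=0.0, sigma2=1.0, rho_s=0.5, phi=0.5, tau2=1.0)

        def width(n_eff):
            rows = [("s", "A", 2000, 0.3, n_eff, math.log(0.3 / 0.7), False)]
            data = assemble_dataset(obs_frame(rows), g, range(2000, 2002))
            est = SpatioTemporalGPR(
                n_iter=4100,
                burn_in=100,
                thin=2,
                seed=8,
                init_params=fixed,
                sample_alpha=False,
                sample_hyperparams=False,
            ).fit(data)
            _, lo, hi = est.surface_.at("A", 2000)
            return hi - lo

        assert width(5.0) > width(5000.0)

    def test_posterior_mean_tracks_pooled_estimate_at_high_n_eff(self):
        # shrinkage vanishes as n_eff grows: conjugate-limit check
        g = RegionGraph.from_edge_list([("A", "B")])
        q = 0.37
        rows = [
            (f"s{i}", "A", 2000, q, 1e6, math.log(q / (1 - q)), False)
            for i in range(30)
        ]
        data = assemble_dataset(obs_frame(rows), g, [2000, 2000])
        fixed = ModelParams(alpha=0.0, sigma2=1.0, rho_s=0.5, phi=0.5, tau2=1.0)
        est = SpatioTemporalGPR(
            n_iter=4100,
            burn_in=100,
            thin=2,
            seed=8,
            init_params=fixed,
            sample_alpha=False,
            sample_hyperparams=False,
        ).fit(data)
        assert est.surface_.at("A", 2000)[0] == pytest.approx(q, abs=0.005)

    def test_single_cell_posterior_matches_conjugate_closed_form(self):
        # fixed hyperparameters: the latent-cell posterior is exactly normal
        g = RegionGraph.from_edge_list([("A", "B")])
        p = ModelParams(alpha=0.4, sigma2=0.8, rho_s=0.5, phi=0.5, tau2=1.2)
        y, n_eff = 0.9, 150.0
        rows = [("s", "A", 2000, expit(y), n_eff, y, False)]
        data = assemble_dataset(obs_frame(rows), g, [2000, 2000])
        est = SpatioTemporalGPR(
            n_iter=10_100,
            burn_in=100,
            thin=1,
            seed=12,
            init_params=p,
            sample_alpha=False,
            sample_hyperparams=False,
        ).fit(data)
        draws = est.draws_["alpha"] + est.draws_["field"][:, 0, 0]

        # closed form on the 2-region latent vector, observation on A
        R = build_car_correlation(g, p.rho_s).values
        prior_prec = np.linalg.inv(p.sigma2 * R)
        w = math.log(n_eff) / p.tau2
        post_prec = prior_prec + np.diag([w, 0.0])
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ np.array([w * (y - p.alpha), 0.0])
        mu = p.alpha + post_mean[0]
        sd = math.sqrt(post_cov[0, 0])

        M = len(draws)
        se_mean = sd / math.sqrt(M)
        assert abs(draws.mean() - mu) < 3 * se_mean
        se_sd = sd / math.sqrt(2 * (M - 1))
        assert abs(draws.std(ddof=1) - sd) < 3 * se_sd

    def test_predict_requires_fit(self):
        with pytest.raises(RuntimeError, match="fit"):
            SpatioTemporalGPR().predict()

    def test_predict_at_cells(self):
        est = self.fit(self.small_data())
        q = est.predict(pd.DataFrame({"region_id": ["A", "C"], "year": [2000, 2002]}))
        assert q[0] == pytest.approx(est.surface_.at("A", 2000)[0])
        assert q[1] == pytest.approx(est.surface_.at("C", 2002)[0])

    def test_get_params_round_trip(self):
        est = SpatioTemporalGPR(n_iter=500, burn_in=100, thin=4, seed=7)
        clone = SpatioTemporalGPR(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestPredictSurface:
    def test_zero_draws_give_half_everywhere(self):
        draws = {"alpha": np.zeros(10), "field": np.zeros((10, 2, 3))}
        s = predict_surface(draws, ("A", "B"), (2000, 2001, 2002))
        assert np.all(s.mean == 0.5)
        assert np.all(s.lo95 == 0.5)

    def test_summary_ordering_and_range(self):
        rng = np.random.default_rng(1)
        draws = {
            "alpha": rng.standard_normal(500),
            "field": rng.standard_normal((500, 3, 2)),
        }
        s = predict_surface(draws, ("A", "B", "C"), (2000, 2001))
        assert np.all((s.draws > 0) & (s.draws < 1))
        assert np.all(s.lo95 <= s.mean) and np.all(s.mean <= s.hi95)

    def test_empty_store_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            predict_surface(
                {"alpha": np.empty(0), "field": np.empty((0, 1, 1))}, ("A",), (2000,)
            )
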