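"""Bayesian spatio-temporal Gaussian-process smoothing of survey prevalence.

The model places the empirical-logit observations ``y_ikt`` for survey i,
region k and year t around a latent surface::

    y_ikt = alpha + S_kt + Z_ikt
    S     ~ MVN(0, sigma2 * (R_S kron R_T))
    Z_ikt ~ N(0, tau2 / log(n_eff_ikt))

with ``R_S`` a proper-CAR correlation on the region graph and ``R_T`` an
AR(1) correlation over years.  Observation noise shrinks as the
effective sample size grows, so sparse, small surveys are smoothed
harder than censuses.  Prevalence is reported as the posterior of
``expit(alpha + S_kt)`` on the probability scale for every cell,
including region-years no survey covered.

Inference is Metropolis-within-Gibbs: the latent field has a Gaussian
full conditional (sampled exactly by a Cholesky solve, with the prior
precision assembled from the Kronecker factors), the intercept is a
conjugate Gibbs draw, and the four hyperparameters move by random-walk
Metropolis on unconstrained transforms with proposal scales adapted
during burn-in only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit
from sklearn.base import BaseEstimator

from .graph import RegionGraph, ar1_correlation_inverse, car_correlation_inverse
from .survey import FactorDataset

__all__ = [
    "ModelParams",
    "Priors",
    "McmcConfig",
    "PosteriorSurface",
    "SpatioTemporalGPR",
    "noise_variance",
    "log_likelihood",
    "log_prior",
    "mcmc_fit",
    "predict_surface",
]

LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelParams:
    """Hyperparameters of the smoothing model (logit scale).

    alpha  : intercept.
    sigma2 : marginal variance of the latent field (logit^2 units).
    rho_s  : proper-CAR spatial dependence, in (0, 1).
    phi    : AR(1) temporal coefficient, in (-1, 1).
    tau2   : noise scale; an observation with effective sample size n
             has variance tau2 / log(n).
    """

    alpha: float
    sigma2: float
    rho_s: float
    phi: float
    tau2: float

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if self.tau2 <= 0:
            raise ValueError(f"tau2 must be positive, got {self.tau2}")
        if not 0.0 < self.rho_s < 1.0:
            raise ValueError(f"rho_s must be in (0, 1), got {self.rho_s}")
        if not -1.0 < self.phi < 1.0:
            raise ValueError(f"phi must be in (-1, 1), got {self.phi}")


@dataclass(frozen=True)
class Priors:
    """Weakly informative hyperpriors on the logit scale.

    alpha ~ Normal(0, alpha_sd^2); the field and noise standard
    deviations sqrt(sigma2), sqrt(tau2) ~ Half-Normal(scale); rho_s
    uniform on (0, 1); phi uniform on (-1, 1).
    """

    alpha_sd: float = 10.0
    sigma_sd: float = 5.0
    tau_sd: float = 5.0


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    Defaults follow the production schedule: 110 000 iterations, the
    first 10 000 discarded as burn-in, every 10th kept thereafter, for
    10 000 retained posterior draws.
    """

    n_iter: int = 110_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    proposal_scales: dict = field(
        default_factory=lambda: {
            "sigma2": 0.3,
            "tau2": 0.3,
            "rho_s": 0.8,
            "phi": 0.3,
        }
    )
    sample_alpha: bool = True
    sample_hyperparams: bool = True
    adapt: bool = True

    def __post_init__(self):
        n_keep, rem = divmod(self.n_iter - self.burn_in, self.thin)
        if n_keep <= 0 or rem != 0:
            raise ValueError(
                "(n_iter - burn_in) / thin must be a positive integer, got "
                f"({self.n_iter} - {self.burn_in}) / {self.thin}"
            )

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass(frozen=True)
class PosteriorSurface:
    """Posterior prevalence draws and summaries per (region, year)."""

    region_ids: tuple
    years: tuple
    draws: np.ndarray  # (n_draws, K, T), probability scale
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray

    def at(self, region_id, year):
        """(mean, lo95, hi95) for one cell."""
        k = self.region_ids.index(region_id)
        t = self.years.index(year)
        return self.mean[k, t], self.lo95[k, t], self.hi95[k, t]

    def cell_draws(self, region_id, year) -> np.ndarray:
        k = self.region_ids.index(region_id)
        t = self.years.index(year)
        return self.draws[:, k, t]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, r in enumerate(self.region_ids):
            for t, y in enumerate(self.years):
                rows.append(
                    (r, y, self.mean[k, t], self.lo95[k, t], self.hi95[k, t])
                )
        return pd.DataFrame(
            rows, columns=["region_id", "year", "mean", "lo95", "hi95"]
        )


def noise_variance(n_eff: float, tau2: float) -> float:
    """Observation noise variance ``tau2 / log(n_eff)``.

    Precision grows with the log of the effective sample size, so large
    surveys pin the surface down while tiny ones are shrunk toward it.
    """
    if tau2 <= 0:
        raise ValueError(f"tau2 must be positive, got {tau2}")
    if n_eff <= 1.0:
        raise ValueError(
            f"n_eff must exceed 1 (log(n_eff) must be positive), got {n_eff}"
        )
    return tau2 / math.log(n_eff)


# ----------------------------------------------------------------------
# density pieces


def _car_factor(graph: RegionGraph, rho_s: float):
    """(precision of the CAR correlation, its log-determinant's negative).

    Returns (Q_S, logdet R_S) where Q_S = R_S^{-1}.
    """
    Q = car_correlation_inverse(graph, rho_s)
    sign, ld = np.linalg.slogdet(Q)
    if sign <= 0:
        raise np.linalg.LinAlgError("CAR precision not positive definite")
    return Q, -ld


def _ar1_factor(n_years: int, phi: float):
    Q = ar1_correlation_inverse(n_years, phi)
    ld = (n_years - 1) * math.log1p(-phi * phi)
    return Q, ld


def _field_logpdf_parts(S: np.ndarray, Qs, ld_s, Qt, ld_t, sigma2: float):
    """Log MVN(0, sigma2 * (R_S kron R_T)) density of the K x T field.

    Uses the Kronecker identities logdet = KT log sigma2 + T logdet R_S
    + K logdet R_T and quad = tr(Q_S S Q_T S') / sigma2; never forms the
    KT x KT covariance.
    """
    K, T = S.shape
    logdet = K * T * math.log(sigma2) + T * ld_s + K * ld_t
    quad = float(((Qs @ S) @ Qt * S).sum()) / sigma2
    return -0.5 * (K * T * LOG2PI + logdet + quad)


def log_likelihood(
    params: ModelParams, field_values: np.ndarray, data: FactorDataset
) -> float:
    """Gaussian log-likelihood of the empirical-logit observations.

    Observations sharing a (region, year) cell share the same latent
    value; each contributes a normal term with its own
    ``tau2 / log(n_eff)`` variance.  An empty dataset contributes 0.
    """
    S = np.asarray(field_values, dtype=float)
    if S.shape != (data.n_regions, data.n_years):
        raise ValueError(
            f"field shape {S.shape} does not match dataset "
            f"({data.n_regions}, {data.n_years})"
        )
    if data.n_obs == 0:
        return 0.0
    obs = data.observations
    y = obs["y_logit"].to_numpy(dtype=float)
    n_eff = obs["n_eff"].to_numpy(dtype=float)
    if np.any(n_eff <= 1.0):
        raise ValueError("all n_eff must exceed 1")
    w = np.log(n_eff)  # per-observation precision multiplier
    r = y - params.alpha - S[obs["k"].to_numpy(), obs["t"].to_numpy()]
    v = params.tau2 / w
    return float(-0.5 * np.sum(LOG2PI + np.log(v) + r * r / v))


def log_prior(
    params: ModelParams,
    field_values: np.ndarray,
    graph: RegionGraph,
    years,
    priors: Priors = Priors(),
) -> float:
    """Log prior density: MVN field term plus hyperprior terms."""
    S = np.asarray(field_values, dtype=float)
    T = len(tuple(years))
    Qs, ld_s = _car_factor(graph, params.rho_s)
    Qt, ld_t = _ar1_factor(T, params.phi)
    lp = _field_logpdf_parts(S, Qs, ld_s, Qt, ld_t, params.sigma2)
    lp += -0.5 * (params.alpha / priors.alpha_sd) ** 2 - math.log(
        priors.alpha_sd
    ) - 0.5 * LOG2PI
    for var, sd in ((params.sigma2, priors.sigma_sd), (params.tau2, priors.tau_sd)):
        s = math.sqrt(var)
        # half-normal on the SD scale, including the SD->variance Jacobian
        lp += (
            0.5 * math.log(2.0 / math.pi)
            - math.log(sd)
            - 0.5 * (s / sd) ** 2
            - math.log(2.0 * s)
        )
    # rho_s ~ U(0,1), phi ~ U(-1,1)
    lp += -math.log(2.0)
    return float(lp)


# ----------------------------------------------------------------------
# the estimator


class SpatioTemporalGPR(BaseEstimator):
    """Spatio-temporal Gaussian-process smoother for survey prevalence.

    scikit-learn-style estimator: configure in the constructor, call
    :meth:`fit` on a :class:`~prevsmooth.survey.FactorDataset` (or an
    observation table plus ``graph``/``years``), then read the posterior
    from ``surface_`` or :meth:`predict`.

    Parameters
    ----------
    n_iter, burn_in, thin : int
        MCMC schedule; defaults 110000 / 10000 / 10 retain 10 000 draws.
    seed : int
        Seed for the sampler's generator; runs are reproducible.
    priors : Priors
    init_params : ModelParams or None
        Starting state; also the fixed values for any block whose
        sampling is switched off.
    sample_alpha, sample_hyperparams : bool
        Switch off to hold the intercept / hyperparameters at their
        initial values (used for conjugate checks and debugging).
    proposal_scales : dict or None
        Initial random-walk scales on the transformed axes; adapted
        during burn-in toward standard scalar acceptance (0.44) and
        frozen afterwards.
    adapt : bool
        Disable to keep proposal scales fixed throughout.

    Attributes
    ----------
    draws_ : dict of arrays
        ``alpha, sigma2, rho_s, phi, tau2`` of shape (M,) and ``field``
        of shape (M, K, T) on the logit scale.
    surface_ : PosteriorSurface
        Posterior prevalence per (region, year), probability scale.
    acceptance_rates_ : dict
        Post-burn-in Metropolis acceptance rate per hyperparameter.
    params_mean_, params_sd_ : dict
        Posterior means / SDs of the scalar parameters.
    """

    def __init__(
        self,
        n_iter: int = 110_000,
        burn_in: int = 10_000,
        thin: int = 10,
        seed: int = 0,
        priors: Priors = Priors(),
        init_params: ModelParams | None = None,
        sample_alpha: bool = True,
        sample_hyperparams: bool = True,
        proposal_scales: dict | None = None,
        adapt: bool = True,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.priors = priors
        self.init_params = init_params
        self.sample_alpha = sample_alpha
        self.sample_hyperparams = sample_hyperparams
        self.proposal_scales = proposal_scales
        self.adapt = adapt

    # -- fitting -------------------------------------------------------

    def _config(self) -> McmcConfig:
        cfg = McmcConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            sample_alpha=self.sample_alpha,
            sample_hyperparams=self.sample_hyperparams,
            adapt=self.adapt,
        )
        if self.proposal_scales:
            cfg = replace(
                cfg,
                proposal_scales={**cfg.proposal_scales, **self.proposal_scales},
            )
        return cfg

    def fit(self, X, y=None, graph: RegionGraph = None, years=None):
        """Run the sampler.

        ``X`` is a :class:`FactorDataset`, or an observation DataFrame
        in which case ``graph`` and ``years`` must be given.
        """
        if isinstance(X, FactorDataset):
            data = X
        else:
            if graph is None or years is None:
                raise ValueError(
                    "graph and years are required when X is not a FactorDataset"
                )
            data = FactorDataset(X, graph, years)
        cfg = self._config()
        self.dataset_ = data
        self.draws_, self.acceptance_rates_ = _run_mcmc(
            data, cfg, self.priors, self.init_params
        )
        self.params_mean_ = {
            p: float(self.draws_[p].mean())
            for p in ("alpha", "sigma2", "rho_s", "phi", "tau2")
        }
        self.params_sd_ = {
            p: float(self.draws_[p].std(ddof=1))
            for p in ("alpha", "sigma2", "rho_s", "phi", "tau2")
        }
        self.surface_ = predict_surface(
            self.draws_, data.graph.region_ids, data.years
        )
        return self

    # -- prediction ----------------------------------------------------

    def predict(self, X=None) -> np.ndarray:
        """Posterior-mean prevalence.

        With ``X=None`` returns the full K x T surface; with a DataFrame
        carrying ``region_id`` and ``year`` columns returns one value
        per row.
        """
        if not hasattr(self, "surface_"):
            raise RuntimeError("call fit before predict")
        if X is None:
            return self.surface_.mean
        out = np.empty(len(X), dtype=float)
        for i, (r, yr) in enumerate(zip(X["region_id"], X["year"])):
            out[i] = self.surface_.at(r, int(yr))[0]
        return out


def _run_mcmc(data: FactorDataset, cfg: McmcConfig, priors: Priors, init):
    rng = np.random.default_rng(cfg.seed)
    K, T = data.n_regions, data.n_years
    graph = data.graph
    obs = data.observations

    if data.n_obs:
        y = obs["y_logit"].to_numpy(dtype=float)
        n_eff = obs["n_eff"].to_numpy(dtype=float)
        if np.any(n_eff <= 1.0):
            raise ValueError("all n_eff must exceed 1 for the noise model")
        w = np.log(n_eff)
        ki = obs["k"].to_numpy()
        ti = obs["t"].to_numpy()
        sum_w = np.zeros((K, T))
        sum_wy = np.zeros((K, T))
        np.add.at(sum_w, (ki, ti), w)
        np.add.at(sum_wy, (ki, ti), w * y)
        n_obs = len(y)
        sum_log_w = float(np.log(w).sum())
        y_mean = float(np.average(y, weights=w))
    else:
        y = w = ki = ti = None
        sum_w = np.zeros((K, T))
        sum_wy = np.zeros((K, T))
        n_obs = 0
        sum_log_w = 0.0
        y_mean = 0.0

    if init is None:
        init = ModelParams(alpha=y_mean, sigma2=1.0, rho_s=0.5, phi=0.5, tau2=1.0)
    alpha = init.alpha
    sigma2, rho_s, phi, tau2 = init.sigma2, init.rho_s, init.phi, init.tau2
    S = np.zeros((K, T))

    Qs, ld_s = _car_factor(graph, rho_s)
    Qt, ld_t = _ar1_factor(T, phi)

    def weighted_ssr(alpha_, S_):
        if n_obs == 0:
            return 0.0
        r = y - alpha_ - S_[ki, ti]
        return float(np.sum(w * r * r))

    def loglik_tau(tau2_, ssr):
        if n_obs == 0:
            return 0.0
        return -0.5 * (
            n_obs * (LOG2PI + math.log(tau2_)) - sum_log_w + ssr / tau2_
        )

    def halfnormal_lp(var, sd):
        s = math.sqrt(var)
        return -0.5 * (s / sd) ** 2 - math.log(2.0 * s)

    # transformed-scale proposal state
    names = ("sigma2", "tau2", "rho_s", "phi")
    log_scale = {p: math.log(cfg.proposal_scales[p]) for p in names}
    acc_post = {p: 0 for p in names}
    n_post = 0
    target_acc = 0.44

    M = cfg.n_retained
    out = {
        "alpha": np.empty(M),
        "sigma2": np.empty(M),
        "rho_s": np.empty(M),
        "phi": np.empty(M),
        "tau2": np.empty(M),
        "field": np.empty((M, K, T)),
    }
    m = 0

    for it in range(1, cfg.n_iter + 1):
        # --- latent field: exact Gaussian conditional -----------------
        prior_prec = np.kron(Qs, Qt) / sigma2
        A = prior_prec + np.diag((sum_w / tau2).ravel())
        b = ((sum_wy - alpha * sum_w) / tau2).ravel()
        try:
            c, low = cho_factor(A, lower=True, check_finite=False)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise RuntimeError(
                f"latent-field conditional solve failed at iteration {it} "
                f"(sigma2={sigma2:.3g}, rho_s={rho_s:.3g}, phi={phi:.3g}): {err}"
            ) from err
        mean = cho_solve((c, low), b, check_finite=False)
        z = rng.standard_normal(K * T)
        S = (mean + solve_triangular(c, z, lower=True, trans="T", check_finite=False)).reshape(K, T)

        # --- intercept: conjugate Gibbs -------------------------------
        if cfg.sample_alpha:
            prior_prec_a = 1.0 / priors.alpha_sd**2
            if n_obs:
                like_prec = float(sum_w.sum()) / tau2
                resid_sum = float((sum_wy - S * sum_w).sum()) / tau2
            else:
                like_prec = 0.0
                resid_sum = 0.0
            post_prec = prior_prec_a + like_prec
            post_mean = resid_sum / post_prec
            alpha = post_mean + rng.standard_normal() / math.sqrt(post_prec)

        # --- hyperparameters: random-walk Metropolis ------------------
        if cfg.sample_hyperparams:
            ssr = weighted_ssr(alpha, S)

            # sigma2 (log transform)
            theta = math.log(sigma2)
            prop = theta + math.exp(log_scale["sigma2"]) * rng.standard_normal()
            sigma2_p = math.exp(prop)
            cur = (
                _field_logpdf_parts(S, Qs, ld_s, Qt, ld_t, sigma2)
                + halfnormal_lp(sigma2, priors.sigma_sd)
                + theta
            )
            new = (
                _field_logpdf_parts(S, Qs, ld_s, Qt, ld_t, sigma2_p)
                + halfnormal_lp(sigma2_p, priors.sigma_sd)
                + prop
            )
            acc = math.log(rng.random()) < new - cur
            if acc:
                sigma2 = sigma2_p
            _adapt(log_scale, acc_post, "sigma2", acc, it, cfg, target_acc)

            # tau2 (log transform)
            theta = math.log(tau2)
            prop = theta + math.exp(log_scale["tau2"]) * rng.standard_normal()
            tau2_p = math.exp(prop)
            cur = loglik_tau(tau2, ssr) + halfnormal_lp(tau2, priors.tau_sd) + theta
            new = (
                loglik_tau(tau2_p, ssr) + halfnormal_lp(tau2_p, priors.tau_sd) + prop
            )
            acc = math.log(rng.random()) < new - cur
            if acc:
                tau2 = tau2_p
            _adapt(log_scale, acc_post, "tau2", acc, it, cfg, target_acc)

            # rho_s (logit transform, uniform prior)
            theta = math.log(rho_s / (1.0 - rho_s))
            prop = theta + math.exp(log_scale["rho_s"]) * rng.standard_normal()
            rho_p = 1.0 / (1.0 + math.exp(-prop))
            if 0.0 < rho_p < 1.0:
                Qs_p, ld_s_p = _car_factor(graph, rho_p)
                cur = _field_logpdf_parts(S, Qs, ld_s, Qt, ld_t, sigma2) + math.log(
                    rho_s * (1.0 - rho_s)
                )
                new = _field_logpdf_parts(
                    S, Qs_p, ld_s_p, Qt, ld_t, sigma2
                ) + math.log(rho_p * (1.0 - rho_p))
                acc = math.log(rng.random()) < new - cur
                if acc:
                    rho_s, Qs, ld_s = rho_p, Qs_p, ld_s_p
            else:  # numerically saturated proposal
                acc = False
            _adapt(log_scale, acc_post, "rho_s", acc, it, cfg, target_acc)

            # phi (atanh transform, uniform prior)
            theta = math.atanh(phi)
            prop = theta + math.exp(log_scale["phi"]) * rng.standard_normal()
            phi_p = math.tanh(prop)
            if -1.0 < phi_p < 1.0:
                Qt_p, ld_t_p = _ar1_factor(T, phi_p)
                cur = _field_logpdf_parts(S, Qs, ld_s, Qt, ld_t, sigma2) + math.log(
                    1.0 - phi * phi
                )
                new = _field_logpdf_parts(
                    S, Qs, ld_s, Qt_p, ld_t_p, sigma2
                ) + math.log(1.0 - phi_p * phi_p)
                acc = math.log(rng.random()) < new - cur
                if acc:
                    phi, Qt, ld_t = phi_p, Qt_p, ld_t_p
            else:
                acc = False
            _adapt(log_scale, acc_post, "phi", acc, it, cfg, target_acc)

            if it > cfg.burn_in:
                n_post += 1

        # --- retention ------------------------------------------------
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            out["alpha"][m] = alpha
            out["sigma2"][m] = sigma2
            out["rho_s"][m] = rho_s
            out["phi"][m] = phi
            out["tau2"][m] = tau2
            out["field"][m] = S
            m += 1

    rates = {}
    if cfg.sample_hyperparams and n_post:
        for p in names:
            rates[p] = acc_post[p] / n_post
            if not 0.05 <= rates[p] <= 0.8:
                warnings.warn(
                    f"post-burn-in acceptance rate for {p} is {rates[p]:.2f}, "
                    "outside [0.05, 0.8]; check mixing",
                    RuntimeWarning,
                    stacklevel=2,
                )
    return out, rates


def _adapt(log_scale, acc_post, name, accepted, it, cfg, target):
    if it > cfg.burn_in:
        acc_post[name] += int(accepted)
    elif cfg.adapt:
        # Robbins-Monro on the log proposal scale, burn-in only
        gamma = min(0.25, it ** -0.6)
        log_scale[name] += gamma * ((1.0 if accepted else 0.0) - target)


def predict_surface(draws: dict, region_ids, years) -> PosteriorSurface:
    """Posterior prevalence surface from a draw store.

    Per draw, ``Q_kt = expit(alpha + S_kt)`` for every cell, including
    region-years with no observations; summarised by the mean and the
    2.5% / 97.5% draw quantiles.
    """
    alpha = np.asarray(draws["alpha"], dtype=float)
    S = np.asarray(draws["field"], dtype=float)
    if alpha.size == 0:
        raise ValueError("empty draw store")
    q = expit(alpha[:, None, None] + S)
    lo, hi = np.quantile(q, [0.025, 0.975], axis=0)
    return PosteriorSurface(
        region_ids=tuple(region_ids),
        years=tuple(int(t) for t in years),
        draws=q,
        mean=q.mean(axis=0),
        lo95=lo,
        hi95=hi,
    )


def mcmc_fit(
    data: FactorDataset,
    config: McmcConfig = McmcConfig(),
    priors: Priors = Priors(),
    init_params: ModelParams | None = None,
) -> dict:
    """Functional wrapper: run the sampler, return the draw store."""
    est = SpatioTemporalGPR(
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.seed,
        priors=priors,
        init_params=init_params,
        sample_alpha=config.sample_alpha,
        sample_hyperparams=config.sample_hyperparams,
        proposal_scales=config.proposal_scales,
        adapt=config.adapt,
    )
    est.fit(data)
    return est.draws_
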