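"""Single-season binomial N-mixture model on camera-trap detection histories.

The model of repeated counts at R sample units (camera-years): latent
abundance ``N_i ~ Poisson(lambda_i)`` with ``log lambda_i = x_i' beta``
(intercept plus optional camera-identity fixed effects), and observed counts
``y_it ~ Binomial(N_i, p_it)`` with ``logit p_it = gamma_0 + gamma_1 *
effort_it / period_days`` (active camera nights as an observation-level
covariate).  The latent abundances are marginalized out by truncated
summation to bound K, giving the integrated likelihood

    L = prod_i sum_{N=0}^{K} [ prod_{t observed} Bin(y_it | N, p_it) ]
                              Pois(N | lambda_i)

which is maximized directly (quasi-Newton) or explored by an adaptive
random-walk Metropolis sampler; the posterior, not a particular sampler, is
the contract.  Everything is computed in log space.  The per-unit inner sum
is evaluated with the standard separation trick: the binomial terms factor
into a parameter-free combinatorial table A[i, N] = sum_t log C(N, y_it)
plus terms linear in N, so one likelihood evaluation costs O(units x K).

Relative abundance — the average number of animals per camera station — is
the across-unit mean of lambda_i, summarized over posterior draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, log_expit, logsumexp

from .detections import DetectionHistory
from .errors import ModelError

__all__ = [
    "NMixtureModel",
    "PriorSpec",
    "MLEFit",
    "PosteriorDraws",
    "ConvergenceReport",
    "AbundanceEstimate",
    "marginal_loglik",
    "fit_mle",
    "sample_posterior",
    "gelman_rubin",
    "mean_relative_abundance",
    "default_truncation",
]


def default_truncation(data: DetectionHistory, tail: float = 1e-8) -> int:
    """Upper bound K for the latent-abundance sum.

    Max observed count plus a high Poisson quantile of a naive abundance
    estimate (the mean over units of the per-unit maximum count, at least 1):
    generous enough that the truncated sum has stabilized, cheap enough that
    likelihood evaluations stay fast.  Overridable everywhere K is accepted.
    """
    obs = data.counts[data.observed]
    unit_max = np.nanmax(np.where(data.observed, data.counts, 0.0), axis=1)
    lam0 = max(1.0, float(unit_max.mean()))
    return int(data.max_count + np.ceil(stats.poisson.ppf(1.0 - tail, lam0)))


class NMixtureModel:
    """Design matrices, truncation bound and marginal likelihood for one species.

    Parameters are stacked as ``theta = (beta, gamma)``: abundance
    coefficients on the log scale, then detection coefficients on the logit
    scale.  ``camera_effects`` adds reference-coded station fixed effects
    (sum-to-zero coding available via ``camera_coding="sum"``);
    ``effort_covariate`` adds the scaled active-nights slope to detection.
    """

    def __init__(
        self,
        data: DetectionHistory,
        camera_effects: bool = False,
        effort_covariate: bool = True,
        camera_coding: str = "reference",
        K: int | None = None,
    ):
        self.data = data
        self.K = default_truncation(data) if K is None else int(K)
        if self.K < data.max_count:
            raise ModelError(
                f"truncation bound K={self.K} is below the maximum observed count "
                f"{data.max_count}"
            )
        self.camera_effects = camera_effects
        self.effort_covariate = effort_covariate

        X = [np.ones(data.n_units)]
        names = ["beta:(Intercept)"]
        if camera_effects:
            stations = data.unit_covariates["station_id"].astype(str)
            levels = sorted(stations.unique())
            if camera_coding == "sum":
                for lev in levels[:-1]:
                    col = (stations == lev).astype(float) - (stations == levels[-1]).astype(float)
                    X.append(col.to_numpy())
                    names.append(f"beta:station[{lev}]")
            else:
                for lev in levels[1:]:  # first level is the reference
                    X.append((stations == lev).to_numpy(dtype=float))
                    names.append(f"beta:station[{lev}]")
        self.X = np.column_stack(X)
        # drop aliased columns so the abundance design is full rank
        q, r = np.linalg.qr(self.X)
        keep = np.abs(np.diag(r)) > 1e-10
        if not keep.all():
            self.X = self.X[:, keep]
            names = [n for n, k in zip(names, keep) if k]
        self.n_beta = self.X.shape[1]
        names.append("gamma:(Intercept)")
        if effort_covariate:
            names.append("gamma:effort")
        self.parameter_names = names
        self.n_gamma = 1 + int(effort_covariate)
        self.n_params = self.n_beta + self.n_gamma

        self._mask = data.observed
        self._y = np.where(self._mask, data.counts, 0.0)
        self._effort_scaled = data.effort / data.period_days
        self._A = self._binomial_table()

    def _binomial_table(self) -> np.ndarray:
        """A[i, N] = sum over observed t of log C(N, y_it); -inf where N < max y_i."""
        N = np.arange(self.K + 1)
        y = self._y[:, :, None]
        d = N[None, None, :] - y
        logc = gammaln(N + 1)[None, None, :] - gammaln(y + 1) - gammaln(np.maximum(d, 0) + 1)
        logc = np.where(d < 0, -np.inf, logc)
        logc = np.where(self._mask[:, :, None], logc, 0.0)
        with np.errstate(invalid="ignore"):
            return logc.sum(axis=1)

    def split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        return theta[: self.n_beta], theta[self.n_beta :]

    def loglik(self, theta: Sequence[float]) -> float:
        """Marginal log-likelihood at stacked parameters ``theta``."""
        beta, gamma = self.split(theta)
        if not (np.isfinite(beta).all() and np.isfinite(gamma).all()):
            raise ModelError("non-finite parameter passed to the likelihood")
        log_lam = self.X @ beta
        eta = np.full(self._y.shape, gamma[0])
        if self.effort_covariate:
            eta = eta + gamma[1] * self._effort_scaled
        # log p and log(1-p) via log-sigmoid for stability at extreme eta
        logp = log_expit(eta)
        log1mp = log_expit(-eta)
        m = self._mask
        s_ylogp = np.sum(np.where(m, self._y * logp, 0.0), axis=1)
        s_log1mp = np.sum(np.where(m, log1mp, 0.0), axis=1)
        s_ylog1mp = np.sum(np.where(m, self._y * log1mp, 0.0), axis=1)
        N = np.arange(self.K + 1)
        inner = (
            self._A
            + (s_ylogp - s_ylog1mp)[:, None]
            + N[None, :] * (s_log1mp + log_lam)[:, None]
            - np.exp(log_lam)[:, None]
            - gammaln(N + 1)[None, :]
        )
        return float(logsumexp(inner, axis=1).sum())

    def per_unit_lambda(self, theta: Sequence[float]) -> np.ndarray:
        beta, _ = self.split(theta)
        return np.exp(self.X @ beta)

    def default_init(self) -> np.ndarray:
        unit_max = np.nanmax(np.where(self._mask, self.data.counts, 0.0), axis=1)
        theta = np.zeros(self.n_params)
        theta[0] = np.log(max(unit_max.mean(), 0.25) + 0.5)
        return theta


def marginal_loglik(model: NMixtureModel, theta: Sequence[float]) -> float:
    """Module-level alias for :meth:`NMixtureModel.loglik`."""
    return model.loglik(theta)


# ---------------------------------------------------------------------------
# Maximum likelihood


@dataclass
class MLEFit:
    model: NMixtureModel
    theta: np.ndarray
    loglik: float
    cov: np.ndarray
    se: np.ndarray
    converged: bool
    message: str

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.theta, index=self.model.parameter_names)

    def mean_relative_abundance(self) -> tuple[float, tuple[float, float]]:
        """Across-unit mean lambda with a delta-method Wald 95% interval."""
        lam = self.model.per_unit_lambda(self.theta)
        est = float(lam.mean())
        grad = np.zeros(self.model.n_params)
        grad[: self.model.n_beta] = (lam[:, None] * self.model.X).mean(axis=0)
        var = float(grad @ self.cov @ grad)
        half = 1.96 * np.sqrt(max(var, 0.0))
        return est, (max(0.0, est - half), est + half)


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; adequate for Wald standard errors."""
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_mle(
    data_or_model: DetectionHistory | NMixtureModel,
    K: int | None = None,
    init: Sequence[float] | None = None,
    fixed_gamma: Sequence[float] | None = None,
    gtol: float = 1e-6,
    **model_kwargs,
) -> MLEFit:
    """Maximize the marginal likelihood by BFGS from ``init``.

    ``fixed_gamma`` pins the detection coefficients (e.g. perfect detection
    ``fixed_gamma=[+inf]`` is approximated by a large logit) and optimizes
    the abundance coefficients only.  Non-convergence is flagged on the
    result, not raised.  Standard errors come from the inverse observed
    information (central-difference Hessian).
    """
    model = (
        data_or_model
        if isinstance(data_or_model, NMixtureModel)
        else NMixtureModel(data_or_model, K=K, **model_kwargs)
    )
    theta0 = model.default_init() if init is None else np.asarray(init, dtype=float)

    if fixed_gamma is not None:
        gam = np.asarray(fixed_gamma, dtype=float)
        gam = np.clip(gam, -35.0, 35.0)  # keep the likelihood finite at p ~ 0 or 1

        def nll(b):
            return -model.loglik(np.concatenate([b, gam]))

        res = optimize.minimize(nll, theta0[: model.n_beta], method="BFGS",
                                options={"gtol": gtol})
        theta = np.concatenate([res.x, gam])
        free = np.arange(model.n_beta)
    else:

        def nll(th):
            return -model.loglik(th)

        res = optimize.minimize(nll, theta0, method="BFGS", options={"gtol": gtol})
        theta = res.x
        free = np.arange(model.n_params)

    cov = np.full((model.n_params, model.n_params), np.nan)
    try:
        H = _numeric_hessian(lambda v: -model.loglik(_embed(theta, free, v)), theta[free])
        cov_free = np.linalg.pinv(H)
        cov[np.ix_(free, free)] = cov_free
    except (np.linalg.LinAlgError, ModelError):
        pass
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return MLEFit(
        model=model,
        theta=theta,
        loglik=-float(res.fun),
        cov=np.nan_to_num(cov, nan=0.0) if fixed_gamma is not None else cov,
        se=se,
        converged=bool(res.success),
        message=str(res.message),
    )


def _embed(theta, free, values):
    out = theta.copy()
    out[free] = values
    return out


# ---------------------------------------------------------------------------
# Bayesian fitting: adaptive random-walk Metropolis on the marginal posterior


@dataclass
class PriorSpec:
    """Independent Normal priors on all link-scale coefficients.

    Diffuse by default (sd 10): likelihood-dominated at survey data volumes.
    """

    mean: float = 0.0
    sd: float = 10.0

    def __post_init__(self):
        if not (self.sd > 0 and np.isfinite(self.sd)):
            raise ModelError("prior sd must be positive and finite (proper prior)")

    def logpdf(self, theta: np.ndarray) -> float:
        return float(stats.norm.logpdf(theta, self.mean, self.sd).sum())


@dataclass
class PosteriorDraws:
    """Retained (post burn-in, unthinned) MCMC draws: chains x iterations x params."""

    draws: np.ndarray
    parameter_names: list[str]
    seed: int
    settings: dict
    accept_rate: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.draws.shape[1]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        c, n, p = self.draws.shape
        df = pd.DataFrame(self.flat(), columns=self.parameter_names)
        df.insert(0, "iteration", np.tile(np.arange(n), c))
        df.insert(0, "chain", np.repeat(np.arange(c), n))
        return df


def sample_posterior(
    model: NMixtureModel,
    prior: PriorSpec | None = None,
    chains: int = 4,
    iterations: int = 4000,
    burn_in: int = 2000,
    seed: int = 0,
    init: Sequence[float] | None = None,
    target_accept: float = 0.3,
) -> PosteriorDraws:
    """Adaptive random-walk Metropolis on the marginalized posterior.

    Each of ``chains`` independent chains runs ``iterations`` total sweeps
    and discards the first ``burn_in`` (defaults follow the survey protocol:
    4 chains of 4000 with 2000 burn-in, unthinned, 8000 retained draws).
    During burn-in the joint Gaussian proposal adapts: a global scale chases
    ``target_accept`` (Robbins-Monro on the log scale) and, once enough
    history exists, the proposal covariance tracks the running empirical
    covariance (scaled 2.38^2/d).  Adaptation stops at the end of burn-in,
    so the retained chain is a valid Markov chain.  Bit-reproducible for a
    given (seed, data, settings).
    """
    if chains < 2:
        raise ModelError("at least two chains are required")
    if not 0 < burn_in < iterations:
        raise ModelError("need 0 < burn_in < iterations")
    prior = prior or PriorSpec()
    d = model.n_params
    kept = iterations - burn_in
    draws = np.empty((chains, kept, d))
    acc_rates = np.empty(chains)
    warnings: list[str] = []

    theta0 = model.default_init() if init is None else np.asarray(init, dtype=float)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(chains)]

    def logpost(th):
        return model.loglik(th) + prior.logpdf(th)

    for c, rng in enumerate(streams):
        theta = theta0 + 0.1 * rng.standard_normal(d)
        lp = logpost(theta)
        log_scale = np.log(0.1)
        chol = np.eye(d)
        mean = theta.copy()
        M2 = np.zeros((d, d))
        n_hist = 0
        accepted_post = 0
        for it in range(iterations):
            adapting = it < burn_in
            step = np.exp(log_scale) * (chol @ rng.standard_normal(d))
            prop = theta + step
            lp_prop = logpost(prop)
            accept = np.log(rng.uniform()) < lp_prop - lp
            if accept:
                theta, lp = prop, lp_prop
                if not adapting:
                    accepted_post += 1
            if adapting:
                # Robbins-Monro on the global log-scale
                rate = 1.0 if accept else 0.0
                log_scale += (rate - target_accept) / (1.0 + it / 100.0)
                # running covariance (Welford) for the proposal shape
                n_hist += 1
                delta = theta - mean
                mean += delta / n_hist
                M2 += np.outer(delta, theta - mean)
                if n_hist > max(50, 2 * d) and it % 25 == 0:
                    cov = M2 / (n_hist - 1) * (2.38**2 / d) + 1e-9 * np.eye(d)
                    try:
                        chol = np.linalg.cholesky(cov)
                        log_scale = 0.0
                    except np.linalg.LinAlgError:
                        pass
            else:
                draws[c, it - burn_in] = theta
        acc_rates[c] = accepted_post / kept
        if acc_rates[c] == 0.0:
            warnings.append(
                f"chain {c}: zero acceptance after adaptation — posterior draws are "
                "degenerate; inspect the model or rescale the proposal"
            )

    return PosteriorDraws(
        draws=draws,
        parameter_names=list(model.parameter_names),
        seed=seed,
        settings={
            "chains": chains,
            "iterations": iterations,
            "burn_in": burn_in,
            "target_accept": target_accept,
            "prior_mean": prior.mean,
            "prior_sd": prior.sd,
        },
        accept_rate=acc_rates,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics


@dataclass
class ConvergenceReport:
    rhat: pd.Series
    flags: list[str]
    threshold: float
    notes: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return not self.flags

    def to_dict(self) -> dict:
        return {
            "rhat": {k: (None if np.isnan(v) else float(v)) for k, v in self.rhat.items()},
            "flags": self.flags,
            "threshold": self.threshold,
            "notes": self.notes,
        }


def gelman_rubin(draws: PosteriorDraws, threshold: float = 1.1) -> ConvergenceReport:
    """Classical potential scale reduction factor, per parameter.

    With m chains of length n, within-chain variance W (mean of per-chain
    sample variances), between-chain variance B = n * var(chain means), the
    statistic is sqrt(((n-1)/n * W + B/n) / W).  Values can fall slightly
    below 1 when B is near zero (identical chains give sqrt((n-1)/n)); a
    note records this.  Zero within-chain variance in all chains makes the
    statistic undefined: reported as NaN and flagged, never raised.
    """
    x = draws.draws
    m, n, p = x.shape
    if m < 2 or n < 10:
        raise ModelError("Gelman-Rubin needs >= 2 chains and >= 10 retained iterations")
    chain_means = x.mean(axis=1)  # m x p
    chain_vars = x.var(axis=1, ddof=1)  # m x p
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((n - 1) / n * W + B / n) / W)
    rhat = pd.Series(rhat, index=draws.parameter_names, name="rhat")
    flags = [name for name, v in rhat.items() if np.isnan(v) or v > threshold]
    notes = []
    for name, v in rhat.items():
        if np.isnan(v):
            notes.append(f"{name}: zero within-chain variance, rhat undefined")
        elif v < 1.0:
            notes.append(f"{name}: rhat {v:.4f} < 1 (between-chain variance near zero)")
    return ConvergenceReport(rhat=rhat, flags=flags, threshold=threshold, notes=notes)


# ---------------------------------------------------------------------------
# Relative abundance


@dataclass
class AbundanceEstimate:
    """Posterior summary of the average number of animals per camera station."""

    species: str
    mean_relative_abundance: float
    interval: tuple[float, float]
    per_unit_lambda: pd.Series
    average_draws: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "mean_relative_abundance": self.mean_relative_abundance,
            "interval_95": list(self.interval),
            "per_unit_lambda": {k: float(v) for k, v in self.per_unit_lambda.items()},
        }


def mean_relative_abundance(
    draws: PosteriorDraws, model: NMixtureModel
) -> AbundanceEstimate:
    """Posterior mean and central 95% interval of the unit-averaged lambda.

    For every retained draw, lambda_i is computed for each unit and averaged
    across units; the posterior of that average is summarized.  (Averaging
    per-unit posterior means instead gives the same point estimate by
    linearity; the interval is what distinguishes the two readings.)
    """
    flat = draws.flat()
    beta = flat[:, : model.n_beta]
    lam = np.exp(model.X @ beta.T)  # units x draws
    avg = lam.mean(axis=0)
    lo, hi = np.percentile(avg, [2.5, 97.5])
    return AbundanceEstimate(
        species=model.data.species,
        mean_relative_abundance=float(avg.mean()),
        interval=(float(lo), float(hi)),
        per_unit_lambda=pd.Series(lam.mean(axis=1), index=model.data.units),
        average_draws=avg,
    )
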