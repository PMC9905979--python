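"""Posterior inference backends and summaries.

Two interchangeable backends are provided for any model object exposing
``log_posterior`` / ``grad_log_posterior`` over an unconstrained parameter
vector:

``laplace``
    MAP via L-BFGS with analytic gradients, Gaussian approximation from the
    negative inverse Hessian (finite differences of the gradient), then
    exact draws from that Gaussian.  Fast; the default.
``mh``
    Adaptive random-walk Metropolis started at the MAP with the Laplace
    covariance as proposal shape, multiple chains, split-R-hat convergence
    check (warning above 1.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize


def posterior_prob_positive(draws) -> float:
    """Fraction of posterior draws strictly greater than zero."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("no posterior draws")
    return float(np.mean(draws > 0))


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, 95% interval and P(beta > 0)."""

    table: pd.DataFrame
    draws: pd.DataFrame = field(repr=False)
    method: str = "laplace"
    warnings: list = field(default_factory=list)

    def __getitem__(self, parameter: str) -> pd.Series:
        return self.table.loc[parameter]


def summarize_draws(draws: pd.DataFrame, method: str = "laplace",
                    warns: list | None = None) -> PosteriorSummary:
    """Build the printed-table-shaped summary from a draws frame."""
    rows = {}
    for name in draws.columns:
        d = draws[name].to_numpy()
        rows[name] = {
            "estimate": float(np.mean(d)),
            "q2.5": float(np.quantile(d, 0.025)),
            "q97.5": float(np.quantile(d, 0.975)),
            "p_gt_0": posterior_prob_positive(d),
        }
    table = pd.DataFrame(rows).T[["estimate", "q2.5", "q97.5", "p_gt_0"]]
    table.index.name = "parameter"
    return PosteriorSummary(table=table, draws=draws, method=method,
                            warnings=list(warns or []))


@dataclass
class FitConfig:
    """Sampler configuration shared by all models."""

    method: str = "laplace"          # "laplace" | "mh"
    n_draws: int = 4000              # total posterior draws
    chains: int = 4                  # mh only
    warmup: int = 1000               # mh only, per chain
    seed: int = 0
    beta_prior_sd: float = 2.5       # N(0, sd) on standardized fixed effects
    intercept_prior_sd: float = 5.0
    scale_prior_df: float = 3.0      # half-Student-t on group / baseline scales
    scale_prior_scale: float = 2.5
    rhat_limit: float = 1.05


def half_t_logpdf(x: float, df: float, scale: float) -> float:
    """Unnormalized log density of a half-Student-t at x >= 0."""
    return -0.5 * (df + 1.0) * np.log1p(x * x / (df * scale * scale))


def half_t_dlogpdf(x: float, df: float, scale: float) -> float:
    return -(df + 1.0) * x / (df * scale * scale + x * x)


def _map_estimate(model, x0=None):
    if x0 is None:
        x0 = model.initial_point()
    res = minimize(
        lambda th: -model.log_posterior(th),
        x0,
        jac=lambda th: -model.grad_log_posterior(th),
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    return res.x, res


def _hessian_fd(model, theta, eps: float = 1e-5) -> np.ndarray:
    """Hessian of the log posterior by central differences of the gradient."""
    n = theta.size
    h = np.empty((n, n))
    for i in range(n):
        step = eps * max(1.0, abs(theta[i]))
        tp = theta.copy(); tp[i] += step
        tm = theta.copy(); tm[i] -= step
        h[:, i] = (model.grad_log_posterior(tp) - model.grad_log_posterior(tm)) / (2 * step)
    return 0.5 * (h + h.T)


def _laplace_cov(model, theta_map) -> np.ndarray:
    h = _hessian_fd(model, theta_map)
    neg_h = -h
    # Regularize until positive definite.
    jitter = 0.0
    for _ in range(12):
        try:
            np.linalg.cholesky(neg_h + jitter * np.eye(len(theta_map)))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-8)
    return np.linalg.inv(neg_h + jitter * np.eye(len(theta_map)))


def laplace_draws(model, config: FitConfig):
    """MAP + Gaussian-approximation draws; returns (draws, map, warnings)."""
    theta_map, res = _map_estimate(model)
    warns = []
    if not res.success:
        warns.append(f"MAP optimizer did not converge: {res.message}")
    cov = _laplace_cov(model, theta_map)
    rng = np.random.default_rng(config.seed)
    draws = rng.multivariate_normal(theta_map, cov, size=config.n_draws,
                                    method="cholesky")
    return draws, theta_map, warns


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat for one scalar parameter; chains shaped (n_chain, n_draw)."""
    n_chain, n_draw = chains.shape
    half = n_draw // 2
    segs = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    b = n * means.var(ddof=1)
    w = segs.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def metropolis_draws(model, config: FitConfig):
    """Adaptive random-walk Metropolis seeded at the MAP."""
    theta_map, res = _map_estimate(model)
    warns = []
    if not res.success:
        warns.append(f"MAP optimizer did not converge: {res.message}")
    cov = _laplace_cov(model, theta_map)
    d = theta_map.size
    chol = np.linalg.cholesky(cov * (2.38 ** 2 / d) + 1e-12 * np.eye(d))
    rng = np.random.default_rng(config.seed)
    per_chain = max(1, config.n_draws // config.chains)
    all_chains = np.empty((config.chains, per_chain, d))
    for c in range(config.chains):
        theta = theta_map + 0.1 * chol @ rng.standard_normal(d)
        lp = model.log_posterior(theta)
        scale = 1.0
        kept = np.empty((per_chain, d))
        n_total = config.warmup + per_chain
        accepted = 0
        for it in range(n_total):
            prop = theta + scale * (chol @ rng.standard_normal(d))
            lp_prop = model.log_posterior(prop)
            if np.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accepted += 1
            if it < config.warmup and (it + 1) % 50 == 0:
                rate = accepted / (it + 1)
                scale *= np.exp(0.5 * (rate - 0.234))
            if it >= config.warmup:
                kept[it - config.warmup] = theta
        all_chains[c] = kept
    rhats = np.array([split_rhat(all_chains[:, :, j]) for j in range(d)])
    if np.any(rhats > config.rhat_limit):
        warns.append(
            f"sampler convergence warning: max split-R-hat "
            f"{rhats.max():.3f} > {config.rhat_limit}"
        )
    draws = all_chains.reshape(-1, d)
    return draws, theta_map, warns


def sample_posterior(model, config: FitConfig):
    """Dispatch to the configured backend."""
    if config.method == "laplace":
        return laplace_draws(model, config)
    if config.method == "mh":
        return metropolis_draws(model, config)
    raise ValueError(f"unknown inference method {config.method!r}")
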