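"""Bayesian logistic regression with optional random intercepts.

Used for the routing (offshore vs onshore) and landing (landed vs not)
decisions.  Fixed effects get Normal priors on the standardized scale;
random-intercept scales get half-Student-t priors.  Group effects use the
non-centred parametrization ``b = sigma * z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (
    FitConfig,
    PosteriorSummary,
    half_t_dlogpdf,
    half_t_logpdf,
    sample_posterior,
    summarize_draws,
)


def _log1pexp(x):
    out = np.empty_like(x)
    small = x < 30
    out[small] = np.log1p(np.exp(x[small]))
    out[~small] = x[~small]
    return out


class LogisticGLMM:
    """Bernoulli-logit model over an unconstrained parameter vector.

    Parameter layout: intercept, fixed betas, then per random-intercept
    group its standardized effects z (one per level) followed by the log
    group scale.
    """

    def __init__(self, y, X, fixed_names, groups=None,
                 config: FitConfig | None = None,
                 fixed_group_sd: float | None = None):
        self.y = np.asarray(y, dtype=float)
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if self.y.min() == self.y.max():
            raise ValueError("response has a single class; model not identifiable")
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("design matrix shape mismatch")
        self.fixed_names = list(fixed_names)
        if len(self.fixed_names) != self.X.shape[1]:
            raise ValueError("fixed effect names do not match design columns")
        self.groups = {}
        for name, codes in (groups or {}).items():
            codes = np.asarray(codes)
            levels, idx = np.unique(codes, return_inverse=True)
            self.groups[name] = (idx, len(levels))
        self.config = config or FitConfig()
        # fixed_group_sd pins every group scale (no log-scale parameter);
        # used to take the sd -> 0 limit where the model reduces to
        # ordinary logistic regression
        self.fixed_group_sd = fixed_group_sd

    # -- parameter layout ------------------------------------------------
    @property
    def _has_free_sd(self) -> bool:
        return self.fixed_group_sd is None

    @property
    def param_names(self):
        names = ["intercept"] + self.fixed_names
        for g, (_, n_lev) in self.groups.items():
            names += [f"z[{g},{j}]" for j in range(n_lev)]
            if self._has_free_sd:
                names += [f"log_sd({g})"]
        return names

    @property
    def n_params(self):
        per_group = 1 if self._has_free_sd else 0
        return 1 + self.X.shape[1] + sum(
            n + per_group for _, n in self.groups.values())

    def initial_point(self):
        return np.zeros(self.n_params)

    def _unpack(self, theta):
        p = self.X.shape[1]
        b0 = theta[0]
        beta = theta[1: 1 + p]
        pos = 1 + p
        zs, lams = {}, {}
        for g, (_, n_lev) in self.groups.items():
            zs[g] = theta[pos: pos + n_lev]
            pos += n_lev
            if self._has_free_sd:
                lams[g] = theta[pos]
                pos += 1
            else:
                lams[g] = np.log(self.fixed_group_sd)
        return b0, beta, zs, lams

    def _eta(self, b0, beta, zs, lams):
        eta = b0 + self.X @ beta
        for g, (idx, _) in self.groups.items():
            eta = eta + np.exp(lams[g]) * zs[g][idx]
        return eta

    # -- log posterior ---------------------------------------------------
    def log_posterior(self, theta):
        c = self.config
        b0, beta, zs, lams = self._unpack(theta)
        eta = self._eta(b0, beta, zs, lams)
        ll = float(self.y @ eta - _log1pexp(eta).sum())
        lp = ll
        lp -= 0.5 * b0 * b0 / c.intercept_prior_sd ** 2
        lp -= 0.5 * float(beta @ beta) / c.beta_prior_sd ** 2
        for g in self.groups:
            lp -= 0.5 * float(zs[g] @ zs[g])
            if self._has_free_sd:
                sigma = np.exp(lams[g])
                lp += half_t_logpdf(sigma, c.scale_prior_df, c.scale_prior_scale)
                lp += lams[g]  # log-Jacobian of sigma = exp(lambda)
        return lp

    def grad_log_posterior(self, theta):
        c = self.config
        b0, beta, zs, lams = self._unpack(theta)
        eta = self._eta(b0, beta, zs, lams)
        resid = self.y - 1.0 / (1.0 + np.exp(-eta))
        grad = np.empty_like(theta)
        grad[0] = resid.sum() - b0 / c.intercept_prior_sd ** 2
        p = self.X.shape[1]
        grad[1: 1 + p] = self.X.T @ resid - beta / c.beta_prior_sd ** 2
        pos = 1 + p
        for g, (idx, n_lev) in self.groups.items():
            sigma = np.exp(lams[g])
            gz = sigma * np.bincount(idx, weights=resid, minlength=n_lev) - zs[g]
            grad[pos: pos + n_lev] = gz
            pos += n_lev
            if self._has_free_sd:
                dsig = float(resid @ zs[g][idx])
                grad[pos] = (
                    sigma * dsig
                    + sigma * half_t_dlogpdf(sigma, c.scale_prior_df,
                                             c.scale_prior_scale)
                    + 1.0
                )
                pos += 1
        return grad


@dataclass
class GLMMFit:
    """Fitted logistic GLMM with posterior summary and scaling record."""

    summary: PosteriorSummary
    scaling: dict = field(default_factory=dict)
    fixed_names: list = field(default_factory=list)
    group_names: list = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        return self.summary.table


def standardize_columns(df: pd.DataFrame, cols):
    """Centre/scale continuous columns (binary 0/1 columns pass through).

    Returns (matrix, scaling dict col -> (mean, sd)).
    """
    mats, scaling = [], {}
    for col in cols:
        x = df[col].to_numpy(dtype=float)
        uniq = np.unique(x)
        if len(uniq) <= 2 and set(uniq).issubset({0.0, 1.0}):
            mats.append(x)
            continue
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        mean = x.mean()
        scaling[col] = (float(mean), float(sd))
        mats.append((x - mean) / sd)
    return np.column_stack(mats) if mats else np.empty((len(df), 0)), scaling


def fit_logistic_glmm(
    df: pd.DataFrame,
    response: str,
    fixed,
    groups=(),
    config: FitConfig | None = None,
    group_sd: float | None = None,
) -> GLMMFit:
    """Fit a Bernoulli-logit model with the named fixed effects and
    random-intercept grouping columns; continuous fixed effects are centred
    and scaled to one s.d. first.

    Returns a :class:`GLMMFit` whose summary table has one row per fixed
    effect (posterior mean, 95% interval, P(beta > 0)) plus one per group
    scale.  ``group_sd`` pins all group scales to a fixed value instead of
    estimating them (``group_sd -> 0`` reduces to ordinary logistic
    regression).

    Note: under the default ``laplace`` backend the group-scale posteriors
    come from a joint-mode Gaussian approximation and are diffuse; prefer
    ``method="mh"`` when the scales themselves are of interest.
    """
    config = config or FitConfig()
    fixed = list(fixed)
    X, scaling = standardize_columns(df, fixed)
    y = df[response].to_numpy(dtype=float)
    group_codes = {g: df[g].to_numpy() for g in groups}
    model = LogisticGLMM(y, X, fixed, groups=group_codes, config=config,
                         fixed_group_sd=group_sd)
    draws, theta_map, warns = sample_posterior(model, config)
    if np.any(np.abs(theta_map[1: 1 + len(fixed)]) > 4.0):
        warns = list(warns) + [
            "extreme coefficient magnitude at MAP; possible complete separation"
        ]
    names = model.param_names
    keep = {"intercept": draws[:, 0]}
    for j, f in enumerate(fixed):
        keep[f] = draws[:, 1 + j]
    if group_sd is None:
        for g in group_codes:
            lam_idx = names.index(f"log_sd({g})")
            keep[f"sd({g})"] = np.exp(draws[:, lam_idx])
    summary = summarize_draws(pd.DataFrame(keep), method=config.method, warns=warns)
    return GLMMFit(summary=summary, scaling=scaling, fixed_names=fixed,
                   group_names=list(groups))
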