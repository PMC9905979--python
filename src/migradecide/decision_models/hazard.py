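"""Discrete-night proportional-hazards departure model.

Unit of analysis is one bird-night: night ``t`` (1-based, days since
capture) covers the interval ``[t-1, t)``.  Covariates are piecewise
constant per night.  The hazard is ``h(t | x) = h0(t) * exp(x beta)`` with
``h0`` either constant or a nonnegative M-spline combination; a departure
on night ``t`` contributes ``log h(t)``, every observed night contributes
minus its integrated hazard, and never-departing birds may enter as
right-censored rows (event = 0 on every row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import ConstantBaseline, MSplineBaseline
from .inference import (
    FitConfig,
    PosteriorSummary,
    half_t_dlogpdf,
    half_t_logpdf,
    sample_posterior,
    summarize_draws,
)
from .splines import MSplineBasis, orthogonal_poly


def hazard_loglik(table: pd.DataFrame, baseline, beta=None, covariate_cols=None):
    """Log-likelihood of a bird-night table under a proportional-hazards model.

    ``table`` needs columns ``night`` (1-based int) and ``event`` (0/1, at
    most one event per bird, on its last row).  ``baseline`` is a
    :class:`ConstantBaseline` or :class:`MSplineBaseline`; ``beta`` and
    ``covariate_cols`` give the linear predictor (omitted = zero).
    """
    t = table["night"].to_numpy(dtype=float)
    if np.any(t < 1):
        raise ValueError("night indices must be >= 1")
    event = table["event"].to_numpy(dtype=float)
    if beta is not None:
        X = table[list(covariate_cols)].to_numpy(dtype=float)
        eta = X @ np.asarray(beta, dtype=float)
    else:
        eta = np.zeros(len(table))
    dH0 = baseline.cumulative(t) - baseline.cumulative(t - 1.0)
    cum = float(dH0 @ np.exp(eta))
    ev_mask = event == 1
    h0_ev = baseline.hazard(t[ev_mask])
    if np.any(h0_ev <= 0):
        raise ValueError("zero baseline hazard at an event time")
    ev = float(np.sum(np.log(h0_ev) + eta[ev_mask]))
    return ev - cum


class HazardModel:
    """Unconstrained-parameter proportional-hazards model for inference.

    Layout: baseline log-weights (K for M-spline, 1 for constant), fixed
    betas, then per random-intercept group its z vector and log scale.
    """

    def __init__(self, night, event, X, fixed_names, basis: MSplineBasis | None,
                 groups=None, config: FitConfig | None = None):
        self.t = np.asarray(night, dtype=float)
        if np.any(self.t < 1):
            raise ValueError("night indices must be >= 1")
        self.event = np.asarray(event, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.fixed_names = list(fixed_names)
        self.basis = basis
        self.config = config or FitConfig()
        self.groups = {}
        for name, codes in (groups or {}).items():
            codes = np.asarray(codes)
            levels, idx = np.unique(codes, return_inverse=True)
            self.groups[name] = (idx, len(levels))
        self.ev_mask = self.event == 1
        if basis is not None:
            self.K = basis.n_basis
            self.dI = basis.ispline(self.t) - basis.ispline(self.t - 1.0)
            self.M_ev = basis.mspline(self.t[self.ev_mask])
        else:
            self.K = 1
            self.dI = np.ones((len(self.t), 1))
            self.M_ev = np.ones((int(self.ev_mask.sum()), 1))

    @property
    def param_names(self):
        if self.basis is not None:
            names = [f"log_w[{k}]" for k in range(self.K)]
        else:
            names = ["log_rate"]
        names += self.fixed_names
        for g, (_, n_lev) in self.groups.items():
            names += [f"z[{g},{j}]" for j in range(n_lev)] + [f"log_sd({g})"]
        return names

    @property
    def n_params(self):
        return self.K + self.X.shape[1] + sum(n + 1 for _, n in self.groups.values())

    def initial_point(self):
        theta = np.zeros(self.n_params)
        # start baseline near the crude event rate per bird-night
        rate = max(self.event.mean(), 1e-3)
        theta[: self.K] = np.log(rate) - (np.log(self.K) if self.basis is not None else 0.0)
        return theta

    def _unpack(self, theta):
        gamma = theta[: self.K]
        p = self.X.shape[1]
        beta = theta[self.K: self.K + p]
        pos = self.K + p
        zs, lams = {}, {}
        for g, (_, n_lev) in self.groups.items():
            zs[g] = theta[pos: pos + n_lev]
            lams[g] = theta[pos + n_lev]
            pos += n_lev + 1
        return gamma, beta, zs, lams

    def _eta(self, beta, zs, lams):
        eta = self.X @ beta if self.X.shape[1] else np.zeros(len(self.t))
        for g, (idx, _) in self.groups.items():
            eta = eta + np.exp(lams[g]) * zs[g][idx]
        return eta

    def log_posterior(self, theta):
        c = self.config
        gamma, beta, zs, lams = self._unpack(theta)
        w = np.exp(gamma)
        eta = self._eta(beta, zs, lams)
        dH = self.dI @ w
        lp = -float(dH @ np.exp(eta))
        h0_ev = self.M_ev @ w
        lp += float(np.sum(np.log(h0_ev))) + float(eta[self.ev_mask].sum())
        # priors
        s = w.sum()
        lp += half_t_logpdf(s, c.scale_prior_df, c.scale_prior_scale)
        if self.basis is not None:
            lp -= (self.K - 1) * np.log(s)   # flat Dirichlet on the simplex
        lp += gamma.sum()                    # Jacobian of w = exp(gamma)
        lp -= 0.5 * float(beta @ beta) / c.beta_prior_sd ** 2
        for g in self.groups:
            sigma = np.exp(lams[g])
            lp -= 0.5 * float(zs[g] @ zs[g])
            lp += half_t_logpdf(sigma, c.scale_prior_df, c.scale_prior_scale)
            lp += lams[g]
        return lp

    def grad_log_posterior(self, theta):
        c = self.config
        gamma, beta, zs, lams = self._unpack(theta)
        w = np.exp(gamma)
        eta = self._eta(beta, zs, lams)
        e_eta = np.exp(eta)
        h0_ev = self.M_ev @ w
        grad = np.empty_like(theta)
        # d/dw then chain through w = exp(gamma)
        dw = self.M_ev.T @ (1.0 / h0_ev) - self.dI.T @ e_eta
        s = w.sum()
        ds = half_t_dlogpdf(s, c.scale_prior_df, c.scale_prior_scale)
        if self.basis is not None:
            ds -= (self.K - 1) / s
        grad[: self.K] = w * (dw + ds) + 1.0
        # d/d eta per row
        dH_row = self.dI @ w
        deta = self.event - dH_row * e_eta
        p = self.X.shape[1]
        if p:
            grad[self.K: self.K + p] = self.X.T @ deta - beta / c.beta_prior_sd ** 2
        pos = self.K + p
        for g, (idx, n_lev) in self.groups.items():
            sigma = np.exp(lams[g])
            gz = sigma * np.bincount(idx, weights=deta, minlength=n_lev) - zs[g]
            grad[pos: pos + n_lev] = gz
            dsig = float(deta @ zs[g][idx])
            grad[pos + n_lev] = (
                sigma * dsig
                + sigma * half_t_dlogpdf(sigma, c.scale_prior_df, c.scale_prior_scale)
                + 1.0
            )
            pos += n_lev + 1
        return grad


@dataclass
class HazardFit:
    """Fitted departure model: posterior summary plus design records."""

    summary: PosteriorSummary
    basis: MSplineBasis | None
    weight_draws: np.ndarray = field(repr=False)
    beta_draws: np.ndarray = field(repr=False)
    fixed_names: list = field(default_factory=list)
    scaling: dict = field(default_factory=dict)
    ortho: dict = field(default_factory=dict)
    max_night: float = 0.0

    @property
    def table(self) -> pd.DataFrame:
        return self.summary.table


FULL_COVARIATES = ("u", "v", "du24", "dv24", "dp24", "cloud", "rain")


def build_hazard_design(table: pd.DataFrame, covariates=None,
                        species_effects: bool = True):
    """Design matrix for the departure model.

    With ``covariates=None`` the final-model design is built: orthogonal
    linear+quadratic polynomials of both wind components, standardized 24-h
    wind/pressure changes and cloud cover, binary rain, species contrasts
    (first species alphabetically is the reference) and species-by-pressure-
    change interactions.  With an explicit list, those columns are used
    directly (continuous ones centred and scaled).
    """
    from .logistic import standardize_columns

    ortho = {}
    if covariates is not None:
        X, scaling = standardize_columns(table, covariates)
        return X, list(covariates), scaling, ortho

    cols, names = [], []
    scaling = {}
    for wind in ("u", "v"):
        x = table[wind].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"column {wind!r} has zero variance")
        scaling[wind] = (float(x.mean()), float(sd))
        basis, rec = orthogonal_poly((x - x.mean()) / sd, degree=2)
        # scale to unit variance so priors act on a comparable scale
        n = len(x)
        basis = basis * np.sqrt(n)
        ortho[wind] = (rec, np.sqrt(n))
        cols += [basis[:, 0], basis[:, 1]]
        names += [f"{wind}_lin", f"{wind}_quad"]
    Xc, sc = standardize_columns(table, ["du24", "dv24", "dp24", "cloud", "rain"])
    scaling.update(sc)
    cols += [Xc[:, j] for j in range(Xc.shape[1])]
    names += ["du24", "dv24", "dp24", "cloud", "rain"]
    if species_effects and "species" in table.columns:
        species = sorted(table["species"].unique())
        dp = cols[names.index("dp24")]
        for sp in species[1:]:
            ind = (table["species"] == sp).to_numpy(dtype=float)
            cols.append(ind)
            names.append(f"species[{sp}]")
            cols.append(ind * dp)
            names.append(f"species[{sp}]:dp24")
    return np.column_stack(cols), names, scaling, ortho


def fit_departure_model(
    table: pd.DataFrame,
    config: FitConfig | None = None,
    covariates=None,
    baseline: str = "mspline",
    n_basis: int = 5,
    degree: int = 3,
    random_intercepts=("year_species", "doy"),
) -> HazardFit:
    """Fit the daily departure hazard model on a bird-night table.

    ``table`` must contain ``bird``, ``night``, ``event`` plus covariate
    columns; random-intercept columns listed in ``random_intercepts`` are
    used when present.  Baseline is an M-spline (interior knots at event-
    night quantiles) or constant.
    """
    config = config or FitConfig()
    if table.loc[table["event"] == 1].groupby("bird").size().max() > 1:
        raise ValueError("more than one departure event for a bird")
    night = table["night"].to_numpy(dtype=float)
    event = table["event"].to_numpy(dtype=float)
    if event.sum() == 0:
        raise ValueError("no departure events in table")
    X, names, scaling, ortho = build_hazard_design(table, covariates)
    max_night = float(night.max())
    if baseline == "mspline":
        ev_nights = night[event == 1]
        basis = MSplineBasis.from_quantiles(
            ev_nights, n_basis=n_basis, degree=degree, lo=0.0, hi=max_night
        )
    elif baseline == "constant":
        basis = None
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    groups = {
        g: table[g].to_numpy() for g in random_intercepts if g in table.columns
    }
    model = HazardModel(night, event, X, names, basis, groups=groups, config=config)
    draws, theta_map, warns = sample_posterior(model, config)
    K = model.K
    keep = {}
    for j, f in enumerate(names):
        keep[f] = draws[:, K + j]
    pnames = model.param_names
    for g in groups:
        keep[f"sd({g})"] = np.exp(draws[:, pnames.index(f"log_sd({g})")])
    summary = summarize_draws(pd.DataFrame(keep), method=config.method, warns=warns)
    return HazardFit(
        summary=summary,
        basis=basis,
        weight_draws=np.exp(draws[:, :K]),
        beta_draws=draws[:, K: K + len(names)],
        fixed_names=names,
        scaling=scaling,
        ortho=ortho,
        max_night=max_night,
    )
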