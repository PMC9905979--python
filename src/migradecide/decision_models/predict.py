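"""Posterior predictions from the fitted departure model."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hazard import HazardFit


def _profile_design(fit: HazardFit, profile: dict) -> np.ndarray:
    """Row of the fitted design for one covariate profile (natural units).

    Unspecified covariates default to their training means (0 on the
    standardized scale); species defaults to the reference level.
    """
    x = np.zeros(len(fit.fixed_names))
    for key, value in profile.items():
        if key in ("u", "v") and key in fit.ortho:
            mean, sd = fit.scaling[key]
            rec, norm = fit.ortho[key]
            z = (float(value) - mean) / sd
            cols = rec.transform(np.array([z]))[0] * norm
            x[fit.fixed_names.index(f"{key}_lin")] = cols[0]
            x[fit.fixed_names.index(f"{key}_quad")] = cols[1]
        elif key == "species":
            name = f"species[{value}]"
            if name in fit.fixed_names:
                x[fit.fixed_names.index(name)] = 1.0
        elif key in fit.scaling:
            mean, sd = fit.scaling[key]
            x[fit.fixed_names.index(key)] = (float(value) - mean) / sd
        elif key in fit.fixed_names:
            x[fit.fixed_names.index(key)] = float(value)
        else:
            raise KeyError(f"unknown covariate {key!r}")
    # species x pressure-change interactions
    if "species" in profile:
        inter = f"species[{profile['species']}]:dp24"
        if inter in fit.fixed_names and "dp24" in fit.scaling:
            mean, sd = fit.scaling["dp24"]
            dp = (float(profile.get("dp24", mean)) - mean) / sd
            x[fit.fixed_names.index(inter)] = dp
    return x


def predict_departure_prob(fit: HazardFit, profile: dict, nights) -> pd.DataFrame:
    """Per-night departure probability with a 95% credible band.

    For each posterior draw the probability of departing on night ``t``
    given presence at its start is ``1 - exp(-(H0(t) - H0(t-1)) * exp(eta))``
    with random intercepts at zero.  ``profile`` maps covariate names to
    natural-unit values; anything omitted sits at its training mean.
    """
    nights = np.atleast_1d(np.asarray(nights, dtype=float))
    if np.any(nights < 1) or np.any(nights > fit.max_night):
        raise ValueError("night outside the fitted baseline range")
    x = _profile_design(fit, profile)
    eta = fit.beta_draws @ x                      # (n_draws,)
    if fit.basis is not None:
        dI = fit.basis.ispline(nights) - fit.basis.ispline(nights - 1.0)
        dH = fit.weight_draws @ dI.T              # (n_draws, n_nights)
    else:
        dH = np.repeat(fit.weight_draws, len(nights), axis=1)
    prob = 1.0 - np.exp(-dH * np.exp(eta)[:, None])
    return pd.DataFrame(
        {
            "night": nights,
            "mean": prob.mean(axis=0),
            "q2.5": np.quantile(prob, 0.025, axis=0),
            "q97.5": np.quantile(prob, 0.975, axis=0),
        }
    )
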