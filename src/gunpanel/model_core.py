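"""Gamma-Poisson likelihood, linear predictors, priors, posterior density.

The outcome model is

    D_i ~ GammaPoisson(lambda_i, phi)
    log lambda_i = log pi_i + alpha_{state[i]} + x_i' beta

where ``log pi_i`` is the population offset and the Gamma-Poisson
(negative binomial) is parameterized by *mean* ``lambda`` and *shape*
``phi``, so Var(D) = lambda + lambda^2 / phi.  This mean/shape
convention is the one used throughout; negative-binomial
parameterizations vary across software, so it is worth stating plainly:
``phi`` is the Gamma shape of the latent rate multiplier, and
``phi -> inf`` recovers the Poisson.

Priors (hierarchical / Mundlak and naive variants):

    alpha_state ~ Normal(alpha_bar, tau)
    alpha_bar   ~ Normal(-10, 1)
    tau         ~ Exponential(1)
    beta_k      ~ Normal(0, 1)
    phi         ~ Exponential(1)

Fixed-effects variant: alpha_state ~ Normal(-10, 1) independently, no
(alpha_bar, tau).  The Normal(-10, 1) center corresponds to a baseline
rate of exp(-10) ~= 4.5 per 100,000 person-years on the log-population
offset scale.  All Normal priors are (mean, SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

from .exceptions import ConfigurationError
from .panel_data import ModelData, ModelKind

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
#: log-rate above which exp() would overflow the count scale
_LP_OVERFLOW = 700.0


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the weakly informative priors (overridable)."""

    alpha_bar_loc: float = -10.0
    alpha_bar_scale: float = 1.0
    tau_rate: float = 1.0
    beta_scale: float = 1.0
    fe_alpha_loc: float = -10.0
    fe_alpha_scale: float = 1.0
    phi_rate: float = 1.0


DEFAULT_PRIORS = PriorConfig()


@dataclass
class Parameters:
    """One point in parameter space for a given ModelData configuration.

    ``alpha_bar``/``tau`` are None for the fixed-effects model; ``beta``
    follows ``ModelData.beta_names`` order.
    """

    alpha_state: np.ndarray
    beta: np.ndarray
    phi: float
    alpha_bar: float | None = None
    tau: float | None = None

    def replace(self, **kw) -> "Parameters":
        return replace(self, **kw)


def gamma_poisson_log_pmf(y, lam, phi):
    """Log pmf of the mean/shape Gamma-Poisson (negative binomial).

    log P(Y=y) = log C(y+phi-1, y) + phi log(phi/(phi+lam))
               + y log(lam/(phi+lam))

    computed with log-gamma functions, stable up to y ~ 1e6 and beyond.
    Broadcasts over array arguments.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(lam <= 0) or np.any(phi <= 0):
        raise ValueError("lam and phi must be strictly positive")
    yf = np.asarray(y, dtype=float)
    if np.any(yf < 0) or np.any(yf % 1 != 0):
        raise ValueError("y must be a non-negative integer")
    log_denom = np.log(phi + lam)
    out = (
        gammaln(yf + phi)
        - gammaln(phi)
        - gammaln(yf + 1.0)
        + phi * (np.log(phi) - log_denom)
        + yf * (np.log(lam) - log_denom)
    )
    return out if out.ndim else float(out)


def linear_predictor(data: ModelData, params: Parameters) -> np.ndarray:
    """log lambda for every observation: offset + state intercept + x'beta."""
    _check_consistency(data, params)
    lp = data.log_offset + params.alpha_state[data.group_index]
    X = data.design_matrix()
    if X.shape[1]:
        lp = lp + X @ params.beta
    return lp


def _check_consistency(data: ModelData, params: Parameters) -> None:
    if params.alpha_state.shape != (data.n_states,):
        raise ConfigurationError(
            f"alpha_state has shape {params.alpha_state.shape}, "
            f"expected ({data.n_states},)"
        )
    k = len(data.beta_names)
    if params.beta.shape != (k,):
        raise ConfigurationError(
            f"beta has shape {params.beta.shape}, expected ({k},) "
            f"for {data.model_kind.value} adjusted={data.adjusted}"
        )
    if data.model_kind.hierarchical and (
        params.alpha_bar is None or params.tau is None
    ):
        raise ConfigurationError(
            "hierarchical models require alpha_bar and tau"
        )


def log_likelihood(data: ModelData, params: Parameters) -> float:
    """Sum of Gamma-Poisson log pmfs at the model's rates.

    Returns -inf (with a warning) if the linear predictor overflows the
    exp scale; samplers treat that as a rejected point.
    """
    lp = linear_predictor(data, params)
    if np.any(lp > _LP_OVERFLOW):
        warnings.warn("linear predictor overflow; log-likelihood set to -inf",
                      stacklevel=2)
        return -np.inf
    return float(np.sum(gamma_poisson_log_pmf(data.y, np.exp(lp), params.phi)))


def _normal_logpdf(x, loc, scale):
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -0.5 * z * z - np.log(scale) - _LOG_SQRT_2PI


def log_prior(
    params: Parameters,
    model_kind: ModelKind | str,
    priors: PriorConfig = DEFAULT_PRIORS,
) -> float:
    """Joint log prior density; -inf outside the support (tau, phi <= 0)."""
    model_kind = ModelKind(model_kind)
    if params.phi is None or params.phi <= 0:
        return -np.inf
    total = float(priors.phi_rate * -params.phi + np.log(priors.phi_rate))
    if model_kind.hierarchical:
        if params.tau is None or params.tau <= 0:
            return -np.inf
        total += float(
            _normal_logpdf(params.alpha_bar, priors.alpha_bar_loc,
                           priors.alpha_bar_scale)
        )
        total += float(np.log(priors.tau_rate) - priors.tau_rate * params.tau)
        total += float(
            np.sum(_normal_logpdf(params.alpha_state, params.alpha_bar,
                                  params.tau))
        )
    else:
        total += float(
            np.sum(_normal_logpdf(params.alpha_state, priors.fe_alpha_loc,
                                  priors.fe_alpha_scale))
        )
    total += float(np.sum(_normal_logpdf(params.beta, 0.0, priors.beta_scale)))
    return total


def log_posterior(
    data: ModelData,
    params: Parameters,
    priors: PriorConfig = DEFAULT_PRIORS,
) -> float:
    """Unnormalized log posterior: log_likelihood + log_prior."""
    lp = log_prior(params, data.model_kind, priors)
    if not np.isfinite(lp):
        return -np.inf
    return log_likelihood(data, params) + lp
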