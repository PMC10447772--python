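"""Posterior sampling, convergence diagnostics, and interval summaries.

The reference ``built_in`` backend is an adaptive random-walk
Metropolis sampler applied coordinate-wise (Metropolis-within-Gibbs)
on an unconstrained parameterization: ``tau`` and ``phi`` are sampled
on the log scale with the Jacobian adjustment, and the per-state
intercepts are updated in a single vectorized block with independent
per-state accept/reject decisions — valid because, given the global
parameters, both the likelihood and the intercept prior factorize over
states.  Proposal scales adapt toward a 0.44 acceptance rate during
warmup only.  Identical (seed, config, data) gives bit-identical draws.

An ``external`` backend delegates to :mod:`emcee`'s affine-invariant
ensemble sampler and is used as a cross-check.

Diagnostics follow the standard split-chain formulation: split-R-hat
compares within- to between-half-chain variance, and the effective
sample size is the autocorrelation-based estimate (Geyer-truncated,
via arviz).  Degenerate inputs (zero variance) yield a NaN sentinel
rather than a silent 1.0.  Intervals are highest-posterior-density
intervals (HPDI): the shortest contiguous window of sorted draws
containing ``ceil(mass * n)`` draws, ties broken toward the lowest
lower bound; the default mass is 0.89.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, rankdata

from .exceptions import (
    ConfigurationError,
    InitializationError,
    InsufficientDataError,
)
from .model_core import DEFAULT_PRIORS, Parameters, PriorConfig, log_posterior
from .panel_data import ModelData

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "Diagnostics",
    "Interval",
    "Summary",
    "sample_posterior",
    "split_rhat",
    "effective_sample_size",
    "hpdi",
    "equal_tailed_interval",
    "summarize",
    "diagnostics",
]

_ADAPT_WINDOW = 50
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    ``fix_phi`` pins the dispersion at a known value instead of sampling
    it (useful for Poisson-limit checks).  At least two chains are
    required so split-R-hat is defined.
    """

    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    seed: int = 0
    backend: str = "built_in"
    fix_phi: float | None = None

    def __post_init__(self):
        if self.n_chains < 2:
            raise ConfigurationError("n_chains must be >= 2")
        if self.backend not in ("built_in", "external"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")


@dataclass
class PosteriorDraws:
    """Draws on the natural scale, indexed (chain, iteration, parameter)."""

    draws: np.ndarray
    parameter_names: list[str]
    config: SamplerConfig
    sampler_warnings: int = 0

    def get(self, name: str) -> np.ndarray:
        """(chain, iteration) array for one named parameter."""
        try:
            j = self.parameter_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r}; available: {self.parameter_names}"
            ) from None
        return self.draws[:, :, j]

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_samples(self) -> int:
        return self.draws.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame: chain, iteration, one column per parameter."""
        n_chains, n_iter, _ = self.draws.shape
        frame = pd.DataFrame(
            self.draws.reshape(n_chains * n_iter, -1),
            columns=self.parameter_names,
        )
        frame.insert(0, "iteration", np.tile(np.arange(n_iter), n_chains))
        frame.insert(0, "chain", np.repeat(np.arange(n_chains), n_iter))
        return frame


@dataclass(frozen=True)
class Interval:
    """A posterior interval with its nominal mass."""

    lower: float
    upper: float
    mass: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower must be <= upper")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class Summary:
    """The reporting triple: posterior mean, SD ('SE'), and HPDI."""

    mean: float
    se: float
    interval: Interval


@dataclass
class Diagnostics:
    """Per-parameter convergence diagnostics plus sampler anomaly count."""

    rhat: dict[str, float]
    ess: dict[str, float]
    sampler_warnings: int = 0

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return max(vals) if vals else float("nan")

    def converged(self, threshold: float = 1.05) -> bool:
        return np.isfinite(self.max_rhat) and self.max_rhat <= threshold

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess": self.ess,
            "sampler_warnings": self.sampler_warnings,
            "max_rhat": self.max_rhat,
        }


# ---------------------------------------------------------------------------
# built-in sampler


class _Model:
    """Precomputed arrays and per-observation likelihood for fast updates.

    The built-in sampler works in sheared coordinates: the exposure
    column is replaced by its within-state deviation and the between
    component is folded into per-state intercepts ``a_s = alpha_s +
    c * Gbar_s`` (``c`` = exposure coefficient, plus the group-mean
    coefficient for the Mundlak model).  This is an exact linear
    reparameterization (unit Jacobian) that removes the near-collinear
    ridge between the exposure slope and the intercepts which would
    otherwise cripple coordinate-wise random-walk mixing; the recorded
    draws are mapped back to the natural parameterization.
    """

    def __init__(self, data: ModelData, priors: PriorConfig):
        from .panel_data import compute_state_means

        self.data = data
        self.priors = priors
        self.y = data.y.astype(float)
        self.gln_y1 = gammaln(self.y + 1.0)
        self.X = data.design_matrix()
        self.offset = data.log_offset
        self.g = data.group_index
        self.n_states = data.n_states
        self.hier = data.model_kind.hierarchical
        self.mundlak = data.model_kind.has_group_mean
        self.k = self.X.shape[1]
        # sampling design: within-state deviations of every likelihood
        # column; the state-mean parts live inside the sheared intercepts
        cols = [data.G_std]
        if data.adjusted:
            cols += [data.VC_std, data.PC_std, data.VC_std * data.PC_std]
        raw = np.column_stack(cols)
        self.k_lik = raw.shape[1]
        self.Xbar = np.column_stack(
            [compute_state_means(raw[:, j], self.g, self.n_states)
             for j in range(self.k_lik)]
        )  # (n_states, k_lik)
        self.Xs = raw - self.Xbar[self.g]
        self.Gbar = self.Xbar[:, 0]

    def obs_loglik(self, lp: np.ndarray, phi: float) -> np.ndarray:
        """Per-observation Gamma-Poisson log pmf at log-rate ``lp``."""
        with np.errstate(over="ignore", invalid="ignore"):
            lam = np.exp(lp)
            log_denom = np.log(phi + lam)
            ll = (
                gammaln(self.y + phi)
                - gammaln(phi)
                - self.gln_y1
                + phi * (math.log(phi) - log_denom)
                + self.y * (lp - log_denom)
            )
        return np.where(np.isfinite(ll), ll, -np.inf)

    def alpha_prior(self, alpha, alpha_bar, tau):
        pr = self.priors
        if self.hier:
            z = (alpha - alpha_bar) / tau
            return -0.5 * z * z - math.log(tau) - 0.5 * math.log(2 * math.pi)
        z = (alpha - pr.fe_alpha_loc) / pr.fe_alpha_scale
        return (
            -0.5 * z * z
            - math.log(pr.fe_alpha_scale)
            - 0.5 * math.log(2 * math.pi)
        )

    def global_prior(self, alpha_bar, log_tau, beta, log_phi, fix_phi):
        """Prior of the globals + Jacobians of the log transforms.

        Excludes the per-state intercept prior (handled separately).
        """
        pr = self.priors
        total = -0.5 * float(beta @ beta) / pr.beta_scale**2 - beta.size * (
            math.log(pr.beta_scale) + 0.5 * math.log(2 * math.pi)
        )
        if fix_phi is None:
            phi = math.exp(log_phi)
            total += math.log(pr.phi_rate) - pr.phi_rate * phi + log_phi
        if self.hier:
            z = (alpha_bar - pr.alpha_bar_loc) / pr.alpha_bar_scale
            total += (
                -0.5 * z * z
                - math.log(pr.alpha_bar_scale)
                - 0.5 * math.log(2 * math.pi)
            )
            tau = math.exp(log_tau)
            total += math.log(pr.tau_rate) - pr.tau_rate * tau + log_tau
        return total


def _init_state(model: _Model, rng, fix_phi):
    """Overdispersed, data-informed jittered starting point (natural scale)."""
    d = model.data
    sums_y = np.bincount(d.group_index, weights=model.y, minlength=d.n_states)
    sums_pi = np.bincount(
        d.group_index, weights=np.exp(d.log_offset), minlength=d.n_states
    )
    crude = np.log((sums_y + 0.5) / sums_pi)
    alpha = crude + 0.2 * rng.standard_normal(d.n_states)
    alpha_bar = float(np.mean(crude) + 0.3 * rng.standard_normal())
    log_tau = float(
        math.log(max(float(np.std(crude)), 0.05)) + 0.4 * rng.standard_normal()
    )
    beta = 0.1 * rng.standard_normal(model.k)
    log_phi = float(math.log(2.0) + 0.5 * rng.standard_normal())
    if fix_phi is not None:
        log_phi = math.log(fix_phi)
    return alpha_bar, log_tau, alpha, beta, log_phi


def _run_chain(model: _Model, seed_seq, n_warmup, n_samples, fix_phi,
               init: Parameters | None):
    rng = np.random.default_rng(seed_seq)
    hier = model.hier
    mundlak = model.mundlak
    Gbar = model.Gbar
    pr = model.priors

    # --- initialization (natural scale), then shear into sampling coords
    for _ in range(50):
        if init is not None:
            alpha0 = init.alpha_state.astype(float).copy()
            beta0 = init.beta.astype(float).copy()
            log_phi = math.log(fix_phi if fix_phi is not None else init.phi)
            alpha_bar = float(init.alpha_bar) if hier else 0.0
            log_tau = math.log(init.tau) if hier else 0.0
            # jitter even explicit inits so chains are overdispersed
            alpha0 = alpha0 + 0.1 * rng.standard_normal(alpha0.size)
            beta0 = beta0 + 0.05 * rng.standard_normal(beta0.size)
        else:
            alpha_bar, log_tau, alpha0, beta0, log_phi = _init_state(
                model, rng, fix_phi
            )
        phi = math.exp(log_phi)
        tau = math.exp(log_tau) if hier else None
        # sampling coordinates: b over [G_dev, crime...], optional
        # between coefficient bB (Mundlak), sheared intercepts a
        b = np.empty(model.k_lik)
        b[0] = beta0[0]
        if model.k_lik > 1:
            b[1:] = beta0[1:model.k_lik]
        bB = (beta0[0] + beta0[-1]) if mundlak else 0.0
        c = b.copy()
        if mundlak:
            c[0] = bB
        alpha = alpha0
        a = alpha + model.Xbar @ c
        lp = model.offset + a[model.g] + model.Xs @ b
        ll = model.obs_loglik(lp, phi)
        if np.all(np.isfinite(ll)):
            break
    else:
        raise InitializationError(
            "no finite log-posterior found in 50 initialization attempts"
        )

    ll_sum = float(ll.sum())

    def beta_prior(b0, bB_):
        """Prior of the natural-scale coefficients at sampling coords."""
        total = _norm_lp(b0, 0.0, pr.beta_scale)
        if mundlak:
            total += _norm_lp(bB_ - b0, 0.0, pr.beta_scale)
        return total

    scale_a = np.full(model.n_states, 0.1)
    scale_b = np.full(model.k_lik, 0.05)
    scale_bB = 0.05
    scale_abar, scale_ltau, scale_lphi = 0.1, 0.3, 0.3
    acc_a = np.zeros(model.n_states)
    acc_b = np.zeros(model.k_lik)
    acc = {"abar": 0.0, "ltau": 0.0, "lphi": 0.0, "bB": 0.0}

    n_params = (2 if hier else 0) + model.n_states + model.k + 1
    out = np.empty((n_samples, n_params))
    n_warn = 0

    for it in range(n_warmup + n_samples):
        warm = it < n_warmup

        if hier:
            # alpha_bar and log_tau touch only the intercept prior
            cur_ap = float(np.sum(model.alpha_prior(alpha, alpha_bar, tau)))
            prop = alpha_bar + scale_abar * rng.standard_normal()
            delta = (
                float(np.sum(model.alpha_prior(alpha, prop, tau)))
                - cur_ap
                + _norm_lp(prop, pr.alpha_bar_loc, pr.alpha_bar_scale)
                - _norm_lp(alpha_bar, pr.alpha_bar_loc, pr.alpha_bar_scale)
            )
            if math.log(rng.random()) < delta:
                alpha_bar = prop
                cur_ap = float(
                    np.sum(model.alpha_prior(alpha, alpha_bar, tau))
                )
                if warm:
                    acc["abar"] += 1

            prop_lt = log_tau + scale_ltau * rng.standard_normal()
            prop_tau = math.exp(prop_lt)
            delta = (
                float(np.sum(model.alpha_prior(alpha, alpha_bar, prop_tau)))
                - cur_ap
                + (-pr.tau_rate * prop_tau + prop_lt)
                - (-pr.tau_rate * tau + log_tau)
            )
            if math.log(rng.random()) < delta:
                log_tau, tau = prop_lt, prop_tau
                if warm:
                    acc["ltau"] += 1

        # sheared intercept block: independent accept/reject per state
        # (a and alpha move together; coefficients fixed within this move)
        da = scale_a * rng.standard_normal(model.n_states)
        lp_new = lp + da[model.g]
        ll_new = model.obs_loglik(lp_new, phi)
        dll = np.bincount(model.g, weights=ll_new - ll,
                          minlength=model.n_states)
        dprior = model.alpha_prior(alpha + da, alpha_bar, tau) - \
            model.alpha_prior(alpha, alpha_bar, tau)
        accept = np.log(rng.random(model.n_states)) < (dll + dprior)
        if not warm:
            n_warn += int(np.sum(~np.isfinite(dll)))
        if np.any(accept):
            a = np.where(accept, a + da, a)
            alpha = np.where(accept, alpha + da, alpha)
            obs_acc = accept[model.g]
            lp = np.where(obs_acc, lp_new, lp)
            ll = np.where(obs_acc, ll_new, ll)
            ll_sum = float(ll.sum())
        if warm:
            acc_a += accept

        # likelihood-bearing coefficients, one coordinate at a time
        for j in range(model.k_lik):
            db = scale_b[j] * rng.standard_normal()
            lp_new = lp + db * model.Xs[:, j]
            ll_new = model.obs_loglik(lp_new, phi)
            new_sum = float(ll_new.sum())
            delta = new_sum - ll_sum
            if j == 0:
                delta += beta_prior(b[0] + db, bB) - beta_prior(b[0], bB)
            else:
                delta += (
                    _norm_lp(b[j] + db, 0.0, pr.beta_scale)
                    - _norm_lp(b[j], 0.0, pr.beta_scale)
                )
            alpha_new = None
            if not (mundlak and j == 0):
                # the column's between part is tied to its coefficient:
                # intercepts shift under the shear
                alpha_new = alpha - db * model.Xbar[:, j]
                delta += float(
                    np.sum(model.alpha_prior(alpha_new, alpha_bar, tau))
                    - np.sum(model.alpha_prior(alpha, alpha_bar, tau))
                )
            if not warm and not np.isfinite(new_sum):
                n_warn += 1
            if np.isfinite(delta) and math.log(rng.random()) < delta:
                b[j] += db
                if alpha_new is not None:
                    alpha = alpha_new
                lp, ll, ll_sum = lp_new, ll_new, new_sum
                if warm:
                    acc_b[j] += 1

        if mundlak:
            # between coefficient: prior-only move (no likelihood term)
            dbB = scale_bB * rng.standard_normal()
            alpha_new = alpha - dbB * Gbar
            delta = (
                beta_prior(b[0], bB + dbB)
                - beta_prior(b[0], bB)
                + float(
                    np.sum(model.alpha_prior(alpha_new, alpha_bar, tau))
                    - np.sum(model.alpha_prior(alpha, alpha_bar, tau))
                )
            )
            if math.log(rng.random()) < delta:
                bB += dbB
                alpha = alpha_new
                if warm:
                    acc["bB"] += 1

        if fix_phi is None:
            prop_lphi = log_phi + scale_lphi * rng.standard_normal()
            prop_phi = math.exp(prop_lphi)
            ll_new = model.obs_loglik(lp, prop_phi)
            new_sum = float(ll_new.sum())
            delta = (
                new_sum
                - ll_sum
                + (-pr.phi_rate * prop_phi + prop_lphi)
                - (-pr.phi_rate * phi + log_phi)
            )
            if not warm and not np.isfinite(new_sum):
                n_warn += 1
            if np.isfinite(delta) and math.log(rng.random()) < delta:
                log_phi, phi = prop_lphi, prop_phi
                ll, ll_sum = ll_new, new_sum
                if warm:
                    acc["lphi"] += 1

        # windowed scale adaptation, warmup only
        if warm and (it + 1) % _ADAPT_WINDOW == 0:
            scale_a *= np.exp(acc_a / _ADAPT_WINDOW - _TARGET_ACCEPT)
            acc_a[:] = 0
            scale_b *= np.exp(acc_b / _ADAPT_WINDOW - _TARGET_ACCEPT)
            acc_b[:] = 0
            scale_abar *= math.exp(acc["abar"] / _ADAPT_WINDOW - _TARGET_ACCEPT)
            scale_ltau *= math.exp(acc["ltau"] / _ADAPT_WINDOW - _TARGET_ACCEPT)
            scale_lphi *= math.exp(acc["lphi"] / _ADAPT_WINDOW - _TARGET_ACCEPT)
            scale_bB *= math.exp(acc["bB"] / _ADAPT_WINDOW - _TARGET_ACCEPT)
            acc = {k: 0.0 for k in acc}

        if not warm:
            beta_nat = np.empty(model.k)
            beta_nat[:model.k_lik] = b
            if mundlak:
                beta_nat[-1] = bB - b[0]
            head = [alpha_bar, tau] if hier else []
            out[it - n_warmup] = np.concatenate([head, alpha, beta_nat, [phi]])

    return out, n_warn


def _norm_lp(x, loc, scale):
    z = (x - loc) / scale
    return -0.5 * z * z


def parameter_names(data: ModelData) -> list[str]:
    """Natural-scale parameter labels in draw-column order."""
    names = []
    if data.model_kind.hierarchical:
        names += ["alpha_bar", "tau"]
    names += [f"alpha[{s}]" for s in data.state_labels]
    names += data.beta_names
    names += ["phi"]
    return names


def sample_posterior(
    data: ModelData,
    config: SamplerConfig,
    init: Parameters | None = None,
    priors: PriorConfig = DEFAULT_PRIORS,
) -> PosteriorDraws:
    """Draw posterior samples for the configured model.

    The built_in backend is deterministic: identical (data, config,
    init) reproduce bit-identical draws.
    """
    model = _Model(data, priors)
    names = parameter_names(data)
    if config.backend == "external":
        return _sample_emcee(data, config, priors, names)
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    warn_total = 0
    for c in range(config.n_chains):
        draws, n_warn = _run_chain(
            model, children[c], config.n_warmup, config.n_samples,
            config.fix_phi, init,
        )
        chains.append(draws)
        warn_total += n_warn
    return PosteriorDraws(
        draws=np.stack(chains),
        parameter_names=names,
        config=config,
        sampler_warnings=warn_total,
    )


def _sample_emcee(data, config, priors, names):
    """Affine-invariant ensemble backend (cross-check oracle)."""
    import emcee

    hier = data.model_kind.hierarchical
    k = len(data.beta_names)
    ndim = (2 if hier else 0) + data.n_states + k + (
        0 if config.fix_phi is not None else 1
    )

    def unpack(theta):
        i = 0
        alpha_bar = tau = None
        if hier:
            alpha_bar, log_tau = theta[0], theta[1]
            tau = math.exp(log_tau)
            i = 2
        alpha = theta[i:i + data.n_states]
        beta = theta[i + data.n_states:i + data.n_states + k]
        if config.fix_phi is not None:
            phi, jac = config.fix_phi, 0.0
        else:
            log_phi = theta[-1]
            phi = math.exp(log_phi)
            jac = log_phi
        if hier:
            jac += math.log(tau)
        return Parameters(alpha_state=alpha, beta=beta, phi=phi,
                          alpha_bar=alpha_bar, tau=tau), jac

    def log_prob(theta):
        params, jac = unpack(theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val = log_posterior(data, params, priors)
        return val + jac if np.isfinite(val) else -np.inf

    rng = np.random.default_rng(config.seed)
    model = _Model(data, priors)
    nwalkers = max(2 * ndim + 2, 2 * config.n_chains)
    nwalkers += nwalkers % 2
    p0 = np.empty((nwalkers, ndim))
    for w in range(nwalkers):
        alpha_bar, log_tau, alpha, beta, log_phi = _init_state(
            model, rng, config.fix_phi
        )
        theta = []
        if hier:
            theta += [alpha_bar, log_tau]
        theta = np.concatenate([theta, alpha, beta])
        if config.fix_phi is None:
            theta = np.concatenate([theta, [log_phi]])
        p0[w] = theta

    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed))
    state = sampler.run_mcmc(state, config.n_warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, config.n_samples, progress=False)
    raw = sampler.get_chain()  # (iter, walker, dim)

    # map walkers onto the requested number of reported chains
    raw = np.moveaxis(raw, 0, 1)  # (walker, iter, dim)
    per = nwalkers // config.n_chains
    raw = raw[: per * config.n_chains].reshape(
        config.n_chains, per * config.n_samples, ndim
    )
    cols = []
    i = 0
    if hier:
        cols += [raw[:, :, 0], np.exp(raw[:, :, 1])]
        i = 2
    for j in range(data.n_states + k):
        cols.append(raw[:, :, i + j])
    if config.fix_phi is None:
        cols.append(np.exp(raw[:, :, -1]))
    else:
        cols.append(np.full(raw.shape[:2], config.fix_phi))
    return PosteriorDraws(
        draws=np.stack(cols, axis=-1),
        parameter_names=names,
        config=config,
        sampler_warnings=0,
    )


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(draws: np.ndarray, rank_normalized: bool = False) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is split in half; R-hat = sqrt(((N-1)/N * W + B/N) / W)
    over the resulting half-chains.  Returns NaN (sentinel) when the
    within-chain variance is zero, i.e. the diagnostic is undefined.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 4:
        raise InsufficientDataError("split_rhat needs >= 2 chains x >= 4 draws")
    if rank_normalized:
        flat = rankdata(draws, axis=None)
        draws = norm.ppf((flat - 0.375) / (draws.size + 0.25)).reshape(
            draws.shape
        )
    n_half = draws.shape[1] // 2
    halves = np.concatenate(
        [draws[:, :n_half], draws[:, n_half: 2 * n_half]], axis=0
    )
    W = float(np.mean(np.var(halves, axis=1, ddof=1)))
    if W == 0.0 or not np.isfinite(W):
        return float("nan")
    B = n_half * float(np.var(np.mean(halves, axis=1), ddof=1))
    var_plus = (n_half - 1) / n_half * W + B / n_half
    return float(np.sqrt(var_plus / W))


def effective_sample_size(draws: np.ndarray) -> float:
    """Autocorrelation-based ESS (Geyer initial-monotone truncation).

    Returns NaN (sentinel) for degenerate (constant) draws.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise InsufficientDataError("effective_sample_size needs >= 2 chains")
    if np.ptp(draws) == 0.0:
        return float("nan")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = float(az.ess(draws, method="mean"))
    return ess


def diagnostics(posterior: PosteriorDraws) -> Diagnostics:
    """Split-R-hat and ESS for every parameter, plus sampler warnings."""
    rhat = {}
    ess = {}
    for name in posterior.parameter_names:
        d = posterior.get(name)
        rhat[name] = split_rhat(d)
        ess[name] = effective_sample_size(d)
    return Diagnostics(
        rhat=rhat, ess=ess, sampler_warnings=posterior.sampler_warnings
    )


# ---------------------------------------------------------------------------
# intervals and summaries


def hpdi(draws, mass: float = 0.89) -> Interval:
    """Highest-posterior-density interval of the given mass.

    Sorts the draws and returns the narrowest contiguous window
    containing ``ceil(mass * n)`` of them; ties go to the window with
    the lowest lower bound.
    """
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    n = draws.size
    if n < 10:
        raise InsufficientDataError(f"hpdi needs >= 10 draws, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = min(max(int(math.ceil(mass * n)), 1), n)
    widths = draws[m - 1:] - draws[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first => lowest lower bound
    return Interval(float(draws[i]), float(draws[i + m - 1]), mass)


def equal_tailed_interval(draws, mass: float = 0.89) -> Interval:
    """Count-symmetric equal-tailed interval on the same ceil(mass*n) rule."""
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    n = draws.size
    if n < 10:
        raise InsufficientDataError(f"interval needs >= 10 draws, got {n}")
    m = min(max(int(math.ceil(mass * n)), 1), n)
    lo = (n - m) // 2
    return Interval(float(draws[lo]), float(draws[lo + m - 1]), mass)


def summarize(
    posterior: PosteriorDraws, parameter: str, mass: float = 0.89
) -> Summary:
    """Posterior mean, posterior SD (reported as SE), and HPDI."""
    d = posterior.get(parameter).ravel()
    return Summary(
        mean=float(np.mean(d)),
        se=float(np.std(d, ddof=1)),
        interval=hpdi(d, mass) if np.ptp(d) > 0 else Interval(
            float(d[0]), float(d[0]), mass
        ),
    )
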