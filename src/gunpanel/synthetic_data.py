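"""Synthetic state-year panels with the study's causal structure.

The generator emulates a 50-state x 18-year firearm-mortality panel in
which an unobserved state-level confound U_s raises both the baseline
homicide log-rate and the state's long-run mean gun ownership, so the
*state mean* of the exposure is a descendant of the confound while the
year-to-year exposure variation around that mean is clean.  Crime-rate
predictors follow stationary AR(1) series generated independently of
the exposure (a correlation knob exists for sensitivity experiments but
defaults to zero).  Counts are Gamma-Poisson with a log-population
offset.

Scales are calibrated to the emulated panel: median ownership ~40%,
total ownership SD ~13.6 percentage points (split into ~13.45 between
states and 2 within), state populations log-normal around ~4 million,
and a baseline log-rate of -10 (~4.5 deaths per 100,000 person-years).

Confound strengths are unitless loadings: the state-mean exposure is

    m_s = 40 + s_between * (delta * U_s + V_s) / sqrt(1 + delta^2)

with U_s, V_s ~ Normal(0, 1), so ``delta`` controls the correlation
between mean ownership and the confound (delta = 0.5 gives corr ~0.45)
without changing the marginal exposure spread, and the baseline
intercept is alpha_s = alpha_bar + gamma * U_s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import GenerationError
from .inference import SamplerConfig, hpdi, sample_posterior, summarize
from .panel_data import ModelKind, PanelTable, build_model_data, standardize

__all__ = [
    "CrimeParams",
    "GeneratorConfig",
    "TrueParameters",
    "simulate_panel",
    "calibration_report",
    "recovery_study",
    "recovery_summary",
]


@dataclass(frozen=True)
class CrimeParams:
    """Stationary AR(1) specification for one crime-rate series.

    Each state gets its own long-run mean ~ Normal(mean, between_sd);
    deviations follow AR(1) with stationary SD ``within_sd`` and
    autocorrelation ``rho``.  Rates are clipped at zero.
    """

    mean: float
    between_sd: float
    within_sd: float
    rho: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of the synthetic world (all knobs explicit)."""

    n_states: int = 50
    n_years: int = 18
    first_year: int = 1999
    # true coefficients on the standardized covariate scale
    beta_gun: float = 0.06
    beta_violent_crime: float = 0.2
    beta_property_crime: float = 0.1
    beta_crime_interaction: float = 0.0
    phi_true: float = 5.0
    alpha_bar_true: float = -10.0
    # confounding structure (unitless loadings of U_s)
    confound_strength_gamma: float = 0.5
    confound_to_exposure_delta: float = 0.5
    # exposure scale, percentage points
    exposure_mean: float = 40.0
    exposure_between_sd: float = 13.45
    exposure_within_sd: float = 2.0
    ownership_bounds: tuple[float, float] = (2.0, 70.0)
    # population (persons), log-normal across states, constant over years
    population_log_mean: float = math.log(4.0e6)
    population_log_sd: float = 0.9
    population_drift_sd: float = 0.0
    # crime predictors
    violent_crime: CrimeParams = field(
        default_factory=lambda: CrimeParams(380.0, 120.0, 60.0, 0.85)
    )
    property_crime: CrimeParams = field(
        default_factory=lambda: CrimeParams(3000.0, 700.0, 250.0, 0.85)
    )
    crime_exposure_loading: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.phi_true <= 0:
            raise ValueError("phi_true must be > 0")
        if self.exposure_within_sd < 0:
            raise ValueError("exposure_within_sd must be >= 0")

    def beta_dict(self) -> dict[str, float]:
        return {
            "beta_gun": self.beta_gun,
            "beta_violent_crime": self.beta_violent_crime,
            "beta_property_crime": self.beta_property_crime,
            "beta_crime_interaction": self.beta_crime_interaction,
        }


@dataclass
class TrueParameters:
    """Ground truth realized during generation, kept for recovery tests."""

    alpha_bar: float
    alpha_state: np.ndarray
    beta: dict[str, float]
    phi: float
    U_s: np.ndarray
    state_mean_ownership: np.ndarray
    population: np.ndarray
    n_ownership_clipped: int

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("alpha_state", "U_s", "state_mean_ownership", "population"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def _ar1(rng, n_states, n_years, p: CrimeParams) -> np.ndarray:
    """(n_states, n_years) stationary AR(1) panels around state means."""
    mu = p.mean + p.between_sd * rng.standard_normal(n_states)
    x = np.empty((n_states, n_years))
    x[:, 0] = mu + p.within_sd * rng.standard_normal(n_states)
    innov_sd = p.within_sd * math.sqrt(max(1.0 - p.rho**2, 0.0))
    for t in range(1, n_years):
        x[:, t] = mu + p.rho * (x[:, t - 1] - mu) + innov_sd * \
            rng.standard_normal(n_states)
    return np.clip(x, 0.0, None)


def simulate_panel(
    config: GeneratorConfig,
) -> tuple[PanelTable, TrueParameters]:
    """Generate one balanced panel plus the truth used to make it.

    Deterministic in ``config.seed``.  Raises
    :class:`GenerationError` if the configuration drives the count rate
    past the overflow threshold.
    """
    rng = np.random.default_rng(config.seed)
    S, T = config.n_states, config.n_years

    U = rng.standard_normal(S)
    V = rng.standard_normal(S)
    delta = config.confound_to_exposure_delta
    mix = (delta * U + V) / math.sqrt(1.0 + delta * delta)
    m_raw = config.exposure_mean + config.exposure_between_sd * mix
    lo, hi = config.ownership_bounds
    m = np.clip(m_raw, lo, hi)
    n_clipped = int(np.sum(m != m_raw))

    alpha = config.alpha_bar_true + config.confound_strength_gamma * U
    pop0 = rng.lognormal(config.population_log_mean, config.population_log_sd,
                         size=S)
    pop = np.repeat(pop0[:, None], T, axis=1)
    if config.population_drift_sd > 0:
        drift = np.cumsum(
            config.population_drift_sd * rng.standard_normal((S, T)), axis=1
        )
        pop = pop * np.exp(drift - drift[:, [0]])
    pop = np.maximum(np.round(pop), 1.0)

    G = m[:, None] + config.exposure_within_sd * rng.standard_normal((S, T))
    G = np.clip(G, 0.0, 100.0)
    n_clipped += int(np.sum((G == 0.0) | (G == 100.0)))

    c = config.crime_exposure_loading
    vc = _ar1(rng, S, T, config.violent_crime)
    pc = _ar1(rng, S, T, config.property_crime)
    if c != 0.0:
        # optional sensitivity knob: load the confound onto crime means
        vc = vc + c * config.violent_crime.between_sd * U[:, None]
        pc = pc + c * config.property_crime.between_sd * U[:, None]
        vc, pc = np.clip(vc, 0.0, None), np.clip(pc, 0.0, None)

    # the true effects apply to the covariates as the fitted models see
    # them: standardized pooled over the realized sample
    G_std = standardize(G.ravel())[0].reshape(S, T)
    VC_std = standardize(vc.ravel())[0].reshape(S, T)
    PC_std = standardize(pc.ravel())[0].reshape(S, T)

    log_lam = (
        np.log(pop)
        + alpha[:, None]
        + config.beta_gun * G_std
        + config.beta_violent_crime * VC_std
        + config.beta_property_crime * PC_std
        + config.beta_crime_interaction * VC_std * PC_std
    )
    if np.any(log_lam > 30.0):
        worst = float(log_lam.max())
        raise GenerationError(
            f"log rate overflow (max log lambda = {worst:.1f}); check "
            "alpha_bar_true / confound_strength_gamma / population scale"
        )
    lam = np.exp(log_lam)
    mult = rng.gamma(shape=config.phi_true, scale=1.0 / config.phi_true,
                     size=lam.shape)
    deaths = rng.poisson(lam * mult)

    years = np.arange(config.first_year, config.first_year + T)
    width = len(str(S))
    states = [f"S{i + 1:0{width}d}" for i in range(S)]
    df = pd.DataFrame(
        {
            "state": np.repeat(states, T),
            "year": np.tile(years, S),
            "deaths": deaths.ravel(),
            "population": pop.ravel().astype(np.int64),
            "gun_ownership": G.ravel(),
            "violent_crime_rate": vc.ravel(),
            "property_crime_rate": pc.ravel(),
        }
    )
    truth = TrueParameters(
        alpha_bar=config.alpha_bar_true,
        alpha_state=alpha,
        beta=config.beta_dict(),
        phi=config.phi_true,
        U_s=U,
        state_mean_ownership=m,
        population=pop0,
        n_ownership_clipped=n_clipped,
    )
    return PanelTable(df), truth


def calibration_report(panel: PanelTable) -> pd.DataFrame:
    """Descriptive statistics in the style of a panel summary table.

    Rows: deaths, death rate per 100,000, ownership %, violent and
    property crime rates; columns: median, IQR, min, max, SD.
    """
    df = panel.df
    series = {
        "deaths": df["deaths"].astype(float),
        "death_rate_per_100k": df["deaths"] / df["population"] * 1e5,
        "gun_ownership_pct": df["gun_ownership"].astype(float),
        "violent_crime_rate": df["violent_crime_rate"].astype(float),
        "property_crime_rate": df["property_crime_rate"].astype(float),
    }
    rows = []
    for name, s in series.items():
        q1, med, q3 = np.percentile(s, [25, 50, 75])
        rows.append(
            {
                "variable": name,
                "median": med,
                "iqr": q3 - q1,
                "min": float(s.min()),
                "max": float(s.max()),
                "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def recovery_study(
    gen_config: GeneratorConfig,
    sampler_config: SamplerConfig,
    n_reps: int = 20,
    model_kinds: tuple = (ModelKind.MUNDLAK, ModelKind.FIXED_EFFECTS),
    adjusted: bool = False,
    base_seed: int = 0,
    mass: float = 0.89,
    parameter: str = "beta_gun",
) -> pd.DataFrame:
    """Replicate simulate-and-fit study for interval coverage and bias.

    Returns one row per (replicate, model) with the posterior mean/SD,
    HPDI bounds, whether the interval covers the truth, and the
    z-distance of the posterior mean from the truth.  All seeds derive
    deterministically from ``base_seed``.
    """
    from dataclasses import replace as _replace

    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_reps, 2))
    truth_val = gen_config.beta_dict().get(parameter)
    rows = []
    for rep in range(n_reps):
        cfg = _replace(gen_config, seed=int(seeds[rep, 0]))
        panel, _truth = simulate_panel(cfg)
        for kind in model_kinds:
            kind = ModelKind(kind)
            data = build_model_data(panel, kind, adjusted=adjusted)
            sc = _replace(sampler_config, seed=int(seeds[rep, 1]))
            post = sample_posterior(data, sc)
            summ = summarize(post, parameter, mass)
            rows.append(
                {
                    "rep": rep,
                    "model": kind.value,
                    "mean": summ.mean,
                    "sd": summ.se,
                    "lower": summ.interval.lower,
                    "upper": summ.interval.upper,
                    "truth": truth_val,
                    "covers": summ.interval.contains(truth_val),
                    "z": (summ.mean - truth_val) / summ.se,
                }
            )
    return pd.DataFrame(rows)


def recovery_summary(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a recovery study: coverage, bias, bias MC error per model."""
    out = []
    for model, grp in per_rep.groupby("model", sort=False):
        bias = grp["mean"] - grp["truth"]
        out.append(
            {
                "model": model,
                "n_reps": len(grp),
                "coverage": float(grp["covers"].mean()),
                "mean_bias": float(bias.mean()),
                "bias_mc_se": float(bias.std(ddof=1) / math.sqrt(len(grp))),
                "mean_posterior_sd": float(grp["sd"].mean()),
                "frac_beyond_2sd": float((grp["z"].abs() > 2).mean()),
            }
        )
    return pd.DataFrame(out).set_index("model")
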