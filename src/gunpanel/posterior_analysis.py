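"""Reported quantities: IRR, densities, posterior predictive, forest data.

Because the exposure enters the model standardized, the coefficient on
gun ownership is a log-rate change per one sample SD of ownership
(about 13.6 percentage points on the scales this package emulates), and
exp(beta) is the incidence rate ratio (IRR) per SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .exceptions import ConfigurationError
from .inference import Interval, PosteriorDraws
from .panel_data import ModelData

__all__ = [
    "IRRReport",
    "PredictiveSample",
    "DensitySummary",
    "irr_from_coefficient",
    "posterior_predictive",
    "predictive_coverage",
    "density_summary",
    "forest_table",
    "forest_plot",
    "density_plot",
    "predictive_plot",
]


@dataclass(frozen=True)
class IRRReport:
    """Incidence-rate-ratio conversion of a log-rate coefficient.

    ``exposure_sd_original_units`` is annotation only (the coefficient
    is already per-SD); ``percent_change`` keeps full precision, with
    integer rounding applied only in :meth:`display`.
    """

    coefficient_mean: float
    irr: float
    percent_change: float
    exposure_sd_original_units: float | None = None

    def display(self) -> str:
        return f"{round(self.percent_change):d}%"


def irr_from_coefficient(
    beta_mean: float, exposure_sd: float | None = None
) -> IRRReport:
    """IRR = exp(beta); percent change = (IRR - 1) * 100."""
    if not math.isfinite(beta_mean):
        raise ValueError("coefficient must be finite")
    irr = math.exp(beta_mean)
    return IRRReport(
        coefficient_mean=float(beta_mean),
        irr=irr,
        percent_change=(irr - 1.0) * 100.0,
        exposure_sd_original_units=exposure_sd,
    )


@dataclass
class PredictiveSample:
    """Simulated counts (draw x observation) next to the observed ones."""

    simulated_counts: np.ndarray
    observed_counts: np.ndarray


def posterior_predictive(
    posterior: PosteriorDraws,
    data: ModelData,
    n_draws: int = 200,
    seed: int = 0,
) -> PredictiveSample:
    """Simulate replicate count panels from sampled parameter draws.

    For each selected posterior draw, computes the rate vector through
    the linear predictor and draws counts from the Gamma-Poisson via
    its latent-Gamma representation (rate multiplier ~ Gamma(phi, phi)).
    """
    total = posterior.n_chains * posterior.n_samples
    if n_draws > total:
        raise ConfigurationError(
            f"n_draws={n_draws} exceeds available posterior draws ({total})"
        )
    names = posterior.parameter_names
    flat = posterior.draws.reshape(total, len(names))
    cols = {n: j for j, n in enumerate(names)}
    alpha_idx = [cols[f"alpha[{s}]"] for s in data.state_labels]
    beta_idx = [cols[b] for b in data.beta_names]
    phi_idx = cols["phi"]

    rng = np.random.default_rng(seed)
    sel = rng.choice(total, size=n_draws, replace=False)
    X = data.design_matrix()
    sims = np.empty((n_draws, data.n_obs), dtype=np.int64)
    for r, idx in enumerate(sel):
        row = flat[idx]
        lp = data.log_offset + row[alpha_idx][data.group_index]
        if beta_idx:
            lp = lp + X @ row[beta_idx]
        lam = np.exp(lp)
        phi = row[phi_idx]
        mult = rng.gamma(shape=phi, scale=1.0 / phi, size=lam.size)
        sims[r] = rng.poisson(lam * mult)
    return PredictiveSample(simulated_counts=sims, observed_counts=data.y)


def predictive_coverage(sample: PredictiveSample, mass: float = 0.89) -> float:
    """Fraction of observed counts inside their pointwise HPD intervals."""
    from .inference import hpdi

    sims = sample.simulated_counts
    inside = 0
    for j in range(sims.shape[1]):
        iv = hpdi(sims[:, j], mass)
        inside += iv.contains(float(sample.observed_counts[j]))
    return inside / sims.shape[1]


@dataclass
class DensitySummary:
    """Kernel density of one parameter on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    is_point_mass: bool = False


def density_summary(
    posterior: PosteriorDraws,
    parameter: str,
    grid_size: int = 256,
    bw_method="silverman",
) -> DensitySummary:
    """Gaussian KDE over the draw range (Silverman bandwidth default)."""
    d = posterior.get(parameter).ravel()
    if np.ptp(d) == 0.0:
        return DensitySummary(
            grid=np.array([d[0]]),
            density=np.array([np.nan]),
            is_point_mass=True,
        )
    kde = gaussian_kde(d, bw_method=bw_method)
    grid = np.linspace(d.min(), d.max(), grid_size)
    return DensitySummary(grid=grid, density=kde(grid))


def forest_table(
    summaries: list[tuple[str, float, Interval]]
) -> pd.DataFrame:
    """Forest-plot data: one row per model with mean, bounds, zero flag."""
    if not summaries:
        raise ValueError("forest_table needs at least one entry")
    rows = [
        {
            "model": label,
            "mean": mean,
            "lower": iv.lower,
            "upper": iv.upper,
            "mass": iv.mass,
            "includes_zero": iv.lower <= 0.0 <= iv.upper,
        }
        for label, mean, iv in summaries
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plot artifacts (not part of the testable numeric contract)


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def forest_plot(table: pd.DataFrame, path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(table) + 1.5))
    ypos = np.arange(len(table))[::-1]
    ax.hlines(ypos, table["lower"], table["upper"], color="k")
    ax.plot(table["mean"], ypos, "ko")
    ax.axvline(0.0, color="grey", ls="--", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["model"])
    ax.set_xlabel("gun-ownership coefficient (per exposure SD), with HPDI")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def density_plot(summary: DensitySummary, path, label: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if summary.is_point_mass:
        ax.axvline(summary.grid[0], color="k")
    else:
        ax.plot(summary.grid, summary.density, "k-")
        ax.fill_between(summary.grid, summary.density, alpha=0.2)
    ax.set_xlabel(label or "parameter")
    ax.set_ylabel("posterior density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def predictive_plot(sample: PredictiveSample, path, n_show: int = 50) -> None:
    """Observed count distribution overlaid with predictive replicates."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    obs = sample.observed_counts
    grid = np.linspace(0, np.percentile(obs, 99.5) * 1.3, 200)
    for sim in sample.simulated_counts[:n_show]:
        kde = gaussian_kde(np.log1p(sim))
        ax.plot(np.log1p(grid), kde(np.log1p(grid)), color="C0", alpha=0.15,
                lw=0.8)
    kde = gaussian_kde(np.log1p(obs))
    ax.plot(np.log1p(grid), kde(np.log1p(grid)), color="k", lw=2,
            label="observed")
    ax.set_xlabel("log(1 + deaths)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
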