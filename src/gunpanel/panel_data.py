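"""State-year panel ingestion and model-ready design construction.

The analysis dataset is a (state, year) panel of firearm-homicide death
counts with a population offset, a household gun-ownership exposure
(percent), and violent/property crime rates per 100,000.  This module
validates such panels, standardizes the continuous covariates (pooled
across all state-years, sample SD with the n-1 denominator), and
assembles the design arrays consumed by the count models:

* ``mundlak`` — hierarchical state intercepts plus the state mean of the
  standardized exposure as an extra covariate (the Mundlak device);
* ``fixed_effects`` — one free intercept per state, no group-mean term;
* ``naive`` — hierarchical intercepts *without* the group-mean term, a
  deliberately misspecified variant used to demonstrate confounding bias.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateVarianceError,
    MissingGroupError,
    PanelValidationError,
    SchemaError,
)

#: canonical column names, in canonical order
PANEL_COLUMNS = (
    "state",
    "year",
    "deaths",
    "population",
    "gun_ownership",
    "violent_crime_rate",
    "property_crime_rate",
)


class ModelKind(str, enum.Enum):
    """Which linear predictor / intercept structure to fit."""

    MUNDLAK = "mundlak"
    FIXED_EFFECTS = "fixed_effects"
    NAIVE = "naive"

    @property
    def hierarchical(self) -> bool:
        """True when state intercepts are partially pooled."""
        return self is not ModelKind.FIXED_EFFECTS

    @property
    def has_group_mean(self) -> bool:
        """True when the state-mean exposure covariate is included."""
        return self is ModelKind.MUNDLAK


@dataclass(frozen=True)
class StandardizationParams:
    """Mean/SD pair (original units) defining a z-score transform."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise DegenerateVarianceError(f"sd must be > 0, got {self.sd}")

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(x) -> tuple[np.ndarray, StandardizationParams]:
    """Z-score a vector; returns the scores and the inverting parameters.

    Uses the pooled sample mean and the n-1 sample SD.  Raises
    :class:`DegenerateVarianceError` for (near-)constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize expects a 1-d vector of length >= 2")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateVarianceError(
            f"cannot standardize a constant vector (sd={sd})"
        )
    params = StandardizationParams(mean=mean, sd=sd)
    return params.apply(x), params


def compute_state_means(values, group_index, n_states: int) -> np.ndarray:
    """Per-group arithmetic means; ``group_index`` is 0-based.

    Raises :class:`MissingGroupError` if any group in ``0..n_states-1``
    has no observations.
    """
    values = np.asarray(values, dtype=float)
    group_index = np.asarray(group_index)
    if values.shape != group_index.shape:
        raise ValueError("values and group_index must be aligned")
    counts = np.bincount(group_index, minlength=n_states)
    if counts.size > n_states:
        raise ValueError("group_index exceeds n_states")
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise MissingGroupError(f"groups with no observations: {empty.tolist()}")
    sums = np.bincount(group_index, weights=values, minlength=n_states)
    return sums / counts


class PanelTable:
    """A validated state-year panel.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical
    columns; guarantees the record invariants (non-negative integer
    counts, positive population, ownership in [0, 100], non-negative
    crime rates) and unique (state, year) keys.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing panel columns: {missing}")
        df = df.loc[:, list(PANEL_COLUMNS)].reset_index(drop=True)
        _validate_records(df)
        dup = df.duplicated(subset=["state", "year"])
        if dup.any():
            rows = (df.index[dup] + 1).tolist()
            raise PanelValidationError(
                f"duplicate (state, year) pairs at data rows {rows}", rows
            )
        df = df.astype(
            {"year": int, "deaths": int, "population": int}, errors="raise"
        )
        self.df = df
        if not self.is_balanced:
            warnings.warn(
                "panel is unbalanced: "
                f"{self.n_records} records != {self.n_states} states x "
                f"{self.n_years} years",
                stacklevel=2,
            )

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_states(self) -> int:
        return self.df["state"].nunique()

    @property
    def n_years(self) -> int:
        return self.df["year"].nunique()

    @property
    def is_balanced(self) -> bool:
        return self.n_records == self.n_states * self.n_years

    @property
    def state_labels(self) -> list:
        return sorted(self.df["state"].unique())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def __repr__(self):
        return (
            f"PanelTable(n_records={self.n_records}, n_states={self.n_states},"
            f" n_years={self.n_years}, balanced={self.is_balanced})"
        )


def _validate_records(df: pd.DataFrame) -> None:
    """Collect invariant violations and raise with 1-based row numbers."""
    problems: dict[int, list[str]] = {}

    def flag(mask, message):
        for idx in np.flatnonzero(np.asarray(mask)):
            problems.setdefault(int(idx) + 1, []).append(message)

    numeric = {}
    for col in PANEL_COLUMNS[2:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        flag(vals.isna(), f"{col} is non-numeric or missing")
        numeric[col] = vals

    deaths = numeric["deaths"]
    ok = deaths.notna()
    flag(ok & (deaths < 0), "deaths < 0")
    flag(ok & (deaths % 1 != 0), "deaths is not an integer")
    pop = numeric["population"]
    flag(pop.notna() & (pop <= 0), "population <= 0")
    own = numeric["gun_ownership"]
    flag(own.notna() & ((own < 0) | (own > 100)), "gun_ownership outside [0, 100]")
    for col in ("violent_crime_rate", "property_crime_rate"):
        v = numeric[col]
        flag(v.notna() & (v < 0), f"{col} < 0")

    if problems:
        lines = [
            f"  row {row}: {'; '.join(msgs)}"
            for row, msgs in sorted(problems.items())
        ]
        raise PanelValidationError(
            "invalid panel rows:\n" + "\n".join(lines), sorted(problems)
        )


def load_panel(path, schema: dict | None = None) -> PanelTable:
    """Read a panel CSV, optionally remapping column names.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping ``{canonical_name: column_name_in_file}`` for
        files whose headers differ from :data:`PANEL_COLUMNS`.
    """
    df = pd.read_csv(path)
    if schema:
        unknown = set(schema) - set(PANEL_COLUMNS)
        if unknown:
            raise SchemaError(f"schema maps unknown canonical columns: {sorted(unknown)}")
        missing = [src for src in schema.values() if src not in df.columns]
        if missing:
            raise SchemaError(f"schema refers to absent columns: {missing}")
        df = df.rename(columns={src: canon for canon, src in schema.items()})
    return PanelTable(df)


@dataclass
class ModelData:
    """Design arrays for one model variant, all aligned on n observations.

    ``group_index`` is 0-based into ``state_labels``; ``G_bar_by_state``
    is on the standardized scale and present only for the Mundlak model.
    """

    y: np.ndarray
    log_offset: np.ndarray
    group_index: np.ndarray
    n_states: int
    G_std: np.ndarray
    VC_std: np.ndarray | None
    PC_std: np.ndarray | None
    G_bar_by_state: np.ndarray | None
    model_kind: ModelKind
    adjusted: bool
    standardization: dict[str, StandardizationParams]
    state_labels: list = field(default_factory=list)
    _X: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def beta_names(self) -> list[str]:
        names = ["beta_gun"]
        if self.adjusted:
            names += [
                "beta_violent_crime",
                "beta_property_crime",
                "beta_crime_interaction",
            ]
        if self.model_kind.has_group_mean:
            names.append("beta_gun_state_mean")
        return names

    def design_matrix(self) -> np.ndarray:
        """Covariate columns in ``beta_names`` order (n x k)."""
        if self._X is None:
            cols = [self.G_std]
            if self.adjusted:
                cols += [self.VC_std, self.PC_std, self.VC_std * self.PC_std]
            if self.model_kind.has_group_mean:
                cols.append(self.G_bar_by_state[self.group_index])
            self._X = np.column_stack(cols)
        return self._X

    def summary(self) -> dict:
        """JSON-serializable description for reproducibility logs."""
        return {
            "model_kind": self.model_kind.value,
            "adjusted": self.adjusted,
            "n_obs": int(self.n_obs),
            "n_states": int(self.n_states),
            "beta_names": self.beta_names,
            "standardization": {
                k: {"mean": p.mean, "sd": p.sd}
                for k, p in self.standardization.items()
            },
            "total_deaths": int(self.y.sum()),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def build_model_data(
    panel: PanelTable,
    model_kind: ModelKind | str = ModelKind.MUNDLAK,
    adjusted: bool = True,
) -> ModelData:
    """Assemble standardized design arrays from a validated panel.

    Standardization of the exposure and crime rates is pooled over all
    state-years; the crime interaction is the product of the two
    standardized rates; the offset is the natural log of the raw
    person-count population.  The Mundlak group mean is computed on the
    standardized exposure so its coefficient shares units with the
    within-state exposure coefficient.
    """
    model_kind = ModelKind(model_kind)
    df = panel.df.sort_values(["state", "year"], kind="mergesort").reset_index(
        drop=True
    )
    labels = panel.state_labels
    label_to_idx = {s: i for i, s in enumerate(labels)}
    group_index = df["state"].map(label_to_idx).to_numpy()

    G_std, g_params = standardize(df["gun_ownership"].to_numpy())
    standardization = {"gun_ownership": g_params}
    VC_std = PC_std = None
    if adjusted:
        VC_std, vc_params = standardize(df["violent_crime_rate"].to_numpy())
        PC_std, pc_params = standardize(df["property_crime_rate"].to_numpy())
        standardization["violent_crime_rate"] = vc_params
        standardization["property_crime_rate"] = pc_params

    G_bar = None
    if model_kind.has_group_mean:
        G_bar = compute_state_means(G_std, group_index, len(labels))

    return ModelData(
        y=df["deaths"].to_numpy(dtype=np.int64),
        log_offset=np.log(df["population"].to_numpy(dtype=float)),
        group_index=group_index,
        n_states=len(labels),
        G_std=G_std,
        VC_std=VC_std,
        PC_std=PC_std,
        G_bar_by_state=G_bar,
        model_kind=model_kind,
        adjusted=adjusted,
        standardization=standardization,
        state_labels=labels,
    )
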