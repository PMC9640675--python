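"""nifH-based upscaling of diazotroph N2 fixation and the contribution
fraction R_Tr.

A group's volumetric fixation rate is its nifH gene abundance divided by
the copies-per-cell conversion factor, times the cell-specific rate;
daily rates assume a fixed photoperiod of nitrogenase activity (12 h by
default).  Group shares of the summed rate give per-group contribution
fractions, of which the Trichodesmium entry is R_Tr.

The spatial abundance mapping is a pluggable regressor interface: any
object with ``predict(predictors) -> abundance`` per group can stand in
for a trained model.  The bundled default is a deterministic parametric
response surface (log10 abundance linear in a temperature proxy), so the
pipeline runs end-to-end without learned weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from trichoproj.errors import (
    ConfigurationError,
    DomainError,
    ShapeError,
    UndefinedFractionError,
)
from trichoproj.ocean import GriddedField

DEFAULT_ACTIVE_HOURS = 12.0


@dataclass(frozen=True)
class DiazotrophGroupParams:
    """Per-group conversion constants for the abundance-to-rate step.

    nifh_copies_per_cell converts gene copies L-1 to cells L-1;
    cell_rate is fmol N cell-1 h-1; active_hours the daily window of
    nitrogenase activity.  Values are configuration (group-specific
    literature averages), not package constants.
    """

    group: str
    nifh_copies_per_cell: float
    cell_rate: float
    active_hours: float = DEFAULT_ACTIVE_HOURS

    def __post_init__(self) -> None:
        if self.nifh_copies_per_cell <= 0:
            raise ConfigurationError("nifh_copies_per_cell must be positive")
        if self.cell_rate < 0:
            raise ConfigurationError("cell_rate must be non-negative")
        if not 0 < self.active_hours <= 24:
            raise ConfigurationError("active_hours must lie in (0, 24]")


def load_group_params(path=None) -> dict[str, DiazotrophGroupParams]:
    """Read a group parameter CSV (group, nifh_copies_per_cell,
    cell_rate_fmol_h, active_hours).

    Without a path, loads the bundled editable placeholder table
    (``data/diazotroph_groups.csv``); its values are illustrative
    defaults, not literature constants.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "diazotroph_groups.csv"
    df = pd.read_csv(path, comment="#")
    out = {}
    for _, row in df.iterrows():
        out[row["group"]] = DiazotrophGroupParams(
            group=row["group"],
            nifh_copies_per_cell=float(row["nifh_copies_per_cell"]),
            cell_rate=float(row["cell_rate_fmol_h"]),
            active_hours=float(row.get("active_hours", DEFAULT_ACTIVE_HOURS)),
        )
    return out


@dataclass
class GroupRates:
    """Per-group volumetric rates and contribution fractions."""

    hourly: dict[str, float]  # fmol N L-1 h-1
    daily: dict[str, float]  # fmol N L-1 d-1
    fractions: dict[str, float]


def group_rate_from_nifh(abundance, params: DiazotrophGroupParams):
    """Volumetric rate (fmol N L-1 h-1) from a nifH abundance (copies L-1)."""
    abundance = np.asarray(abundance, dtype=float)
    if np.any(abundance[np.isfinite(abundance)] < 0):
        raise DomainError("abundance must be non-negative")
    out = abundance / params.nifh_copies_per_cell * params.cell_rate
    return float(out) if out.ndim == 0 else out


def daily_rate(hourly_rate, active_hours: float = DEFAULT_ACTIVE_HOURS):
    """Daily rate from an hourly rate over the active photoperiod."""
    if not 0 < active_hours <= 24:
        raise ConfigurationError("active_hours must lie in (0, 24]")
    hourly_rate = np.asarray(hourly_rate, dtype=float)
    if np.any(hourly_rate[np.isfinite(hourly_rate)] < 0):
        raise DomainError("hourly rate must be non-negative")
    out = hourly_rate * active_hours
    return float(out) if out.ndim == 0 else out


def contribution_fraction(group_rates: Mapping[str, float]) -> dict[str, float]:
    """Share of each group in the summed rate; values sum to 1."""
    rates = {g: float(r) for g, r in group_rates.items()}
    if any(r < 0 for r in rates.values()):
        raise DomainError("rates must be non-negative")
    total = sum(rates.values())
    if total <= 0:
        raise UndefinedFractionError("total rate is zero; fractions undefined")
    return {g: r / total for g, r in rates.items()}


def compute_rates(
    abundances: Mapping[str, float],
    params: Mapping[str, DiazotrophGroupParams],
) -> GroupRates:
    """Abundances -> hourly and daily rates -> contribution fractions."""
    hourly = {}
    daily = {}
    for group, abundance in abundances.items():
        if group not in params:
            raise ConfigurationError(f"no parameters for group {group!r}")
        p = params[group]
        h = group_rate_from_nifh(abundance, p)
        hourly[group] = h
        daily[group] = daily_rate(h, p.active_hours)
    return GroupRates(hourly, daily, contribution_fraction(daily))


class AbundanceRegressor(Protocol):
    """Contract for pluggable abundance models: named predictor fields in,
    one non-negative abundance field per group out."""

    groups: Sequence[str]

    def predict(self, predictors: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        ...


@dataclass
class ParametricAbundanceModel:
    """Deterministic default regressor: abundance = intercept * 10^(slope*T).

    log10 abundance is linear in the temperature proxy; at a zero proxy
    the predicted abundance equals the intercept (copies L-1).
    """

    intercepts: dict[str, float]
    slopes: dict[str, float]
    predictor: str = "temperature"

    def __post_init__(self) -> None:
        if set(self.intercepts) != set(self.slopes):
            raise ConfigurationError("intercepts and slopes must cover the same groups")
        if any(v <= 0 for v in self.intercepts.values()):
            raise ConfigurationError("intercepts must be positive abundances")
        self.groups = sorted(self.intercepts)

    def predict(self, predictors: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        if self.predictor not in predictors:
            raise ConfigurationError(f"missing predictor {self.predictor!r}")
        t = np.asarray(predictors[self.predictor], dtype=float)
        return {
            g: self.intercepts[g] * 10.0 ** (self.slopes[g] * t) for g in self.groups
        }


def map_abundance(
    predictors: Mapping[str, GriddedField],
    regressor: AbundanceRegressor,
) -> dict[str, GriddedField]:
    """Evaluate an abundance model over gridded predictors.

    Returns one abundance field (nifH copies L-1) per diazotroph group;
    negative model output is a contract violation.
    """
    if not predictors:
        raise ConfigurationError("need at least one predictor field")
    shapes = {f.values.shape for f in predictors.values()}
    if len(shapes) != 1:
        raise ShapeError(f"predictor shapes differ: {shapes}")
    era = next(iter(predictors.values())).era
    arrays = {name: f.values for name, f in predictors.items()}
    predicted = regressor.predict(arrays)
    out = {}
    for group, values in predicted.items():
        values = np.asarray(values, dtype=float)
        if values.shape not in shapes:
            raise ShapeError(f"regressor output for {group!r} has wrong shape")
        if np.any(values[np.isfinite(values)] < 0):
            raise ConfigurationError(
                f"regressor produced negative abundance for group {group!r}"
            )
        out[group] = GriddedField(f"nifh_{group}", "copies L-1", values, era)
    return out
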