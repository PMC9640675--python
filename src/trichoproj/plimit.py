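"""Dual-substrate Michaelis-Menten phosphorus limitation.

Diazotrophs can use both phosphate (PO4) and dissolved organic phosphorus
(DOP); the combined limiting factor shares one saturation denominator:

    V_PO4 = (PO4/K_PO4) / (1 + PO4/K_PO4 + DOP/K_DOP)
    V_DOP = (DOP/K_DOP) / (1 + PO4/K_PO4 + DOP/K_DOP)
    V_P   = V_PO4 + V_DOP

with K_PO4 about five times smaller than K_DOP, expressing the preference
for phosphate.  A cell is P-limited where V_P falls below every other
nutrient's limitation factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from trichoproj.errors import ConfigurationError, DomainError, ShapeError
from trichoproj.ocean import GriddedField

#: Default half-saturations (mmol m-3).  Only the 5:1 K_DOP:K_PO4
#: relationship is constrained; the absolute values are package defaults
#: and fully overridable.
DEFAULT_K_PO4 = 0.01
DEFAULT_K_DOP = 0.05


@dataclass(frozen=True)
class PLimitationParams:
    k_po4: float = DEFAULT_K_PO4
    k_dop: float = DEFAULT_K_DOP

    def __post_init__(self) -> None:
        if self.k_po4 <= 0 or self.k_dop <= 0:
            raise ConfigurationError("half-saturation constants must be positive")


@dataclass
class LimitationFactors:
    """Per-cell (or scalar) limitation terms; v_p = v_po4 + v_dop < 1."""

    v_po4: np.ndarray | float
    v_dop: np.ndarray | float
    v_p: np.ndarray | float


def p_limitation_factors(
    po4, dop, params: PLimitationParams = PLimitationParams()
) -> LimitationFactors:
    """Evaluate the dual-substrate limitation factor element-wise.

    Accepts scalars or arrays (NaN passes through, so land cells of a
    gridded field stay NaN).
    """
    po4 = np.asarray(po4, dtype=float)
    dop = np.asarray(dop, dtype=float)
    if np.any(po4[np.isfinite(po4)] < 0) or np.any(dop[np.isfinite(dop)] < 0):
        raise DomainError("concentrations must be non-negative")
    s_po4 = po4 / params.k_po4
    s_dop = dop / params.k_dop
    denom = 1.0 + s_po4 + s_dop
    v_po4 = s_po4 / denom
    v_dop = s_dop / denom
    if v_po4.ndim == 0:
        return LimitationFactors(float(v_po4), float(v_dop), float(v_po4 + v_dop))
    return LimitationFactors(v_po4, v_dop, v_po4 + v_dop)


def p_limited_mask(
    v_p: GriddedField,
    aux_limits: Mapping[str, GriddedField],
    mode: Literal["argmin", "threshold"] = "argmin",
    threshold: float | None = None,
) -> GriddedField:
    """Flag the grid cells where P is the limiting nutrient.

    argmin mode (default): a cell is P-limited iff its P limitation
    factor is strictly smaller than every auxiliary (non-P) limitation
    factor there; ties resolve to not-P-limited, which routes the cell to
    the milder P-replete acidification scaling.  threshold mode flags
    cells with v_p below a fixed cutoff instead.
    """
    vp = np.asarray(v_p.values, dtype=float)
    for name, f in aux_limits.items():
        if np.asarray(f.values).shape != vp.shape:
            raise ShapeError(f"aux limit {name!r} shape mismatch")
    if mode == "argmin":
        if not aux_limits:
            raise ConfigurationError("argmin mode needs at least one auxiliary factor")
        aux_stack = np.stack([np.asarray(f.values, float) for f in aux_limits.values()])
        limited = vp < np.min(aux_stack, axis=0)
    elif mode == "threshold":
        if threshold is None or not 0.0 < threshold < 1.0:
            raise ConfigurationError("threshold mode needs threshold in (0, 1)")
        limited = vp < threshold
    else:
        raise ConfigurationError(f"unknown mask mode {mode!r}")
    limited = np.where(np.isfinite(vp), limited, False)
    return GriddedField("p_limited", "0/1", limited.astype(float), v_p.era)
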