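"""Acidification scalings of Trichodesmium N2 fixation and global integrals.

The reference climatology is NF_Tr = NF x R_Tr per grid cell (total N2
fixation times the Trichodesmium contribution fraction), taken from an
era's ocean state without any acidification effect.  Two linear-in-[H+]
scalings project it forward:

* P-replete (oa-only):   factor = 1 + oa * x
* P-limited (oa + P):    factor = (1 + oap_c * x) * (1 + oap_n * x)

with x = ([H+]_s - [H+]_0) / ([H+]_1 - [H+]_0) interpolating (and
extrapolating) the laboratory calibration interval.  Each linear term is
clamped below at zero before use, since neither biomass nor a fixation
rate can be negative; factors above 1 (cells more alkaline than the lower
anchor) are allowed and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from trichoproj.calibration import EffectParameters
from trichoproj.errors import ConfigurationError, DomainError, ShapeError
from trichoproj.grid import GridGeometry
from trichoproj.ocean import GriddedField, OceanState

_GRAMS_PER_TG = 1e12

Scenario = Literal["oa_only", "oa_plus_p"]


def h_from_ph(ph_t):
    """Hydrogen-ion concentration (mol L-1) from pH on the total scale."""
    ph = np.asarray(ph_t, dtype=float)
    finite = ph[np.isfinite(ph)]
    if np.any((finite <= 0) | (finite >= 14)):
        raise DomainError("pH outside (0, 14)")
    out = 10.0 ** (-ph)
    return float(out) if out.ndim == 0 else out


def ph_from_h(h):
    """Inverse of :func:`h_from_ph`; exact round-trip."""
    h = np.asarray(h, dtype=float)
    if np.any(h[np.isfinite(h)] <= 0):
        raise DomainError("[H+] must be positive")
    out = -np.log10(h)
    return float(out) if out.ndim == 0 else out


def _interp_coordinate(h_s, params: EffectParameters):
    if params.h1 <= params.h0:
        raise ConfigurationError("require h1 > h0")
    h_s = np.asarray(h_s, dtype=float)
    if np.any(h_s[np.isfinite(h_s)] <= 0):
        raise DomainError("[H+] must be positive")
    return (h_s - params.h0) / (params.h1 - params.h0)


def oa_scaling_factor(h_s, params: EffectParameters = EffectParameters()):
    """P-replete scaling factor 1 + oa * x, clamped below at 0."""
    x = _interp_coordinate(h_s, params)
    out = np.maximum(1.0 + params.oa * x, 0.0)
    return float(out) if out.ndim == 0 else out


def oap_scaling_factor(h_s, params: EffectParameters = EffectParameters()):
    """P-limited scaling factor (1 + oap_c*x)(1 + oap_n*x), each bracket
    clamped below at 0 before multiplying."""
    x = _interp_coordinate(h_s, params)
    c = np.maximum(1.0 + params.oap_c * x, 0.0)
    n = np.maximum(1.0 + params.oap_n * x, 0.0)
    out = c * n
    return float(out) if out.ndim == 0 else out


@dataclass
class ProjectionResult:
    """Reference and projected Trichodesmium N2 fixation, with integrals.

    Fields are g N m-2 yr-1; integrals Tg N yr-1.  ``any_factor_above_1``
    flags grid cells more alkaline than the lower calibration anchor,
    where linear extrapolation amplifies rather than reduces fixation.
    """

    scenario: Scenario
    era: str
    reference_nf_tr: GriddedField
    projected_nf_tr: GriddedField
    delta: GriddedField
    global_reference: float
    global_projected: float
    global_delta: float
    any_factor_above_1: bool

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "era": self.era,
            "global_reference_tg": self.global_reference,
            "global_projected_tg": self.global_projected,
            "global_delta_tg": self.global_delta,
            "any_factor_above_1": self.any_factor_above_1,
        }


def global_integral(field: GriddedField, geometry: GridGeometry) -> float:
    """Area-integrate an areal field (g N m-2 yr-1) to Tg N yr-1."""
    values = np.asarray(field.values, dtype=float)
    if values.shape != geometry.shape:
        raise ShapeError(f"field shape {values.shape} != grid {geometry.shape}")
    mask = geometry.ocean_mask
    return float(np.sum(values[mask] * geometry.cell_area[mask]) / _GRAMS_PER_TG)


def project_nf(
    state: OceanState,
    params: EffectParameters = EffectParameters(),
    p_mask: GriddedField | None = None,
    scenario: Scenario = "oa_only",
) -> ProjectionResult:
    """Apply an acidification scenario to one era's ocean state.

    The per-cell reference is NF x R_Tr.  Under ``oa_only`` the P-replete
    factor applies everywhere; under ``oa_plus_p`` the combined factor
    applies on P-limited cells (given by ``p_mask``) and the P-replete
    factor elsewhere.
    """
    if scenario not in ("oa_only", "oa_plus_p"):
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    geom = state.geometry
    reference = state.nf.values * state.r_tr.values
    h_s = h_from_ph(state.ph_t.values)
    factor_oa = oa_scaling_factor(h_s, params)
    if scenario == "oa_only":
        factor = factor_oa
    else:
        if p_mask is None:
            raise ConfigurationError("oa_plus_p scenario requires a P-limited mask")
        mask_vals = np.asarray(p_mask.values)
        if mask_vals.shape != geom.shape:
            raise ShapeError("P-limited mask shape mismatch")
        limited = np.nan_to_num(mask_vals) != 0
        factor = np.where(limited, oap_scaling_factor(h_s, params), factor_oa)
    projected = reference * factor
    delta = projected - reference

    ref_f = GriddedField("nf_tr_reference", state.nf.units, reference, state.era)
    proj_f = GriddedField(f"nf_tr_{scenario}", state.nf.units, projected, state.era)
    delta_f = GriddedField("nf_tr_delta", state.nf.units, delta, state.era)
    g_ref = global_integral(ref_f, geom)
    g_proj = global_integral(proj_f, geom)
    ocean_factor = np.asarray(factor)[geom.ocean_mask]
    return ProjectionResult(
        scenario=scenario,
        era=state.era,
        reference_nf_tr=ref_f,
        projected_nf_tr=proj_f,
        delta=delta_f,
        global_reference=g_ref,
        global_projected=g_proj,
        global_delta=g_proj - g_ref,
        any_factor_above_1=bool(np.any(ocean_factor > 1.0)),
    )
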