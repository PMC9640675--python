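"""Chemostat culture arithmetic: stoichiometry, percent changes, paired
tests, cellular P quotas, and the acidification effect parameters.

The effect parameters feed the projection scalings: ``oa`` is the decline
in C-biomass-specific N2 fixation between the two pH anchor points under
P-replete growth (an external constant from a prior study), while
``oap_c`` and ``oap_n`` are the declines in C biomass (POC:POP) and in
C-biomass-specific N2 fixation measured in P-limited chemostats, derived
here from replicate culture tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from trichoproj.errors import (
    ConfigurationError,
    DegenerateVarianceError,
    DomainError,
    PairingError,
)

AVOGADRO = 6.02214076e23
#: Average molar mass of one nucleotide residue within a polynucleotide
#: (g mol-1); one phosphorus atom per residue.
RNA_NUCLEOTIDE_MW = 320.5
#: Moles of ethylene produced per mole of N2 fixed in the acetylene
#: reduction assay.
ACETYLENE_RATIO = 4.0
#: Genome size of Trichodesmium erythraeum IMS101 (base pairs) and the
#: assumed polyploidy under P limitation.
IMS101_GENOME_BP = 7_750_108
DEFAULT_GENOME_COPIES = 100

CULTURE_COLUMNS = ("n2_fix_per_cell", "c_fix_per_cell", "poc", "pon", "pop")


@dataclass(frozen=True)
class EffectParameters:
    """Calibration constants of the acidification scalings.

    h0, h1 : mol L-1, the [H+] anchor points of the laboratory pH
        interval (defaults 10^-8.01 and 10^-7.81).
    oa : fractional change in N2 fixation over [h0, h1] when P is replete
        (default -0.184).
    oap_c, oap_n : fractional changes in C biomass and C-biomass-specific
        N2 fixation over the same interval under P limitation (defaults
        -0.392 and -0.101).
    """

    h0: float = 10.0**-8.01
    h1: float = 10.0**-7.81
    oa: float = -0.184
    oap_c: float = -0.392
    oap_n: float = -0.101

    def __post_init__(self) -> None:
        if not self.h1 > self.h0 > 0:
            raise ConfigurationError("require h1 > h0 > 0")
        for name in ("oa", "oap_c", "oap_n"):
            v = getattr(self, name)
            if not -1.0 < v <= 0.0:
                raise ConfigurationError(f"{name}={v} outside (-1, 0]")

    def to_dict(self) -> dict[str, float]:
        return {
            "h0": self.h0,
            "h1": self.h1,
            "oa": self.oa,
            "oap_c": self.oap_c,
            "oap_n": self.oap_n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectParameters":
        return cls(**{k: float(d[k]) for k in ("h0", "h1", "oa", "oap_c", "oap_n")})


class CultureTable:
    """Paired ambient/acidified replicate measurements (per-cell units).

    Wraps a DataFrame with columns ``treatment`` (ambient | acidified),
    ``replicate``, and the five per-cell quantities: N2 and C fixation
    rates (fmol cell-1 h-1) and POC/PON/POP quotas (fmol cell-1).
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        missing = {"treatment", "replicate", *CULTURE_COLUMNS} - set(df.columns)
        if missing:
            raise ConfigurationError(f"culture table missing columns {sorted(missing)}")
        bad = set(df["treatment"]) - {"ambient", "acidified"}
        if bad:
            raise ConfigurationError(f"unknown treatments {sorted(bad)}")
        amb = set(df.loc[df.treatment == "ambient", "replicate"])
        acid = set(df.loc[df.treatment == "acidified", "replicate"])
        if amb != acid:
            raise PairingError(
                f"unpaired replicates: ambient-only {sorted(amb - acid)}, "
                f"acidified-only {sorted(acid - amb)}"
            )
        if len(amb) < 2:
            raise ConfigurationError("need at least 2 paired replicates")
        if (df[list(CULTURE_COLUMNS)] <= 0).any().any():
            raise DomainError("all culture measurements must be positive")
        self.data = df.sort_values(["treatment", "replicate"]).reset_index(drop=True)

    def treatment(self, name: str) -> pd.DataFrame:
        return self.data[self.data.treatment == name].set_index("replicate")

    def paired(self, column: str) -> list[tuple[float, float]]:
        """(ambient, acidified) value pairs for one column, by replicate."""
        amb = self.treatment("ambient")[column]
        acid = self.treatment("acidified")[column]
        return [(float(amb[r]), float(acid[r])) for r in sorted(amb.index)]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CultureTable":
        return cls(pd.read_csv(path))


def percent_change(ambient: float, acidified: float) -> float:
    """Signed percent change from ambient to acidified, 100*(b - a)/a."""
    if ambient <= 0:
        raise DomainError("ambient value must be positive")
    return 100.0 * (acidified - ambient) / ambient


def normalized_rate(rate_per_cell: float, quota_per_cell: float) -> float:
    """Biomass-specific rate: per-cell rate over a per-cell quota."""
    if quota_per_cell <= 0:
        raise DomainError("quota must be positive")
    return rate_per_cell / quota_per_cell


def stoichiometric_ratio(numerator_quota: float, denominator_quota: float) -> float:
    """Dimensionless molar ratio of two per-cell elemental quotas."""
    if numerator_quota <= 0 or denominator_quota <= 0:
        raise DomainError("quotas must be positive")
    return numerator_quota / denominator_quota


def derive_effect_parameters(
    table: CultureTable,
    h0: float = 10.0**-8.01,
    h1: float = 10.0**-7.81,
    oa: float = -0.184,
    method: Literal["ratio_of_means", "mean_of_ratios"] = "ratio_of_means",
) -> EffectParameters:
    """Derive oap_c and oap_n from a paired culture table.

    oap_c is the fractional change in treatment-level POC:POP (C biomass
    per unit P); oap_n the fractional change in C-biomass-specific N2
    fixation (n2_fix_per_cell / poc).  ``oa`` comes from a prior
    P-replete study and is passed through unchanged.

    method='ratio_of_means' (default) forms each treatment's statistic
    from the means of the raw quotas, matching how culture stoichiometry
    ratios are conventionally reported; 'mean_of_ratios' averages the
    per-replicate ratios instead.
    """
    stats_by_treatment: dict[str, tuple[float, float]] = {}
    for name in ("ambient", "acidified"):
        sub = table.treatment(name)
        if method == "ratio_of_means":
            c_per_p = sub["poc"].mean() / sub["pop"].mean()
            n_per_c = sub["n2_fix_per_cell"].mean() / sub["poc"].mean()
        elif method == "mean_of_ratios":
            c_per_p = (sub["poc"] / sub["pop"]).mean()
            n_per_c = (sub["n2_fix_per_cell"] / sub["poc"]).mean()
        else:
            raise ConfigurationError(f"unknown method {method!r}")
        if c_per_p <= 0 or n_per_c <= 0:
            raise DomainError("treatment means must be positive")
        stats_by_treatment[name] = (float(c_per_p), float(n_per_c))
    amb_cp, amb_nc = stats_by_treatment["ambient"]
    acid_cp, acid_nc = stats_by_treatment["acidified"]
    return EffectParameters(
        h0=h0,
        h1=h1,
        oa=oa,
        oap_c=percent_change(amb_cp, acid_cp) / 100.0,
        oap_n=percent_change(amb_nc, acid_nc) / 100.0,
    )


def paired_t_test(
    pairs: Sequence[tuple[float, float]], tails: int = 2
) -> tuple[float, float]:
    """Paired Student's t-test on (ambient, acidified) pairs.

    Returns (t, p) with t computed on differences acidified - ambient and
    n-1 degrees of freedom.  ``tails=1`` returns the one-tailed p for the
    direction favoured by the observed mean difference (half the
    two-tailed p), as used for field incubation data.
    """
    if tails not in (1, 2):
        raise ConfigurationError("tails must be 1 or 2")
    if len(pairs) < 2:
        raise DomainError("need at least 2 pairs")
    amb = np.array([a for a, _ in pairs], dtype=float)
    acid = np.array([b for _, b in pairs], dtype=float)
    diff = acid - amb
    if np.allclose(diff, diff[0], rtol=0.0, atol=0.0):
        raise DegenerateVarianceError("all paired differences identical")
    t, p = stats.ttest_rel(acid, amb)
    if tails == 1:
        p = p / 2.0
    return float(t), float(p)


def cells_per_ml(
    total_filament_length_per_ml: float,
    sampled_filament_lengths: Iterable[float],
    sampled_cell_counts: Iterable[int],
) -> float:
    """Cell density from filament length measurements.

    The mean cell length is the summed length of the sampled filaments
    over their summed cell count; density is total filament length per
    mL divided by that mean cell length.
    """
    lengths = np.asarray(list(sampled_filament_lengths), dtype=float)
    counts = np.asarray(list(sampled_cell_counts), dtype=float)
    if lengths.shape != counts.shape:
        raise DomainError("lengths and counts must align")
    total_cells = counts.sum()
    if total_cells <= 0:
        raise DomainError("total sampled cell count must be positive")
    if total_filament_length_per_ml < 0 or np.any(lengths < 0):
        raise DomainError("filament lengths must be non-negative")
    avg_cell_length = lengths.sum() / total_cells
    return total_filament_length_per_ml / avg_cell_length


def dna_p_quota(
    genome_bp: int = IMS101_GENOME_BP, ploidy_copies: int = DEFAULT_GENOME_COPIES
) -> float:
    """Cellular DNA phosphorus quota in fmol P cell-1.

    Two phosphate groups per base pair (one per strand position), times
    genome size and genome copy number.
    """
    if genome_bp <= 0 or ploidy_copies <= 0:
        raise DomainError("genome size and copy number must be positive")
    atoms = 2.0 * genome_bp * ploidy_copies
    return atoms / AVOGADRO * 1e15


def rna_p_quota(rna_mass_ng: float) -> float:
    """RNA phosphorus in nmol from an RNA mass in ng.

    One P per nucleotide residue at 320.5 g mol-1; ng / (g mol-1) is
    numerically nmol.
    """
    if rna_mass_ng < 0:
        raise DomainError("RNA mass must be non-negative")
    return rna_mass_ng / RNA_NUCLEOTIDE_MW


def ethylene_to_n2(ethylene_rate: float) -> float:
    """Convert an ethylene production rate to N2 fixation (4:1 ratio)."""
    if ethylene_rate < 0:
        raise DomainError("rate must be non-negative")
    return ethylene_rate / ACETYLENE_RATIO


def synthetic_culture_table(
    n_replicates: int = 3,
    seed: int = 0,
    ambient_means: dict[str, float] | None = None,
    effect: dict[str, float] | None = None,
    noise_cv: float = 0.0,
) -> CultureTable:
    """Build a paired culture table with known multiplicative effects.

    Ambient replicate means default to values of the magnitude seen in
    P-limited chemostats (fmol cell-1 and fmol cell-1 h-1).  ``effect``
    maps column names to multiplicative acidified/ambient factors (e.g.
    ``{"poc": 0.78}`` for a 22 % POC decline); unlisted columns get 1.
    ``noise_cv`` adds log-normal replicate noise at that coefficient of
    variation; at 0 the table is exactly deterministic, so parameter
    recovery is exact.
    """
    if n_replicates < 2:
        raise DomainError("need at least 2 replicates")
    defaults = {
        "n2_fix_per_cell": 1.6,
        "c_fix_per_cell": 11.0,
        "poc": 830.0,
        "pon": 120.0,
        "pop": 2.5,
    }
    means = {**defaults, **(ambient_means or {})}
    eff = {c: 1.0 for c in CULTURE_COLUMNS}
    eff.update(effect or {})
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    rows = []
    for treatment in ("ambient", "acidified"):
        for rep in range(1, n_replicates + 1):
            row: dict[str, object] = {"treatment": treatment, "replicate": rep}
            for col in CULTURE_COLUMNS:
                val = means[col] * (eff[col] if treatment == "acidified" else 1.0)
                if sigma > 0:
                    val *= np.exp(rng.normal(-0.5 * sigma**2, sigma))
                row[col] = val
            rows.append(row)
    return CultureTable(pd.DataFrame(rows))
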