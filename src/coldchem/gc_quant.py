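"""Internal-standard quantification of GC-FID FAME peak tables.

A known mass of di-C19:0 phosphatidylcholine is added to each biomass
aliquot before transesterification; its two nonadecanoate chains appear
in the chromatogram as the C19:0 peak. The mass of every other fatty
acid follows from the area ratio to that peak,

    mass_i = (area_i / area_IS) * is_mass_mg * RRF_i,

and total lipid content is the FAME sum (internal standard excluded)
relative to the dry biomass weighed in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "PeakTable",
    "RRFTable",
    "FAWeightProfile",
    "QuantificationError",
    "quantify_fames",
    "total_lipid_content",
    "molar_mass",
    "DEFAULT_IS_MASS_MG",
]

# Standard atomic weights, g/mol (IUPAC 2021, abridged).
_ATOMIC_WEIGHTS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass(formula: str) -> float:
    """Molar mass (g/mol) of a Hill-style formula such as ``C46H92NO8P``."""
    mass = 0.0
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        element, count = m.group(1), int(m.group(2) or 1)
        if element not in _ATOMIC_WEIGHTS:
            raise ValueError(f"unsupported element {element!r}")
        mass += _ATOMIC_WEIGHTS[element] * count
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return mass


# Nonadecanoic acid and 1,2-dinonadecanoyl-sn-glycero-3-phosphocholine.
_M_C19_ACID = molar_mass("C19H38O2")
_M_DI_C19_PC = molar_mass("C46H92NO8P")

# 50 uL of a 10 mg/mL PC solution = 0.5 mg PC per sample; only the two
# acyl chains are quantifiable as the C19:0 peak.
DEFAULT_IS_MASS_MG = 0.5 * 2.0 * _M_C19_ACID / _M_DI_C19_PC

# Free acid -> methyl ester adds CH2 (transesterification replaces the
# acidic H by CH3).
_FAME_OVER_FA = (_M_C19_ACID + molar_mass("CH2")) / _M_C19_ACID


class QuantificationError(ValueError):
    """Internal-standard quantification cannot proceed."""


@dataclass
class PeakTable:
    """One sample's integrated GC-FID peak areas plus quantification info.

    ``areas`` maps fatty-acid label to detector area (arbitrary units).
    ``biomass_dry_mg`` is the freeze-dried biomass weighed into the
    extraction; ``is_mass_mg`` the quantifiable internal-standard acyl
    mass (defaults to the acyl fraction of 0.5 mg di-C19:0 PC).
    """

    sample_id: str
    areas: dict[str, float]
    biomass_dry_mg: float
    is_label: str = "C19:0"
    is_mass_mg: float = DEFAULT_IS_MASS_MG

    def __post_init__(self) -> None:
        if self.biomass_dry_mg <= 0:
            raise ValueError("biomass_dry_mg must be positive")
        if self.is_mass_mg <= 0:
            raise ValueError("is_mass_mg must be positive")
        for label, area in self.areas.items():
            if area < 0:
                raise ValueError(
                    f"negative area for {label!r} in sample {self.sample_id!r}"
                )


@dataclass
class RRFTable:
    """Relative response factors mapping peak area to mass.

    FID response per unit mass differs slightly between analytes; the
    factor for an unlisted label falls back to ``default`` (1.0 when no
    published response table is supplied).
    """

    factors: dict[str, float] = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self) -> None:
        if self.default <= 0 or any(v <= 0 for v in self.factors.values()):
            raise ValueError("response factors must be positive")

    def get(self, label: str) -> float:
        return self.factors.get(label, self.default)


@dataclass
class FAWeightProfile:
    """Per-sample fatty-acid masses (mg), internal standard excluded."""

    sample_id: str
    masses: dict[str, float]

    def total_mass_mg(self) -> float:
        return float(sum(self.masses.values()))

    def percent(self) -> dict[str, float]:
        """Relative weight percent per fatty acid."""
        total = self.total_mass_mg()
        if total <= 0:
            return {label: 0.0 for label in self.masses}
        return {k: 100.0 * v / total for k, v in self.masses.items()}


def quantify_fames(
    pt: PeakTable,
    rrf: RRFTable | Mapping[str, float] | None = None,
    fame_basis: bool = True,
) -> FAWeightProfile:
    """Convert peak areas to fatty-acid masses via the internal standard.

    ``mass_i = (area_i / area_IS) * is_mass_mg * RRF_i`` for every non-IS
    row; the internal-standard row is removed from the output. With
    ``fame_basis=False`` masses are rescaled from the methyl-ester to the
    free-acid basis using the C19:0 ester/acid mass ratio.
    """
    if rrf is None:
        rrf = RRFTable()
    elif not isinstance(rrf, RRFTable):
        rrf = RRFTable(factors=dict(rrf))

    if pt.is_label not in pt.areas:
        raise QuantificationError(
            f"internal standard {pt.is_label!r} missing from sample "
            f"{pt.sample_id!r}"
        )
    area_is = pt.areas[pt.is_label]
    if area_is <= 0:
        raise QuantificationError(
            f"internal standard area is zero in sample {pt.sample_id!r}"
        )

    scale = 1.0 if fame_basis else 1.0 / _FAME_OVER_FA
    masses = {
        label: (area / area_is) * pt.is_mass_mg * rrf.get(label) * scale
        for label, area in pt.areas.items()
        if label != pt.is_label
    }
    return FAWeightProfile(sample_id=pt.sample_id, masses=masses)


def total_lipid_content(
    profile: FAWeightProfile, biomass_dry_mg: float
) -> float:
    """Total lipid content as percent of cell dry weight.

    The FAME sum (internal standard already excluded from the profile)
    divided by the dry biomass, times 100.
    """
    if biomass_dry_mg <= 0:
        raise ValueError("biomass_dry_mg must be positive")
    return 100.0 * profile.total_mass_mg() / biomass_dry_mg
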