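"""Flux-unit parsing and conversion to canonical element-mass rates.

Chamber and eddy-covariance studies report greenhouse-gas fluxes in a zoo
of unit dialects: element mass (CO2-C, CH4-C, N2O-N) or molecule mass or
molar amount, per m² or per hectare, per second/hour/day/year, and
occasionally already converted to CO2-equivalents.  This module parses the
dialects occurring in the compilation's source footnotes and converts any
flux to canonical kg element ha⁻¹ yr⁻¹ (C for the carbon gases, N for N2O);
CO2-equivalent inputs keep their equivalence basis and are flagged.

It is deliberately not a general dimensional-analysis engine: the grammar
covers the dialects of the compilation plus canonical forms.

Conventions: year = 365 d = 8760 h; 1 ha = 10⁴ m²; molar masses
C = 12, N = 14 (N2O carries 2 N), CO2 = 44, CH4 = 16, N2O = 44 g mol⁻¹.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .flux_table import FluxRecord


class Gas(str, Enum):
    CO2 = "co2"
    CH4 = "ch4"
    N2O = "n2o"


class UnitError(ValueError):
    """Unit string not in the recognized grammar."""


# g per mol
MOLECULE_MOLAR_MASS = {Gas.CO2: 44.0, Gas.CH4: 16.0, Gas.N2O: 44.0}
# grams of the accounting element (C or N) per mol of gas; N2O carries 2 N
ELEMENT_G_PER_MOL = {Gas.CO2: 12.0, Gas.CH4: 12.0, Gas.N2O: 28.0}
ELEMENT_OF_GAS = {Gas.CO2: "c", Gas.CH4: "c", Gas.N2O: "n"}

HOURS_PER_YEAR = 8760.0
DAYS_PER_YEAR = 365.0
SECONDS_PER_YEAR = DAYS_PER_YEAR * 86400.0
M2_PER_HA = 1.0e4

_MASS_PREFIX_KG = {
    "ng": 1e-12,
    "ug": 1e-9,
    "mg": 1e-6,
    "g": 1e-3,
    "kg": 1.0,
    "t": 1000.0,
    "Mg": 1000.0,
}
_MOL_PREFIX_MOL = {"nmol": 1e-9, "umol": 1e-6, "mmol": 1e-3, "mol": 1.0}
_TIME_PER_YEAR = {
    "s": SECONDS_PER_YEAR,
    "h": HOURS_PER_YEAR,
    "d": DAYS_PER_YEAR,
    "yr": 1.0,
}


class AmountBasis(str, Enum):
    ELEMENT = "mass_of_element"
    MOLECULE = "mass_of_molecule"
    CO2_EQUIVALENT = "mass_co2_equivalent"
    MOL = "amount_mol"


@dataclass(frozen=True)
class FluxUnit:
    """A parsed flux unit: amount basis × prefix × area × time, for a gas."""

    gas: Gas
    basis: AmountBasis
    prefix: str
    area: str  # "m2" | "ha"
    time: str  # "s" | "h" | "d" | "yr"

    def __post_init__(self) -> None:
        if self.basis is AmountBasis.MOL:
            if self.prefix not in _MOL_PREFIX_MOL:
                raise UnitError(f"molar basis needs a mol prefix, got {self.prefix!r}")
        elif self.prefix not in _MASS_PREFIX_KG:
            raise UnitError(f"unknown mass prefix {self.prefix!r}")
        if self.area not in ("m2", "ha"):
            raise UnitError(f"unknown area {self.area!r}")
        if self.time not in _TIME_PER_YEAR:
            raise UnitError(f"unknown time {self.time!r}")

    # -- independent conversion factors, exposed for cross-checking ------
    def mass_factor(self) -> float:
        """kg of the canonical accounting quantity per printed amount unit."""
        if self.basis is AmountBasis.ELEMENT:
            return _MASS_PREFIX_KG[self.prefix]
        if self.basis is AmountBasis.MOLECULE:
            return (
                _MASS_PREFIX_KG[self.prefix]
                * ELEMENT_G_PER_MOL[self.gas]
                / MOLECULE_MOLAR_MASS[self.gas]
            )
        if self.basis is AmountBasis.CO2_EQUIVALENT:
            return _MASS_PREFIX_KG[self.prefix]
        # mol: amount × g element per mol, to kg
        return _MOL_PREFIX_MOL[self.prefix] * ELEMENT_G_PER_MOL[self.gas] / 1000.0

    def area_factor(self) -> float:
        return M2_PER_HA if self.area == "m2" else 1.0

    def time_factor(self) -> float:
        return _TIME_PER_YEAR[self.time]

    def factor_to_canonical(self) -> float:
        return self.mass_factor() * self.area_factor() * self.time_factor()

    @property
    def is_canonical(self) -> bool:
        return (
            self.basis is AmountBasis.ELEMENT
            and self.prefix == "kg"
            and self.area == "ha"
            and self.time == "yr"
        )


@dataclass(frozen=True)
class CanonicalFlux:
    """A flux in kg element ha⁻¹ yr⁻¹ (or kg CO2-eq ha⁻¹ yr⁻¹ when the
    source was already equivalenced).  Negative = uptake."""

    gas: Gas
    value: float
    was_co2_equivalent: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite flux value {self.value}")


def _normalize_unit_text(text: str) -> str:
    out = text
    for bad, good in {
        "µ": "u", "μ": "u",
        "−": "-", "–": "-", "—": "-",
        "⁻¹": "-1", "⁻²": "-2", "−1": "-1", "−2": "-2",
        "_": "", "^": "",
    }.items():
        out = out.replace(bad, good)
    out = re.sub(r"\s+", " ", out).strip()
    return out


_UNIT_RE = re.compile(
    r"^(?P<prefix>ng|ug|mg|kg|Mg|g|t|nmol|umol|mmol|mol)\s*"
    r"(?P<species>CO2-C|CH4-C|N2O-N|CO2-eq|CO2 C|CH4 C|N2O N|CO2|CH4|N2O|C|N)\s+"
    r"(?P<area>m-2|ha-1)\s+"
    r"(?P<time>s|h|d|yr|y|a)-1$",
    re.IGNORECASE,
)


def parse_unit(text: str, gas: Gas) -> FluxUnit:
    """Parse a printed flux-unit string for a given gas.

    Tolerant to µ/μ variants, typographic minus/dash, superscript
    renderings and "CO2 C"-style element separators.  Some footnote
    strings omit the gas (plain "kg C ha-1 yr-1"), which is why the gas
    must be supplied.
    """
    gas = Gas(gas)
    norm = _normalize_unit_text(text)
    m = _UNIT_RE.match(norm)
    if not m:
        raise UnitError(f"unrecognized unit string {text!r}")
    prefix = m.group("prefix")
    # prefix case: only Mg (megagram) is case-sensitive vs mg
    if prefix.lower() != "mg":
        prefix = prefix.lower()
    species = re.sub(r"\s", "-", m.group("species").upper())
    area = "m2" if m.group("area").lower() == "m-2" else "ha"
    time = m.group("time").lower()
    if time in ("y", "a"):
        time = "yr"

    if species == "CO2-EQ":
        basis = AmountBasis.CO2_EQUIVALENT
        species_gas = None
    elif species in ("CO2-C", "CH4-C", "N2O-N"):
        # "nmol N2O-N" style: a molar amount accounted as the element,
        # which is the same conversion as a plain molar amount
        basis = AmountBasis.MOL if prefix in _MOL_PREFIX_MOL else AmountBasis.ELEMENT
        species_gas = Gas(species.split("-")[0].lower())
    elif species in ("CO2", "CH4", "N2O"):
        basis = AmountBasis.MOL if prefix in _MOL_PREFIX_MOL else AmountBasis.MOLECULE
        species_gas = Gas(species.lower())
    else:  # bare element symbol: canonical shorthand "kg C ha-1 yr-1"
        basis = AmountBasis.ELEMENT
        species_gas = None
        if species.lower() != ELEMENT_OF_GAS[gas]:
            raise UnitError(
                f"unit {text!r} accounts element {species} but gas {gas.value} "
                f"is accounted as {ELEMENT_OF_GAS[gas].upper()}"
            )
    if species_gas is not None and species_gas is not gas:
        raise UnitError(f"unit {text!r} names gas {species_gas.value}, expected {gas.value}")
    if prefix in _MOL_PREFIX_MOL and basis is not AmountBasis.MOL:
        raise UnitError(f"molar prefix with non-molar species in {text!r}")
    return FluxUnit(gas=gas, basis=basis, prefix=prefix, area=area, time=time)


def convert_flux(value: float, unit: FluxUnit) -> CanonicalFlux:
    """Convert a flux to canonical kg element ha⁻¹ yr⁻¹ (sign preserved).

    CO2-equivalent inputs are rescaled in mass/area/time only and flagged.
    """
    if not math.isfinite(value):
        raise ValueError(f"non-finite flux value {value}")
    return CanonicalFlux(
        gas=unit.gas,
        value=value * unit.factor_to_canonical(),
        was_co2_equivalent=unit.basis is AmountBasis.CO2_EQUIVALENT,
    )


def to_source_unit(canonical_value: float, unit: FluxUnit) -> float:
    """Inverse of :func:`convert_flux` for round-trip checks."""
    return canonical_value / unit.factor_to_canonical()


CANONICAL_UNIT_STRING = {
    Gas.CO2: "kg CO2-C ha-1 yr-1",
    Gas.CH4: "kg CH4-C ha-1 yr-1",
    Gas.N2O: "kg N2O-N ha-1 yr-1",
}

_GAS_OF_COLUMN = {"nee": Gas.CO2, "ch4": Gas.CH4, "n2o": Gas.N2O}


def harmonize_record(
    record: FluxRecord, mode: str = "paper"
) -> dict[str, CanonicalFlux]:
    """Harmonize one record's gases; absent gases stay absent.

    mode="paper" (default) trusts the compilation caption, which declares
    the tabulated values to be kg C / kg N ha⁻¹ yr⁻¹ already — the reading
    under which the published category means are reproducible.  mode=
    "literal" applies each source's footnote unit string through the
    converter instead; for several rows the two readings differ by orders
    of magnitude, which is a documented inconsistency of the compilation.
    """
    if mode not in ("paper", "literal"):
        raise ValueError("mode must be 'paper' or 'literal'")
    out: dict[str, CanonicalFlux] = {}
    for column, gas in _GAS_OF_COLUMN.items():
        v = record.value(column)
        if v is None:
            continue
        collapsed = v.collapse()
        if mode == "paper":
            out[column] = CanonicalFlux(gas=gas, value=float(collapsed))
            continue
        try:
            unit = parse_unit(record.unit(column), gas)
            out[column] = convert_flux(collapsed, unit)
        except (UnitError, ValueError) as exc:
            raise UnitError(
                f"{record.site_name} [{record.source}], column {column}: {exc}"
            ) from exc
    return out


def harmonize_table(records, mode: str = "paper"):
    """Harmonize a record list into a tidy DataFrame (one row per record,
    NaN for absent gases) with provenance columns carried along."""
    import pandas as pd

    rows = []
    for r in records:
        fluxes = harmonize_record(r, mode=mode)
        rows.append(
            {
                "site_name": r.site_name,
                "category": r.category.value,
                "subgroup": r.subgroup,
                "nutrient_status": r.nutrient_status.value,
                "source": r.source,
                "season_only": "season_only" in r.flags,
                "co2_equivalent": (
                    any(f.was_co2_equivalent for f in fluxes.values())
                    if mode == "literal"
                    else "co2_equivalent" in r.flags
                ),
                "review": "review" in r.flags,
                "nee": fluxes["nee"].value if "nee" in fluxes else float("nan"),
                "ch4": fluxes["ch4"].value if "ch4" in fluxes else float("nan"),
                "n2o": fluxes["n2o"].value if "n2o" in fluxes else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_name", "category", "subgroup", "nutrient_status", "source",
            "season_only", "co2_equivalent", "review", "nee", "ch4", "n2o",
        ],
    )
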