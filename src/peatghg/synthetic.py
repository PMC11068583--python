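"""Synthetic flux tables and perturbed scenario parameter sets.

The flux generator draws per-category, per-gas values in canonical
kg element ha⁻¹ yr⁻¹ from a known distribution and then re-expresses each
value in a randomly chosen reporting dialect (the exact inverse of the
unit converter), emulating the mixed-unit structure of a literature
compilation while keeping the ground truth known.  It is a testing
device, not a statistical emulator of field variability: values are
independent draws with no spatial or temporal autocorrelation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .carbon_model import AllometryParams, ScenarioSpec, Schedule
from .flux_table import Category, FluxRecord, NutrientStatus, ValueKind, ValueOrRange
from .units import CANONICAL_UNIT_STRING, Gas, parse_unit, to_source_unit

_GAS_OF_COLUMN = {"nee": Gas.CO2, "ch4": Gas.CH4, "n2o": Gas.N2O}

#: Reporting dialects the generator may choose from, per gas column.
DEFAULT_DIALECTS: dict[str, tuple[tuple[str, float], ...]] = {
    "nee": (
        ("kg CO2-C ha-1 yr-1", 0.4),
        ("mg CO2-C m-2 h-1", 0.3),
        ("g CO2-C m-2 yr-1", 0.2),
        ("t CO2 ha-1 yr-1", 0.1),
    ),
    "ch4": (
        ("kg CH4-C ha-1 yr-1", 0.4),
        ("ug CH4-C m-2 h-1", 0.3),
        ("mg CH4 m-2 d-1", 0.2),
        ("mmol CH4 m-2 h-1", 0.1),
    ),
    "n2o": (
        ("kg N2O-N ha-1 yr-1", 0.4),
        ("ug N2O-N m-2 h-1", 0.3),
        ("mg N2O-N m-2 yr-1", 0.2),
        ("umol N2O m-2 h-1", 0.1),
    ),
}

#: Canonical-unit per-category (mean, sd) defaults, seeded from the
#: published category means where available (e.g. rewetted-forest NEE
#: −928 kg CO2-C ha⁻¹ yr⁻¹, CH4 218 kg CH4-C ha⁻¹ yr⁻¹).
DEFAULT_CATEGORY_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    Category.REWETTED_GENERAL.value: {
        "nee": (-1200.0, 1500.0), "ch4": (150.0, 180.0), "n2o": (2.0, 2.5),
    },
    Category.REWETTED_FOREST.value: {
        "nee": (-928.0, 1200.0), "ch4": (218.0, 140.0), "n2o": (0.3, 0.3),
    },
    Category.PALUDICULTURE.value: {
        "nee": (-528.0, 2500.0), "ch4": (122.0, 160.0), "n2o": (3.0, 7.0),
    },
    Category.SHALLOW_LAKE.value: {
        "nee": (300.0, 2500.0), "ch4": (451.0, 400.0), "n2o": (1.0, 1.8),
    },
    Category.OPEN_BOG_FEN.value: {
        "nee": (-534.0, 700.0), "ch4": (163.0, 200.0), "n2o": (0.1, 0.5),
    },
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for a synthetic flux table."""

    category_params: dict = field(
        default_factory=lambda: {
            c: dict(g) for c, g in DEFAULT_CATEGORY_PARAMS.items()
        }
    )
    records_per_category: int = 20
    dialects: dict = field(
        default_factory=lambda: {g: tuple(d) for g, d in DEFAULT_DIALECTS.items()}
    )
    distribution: str = "normal"  # or "lognormal_signed" for heavy tails
    seed: int = 0

    def __post_init__(self) -> None:
        if self.records_per_category < 1:
            raise ValueError("records_per_category must be >= 1")
        if self.distribution not in ("normal", "lognormal_signed"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        for cat, gases in self.category_params.items():
            Category(cat)
            for gas, (mean, sd) in gases.items():
                if gas not in _GAS_OF_COLUMN:
                    raise ValueError(f"unknown gas {gas!r}")
                if sd < 0:
                    raise ValueError(f"negative sd for {cat}/{gas}")
        for gas, dialects in self.dialects.items():
            probs = [p for _, p in dialects]
            if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0):
                raise ValueError(f"dialect probabilities for {gas} must sum to 1")
            for unit_string, _ in dialects:
                parse_unit(unit_string, _GAS_OF_COLUMN[gas])  # validate early


def _draw(rng: np.random.Generator, mean: float, sd: float, dist: str) -> float:
    if dist == "normal" or sd == 0.0:
        return float(rng.normal(mean, sd))
    # heavy-tailed option: log-normal magnitude carrying the mean's sign
    scale = max(abs(mean), sd)
    sigma = 0.75
    mag = float(rng.lognormal(math.log(scale) - 0.5 * sigma**2, sigma))
    return math.copysign(mag, mean if mean != 0 else 1.0)


def generate_flux_table(spec: SyntheticSpec) -> list[FluxRecord]:
    """Generate a category-structured flux table with mixed unit dialects.

    Values are drawn in canonical units, then stored in the chosen dialect
    via the exact inverse of the converter, so harmonizing the table
    recovers the generating values bit-for-bit up to float division.
    Reproducible from the seed.
    """
    # separate streams so the drawn values are invariant to the dialect mix
    seq = np.random.SeedSequence(spec.seed)
    value_rng, unit_rng = (np.random.default_rng(s) for s in seq.spawn(2))
    records: list[FluxRecord] = []
    for cat_name in sorted(spec.category_params):
        gases = spec.category_params[cat_name]
        for i in range(spec.records_per_category):
            values: dict[str, ValueOrRange] = {}
            units: dict[str, str] = {}
            for gas in ("nee", "ch4", "n2o"):
                if gas not in gases:
                    continue
                mean, sd = gases[gas]
                canonical = _draw(value_rng, mean, sd, spec.distribution)
                dialects = spec.dialects.get(
                    gas, ((CANONICAL_UNIT_STRING[_GAS_OF_COLUMN[gas]], 1.0),)
                )
                idx = unit_rng.choice(len(dialects), p=[p for _, p in dialects])
                unit_string = dialects[int(idx)][0]
                unit = parse_unit(unit_string, _GAS_OF_COLUMN[gas])
                values[gas] = ValueOrRange(
                    ValueKind.POINT, to_source_unit(canonical, unit)
                )
                units[gas] = unit_string
            records.append(
                FluxRecord(
                    site_name=f"synthetic-{cat_name}-{i:03d}",
                    category=Category(cat_name),
                    country="synthetic",
                    nutrient_status=NutrientStatus.UNKNOWN,
                    nee=values.get("nee"),
                    ch4=values.get("ch4"),
                    n2o=values.get("n2o"),
                    nee_unit=units.get("nee", ""),
                    ch4_unit=units.get("ch4", ""),
                    n2o_unit=units.get("n2o", ""),
                    source=f"synthetic seed={spec.seed}",
                )
            )
    return records


def perturb_scenario(
    spec: ScenarioSpec, relative_amplitude: float, seed: int
) -> ScenarioSpec:
    """Scenario with rates and allometric ratios each multiplied by an
    independent uniform factor in [1-a, 1+a]; structural fields (name,
    initial stocks, harvest cycle, schedule breakpoint years) untouched."""
    if not 0.0 <= relative_amplitude <= 0.5:
        raise ValueError("relative_amplitude must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)

    def factor() -> float:
        return float(rng.uniform(1.0 - relative_amplitude, 1.0 + relative_amplitude))

    def scaled(schedule: Schedule) -> Schedule:
        return schedule.scaled([factor() for _ in schedule.breakpoints])

    a = spec.allometry
    return ScenarioSpec(
        name=spec.name,
        initial_peat_c=spec.initial_peat_c,
        initial_stem_volume=spec.initial_stem_volume,
        increment_schedule=scaled(spec.increment_schedule),
        peat_flux_schedule=scaled(spec.peat_flux_schedule),
        harvest_cycle=spec.harvest_cycle,
        residue_decay_rate=spec.residue_decay_rate * factor(),
        allometry=AllometryParams(
            wood_density=a.wood_density * factor(),
            carbon_fraction=min(a.carbon_fraction * factor(), 0.99),
            branch_ratio=min(a.branch_ratio * factor(), 0.99),
            coarse_root_ratio=min(a.coarse_root_ratio * factor(), 0.99),
        ),
    )
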