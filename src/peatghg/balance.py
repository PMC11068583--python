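"""Category-level flux aggregation and CO2-equivalent GHG balances.

Category means are unweighted arithmetic means over the harmonized values
present for each gas (rows missing a gas simply do not contribute), which
is how the published compilation's own averages were formed.  Growing-
season-only rates are excluded from annual means, as are CO2-equivalent
rows when averaging on an element-mass basis.

The CO2-equivalent balance of a (NEE, CH4, N2O) triple under a global-
warming-potential specification with factors (g_CH4, g_N2O) is

    B = NEE_C · 44/12  +  g_CH4 · CH4_C · 16/12  +  g_N2O · N2O_N · 44/28

in kg CO2-eq ha⁻¹ yr⁻¹: element-mass fluxes are first restored to molecule
mass, then weighted.  Default factor sets: (25, 298) for the 100-year
horizon and (7.6, 153) for the 500-year horizon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .flux_table import Category, FluxRecord
from .units import Gas, harmonize_table

GASES = ("nee", "ch4", "n2o")
_MOLECULE_PER_ELEMENT = {"nee": 44.0 / 12.0, "ch4": 16.0 / 12.0, "n2o": 44.0 / 28.0}


@dataclass(frozen=True)
class GWPSpec:
    """CO2-equivalence factors for one time horizon (mass of CO2 with the
    same radiative effect as unit mass of the gas)."""

    horizon: int
    ch4_factor: float
    n2o_factor: float

    def __post_init__(self) -> None:
        if self.ch4_factor <= 0 or self.n2o_factor <= 0:
            raise ValueError("GWP factors must be positive")


GWP100 = GWPSpec(horizon=100, ch4_factor=25.0, n2o_factor=298.0)
GWP500 = GWPSpec(horizon=500, ch4_factor=7.6, n2o_factor=153.0)
#: Factors including climate-carbon feedbacks, offered for sensitivity runs.
GWP100_FEEDBACK = GWPSpec(horizon=100, ch4_factor=34.0, n2o_factor=298.0)
DEFAULT_GWPS = (GWP100, GWP500)


def co2_equivalent(
    nee_c: Optional[float],
    ch4_c: Optional[float],
    n2o_n: Optional[float],
    gwp: GWPSpec,
) -> float:
    """CO2-equivalent balance in kg CO2-eq ha⁻¹ yr⁻¹; additive in gases.

    Absent gases are treated as zero flux, with a warning.
    """
    parts = {"nee": nee_c, "ch4": ch4_c, "n2o": n2o_n}
    total = 0.0
    for gas, value in parts.items():
        if value is None or (isinstance(value, float) and math.isnan(value)):
            warnings.warn(
                f"co2_equivalent: {gas} absent, treated as zero flux",
                stacklevel=2,
            )
            continue
        if not math.isfinite(value):
            raise ValueError(f"non-finite {gas} flux {value}")
        factor = {"nee": 1.0, "ch4": gwp.ch4_factor, "n2o": gwp.n2o_factor}[gas]
        total += factor * value * _MOLECULE_PER_ELEMENT[gas]
    return total


def round_half_away(x: float) -> int:
    """Display rounding to integer, halves away from zero (-927.5 -> -928)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class GasStats:
    """Summary statistics of one gas within one category (canonical units)."""

    n: int
    mean: float
    sd: float
    min: float
    max: float


class NoDataError(ValueError):
    """An aggregation was requested over an empty selection."""


def _annual_mask(df: pd.DataFrame, include_co2eq: bool) -> pd.Series:
    mask = ~df["season_only"]
    if not include_co2eq:
        mask &= ~df["co2_equivalent"]
    return mask


def aggregate_by_category(
    harmonized: pd.DataFrame,
    category: Category | str,
    gas: str,
    subset: Optional[Callable[[pd.Series], bool]] = None,
    include_co2eq: bool = True,
) -> GasStats:
    """Unweighted summary of one gas over a category's annual records.

    subset optionally restricts to rows satisfying a predicate (e.g. only
    the multi-site review rows).  Empty selections raise NoDataError —
    "no data" is never reported as zero.
    """
    if gas not in GASES:
        raise ValueError(f"unknown gas {gas!r}")
    category = Category(category)
    df = harmonized[harmonized["category"] == category.value]
    df = df[_annual_mask(df, include_co2eq)]
    if subset is not None:
        df = df[df.apply(subset, axis=1)]
    values = df[gas].dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise NoDataError(f"no {gas} data in category {category.value}")
    return GasStats(
        n=int(values.size),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        min=float(np.min(values)),
        max=float(np.max(values)),
    )


@dataclass
class CategorySummary:
    """Per-category gas statistics plus CO2-eq balances from the means."""

    category: Category
    gas_stats: dict = field(default_factory=dict)  # gas -> GasStats | None
    co2eq_balance: dict = field(default_factory=dict)  # horizon -> kg CO2-eq

    def to_dict(self) -> dict:
        out = {"category": self.category.value, "gases": {}, "co2eq": {}}
        for gas, stats in self.gas_stats.items():
            out["gases"][gas] = (
                None
                if stats is None
                else {
                    "n": stats.n,
                    "mean": stats.mean,
                    "mean_rounded": round_half_away(stats.mean),
                    "sd": stats.sd,
                    "min": stats.min,
                    "max": stats.max,
                }
            )
        out["co2eq"] = {str(h): v for h, v in self.co2eq_balance.items()}
        return out


def balance_report(
    records: Iterable[FluxRecord],
    gwps: Sequence[GWPSpec] = DEFAULT_GWPS,
    mode: str = "paper",
    include_co2eq: Optional[bool] = None,
) -> list[CategorySummary]:
    """One summary per category present in the record set, with CO2-eq
    balances computed from the category's per-gas means for each GWPSpec.

    Categories missing a gas entirely carry None for that gas, and the
    balance is computed from the available means (absent treated as zero,
    with the warning from co2_equivalent).  In paper mode all tabulated
    values are element mass, so CO2-eq-footnoted rows are included; in
    literal mode they really are CO2-equivalents and are excluded from
    element-mass means by default.
    """
    if include_co2eq is None:
        include_co2eq = mode == "paper"
    records = list(records)
    if not records:
        return []
    harmonized = harmonize_table(records, mode=mode)
    summaries: list[CategorySummary] = []
    for category in Category:
        if not (harmonized["category"] == category.value).any():
            continue
        summary = CategorySummary(category=category)
        means: dict[str, Optional[float]] = {}
        for gas in GASES:
            try:
                stats = aggregate_by_category(
                    harmonized, category, gas, include_co2eq=include_co2eq
                )
            except NoDataError:
                stats = None
            summary.gas_stats[gas] = stats
            means[gas] = None if stats is None else stats.mean
        for gwp in gwps:
            summary.co2eq_balance[gwp.horizon] = co2_equivalent(
                means["nee"], means["ch4"], means["n2o"], gwp
            )
        summaries.append(summary)
    return summaries
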