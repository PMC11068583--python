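"""One-shot summary report wiring all pipeline stages together.

Runs the flux harmonization, the category CO2-equivalent balances and the
scenario simulations in one pass and emits a JSON document plus trajectory
files, so every headline number (category gas means, GHG balances at both
GWP horizons, carbon-neutrality years, mean annual stock changes) comes
from a stage output rather than ad-hoc computation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .balance import DEFAULT_GWPS, GWP100, GWP500, GWPSpec, balance_report
from .carbon_model import (
    default_scenarios,
    mean_annual_change,
    neutrality_year,
    simulate,
)
from .flux_table import load_reference_table, read_flux_table

log = logging.getLogger("peatghg")

#: Diagnostic windows (from_year, to_year) reported per scenario where the
#: trajectory has a physically meaningful steady phase.
DIAGNOSTIC_WINDOWS = {
    "restored_bog": (20, 300),
    "regenerated_unmanaged_forest": (160, 300),
}


@dataclass
class RunConfig:
    """Configuration of a full report run."""

    flux_table: Optional[str] = None  # None -> packaged compilation
    gwp_horizons: Sequence[int] = (100, 500)
    scenarios: Sequence[str] = ()  # empty -> all packaged scenarios
    horizon_years: int = 300
    mode: str = "paper"  # harmonization mode
    out_dir: Optional[str] = None
    seed: int = 0

    def gwps(self) -> list[GWPSpec]:
        known = {g.horizon: g for g in (GWP100, GWP500)}
        specs = []
        for h in self.gwp_horizons:
            if h not in known:
                raise ValueError(
                    f"no packaged GWP factors for horizon {h}; pass a GWPSpec"
                )
            specs.append(known[h])
        return specs

    def to_dict(self) -> dict:
        return {
            "flux_table": self.flux_table,
            "gwp_horizons": list(self.gwp_horizons),
            "scenarios": list(self.scenarios),
            "horizon_years": self.horizon_years,
            "mode": self.mode,
            "seed": self.seed,
        }


def run_report(config: RunConfig) -> tuple[dict, bool]:
    """Execute all stages; returns (report document, fully_ok flag).

    fully_ok is False when a section had no data (partial success); stage
    errors propagate with module and row/year context attached by the
    stages themselves.
    """
    fully_ok = True
    report: dict = {
        "tool": {"name": "peatghg", "version": __version__},
        "config": config.to_dict(),
    }

    log.info("reading flux table")
    if config.flux_table is None:
        records = load_reference_table()
    else:
        records = read_flux_table(config.flux_table)
    report["n_records"] = len(records)
    if not records:
        log.warning("flux table empty: balance section has no data")
        report["balance"] = {"no_data": True}
        fully_ok = False
    else:
        log.info("computing category balances for %d records", len(records))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # absent-gas-as-zero warnings
            summaries = balance_report(records, config.gwps(), mode=config.mode)
        report["balance"] = {
            "mode": config.mode,
            "categories": [s.to_dict() for s in summaries],
        }

    log.info("simulating scenarios")
    scenarios = default_scenarios()
    names = list(config.scenarios) or list(scenarios)
    out_dir = Path(config.out_dir) if config.out_dir else None
    scenario_section = {}
    for name in names:
        if name not in scenarios:
            raise ValueError(f"unknown scenario {name!r}")
        traj = simulate(scenarios[name], horizon=config.horizon_years)
        diag = {
            "neutrality_year": neutrality_year(traj),
            "total_c_start": traj.total_c[0],
            "total_c_end": float(traj.total_c[-1]),
            "cumulative_export_c": traj[-1].cumulative_export_c,
            "mean_annual_change_full": mean_annual_change(
                traj, 0, config.horizon_years
            ),
            "mean_annual_peat_change_full": (
                (traj[-1].peat_c - traj[0].peat_c) / config.horizon_years
            ),
        }
        window = DIAGNOSTIC_WINDOWS.get(name)
        if window and window[1] <= config.horizon_years:
            diag["window"] = list(window)
            diag["mean_annual_change_window"] = mean_annual_change(traj, *window)
        scenario_section[name] = diag
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            traj.to_dataframe().to_csv(out_dir / f"trajectory_{name}.csv", index=False)
    report["scenarios"] = scenario_section

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(out_dir / "report.txt", "w", encoding="utf-8") as fh:
            fh.write(render_text(report))
    return report, fully_ok


def render_text(report: dict) -> str:
    """Human-readable rendering of the report document."""
    lines = ["peatghg summary report", "======================", ""]
    balance = report.get("balance", {})
    if balance.get("no_data"):
        lines += ["Flux balance: no data", ""]
    else:
        lines.append(f"Flux balance ({balance.get('mode')} mode)")
        for cat in balance.get("categories", []):
            lines.append(f"  {cat['category']}:")
            for gas, stats in cat["gases"].items():
                if stats is None:
                    lines.append(f"    {gas}: no data")
                else:
                    lines.append(
                        f"    {gas}: mean {stats['mean_rounded']} "
                        f"(n={stats['n']}, range {stats['min']:.6g}"
                        f" to {stats['max']:.6g}) kg element/ha/yr"
                    )
            for horizon, value in cat["co2eq"].items():
                lines.append(
                    f"    GWP{horizon} balance: {value:.1f} kg CO2-eq/ha/yr"
                )
        lines.append("")
    lines.append("Scenario diagnostics (t C/ha)")
    for name, diag in report.get("scenarios", {}).items():
        lines.append(f"  {name}:")
        lines.append(f"    neutrality year: {diag['neutrality_year']}")
        lines.append(
            f"    total C {diag['total_c_start']:.1f} -> {diag['total_c_end']:.2f}"
            f" (mean annual change {diag['mean_annual_change_full']:+.3f} t C/ha/yr)"
        )
        if "mean_annual_change_window" in diag:
            w = diag["window"]
            lines.append(
                f"    mean annual change years {w[0]}-{w[1]}: "
                f"{diag['mean_annual_change_window']:+.4f} t C/ha/yr"
            )
        if diag["cumulative_export_c"]:
            lines.append(
                f"    timber exported: {diag['cumulative_export_c']:.2f} t C/ha"
            )
    lines.append("")
    return "\n".join(lines)
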