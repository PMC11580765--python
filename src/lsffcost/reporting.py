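"""Summary metrics, report writers and one-at-a-time sensitivity sweeps.

Summary conventions: cost per MT divides the 10-year total program cost by
cumulative fortified tonnage over the operational years; cost per consumer
reached divides the mean annual operational-phase cost (firm + government +
premix) by the mean consuming population over the operational years. Both
product requirements (fortified MT/year, premix MT/year) are operational-
phase annual averages.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from .demand import DemandProjection, project
from .engine import CostReport, total_program_cost
from .premix import PremixFormulation, formulation_from_spec
from .scenario import Scenario

__all__ = [
    "SummaryMetrics",
    "summarize",
    "summarize_scenario",
    "sweep",
    "write_summary",
    "write_report_csv",
    "plot_category_breakdown",
]


@dataclass(frozen=True)
class SummaryMetrics:
    """Program-level summary of a cost report."""

    total_cost: float  # TPC over the full horizon, USD
    annual_average: float  # TPC / horizon
    cost_per_mt: float | None  # USD per MT fortified vehicle (None if none fortified)
    cost_per_consumer: float  # USD per consumer reached per operational year
    shares: dict[str, float]  # government / industry / premix fractions of TPC
    fortified_mt_per_year: float  # operational-phase annual average
    premix_mt_per_year: float

    def as_dict(self) -> dict[str, Any]:
        return {
            "total_cost": self.total_cost,
            "annual_average": self.annual_average,
            "cost_per_mt": self.cost_per_mt,
            "cost_per_consumer": self.cost_per_consumer,
            "shares": dict(self.shares),
            "fortified_mt_per_year": self.fortified_mt_per_year,
            "premix_mt_per_year": self.premix_mt_per_year,
        }


def summarize(
    report: CostReport, demand: DemandProjection, formulation: PremixFormulation
) -> SummaryMetrics:
    """Compute summary metrics from a complete cost report."""
    op = slice(report.startup_years, report.horizon)
    n_op = report.horizon - report.startup_years
    fortified = demand.fortified_domestic[op] + demand.fortified_imported[op]
    cum_fortified = float(fortified.sum())
    mean_fortified = cum_fortified / n_op
    tpc = report.tpc

    operational_total = report.opc_firm + report.opc_gov + report.pmx
    mean_consumers = float(demand.consuming_population[op].mean())
    cpc = (operational_total / n_op) / mean_consumers if mean_consumers > 0 else float("nan")

    shares = {
        "government": (report.suc_gov + report.opc_gov) / tpc if tpc else 0.0,
        "industry": (report.suc_firm + report.opc_firm) / tpc if tpc else 0.0,
        "premix": report.pmx / tpc if tpc else 0.0,
    }
    return SummaryMetrics(
        total_cost=tpc,
        annual_average=tpc / report.horizon,
        cost_per_mt=tpc / cum_fortified if cum_fortified > 0 else None,
        cost_per_consumer=cpc,
        shares=shares,
        fortified_mt_per_year=mean_fortified,
        premix_mt_per_year=mean_fortified * formulation.addition_rate * 1e-6,
    )


def summarize_scenario(scenario: Scenario) -> SummaryMetrics:
    """Run the full engine for a scenario and summarize it."""
    return summarize(
        total_program_cost(scenario), project(scenario), formulation_from_spec(scenario.premix)
    )


# ---------------------------------------------------------------------------
# Sensitivity sweeps

_PATH_TOKEN = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)|\[(\d+)\]")


def _resolve(scenario: Scenario, path: str):
    """Walk a dotted path with list indices, e.g. ``premix.nutrients[0].price``.

    Returns (parent object, final attribute/index).
    """
    tokens: list[str | int] = []
    pos = 0
    for m in _PATH_TOKEN.finditer(path.replace(".", " ")):
        tokens.append(int(m.group(2)) if m.group(2) is not None else m.group(1))
        pos = m.end()
    if not tokens:
        raise KeyError(f"empty parameter path {path!r}")
    obj: Any = scenario
    for tok in tokens[:-1]:
        obj = obj[tok] if isinstance(tok, int) else _get_attr_or_key(obj, tok)
    return obj, tokens[-1]


def _get_attr_or_key(obj: Any, name: str) -> Any:
    if isinstance(obj, dict):
        if name not in obj:
            raise KeyError(f"unknown key {name!r}")
        return obj[name]
    if not hasattr(obj, name):
        raise KeyError(f"unknown field {name!r} on {type(obj).__name__}")
    return getattr(obj, name)


def sweep(scenario: Scenario, parameter_path: str, values: Sequence[float]) -> pd.DataFrame:
    """Re-run the full engine for each value of one scalar parameter.

    Returns a table with columns (parameter, value, tpc, pmx, cost_per_mt).
    The input scenario is left unmodified; each run uses a deep copy.
    """
    parent, last = _resolve(scenario, parameter_path)  # fail fast on unknown paths
    if isinstance(last, int):
        parent[last]
    else:
        _get_attr_or_key(parent, last)
    rows = []
    for value in values:
        trial = copy.deepcopy(scenario)
        parent, last = _resolve(trial, parameter_path)
        if isinstance(last, int):
            parent[last] = value
        elif isinstance(parent, dict):
            parent[last] = value
        else:
            current = getattr(parent, last)
            if not isinstance(current, (int, float)) or isinstance(current, bool):
                raise KeyError(f"parameter {parameter_path!r} is not numeric")
            setattr(parent, last, value)
        metrics = summarize_scenario(trial)
        report = total_program_cost(trial)
        rows.append(
            {
                "parameter": parameter_path,
                "value": value,
                "tpc": report.tpc,
                "pmx": report.pmx,
                "cost_per_mt": metrics.cost_per_mt,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers


def write_report_csv(report: CostReport, path: str | Path) -> None:
    """Long-format per-year CSV: model_year, year, actor, category, amount_usd."""
    cells = report.cells.sort_values(
        ["model_year", "actor", "category"], kind="stable"
    ).reset_index(drop=True)
    cells.to_csv(path, index=False, float_format="%.6f")


def write_summary(
    report: CostReport, metrics: SummaryMetrics, path: str | Path
) -> None:
    """JSON summary: phase totals plus summary metrics."""
    payload = {
        "scenario": report.scenario_name,
        "totals": report.summary_dict(),
        "metrics": metrics.as_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def plot_category_breakdown(report: CostReport, path: str | Path) -> None:
    """Bar chart of total cost by actor and category (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    totals = (
        report.cells.groupby(["actor", "category"]).amount_usd.sum().sort_values(ascending=False)
    )
    fig, ax = plt.subplots(figsize=(9, 5))
    totals.plot.bar(ax=ax)
    ax.set_ylabel("USD over horizon")
    ax.set_title(f"Cost by actor and category: {report.scenario_name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
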