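"""Cost engine: start-up and operational cost schedules for firms and
government, annual premix requirements and costs by channel, and the total
program cost identity

    TPC = SUC_F + SUC_G + OPC_F + OPC_G + PMX

Start-up years carry no premix cost (no fortification occurs); premix
purchases and all operational schedules begin in the first operational
year. Firm management/overhead is a fixed fraction of the domestic-channel
premix value (imported-product premix is managed by foreign producers);
government management is the same kind of fraction applied to the annual
monitoring subtotal (factory, import, commercial and household monitoring
line items).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demand import DemandProjection, project
from .premix import (
    PremixFormulation,
    cost_per_mt_vehicle,
    formulation_from_spec,
    landed_price_per_kg,
)
from .scenario import CostLineItem, Scenario

__all__ = [
    "AnnualPremixRequirement",
    "CostReport",
    "line_item_cost",
    "startup_costs",
    "operational_costs_firm",
    "operational_costs_gov",
    "premix_requirements",
    "channel_cost_per_mt",
    "total_program_cost",
]

CHANNELS = ("domestic_production", "imported_product")


@dataclass(frozen=True)
class AnnualPremixRequirement:
    """Premix needed for one (year, channel) cell."""

    year: int  # model year, 1-based
    calendar_year: int
    channel: str
    fortified_volume: float  # MT vehicle
    premix_mass: float  # MT premix
    cost: float  # USD


@dataclass
class CostReport:
    """Per-year, per-actor, per-category cost cells plus phase totals.

    ``cells`` is a long table with columns model_year, year, actor
    (firm / government / premix_domestic / premix_imported), category and
    amount_usd. Every total equals the sum of its cells; TPC is the sum of
    the five components.
    """

    scenario_name: str
    startup_years: int
    horizon: int
    cells: pd.DataFrame
    premix_requirements: list[AnnualPremixRequirement] = field(default_factory=list)
    suc_firm: float = 0.0
    suc_gov: float = 0.0
    opc_firm: float = 0.0
    opc_gov: float = 0.0
    pmx: float = 0.0

    @property
    def tpc(self) -> float:
        return self.suc_firm + self.suc_gov + self.opc_firm + self.opc_gov + self.pmx

    def annual(self, actor: str | None = None) -> pd.Series:
        """Total cost per model year, optionally for one actor."""
        df = self.cells if actor is None else self.cells[self.cells.actor == actor]
        return df.groupby("model_year").amount_usd.sum()

    def summary_dict(self) -> dict[str, float]:
        return {
            "SUC_F": self.suc_firm,
            "SUC_G": self.suc_gov,
            "OPC_F": self.opc_firm,
            "OPC_G": self.opc_gov,
            "PMX": self.pmx,
            "TPC": self.tpc,
        }


def _scope_multiplier(item: CostLineItem, scenario: Scenario) -> float:
    if item.scope == "per_factory":
        return float(scenario.n_factories)
    if item.scope == "per_port":
        return float(scenario.n_ports)
    return 1.0


def line_item_cost(item: CostLineItem, scenario: Scenario, year: int) -> float:
    """Cost of one line item in one model year (1-based).

    quantity x unit price x scope multiplier x schedule multiplier, grossed
    up by the item's markups combined additively.
    """
    if not 1 <= year <= scenario.horizon:
        raise ValueError(f"model year {year} outside 1..{scenario.horizon}")
    sched = scenario.schedule_for(item)[year - 1]
    base = item.quantity * item.unit_price * _scope_multiplier(item, scenario) * sched
    return base * (1.0 + sum(f for _, f in item.markups))


def startup_costs(scenario: Scenario, actor: str) -> np.ndarray:
    """Per-year start-up costs for one actor (years 1..startup_years)."""
    items = [i for i in scenario.cost_items if i.actor == actor and i.phase == "startup"]
    return np.array(
        [sum(line_item_cost(i, scenario, y) for i in items)
         for y in range(1, scenario.startup_years + 1)]
    )


def channel_cost_per_mt(scenario: Scenario, formulation: PremixFormulation, channel: str) -> float:
    """Landed premix cost per MT of fortified vehicle for one supply channel."""
    landed = landed_price_per_kg(formulation.base_price_per_kg, scenario.channels[channel])
    return cost_per_mt_vehicle(landed, formulation.addition_rate)


def premix_requirements(
    scenario: Scenario, demand: DemandProjection, formulation: PremixFormulation
) -> list[AnnualPremixRequirement]:
    """Premix mass and cost per operational year and channel.

    Per-nutrient masses are derivable from each cell as
    ``premix_mass * nutrient proportion``.
    """
    out: list[AnnualPremixRequirement] = []
    for channel, stream in (
        ("domestic_production", demand.fortified_domestic),
        ("imported_product", demand.fortified_imported),
    ):
        per_mt = channel_cost_per_mt(scenario, formulation, channel)
        kg_per_mt = formulation.kg_premix_per_mt_vehicle
        for year in scenario.operational_years():
            vol = float(stream[year - 1])
            out.append(
                AnnualPremixRequirement(
                    year=year,
                    calendar_year=int(demand.years[year - 1]),
                    channel=channel,
                    fortified_volume=vol,
                    premix_mass=vol * kg_per_mt * 1e-3,  # kg -> MT premix
                    cost=vol * per_mt,
                )
            )
    return out


def _premix_cost(
    scenario: Scenario,
    demand: DemandProjection,
    formulation: PremixFormulation,
    year: int,
    channel: str,
) -> float:
    if year <= scenario.startup_years:
        return 0.0
    stream = (
        demand.fortified_domestic if channel == "domestic_production" else demand.fortified_imported
    )
    return float(stream[year - 1]) * channel_cost_per_mt(scenario, formulation, channel)


def operational_costs_firm(
    scenario: Scenario,
    demand: DemandProjection,
    formulation: PremixFormulation,
    year: int,
) -> float:
    """Firm operational cost in one model year: fixed line items plus
    management/overhead as a fraction of that year's domestic premix value."""
    items = [i for i in scenario.cost_items if i.actor == "firm" and i.phase == "operational"]
    fixed = sum(line_item_cost(i, scenario, year) for i in items)
    mgmt = scenario.firm_mgmt_rate * _premix_cost(
        scenario, demand, formulation, year, "domestic_production"
    )
    return fixed + mgmt


def operational_costs_gov(scenario: Scenario, year: int) -> float:
    """Government operational cost in one model year: monitoring and other
    line items plus management as a fraction of the monitoring subtotal."""
    items = [i for i in scenario.cost_items if i.actor == "government" and i.phase == "operational"]
    total = sum(line_item_cost(i, scenario, year) for i in items)
    base = sum(line_item_cost(i, scenario, year) for i in items if i.management_base)
    return total + scenario.gov_mgmt_rate * base


def total_program_cost(scenario: Scenario) -> CostReport:
    """Run the full model: demand -> formulation -> all cost schedules."""
    demand = project(scenario)
    formulation = formulation_from_spec(scenario.premix)
    years = scenario.population.years
    rows: list[tuple] = []

    def add(year: int, actor: str, category: str, amount: float) -> None:
        if amount != 0.0:
            rows.append((year, years[year - 1], actor, category, amount))

    for item in scenario.cost_items:
        for year in range(1, scenario.horizon + 1):
            add(year, item.actor, item.category or item.label, line_item_cost(item, scenario, year))

    gov_op = [i for i in scenario.cost_items
              if i.actor == "government" and i.phase == "operational" and i.management_base]
    for year in range(1, scenario.horizon + 1):
        base = sum(line_item_cost(i, scenario, year) for i in gov_op)
        add(year, "government", "management", scenario.gov_mgmt_rate * base)
        add(
            year,
            "firm",
            "management",
            scenario.firm_mgmt_rate
            * _premix_cost(scenario, demand, formulation, year, "domestic_production"),
        )

    reqs = premix_requirements(scenario, demand, formulation)
    for req in reqs:
        actor = "premix_domestic" if req.channel == "domestic_production" else "premix_imported"
        add(req.year, actor, "premix", req.cost)

    cells = pd.DataFrame(
        rows, columns=["model_year", "year", "actor", "category", "amount_usd"]
    )
    startup = cells.model_year <= scenario.startup_years
    report = CostReport(
        scenario_name=scenario.name,
        startup_years=scenario.startup_years,
        horizon=scenario.horizon,
        cells=cells,
        premix_requirements=reqs,
        suc_firm=float(cells.amount_usd[startup & (cells.actor == "firm")].sum()),
        suc_gov=float(cells.amount_usd[startup & (cells.actor == "government")].sum()),
        opc_firm=float(cells.amount_usd[~startup & (cells.actor == "firm")].sum()),
        opc_gov=float(cells.amount_usd[~startup & (cells.actor == "government")].sum()),
        pmx=float(cells.amount_usd[cells.actor.str.startswith("premix")].sum()),
    )
    return report
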