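"""Cost engine: line items, schedules, premix accounting and the total-cost
identity, checked against published yearly totals and a brute-force oracle."""

import numpy as np
import pytest

from lsffcost import (
    CostLineItem,
    line_item_cost,
    operational_costs_firm,
    operational_costs_gov,
    premix_requirements,
    project,
    random_scenario,
    startup_costs,
    total_program_cost,
)
from lsffcost.premix import formulation_from_spec


# ---------------------------------------------------------------------------
# Brute-force oracle: a deliberately plain year-by-year recomputation of the
# total program cost sharing no code with the engine.


def brute_force_tpc(s):
    if s.availability_override is not None:
        avail = s.availability_override
    else:
        avail = sum(t.population_share * t.reach * t.intake for t in s.strata)

    subtotal = 0.0
    nutrient_cost = 0.0
    for n in s.premix.nutrients:
        amount = n.target_level * (1 + n.overage_fraction) / n.activity
        subtotal += amount
        nutrient_cost += amount / s.premix.addition_rate * n.price
    base_price = (
        nutrient_cost
        + (s.premix.addition_rate - subtotal) / s.premix.addition_rate * s.premix.excipient_price
        + s.premix.upcharge_per_kg
    )
    per_mt = {}
    for channel, p in s.channels.items():
        landed = base_price * (1 + p.duty_fraction) + p.transport_per_kg
        per_mt[channel] = landed * s.premix.addition_rate * 1e-3

    def item_cost(item, idx):
        if item.year_schedule is not None:
            mult = item.year_schedule[idx]
        else:
            in_startup = (idx + 1) <= s.startup_years
            mult = 1.0 if (item.phase == "startup") == in_startup else 0.0
        if item.scope == "per_factory":
            scope = s.n_factories
        elif item.scope == "per_port":
            scope = s.n_ports
        else:
            scope = 1
        return (item.quantity * item.unit_price * scope * mult
                * (1 + sum(f for _, f in item.markups)))

    total = 0.0
    for idx in range(s.horizon):
        for item in s.cost_items:
            total += item_cost(item, idx)
        monitoring = sum(
            item_cost(item, idx)
            for item in s.cost_items
            if item.actor == "government" and item.phase == "operational"
            and item.management_base
        )
        total += s.gov_mgmt_rate * monitoring
        if idx + 1 > s.startup_years:
            volume = avail * s.population.totals[idx] * 365 * 1e-6
            fortified_dom = volume * s.domestic_share * s.industrial_share * s.compliance
            fortified_imp = (volume - volume * s.domestic_share) \
                * s.industrial_share * s.compliance
            dom_cost = fortified_dom * per_mt["domestic_production"]
            total += dom_cost + fortified_imp * per_mt["imported_product"]
            total += s.firm_mgmt_rate * dom_cost
    return total


# ---------------------------------------------------------------------------
# Line items and start-up schedules


def test_feeder_line_item(nigeria):
    feeder = next(i for i in nigeria.cost_items if i.label.startswith("feeder"))
    no_markup = feeder.model_copy(update={"markups": []})
    assert line_item_cost(no_markup, nigeria, 1) == pytest.approx(40_000)


def test_equipment_markups_combine_additively(nigeria):
    equipment = [i for i in nigeria.cost_items
                 if i.category == "equipment" and i.actor == "firm"]
    total = sum(line_item_cost(i, nigeria, 1) for i in equipment)
    # (40,000 + 100,312) x (1 + 0.10 + 0.10 + 0.08)
    assert total == pytest.approx(179_599.36, abs=0.01)


def test_zero_schedule_year_costs_nothing(nigeria):
    feeder = next(i for i in nigeria.cost_items if i.label.startswith("feeder"))
    assert line_item_cost(feeder, nigeria, 5) == 0.0


def test_factory_startup_years(nigeria):
    per_year = startup_costs(nigeria, "firm")
    assert per_year[0] == pytest.approx(188_195, abs=10)
    assert per_year[1] == pytest.approx(5_979, abs=1)


def test_government_startup_total(nigeria):
    assert startup_costs(nigeria, "government").sum() == pytest.approx(716_556, abs=1)


def test_no_startup_items_means_zero():
    s = random_scenario(7).model_copy(deep=True)
    s.cost_items = [i for i in s.cost_items if i.phase != "startup"
                    and i.year_schedule is None]
    assert startup_costs(s, "firm").sum() == 0.0
    assert startup_costs(s, "government").sum() == 0.0


# ---------------------------------------------------------------------------
# Premix requirements and operational schedules


def test_domestic_premix_series(nigeria, nigeria_demand, nigeria_formulation):
    published_thousands = [64065, 65659, 67283, 68935, 70616, 72325, 74062, 75828]
    reqs = [r for r in premix_requirements(nigeria, nigeria_demand, nigeria_formulation)
            if r.channel == "domestic_production"]
    assert [r.calendar_year for r in reqs] == list(range(2023, 2031))
    for req, published in zip(reqs, published_thousands):
        assert req.cost / 1000 == pytest.approx(published, rel=5e-4)


def test_premix_mass_consistent(nigeria, nigeria_demand, nigeria_formulation):
    reqs = premix_requirements(nigeria, nigeria_demand, nigeria_formulation)
    for req in reqs:
        assert req.premix_mass == pytest.approx(req.fortified_volume * 16.25e-3, rel=1e-12)


def test_firm_operational_years(nigeria, nigeria_demand, nigeria_formulation):
    y2023 = operational_costs_firm(nigeria, nigeria_demand, nigeria_formulation, 3)
    y2026 = operational_costs_firm(nigeria, nigeria_demand, nigeria_formulation, 6)
    assert y2023 == pytest.approx(3_447_914, rel=1e-4)
    assert y2026 == pytest.approx(3_691_432, rel=1e-4)


def test_firm_fixed_costs_without_premix(nigeria, nigeria_formulation):
    s = nigeria.model_copy(deep=True)
    s.compliance = 0.0
    fixed = operational_costs_firm(s, project(s), nigeria_formulation, 3)
    assert fixed == pytest.approx(244_682, abs=1)


def test_gov_operational_years(nigeria):
    assert operational_costs_gov(nigeria, 3) == pytest.approx(158_517, abs=1)
    # +30,000 household monitoring, which also enters the management base
    assert operational_costs_gov(nigeria, 4) == pytest.approx(190_017, abs=1)
    # inspections and their reagents halved from the fourth operational year
    assert operational_costs_gov(nigeria, 6) == pytest.approx(148_340, abs=1)
    assert operational_costs_gov(nigeria, 10) == pytest.approx(148_340, abs=1)


# ---------------------------------------------------------------------------
# Whole-model identities and properties


def test_total_cost_identity_and_cells(nigeria_report):
    r = nigeria_report
    assert r.tpc == r.suc_firm + r.suc_gov + r.opc_firm + r.opc_gov + r.pmx
    assert r.cells.amount_usd.sum() == pytest.approx(r.tpc, rel=1e-12)


@pytest.mark.parametrize("block", range(2))
def test_engine_matches_brute_force_oracle(block):
    """Engine vs independent year-by-year recomputation, 100 random scenarios."""
    for seed in range(block * 50, (block + 1) * 50):
        s = random_scenario(seed)
        report = total_program_cost(s)
        oracle = brute_force_tpc(s)
        assert report.tpc == pytest.approx(oracle, rel=1e-9), f"seed {seed}"


def test_price_homogeneity_of_tpc():
    s = random_scenario(11)
    scale = 3.7
    scaled = s.model_copy(deep=True)
    for n in scaled.premix.nutrients:
        n.price *= scale
    scaled.premix.excipient_price *= scale
    scaled.premix.upcharge_per_kg *= scale
    for ch in scaled.channels.values():
        ch.transport_per_kg *= scale
    for item in scaled.cost_items:
        item.unit_price *= scale
    assert total_program_cost(scaled).tpc == pytest.approx(
        total_program_cost(s).tpc * scale, rel=1e-9)


def test_tpc_monotone_in_compliance_population_and_prices():
    s = random_scenario(23)
    base = total_program_cost(s).tpc

    up = s.model_copy(deep=True)
    up.compliance = min(1.0, s.compliance + 0.1)
    assert total_program_cost(up).tpc >= base

    up = s.model_copy(deep=True)
    up.population.totals = [t * 1.1 for t in up.population.totals]
    assert total_program_cost(up).tpc >= base

    up = s.model_copy(deep=True)
    up.cost_items[0].unit_price += 1000
    assert total_program_cost(up).tpc >= base

    up = s.model_copy(deep=True)
    up.premix.nutrients[0].price += 10
    assert total_program_cost(up).tpc >= base


def test_zero_compliance_limit(nigeria):
    """No premix is bought and firm management vanishes, while government
    costs are unchanged."""
    s = nigeria.model_copy(deep=True)
    s.compliance = 0.0
    zero = total_program_cost(s)
    full = total_program_cost(nigeria)
    assert zero.pmx == 0.0
    mgmt = zero.cells[(zero.cells.actor == "firm") & (zero.cells.category == "management")]
    assert mgmt.empty
    assert zero.opc_gov == pytest.approx(full.opc_gov, rel=1e-12)
    assert zero.suc_gov == full.suc_gov


def test_all_prices_zero_gives_zero_tpc():
    s = random_scenario(3).model_copy(deep=True)
    for n in s.premix.nutrients:
        n.price = 0.0
    s.premix.excipient_price = 0.0
    s.premix.upcharge_per_kg = 0.0
    for ch in s.channels.values():
        ch.transport_per_kg = 0.0
    for item in s.cost_items:
        item.unit_price = 0.0
    assert total_program_cost(s).tpc == 0.0


def test_startup_years_carry_no_premix(nigeria_report):
    premix_cells = nigeria_report.cells[nigeria_report.cells.actor.str.startswith("premix")]
    assert (premix_cells.model_year > nigeria_report.startup_years).all()


def test_nigeria_startup_total(nigeria_report):
    assert nigeria_report.suc_firm + nigeria_report.suc_gov == pytest.approx(
        910_730, rel=1e-3)
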