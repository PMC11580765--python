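"""Scenario configuration: domain types, validation, file I/O, fixtures, random generator.

A :class:`Scenario` is a complete country configuration for a 10-year
fortification program: population series, subnational consumption strata,
industry structure, the premix nutrient specification, premix supply-channel
parameters, and the itemized start-up / operational cost schedules for firms
and government. Scenario files are a YAML 1.1 subset (JSON also parses);
all keys are snake_case and all monetary values are plain numbers in
constant 2021 USD.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "NutrientSpec",
    "PremixChannelParams",
    "PremixSpec",
    "ConsumptionStratum",
    "PopulationSeries",
    "CostLineItem",
    "Scenario",
    "ScenarioFormatError",
    "ScenarioValidationError",
    "load_scenario",
    "save_scenario",
    "build_fixture",
    "random_scenario",
    "FIXTURE_COUNTRIES",
]

FIXTURE_COUNTRIES = ("nigeria", "senegal", "burkina_faso")

SHARE_TOL = 1e-6


class ScenarioFormatError(ValueError):
    """The file did not parse as the documented YAML/JSON dialect."""


class ScenarioValidationError(ValueError):
    """The parsed configuration violates a scenario invariant."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NutrientSpec(_Model):
    """One micronutrient line in the premix.

    ``activity`` is the mass fraction of micronutrient in its fortificant
    compound; ``target_level`` is mg micronutrient per kg of food vehicle;
    ``overage_fraction`` is the extra fraction of the target added to
    compensate for degradation before consumption; ``price`` is USD per kg
    of fortificant.
    """

    name: str
    compound: str = ""
    activity: float = Field(gt=0, le=1)
    target_level: float = Field(ge=0)
    overage_fraction: float = Field(default=0.0, ge=0)
    price: float = Field(ge=0)


class PremixChannelParams(_Model):
    """Adders that turn a base premix price into a landed price for one channel."""

    duty_fraction: float = Field(default=0.0, ge=0)
    transport_per_kg: float = Field(default=0.0, ge=0)


class PremixSpec(_Model):
    """Premix formulation inputs: nutrient lines plus blending parameters.

    ``addition_rate`` is mg premix per kg vehicle (equivalently kg premix per
    MT). The excipient fills the mass not occupied by fortificants; the
    up-charge is the blender's margin per kg of finished premix.
    """

    nutrients: list[NutrientSpec]
    addition_rate: float = Field(gt=0)
    excipient_price: float = Field(default=0.0, ge=0)
    upcharge_per_kg: float = Field(default=0.0, ge=0)


class ConsumptionStratum(_Model):
    """A subnational consumption stratum.

    ``reach`` is the fraction of the stratum population consuming the
    vehicle; ``intake`` is g/day per consumer.
    """

    name: str
    population_share: float = Field(ge=0, le=1)
    reach: float = Field(ge=0, le=1)
    intake: float = Field(ge=0)


class PopulationSeries(_Model):
    """Annual population over the model horizon (calendar years, contiguous)."""

    years: list[int]
    totals: list[float]
    consuming_fraction: float = Field(default=1.0, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "PopulationSeries":
        if len(self.years) != len(self.totals):
            raise ValueError("population: years and totals must have equal length")
        if any(b - a != 1 for a, b in zip(self.years, self.years[1:])):
            raise ValueError("population: years must be contiguous and increasing")
        if any(t <= 0 for t in self.totals):
            raise ValueError("population: totals must be positive")
        return self


Actor = Literal["firm", "government"]
Phase = Literal["startup", "operational"]
Scope = Literal["per_factory", "per_port", "national"]


class CostLineItem(_Model):
    """One priced activity or investment in a cost schedule.

    The annual cost is ``quantity * unit_price * scope_multiplier *
    year_schedule[year] * (1 + sum of markup fractions)`` — markups combine
    additively. ``year_schedule`` holds one multiplier per model year
    (1..horizon); if omitted, it defaults to 1 in every year of the item's
    phase and 0 elsewhere. ``management_base`` marks government monitoring
    items whose annual cost enters the base for the government
    management/overhead percentage.
    """

    label: str
    actor: Actor
    phase: Phase
    category: str = ""
    scope: Scope = "national"
    quantity: float = Field(ge=0)
    unit_price: float = Field(ge=0)
    markups: list[tuple[str, float]] = Field(default_factory=list)
    year_schedule: Optional[list[float]] = None
    management_base: bool = False

    @model_validator(mode="after")
    def _check(self) -> "CostLineItem":
        if any(f < 0 for _, f in self.markups):
            raise ValueError(f"cost item {self.label!r}: markup fractions must be >= 0")
        if self.year_schedule is not None and any(m < 0 for m in self.year_schedule):
            raise ValueError(f"cost item {self.label!r}: year_schedule multipliers must be >= 0")
        return self


class Scenario(_Model):
    """A complete country configuration for the cost model."""

    name: str
    approximate: bool = False
    horizon: int = Field(default=10, gt=0)
    startup_years: int = Field(default=2, ge=0)
    population: PopulationSeries
    strata: list[ConsumptionStratum]
    availability_override: Optional[float] = Field(default=None, ge=0)
    domestic_share: float = Field(ge=0, le=1)
    industrial_share: float = Field(default=1.0, ge=0, le=1)
    compliance: float = Field(ge=0, le=1)
    n_factories: int = Field(ge=0)
    n_ports: int = Field(default=0, ge=0)
    production_days: int = Field(default=250, gt=0)
    premix: PremixSpec
    channels: dict[Literal["domestic_production", "imported_product"], PremixChannelParams]
    firm_mgmt_rate: float = Field(default=0.0, ge=0)
    gov_mgmt_rate: float = Field(default=0.0, ge=0)
    cost_items: list[CostLineItem] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "Scenario":
        if self.startup_years >= self.horizon:
            raise ValueError("startup_years must be smaller than horizon")
        if len(self.population.years) != self.horizon:
            raise ValueError(
                f"population series length {len(self.population.years)} != horizon {self.horizon}"
            )
        if not self.strata:
            raise ValueError("strata: at least one consumption stratum is required")
        total_share = sum(s.population_share for s in self.strata)
        if abs(total_share - 1.0) > SHARE_TOL:
            raise ValueError(f"strata: population shares sum to {total_share}, expected 1")
        for key in ("domestic_production", "imported_product"):
            if key not in self.channels:
                raise ValueError(f"channels: missing {key!r}")
        for item in self.cost_items:
            if item.year_schedule is not None and len(item.year_schedule) != self.horizon:
                raise ValueError(
                    f"cost item {item.label!r}: year_schedule length must equal horizon"
                )
        return self

    def schedule_for(self, item: CostLineItem) -> np.ndarray:
        """Effective per-model-year multiplier vector (length ``horizon``)."""
        if item.year_schedule is not None:
            return np.asarray(item.year_schedule, dtype=float)
        sched = np.zeros(self.horizon)
        if item.phase == "startup":
            sched[: self.startup_years] = 1.0
        else:
            sched[self.startup_years :] = 1.0
        return sched

    def operational_years(self) -> range:
        """Model years (1-based) of the operational phase."""
        return range(self.startup_years + 1, self.horizon + 1)


# ---------------------------------------------------------------------------
# File I/O


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario configuration file (YAML or JSON).

    Raises :class:`ScenarioFormatError` on parse failure (naming the line)
    and :class:`ScenarioValidationError` on invariant violation (naming the
    field).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ScenarioFormatError(f"{path}: not valid YAML/JSON{where}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ScenarioFormatError(f"{path}: top level must be a mapping")
    return scenario_from_dict(raw, source=str(path))


def scenario_from_dict(raw: dict, source: str = "<dict>") -> Scenario:
    """Validate a raw mapping into a :class:`Scenario`."""
    try:
        return Scenario.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ScenarioValidationError(f"{source}: invalid field {loc}: {first['msg']}") from exc


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as normalized YAML (stable key order, defaults filled)."""
    data = scenario.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True, default_flow_style=False))


def build_fixture(country: str) -> Scenario:
    """Return a packaged reference scenario (``nigeria``, ``senegal``, ``burkina_faso``).

    The Nigeria scenario is fully itemized from published program costing
    tables (with unrounded unit values calibrated to the published subtotals,
    documented inline in the fixture file). Senegal and Burkina Faso carry
    ``approximate=True``: their cost schedules are aggregate category totals,
    not itemized schedules.
    """
    key = country.strip().lower().replace("-", "_").replace(" ", "_")
    if key not in FIXTURE_COUNTRIES:
        raise KeyError(f"unknown fixture country {country!r}; expected one of {FIXTURE_COUNTRIES}")
    text = resources.files("lsffcost.data").joinpath(f"{key}.yaml").read_text()
    return scenario_from_dict(yaml.safe_load(text), source=f"fixture:{key}")


# ---------------------------------------------------------------------------
# Random scenario generator (property-test input space)


def random_scenario(seed: int) -> Scenario:
    """Deterministically generate a valid random scenario from ``seed``.

    Draws a 1-300M population with smooth growth, 1-15 consumption strata,
    1-6 premix nutrients with positive prices, a feasible addition rate
    (smallest 250 mg/kg multiple >= 110% of the fortificant mass subtotal),
    and a handful of start-up/operational cost items for each actor.
    """
    rng = np.random.default_rng(seed)
    horizon = 10
    startup_years = int(rng.integers(1, 4))

    base_year = int(rng.integers(2015, 2030))
    base_pop = float(rng.uniform(1e6, 3e8))
    growth = float(rng.uniform(-0.01, 0.04))
    totals = [base_pop * (1 + growth) ** k for k in range(horizon)]

    n_strata = int(rng.integers(1, 16))
    shares = rng.dirichlet(np.ones(n_strata))
    shares = shares / shares.sum()
    strata = [
        ConsumptionStratum(
            name=f"stratum_{i}",
            population_share=float(shares[i]),
            reach=float(rng.uniform(0, 1)),
            intake=float(rng.uniform(0, 6)),
        )
        for i in range(n_strata)
    ]
    # fix any residual float drift in the share total
    strata[-1].population_share = max(0.0, 1.0 - sum(s.population_share for s in strata[:-1]))

    n_nutrients = int(rng.integers(1, 7))
    nutrients = [
        NutrientSpec(
            name=f"nutrient_{k}",
            compound=f"compound_{k}",
            activity=float(rng.uniform(0.01, 1.0)),
            target_level=float(rng.uniform(1, 3000)),
            overage_fraction=float(rng.choice([0.0, 0.1, 0.3])),
            price=float(rng.uniform(0.5, 100)),
        )
        for k in range(n_nutrients)
    ]
    subtotal = sum(n.target_level * (1 + n.overage_fraction) / n.activity for n in nutrients)
    addition_rate = max(250.0, 250.0 * math.ceil(1.1 * subtotal / 250.0))

    def _items() -> list[CostLineItem]:
        items = []
        for actor in ("firm", "government"):
            for phase in ("startup", "operational"):
                for j in range(int(rng.integers(1, 4))):
                    sched = None
                    if rng.random() < 0.3:
                        sched = [float(rng.choice([0.0, 0.5, 1.0])) for _ in range(horizon)]
                    markups = []
                    if rng.random() < 0.4:
                        markups = [("markup", float(rng.uniform(0, 0.3)))]
                    items.append(
                        CostLineItem(
                            label=f"{actor}_{phase}_{j}",
                            actor=actor,
                            phase=phase,
                            category=phase,
                            scope=str(rng.choice(["per_factory", "per_port", "national"])),
                            quantity=float(rng.uniform(0, 100)),
                            unit_price=float(rng.uniform(0, 5e4)),
                            markups=markups,
                            year_schedule=sched,
                            management_base=(actor == "government" and phase == "operational"
                                             and bool(rng.random() < 0.5)),
                        )
                    )
        return items

    return Scenario(
        name=f"random_{seed}",
        approximate=False,
        horizon=horizon,
        startup_years=startup_years,
        population=PopulationSeries(
            years=list(range(base_year, base_year + horizon)),
            totals=totals,
            consuming_fraction=float(rng.uniform(0.3, 1.0)),
        ),
        strata=strata,
        availability_override=float(rng.uniform(0.1, 6)) if rng.random() < 0.5 else None,
        domestic_share=float(rng.uniform(0, 1)),
        industrial_share=float(rng.uniform(0.5, 1)),
        compliance=float(rng.uniform(0, 1)),
        n_factories=int(rng.integers(1, 21)),
        n_ports=int(rng.integers(1, 21)),
        production_days=int(rng.integers(200, 301)),
        premix=PremixSpec(
            nutrients=nutrients,
            addition_rate=addition_rate,
            excipient_price=float(rng.uniform(0, 5)),
            upcharge_per_kg=float(rng.uniform(0, 3)),
        ),
        channels={
            "domestic_production": PremixChannelParams(
                duty_fraction=float(rng.uniform(0, 0.4)),
                transport_per_kg=float(rng.uniform(0, 1)),
            ),
            "imported_product": PremixChannelParams(
                duty_fraction=float(rng.uniform(0, 0.4)),
                transport_per_kg=float(rng.uniform(0, 1)),
            ),
        },
        firm_mgmt_rate=float(rng.uniform(0, 0.1)),
        gov_mgmt_rate=float(rng.uniform(0, 0.1)),
        cost_items=_items(),
    )
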