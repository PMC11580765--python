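"""Demand projection: national consumption, annual vehicle volumes, and the
split into domestic/imported and fortified/unfortified streams.

Only the population varies over the horizon; per-capita availability, the
domestic share, the industrial (fortifiable) share and compliance are held
constant. A model year is 365 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario import ConsumptionStratum, Scenario

__all__ = ["DemandProjection", "national_daily_consumption", "availability", "project"]

DAYS_PER_YEAR = 365.0
G_TO_MT = 1e-6


@dataclass(frozen=True)
class DemandProjection:
    """Annual vehicle volumes (MT) by stream over the model horizon.

    ``domestic_volume + imported_volume == annual_volume`` each year by
    construction; fortified streams are each stream times the industrial
    share times compliance.
    """

    years: np.ndarray  # calendar years
    per_capita_availability: float  # g/capita/day
    population: np.ndarray  # persons
    consuming_population: np.ndarray  # persons
    annual_volume: np.ndarray  # MT vehicle
    domestic_volume: np.ndarray
    imported_volume: np.ndarray
    fortified_domestic: np.ndarray
    fortified_imported: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Per-year long table (one row per calendar year)."""
        return pd.DataFrame(
            {
                "year": self.years,
                "population": self.population,
                "annual_volume_mt": self.annual_volume,
                "domestic_mt": self.domestic_volume,
                "imported_mt": self.imported_volume,
                "fortified_domestic_mt": self.fortified_domestic,
                "fortified_imported_mt": self.fortified_imported,
            }
        )


def national_daily_consumption(population: float, strata: list[ConsumptionStratum]) -> float:
    """Total national consumption (g/day): sum over strata of
    population x share x reach x intake."""
    if not strata:
        raise ValueError("at least one consumption stratum is required")
    return sum(population * s.population_share * s.reach * s.intake for s in strata)


def availability(scenario: Scenario) -> float:
    """Per-capita availability of the vehicle in the food supply (g/capita/day).

    Uses the scenario's explicit override when present (fixtures calibrate
    it against published annual volumes, since rounded stratum reach/intake
    values do not recompose the published national totals exactly);
    otherwise derives it from the strata in the base year.
    """
    if scenario.availability_override is not None:
        return scenario.availability_override
    base_pop = scenario.population.totals[0]
    return national_daily_consumption(base_pop, scenario.strata) / base_pop


def project(scenario: Scenario) -> DemandProjection:
    """Project annual vehicle volumes and their streams over the horizon."""
    avail = availability(scenario)
    pop = np.asarray(scenario.population.totals, dtype=float)
    annual = avail * pop * DAYS_PER_YEAR * G_TO_MT
    domestic = annual * scenario.domestic_share
    imported = annual - domestic  # exact conservation
    frac = scenario.industrial_share * scenario.compliance
    return DemandProjection(
        years=np.asarray(scenario.population.years),
        per_capita_availability=avail,
        population=pop,
        consuming_population=pop * scenario.population.consuming_fraction,
        annual_volume=annual,
        domestic_volume=domestic,
        imported_volume=imported,
        fortified_domestic=domestic * frac,
        fortified_imported=imported * frac,
    )
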