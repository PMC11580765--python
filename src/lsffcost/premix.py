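"""Micronutrient premix cost calculator.

Builds a premix formulation from nutrient specifications and prices it per
kg of premix, per kg landed (after channel duty and transport adders), and
per metric ton of fortified food vehicle.

Units: fortification levels and fortificant amounts are mg per kg of
vehicle; the addition rate (mg premix / kg vehicle) is numerically equal to
kg premix per MT of vehicle divided by 1e-3. Prices are USD/kg; per-MT
costs are USD per MT of vehicle. All arithmetic is carried at full
precision; rounding to cents happens only in display code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .scenario import NutrientSpec, PremixChannelParams, PremixSpec

__all__ = [
    "FormulationError",
    "NutrientLine",
    "PremixFormulation",
    "level_from_nrv",
    "fortificant_amount",
    "suggest_addition_rate",
    "build_formulation",
    "formulation_from_spec",
    "landed_price_per_kg",
    "cost_per_mt_vehicle",
]

MG_PER_KG_TO_KG_PER_MT = 1e-3  # 1 mg/kg == 1 g/MT == 1e-3 kg/MT


class FormulationError(ValueError):
    """The requested premix formulation is infeasible."""


@dataclass(frozen=True)
class NutrientLine:
    """One priced nutrient row of an assembled formulation."""

    spec: NutrientSpec
    fortificant_amount: float  # mg fortificant per kg vehicle
    proportion: float  # mass fraction of the premix
    cost_contribution: float  # USD per kg premix


@dataclass(frozen=True)
class PremixFormulation:
    """An assembled premix with its per-kg price decomposition.

    Invariants (maintained by :func:`build_formulation`): nutrient
    proportions plus the excipient share sum to 1; excipient mass equals
    addition_rate minus the fortificant mass subtotal; the base price is
    the sum of nutrient contributions, the excipient share cost and the
    up-charge.
    """

    nutrients: tuple[NutrientLine, ...]
    nutrient_mass_subtotal: float  # mg/kg vehicle
    addition_rate: float  # mg premix per kg vehicle
    excipient_mass: float  # mg/kg vehicle
    excipient_price: float  # USD/kg
    upcharge: float  # USD per kg premix
    base_price_per_kg: float  # USD per kg premix

    @property
    def excipient_proportion(self) -> float:
        return self.excipient_mass / self.addition_rate

    @property
    def kg_premix_per_mt_vehicle(self) -> float:
        return self.addition_rate * MG_PER_KG_TO_KG_PER_MT


def level_from_nrv(
    nrv_amount: float, fraction: float, serving: float, conversion_factor: float = 1.0
) -> float:
    """Fortification level (mg/kg vehicle) delivering ``fraction`` of a
    nutrient reference value in one ``serving`` (g) of the vehicle.

    ``conversion_factor`` handles unit conventions (e.g. folic acid
    equivalents) and is deliberately explicit rather than looked up.
    """
    if serving <= 0:
        raise ValueError("serving size must be positive")
    if min(nrv_amount, fraction, conversion_factor) < 0:
        raise ValueError("inputs must be non-negative")
    return nrv_amount * fraction * conversion_factor / serving * 1000.0


def fortificant_amount(spec: NutrientSpec) -> float:
    """mg of fortificant compound per kg of vehicle for one nutrient line.

    The target level is grossed up by the overage (degradation allowance)
    and divided by the compound's activity (micronutrient mass fraction).
    """
    if spec.activity <= 0:
        raise ValueError(f"{spec.name}: activity must be positive")
    return spec.target_level * (1.0 + spec.overage_fraction) / spec.activity


def suggest_addition_rate(nutrient_mass_subtotal: float, granularity: float = 250.0) -> float:
    """Smallest multiple of ``granularity`` >= 110% of the fortificant subtotal.

    Advisory only: the addition rate actually used is always an explicit
    scenario input.
    """
    if nutrient_mass_subtotal <= 0:
        raise ValueError("subtotal must be positive")
    return granularity * math.ceil(1.10 * nutrient_mass_subtotal / granularity)


def build_formulation(
    nutrients: list[NutrientSpec],
    addition_rate: float,
    excipient_price: float = 0.0,
    upcharge_per_kg: float = 0.0,
) -> PremixFormulation:
    """Assemble and price a premix formulation.

    Each nutrient occupies ``fortificant_amount / addition_rate`` of the
    premix mass and contributes that proportion times its price to the
    per-kg cost; the excipient fills the remaining mass at its own price;
    the blender's up-charge is added per kg of finished premix.
    """
    amounts = [fortificant_amount(spec) for spec in nutrients]
    subtotal = sum(amounts)
    if addition_rate < subtotal:
        raise FormulationError(
            f"addition rate {addition_rate} mg/kg below fortificant subtotal {subtotal} mg/kg"
        )
    lines = tuple(
        NutrientLine(
            spec=spec,
            fortificant_amount=amt,
            proportion=amt / addition_rate,
            cost_contribution=amt / addition_rate * spec.price,
        )
        for spec, amt in zip(nutrients, amounts)
    )
    excipient_mass = addition_rate - subtotal
    base = (
        sum(line.cost_contribution for line in lines)
        + excipient_mass / addition_rate * excipient_price
        + upcharge_per_kg
    )
    return PremixFormulation(
        nutrients=lines,
        nutrient_mass_subtotal=subtotal,
        addition_rate=addition_rate,
        excipient_mass=excipient_mass,
        excipient_price=excipient_price,
        upcharge=upcharge_per_kg,
        base_price_per_kg=base,
    )


def formulation_from_spec(spec: PremixSpec) -> PremixFormulation:
    """Build the formulation described by a scenario's premix block."""
    return build_formulation(
        spec.nutrients, spec.addition_rate, spec.excipient_price, spec.upcharge_per_kg
    )


def landed_price_per_kg(base: float, channel: PremixChannelParams) -> float:
    """Landed premix price: base price plus import duty plus transport.

    ``base * (1 + duty) + transport`` — the duty is ad valorem on the premix
    value, transport/distribution/storage is a flat per-kg adder.
    """
    if base < 0:
        raise ValueError("base price must be non-negative")
    return base * (1.0 + channel.duty_fraction) + channel.transport_per_kg


def cost_per_mt_vehicle(landed: float, addition_rate: float) -> float:
    """Premix cost per MT of fortified vehicle at the given addition rate."""
    if landed < 0 or addition_rate < 0:
        raise ValueError("inputs must be non-negative")
    return landed * addition_rate * MG_PER_KG_TO_KG_PER_MT
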