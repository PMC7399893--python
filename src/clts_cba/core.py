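"""End-to-end scenario runs: NPV, benefit-cost ratio, per-unit metrics.

The base case holds intervention effects constant over the horizon. The
slippage scenario decays all three benefit quantities (cases averted, costs
averted, time savings) by a constant annual rate, leaving sunk costs and
O&M/education unchanged. The population-growth scenario compounds the
population from year 1. The caregiver-costs scenario swaps in an alternative
care-seeking cost overlay (e.g. caregiver-reported rather than official
charges).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .benefits import BenefitBreakdown, total_benefits_pv
from .costs import CostSummary, total_costs_pv
from .parameters import CareSeekingParams, EconParams, ParameterSet

SCENARIO_NAMES = ("base", "slippage", "population_growth", "caregiver_costs")


class ScenarioError(ValueError):
    pass


@dataclass
class Scenario:
    name: str = "base"
    slippage_rate: float = 0.035
    pop_growth_rate: float = 0.025
    alt_care_costs: CareSeekingParams | None = None

    def validate(self) -> list[str]:
        errs = []
        if self.name not in SCENARIO_NAMES:
            errs.append(f"scenario.name: unknown scenario '{self.name}'")
        for nm in ("slippage_rate", "pop_growth_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v < 1.0:
                errs.append(f"scenario.{nm}: rate out of [0,1)")
        if self.name == "caregiver_costs" and self.alt_care_costs is None:
            errs.append("scenario caregiver_costs requires alt_care_costs")
        return errs


@dataclass
class CBAResult:
    """Full output of one scenario run."""

    scenario: str
    benefits: BenefitBreakdown
    costs: CostSummary
    npv: float
    bcr: float
    npv_per_household: float
    npv_per_community: float

    def to_dict(self) -> dict:
        from .parameters import BANDS

        return {
            "scenario": self.scenario,
            "benefits": {
                item: {b.value: self.benefits.cells[item][b] for b in BANDS}
                for item in self.benefits.cells
            },
            "benefits_total": self.benefits.grand_total,
            "costs": self.costs.to_dict(),
            "npv": self.npv,
            "bcr": self.bcr,
            "npv_per_household": self.npv_per_household,
            "npv_per_community": self.npv_per_community,
        }


def npv_bcr(benefits: float, costs: float) -> tuple[float, float]:
    """Net present value and benefit-cost ratio."""
    if costs <= 0:
        raise ScenarioError("BCR undefined: total costs must be > 0")
    return benefits - costs, benefits / costs


def per_unit_metrics(npv: float, econ: EconParams) -> tuple[float, float]:
    """NPV per household and per community."""
    if econ.households <= 0 or econ.communities <= 0:
        raise ScenarioError("per-unit metrics need positive denominators")
    return npv / econ.households, npv / econ.communities


def run_scenario(p: ParameterSet, scenario: Scenario | None = None) -> CBAResult:
    """Run one scenario end-to-end and assemble the result panel."""
    scenario = scenario or Scenario()
    errs = scenario.validate()
    if errs:
        raise ScenarioError("; ".join(errs))
    p.require_valid()

    T = p.econ.horizon_years
    t = np.arange(1, T + 1)
    quantity_mult = None
    population_mult = None
    if scenario.name == "slippage":
        # decay indexed by t like all other year-t dynamics (end-of-year flows)
        quantity_mult = (1.0 - scenario.slippage_rate) ** t
    elif scenario.name == "population_growth":
        population_mult = (1.0 + scenario.pop_growth_rate) ** t
    elif scenario.name == "caregiver_costs":
        p = copy.deepcopy(p)
        p.care = scenario.alt_care_costs
        p.require_valid()

    benefits = total_benefits_pv(p, quantity_mult, population_mult)
    costs = total_costs_pv(p)
    npv, bcr = npv_bcr(benefits.grand_total, costs.total_pv)
    per_hh, per_comm = per_unit_metrics(npv, p.econ)
    return CBAResult(
        scenario=scenario.name,
        benefits=benefits,
        costs=costs,
        npv=npv,
        bcr=bcr,
        npv_per_household=per_hh,
        npv_per_community=per_comm,
    )
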