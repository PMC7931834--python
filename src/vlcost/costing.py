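"""Component costing and cost ratios for one scenario.

Annual system cost is the sum of four components: testing on dried
specimens, testing on plasma, facility visits for results (one visit per
test performed), and the scenario's transport-network cost. Ratios divide
the system cost by patients accessing (cost per patient with a VL result)
and by patients correctly classified (cost per correct result).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .access import AccessResult
from .parameters import Specimen, SpecimenUnitCost, ScenarioSpec
from .testing import CorrectResults, TestVolumes


@dataclass(frozen=True)
class CostBreakdown:
    """Annual USD cost components; the system total is their exact sum."""

    dried_testing: float
    plasma_testing: float
    facility_visits: float
    transport: float

    @property
    def system_total(self) -> float:
        return self.dried_testing + self.plasma_testing + self.facility_visits + self.transport


@dataclass(frozen=True)
class ScenarioOutcome:
    """Everything the model computes for one scenario (one report column)."""

    spec: ScenarioSpec
    access: AccessResult
    volumes: TestVolumes
    correct: CorrectResults
    costs: CostBreakdown
    visit_count: int
    access_reported: int  # patient count as reported (rounded or pinned)
    correct_reported: int

    @property
    def cost_per_result(self) -> float:
        return self.costs.system_total / self.access_reported

    @property
    def cost_per_correct(self) -> float:
        return self.costs.system_total / self.correct_reported

    @property
    def name(self) -> str:
        return self.spec.name


def unit_test_cost(specimen: Specimen, unit_costs: Mapping[Specimen, SpecimenUnitCost]) -> float:
    """All-inclusive USD cost of one VL test on the given specimen."""
    try:
        uc = unit_costs[specimen]
    except KeyError as exc:
        raise KeyError(f"no unit cost registered for specimen {specimen.value}") from exc
    return uc.total


def scenario_costs(
    volumes: TestVolumes,
    unit_costs: Mapping[Specimen, SpecimenUnitCost],
    visit_cost: float,
    transport: float,
) -> CostBreakdown:
    """Component costs from test volumes and unit prices.

    Testing components multiply per-specimen test counts by the specimen's
    total unit cost; visits are costed at one per test performed;
    transport is the scenario's annual network cost, passed through.
    """
    dried = 0.0
    plasma = 0.0
    for specimen, vol in volumes.by_specimen.items():
        cost = vol.total * unit_test_cost(specimen, unit_costs)
        if specimen is Specimen.PLASMA:
            plasma += cost
        else:
            dried += cost
    visits = volumes.total_tests * visit_cost
    return CostBreakdown(dried, plasma, visits, transport)


def cost_ratios(costs: CostBreakdown, access: float, correct: float) -> tuple[float, float]:
    """(cost per patient with a VL result, cost per correct result)."""
    if access <= 0 or correct <= 0:
        raise ValueError("access and correct counts must be positive for cost ratios")
    return costs.system_total / access, costs.system_total / correct
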