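"""The scale-up model: fit a facility panel + parameter set, get results.

:class:`ViralLoadScaleUpModel` couples a facility panel (real or
synthetic) with a :class:`~vlcost.parameters.ModelConfig` and, on
``fit()``, runs the full pipeline for every scenario — access, effective
assay performance, repeat-test volumes, correct results, component costs —
and the incremental cost-effectiveness analysis across scenarios,
returning a :class:`ScaleUpResults`.

Two run modes exist:

* ``model`` (default) — every quantity is computed from primitives.
* ``golden`` — patient/test counts and visit/transport component costs
  are pinned to the published reference figures carried in the config,
  and only unit-cost arithmetic is recomputed. This insulates
  ratio-identity checks (and kit-price threshold analysis) from the
  small residuals of the correct-result formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import pandas as pd

from . import access as access_mod
from .cea import CEATable, incremental_analysis
from .costing import CostBreakdown, ScenarioOutcome, scenario_costs
from .network import FacilityPanel, calibrated_zambia_panel
from .parameters import (
    DRIED_SPECIMENS,
    AssayPerformance,
    ModelConfig,
    Platform,
    ScenarioSpec,
    Specimen,
    default_config,
)
from .testing import (
    SpecimenVolume,
    TestVolumes,
    calibrate_failure_prevalence,
    correct_results,
    effective_performance,
    positivity_rate,
    test_volumes,
)

MODES = ("model", "golden")


class ViralLoadScaleUpModel:
    """Cost-and-impact model of national viral-load testing scale-up.

    Parameters
    ----------
    panel : FacilityPanel
        Facilities with ART cohort sizes, volume stratum and plasma
        reachability; typically the output of a geospatial transport
        model, or a synthetic panel from :mod:`vlcost.network`.
    config : ModelConfig
        Assay performance, unit costs, access multipliers, epidemiology
        and scenario definitions.
    """

    def __init__(self, panel: FacilityPanel, config: ModelConfig):
        self.panel = panel
        self.config = config

    # -- constructors --------------------------------------------------

    @classmethod
    def from_config(cls, config: ModelConfig | None = None, seed: int | None = None) -> "ViralLoadScaleUpModel":
        """Build from a config alone, generating the calibrated Zambia panel."""
        config = config or default_config()
        seed = config.seed if seed is None else seed
        panel = calibrated_zambia_panel(seed=seed)
        if not panel.transport_cost_by_scenario:
            panel.transport_cost_by_scenario = dict(
                config.visit_transport.transport_cost_by_scenario
            )
        return cls(panel, config)

    @classmethod
    def from_dataframe(
        cls,
        facilities: pd.DataFrame,
        config: ModelConfig,
        transport_cost_by_scenario: Mapping[str, float] | None = None,
    ) -> "ViralLoadScaleUpModel":
        """Build from a facility table (columns id, stratum, plasma_reachable, art_patients)."""
        panel = FacilityPanel.from_frame(
            facilities,
            transport_cost_by_scenario or config.visit_transport.transport_cost_by_scenario,
        )
        return cls(panel, config)

    def with_config(self, config: ModelConfig) -> "ViralLoadScaleUpModel":
        """Same panel, different parameters (used by sensitivity sweeps)."""
        return ViralLoadScaleUpModel(self.panel, config)

    # -- pieces --------------------------------------------------------

    def failure_prevalence(self) -> float:
        """The failure prevalence p: configured value or calibrated."""
        epi = self.config.epi
        if epi.failure_prevalence is not None:
            return epi.failure_prevalence
        cal = epi.calibration
        if cal is None:
            raise ValueError("epi.failure_prevalence unset and no calibration block given")
        perf = self.config.assay(cal.specimen, cal.platform)
        return calibrate_failure_prevalence(cal.observed_tests, cal.observed_patients, perf)

    def scenario_performance(self, spec: ScenarioSpec) -> dict[Specimen, AssayPerformance]:
        """Effective assay performance per specimen used by a scenario.

        Plasma always runs on CAP/CTM; dried specimens are mixed over the
        scenario's platform shares.
        """
        out: dict[Specimen, AssayPerformance] = {}
        for specimen in {spec.specimen_high, spec.specimen_low}:
            if specimen in DRIED_SPECIMENS:
                components = [
                    (w, self.config.assay(specimen, platform))
                    for platform, w in spec.platform_mix.items()
                ]
                out[specimen] = effective_performance(components)
            else:
                out[specimen] = self.config.assay(specimen, Platform.CAPCTM)
        return out

    def _transport(self, spec: ScenarioSpec) -> float:
        costs = self.panel.transport_cost_by_scenario or self.config.visit_transport.transport_cost_by_scenario
        key = spec.transport_key or spec.name
        try:
            return float(costs[key])
        except KeyError as exc:
            raise KeyError(f"no transport cost for scenario key {key!r}") from exc

    def _fit_scenario(self, spec: ScenarioSpec, p: float, mode: str) -> ScenarioOutcome:
        cfg = self.config
        acc = access_mod.annual_access(self.panel, spec, cfg.multipliers)
        perf = self.scenario_performance(spec)
        q = {s: positivity_rate(p, pf) for s, pf in perf.items()}
        volumes = test_volumes(acc, q)
        correct = correct_results(acc, perf, p, model=cfg.epi.correctness_model)
        unit_costs = {u.specimen: u for u in cfg.unit_costs}

        if mode == "model":
            costs = scenario_costs(
                volumes, unit_costs, cfg.visit_transport.visit_cost, self._transport(spec)
            )
            return ScenarioOutcome(
                spec=spec,
                access=acc,
                volumes=volumes,
                correct=correct,
                costs=costs,
                visit_count=volumes.total_tests,
                access_reported=acc.total_patients_rounded,
                correct_reported=correct.correct_rounded,
            )

        # golden: counts pinned to the published table, unit costs live
        try:
            row = cfg.golden[spec.name]
        except KeyError as exc:
            raise KeyError(
                f"golden mode requested but config carries no printed row for {spec.name!r}"
            ) from exc
        dried_specimen = spec.specimen_low if spec.specimen_low in DRIED_SPECIMENS else spec.specimen_high
        by_specimen: dict[Specimen, SpecimenVolume] = {}
        if row.plasma_tests:
            by_specimen[Specimen.PLASMA] = SpecimenVolume(row.plasma_tests, 0)
        if row.dried_tests:
            by_specimen[dried_specimen] = SpecimenVolume(row.dried_tests, 0)
        pinned_volumes = TestVolumes(by_specimen, q)
        dried_cost = sum(
            v.total * unit_costs[s].total for s, v in by_specimen.items() if s is not Specimen.PLASMA
        )
        plasma_cost = row.plasma_tests * unit_costs[Specimen.PLASMA].total if row.plasma_tests else 0.0
        costs = CostBreakdown(
            dried_testing=dried_cost,
            plasma_testing=plasma_cost,
            facility_visits=row.visit_cost,
            transport=row.transport_cost,
        )
        return ScenarioOutcome(
            spec=spec,
            access=acc,
            volumes=pinned_volumes,
            correct=correct,
            costs=costs,
            visit_count=row.visit_count,
            access_reported=row.access,
            correct_reported=row.correct,
        )

    # -- the fit -------------------------------------------------------

    def fit(self, mode: str = "model") -> "ScaleUpResults":
        """Run every scenario and the incremental analysis."""
        if mode not in MODES:
            raise ValueError(f"unknown run mode {mode!r}; expected one of {MODES}")
        p = self.failure_prevalence()
        outcomes: dict[str, ScenarioOutcome] = {}
        for spec in self.config.scenarios:
            try:
                outcomes[spec.name] = self._fit_scenario(spec, p, mode)
            except Exception as exc:
                raise RuntimeError(f"scenario {spec.name!r}: {exc}") from exc
        cea = incremental_analysis(list(outcomes.values())) if outcomes else None
        return ScaleUpResults(
            model=self,
            mode=mode,
            failure_prevalence=p,
            outcomes=outcomes,
            cea=cea,
        )


@dataclass
class ScaleUpResults:
    """Fitted results: per-scenario outcomes plus the CEA league table."""

    model: ViralLoadScaleUpModel
    mode: str
    failure_prevalence: float
    outcomes: dict[str, ScenarioOutcome]
    cea: CEATable | None

    def outcome(self, name: str) -> ScenarioOutcome:
        try:
            return self.outcomes[name]
        except KeyError as exc:
            raise KeyError(f"no scenario named {name!r} in results") from exc

    @property
    def scenario_names(self) -> list[str]:
        return list(self.outcomes)

    def metric(self, name: str, scenario: str) -> float:
        """Named scalar metric for one scenario (used by sensitivity sweeps)."""
        o = self.outcome(scenario)
        extractors: dict[str, Callable[[ScenarioOutcome], float]] = {
            "system_cost": lambda o: o.costs.system_total,
            "cost_per_result": lambda o: o.cost_per_result,
            "cost_per_correct": lambda o: o.cost_per_correct,
            "correct": lambda o: float(o.correct_reported),
            "access": lambda o: float(o.access_reported),
            "total_tests": lambda o: float(o.volumes.total_tests),
        }
        try:
            return extractors[name](o)
        except KeyError as exc:
            raise KeyError(
                f"unknown metric {name!r}; expected one of {sorted(extractors)}"
            ) from exc

    def access_increase_pct(self, base: str, alt: str) -> float:
        """Percentage access increase of scenario ``alt`` over ``base``."""
        return access_mod.access_increase(self.outcome(base).access, self.outcome(alt).access)

    def to_frame(self) -> pd.DataFrame:
        """One row per scenario with the headline quantities (unrounded)."""
        rows = []
        for name, o in self.outcomes.items():
            cea_row = self.cea.row(name) if self.cea is not None else None
            rows.append(
                {
                    "scenario": name,
                    "access": o.access_reported,
                    "facilities_reached": o.access.facilities_reached,
                    "correct_results": o.correct_reported,
                    "dried_tests": sum(
                        v.total for s, v in o.volumes.by_specimen.items() if s is not Specimen.PLASMA
                    ),
                    "plasma_tests": o.volumes.tests_for(Specimen.PLASMA),
                    "visit_count": o.visit_count,
                    "dried_testing_cost": o.costs.dried_testing,
                    "plasma_testing_cost": o.costs.plasma_testing,
                    "facility_visit_cost": o.costs.facility_visits,
                    "transport_cost": o.costs.transport,
                    "system_cost": o.costs.system_total,
                    "cost_per_result": o.cost_per_result,
                    "cost_per_correct": o.cost_per_correct,
                    "avg_cer_vs_base": cea_row.avg_cer_vs_base if cea_row else None,
                    "status": cea_row.status if cea_row else None,
                    "icer": cea_row.icer if cea_row else None,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report table (markdown)."""
        from .report import render_table

        return render_table(self, fmt="markdown")

    def save(self, out_dir, fmt: str = "csv", seed: int | None = None):
        from .report import save_results

        return save_results(self, out_dir, fmt=fmt, seed=seed)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ScaleUpResults mode={self.mode!r} scenarios={len(self.outcomes)} "
            f"p={self.failure_prevalence:.4f}>"
        )
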