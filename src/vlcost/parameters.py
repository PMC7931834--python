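"""Typed model inputs, configuration ingestion and validation.

All quantities the cost-and-impact model consumes are declared here:
assay performance (sensitivity/specificity at the 1000 copies/mL
virological-failure threshold, with uncertainty bounds), per-test unit
costs split into collection consumables / collection overhead / laboratory
analysis, facility-access multipliers, epidemiological parameters, visit
and transport costs, and the scenario definitions that assign a specimen
type to each facility stratum.

Money is carried as floats in USD; fractional cents are kept throughout
and rounded only when a report is rendered (two decimals for ratios,
integers for totals).
"""

from __future__ import annotations

import copy
import io
import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml


class Specimen(str, Enum):
    """Specimen type used for viral-load sample collection."""

    PLASMA = "plasma"
    DBS = "dbs"  # dried blood spot
    PSC = "psc"  # plasma separation card (dried plasma spot)


class Platform(str, Enum):
    """Centralised laboratory testing platform."""

    CAPCTM = "capctm"  # Roche Cobas Ampliprep / Cobas TaqMan
    COBAS8800 = "cobas8800"


#: Specimen types that travel dry (no cold chain).
DRIED_SPECIMENS = frozenset({Specimen.DBS, Specimen.PSC})


class ConfigError(ValueError):
    """Raised when a configuration fails validation; carries the findings."""

    def __init__(self, findings: Sequence[str]):
        self.findings = list(findings)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.findings))


def _check_proportion(findings: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        findings.append(f"{name} = {value!r} is not a proportion in [0, 1]")


def _check_nonneg(findings: list[str], name: str, value: float) -> None:
    if value < 0:
        findings.append(f"{name} = {value!r} is negative")


@dataclass(frozen=True)
class AssayPerformance:
    """Sensitivity and specificity of a specimen-platform pair.

    Point estimates plus low/high bounds; bounds are used only by the
    sensitivity-analysis module.
    """

    specimen: Specimen
    platform: Platform
    sensitivity: float
    specificity: float
    sens_low: float = None  # type: ignore[assignment]
    sens_high: float = None  # type: ignore[assignment]
    spec_low: float = None  # type: ignore[assignment]
    spec_high: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        # default bounds collapse onto the point estimate
        for bound, point in (
            ("sens_low", "sensitivity"),
            ("sens_high", "sensitivity"),
            ("spec_low", "specificity"),
            ("spec_high", "specificity"),
        ):
            if getattr(self, bound) is None:
                object.__setattr__(self, bound, getattr(self, point))

    def findings(self, prefix: str = "") -> list[str]:
        out: list[str] = []
        for name in ("sensitivity", "specificity", "sens_low", "sens_high", "spec_low", "spec_high"):
            _check_proportion(out, prefix + name, getattr(self, name))
        if not (self.sens_low <= self.sensitivity <= self.sens_high):
            out.append(
                f"{prefix}sensitivity bounds violated: "
                f"{self.sens_low} <= {self.sensitivity} <= {self.sens_high} is false"
            )
        if not (self.spec_low <= self.specificity <= self.spec_high):
            out.append(
                f"{prefix}specificity bounds violated: "
                f"{self.spec_low} <= {self.specificity} <= {self.spec_high} is false"
            )
        return out


@dataclass(frozen=True)
class SpecimenUnitCost:
    """Per-test cost components (USD) for one specimen type.

    ``consumables`` is the collection kit, ``collection_overhead`` covers
    staff/equipment/overhead at the facility, ``lab_analysis`` is the
    all-inclusive centralised laboratory cost on the Roche platform.
    """

    specimen: Specimen
    consumables: float
    collection_overhead: float
    lab_analysis: float

    @property
    def total(self) -> float:
        return self.consumables + self.collection_overhead + self.lab_analysis

    def findings(self, prefix: str = "") -> list[str]:
        out: list[str] = []
        for name in ("consumables", "collection_overhead", "lab_analysis"):
            _check_nonneg(out, prefix + name, getattr(self, name))
        return out


@dataclass(frozen=True)
class AccessMultipliers:
    """Annual fraction of ART patients reaching a usable VL test, by stratum.

    High-volume facilities sit on daily plasma transport routes and retain
    80% access regardless of specimen. Low-volume facilities reach only
    40% of patients with plasma (weekly pickup, cold-chain losses) but 80%
    with dried specimens; facilities unreachable for plasma transport get
    80% access once dried specimens are adopted.
    """

    high_volume: float = 0.80
    low_volume_plasma: float = 0.40
    low_volume_dried: float = 0.80
    unreachable_dried: float = 0.80

    def findings(self, prefix: str = "") -> list[str]:
        out: list[str] = []
        for name in ("high_volume", "low_volume_plasma", "low_volume_dried", "unreachable_dried"):
            _check_proportion(out, prefix + name, getattr(self, name))
        return out


@dataclass(frozen=True)
class PrevalenceCalibration:
    """Observed testing-cascade marginals used to back out failure prevalence.

    When ``EpidemiologyParams.failure_prevalence`` is not given, the model
    inverts the positivity equation against these observed plasma volumes.
    """

    observed_tests: float
    observed_patients: float
    specimen: Specimen = Specimen.PLASMA
    platform: Platform = Platform.CAPCTM


@dataclass(frozen=True)
class EpidemiologyParams:
    """True virological-failure prevalence and correct-result accounting model.

    ``failure_prevalence`` may be None, in which case it is calibrated at
    fit time from ``calibration``. ``correctness_model`` chooses how a
    "correct result" is counted: ``product`` (Se*Sp per patient) or
    ``prevalence_weighted`` (p*Se + (1-p)*Sp).
    """

    failure_prevalence: float | None = None
    correctness_model: str = "product"
    calibration: PrevalenceCalibration | None = None

    def findings(self, prefix: str = "") -> list[str]:
        out: list[str] = []
        if self.failure_prevalence is not None:
            _check_proportion(out, prefix + "failure_prevalence", self.failure_prevalence)
        elif self.calibration is None:
            out.append(prefix + "failure_prevalence is unset and no calibration block is given")
        if self.correctness_model not in ("product", "prevalence_weighted"):
            out.append(f"{prefix}correctness_model = {self.correctness_model!r} unknown")
        return out


@dataclass(frozen=True)
class VisitAndTransportCosts:
    """Cost of a results visit and annual transport-network cost per scenario key."""

    visit_cost: float = 3.65
    transport_cost_by_scenario: Mapping[str, float] = field(default_factory=dict)

    def findings(self, prefix: str = "") -> list[str]:
        out: list[str] = []
        _check_nonneg(out, prefix + "visit_cost", self.visit_cost)
        for key, value in self.transport_cost_by_scenario.items():
            _check_nonneg(out, f"{prefix}transport_cost_by_scenario[{key}]", value)
        return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Assignment of specimen types to facility strata for one scenario.

    ``platform_mix`` gives the share of dried-specimen volume analysed on
    each platform; plasma is always run on CAP/CTM. ``include_unreachable``
    opens facilities that plasma transport cannot serve; it must hold
    exactly when a dried specimen is used at low-volume sites.
    """

    name: str
    specimen_high: Specimen
    specimen_low: Specimen
    include_unreachable: bool
    platform_mix: Mapping[Platform, float] = field(default_factory=lambda: {Platform.CAPCTM: 1.0})
    transport_key: str = ""

    def findings(self, prefix: str = "") -> list[str]:
        out: list[str] = []
        total = 0.0
        for platform, weight in self.platform_mix.items():
            _check_nonneg(out, f"{prefix}platform_mix[{platform.value}]", weight)
            total += weight
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            out.append(f"{prefix}platform_mix weights sum to {total!r}, expected 1")
        dried_low = self.specimen_low in DRIED_SPECIMENS
        if self.include_unreachable != dried_low:
            out.append(
                f"{prefix}include_unreachable = {self.include_unreachable} but "
                f"specimen_low = {self.specimen_low.value}; unreachable facilities are "
                "served exactly when low-volume sites use a dried specimen"
            )
        return out


@dataclass(frozen=True)
class PrintedScenarioRow:
    """One reference-table column: published access/volume/cost figures.

    Used by the golden run mode, where counts are pinned to the published
    values and only unit-cost arithmetic is recomputed, insulating
    ratio-identity checks from the under-specified correct-result formula.
    """

    access: int
    facilities_reached: int
    correct: int
    dried_tests: int
    plasma_tests: int
    visit_count: int
    dried_cost: float
    plasma_cost: float
    visit_cost: float
    transport_cost: float
    system_cost: float


@dataclass
class ModelConfig:
    """Complete validated input set for the scale-up model."""

    assays: list[AssayPerformance]
    unit_costs: list[SpecimenUnitCost]
    multipliers: AccessMultipliers
    epi: EpidemiologyParams
    visit_transport: VisitAndTransportCosts
    scenarios: list[ScenarioSpec]
    seed: int = 0
    golden: dict[str, PrintedScenarioRow] = field(default_factory=dict)

    # -- lookups -------------------------------------------------------

    def assay(self, specimen: Specimen, platform: Platform) -> AssayPerformance:
        for a in self.assays:
            if a.specimen == specimen and a.platform == platform:
                return a
        raise KeyError(f"no assay entry for {specimen.value} on {platform.value}")

    def unit_cost(self, specimen: Specimen) -> SpecimenUnitCost:
        for u in self.unit_costs:
            if u.specimen == specimen:
                return u
        raise KeyError(f"no unit cost entry for specimen {specimen.value}")

    def scenario(self, name: str) -> ScenarioSpec:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise KeyError(f"no scenario named {name!r}")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def enc(obj: Any) -> Any:
            if isinstance(obj, Enum):
                return obj.value
            if isinstance(obj, Mapping):
                return {enc(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        d = {
            "assays": [enc(asdict(a)) for a in self.assays],
            "unit_costs": [enc(asdict(u)) for u in self.unit_costs],
            "multipliers": asdict(self.multipliers),
            "epi": enc(asdict(self.epi)),
            "visit_transport": enc(asdict(self.visit_transport)),
            "scenarios": [enc(asdict(s)) for s in self.scenarios],
            "seed": self.seed,
        }
        if self.golden:
            d["golden"] = {name: asdict(row) for name, row in self.golden.items()}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))


# ---------------------------------------------------------------------------
# construction from plain dicts / YAML / CSV


def _config_from_dict(data: Mapping[str, Any], base_dir: Path | None = None) -> ModelConfig:
    try:
        assay_rows = data["assays"]
        cost_rows = data["unit_costs"]
    except KeyError as exc:
        raise ConfigError([f"missing required field {exc.args[0]!r}"]) from exc

    if isinstance(assay_rows, str):
        assay_rows = _read_csv_rows(assay_rows, base_dir)
    if isinstance(cost_rows, str):
        cost_rows = _read_csv_rows(cost_rows, base_dir)

    findings: list[str] = []

    def build(cls, row, **casts):
        kwargs = {}
        for key, value in dict(row).items():
            cast = casts.get(key)
            kwargs[key] = cast(value) if cast is not None and value is not None else value
        return cls(**kwargs)

    try:
        assays = [
            build(AssayPerformance, row, specimen=Specimen, platform=Platform)
            for row in assay_rows
        ]
        unit_costs = [build(SpecimenUnitCost, row, specimen=Specimen) for row in cost_rows]
        multipliers = AccessMultipliers(**data.get("multipliers", {}))
        epi_raw = dict(data.get("epi", {}))
        if epi_raw.get("calibration") is not None:
            epi_raw["calibration"] = build(
                PrevalenceCalibration, epi_raw["calibration"], specimen=Specimen, platform=Platform
            )
        epi = EpidemiologyParams(**epi_raw)
        vt_raw = dict(data.get("visit_transport", {}))
        visit_transport = VisitAndTransportCosts(**vt_raw)
        scenarios = []
        for row in data.get("scenarios", []):
            row = dict(row)
            row["specimen_high"] = Specimen(row["specimen_high"])
            row["specimen_low"] = Specimen(row["specimen_low"])
            row["platform_mix"] = {
                Platform(k): float(v) for k, v in row.get("platform_mix", {"capctm": 1.0}).items()
            }
            scenarios.append(ScenarioSpec(**row))
        golden = {
            name: PrintedScenarioRow(**row) for name, row in data.get("golden", {}).items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError([f"malformed configuration: {exc}"]) from exc

    cfg = ModelConfig(
        assays=assays,
        unit_costs=unit_costs,
        multipliers=multipliers,
        epi=epi,
        visit_transport=visit_transport,
        scenarios=scenarios,
        seed=int(data.get("seed", 0)),
        golden=golden,
    )
    findings = validate_config(cfg)
    if findings:
        raise ConfigError(findings)
    return cfg


def _read_csv_rows(name: str, base_dir: Path | None) -> list[dict[str, Any]]:
    path = Path(name)
    if base_dir is not None and not path.is_absolute():
        path = base_dir / path
    frame = pd.read_csv(path)
    return frame.to_dict(orient="records")


def load_config(source: str | Path | Mapping[str, Any]) -> ModelConfig:
    """Load and validate a model configuration.

    ``source`` may be a mapping, a path to a YAML/JSON document, or a YAML
    text blob. The document may reference sibling CSV tables for the
    ``assays`` and ``unit_costs`` sections by filename.

    Raises :class:`ConfigError` listing every violated invariant.
    """
    if isinstance(source, Mapping):
        return _config_from_dict(source)
    base_dir: Path | None = None
    text: str
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        path = Path(source)
        base_dir = path.parent
        text = path.read_text()
    else:
        text = str(source)
    data = yaml.safe_load(io.StringIO(text))
    if not isinstance(data, Mapping):
        raise ConfigError(["configuration document is not a mapping"])
    return _config_from_dict(data, base_dir=base_dir)


def validate_config(cfg: ModelConfig) -> list[str]:
    """Check every invariant; return one finding string per violation.

    An empty list means the configuration is valid. Findings name the
    offending field and its value; nothing is raised.
    """
    findings: list[str] = []
    for a in cfg.assays:
        findings.extend(a.findings(prefix=f"assays[{a.specimen.value}/{a.platform.value}]."))
    seen: set[Specimen] = set()
    for u in cfg.unit_costs:
        findings.extend(u.findings(prefix=f"unit_costs[{u.specimen.value}]."))
        if u.specimen in seen:
            findings.append(f"unit_costs has more than one entry for specimen {u.specimen.value}")
        seen.add(u.specimen)
    findings.extend(cfg.multipliers.findings(prefix="multipliers."))
    findings.extend(cfg.epi.findings(prefix="epi."))
    findings.extend(cfg.visit_transport.findings(prefix="visit_transport."))
    assay_specimens = {a.specimen for a in cfg.assays}
    names: set[str] = set()
    for s in cfg.scenarios:
        prefix = f"scenarios[{s.name}]."
        findings.extend(s.findings(prefix=prefix))
        if s.name in names:
            findings.append(f"duplicate scenario name {s.name!r}")
        names.add(s.name)
        for specimen in {s.specimen_high, s.specimen_low}:
            if specimen not in seen:
                findings.append(f"{prefix}specimen {specimen.value} has no unit cost entry")
            if specimen not in assay_specimens:
                findings.append(f"{prefix}specimen {specimen.value} has no assay entry")
        if s.transport_key and s.transport_key not in cfg.visit_transport.transport_cost_by_scenario:
            findings.append(
                f"{prefix}transport_key {s.transport_key!r} not in visit_transport.transport_cost_by_scenario"
            )
    return findings


def default_config() -> ModelConfig:
    """The packaged Zambia configuration (all published model inputs)."""
    path = Path(__file__).parent / "data" / "zambia.yaml"
    return load_config(path)
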