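"""Annual patient access to viral-load testing, per scenario.

Access is deterministic: each facility stratum contributes its ART cohort
scaled by a flat multiplier that depends on the specimen collected there.
High-volume sites keep 80% access with any specimen; low-volume sites
reach 40% of patients with plasma but 80% with dried specimens; facilities
unreachable for plasma transport contribute only in dried scenarios.

Stratum contributions are carried as reals and rounded (half away from
zero) only when counts are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._common import iround
from .network import HIGH_VOLUME, LOW_VOLUME, FacilityPanel
from .parameters import DRIED_SPECIMENS, AccessMultipliers, ScenarioSpec, Specimen

#: Stratum labels used as keys in access breakdowns.
STRATUM_HIGH = "high_volume"
STRATUM_LOW_REACHABLE = "low_volume_reachable"
STRATUM_LOW_UNREACHABLE = "low_volume_unreachable"


@dataclass(frozen=True)
class AccessResult:
    """Patients accessing VL testing annually, by stratum and specimen."""

    patients_by_stratum_and_specimen: Mapping[tuple[str, Specimen], float]
    facilities_reached: int

    @property
    def total_patients(self) -> float:
        return sum(self.patients_by_stratum_and_specimen.values())

    @property
    def total_patients_rounded(self) -> int:
        return iround(self.total_patients)

    def patients_by_specimen(self) -> dict[Specimen, float]:
        out: dict[Specimen, float] = {}
        for (_, specimen), n in self.patients_by_stratum_and_specimen.items():
            out[specimen] = out.get(specimen, 0.0) + n
        return out

    def patients_in_stratum(self, stratum: str) -> float:
        return sum(
            n for (s, _), n in self.patients_by_stratum_and_specimen.items() if s == stratum
        )

    def to_records(self, scenario: str = "") -> list[dict]:
        rows = []
        for (stratum, specimen), n in sorted(
            self.patients_by_stratum_and_specimen.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
        ):
            rows.append(
                {
                    "scenario": scenario,
                    "stratum": stratum,
                    "specimen": specimen.value,
                    "patients": n,
                }
            )
        return rows


def annual_access(
    panel: FacilityPanel, spec: ScenarioSpec, mult: AccessMultipliers
) -> AccessResult:
    """Patients accessing VL testing annually under one scenario.

    High-volume patients are scaled by ``mult.high_volume`` regardless of
    specimen; low-volume reachable patients by ``mult.low_volume_plasma``
    or ``mult.low_volume_dried`` depending on the scenario's low-volume
    specimen; unreachable patients enter only when the scenario serves
    them (dried specimens), scaled by ``mult.unreachable_dried``. A
    facility counts as reached when its stratum participates with a
    positive multiplier.
    """
    high = panel.subset(HIGH_VOLUME)
    low_reach = panel.subset(LOW_VOLUME, plasma_reachable=True)
    low_unreach = panel.subset(LOW_VOLUME, plasma_reachable=False)

    low_mult = (
        mult.low_volume_dried
        if spec.specimen_low in DRIED_SPECIMENS
        else mult.low_volume_plasma
    )

    cells: dict[tuple[str, Specimen], float] = {}
    facilities = 0

    def add(stratum: str, specimen: Specimen, fs, m: float) -> None:
        nonlocal facilities
        cells[(stratum, specimen)] = m * sum(f.art_patients for f in fs)
        if m > 0:
            facilities += len(fs)

    add(STRATUM_HIGH, spec.specimen_high, high, mult.high_volume)
    add(STRATUM_LOW_REACHABLE, spec.specimen_low, low_reach, low_mult)
    if spec.include_unreachable:
        add(STRATUM_LOW_UNREACHABLE, spec.specimen_low, low_unreach, mult.unreachable_dried)

    return AccessResult(cells, facilities)


def access_increase(base: AccessResult, alt: AccessResult) -> float:
    """Percentage increase in total access of ``alt`` over ``base``."""
    if base.total_patients <= 0:
        raise ValueError("base access is zero; relative increase undefined")
    return 100.0 * (alt.total_patients - base.total_patients) / base.total_patients
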