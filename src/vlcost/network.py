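"""Synthetic health-facility networks.

The access model only needs, per facility: its ART patient count, whether
it is a high-volume site (>= 10 anticipated VL specimens/day, served by
daily plasma transport) and whether plasma transport can reach it at all.
Real inputs of this shape come from a geospatial transport-optimisation
model; this module generates synthetic panels with the same schema, plus a
calibrated Zambia panel whose stratum totals reproduce the published
national access figures.

Facility-level patient counts are drawn from a rounded lognormal (ART
cohort sizes are strongly right-skewed) and then rescaled so each
stratum's total matches its requested total exactly; every published
outcome depends only on the stratum totals, so the within-stratum
allocation is free to vary with the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

HIGH_VOLUME = "high_volume"
LOW_VOLUME = "low_volume"

_PROVINCES = (
    "Central", "Copperbelt", "Eastern", "Luapula", "Lusaka",
    "Muchinga", "Northern", "North-Western", "Southern", "Western",
)

# Calibrated Zambia stratum patient totals. Derived by inverting the access
# multipliers against the published national marginals:
#   0.8 * H                       = 708,525   (high-volume access, partial scenarios)
#   0.8 * H + 0.4 * L_reach       = 814,066   (plasma-only access)
#   0.8 * (H + L_reach + L_unreach) = 965,587 (dried-scenario access)
ZAMBIA_HIGH_VOLUME_PATIENTS = 885_656
ZAMBIA_LOW_REACHABLE_PATIENTS = 263_853
ZAMBIA_LOW_UNREACHABLE_PATIENTS = 57_475

ZAMBIA_N_HIGH = 152
ZAMBIA_N_LOW_REACHABLE = 648
# 1,041 facilities reached with dried specimens minus 800 reached with plasma
ZAMBIA_N_LOW_UNREACHABLE = 241

ZAMBIA_TRANSPORT_COSTS = {
    "plasma_only": 3_264_509.0,
    "dried_partial": 3_637_168.0,
    "dried_full": 2_390_317.0,
}


@dataclass(frozen=True)
class Facility:
    """One health facility in the viral-load network."""

    id: str
    stratum: str  # high_volume | low_volume
    plasma_reachable: bool
    art_patients: int
    province: str = ""

    def __post_init__(self) -> None:
        if self.stratum not in (HIGH_VOLUME, LOW_VOLUME):
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.stratum == HIGH_VOLUME and not self.plasma_reachable:
            # high-volume sites sit on daily plasma routes by definition
            raise ValueError(f"facility {self.id}: high_volume implies plasma_reachable")
        if self.art_patients < 0:
            raise ValueError(f"facility {self.id}: negative art_patients")


@dataclass
class FacilityPanel:
    """A set of facilities plus scenario-keyed annual transport costs."""

    facilities: list[Facility]
    transport_cost_by_scenario: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.facilities]
        if len(set(ids)) != len(ids):
            raise ValueError("facility ids are not unique")

    def subset(self, stratum: str | None = None, plasma_reachable: bool | None = None) -> list[Facility]:
        out = self.facilities
        if stratum is not None:
            out = [f for f in out if f.stratum == stratum]
        if plasma_reachable is not None:
            out = [f for f in out if f.plasma_reachable == plasma_reachable]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [f.id for f in self.facilities],
                "stratum": [f.stratum for f in self.facilities],
                "plasma_reachable": [f.plasma_reachable for f in self.facilities],
                "art_patients": [f.art_patients for f in self.facilities],
                "province": [f.province for f in self.facilities],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, transport_cost_by_scenario: Mapping[str, float] | None = None
    ) -> "FacilityPanel":
        facilities = [
            Facility(
                id=str(row.id),
                stratum=str(row.stratum),
                plasma_reachable=bool(row.plasma_reachable),
                art_patients=int(row.art_patients),
                province=str(getattr(row, "province", "")),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(facilities, dict(transport_cost_by_scenario or {}))

    @classmethod
    def from_csv(
        cls, path: str | Path, transport_cost_by_scenario: Mapping[str, float] | None = None
    ) -> "FacilityPanel":
        return cls.from_frame(pd.read_csv(path), transport_cost_by_scenario)


@dataclass(frozen=True)
class PanelSummary:
    """Stratum patient totals and facility counts for a panel."""

    patients_high: int
    patients_low_reachable: int
    patients_low_unreachable: int
    n_high: int
    n_low_reachable: int
    n_low_unreachable: int

    @property
    def patients_total(self) -> int:
        return self.patients_high + self.patients_low_reachable + self.patients_low_unreachable

    @property
    def n_facilities(self) -> int:
        return self.n_high + self.n_low_reachable + self.n_low_unreachable


def _allocate(total: int, n: int, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` patients over ``n`` facilities, each >= 1, exactly.

    Lognormal weights give the right-skewed size distribution; integerising
    uses the largest-remainder method so the stratum total is hit exactly.
    """
    if n <= 0:
        raise ValueError("facility count must be positive")
    if total < n:
        raise ValueError(f"cannot place {total} patients in {n} facilities at >=1 each")
    weights = rng.lognormal(mean=0.0, sigma=dispersion, size=n)
    remaining = total - n
    raw = remaining * weights / weights.sum()
    base = np.floor(raw).astype(np.int64)
    shortfall = remaining - int(base.sum())
    # give the leftover units to the largest fractional remainders
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:shortfall]] += 1
    return base + 1


def generate_panel(
    n_high: int,
    n_low_reachable: int,
    n_low_unreachable: int,
    patient_totals: tuple[int, int, int],
    dispersion: float = 1.0,
    seed: int = 0,
    transport_cost_by_scenario: Mapping[str, float] | None = None,
) -> FacilityPanel:
    """Generate a synthetic facility panel with exact stratum totals.

    ``patient_totals`` gives (high-volume, low-volume reachable, low-volume
    unreachable) ART patient totals; each stratum's facility-level counts
    sum to its total exactly. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    h_tot, lr_tot, lu_tot = patient_totals
    groups = [
        ("HV", HIGH_VOLUME, True, n_high, h_tot),
        ("LVR", LOW_VOLUME, True, n_low_reachable, lr_tot),
        ("LVU", LOW_VOLUME, False, n_low_unreachable, lu_tot),
    ]
    facilities: list[Facility] = []
    for tag, stratum, reachable, n, total in groups:
        counts = _allocate(total, n, dispersion, rng)
        provinces = rng.choice(_PROVINCES, size=n)
        facilities.extend(
            Facility(
                id=f"{tag}-{i:04d}",
                stratum=stratum,
                plasma_reachable=reachable,
                art_patients=int(c),
                province=str(p),
            )
            for i, (c, p) in enumerate(zip(counts, provinces))
        )
    return FacilityPanel(facilities, dict(transport_cost_by_scenario or {}))


def calibrated_zambia_panel(seed: int = 0, dispersion: float = 1.0) -> FacilityPanel:
    """The calibrated Zambia panel.

    Stratum totals are fixed to the values derived from the published
    national access marginals (see module constants); 152 high-volume and
    648 low-volume facilities are plasma-reachable, and 241 further
    low-volume facilities are reachable only with dried specimens, so the
    reached-facility counts are 800 (plasma) and 1,041 (dried). Transport
    costs carry the published per-scenario network costs.
    """
    return generate_panel(
        ZAMBIA_N_HIGH,
        ZAMBIA_N_LOW_REACHABLE,
        ZAMBIA_N_LOW_UNREACHABLE,
        (
            ZAMBIA_HIGH_VOLUME_PATIENTS,
            ZAMBIA_LOW_REACHABLE_PATIENTS,
            ZAMBIA_LOW_UNREACHABLE_PATIENTS,
        ),
        dispersion=dispersion,
        seed=seed,
        transport_cost_by_scenario=dict(ZAMBIA_TRANSPORT_COSTS),
    )


def summarize_panel(panel: FacilityPanel) -> PanelSummary:
    """Stratum totals and facility counts (sums over facilities)."""
    def agg(fs: Sequence[Facility]) -> tuple[int, int]:
        return sum(f.art_patients for f in fs), len(fs)

    ph, nh = agg(panel.subset(HIGH_VOLUME))
    plr, nlr = agg(panel.subset(LOW_VOLUME, plasma_reachable=True))
    plu, nlu = agg(panel.subset(LOW_VOLUME, plasma_reachable=False))
    return PanelSummary(ph, plr, plu, nh, nlr, nlu)
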