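"""The testing cascade: platform mixes, repeat volumes, correct results.

Every patient with a positive (>1000 copies/mL) initial result receives
one confirmatory repeat test, so test volume exceeds patient volume by the
screen-positivity rate

    q = p * Se + (1 - p) * (1 - Sp),

where p is the true prevalence of virological failure among tested
patients and (Se, Sp) the effective assay performance of the scenario's
specimen/platform mix. Inverting this relation against an observed
tests-per-patient ratio recovers p (``calibrate_failure_prevalence``).

Two accountings of a "correct result" are provided:

* ``product`` — a patient is correct when neither error occurs,
  N * Se * Sp; reproduces the published plasma-only count to 0.02% and is
  the default for reference-table comparisons.
* ``prevalence_weighted`` — the textbook expected accuracy
  N * (p * Se + (1 - p) * Sp), the default for prospective analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from ._common import iround
from .access import AccessResult
from .parameters import AssayPerformance, Specimen


@dataclass(frozen=True)
class SpecimenVolume:
    """Initial and confirmatory test counts for one specimen type."""

    initial: int
    confirmatory: int

    @property
    def total(self) -> int:
        return self.initial + self.confirmatory


@dataclass(frozen=True)
class TestVolumes:
    """Annual test volumes by specimen, with the positivity rate used."""

    by_specimen: Mapping[Specimen, SpecimenVolume]
    positivity_by_specimen: Mapping[Specimen, float]

    @property
    def total_tests(self) -> int:
        return sum(v.total for v in self.by_specimen.values())

    @property
    def initial_tests(self) -> int:
        return sum(v.initial for v in self.by_specimen.values())

    @property
    def confirmatory_tests(self) -> int:
        return sum(v.confirmatory for v in self.by_specimen.values())

    def tests_for(self, specimen: Specimen) -> int:
        vol = self.by_specimen.get(specimen)
        return vol.total if vol is not None else 0


@dataclass(frozen=True)
class CorrectResults:
    """Expected number of patients whose final VL classification is right."""

    correct: float
    by_cell: Mapping[tuple[str, Specimen], float]
    model_used: str

    @property
    def correct_rounded(self) -> int:
        return iround(self.correct)


def effective_performance(
    components: Iterable[tuple[float, AssayPerformance]]
) -> AssayPerformance:
    """Volume-weighted assay performance over a platform mix.

    All components must test the same specimen; weights must be
    non-negative and sum to one (tolerance 1e-9). Sensitivity,
    specificity and their bounds are weight-averaged.
    """
    components = list(components)
    if not components:
        raise ValueError("no components given")
    total = sum(w for w, _ in components)
    if any(w < 0 for w, _ in components) or abs(total - 1.0) > 1e-9:
        raise ValueError(f"platform-mix weights must be >=0 and sum to 1, got sum {total!r}")
    specimens = {perf.specimen for _, perf in components}
    if len(specimens) != 1:
        raise ValueError(f"mixed specimens in one platform mix: {sorted(s.value for s in specimens)}")

    def avg(attr: str) -> float:
        return sum(w * getattr(perf, attr) for w, perf in components)

    return AssayPerformance(
        specimen=components[0][1].specimen,
        platform=components[0][1].platform,  # representative; mix spans platforms
        sensitivity=avg("sensitivity"),
        specificity=avg("specificity"),
        sens_low=avg("sens_low"),
        sens_high=avg("sens_high"),
        spec_low=avg("spec_low"),
        spec_high=avg("spec_high"),
    )


def positivity_rate(p: float, perf: AssayPerformance) -> float:
    """Screen-positivity rate q = p*Se + (1-p)*(1-Sp)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence p = {p!r} outside [0, 1]")
    return p * perf.sensitivity + (1.0 - p) * (1.0 - perf.specificity)


def calibrate_failure_prevalence(
    observed_tests: float, patients: float, perf: AssayPerformance
) -> float:
    """Recover failure prevalence p from an observed tests-per-patient ratio.

    With one confirmatory test per screen positive, tests/patients = 1 + q;
    inverting q = p*Se + (1-p)*(1-Sp) gives

        p = (tests/patients - 1 - (1 - Sp)) / (Se - (1 - Sp)).

    Requires an informative assay (Se + Sp > 1). The result is clipped to
    [0, 1] with a warning if the observed ratio is inconsistent with the
    assay's attainable positivity range.
    """
    if perf.sensitivity + perf.specificity <= 1.0:
        raise ValueError(
            "assay is non-informative (Se + Sp <= 1); prevalence is not identifiable"
        )
    if observed_tests < patients:
        raise ValueError("observed tests fewer than patients; cascade assumes >=1 test each")
    q = observed_tests / patients - 1.0
    p = (q - (1.0 - perf.specificity)) / (perf.sensitivity - (1.0 - perf.specificity))
    if p < 0.0 or p > 1.0:
        if min(abs(p), abs(p - 1.0)) > 1e-9:  # more than float noise
            warnings.warn(
                f"calibrated prevalence {p:.4f} outside [0, 1]; clipping", stacklevel=2
            )
        p = min(1.0, max(0.0, p))
    return p


def test_volumes(access: AccessResult, q_by_specimen: Mapping[Specimen, float]) -> TestVolumes:
    """Annual test volumes: one initial test per patient plus one repeat per positive.

    Per specimen, the initial volume is the (real-valued) patient count
    accessing with that specimen and the confirmatory volume is initial*q;
    both are rounded half away from zero per specimen cell.
    """
    by_specimen: dict[Specimen, SpecimenVolume] = {}
    for specimen, patients in access.patients_by_specimen().items():
        q = q_by_specimen[specimen]
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"positivity q = {q!r} for {specimen.value} outside [0, 1]")
        by_specimen[specimen] = SpecimenVolume(
            initial=iround(patients), confirmatory=iround(patients * q)
        )
    return TestVolumes(by_specimen, dict(q_by_specimen))


def correct_results(
    access: AccessResult,
    perf_by_specimen: Mapping[Specimen, AssayPerformance],
    p: float,
    model: str = "product",
) -> CorrectResults:
    """Expected patients with a correct final VL classification.

    ``model='product'`` counts N*Se*Sp per cell; ``'prevalence_weighted'``
    counts N*(p*Se + (1-p)*Sp). Summed over (stratum, specimen) cells.
    """
    if model not in ("product", "prevalence_weighted"):
        raise ValueError(f"unknown correctness model {model!r}")
    by_cell: dict[tuple[str, Specimen], float] = {}
    for (stratum, specimen), n in access.patients_by_stratum_and_specimen.items():
        perf = perf_by_specimen[specimen]
        if model == "product":
            frac = perf.sensitivity * perf.specificity
        else:
            frac = p * perf.sensitivity + (1.0 - p) * perf.specificity
        by_cell[(stratum, specimen)] = n * frac
    return CorrectResults(sum(by_cell.values()), by_cell, model)
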