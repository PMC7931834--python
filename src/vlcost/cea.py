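"""Average and incremental cost-effectiveness with dominance classification.

The effect axis here is "patients with a correct VL result", but the
league-table machinery is generic over any scalar effect. Conventions
follow standard health-economics practice:

* strictly *dominated* — some other option attains at least the effect at
  no more cost, with at least one strict inequality;
* *weakly dominated* (extended dominance) — eliminated because its ICER
  against the previous frontier option exceeds the ICER of the next more
  effective option, i.e. a mixture of neighbours is more efficient;
* ICERs are then computed along the remaining efficient frontier, each
  option against the next least effective undominated one.

Post-elimination, frontier ICERs are non-decreasing in effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .costing import ScenarioOutcome

UNDOMINATED = "undominated"
DOMINATED = "dominated"
WEAKLY_DOMINATED = "weakly_dominated"

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CEARow:
    """One league-table row (ordered by effect)."""

    name: str
    cost: float
    effect: float
    avg_cer_vs_base: float | None
    status: str
    icer: float | None


@dataclass(frozen=True)
class CEATable:
    """League table over scenarios, ordered by increasing effect."""

    rows: tuple[CEARow, ...]
    base_name: str

    def row(self, name: str) -> CEARow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(f"no CEA row named {name!r}")

    def frontier(self) -> list[CEARow]:
        return [r for r in self.rows if r.status == UNDOMINATED]


def average_cer(alt: ScenarioOutcome, base: ScenarioOutcome) -> float:
    """Average cost per additional correct result of ``alt`` versus ``base``."""
    return average_cer_from_pairs(
        (alt.costs.system_total, alt.correct_reported),
        (base.costs.system_total, base.correct_reported),
    )


def average_cer_from_pairs(alt: tuple[float, float], base: tuple[float, float]) -> float:
    d_effect = alt[1] - base[1]
    if d_effect == 0:
        raise ValueError("equal effects: average cost-effectiveness ratio undefined")
    return (alt[0] - base[0]) / d_effect


def incremental_analysis(
    outcomes: Sequence[ScenarioOutcome] | Sequence[tuple[str, float, float]],
    base_name: str | None = None,
) -> CEATable:
    """Dominance classification and frontier ICERs over a set of scenarios.

    Accepts either :class:`ScenarioOutcome`s or plain
    ``(name, cost, effect)`` triples. The comparator for average ratios is
    ``base_name`` or, by default, the least costly scenario. Rows are
    ordered by effect ascending, ties broken by name for determinism.
    """
    triples: list[tuple[str, float, float]] = []
    for o in outcomes:
        if isinstance(o, ScenarioOutcome):
            triples.append((o.name, o.costs.system_total, float(o.correct_reported)))
        else:
            name, cost, effect = o
            triples.append((str(name), float(cost), float(effect)))
    if len(triples) < 1:
        raise ValueError("at least one scenario is required")

    triples.sort(key=lambda t: (t[2], t[0]))
    if base_name is None:
        base_name = min(triples, key=lambda t: (t[1], t[0]))[0]
    base = next(t for t in triples if t[0] == base_name)

    status = {name: UNDOMINATED for name, _, _ in triples}

    # strict dominance: pairwise comparison
    for name_i, cost_i, eff_i in triples:
        for name_j, cost_j, eff_j in triples:
            if name_i == name_j:
                continue
            if (
                cost_j <= cost_i + _TIE_TOL
                and eff_j >= eff_i - _TIE_TOL
                and (cost_j < cost_i - _TIE_TOL or eff_j > eff_i + _TIE_TOL)
            ):
                status[name_i] = DOMINATED
                break

    # extended (weak) dominance: iteratively drop frontier candidates whose
    # ICER exceeds that of the next more effective candidate
    while True:
        frontier = [t for t in triples if status[t[0]] == UNDOMINATED]
        removed = False
        for idx in range(1, len(frontier) - 1):
            prev_, cur, nxt = frontier[idx - 1], frontier[idx], frontier[idx + 1]
            icer_cur = (cur[1] - prev_[1]) / (cur[2] - prev_[2])
            icer_nxt = (nxt[1] - cur[1]) / (nxt[2] - cur[2])
            if icer_cur > icer_nxt + _TIE_TOL:
                status[cur[0]] = WEAKLY_DOMINATED
                removed = True
                break
        if not removed:
            break

    frontier = [t for t in triples if status[t[0]] == UNDOMINATED]
    icers: dict[str, float] = {}
    for prev_, cur in zip(frontier, frontier[1:]):
        icers[cur[0]] = (cur[1] - prev_[1]) / (cur[2] - prev_[2])

    rows = []
    for name, cost, effect in triples:
        if name == base[0] or effect == base[2]:
            avg = None
        else:
            avg = (cost - base[1]) / (effect - base[2])
        rows.append(
            CEARow(
                name=name,
                cost=cost,
                effect=effect,
                avg_cer_vs_base=avg,
                status=status[name],
                icer=icers.get(name),
            )
        )
    return CEATable(tuple(rows), base[0])
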