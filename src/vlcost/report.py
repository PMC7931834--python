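"""Report rendering and machine-readable run outputs.

Renders the scenario-by-scenario results in the layout of the published
summary table (counts and component costs, then cost ratios, then the
incremental analysis), and writes CSV/JSON artefacts plus a run manifest.
Money is rounded to whole dollars for totals and two decimals for ratios
at render time only; missing cells print as an ellipsis.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from ._common import iround
from .cea import DOMINATED, WEAKLY_DOMINATED
from .model import ScaleUpResults, ViralLoadScaleUpModel
from .network import FacilityPanel
from .parameters import ModelConfig, Specimen

_ELLIPSIS = "…"
_FORMATS = ("csv", "tsv", "markdown")


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config_hash: str
    seed: int | None
    mode: str
    timestamp: str
    version: str
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def run_pipeline(
    config: ModelConfig,
    panel: FacilityPanel | None = None,
    mode: str = "model",
    seed: int | None = None,
) -> ScaleUpResults:
    """Build the model (generating a panel if none is given) and fit it."""
    if panel is None:
        model = ViralLoadScaleUpModel.from_config(config, seed=seed)
    else:
        model = ViralLoadScaleUpModel(panel, config)
    return model.fit(mode=mode)


def _money(x: float | None) -> str:
    return _ELLIPSIS if x is None else str(iround(x))


def _ratio(x: float | None) -> str:
    return _ELLIPSIS if x is None else f"{x:.2f}"


def _count(x: float | None) -> str:
    return _ELLIPSIS if x is None else str(iround(x))


def table_rows(results: ScaleUpResults) -> list[list[str]]:
    """The report table as rows of strings (first column = row label)."""
    names = results.scenario_names
    outs = [results.outcome(n) for n in names]

    def dried_tests(o):
        n = sum(v.total for s, v in o.volumes.by_specimen.items() if s is not Specimen.PLASMA)
        return n if n else None

    def plasma_tests(o):
        n = o.volumes.tests_for(Specimen.PLASMA)
        return n if n else None

    rows: list[list[str]] = [["quantity", *names]]

    def add(label, fmt, values):
        rows.append([label, *[fmt(v) for v in values]])

    add("Patients accessing VL tests/y", _count, [o.access_reported for o in outs])
    add("ART facilities reached", _count, [o.access.facilities_reached for o in outs])
    add("Patients with correct VL results", _count, [o.correct_reported for o in outs])
    add("VLs on dried specimens", _count, [dried_tests(o) for o in outs])
    add("Cost of VLs on dried specimens", _money,
        [o.costs.dried_testing if dried_tests(o) else 0.0 for o in outs])
    add("VLs on plasma specimens", _count, [plasma_tests(o) for o in outs])
    add("Cost of VLs on plasma specimens", _money,
        [o.costs.plasma_testing if plasma_tests(o) else 0.0 for o in outs])
    add("Facility visits required", _count, [o.visit_count for o in outs])
    add("Cost of facility visits", _money, [o.costs.facility_visits for o in outs])
    add("Transport cost", _money, [o.costs.transport for o in outs])
    add("Annual system cost", _money, [o.costs.system_total for o in outs])
    add("Cost per patient with a VL result", _ratio, [o.cost_per_result for o in outs])
    add("Cost per patient with correct VL results", _ratio, [o.cost_per_correct for o in outs])

    if results.cea is not None:
        cea_rows = {r.name: r for r in results.cea.rows}
        add(
            "Average cost per additional correct result vs base",
            _ratio,
            [cea_rows[n].avg_cer_vs_base for n in names],
        )

        def icer_cell(name: str) -> str:
            r = cea_rows[name]
            if r.status == DOMINATED:
                return "Dominated"
            if r.status == WEAKLY_DOMINATED:
                return "Weakly dominated"
            return _ratio(r.icer)

        rows.append(["Incremental cost per additional correct result", *[icer_cell(n) for n in names]])
    return rows


def render_table(results: ScaleUpResults, fmt: str = "markdown") -> str:
    """Render the report table as csv, tsv or markdown text."""
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    rows = table_rows(results)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        buf = io.StringIO()
        for row in rows:
            buf.write(sep.join(f'"{c}"' if sep in c else c for c in row) + "\n")
        return buf.getvalue()
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    lines = []
    header, *body = rows
    lines.append("| " + " | ".join(c.ljust(w) for c, w in zip(header, widths)) + " |")
    lines.append("|" + "|".join("-" * (w + 2) for w in widths) + "|")
    for row in body:
        lines.append("| " + " | ".join(c.ljust(w) for c, w in zip(row, widths)) + " |")
    return "\n".join(lines) + "\n"


def save_results(
    results: ScaleUpResults,
    out_dir: str | Path,
    fmt: str = "csv",
    seed: int | None = None,
) -> RunManifest:
    """Write scenario outcomes, the CEA table, the report and a manifest.

    Output CSVs are byte-identical across runs with the same config and
    seed; only the manifest timestamp differs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    frame = results.to_frame()
    path = out_dir / "scenario_outcomes.csv"
    frame.to_csv(path, index=False)
    files.append(path.name)

    if results.cea is not None:
        import pandas as pd

        cea_frame = pd.DataFrame(
            [
                {
                    "scenario": r.name,
                    "system_cost": r.cost,
                    "correct_results": r.effect,
                    "avg_cer_vs_base": r.avg_cer_vs_base,
                    "status": r.status,
                    "icer": r.icer,
                }
                for r in results.cea.rows
            ]
        )
        path = out_dir / "cea_table.csv"
        cea_frame.to_csv(path, index=False)
        files.append(path.name)

    ext = "md" if fmt == "markdown" else fmt
    path = out_dir / f"report.{ext}"
    path.write_text(render_table(results, fmt=fmt))
    files.append(path.name)

    manifest = RunManifest(
        config_hash=hashlib.sha256(results.model.config.canonical_json().encode()).hexdigest(),
        seed=seed if seed is not None else results.model.config.seed,
        mode=results.mode,
        timestamp=datetime.now(timezone.utc).isoformat(),
        version=__version__,
        files=files,
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
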