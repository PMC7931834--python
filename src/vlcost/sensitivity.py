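"""Deterministic sensitivity analysis and break-even (threshold) solving.

Any scalar model input is addressable by a dotted path into the config,
e.g. ``unit_costs.psc.consumables``, ``assays.dbs.capctm.specificity``,
``multipliers.low_volume_plasma``, ``epi.failure_prevalence`` or
``visit_transport.transport_cost_by_scenario.dried_partial``. Sweeps are
pure functions of the model: the model's own config is never mutated.

Metrics are either callables on :class:`~vlcost.model.ScaleUpResults` or
strings ``"<metric>/<scenario>"`` (e.g. ``"cost_per_correct/plasma_psc"``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .model import ScaleUpResults, ViralLoadScaleUpModel
from .parameters import ModelConfig, Platform, Specimen

Metric = Callable[[ScaleUpResults], float] | str


class ParameterPathError(KeyError):
    """A dotted parameter path does not resolve into the config."""


def _err(path: str, why: str) -> ParameterPathError:
    return ParameterPathError(f"cannot resolve parameter path {path!r}: {why}")


def get_param(cfg: ModelConfig, path: str) -> float:
    """Read a scalar input addressed by a dotted path."""
    parts = path.split(".")
    try:
        root = parts[0]
        if root == "unit_costs":
            specimen, field = Specimen(parts[1]), parts[2]
            return float(getattr(cfg.unit_cost(specimen), field))
        if root == "assays":
            specimen, platform, field = Specimen(parts[1]), Platform(parts[2]), parts[3]
            return float(getattr(cfg.assay(specimen, platform), field))
        if root == "multipliers":
            return float(getattr(cfg.multipliers, parts[1]))
        if root == "epi":
            value = getattr(cfg.epi, parts[1])
            if parts[1] == "failure_prevalence" and value is None and cfg.epi.calibration:
                # baseline is the calibrated value
                from .testing import calibrate_failure_prevalence

                cal = cfg.epi.calibration
                return calibrate_failure_prevalence(
                    cal.observed_tests, cal.observed_patients, cfg.assay(cal.specimen, cal.platform)
                )
            return float(value) if value is not None else None  # type: ignore[return-value]
        if root == "visit_transport":
            if parts[1] == "visit_cost":
                return float(cfg.visit_transport.visit_cost)
            if parts[1] == "transport_cost_by_scenario":
                return float(cfg.visit_transport.transport_cost_by_scenario[parts[2]])
        raise _err(path, f"unknown root section {root!r}")
    except (IndexError, AttributeError, KeyError, ValueError) as exc:
        if isinstance(exc, ParameterPathError):
            raise
        raise _err(path, str(exc)) from exc


def set_param(cfg: ModelConfig, path: str, value: float) -> ModelConfig:
    """Return a copy of the config with one scalar input replaced.

    Setting an assay point estimate widens its low/high bounds as needed
    so the bound-ordering invariant keeps holding during sweeps.
    """
    cfg = cfg.copy()
    parts = path.split(".")
    try:
        root = parts[0]
        if root == "unit_costs":
            specimen, field = Specimen(parts[1]), parts[2]
            for i, u in enumerate(cfg.unit_costs):
                if u.specimen == specimen:
                    cfg.unit_costs[i] = dataclasses.replace(u, **{field: value})
                    return cfg
            raise _err(path, f"no unit cost for {specimen.value}")
        if root == "assays":
            specimen, platform, field = Specimen(parts[1]), Platform(parts[2]), parts[3]
            for i, a in enumerate(cfg.assays):
                if a.specimen == specimen and a.platform == platform:
                    updates = {field: value}
                    if field == "sensitivity":
                        updates["sens_low"] = min(a.sens_low, value)
                        updates["sens_high"] = max(a.sens_high, value)
                    elif field == "specificity":
                        updates["spec_low"] = min(a.spec_low, value)
                        updates["spec_high"] = max(a.spec_high, value)
                    cfg.assays[i] = dataclasses.replace(a, **updates)
                    return cfg
            raise _err(path, f"no assay for {specimen.value}/{platform.value}")
        if root == "multipliers":
            getattr(cfg.multipliers, parts[1])  # raises if unknown
            cfg.multipliers = dataclasses.replace(cfg.multipliers, **{parts[1]: value})
            return cfg
        if root == "epi":
            getattr(cfg.epi, parts[1])
            cfg.epi = dataclasses.replace(cfg.epi, **{parts[1]: value})
            return cfg
        if root == "visit_transport":
            if parts[1] == "visit_cost":
                cfg.visit_transport = dataclasses.replace(cfg.visit_transport, visit_cost=value)
                return cfg
            if parts[1] == "transport_cost_by_scenario":
                costs = dict(cfg.visit_transport.transport_cost_by_scenario)
                if parts[2] not in costs:
                    raise _err(path, f"unknown transport key {parts[2]!r}")
                costs[parts[2]] = value
                cfg.visit_transport = dataclasses.replace(
                    cfg.visit_transport, transport_cost_by_scenario=costs
                )
                return cfg
        raise _err(path, f"unknown root section {root!r}")
    except (IndexError, AttributeError, TypeError, ValueError) as exc:
        if isinstance(exc, ParameterPathError):
            raise
        raise _err(path, str(exc)) from exc


def make_metric(name: str, scenario: str) -> Callable[[ScaleUpResults], float]:
    """Metric extractor for ``results.metric(name, scenario)``."""
    def extract(results: ScaleUpResults) -> float:
        return results.metric(name, scenario)

    extract.__name__ = f"{name}/{scenario}"
    return extract


def _as_callable(metric: Metric) -> Callable[[ScaleUpResults], float]:
    if callable(metric):
        return metric
    name, _, scenario = str(metric).partition("/")
    if not scenario:
        raise ValueError(f"string metric must look like 'metric/scenario', got {metric!r}")
    return make_metric(name, scenario)


def _metric_name(metric: Metric) -> str:
    return metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")


def evaluate(model: ViralLoadScaleUpModel, metric: Metric, mode: str = "model") -> float:
    """Fit the model and extract one scalar metric."""
    return _as_callable(metric)(model.fit(mode))


def _evaluate_at(
    model: ViralLoadScaleUpModel, assignments: dict[str, float], metric: Metric, mode: str
) -> float:
    cfg = model.config
    for path, value in assignments.items():
        cfg = set_param(cfg, path, value)
    return evaluate(model.with_config(cfg), metric, mode)


@dataclass(frozen=True)
class SensitivityResult:
    """Grid evaluation of one metric over one or two parameters."""

    parameters: tuple[str, ...]
    grids: tuple[tuple[float, ...], ...]
    metric_name: str
    values: np.ndarray  # 1-d for one-way, |grid_a| x |grid_b| for two-way
    baseline: float

    @property
    def low(self) -> float:
        """Metric at the low end of the (one-way) range — tornado entry."""
        return float(np.asarray(self.values).ravel()[0])

    @property
    def high(self) -> float:
        """Metric at the high end of the (one-way) range."""
        return float(np.asarray(self.values).ravel()[-1])


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even solution for one parameter and the achieved residual."""

    parameter: str
    value: float
    residual: float
    metric_name: str

    def __float__(self) -> float:
        return self.value


def default_range(cfg: ModelConfig, parameter: str) -> tuple[float, float]:
    """Default sweep range: stored evidence bounds for assay point estimates,
    otherwise +/-50% around the baseline (proportions clipped to [0, 1])."""
    parts = parameter.split(".")
    if parts[0] == "assays" and parts[-1] in ("sensitivity", "specificity"):
        a = cfg.assay(Specimen(parts[1]), Platform(parts[2]))
        return (a.sens_low, a.sens_high) if parts[-1] == "sensitivity" else (a.spec_low, a.spec_high)
    baseline = get_param(cfg, parameter)
    lo, hi = 0.5 * baseline, 1.5 * baseline
    if parts[0] in ("multipliers",) or parts[-1] == "failure_prevalence":
        hi = min(1.0, hi)
    return lo, hi


def one_way(
    model: ViralLoadScaleUpModel,
    parameter: str,
    low: float | None = None,
    high: float | None = None,
    metric: Metric = "cost_per_correct/plasma_psc",
    mode: str = "model",
) -> SensitivityResult:
    """Evaluate a metric at (low, baseline, high) of one parameter.

    ``low``/``high`` default to :func:`default_range` for the parameter.
    """
    if low is None or high is None:
        d_lo, d_hi = default_range(model.config, parameter)
        low = d_lo if low is None else low
        high = d_hi if high is None else high
    if low > high:
        raise ValueError(f"low {low} exceeds high {high}")
    baseline_value = get_param(model.config, parameter)
    grid = (low, baseline_value, high)
    values = np.array(
        [_evaluate_at(model, {parameter: x}, metric, mode) for x in grid]
    )
    return SensitivityResult(
        parameters=(parameter,),
        grids=(grid,),
        metric_name=_metric_name(metric),
        values=values,
        baseline=float(values[1]),
    )


def two_way(
    model: ViralLoadScaleUpModel,
    parameter_a: str,
    parameter_b: str,
    grid_a: Sequence[float],
    grid_b: Sequence[float],
    metric: Metric,
    mode: str = "model",
) -> SensitivityResult:
    """Metric matrix over the cartesian product of two parameter grids."""
    if len(grid_a) == 0 or len(grid_b) == 0:
        raise ValueError("grids must be non-empty")
    values = np.empty((len(grid_a), len(grid_b)))
    for i, a in enumerate(grid_a):
        for j, b in enumerate(grid_b):
            values[i, j] = _evaluate_at(model, {parameter_a: a, parameter_b: b}, metric, mode)
    baseline = _evaluate_at(model, {}, metric, mode)
    return SensitivityResult(
        parameters=(parameter_a, parameter_b),
        grids=(tuple(grid_a), tuple(grid_b)),
        metric_name=_metric_name(metric),
        values=values,
        baseline=baseline,
    )


def threshold(
    model: ViralLoadScaleUpModel,
    parameter: str,
    metric_a: Metric,
    metric_b: Metric,
    bracket: tuple[float, float],
    tol: float = 0.005,
    mode: str = "model",
) -> ThresholdResult:
    """Solve for the parameter value equating two metrics.

    Uses Brent's method on the metric difference over ``bracket``;
    requires a sign change and reports the achieved residual. ``tol`` is
    the acceptable absolute residual on the metric difference (default
    half a cent for dollar-valued metrics).
    """
    fa = _as_callable(metric_a)
    fb = _as_callable(metric_b)

    def diff(x: float) -> float:
        cfg = set_param(model.config, parameter, x)
        results = model.with_config(cfg).fit(mode)
        return fa(results) - fb(results)

    lo, hi = bracket
    d_lo, d_hi = diff(lo), diff(hi)
    if d_lo == 0.0:
        return ThresholdResult(parameter, lo, 0.0, _metric_name(metric_a))
    if d_hi == 0.0:
        return ThresholdResult(parameter, hi, 0.0, _metric_name(metric_a))
    if np.sign(d_lo) == np.sign(d_hi):
        raise ValueError(
            f"metric difference does not change sign over bracket [{lo}, {hi}]: "
            f"f({lo}) = {d_lo:.6g}, f({hi}) = {d_hi:.6g}"
        )
    root = optimize.brentq(diff, lo, hi, xtol=1e-10, rtol=1e-14)
    residual = abs(diff(root))
    if residual > tol:
        raise ValueError(
            f"threshold solve for {parameter!r} left residual {residual:.6g} > tol {tol}"
        )
    return ThresholdResult(parameter, float(root), float(residual), _metric_name(metric_a))


def tornado(
    model: ViralLoadScaleUpModel,
    ranges: dict[str, tuple[float, float]],
    metric: Metric,
    mode: str = "model",
) -> "pd.DataFrame":
    """One-way results for several parameters, ordered by swing size."""
    import pandas as pd

    rows = []
    for parameter, (low, high) in ranges.items():
        res = one_way(model, parameter, low, high, metric, mode=mode)
        rows.append(
            {
                "parameter": parameter,
                "low_input": low,
                "high_input": high,
                "metric_low": res.low,
                "metric_baseline": res.baseline,
                "metric_high": res.high,
                "swing": abs(res.high - res.low),
            }
        )
    frame = pd.DataFrame(rows).sort_values("swing", ascending=False, ignore_index=True)
    return frame


def plot_tornado(frame, ax=None):  # pragma: no cover - optional plotting hook
    """Horizontal-bar tornado plot of a :func:`tornado` frame (needs matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * len(frame) + 1))
    base = frame["metric_baseline"].iloc[0]
    order = frame.sort_values("swing")
    ax.barh(order["parameter"], order["metric_high"] - base, left=base, color="#cc5500", alpha=0.8)
    ax.barh(order["parameter"], order["metric_low"] - base, left=base, color="#2266aa", alpha=0.8)
    ax.axvline(base, color="k", lw=1)
    ax.set_xlabel("metric value")
    return ax
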