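"""Local sensitivity analysis of response metrics to parameters and reactions.

Coefficients follow the metabolic-control-analysis convention: the
normalized log-log finite difference

    s = ln(q(p·f) / q(p)) / ln(f)

with perturbation factor f = 1.01 by default.  Free parameters are perturbed
one at a time; derived (detailed-balance) parameters are recomputed after
every perturbation so each perturbed model remains thermodynamically
consistent.  Reaction-level coefficients multiply a whole reaction's rate by
the factor instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compiler import CompiledModel
from .simulate import SimulationCondition, evaluate_observables, integrate
from .thermo import apply_constraints

__all__ = ["ResponseMetric", "SensitivityResult", "sensitivity_coefficients"]


@dataclass(frozen=True)
class ResponseMetric:
    name: str
    reducer: str  # integral_of_observable | max_of_observable | value_at_time
    observable: str
    condition: str
    time: Optional[float] = None

    def __post_init__(self):
        if self.reducer not in ("integral_of_observable", "max_of_observable", "value_at_time"):
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.reducer == "value_at_time" and self.time is None:
            raise ValueError("value_at_time metric needs a time")


@dataclass
class SensitivityResult:
    coefficients: pd.DataFrame  # rows = parameter/reaction labels, columns = metrics
    factor: float
    target: str  # "parameters" | "reactions"

    def ranked(self, metric: str) -> pd.DataFrame:
        col = self.coefficients[metric]
        return col.reindex(col.abs().sort_values(ascending=False).index).to_frame()


def _evaluate_metric(
    model: CompiledModel,
    params,
    metric: ResponseMetric,
    conditions: dict,
    rate_scales=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    cond = conditions[metric.condition]
    times = cond.times()
    if metric.reducer == "value_at_time" and metric.time is not None:
        if metric.time not in times:
            times = np.unique(np.concatenate([times, [metric.time]]))
    traj = integrate(model, params, cond, times=times, rate_scales=rate_scales,
                     rtol=rtol, atol=atol)
    series = {s.observable: s for s in evaluate_observables(traj, model.observables)}
    if metric.observable not in series:
        raise KeyError(f"unknown observable {metric.observable!r}")
    s = series[metric.observable]
    if metric.reducer == "integral_of_observable":
        return float(np.trapezoid(s.values, s.times))
    if metric.reducer == "max_of_observable":
        return float(np.max(s.values))
    j = int(np.argmin(np.abs(s.times - metric.time)))
    return float(s.values[j])


def sensitivity_coefficients(
    model: CompiledModel,
    params,
    constraints: list,
    metrics: Sequence[ResponseMetric],
    conditions: Sequence[SimulationCondition],
    factor: float = 1.01,
    target: str = "parameters",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> SensitivityResult:
    """Log-log sensitivity of each metric to each free parameter (or reaction).

    Integration tolerances default tighter than plain simulation because the
    log finite difference amplifies solver noise by 1/ln(factor).  Raises if
    a baseline metric is nonpositive (the log response is undefined there).
    """
    if factor <= 1:
        raise ValueError("perturbation factor must exceed 1")
    params = np.asarray(params, dtype=float)
    cond_map = {c.name: c for c in conditions}
    base = {}
    for m in metrics:
        q = _evaluate_metric(model, params, m, cond_map, rtol=rtol, atol=atol)
        if q <= 0:
            raise ValueError(f"baseline metric {m.name!r} is not positive (q={q:g})")
        base[m.name] = q

    if target == "parameters":
        labels = [model.parameters[i].name for i in model.free_parameter_indices()]
        rows = []
        for i in model.free_parameter_indices():
            pert = params.copy()
            pert[i] *= factor
            if constraints:
                pert = apply_constraints(pert, constraints)
            rows.append([
                math.log(
                    _evaluate_metric(model, pert, m, cond_map, rtol=rtol, atol=atol)
                    / base[m.name]
                ) / math.log(factor)
                for m in metrics
            ])
    elif target == "reactions":
        labels = [f"r{r.index + 1}" for r in model.reactions]
        rows = []
        for r in model.reactions:
            scales = np.ones(len(model.reactions))
            scales[r.index] = factor
            rows.append([
                math.log(
                    _evaluate_metric(model, params, m, cond_map, rate_scales=scales,
                                     rtol=rtol, atol=atol) / base[m.name]
                ) / math.log(factor)
                for m in metrics
            ])
    else:
        raise ValueError(f"unknown target {target!r}")

    frame = pd.DataFrame(rows, index=labels, columns=[m.name for m in metrics])
    return SensitivityResult(frame, factor, target)
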