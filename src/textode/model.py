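"""High-level modelling API.

:class:`ReactionNetworkModel` wraps the full pipeline — parse, compile,
detect detailed-balance loops — behind one object built from model text, in
the style of statsmodels model classes:

>>> m = ReactionNetworkModel.from_text('''
... A is synthesized
... A is phosphorylated --> pA
... pA is degraded
... @obs pA: pA
... @init A = 1
... ''')
>>> traj = m.simulate(duration=10)
>>> res = m.fit(data, FitConfig(n_parameter_sets=10, seed=1))   # doctest: +SKIP
>>> print(res.summary())                                        # doctest: +SKIP

``fit`` returns a :class:`FitResults` object carrying the parameter
ensemble, per-set costs, and ensemble mean/sd trajectories.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import estimate, sensitivity as sens, simulate as sim, thermo
from .compiler import CompiledModel, RateLawRegistry, compile_model, model_report
from .dsl import ParsedModel, parse_model, validate_model
from .graphs import export_graph

__all__ = ["ReactionNetworkModel", "FitResults"]


class ReactionNetworkModel:
    """A reaction network defined by DSL text, compiled to an ODE system.

    Parameters hold their defaults/overrides from the text; detailed-balance
    constraints are detected at construction and re-applied through every
    simulation and fit.
    """

    def __init__(self, parsed: ParsedModel, registry: Optional[RateLawRegistry] = None):
        self.parsed = parsed
        self.issues = validate_model(parsed)
        errors = [i for i in self.issues if i.severity == "error"]
        if errors:
            raise ValueError("model has validation errors: " + "; ".join(i.message for i in errors))
        self.compiled: CompiledModel = compile_model(parsed, registry)
        self.constraints = thermo.detect_and_constrain(self.compiled)

    # --- constructors ------------------------------------------------------
    @classmethod
    def from_text(cls, text: str, source_name: str = "<string>", registry=None):
        return cls(parse_model(text, source_name), registry)

    @classmethod
    def from_file(cls, path, registry=None):
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        return cls(parse_model(text, str(path)), registry)

    # --- introspection -----------------------------------------------------
    @property
    def n_free_parameters(self) -> int:
        return len(self.compiled.free_parameter_indices())

    def report(self) -> str:
        return model_report(self.compiled) + "\n" + thermo.constraint_report(
            self.compiled, self.constraints
        )

    def to_graph(self, fmt: str = "dot") -> str:
        return export_graph(self.compiled, fmt)

    def conditions(self) -> list:
        out = [
            sim.SimulationCondition(name, overrides)
            for name, overrides in self.compiled.conditions.items()
        ]
        return out or [sim.SimulationCondition("control", {})]

    # --- simulation --------------------------------------------------------
    def simulate(
        self,
        condition: Optional[sim.SimulationCondition] = None,
        duration: float = 10.0,
        n_timepoints: int = 101,
        params=None,
    ) -> sim.Trajectory:
        if condition is None:
            condition = sim.SimulationCondition("control", {}, duration, n_timepoints)
        if params is None:
            params = self.compiled.parameter_values()
        params = thermo.apply_constraints(params, self.constraints) if self.constraints else params
        return sim.integrate(self.compiled, params, condition)

    def observables(self, trajectory: sim.Trajectory) -> list:
        return sim.evaluate_observables(trajectory, self.compiled.observables)

    # --- estimation --------------------------------------------------------
    def fit(
        self,
        data: estimate.ExperimentTable,
        config: Optional[estimate.FitConfig] = None,
        conditions: Optional[Sequence[sim.SimulationCondition]] = None,
    ) -> "FitResults":
        config = config or estimate.FitConfig()
        conditions = list(conditions) if conditions is not None else self.conditions()
        ensemble = estimate.fit(self.compiled, self.constraints, data, config, conditions)
        return FitResults(self, ensemble, data, config, conditions)

    # --- sensitivity -------------------------------------------------------
    def sensitivity(
        self,
        metrics: Sequence[sens.ResponseMetric],
        conditions: Optional[Sequence[sim.SimulationCondition]] = None,
        params=None,
        factor: float = 1.01,
        target: str = "parameters",
    ) -> sens.SensitivityResult:
        if params is None:
            params = self.compiled.parameter_values()
        params = thermo.apply_constraints(params, self.constraints) if self.constraints else params
        conditions = list(conditions) if conditions is not None else self.conditions()
        return sens.sensitivity_coefficients(
            self.compiled, params, self.constraints, metrics, conditions, factor, target
        )


@dataclass
class FitResults:
    """Ensemble fit results with statsmodels-style reporting."""

    model: ReactionNetworkModel
    ensemble: estimate.ParameterEnsemble
    data: estimate.ExperimentTable
    config: estimate.FitConfig
    conditions: list

    @property
    def best_parameters(self) -> dict:
        return dict(zip(self.ensemble.parameter_names, self.ensemble.best.parameters))

    @property
    def best_cost(self) -> float:
        return self.ensemble.best.cost

    def parameter_table(self) -> pd.DataFrame:
        """Per-parameter ensemble spread (median and range over members)."""
        stack = np.vstack([m.parameters for m in self.ensemble.members])
        free = set(self.ensemble.free_indices)
        rows = []
        for i, name in enumerate(self.ensemble.parameter_names):
            status = self.model.compiled.parameters[i].status
            rows.append(
                {
                    "parameter": name,
                    "status": status,
                    "best": stack[0, i],
                    "median": float(np.median(stack[:, i])),
                    "min": float(stack[:, i].min()),
                    "max": float(stack[:, i].max()),
                }
            )
        return pd.DataFrame(rows)

    def trajectories(self, times=None) -> pd.DataFrame:
        """Ensemble mean ± sd of normalized observables."""
        if times is None:
            times = np.linspace(0.0, self.conditions[0].duration, self.conditions[0].n_timepoints)
        return estimate.ensemble_summary(
            self.ensemble, self.model.compiled, self.model.constraints, self.conditions, times
        )

    def summary(self) -> str:
        buf = io.StringIO()
        ens = self.ensemble
        buf.write("Reaction network ensemble fit\n")
        buf.write("=============================\n")
        buf.write(f"parameter sets:      {len(ens)}\n")
        buf.write(f"free parameters:     {len(ens.free_indices)}\n")
        buf.write(f"detailed-balance constraints: {len(self.model.constraints)}\n")
        buf.write(f"data points:         {len(self.data.frame)}\n")
        costs = [m.cost for m in ens.members]
        buf.write(f"cost (best/median/worst): {min(costs):.4g} / "
                  f"{float(np.median(costs)):.4g} / {max(costs):.4g}\n\n")
        buf.write(self.parameter_table().to_string(index=False, float_format=lambda x: f"{x:.4g}"))
        buf.write("\n")
        return buf.getvalue()
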