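"""Parameter estimation against time-course data.

Free parameters are fitted in log10 space with seeded differential
evolution, one independent run per requested parameter set, mirroring the
common practice of reporting the trajectory averaged across an ensemble of
independently optimized parameter sets rather than a single best fit.
Detailed-balance constraints are re-applied at every objective evaluation so
each candidate is thermodynamically consistent.

The objective is the sum of squared differences between normalized simulated
observables and normalized data.  Both sides are normalized per observable
group (across all conditions) exactly as in :mod:`textode.simulate`, because
relative immunoblot-style data carry no absolute scale.  When the data table
has an ``sd`` column, residuals are divided by the sd (scaled by the same
group maximum as the values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution

from .compiler import CompiledModel
from .simulate import (
    IntegrationError,
    ObservableSeries,
    SimulationCondition,
    evaluate_observables,
    integrate,
    normalize_series,
)
from .thermo import apply_constraints

__all__ = [
    "ExperimentTable",
    "FitConfig",
    "ParameterEnsemble",
    "EnsembleMember",
    "objective",
    "fit",
    "ensemble_summary",
]

FAILURE_PENALTY = 1e10


@dataclass
class ExperimentTable:
    """Tidy time-course measurements: (observable, condition, time, value[, sd])."""

    frame: pd.DataFrame

    REQUIRED = ("observable", "condition", "time", "value")

    def __post_init__(self):
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"experiment table missing columns {missing}")
        if (df["value"] < 0).any():
            raise ValueError("experiment values must be nonnegative")
        if df.duplicated(subset=["observable", "condition", "time"]).any():
            raise ValueError("duplicate (observable, condition, time) rows")

    @classmethod
    def from_csv(cls, path, sep=None) -> "ExperimentTable":
        df = pd.read_csv(path, sep=sep, engine="python")
        return cls(df)

    def to_csv(self, path, sep="\t"):
        self.frame.to_csv(path, sep=sep, index=False)

    @property
    def observables(self) -> list:
        return sorted(self.frame["observable"].unique())

    @property
    def conditions(self) -> list:
        return sorted(self.frame["condition"].unique())

    def times_for(self, condition: str) -> np.ndarray:
        t = np.unique(self.frame.loc[self.frame["condition"] == condition, "time"].to_numpy(float))
        return t


@dataclass
class FitConfig:
    n_parameter_sets: int = 10
    seed: int = 0
    population_size: int = 15
    max_evaluations: int = 5000
    mutation: tuple = (0.5, 1.0)
    recombination: float = 0.7

    def seeds(self) -> list:
        return [self.seed + i for i in range(self.n_parameter_sets)]


@dataclass
class EnsembleMember:
    parameters: np.ndarray  # full parameter vector (constraints applied)
    cost: float
    seed: int
    n_evaluations: int


@dataclass
class ParameterEnsemble:
    members: list  # sorted by cost ascending
    parameter_names: list
    free_indices: list

    def __len__(self) -> int:
        return len(self.members)

    @property
    def best(self) -> EnsembleMember:
        return self.members[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.members:
            row = {"seed": m.seed, "cost": m.cost, "n_evaluations": m.n_evaluations}
            row.update({n: v for n, v in zip(self.parameter_names, m.parameters)})
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path, sep="\t"):
        self.to_frame().to_csv(path, sep=sep, index=False)


def _check_table_against_model(model: CompiledModel, data: ExperimentTable, conditions):
    cond_names = {c.name for c in conditions}
    for obs in data.observables:
        if obs not in model.observables:
            raise ValueError(f"data references unknown observable {obs!r}")
    for cond in data.conditions:
        if cond not in cond_names:
            raise ValueError(f"data references unknown condition {cond!r}")


class _Aligner:
    """Precomputed mapping between data rows and simulation grid points.

    Built once per fit so the inner objective loop only integrates, scales
    by the per-observable group maximum and gathers.
    """

    def __init__(self, model, conditions, data: ExperimentTable):
        _check_table_against_model(model, data, conditions)
        self.model = model
        df = data.frame
        self.conds = []
        self.grids = []
        for cond in conditions:
            t = data.times_for(cond.name)
            if t.size == 0:
                continue
            self.conds.append(cond)
            self.grids.append(np.unique(np.concatenate([[0.0], t])))
        self.n_rows = len(df)
        self.blocks = []  # (cond position, observable, data row indices, grid indices)
        times_col = df["time"].to_numpy(float)
        for pos, cond in enumerate(self.conds):
            grid = self.grids[pos]
            for obs in model.observables:
                mask = ((df["observable"] == obs) & (df["condition"] == cond.name)).to_numpy()
                rows = np.where(mask)[0]
                if rows.size == 0:
                    continue
                self.blocks.append((pos, obs, rows, np.searchsorted(grid, times_col[rows])))

    def simulate(self, params):
        """Normalized simulated values aligned with the data rows; None on failure."""
        raw = {}
        for pos, cond in enumerate(self.conds):
            try:
                traj = integrate(self.model, params, cond, times=self.grids[pos])
            except IntegrationError:
                return None
            for name, vec in self.model.observables.items():
                raw[(pos, name)] = traj.states @ np.asarray(vec, dtype=float)
        gmax: dict = {}
        for (_, name), vals in raw.items():
            gmax[name] = max(gmax.get(name, 0.0), float(vals.max()))
        out = np.empty(self.n_rows)
        for pos, obs, rows, tidx in self.blocks:
            if gmax[obs] <= 0:
                return None
            out[rows] = raw[(pos, obs)][tidx] / gmax[obs]
        return out


def _simulate_normalized(model, params, conditions, data: ExperimentTable):
    return _Aligner(model, conditions, data).simulate(params)


def _normalized_data(data: ExperimentTable):
    """Per-observable-group normalization of the measured values (and sd)."""
    df = data.frame
    vals = df["value"].to_numpy(float).copy()
    sds = df["sd"].to_numpy(float).copy() if "sd" in df.columns else None
    for obs in df["observable"].unique():
        mask = (df["observable"] == obs).to_numpy()
        gmax = vals[mask].max()
        if gmax <= 0:
            continue  # an all-zero group is a flat baseline; leave it at zero
        vals[mask] /= gmax
        if sds is not None:
            sds[mask] /= gmax
    return vals, sds


def objective(
    free_params,
    model: CompiledModel,
    constraints: list,
    data: ExperimentTable,
    conditions: Sequence[SimulationCondition],
) -> float:
    """Sum of squared normalized residuals; finite penalty on solver failure."""
    _check_table_against_model(model, data, conditions)
    params = model.parameter_values()
    free_idx = model.free_parameter_indices()
    free_params = np.asarray(free_params, dtype=float)
    if free_params.shape != (len(free_idx),):
        raise ValueError(f"expected {len(free_idx)} free parameters, got {free_params.shape}")
    params[free_idx] = free_params
    params = apply_constraints(params, constraints) if constraints else params
    sim = _simulate_normalized(model, params, conditions, data)
    if sim is None:
        return FAILURE_PENALTY
    obs_vals, obs_sds = _normalized_data(data)
    resid = sim - obs_vals
    if obs_sds is not None:
        resid = resid / np.where(obs_sds > 0, obs_sds, 1.0)
    return float(np.sum(resid**2))


def fit(
    model: CompiledModel,
    constraints: list,
    data: ExperimentTable,
    config: FitConfig,
    conditions: Optional[Sequence[SimulationCondition]] = None,
) -> ParameterEnsemble:
    """Seeded multi-start global fit of the free parameters.

    One differential-evolution run per parameter set, searching log10 space
    within each parameter's bounds.  Identical model + data + config yields
    an identical ensemble.
    """
    free_idx = model.free_parameter_indices()
    if not free_idx:
        raise ValueError("nothing to fit: model has zero free parameters")
    if len(data.frame) == 0:
        raise ValueError("experiment table is empty")
    if conditions is None:
        conditions = [
            SimulationCondition(name, overrides) for name, overrides in model.conditions.items()
        ]
        if not conditions:
            conditions = [SimulationCondition("control", {})]
    _check_table_against_model(model, data, conditions)

    log_bounds = [
        (np.log10(model.parameters[i].lower_bound), np.log10(model.parameters[i].upper_bound))
        for i in free_idx
    ]
    obs_vals, obs_sds = _normalized_data(data)
    aligner = _Aligner(model, conditions, data)
    base_params = model.parameter_values()

    def cost_of_log(x) -> float:
        params = base_params.copy()
        params[free_idx] = 10.0 ** np.asarray(x, dtype=float)
        if constraints:
            params = apply_constraints(params, constraints)
        sim = aligner.simulate(params)
        if sim is None:
            return FAILURE_PENALTY
        resid = sim - obs_vals
        if obs_sds is not None:
            resid = resid / np.where(obs_sds > 0, obs_sds, 1.0)
        return float(np.sum(resid**2))

    maxiter = max(1, config.max_evaluations // (config.population_size * len(free_idx)) - 1)
    members = []
    for seed in config.seeds():
        result = differential_evolution(
            cost_of_log,
            bounds=log_bounds,
            seed=seed,
            popsize=config.population_size,
            maxiter=maxiter,
            mutation=config.mutation,
            recombination=config.recombination,
            tol=0.0,
            init="latinhypercube",
            polish=False,
            updating="immediate",
        )
        params = model.parameter_values()
        params[free_idx] = 10.0 ** result.x
        if constraints:
            params = apply_constraints(params, constraints)
        members.append(EnsembleMember(params, float(result.fun), seed, int(result.nfev)))
    members.sort(key=lambda m: m.cost)
    return ParameterEnsemble(members, model.parameter_names, free_idx)


def ensemble_summary(
    ensemble: ParameterEnsemble,
    model: CompiledModel,
    constraints: list,
    conditions: Sequence[SimulationCondition],
    times,
) -> pd.DataFrame:
    """Pointwise mean and sd of normalized observables across ensemble members.

    Members that fail to integrate are excluded with a warning; it is an
    error if every member fails.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    times = np.asarray(times, dtype=float)
    per_member = []
    for m in ensemble.members:
        series = []
        try:
            for cond in conditions:
                traj = integrate(model, m.parameters, cond, times=times)
                series.extend(evaluate_observables(traj, model.observables))
            series = normalize_series(series)
        except (IntegrationError, ValueError) as e:
            warnings.warn(f"ensemble member (seed {m.seed}) excluded: {e}")
            continue
        per_member.append({(s.observable, s.condition): s.normalized for s in series})
    if not per_member:
        raise RuntimeError("all ensemble members failed to integrate")
    rows = []
    keys = sorted(per_member[0].keys())
    for obs, cond in keys:
        stack = np.vstack([pm[(obs, cond)] for pm in per_member])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=0)
        for t, mu, s in zip(times, mean, sd):
            rows.append((obs, cond, t, mu, s))
    return pd.DataFrame(rows, columns=["observable", "condition", "time", "mean", "sd"])
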