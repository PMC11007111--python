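"""Numerical integration of compiled models and observable evaluation.

A stimulus (e.g. growth-factor addition) is modeled as an initial-amount
override applied at t = 0 through a :class:`SimulationCondition`.  Observable
series are normalized the way relative immunoblot data are: each observable
is divided by its maximum over all timepoints *and* conditions of the group,
so the peak of the group is exactly 1 and conditions remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .compiler import CompiledModel

__all__ = [
    "SimulationCondition",
    "Trajectory",
    "ObservableSeries",
    "IntegrationError",
    "integrate",
    "evaluate_observables",
    "normalize_series",
    "series_to_frame",
]

RTOL = 1e-8
ATOL = 1e-10
NEG_CLIP = -1e-8


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_time: Optional[float] = None):
        self.last_time = last_time
        super().__init__(message)


@dataclass(frozen=True)
class SimulationCondition:
    name: str
    initial_overrides: dict = field(default_factory=dict)
    duration: float = 10.0
    n_timepoints: int = 101

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_timepoints)


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # timepoints x species
    condition_name: str
    species_names: list

    def species(self, name: str) -> np.ndarray:
        return self.states[:, self.species_names.index(name)]


@dataclass
class ObservableSeries:
    observable: str
    condition: str
    times: np.ndarray
    values: np.ndarray
    normalized: Optional[np.ndarray] = None


def integrate(
    model: CompiledModel,
    params,
    condition: SimulationCondition,
    times=None,
    rtol: float = RTOL,
    atol: float = ATOL,
    rate_scales=None,
) -> Trajectory:
    """Integrate the ODE system under one condition with a stiff-capable solver.

    ``times`` must be increasing with ``times[0] == 0``; defaults to the
    condition's uniform grid.  Small negative excursions (≥ −1e−8) are
    clipped to zero; anything more negative is reported as a solver failure.
    """
    for name in condition.initial_overrides:
        model.species_index(name)  # raises KeyError for unknown species
    times = condition.times() if times is None else np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0) and times.size > 1:
        raise ValueError("times must be strictly increasing")
    y0 = model.initial_state(condition.initial_overrides)
    params = np.asarray(params, dtype=float)
    if times.size == 1:
        return Trajectory(times, y0[None, :], condition.name, model.species_names)

    sol = solve_ivp(
        model.ode_callable(params, rate_scales),
        (times[0], times[-1]),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"solver failed at t={last:g}: {sol.message}", last_time=last)
    states = sol.y.T
    if states.min() < NEG_CLIP:
        raise IntegrationError(
            f"state went negative ({states.min():.3e}) beyond numerical tolerance",
            last_time=float(times[-1]),
        )
    states = np.clip(states, 0.0, None)
    return Trajectory(times, states, condition.name, model.species_names)


def evaluate_observables(trajectory: Trajectory, observables: dict) -> list:
    """Evaluate each named linear combination of species along a trajectory."""
    out = []
    for name, vec in observables.items():
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (trajectory.states.shape[1],):
            raise ValueError(f"observable {name!r} has wrong dimension")
        out.append(
            ObservableSeries(name, trajectory.condition_name, trajectory.times,
                             trajectory.states @ vec)
        )
    return out


def normalize_series(series: Sequence[ObservableSeries]) -> list:
    """Scale each observable group to a shared maximum of exactly 1.

    The group is one observable across every condition present; all its
    values are divided by the single group-wide maximum.  Raises on an
    all-zero group (nothing to scale by).
    """
    groups: dict[str, list[ObservableSeries]] = {}
    for s in series:
        groups.setdefault(s.observable, []).append(s)
    out = []
    for name, members in groups.items():
        gmax = max(float(np.max(m.values)) for m in members)
        if gmax <= 0:
            raise ValueError(f"cannot normalize observable {name!r}: all values are zero")
        for m in members:
            out.append(
                ObservableSeries(m.observable, m.condition, m.times, m.values,
                                 normalized=m.values / gmax)
            )
    return out


def series_to_frame(series: Sequence[ObservableSeries]) -> pd.DataFrame:
    """Tidy table (condition, observable, time, value, normalized_value)."""
    rows = []
    for s in series:
        norm = s.normalized if s.normalized is not None else np.full_like(s.values, np.nan)
        for t, v, nv in zip(s.times, s.values, norm):
            rows.append((s.condition, s.observable, t, v, nv))
    return pd.DataFrame(rows, columns=["condition", "observable", "time", "value", "normalized_value"])
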