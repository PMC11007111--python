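"""Detailed-balance (Wegscheider) constraints on reaction cycles.

A closed system of reversible mass-action reactions can only reach a true
thermodynamic equilibrium if, around every closed loop of reactions, the
product of equilibrium constants ``Keq = kf/kr`` equals one.  Networks with
alternate assembly paths to the same complex (e.g. A+B→AB→ABC versus
A+C→AC→ABC) contain such loops, and fitting their rate constants
independently produces models that break detailed balance — sustaining a
perpetual flux around the loop at steady state.

This module detects the independent loops of a compiled model and eliminates
one reverse rate constant per loop, turning it into a derived parameter whose
value is recomputed from the remaining free constants so that the loop's
equilibrium-constant product is exactly one.

A loop here is a vector c in the right null space of the stoichiometric
submatrix of the reversible reactions: ∑ c_j · (stoichiometry of reaction j)
= 0, which is precisely the condition under which the Wegscheider identity
∏ Keq_j^{c_j} = 1 must hold at equilibrium.  This catches thermodynamic
cycles that are not cycles of the complex graph (deficiency > 0 networks,
such as the binding diamond).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Optional

import networkx as nx
import numpy as np
import sympy as sp

from .compiler import CompiledModel

__all__ = [
    "ReversibleGraph",
    "CycleConstraint",
    "ThermoError",
    "build_reversible_graph",
    "cycle_basis",
    "assign_constraints",
    "apply_constraints",
    "detect_and_constrain",
    "constraint_report",
]


class ThermoError(ValueError):
    pass


def _is_reversible_mass_action(rxn) -> bool:
    return rxn.reversible and len(rxn.parameter_names) == 2 and \
        rxn.parameter_names[0].startswith("kf") and rxn.parameter_names[1].startswith("kr")


@dataclass
class ReversibleGraph:
    """Composition graph of the reversible reactions (for reporting/plots).

    Nodes are the species compositions consumed or produced by reversible
    mass-action reactions (A+B⇄AB links node {A,B} to node {AB}); each edge
    keeps its forward orientation and rate-constant names.  Cycle *detection*
    uses the stoichiometric null space (see :func:`cycle_basis`), which is
    strictly more complete than the cycles of this graph.
    """

    graph: nx.MultiGraph
    model: CompiledModel
    reversible_indices: tuple

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_reversible_graph(model: CompiledModel) -> ReversibleGraph:
    """Collect reversible mass-action reactions into a composition graph.

    Irreversible reactions (Michaelis–Menten, Hill, degradation, synthesis)
    carry no reverse rate constant and are excluded.
    """
    g = nx.MultiGraph()
    idxs = []
    names = model.species_names
    for r in model.reactions:
        if not _is_reversible_mass_action(r):
            continue
        idxs.append(r.index)
        src = tuple(sorted(names[i] for i in r.reactant_indices))
        dst = tuple(sorted(names[i] for i in r.product_indices))
        g.add_node(src)
        g.add_node(dst)
        g.add_edge(
            src, dst, key=r.index,
            kf_name=r.parameter_names[0], kr_name=r.parameter_names[1],
            forward=(src, dst),
        )
    return ReversibleGraph(g, model, tuple(idxs))


@dataclass(frozen=True)
class CycleConstraint:
    """One independent reaction loop and (once assigned) its derived parameter.

    ``edges`` lists (reaction index, orientation sign); the Wegscheider
    condition for the loop is ∏ (kf/kr)^sign = 1.  After assignment the
    reverse rate constant named ``derived_parameter`` is recomputed from the
    other constants whenever :func:`apply_constraints` runs.
    """

    edges: tuple  # ((reaction_index, sign), ...)
    param_indices: tuple  # ((kf_index, kr_index), ...) aligned with edges
    derived_edge_pos: Optional[int] = None

    @property
    def derived_parameter_index(self) -> Optional[int]:
        if self.derived_edge_pos is None:
            return None
        return self.param_indices[self.derived_edge_pos][1]

    def formula(self, model: CompiledModel) -> str:
        if self.derived_edge_pos is None:
            return "<unassigned>"
        d = self.derived_edge_pos
        kf_d = model.parameters[self.param_indices[d][0]].name
        kr_d = model.parameters[self.param_indices[d][1]].name
        c_d = self.edges[d][1]
        parts = []
        for pos, ((_, sign), (kf_i, kr_i)) in enumerate(zip(self.edges, self.param_indices)):
            if pos == d:
                continue
            kf = model.parameters[kf_i].name
            kr = model.parameters[kr_i].name
            expo = sign / c_d
            parts.append(f"({kf}/{kr})^{expo:g}")
        return f"{kr_d} = {kf_d} * " + " * ".join(parts)

    def cycle_product(self, params: np.ndarray) -> float:
        """∏ over loop edges of (kf/kr)^sign at the given parameter values."""
        prod = 1.0
        for (_, sign), (kf_i, kr_i) in zip(self.edges, self.param_indices):
            prod *= (params[kf_i] / params[kr_i]) ** sign
        return prod


def cycle_basis(graph: ReversibleGraph) -> list:
    """Independent thermodynamic loops of the reversible subnetwork.

    Returns one (unassigned) :class:`CycleConstraint` per integer basis
    vector of the right null space of the reversible stoichiometric
    submatrix, in a deterministic order.  The count equals
    (#reversible reactions − rank), the graph-theoretic E − N + C of a
    faithful loop encoding.
    """
    model = graph.model
    idxs = list(graph.reversible_indices)
    if not idxs:
        return []
    S_rev = sp.Matrix(model.stoichiometric_matrix[:, idxs])
    null = S_rev.nullspace()
    out = []
    for v in null:
        from fractions import Fraction
        fracs = [Fraction(sp.Rational(x)) for x in v]
        denom = math.lcm(*(f.denominator for f in fracs))
        ints = [int(f * denom) for f in fracs]
        g = math.gcd(*(abs(x) for x in ints))
        if g > 1:
            ints = [x // g for x in ints]
        lead = next((x for x in ints if x != 0), 1)
        if lead < 0:
            ints = [-x for x in ints]
        edges = []
        pidx = []
        for pos, c in enumerate(ints):
            if c == 0:
                continue
            r = model.reactions[idxs[pos]]
            edges.append((r.index, int(c)))
            pidx.append(
                (model.parameter_index(r.parameter_names[0]),
                 model.parameter_index(r.parameter_names[1]))
            )
        out.append(CycleConstraint(tuple(edges), tuple(pidx)))
    out.sort(key=lambda c: c.edges)
    return out


def assign_constraints(model: CompiledModel, cycles: list) -> list:
    """Elect one derived reverse rate constant per loop and mark it on the model.

    The reverse constant of the highest-indexed reaction in the loop that is
    not already derived is eliminated; the number of free parameters drops by
    exactly the number of loops.
    """
    assigned = []
    taken = {i for i, p in enumerate(model.parameters) if p.status == "derived"}
    for cyc in cycles:
        candidates = [
            pos for pos, (_, _) in enumerate(cyc.edges)
            if cyc.param_indices[pos][1] not in taken
        ]
        if not candidates:
            raise ThermoError(
                "over-constrained: every reaction in cycle "
                f"{[e for e, _ in cyc.edges]} already has a derived parameter"
            )
        pos = max(candidates, key=lambda p: cyc.edges[p][0])
        cyc = replace(cyc, derived_edge_pos=pos)
        kr_idx = cyc.param_indices[pos][1]
        taken.add(kr_idx)
        model.parameters[kr_idx].status = "derived"
        model.parameters[kr_idx].constraint = cyc
        assigned.append(cyc)
    return assigned


def apply_constraints(params, constraints: list) -> np.ndarray:
    """Overwrite derived reverse rate constants so every loop product is one.

    Pure function: returns a new vector.  Raises on nonpositive rate
    constants (log-space formula undefined).
    """
    out = np.array(params, dtype=float)
    for cyc in constraints:
        if cyc.derived_edge_pos is None:
            raise ThermoError("constraint has no derived parameter assigned")
        d = cyc.derived_edge_pos
        kf_d_idx, kr_d_idx = cyc.param_indices[d]
        c_d = cyc.edges[d][1]
        log_p = 0.0
        for pos, ((_, sign), (kf_i, kr_i)) in enumerate(zip(cyc.edges, cyc.param_indices)):
            if pos == d:
                continue
            kf, kr = out[kf_i], out[kr_i]
            if kf <= 0 or kr <= 0:
                raise ThermoError("rate constants must be positive for detailed balance")
            log_p += sign * (math.log(kf) - math.log(kr))
        if out[kf_d_idx] <= 0:
            raise ThermoError("rate constants must be positive for detailed balance")
        # Keq_d = exp(-log_p / c_d); kr_d = kf_d / Keq_d
        out[kr_d_idx] = out[kf_d_idx] * math.exp(log_p / c_d)
    return out


def detect_and_constrain(model: CompiledModel) -> list:
    """Full pipeline: build graph, find loops, assign and apply constraints.

    Mutates parameter statuses/values on the model and returns the assigned
    constraints.
    """
    graph = build_reversible_graph(model)
    cycles = cycle_basis(graph)
    constraints = assign_constraints(model, cycles)
    if constraints:
        values = apply_constraints(model.parameter_values(), constraints)
        for p, v in zip(model.parameters, values):
            p.value = v
    return constraints


def constraint_report(model: CompiledModel, constraints: list) -> str:
    buf = io.StringIO()
    if not constraints:
        buf.write("No closed loops of reversible reactions detected.\n")
        return buf.getvalue()
    buf.write(f"{len(constraints)} independent loop(s) constrained by detailed balance:\n")
    for i, cyc in enumerate(constraints, 1):
        rxns = ", ".join(
            f"r{e + 1}({'+' if s > 0 else '-'}{abs(s) if abs(s) != 1 else ''})"
            for e, s in cyc.edges
        )
        buf.write(f"  loop {i}: reactions {rxns}\n")
        buf.write(f"    derived: {cyc.formula(model)}\n")
    return buf.getvalue()
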