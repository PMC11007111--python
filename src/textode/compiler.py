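"""Compile a parsed reaction model into an executable ODE system.

Each reaction type is mapped to a rate law through a :class:`RateLawRegistry`.
The built-in registry implements the three families standard in signaling
models — mass action, Michaelis–Menten and Hill — plus zeroth-order synthesis:

* bind / dissociate / state transition: reversible mass action
  ``kf·∏[reactants] − kr·∏[products]``
* enzymatic modification: irreversible Michaelis–Menten with explicit
  enzyme concentration, ``V·[E]·[S]/(K+[S])``
* transcription: Hill regulation ``V·[TF]^n/(K^n+[TF]^n)`` (template not consumed)
* translation / degradation: first-order mass action
* synthesis: zeroth order

The compiled object carries the species table, the parameter table, the
stoichiometric matrix S and a vectorised rate function, so that
``d(state)/dt = S · v(state, params)`` exactly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional, Sequence

import numpy as np
import sympy as sp

from .dsl import ParsedModel, ParsedReaction, RateFamily, ReactionType

__all__ = [
    "RateLawTemplate",
    "RateLawRegistry",
    "Species",
    "Parameter",
    "CompiledReaction",
    "CompiledModel",
    "CompileError",
    "default_registry",
    "register_rate_law",
    "compile_model",
    "rhs",
    "conserved_moieties",
    "model_report",
]

DEFAULT_VALUE = 1.0
DEFAULT_BOUNDS = (1e-3, 1e3)
HILL_N_DEFAULT = 2.0
HILL_N_BOUNDS = (1.0, 4.0)


class CompileError(ValueError):
    pass


# A builder receives sympy symbols for the reaction's participants and slots
# and returns the symbolic rate expression.
Builder = Callable[[dict, list, list, Optional[sp.Symbol]], sp.Expr]


@dataclass(frozen=True)
class RateLawTemplate:
    family: RateFamily
    parameter_slots: tuple[str, ...]
    builder: Builder
    slot_defaults: dict = field(default_factory=dict)
    slot_bounds: dict = field(default_factory=dict)

    def build(self, slots, reactants, products, enzyme) -> sp.Expr:
        return self.builder(slots, reactants, products, enzyme)


def _prod(xs: Sequence[sp.Symbol]) -> sp.Expr:
    out: sp.Expr = sp.Integer(1)
    for x in xs:
        out = out * x
    return out


def _mass_action_reversible(slots, reactants, products, enzyme):
    return slots["kf"] * _prod(reactants) - slots["kr"] * _prod(products)


def _mass_action_irreversible(slots, reactants, products, enzyme):
    # first-order in the template when there is no consumed reactant (translation)
    if not reactants and enzyme is not None:
        return slots["kf"] * enzyme
    return slots["kf"] * _prod(reactants)


def _michaelis_menten(slots, reactants, products, enzyme):
    (s,) = reactants
    return slots["V"] * enzyme * s / (slots["K"] + s)


def _hill(slots, reactants, products, enzyme):
    x = enzyme if enzyme is not None else reactants[0]
    n = slots["n"]
    return slots["V"] * x**n / (slots["K"] ** n + x**n)


def _zeroth(slots, reactants, products, enzyme):
    return slots["kf"]


_MA_REV = RateLawTemplate(RateFamily.MASS_ACTION, ("kf", "kr"), _mass_action_reversible)
_MA_IRR = RateLawTemplate(RateFamily.MASS_ACTION, ("kf",), _mass_action_irreversible)
_MM = RateLawTemplate(RateFamily.MICHAELIS_MENTEN, ("V", "K"), _michaelis_menten)
_HILL = RateLawTemplate(
    RateFamily.HILL, ("V", "K", "n"), _hill,
    slot_defaults={"n": HILL_N_DEFAULT}, slot_bounds={"n": HILL_N_BOUNDS},
)
_ZEROTH = RateLawTemplate(RateFamily.ZEROTH_ORDER, ("kf",), _zeroth)

_BUILTIN = {
    ReactionType.BIND: _MA_REV,
    ReactionType.DISSOCIATE: _MA_REV,
    ReactionType.STATE_TRANSITION: _MA_REV,
    ReactionType.ENZYMATIC_MODIFY: _MM,
    ReactionType.TRANSCRIBE: _HILL,
    ReactionType.TRANSLATE: _MA_IRR,
    ReactionType.DEGRADE: _MA_IRR,
    ReactionType.SYNTHESIZE: _ZEROTH,
}


@dataclass(frozen=True)
class RateLawRegistry:
    """Immutable mapping reaction type → rate-law template."""

    templates: dict

    def lookup(self, reaction_type) -> RateLawTemplate:
        key = reaction_type
        if key not in self.templates:
            raise CompileError(f"no rate law registered for reaction type {key!r}")
        return self.templates[key]

    def __contains__(self, reaction_type) -> bool:
        return reaction_type in self.templates


def default_registry() -> RateLawRegistry:
    return RateLawRegistry(dict(_BUILTIN))


def register_rate_law(
    registry: RateLawRegistry,
    reaction_type,
    template: RateLawTemplate,
    allow_overwrite: bool = False,
) -> RateLawRegistry:
    """Return a new registry with ``reaction_type`` mapped to ``template``.

    Overwriting one of the built-in entries requires ``allow_overwrite=True``.
    """
    if reaction_type in registry.templates and not allow_overwrite:
        raise CompileError(
            f"registering {reaction_type!r} would overwrite a built-in rate law; "
            "pass allow_overwrite=True to replace it"
        )
    new = dict(registry.templates)
    new[reaction_type] = template
    return RateLawRegistry(new)


@dataclass
class Species:
    name: str
    index: int
    initial_amount: float = 0.0


@dataclass
class Parameter:
    name: str
    value: float = DEFAULT_VALUE
    lower_bound: float = DEFAULT_BOUNDS[0]
    upper_bound: float = DEFAULT_BOUNDS[1]
    status: str = "free"  # free | fixed | derived
    constraint: object = None  # CycleConstraint for derived parameters


@dataclass(frozen=True)
class CompiledReaction:
    index: int  # 0-based
    line_number: int
    reaction_type: ReactionType
    reversible: bool
    rate_expr: sp.Expr
    reactant_indices: tuple[int, ...]
    product_indices: tuple[int, ...]
    enzyme_index: Optional[int]
    parameter_names: tuple[str, ...]  # slot order


@dataclass
class CompiledModel:
    species: list
    parameters: list
    reactions: list
    stoichiometric_matrix: np.ndarray  # species x reactions, int
    observables: dict  # name -> coefficient vector over species
    conditions: dict  # name -> {species: initial amount}
    source_name: str = "<string>"

    # --- lookups -----------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def species_names(self) -> list:
        return [s.name for s in self.species]

    @property
    def parameter_names(self) -> list:
        return [p.name for p in self.parameters]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def parameter_index(self, name: str) -> int:
        try:
            return self.parameter_names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def parameter_values(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters], dtype=float)

    def initial_state(self, overrides=None) -> np.ndarray:
        y0 = np.array([s.initial_amount for s in self.species], dtype=float)
        for name, val in (overrides or {}).items():
            y0[self.species_index(name)] = val
        return y0

    def free_parameter_indices(self) -> list:
        return [i for i, p in enumerate(self.parameters) if p.status == "free"]

    # --- numerics ----------------------------------------------------------
    def _ensure_rate_fn(self):
        if getattr(self, "_rate_fn", None) is None:
            y_syms = [sp.Symbol(f"__y{i}") for i in range(self.n_species)]
            p_syms = [sp.Symbol(p.name) for p in self.parameters]
            subs = {sp.Symbol(s.name): y_syms[i] for i, s in enumerate(self.species)}
            exprs = [r.rate_expr.xreplace(subs) for r in self.reactions]
            self._rate_fn = sp.lambdify([y_syms, p_syms], exprs, modules="numpy")
        return self._rate_fn

    def rates(self, state, params, rate_scales=None) -> np.ndarray:
        state = np.asarray(state, dtype=float)
        params = np.asarray(params, dtype=float)
        if state.shape != (self.n_species,):
            raise ValueError(f"state must have length {self.n_species}, got {state.shape}")
        if params.shape != (self.n_parameters,):
            raise ValueError(f"params must have length {self.n_parameters}, got {params.shape}")
        v = np.asarray(self._ensure_rate_fn()(list(state), list(params)), dtype=float)
        if rate_scales is not None:
            v = v * np.asarray(rate_scales, dtype=float)
        return v

    def rhs(self, state, params, rate_scales=None) -> np.ndarray:
        """Time derivative S·v(state, params)."""
        return self.stoichiometric_matrix @ self.rates(state, params, rate_scales)

    def _ensure_ode_fn(self):
        """Flat-scalar lambdified dy/dt = S·v, fast enough for inner fit loops."""
        if getattr(self, "_ode_fn", None) is None:
            y_syms = [sp.Symbol(s.name) for s in self.species]
            p_syms = [sp.Symbol(p.name) for p in self.parameters]
            v = sp.Matrix([r.rate_expr for r in self.reactions])
            dydt = sp.Matrix(self.stoichiometric_matrix) * v
            self._ode_fn = sp.lambdify(y_syms + p_syms, list(dydt), modules="math")
        return self._ode_fn

    def ode_callable(self, params, rate_scales=None):
        """Return f(t, y) for scipy solvers with the parameters baked in."""
        params = np.asarray(params, dtype=float)
        if params.shape != (self.n_parameters,):
            raise ValueError(f"params must have length {self.n_parameters}, got {params.shape}")
        if rate_scales is not None:
            S = self.stoichiometric_matrix
            scales = np.asarray(rate_scales, dtype=float)
            return lambda t, y: S @ (self.rates(y, params, scales))
        f = self._ensure_ode_fn()
        p = tuple(params)
        return lambda t, y: f(*y, *p)


def rhs(model: CompiledModel, state, params) -> np.ndarray:
    return model.rhs(state, params)


def compile_model(parsed: ParsedModel, registry: Optional[RateLawRegistry] = None) -> CompiledModel:
    """Build the executable ODE system from a parsed model.

    Species are enumerated in order of first textual appearance; each reaction
    gets its own parameters named ``<slot>_r<index>`` with 1-based indices.
    Enzymes/templates are modifiers: they enter the rate law but not the
    stoichiometric column.
    """
    registry = registry or default_registry()
    # species in first-appearance order
    names: list[str] = []
    for r in parsed.reactions:
        for s in r.species:
            if s not in names:
                names.append(s)
    species = [Species(n, i) for i, n in enumerate(names)]
    index = {n: i for i, n in enumerate(names)}

    parameters: list[Parameter] = []
    reactions: list[CompiledReaction] = []
    S = np.zeros((len(species), len(parsed.reactions)), dtype=int)
    for j, r in enumerate(parsed.reactions):
        try:
            template = registry.lookup(r.reaction_type)
        except CompileError as e:
            raise CompileError(f"line {r.line_number}: {e}") from None
        overrides = dict(r.parameter_overrides)
        unknown = set(overrides) - set(template.parameter_slots)
        if unknown:
            raise CompileError(
                f"line {r.line_number}: overrides {sorted(unknown)} not in slots "
                f"{template.parameter_slots}"
            )
        slot_syms: dict[str, sp.Symbol] = {}
        pnames: list[str] = []
        for slot in template.parameter_slots:
            pname = f"{slot}_r{j + 1}"
            value = overrides.get(slot, template.slot_defaults.get(slot, DEFAULT_VALUE))
            lo, hi = template.slot_bounds.get(slot, DEFAULT_BOUNDS)
            parameters.append(Parameter(pname, value, lo, hi))
            slot_syms[slot] = sp.Symbol(pname)
            pnames.append(pname)
        r_syms = [sp.Symbol(s) for s in r.reactants]
        p_syms = [sp.Symbol(s) for s in r.products]
        e_sym = sp.Symbol(r.enzyme) if r.enzyme else None
        expr = template.build(slot_syms, r_syms, p_syms, e_sym)
        reactions.append(
            CompiledReaction(
                j, r.line_number, r.reaction_type, r.reversible, expr,
                tuple(index[s] for s in r.reactants),
                tuple(index[s] for s in r.products),
                index[r.enzyme] if r.enzyme else None,
                tuple(pnames),
            )
        )
        for s in r.reactants:
            S[index[s], j] -= 1
        for s in r.products:
            S[index[s], j] += 1

    model = CompiledModel(species, parameters, reactions, S, {}, {}, parsed.source_name)

    # apply directives
    for d in parsed.directives_of("init"):
        species[index[d.arguments[0]]].initial_amount = d.arguments[1]
    for d in parsed.directives_of("obs"):
        name, terms = d.arguments
        vec = np.zeros(len(species))
        for coef, spname in terms:
            vec[index[spname]] += coef
        model.observables[name] = vec
    for d in parsed.directives_of("sim_condition"):
        name, overrides_ = d.arguments
        model.conditions[name] = dict(overrides_)
    pidx = {p.name: p for p in parameters}
    for d in parsed.directives_of("param_bound"):
        pname, lo, hi = d.arguments
        if pname not in pidx:
            raise CompileError(f"line {d.line_number}: unknown parameter {pname!r} in @param_bound")
        pidx[pname].lower_bound = lo
        pidx[pname].upper_bound = hi
        pidx[pname].value = min(max(pidx[pname].value, lo), hi)
    return model


def conserved_moieties(model: CompiledModel) -> list:
    """Integer basis of the left null space of the stoichiometric matrix.

    Each returned vector c satisfies cᵀS = 0, i.e. c·state is constant along
    any trajectory.  Vectors are scaled to smallest integers with positive
    leading entry.
    """
    S = sp.Matrix(model.stoichiometric_matrix)
    basis = S.T.nullspace()
    out = []
    for v in basis:
        fracs = [Fraction(sp.Rational(x)) for x in v]
        denom = math.lcm(*(f.denominator for f in fracs)) if fracs else 1
        ints = [int(f * denom) for f in fracs]
        g = math.gcd(*(abs(x) for x in ints)) if ints else 1
        if g > 1:
            ints = [x // g for x in ints]
        lead = next((x for x in ints if x != 0), 1)
        if lead < 0:
            ints = [-x for x in ints]
        out.append(np.array(ints, dtype=int))
    return out


def model_report(model: CompiledModel) -> str:
    """Human-readable summary: species, parameters, reactions with rate laws."""
    buf = io.StringIO()
    buf.write(f"Model: {model.source_name}\n")
    buf.write(f"{model.n_species} species, {len(model.reactions)} reactions, "
              f"{model.n_parameters} parameters\n\n")
    buf.write("Species (index, name, initial amount):\n")
    for s in model.species:
        buf.write(f"  {s.index:3d}  {s.name:<20s} {s.initial_amount:g}\n")
    buf.write("\nParameters (name, value, bounds, status):\n")
    for p in model.parameters:
        buf.write(f"  {p.name:<12s} {p.value:<10g} [{p.lower_bound:g}, {p.upper_bound:g}]  {p.status}\n")
    buf.write("\nReactions (index, line, rate law):\n")
    for r in model.reactions:
        buf.write(f"  r{r.index + 1} (line {r.line_number}): v = {r.rate_expr}\n")
    if model.observables:
        buf.write("\nObservables:\n")
        for name, vec in model.observables.items():
            terms = " + ".join(
                f"{c:g}*{model.species[i].name}" for i, c in enumerate(vec) if c != 0
            )
            buf.write(f"  {name} = {terms}\n")
    return buf.getvalue()
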