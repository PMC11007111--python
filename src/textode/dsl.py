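"""Line-oriented reaction DSL.

A model file declares one biochemical reaction per line in a constrained
natural-language style::

    EGF binds EGFR --> EGF_EGFR
    EGF_EGFR phosphorylates ERK --> pERK
    pERK is dephosphorylated --> ERK
    pERK transcribes MYC_mRNA
    MYC_mRNA is translated into MYC
    MYC is degraded

Directive lines start with ``@`` and attach observables, initial amounts,
simulation conditions and fit bounds to the reaction network.  ``#`` starts
a comment; blank lines are ignored.

Verb inventory
--------------
========================================  ==================  ==========  ============
line form                                 reaction type       reversible  rate family
========================================  ==================  ==========  ============
``A binds B --> AB``                      bind                yes         mass action
``AB is dissociated into A and B``        dissociate          yes         mass action
``E phosphorylates S --> pS``             enzymatic_modify    no          Michaelis-Menten
``E dephosphorylates pS --> S``           enzymatic_modify    no          Michaelis-Menten
``S is phosphorylated --> pS``            state_transition    yes         mass action
``pS is dephosphorylated --> S``          state_transition    yes         mass action
``TF transcribes M``                      transcribe          no          Hill
``M is translated into P``                translate           no          mass action
``X is degraded``                         degrade             no          mass action
``X is synthesized``                      synthesize          no          zeroth order
========================================  ==================  ==========  ============

Any reaction line may carry a trailing ``| name=value, ...`` clause that
overrides the default values of that line's rate parameters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "ReactionType",
    "RateFamily",
    "StatementKind",
    "Statement",
    "ParsedReaction",
    "Directive",
    "ParsedModel",
    "Issue",
    "DslError",
    "ModelParseError",
    "parse_line",
    "parse_model",
    "validate_model",
    "render_model",
]

SPECIES_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*$")
NUMBER_RE = re.compile(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?$")


class ReactionType(str, Enum):
    BIND = "bind"
    DISSOCIATE = "dissociate"
    STATE_TRANSITION = "state_transition"
    ENZYMATIC_MODIFY = "enzymatic_modify"
    TRANSCRIBE = "transcribe"
    TRANSLATE = "translate"
    SYNTHESIZE = "synthesize"
    DEGRADE = "degrade"
    CUSTOM = "custom"


class RateFamily(str, Enum):
    MASS_ACTION = "mass_action"
    MICHAELIS_MENTEN = "michaelis_menten"
    HILL = "hill"
    ZEROTH_ORDER = "zeroth_order"


class StatementKind(str, Enum):
    REACTION = "reaction"
    DIRECTIVE = "directive"
    COMMENT = "comment"
    BLANK = "blank"


class DslError(ValueError):
    """A single parse/validation error tied to a source line."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        self.message = message
        super().__init__(f"line {line_number}: {message}")


class ModelParseError(ValueError):
    """Aggregate of all errors found while parsing a model file."""

    def __init__(self, errors: list[DslError], source_name: str = "<string>"):
        self.errors = errors
        self.source_name = source_name
        lines = "\n".join(f"  {e}" for e in errors)
        super().__init__(f"{len(errors)} error(s) in {source_name}:\n{lines}")


@dataclass(frozen=True)
class ParsedReaction:
    reaction_type: ReactionType
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    enzyme: Optional[str]  # catalyst (MM) or non-consumed template (transcribe/translate)
    reversible: bool
    rate_family: RateFamily
    parameter_overrides: tuple[tuple[str, float], ...]
    line_number: int
    modification: Optional[str] = None  # "phosphorylate"/"dephosphorylate" for enzymatic lines

    @property
    def species(self) -> tuple[str, ...]:
        """All participant names in role order (enzyme, reactants, products)."""
        out: list[str] = []
        if self.enzyme:
            out.append(self.enzyme)
        out.extend(self.reactants)
        out.extend(self.products)
        return tuple(out)

    def signature(self) -> tuple:
        """Identity of the chemistry, ignoring line number and overrides."""
        return (
            self.reaction_type,
            self.reactants,
            self.products,
            self.enzyme,
            self.modification,
        )


@dataclass(frozen=True)
class Directive:
    keyword: str  # obs | init | sim_condition | param_bound
    arguments: tuple
    line_number: int


@dataclass(frozen=True)
class Statement:
    raw_text: str
    line_number: int
    kind: StatementKind
    payload: Optional[object] = None  # ParsedReaction or Directive


@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    line_number: int
    message: str


@dataclass(frozen=True)
class ParsedModel:
    reactions: tuple[ParsedReaction, ...]
    directives: tuple[Directive, ...]
    source_name: str = "<string>"

    def directives_of(self, keyword: str) -> tuple[Directive, ...]:
        return tuple(d for d in self.directives if d.keyword == keyword)


# ---------------------------------------------------------------------------
# Line grammar
# ---------------------------------------------------------------------------

_ARROW = r"-->"
_SP = r"([A-Za-z_][A-Za-z0-9_]*)"

# Patterns tried in order; first match wins.
_REACTION_PATTERNS: list[tuple[re.Pattern, str]] = [
    (re.compile(rf"{_SP}\s+binds\s+{_SP}\s*{_ARROW}\s*{_SP}$"), "bind"),
    (re.compile(rf"{_SP}\s+is\s+dissociated\s+into\s+{_SP}\s+and\s+{_SP}$"), "dissociate"),
    (re.compile(rf"{_SP}\s+phosphorylates\s+{_SP}\s*{_ARROW}\s*{_SP}$"), "phosphorylates"),
    (re.compile(rf"{_SP}\s+dephosphorylates\s+{_SP}\s*{_ARROW}\s*{_SP}$"), "dephosphorylates"),
    (re.compile(rf"{_SP}\s+is\s+phosphorylated\s*{_ARROW}\s*{_SP}$"), "is_phosphorylated"),
    (re.compile(rf"{_SP}\s+is\s+dephosphorylated\s*{_ARROW}\s*{_SP}$"), "is_dephosphorylated"),
    (re.compile(rf"{_SP}\s+transcribes\s+{_SP}$"), "transcribes"),
    (re.compile(rf"{_SP}\s+is\s+translated\s+into\s+{_SP}$"), "is_translated"),
    (re.compile(rf"{_SP}\s+is\s+degraded$"), "is_degraded"),
    (re.compile(rf"{_SP}\s+is\s+synthesized$"), "is_synthesized"),
]

# rate-parameter slots each line form may override
_ALLOWED_OVERRIDES = {
    "bind": {"kf", "kr"},
    "dissociate": {"kf", "kr"},
    "phosphorylates": {"V", "K"},
    "dephosphorylates": {"V", "K"},
    "is_phosphorylated": {"kf", "kr"},
    "is_dephosphorylated": {"kf", "kr"},
    "transcribes": {"V", "K", "n"},
    "is_translated": {"kf"},
    "is_degraded": {"kf"},
    "is_synthesized": {"kf"},
}


def _parse_overrides(clause: str, line_number: int, allowed: set[str]) -> tuple[tuple[str, float], ...]:
    out: list[tuple[str, float]] = []
    for item in clause.split(","):
        item = item.strip()
        if not item:
            raise DslError(line_number, "empty override entry")
        if "=" not in item:
            raise DslError(line_number, f"malformed override {item!r} (expected name=value)")
        name, _, val = item.partition("=")
        name, val = name.strip(), val.strip()
        if name not in allowed:
            raise DslError(
                line_number,
                f"unknown override {name!r} for this rate law (allowed: {sorted(allowed)})",
            )
        if not NUMBER_RE.match(val):
            raise DslError(line_number, f"malformed override value {val!r}")
        out.append((name, float(val)))
    seen = [n for n, _ in out]
    if len(seen) != len(set(seen)):
        raise DslError(line_number, "duplicate override name")
    return tuple(out)


def _build_reaction(form: str, groups: tuple[str, ...], overrides, line_number: int) -> ParsedReaction:
    T = ReactionType
    F = RateFamily
    if form == "bind":
        a, b, ab = groups
        return ParsedReaction(T.BIND, (a, b), (ab,), None, True, F.MASS_ACTION, overrides, line_number)
    if form == "dissociate":
        ab, a, b = groups
        return ParsedReaction(T.DISSOCIATE, (ab,), (a, b), None, True, F.MASS_ACTION, overrides, line_number)
    if form in ("phosphorylates", "dephosphorylates"):
        e, s, p = groups
        mod = "phosphorylate" if form == "phosphorylates" else "dephosphorylate"
        return ParsedReaction(
            T.ENZYMATIC_MODIFY, (s,), (p,), e, False, F.MICHAELIS_MENTEN, overrides, line_number, mod
        )
    if form in ("is_phosphorylated", "is_dephosphorylated"):
        s, p = groups
        mod = "phosphorylate" if form == "is_phosphorylated" else "dephosphorylate"
        return ParsedReaction(
            T.STATE_TRANSITION, (s,), (p,), None, True, F.MASS_ACTION, overrides, line_number, mod
        )
    if form == "transcribes":
        tf, m = groups
        return ParsedReaction(T.TRANSCRIBE, (), (m,), tf, False, F.HILL, overrides, line_number)
    if form == "is_translated":
        m, p = groups
        return ParsedReaction(T.TRANSLATE, (), (p,), m, False, F.MASS_ACTION, overrides, line_number)
    if form == "is_degraded":
        (x,) = groups
        return ParsedReaction(T.DEGRADE, (x,), (), None, False, F.MASS_ACTION, overrides, line_number)
    if form == "is_synthesized":
        (x,) = groups
        return ParsedReaction(T.SYNTHESIZE, (), (x,), None, False, F.ZEROTH_ORDER, overrides, line_number)
    raise AssertionError(form)


def _parse_obs_expr(expr: str, line_number: int) -> tuple[tuple[float, str], ...]:
    """Parse a linear combination like ``pA + 2*pA_B`` into (coef, species) terms."""
    terms: list[tuple[float, str]] = []
    for raw in expr.split("+"):
        raw = raw.strip()
        if not raw:
            raise DslError(line_number, "empty term in observable expression")
        if "*" in raw:
            coef_s, _, sp = raw.partition("*")
            coef_s, sp = coef_s.strip(), sp.strip()
            if not NUMBER_RE.match(coef_s):
                raise DslError(line_number, f"bad coefficient {coef_s!r}")
            coef = float(coef_s)
        else:
            coef, sp = 1.0, raw
        if not SPECIES_RE.match(sp):
            raise DslError(line_number, f"bad species name {sp!r} in observable")
        terms.append((coef, sp))
    return tuple(terms)


def _parse_directive(body: str, line_number: int) -> Directive:
    m = re.match(r"(\w+)\s*(.*)$", body)
    if not m:
        raise DslError(line_number, "malformed directive")
    keyword, rest = m.group(1), m.group(2).strip()
    if keyword == "obs":
        m2 = re.match(rf"{_SP}\s*:\s*(.+)$", rest)
        if not m2:
            raise DslError(line_number, "expected '@obs name: expr'")
        name, expr = m2.group(1), m2.group(2)
        return Directive("obs", (name, _parse_obs_expr(expr, line_number)), line_number)
    if keyword == "init":
        m2 = re.match(rf"{_SP}\s*=\s*(\S+)$", rest)
        if not m2 or not NUMBER_RE.match(m2.group(2)):
            raise DslError(line_number, "expected '@init Species = value'")
        value = float(m2.group(2))
        if value < 0:
            raise DslError(line_number, "initial amount must be nonnegative")
        return Directive("init", (m2.group(1), value), line_number)
    if keyword == "sim_condition":
        m2 = re.match(rf"{_SP}\s*:\s*(.+)$", rest)
        if not m2:
            raise DslError(line_number, "expected '@sim_condition name: Species=value, ...'")
        name = m2.group(1)
        overrides: list[tuple[str, float]] = []
        for item in m2.group(2).split(","):
            item = item.strip()
            m3 = re.match(rf"{_SP}\s*=\s*(\S+)$", item)
            if not m3 or not NUMBER_RE.match(m3.group(2)):
                raise DslError(line_number, f"malformed condition override {item!r}")
            overrides.append((m3.group(1), float(m3.group(2))))
        return Directive("sim_condition", (name, tuple(overrides)), line_number)
    if keyword == "param_bound":
        m2 = re.match(r"(\w+)\s*=\s*(\S+)\s*,\s*(\S+)$", rest)
        if not m2 or not NUMBER_RE.match(m2.group(2)) or not NUMBER_RE.match(m2.group(3)):
            raise DslError(line_number, "expected '@param_bound name = lower, upper'")
        lo, hi = float(m2.group(2)), float(m2.group(3))
        if not (0 < lo <= hi):
            raise DslError(line_number, "bounds must satisfy 0 < lower <= upper")
        return Directive("param_bound", (m2.group(1), lo, hi), line_number)
    raise DslError(line_number, f"unknown directive @{keyword}")


def parse_line(text: str, line_number: int) -> Statement:
    """Classify one physical line and parse its payload.

    Raises :class:`DslError` on a malformed reaction or directive line.
    """
    if "\n" in text or "\r" in text:
        raise DslError(line_number, "parse_line expects a single physical line")
    raw = text
    stripped = text.strip()
    if not stripped:
        return Statement(raw, line_number, StatementKind.BLANK)
    if stripped.startswith("#"):
        return Statement(raw, line_number, StatementKind.COMMENT)
    # trailing comment
    code = stripped.split("#", 1)[0].strip()
    if not code:
        return Statement(raw, line_number, StatementKind.COMMENT)
    if code.startswith("@"):
        return Statement(raw, line_number, StatementKind.DIRECTIVE, _parse_directive(code[1:], line_number))
    # split off override clause
    override_clause = None
    if "|" in code:
        code, _, override_clause = code.partition("|")
        code = code.strip()
    for pattern, form in _REACTION_PATTERNS:
        m = pattern.match(code)
        if m:
            overrides: tuple[tuple[str, float], ...] = ()
            if override_clause is not None:
                overrides = _parse_overrides(override_clause, line_number, _ALLOWED_OVERRIDES[form])
            return Statement(
                raw, line_number, StatementKind.REACTION,
                _build_reaction(form, m.groups(), overrides, line_number),
            )
    # best-effort diagnosis: name the first token not recognised as a species/keyword
    tokens = code.split()
    verb = tokens[1] if len(tokens) > 1 else (tokens[0] if tokens else code)
    raise DslError(line_number, f"unknown reaction pattern (unmatched token {verb!r})")


def parse_model(text: str, source_name: str = "<string>") -> ParsedModel:
    """Parse a whole model file, aggregating every line error before raising."""
    errors: list[DslError] = []
    reactions: list[ParsedReaction] = []
    directives: list[Directive] = []
    for i, line in enumerate(text.splitlines(), start=1):
        try:
            st = parse_line(line, i)
        except DslError as e:
            errors.append(e)
            continue
        if st.kind is StatementKind.REACTION:
            reactions.append(st.payload)  # type: ignore[arg-type]
        elif st.kind is StatementKind.DIRECTIVE:
            directives.append(st.payload)  # type: ignore[arg-type]
    # duplicate identical reactions
    seen: dict[tuple, int] = {}
    for r in reactions:
        sig = r.signature()
        if sig in seen:
            errors.append(
                DslError(r.line_number, f"duplicate reaction (first declared on line {seen[sig]})")
            )
        else:
            seen[sig] = r.line_number
    if not reactions and not errors:
        errors.append(DslError(0, "no reactions in model"))
    reaction_species = {s for r in reactions for s in r.species}
    for d in directives:
        named: list[str] = []
        if d.keyword == "obs":
            named = [sp for _, sp in d.arguments[1]]
        elif d.keyword == "init":
            named = [d.arguments[0]]
        elif d.keyword == "sim_condition":
            named = [sp for sp, _ in d.arguments[1]]
        for sp in named:
            if sp not in reaction_species:
                errors.append(DslError(d.line_number, f"directive references unknown species {sp!r}"))
    if errors:
        raise ModelParseError(errors, source_name)
    return ParsedModel(tuple(reactions), tuple(directives), source_name)


def validate_model(model: ParsedModel) -> list[Issue]:
    """Static checks beyond grammar; returns issues, never raises.

    Warnings flag species that are consumed or catalytic but have no source
    (no producing reaction and no ``@init``) — a common omission in
    machine-generated models.
    """
    issues: list[Issue] = []
    produced = {s for r in model.reactions for s in r.products}
    synthesized = {s for r in model.reactions if r.reaction_type is ReactionType.SYNTHESIZE for s in r.products}
    produced |= synthesized
    inited = {d.arguments[0] for d in model.directives_of("init") if d.arguments[1] > 0}
    for r in model.reactions:
        participants = list(r.reactants) + ([r.enzyme] if r.enzyme else [])
        for sp in participants:
            if sp not in produced and sp not in inited:
                issues.append(
                    Issue("warning", r.line_number, f"{sp} has no source and no initial value")
                )
    reaction_species = {s for r in model.reactions for s in r.species}
    for d in model.directives_of("obs"):
        for _, sp in d.arguments[1]:
            if sp not in reaction_species:
                issues.append(Issue("error", d.line_number, f"observable references unknown species {sp!r}"))
    # deduplicate
    out: list[Issue] = []
    seen: set[tuple] = set()
    for i in issues:
        key = (i.severity, i.line_number, i.message)
        if key not in seen:
            seen.add(key)
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# Canonical renderer
# ---------------------------------------------------------------------------

def _render_reaction(r: ParsedReaction) -> str:
    T = ReactionType
    if r.reaction_type is T.BIND:
        core = f"{r.reactants[0]} binds {r.reactants[1]} --> {r.products[0]}"
    elif r.reaction_type is T.DISSOCIATE:
        core = f"{r.reactants[0]} is dissociated into {r.products[0]} and {r.products[1]}"
    elif r.reaction_type is T.ENZYMATIC_MODIFY:
        verb = "phosphorylates" if r.modification == "phosphorylate" else "dephosphorylates"
        core = f"{r.enzyme} {verb} {r.reactants[0]} --> {r.products[0]}"
    elif r.reaction_type is T.STATE_TRANSITION:
        verb = "is phosphorylated" if r.modification == "phosphorylate" else "is dephosphorylated"
        core = f"{r.reactants[0]} {verb} --> {r.products[0]}"
    elif r.reaction_type is T.TRANSCRIBE:
        core = f"{r.enzyme} transcribes {r.products[0]}"
    elif r.reaction_type is T.TRANSLATE:
        core = f"{r.enzyme} is translated into {r.products[0]}"
    elif r.reaction_type is T.DEGRADE:
        core = f"{r.reactants[0]} is degraded"
    elif r.reaction_type is T.SYNTHESIZE:
        core = f"{r.products[0]} is synthesized"
    else:
        raise ValueError(f"cannot render reaction type {r.reaction_type}")
    if r.parameter_overrides:
        clause = ", ".join(f"{k}={_fmt(v)}" for k, v in r.parameter_overrides)
        core += f" | {clause}"
    return core


def _fmt(x: float) -> str:
    return repr(x) if x != int(x) else str(int(x))


def _render_directive(d: Directive) -> str:
    if d.keyword == "obs":
        name, terms = d.arguments
        expr = " + ".join(sp if c == 1.0 else f"{_fmt(c)}*{sp}" for c, sp in terms)
        return f"@obs {name}: {expr}"
    if d.keyword == "init":
        return f"@init {d.arguments[0]} = {_fmt(d.arguments[1])}"
    if d.keyword == "sim_condition":
        name, overrides = d.arguments
        body = ", ".join(f"{sp}={_fmt(v)}" for sp, v in overrides)
        return f"@sim_condition {name}: {body}"
    if d.keyword == "param_bound":
        return f"@param_bound {d.arguments[0]} = {_fmt(d.arguments[1])}, {_fmt(d.arguments[2])}"
    raise ValueError(d.keyword)


def render_model(model: ParsedModel) -> str:
    """Emit canonical DSL text; ``parse_model(render_model(m))`` equals ``m``
    up to line numbers and source name."""
    lines = [_render_reaction(r) for r in model.reactions]
    lines += [_render_directive(d) for d in model.directives]
    return "\n".join(lines) + "\n"
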