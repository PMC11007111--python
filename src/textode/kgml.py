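"""KGML pathway import and conversion to reaction DSL text.

KEGG PATHWAY stores each map as a KGML XML file: ``entry`` elements (genes,
compounds, groups, map links) with a ``graphics`` child carrying display
names, and ``relation`` elements typed PPrel/GErel/... with ``subtype``
children (activation, phosphorylation, inhibition, binding/association,
expression, ...).

KEGG diagrams do not carry the activated/phosphorylated states of proteins
as separate nodes, so an executable model needs intermediate species: for
every gene entry targeted by an activating relation we introduce an active
form ("p"+name when phosphorylation is evidenced among the incoming
subtypes, "a"+name otherwise) and re-source that entry's outgoing relations
from the active form.  Conversion then maps each relation to one DSL line,
adds first-order reversion lines for active forms lacking an explicit
deactivator, and appends user-requested degradation lines.  Every manual
step is reified in :class:`ConversionOptions` so the pipeline is fully
scriptable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .dsl import parse_model

__all__ = [
    "KgmlEntry",
    "KgmlRelation",
    "PathwayNetwork",
    "ConversionOptions",
    "ConversionReport",
    "KgmlError",
    "parse_kgml",
    "expand_states",
    "network_to_text",
]

logger = logging.getLogger(__name__)

ENTRY_TYPES = {"gene", "compound", "group", "map", "ortholog"}
RELATION_TYPES = {"PPrel", "GErel", "PCrel", "ECrel"}
SUBTYPES = {
    "activation", "inhibition", "phosphorylation", "dephosphorylation",
    "binding/association", "expression", "repression", "indirect effect",
}
ACTIVATING = {"activation", "phosphorylation"}
DEACTIVATING = {"inhibition", "dephosphorylation"}


class KgmlError(ValueError):
    pass


@dataclass(frozen=True)
class KgmlEntry:
    id: str
    entry_type: str  # gene | compound | group | map | ortholog | other
    display_name: str  # first token of the graphics name
    member_ids: tuple = ()


@dataclass(frozen=True)
class KgmlRelation:
    source: str
    target: str
    relation_type: str  # PPrel | GErel | PCrel | ECrel | other
    subtypes: frozenset


@dataclass
class PathwayNetwork:
    name: str
    entries: dict  # id -> KgmlEntry
    relations: list  # [KgmlRelation] in document order
    state_expanded: bool = False
    species_of: dict = field(default_factory=dict)  # entry id -> base species name
    active_form: dict = field(default_factory=dict)  # entry id -> active species name
    provenance: dict = field(default_factory=dict)  # generated species -> origin


@dataclass(frozen=True)
class ConversionOptions:
    add_reverse_reactions: bool = True
    degradation_species: tuple = ()
    skip_subtypes: frozenset = frozenset({"indirect effect"})
    group_policy: str = "complex_species"  # or "expand_members"


@dataclass
class ConversionReport:
    n_entries: int
    n_relations: int
    n_lines: int
    n_skipped: int
    skipped: list


def _display_name(graphics_name: str, fallback: str) -> str:
    if not graphics_name:
        return fallback
    first = graphics_name.split(",")[0].strip()
    # KEGG names may end with "..." on truncated alias lists
    first = first.rstrip(".")
    return _sanitize(first) or fallback


def _sanitize(name: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in name)
    if out and out[0].isdigit():
        out = "_" + out
    return out


def parse_kgml(xml_text) -> PathwayNetwork:
    """Parse KGML into entries and typed relations.

    Relations with a missing endpoint are dropped with a logged warning; a
    pathway with no entries is an error.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as e:
        raise KgmlError(f"malformed KGML: {e}") from None
    if root.tag != "pathway":
        raise KgmlError(f"expected <pathway> root element, got <{root.tag}>")
    entries: dict[str, KgmlEntry] = {}
    for el in root.findall("entry"):
        eid = el.get("id")
        etype = el.get("type", "other")
        if etype not in ENTRY_TYPES:
            etype = "other"
        graphics = el.find("graphics")
        gname = graphics.get("name", "") if graphics is not None else ""
        members = tuple(c.get("id") for c in el.findall("component"))
        entries[eid] = KgmlEntry(eid, etype, _display_name(gname, f"entry{eid}"), members)
    if not entries:
        raise KgmlError("empty pathway: no entries")
    for e in entries.values():
        for m in e.member_ids:
            if m not in entries:
                raise KgmlError(f"group {e.id} references unknown member {m}")
    relations = []
    for el in root.findall("relation"):
        src, tgt = el.get("entry1"), el.get("entry2")
        if src not in entries or tgt not in entries:
            logger.warning("dropping relation %s->%s: unknown endpoint", src, tgt)
            continue
        rtype = el.get("type", "other")
        if rtype not in RELATION_TYPES:
            rtype = "other"
        subs = frozenset(
            s.get("name") if s.get("name") in SUBTYPES else "other"
            for s in el.findall("subtype")
        ) or frozenset({"other"})
        relations.append(KgmlRelation(src, tgt, rtype, subs))
    return PathwayNetwork(root.get("name", ""), entries, relations)


def _species_candidates(network: PathwayNetwork, options: ConversionOptions) -> dict:
    """Base species name per entry eligible for species generation."""
    out = {}
    for e in network.entries.values():
        if e.entry_type in ("map", "compound"):
            continue
        if e.entry_type == "group":
            names = [network.entries[m].display_name for m in e.member_ids]
            out[e.id] = "_".join(names) if names else e.display_name
        else:
            out[e.id] = e.display_name
    return out


def expand_states(network: PathwayNetwork, options: Optional[ConversionOptions] = None) -> PathwayNetwork:
    """Add intermediate active-form species for every activated entry.

    Each gene/group entry that is the target of at least one activating
    relation (subtype activation or phosphorylation) receives exactly one
    active form; its outgoing relations are re-sourced from that form during
    conversion.  Raises if called on an already expanded network.
    """
    if network.state_expanded:
        raise KgmlError("network already expanded")
    options = options or ConversionOptions()
    species_of = _species_candidates(network, options)
    active_form: dict[str, str] = {}
    provenance: dict[str, tuple] = {}
    taken = set(species_of.values())
    for eid, base in species_of.items():
        incoming = [
            r for r in network.relations
            if r.target == eid and (r.subtypes & ACTIVATING) and r.source in species_of
        ]
        if not incoming:
            continue
        prefix = "p" if any("phosphorylation" in r.subtypes for r in incoming) else "a"
        form = prefix + base
        if form in taken:
            raise KgmlError(f"active-form name collision: {form!r} already exists")
        taken.add(form)
        active_form[eid] = form
        provenance[form] = ("active_form", eid)
    return PathwayNetwork(
        network.name, network.entries, network.relations, True,
        species_of, active_form, provenance,
    )


def network_to_text(network: PathwayNetwork, options: Optional[ConversionOptions] = None):
    """Emit DSL model text from a state-expanded network.

    Returns ``(text, report, provenance)`` where ``provenance`` maps each
    generated line to the relation or option that produced it.  Subtypes not
    covered by the mapping and not in ``skip_subtypes`` are errors — better
    to fail than to guess a mechanism.
    """
    options = options or ConversionOptions()
    if not network.state_expanded:
        raise KgmlError("expand_states must run before conversion")
    species_of = network.species_of
    active = network.active_form
    lines: list[str] = []
    line_provenance: dict[int, tuple] = {}
    skipped: list[tuple] = []
    # entries whose active form gets an explicit deactivating line
    explicit_deactivation: set[str] = set()

    def src_species(eid: str) -> str:
        return active.get(eid, species_of[eid])

    for k, rel in enumerate(network.relations):
        if rel.source not in species_of or rel.target not in species_of:
            skipped.append((rel, "non-protein endpoint"))
            continue
        if rel.subtypes & options.skip_subtypes:
            skipped.append((rel, "skipped subtype"))
            continue
        src = src_species(rel.source)
        tgt = species_of[rel.target]
        if "binding/association" in rel.subtypes:
            line = f"{src} binds {tgt} --> {src}_{tgt}"
        elif rel.relation_type == "GErel" and "expression" in rel.subtypes:
            line = f"{src} transcribes {tgt}"
        elif rel.subtypes & DEACTIVATING:
            form = active.get(rel.target)
            if form is None:
                raise KgmlError(
                    f"cannot map deactivating relation {rel.source}->{rel.target}: "
                    f"target {tgt!r} has no active form to deactivate"
                )
            line = f"{src} dephosphorylates {form} --> {tgt}"
            explicit_deactivation.add(rel.target)
        elif rel.subtypes & ACTIVATING:
            form = active[rel.target]
            line = f"{src} phosphorylates {tgt} --> {form}"
        else:
            raise KgmlError(
                f"unmapped relation {rel.source}->{rel.target} with subtypes "
                f"{sorted(rel.subtypes)}; add to skip_subtypes or extend the mapping"
            )
        if line not in lines:  # parallel duplicate relations collapse to one line
            line_provenance[len(lines)] = ("relation", k)
            lines.append(line)

    if options.add_reverse_reactions:
        for eid, form in active.items():
            if eid in explicit_deactivation:
                continue
            line = f"{form} is dephosphorylated --> {species_of[eid]}"
            line_provenance[len(lines)] = ("reverse", eid)
            lines.append(line)

    generated_species = set()
    for line in lines:
        for tok in line.replace("-->", " ").split():
            if tok not in ("binds", "is", "dephosphorylated", "phosphorylates",
                           "dephosphorylates", "transcribes", "translated", "into",
                           "degraded", "synthesized", "dissociated", "and"):
                generated_species.add(tok)
    for spx in options.degradation_species:
        if spx not in generated_species:
            raise KgmlError(f"degradation species {spx!r} not present in converted model")
        line_provenance[len(lines)] = ("degradation_option", spx)
        lines.append(f"{spx} is degraded")

    text = "\n".join(lines) + "\n" if lines else ""
    if lines:
        parse_model(text, source_name=network.name or "kgml")  # must round-trip cleanly
    report = ConversionReport(
        n_entries=len(network.entries),
        n_relations=len(network.relations),
        n_lines=len(lines),
        n_skipped=len(skipped),
        skipped=skipped,
    )
    return text, report, line_provenance
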