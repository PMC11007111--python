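"""Graph export of compiled models and pathway networks (DOT / GraphML).

Reactions with more than two participants cannot be drawn faithfully as
simple edges, so compiled models are exported as a bipartite species–reaction
graph: species nodes (ellipses) and reaction nodes (small boxes), with
catalytic edges styled dashed to distinguish them from conversion edges.
Pathway networks and enrichment-weighted graphs export as simple graphs.
"""

from __future__ import annotations

import io
from typing import Optional

import networkx as nx

from .compiler import CompiledModel

__all__ = ["model_to_graph", "export_graph"]


def model_to_graph(model: CompiledModel) -> nx.DiGraph:
    """Bipartite species–reaction digraph of a compiled model."""
    g = nx.DiGraph()
    for s in model.species:
        g.add_node(s.name, kind="species")
    for r in model.reactions:
        rn = f"r{r.index + 1}"
        g.add_node(rn, kind="reaction", reversible=r.reversible)
        for i in r.reactant_indices:
            g.add_edge(model.species[i].name, rn, role="reactant")
        for i in r.product_indices:
            g.add_edge(rn, model.species[i].name, role="product")
        if r.enzyme_index is not None:
            g.add_edge(model.species[r.enzyme_index].name, rn, role="catalyst")
    return g


def _dot_escape(s: str) -> str:
    return '"' + s.replace('"', '\\"') + '"'


def _to_dot(g: nx.Graph) -> str:
    directed = g.is_directed()
    buf = io.StringIO()
    buf.write(("digraph" if directed else "graph") + " model {\n")
    for n, attrs in sorted(g.nodes(data=True)):
        style = []
        if attrs.get("kind") == "reaction":
            style.append('shape=box, width=0.2, height=0.2, label=""')
        else:
            style.append("shape=ellipse")
        if "size" in attrs:
            style.append(f'width={attrs["size"]:g}')
        buf.write(f"  {_dot_escape(str(n))} [{', '.join(style)}];\n")
    arrow = "->" if directed else "--"
    for u, v, attrs in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        style = []
        if attrs.get("role") == "catalyst":
            style.append("style=dashed")
        if "width" in attrs:
            style.append(f'penwidth={attrs["width"]:g}')
        suffix = f" [{', '.join(style)}]" if style else ""
        buf.write(f"  {_dot_escape(str(u))} {arrow} {_dot_escape(str(v))}{suffix};\n")
    buf.write("}\n")
    return buf.getvalue()


def _to_graphml(g: nx.Graph) -> str:
    lines = nx.generate_graphml(g)
    return "\n".join(lines) + "\n"


def export_graph(obj, fmt: str = "dot", weights=None) -> str:
    """Serialize a model/network/graph to DOT or GraphML text.

    ``obj`` may be a :class:`CompiledModel`, a ``PathwayNetwork`` or a
    networkx graph (e.g. from :func:`textode.litweights.annotate_network`).
    ``weights`` is an optional EnrichmentResult applied to networks.
    """
    if isinstance(obj, CompiledModel):
        g = model_to_graph(obj)
    elif hasattr(obj, "entries"):  # PathwayNetwork
        if weights is not None:
            from .litweights import annotate_network

            g = annotate_network(obj, weights)
        else:
            g = nx.DiGraph()
            species = obj.species_of or {
                e.id: e.display_name for e in obj.entries.values()
                if e.entry_type not in ("map", "compound")
            }
            for name in species.values():
                g.add_node(name, kind="species")
            for rel in obj.relations:
                if rel.source in species and rel.target in species:
                    g.add_edge(species[rel.source], species[rel.target],
                               subtypes=",".join(sorted(rel.subtypes)))
    elif isinstance(obj, (nx.Graph, nx.DiGraph)):
        g = obj
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")
    if fmt == "dot":
        return _to_dot(g)
    if fmt == "graphml":
        return _to_graphml(g)
    raise ValueError(f"unknown graph format {fmt!r} (expected 'dot' or 'graphml')")
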