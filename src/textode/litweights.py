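"""Literature co-occurrence weighting of pathway nodes and edges.

Given a corpus of annotated documents (PubTator-shaped: one row per entity
mention with document id, entity text and entity type), count for each gene
the documents mentioning it (node weight) and for each gene pair the
documents mentioning both (edge weight).  Repeating the counts on a
query-filtered sub-corpus (e.g. all documents that mention the cell line
"MCF-7") and comparing against the background highlights the pathway
portions most associated with the query.

The comparison statistic is a pseudocounted rate ratio

    fold = ((c_q + π) / (N_q + 2π)) / ((c_b + π) / (N_b + 2π)),   π = 0.5

which is strictly positive, equals 1 exactly when query and background
coincide, and is defined even for zero counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "AnnotatedDocument",
    "Corpus",
    "WeightTable",
    "EnrichmentResult",
    "read_corpus",
    "count_weights",
    "filter_corpus",
    "enrichment",
    "annotate_network",
]

ENTITY_TYPES = {"gene", "disease", "cellline", "chemical", "species", "mutation"}


def _norm(text: str) -> str:
    return text.strip().casefold()


@dataclass(frozen=True)
class AnnotatedDocument:
    doc_id: str
    mentions: frozenset  # {(normalized entity text, entity type)}

    def mentions_text(self, text: str) -> bool:
        t = _norm(text)
        return any(m == t for m, _ in self.mentions)


@dataclass(frozen=True)
class Corpus:
    documents: tuple  # AnnotatedDocument, unique ids

    def __len__(self) -> int:
        return len(self.documents)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "Corpus":
        """rows of (document_id, entity_text, entity_type)."""
        by_doc: dict[str, set] = {}
        for doc_id, text, etype in rows:
            by_doc.setdefault(str(doc_id), set()).add((_norm(text), str(etype)))
        docs = tuple(
            AnnotatedDocument(d, frozenset(m)) for d, m in sorted(by_doc.items())
        )
        return cls(docs)


def read_corpus(path, sep="\t") -> Corpus:
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["document_id", "entity_text", "entity_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"corpus file missing columns {missing}")
    return Corpus.from_rows(df[required].itertuples(index=False, name=None))


@dataclass(frozen=True)
class WeightTable:
    N: int
    node_counts: dict  # gene -> n documents mentioning it
    edge_counts: dict  # frozenset({g, h}) -> n documents mentioning both


@dataclass(frozen=True)
class EnrichmentResult:
    query_term: str
    pseudocount: float
    node_fold: dict  # gene -> fold change
    edge_fold: dict  # frozenset pair -> fold change
    background_N: int
    query_N: int


def count_weights(corpus: Corpus, genes: set, edges: Optional[set] = None) -> WeightTable:
    """Document-level occurrence and co-occurrence counts.

    A gene counts once per document regardless of mention multiplicity;
    matching is exact on case-folded entity text.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    genes = {str(g) for g in genes}
    edges = {frozenset((str(a), str(b))) for a, b in (edges or set())}
    for e in edges:
        if not e <= genes:
            raise ValueError(f"edge {sorted(e)} not within the gene set")
    norm_of = {g: _norm(g) for g in genes}
    node_counts = {g: 0 for g in genes}
    edge_counts = {e: 0 for e in edges}
    for doc in corpus.documents:
        texts = {m for m, _ in doc.mentions}
        present = {g for g in genes if norm_of[g] in texts}
        for g in present:
            node_counts[g] += 1
        for e in edges:
            if e <= present:
                edge_counts[e] += 1
    return WeightTable(len(corpus), node_counts, edge_counts)


def filter_corpus(corpus: Corpus, query: str) -> Corpus:
    """Keep documents with a mention equal to the query (any entity type)."""
    if not query or not query.strip():
        raise ValueError("query must be non-empty")
    return Corpus(tuple(d for d in corpus.documents if d.mentions_text(query)))


def _fold(cq: int, nq: int, cb: int, nb: int, pi: float) -> float:
    return ((cq + pi) / (nq + 2 * pi)) / ((cb + pi) / (nb + 2 * pi))


def enrichment(
    background: WeightTable,
    query: WeightTable,
    pseudocount: float = 0.5,
    query_term: str = "",
) -> EnrichmentResult:
    """Fold change of occurrence rates, query-filtered corpus vs background."""
    if query.N == 0:
        raise ValueError("query matched no documents")
    if background.N < query.N:
        raise ValueError("query corpus cannot be larger than the background")
    pi = pseudocount
    node_fold = {
        g: _fold(query.node_counts.get(g, 0), query.N, cb, background.N, pi)
        for g, cb in background.node_counts.items()
    }
    edge_fold = {
        e: _fold(query.edge_counts.get(e, 0), query.N, cb, background.N, pi)
        for e, cb in background.edge_counts.items()
    }
    return EnrichmentResult(query_term, pi, node_fold, edge_fold, background.N, query.N)


def annotate_network(network, result: EnrichmentResult):
    """Attach fold changes to a pathway network as a weighted networkx graph.

    Node size attribute = node fold change, edge width = edge fold change;
    genes without data default to 1.0.  ``network`` may be a
    :class:`~textode.kgml.PathwayNetwork` or any networkx graph whose node
    labels are gene names.
    """
    import networkx as nx

    if hasattr(network, "entries"):  # PathwayNetwork
        g = nx.Graph()
        species = network.species_of or {
            e.id: e.display_name for e in network.entries.values()
            if e.entry_type not in ("map", "compound")
        }
        for name in species.values():
            g.add_node(name)
        for rel in network.relations:
            if rel.source in species and rel.target in species:
                g.add_edge(species[rel.source], species[rel.target])
    else:
        g = network.copy()
    matched = set(g.nodes) & set(result.node_fold)
    if not matched:
        raise ValueError("no genes matched between network and enrichment result")
    for n in g.nodes:
        g.nodes[n]["size"] = float(result.node_fold.get(n, 1.0))
    for u, v in g.edges:
        g.edges[u, v]["width"] = float(result.edge_fold.get(frozenset((u, v)), 1.0))
    return g
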