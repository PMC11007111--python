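"""Seeded generators of synthetic inputs.

Every consumer module in the package is testable offline through these
generators: toy KGML pathways shaped like the KEGG DTD, PubTator-style
annotated corpora with planted query-associated genes, synthetic noisy time
courses with a hidden ground truth for recovery benchmarks, and the
canonical four-reaction binding diamond — the smallest network whose
alternate assembly paths form a detailed-balance loop.

All generators are pure functions of their arguments and seed: the same
call yields byte-identical output.
"""

from __future__ import annotations

import random
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compiler import CompiledModel
from .estimate import ExperimentTable, _simulate_normalized
from .simulate import SimulationCondition

__all__ = [
    "make_toy_kgml",
    "make_toy_corpus",
    "make_synthetic_timecourse",
    "make_diamond_model",
    "DEFAULT_SUBTYPE_MIX",
]

# weights over subtype combinations drawn per relation
DEFAULT_SUBTYPE_MIX = {
    ("activation", "phosphorylation"): 0.4,
    ("activation",): 0.3,
    ("binding/association",): 0.2,
    ("inhibition",): 0.1,
}


def make_toy_kgml(
    n_genes: int,
    n_relations: int,
    subtype_mix: Optional[dict] = None,
    seed: int = 0,
) -> str:
    """Generate a well-formed KGML pathway with gene entries and typed relations.

    Relations are drawn without replacement over ordered gene pairs.
    Inhibition is only assigned to targets that also receive an activating
    relation (otherwise there is no active form to deactivate), mirroring how
    curated maps pair kinases with phosphatases.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    if n_relations > n_genes * (n_genes - 1):
        raise ValueError(
            f"cannot place {n_relations} relations among {n_genes} genes "
            f"(max {n_genes * (n_genes - 1)} ordered pairs)"
        )
    mix = subtype_mix or DEFAULT_SUBTYPE_MIX
    rng = random.Random(seed)
    names = [f"G{i + 1}" for i in range(n_genes)]
    pairs = [(i, j) for i in range(n_genes) for j in range(n_genes) if i != j]
    chosen = rng.sample(pairs, n_relations)
    combos = list(mix.keys())
    weights = [mix[c] for c in combos]
    drawn = [tuple(rng.choices(combos, weights=weights)[0]) for _ in chosen]
    activated = {j for (i, j), subs in zip(chosen, drawn) if set(subs) & {"activation", "phosphorylation"}}
    fixed = []
    for (i, j), subs in zip(chosen, drawn):
        if set(subs) & {"inhibition", "dephosphorylation"} and j not in activated:
            subs = ("activation", "phosphorylation")  # keep the model mappable
            activated.add(j)
        fixed.append(((i, j), subs))

    out = ['<?xml version="1.0"?>']
    out.append('<pathway name="path:toy" org="toy" number="00000" title="Toy pathway">')
    for i, name in enumerate(names):
        out.append(f'  <entry id="{i + 1}" name="toy:{name}" type="gene">')
        out.append(f'    <graphics name="{name}, {name}_alias" type="rectangle" x="0" y="0"/>')
        out.append("  </entry>")
    for (i, j), subs in fixed:
        rtype = "GErel" if "expression" in subs else "PPrel"
        out.append(f'  <relation entry1="{i + 1}" entry2="{j + 1}" type="{rtype}">')
        for s in subs:
            out.append(f'    <subtype name="{s}" value="--&gt;"/>')
        out.append("  </relation>")
    out.append("</pathway>")
    return "\n".join(out) + "\n"


def make_toy_corpus(
    genes: Sequence[str],
    n_docs: int,
    query_term: str,
    enriched_genes: Sequence[str] = (),
    seed: int = 0,
    p_query: float = 0.2,
    p_enriched: float = 0.8,
    p_background: float = 0.2,
) -> str:
    """Generate a delimited PubTator-style corpus with planted enrichment.

    Documents mention the query term with probability ``p_query``; in
    query-positive documents each enriched gene is mentioned with probability
    ``p_enriched`` (0.8) versus the background rate ``p_background`` (0.2)
    everywhere else, giving planted genes a query-vs-background rate ratio
    around 2.5 at the defaults.  Every document carries a species annotation
    (as real abstract annotations do), so the corpus size is exactly
    ``n_docs``.  Returns TSV text with header
    (document_id, entity_text, entity_type).
    """
    if n_docs < 2:
        raise ValueError("need at least two documents")
    enriched = set(enriched_genes)
    if not enriched <= set(genes):
        raise ValueError("enriched_genes must be a subset of genes")
    rng = random.Random(seed)
    lines = ["document_id\tentity_text\tentity_type"]
    for d in range(n_docs):
        doc_id = f"d{d + 1}"
        lines.append(f"{doc_id}\thuman\tspecies")
        has_query = rng.random() < p_query
        if has_query:
            lines.append(f"{doc_id}\t{query_term}\tcellline")
        for g in genes:
            p = p_enriched if (has_query and g in enriched) else p_background
            if rng.random() < p:
                lines.append(f"{doc_id}\t{g}\tgene")
    return "\n".join(lines) + "\n"


def make_synthetic_timecourse(
    model: CompiledModel,
    true_params,
    conditions: Sequence[SimulationCondition],
    n_times: int = 50,
    noise_cv: float = 0.05,
    seed: int = 0,
    duration: Optional[float] = None,
):
    """Simulate the model at known parameters and emit a noisy data table.

    The clean normalized observables are multiplied by seeded lognormal
    noise with coefficient of variation ``noise_cv`` (unit mean), matching
    the positive, heteroscedastic character of immunoblot intensities.
    Returns ``(ExperimentTable, truth)`` where truth maps parameter names to
    the generating values.
    """
    true_params = np.asarray(true_params, dtype=float)
    if duration is not None:
        conditions = [
            SimulationCondition(c.name, c.initial_overrides, duration, n_times)
            for c in conditions
        ]
    t_end = conditions[0].duration
    times = np.linspace(0.0, t_end, n_times)
    rows = []
    for cond in conditions:
        for obs in model.observables:
            for t in times:
                rows.append((obs, cond.name, float(t), 0.0))
    table = pd.DataFrame(rows, columns=["observable", "condition", "time", "value"])
    data = ExperimentTable(table)
    clean = _simulate_normalized(model, true_params, conditions, data)
    if clean is None:
        raise RuntimeError("model failed to integrate at the true parameters")
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=clean.shape)
        values = clean * noise
    else:
        values = clean.copy()
    table = table.assign(value=values)
    truth = dict(zip(model.parameter_names, true_params))
    return ExperimentTable(table), truth


def make_diamond_model() -> str:
    """The four-reaction reversible binding diamond.

    A+B⇄AB, AB+C⇄ABC, A+C⇄AC, AC+B⇄ABC: two assembly paths to the ternary
    complex forming one thermodynamic loop (6 species, 8 rate constants,
    7 free after the detailed-balance constraint).
    """
    return (
        "A binds B --> AB\n"
        "AB binds C --> ABC\n"
        "A binds C --> AC\n"
        "AC binds B --> ABC\n"
        "@init A = 1\n"
        "@init B = 1\n"
        "@init C = 1\n"
    )
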