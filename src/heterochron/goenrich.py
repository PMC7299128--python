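"""Parent-child GO term enrichment.

The classic term-vs-universe Fisher test overstates enrichment of a term
when its parent terms are already enriched, because annotations propagate
up the DAG.  The parent-child test conditions on the parents: for term t
with parent set pa(t), it asks how surprising the observed number of study
genes annotated to t is, given how many study genes are annotated to the
(pooled) parents.  This is the parent-child-union variant: genes of all
parents are pooled by union, and the p-value is the hypergeometric upper
tail of drawing >= k successes (genes of t) when sampling the study genes
that hit the parent pool.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import obonet
from scipy import stats

BIOLOGICAL_PROCESS = "biological_process"


@dataclass
class GODag:
    """An is_a GO DAG (edges child -> parent) with per-term namespaces."""

    graph: nx.DiGraph
    namespaces: dict[str, str]

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)

    def terms(self) -> list[str]:
        return list(self.graph.nodes)


@dataclass
class GOEnrichmentResult:
    term_id: str
    name: str
    study_count: int
    population_count: int
    parent_population_count: int
    parent_study_count: int
    p: float

    def enriched(self, alpha: float = 0.05) -> bool:
        return self.p <= alpha


def load_go_dag(path_or_handle) -> GODag:
    """Read an OBO file, keeping only is_a relationships."""
    multi = obonet.read_obo(path_or_handle)
    graph = nx.DiGraph()
    graph.add_nodes_from(multi.nodes)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("GO is_a graph contains a cycle")
    namespaces = {
        node: data.get("namespace", "") for node, data in multi.nodes(data=True)
    }
    dag = GODag(graph=graph, namespaces=namespaces)
    dag._names = {  # term names for reporting, "" if absent
        node: data.get("name", "") for node, data in multi.nodes(data=True)
    }
    return dag


def read_annotations(path) -> dict[str, set[str]]:
    """Two-column TSV: gene id, GO term id (one pair per line)."""
    gene2terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            gene2terms.setdefault(gene, set()).add(term)
    return gene2terms


def propagate_annotations(
    dag: GODag, gene2terms: Mapping[str, Iterable[str]]
) -> dict[str, set[str]]:
    """Close annotations over the DAG (true-path rule): a gene annotated to
    a term is annotated to all its ancestors."""
    unknown = sorted(
        {t for terms in gene2terms.values() for t in terms}
        - set(dag.graph.nodes)
    )
    if unknown:
        raise ValueError(f"annotation references unknown terms: {unknown}")
    ancestor_cache: dict[str, set[str]] = {}
    closed: dict[str, set[str]] = {}
    for gene, terms in gene2terms.items():
        full: set[str] = set()
        for t in terms:
            if t not in ancestor_cache:
                ancestor_cache[t] = dag.ancestors(t) | {t}
            full |= ancestor_cache[t]
        closed[gene] = full
    return closed


def parent_child_fisher(
    dag: GODag,
    closed_annotations: Mapping[str, set[str]],
    study: set[str],
    universe: set[str],
    namespace: str | None = BIOLOGICAL_PROCESS,
) -> list[GOEnrichmentResult]:
    """Parent-child-union enrichment over all annotated terms of a
    namespace.

    For term t: M = |universe genes annotated to any parent of t| (pooled by
    union), K = |universe genes annotated to t|, N = |study genes annotated
    to the parent pool|, k = |study genes annotated to t|; p is the
    hypergeometric P(X >= k).  Root terms (no parents) get p = 1.
    """
    outside = study - universe
    if outside:
        raise ValueError(f"study genes outside the universe: {sorted(outside)[:5]}")
    term2genes: dict[str, set[str]] = {}
    for gene, terms in closed_annotations.items():
        if gene not in universe:
            continue
        for t in terms:
            term2genes.setdefault(t, set()).add(gene)
    names = getattr(dag, "_names", {})
    results = []
    for term, genes in term2genes.items():
        if namespace is not None and dag.namespaces.get(term) != namespace:
            continue
        study_genes = genes & study
        parents = dag.parents(term)
        if not parents:
            p = 1.0
            parent_pool: set[str] = genes
            parent_study = study_genes
        else:
            parent_pool = set()
            for parent in parents:
                parent_pool |= term2genes.get(parent, set())
            parent_study = parent_pool & study
            k = len(study_genes)
            p = float(
                stats.hypergeom.sf(
                    k - 1, len(parent_pool), len(genes), len(parent_study)
                )
            )
        results.append(
            GOEnrichmentResult(
                term_id=term,
                name=names.get(term, ""),
                study_count=len(study_genes),
                population_count=len(genes),
                parent_population_count=len(parent_pool),
                parent_study_count=len(parent_study),
                p=min(p, 1.0),
            )
        )
    return results


def filter_enriched(
    results: Iterable[GOEnrichmentResult], alpha: float = 0.05
) -> list[GOEnrichmentResult]:
    """Terms with p <= alpha, ascending by p (ties by term id for a stable
    order)."""
    kept = [r for r in results if r.p <= alpha]
    return sorted(kept, key=lambda r: (r.p, r.term_id))
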