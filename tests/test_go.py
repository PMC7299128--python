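"""Annotation propagation over the GO DAG and the parent-child enrichment
test."""
import io
from itertools import combinations

import networkx as nx
import pytest
from scipy import stats

from heterochron import (
    filter_enriched,
    load_go_dag,
    parent_child_fisher,
    propagate_annotations,
)
from heterochron.goenrich import GOEnrichmentResult


def obo(terms):
    """Build an OBO document from (term_id, name, namespace, parents)."""
    chunks = ["format-version: 1.2\nontology: go\n"]
    for tid, name, ns, parents in terms:
        lines = [f"[Term]\nid: {tid}\nname: {name}\nnamespace: {ns}"]
        lines += [f"is_a: {p} ! parent" for p in parents]
        chunks.append("\n".join(lines) + "\n")
    return io.StringIO("\n".join(chunks))


DIAMOND = [
    ("GO:0001", "root", "biological_process", []),
    ("GO:0002", "left parent", "biological_process", ["GO:0001"]),
    ("GO:0003", "right parent", "biological_process", ["GO:0001"]),
    ("GO:0004", "child", "biological_process", ["GO:0002", "GO:0003"]),
]


class TestPropagation:
    def test_leaf_annotation_reaches_root(self):
        dag = load_go_dag(obo(DIAMOND))
        closed = propagate_annotations(dag, {"g1": ["GO:0004"]})
        assert closed["g1"] == {"GO:0001", "GO:0002", "GO:0003", "GO:0004"}

    def test_diamond_grandparent_counted_once(self):
        dag = load_go_dag(obo(DIAMOND))
        closed = propagate_annotations(dag, {"g1": ["GO:0004"]})
        assert len(closed["g1"]) == 4  # a set: no double-counting via two paths

    def test_unknown_term_listed(self):
        dag = load_go_dag(obo(DIAMOND))
        with pytest.raises(ValueError, match="GO:9999"):
            propagate_annotations(dag, {"g1": ["GO:9999"]})

    def test_closure_matches_transitive_closure_oracle(self):
        terms = [
            ("GO:1", "r", "biological_process", []),
            ("GO:2", "a", "biological_process", ["GO:1"]),
            ("GO:3", "b", "biological_process", ["GO:1"]),
            ("GO:4", "c", "biological_process", ["GO:2"]),
            ("GO:5", "d", "biological_process", ["GO:2", "GO:3"]),
            ("GO:6", "e", "biological_process", ["GO:4", "GO:5"]),
        ]
        dag = load_go_dag(obo(terms))
        annotations = {"g1": ["GO:6"], "g2": ["GO:4", "GO:5"], "g3": ["GO:3"]}
        closed = propagate_annotations(dag, annotations)
        # oracle: brute-force reachability on an independently built digraph
        g = nx.DiGraph(
            [(t, p) for t, _, _, parents in terms for p in parents]
        )
        for gene, terms_of_gene in annotations.items():
            expected = set(terms_of_gene)
            for t in terms_of_gene:
                for other in g.nodes:
                    if other != t and nx.has_path(g, t, other):
                        expected.add(other)
            assert closed[gene] == expected


def flat_dag(n_terms):
    """Every term's only parent is the root."""
    terms = [("GO:0000", "root", "biological_process", [])]
    terms += [
        (f"GO:{i:04d}", f"t{i}", "biological_process", ["GO:0000"])
        for i in range(1, n_terms + 1)
    ]
    return load_go_dag(obo(terms))


class TestParentChildFisher:
    def test_flat_dag_reduces_to_classic_fisher(self):
        """When each term hangs directly off the root, conditioning on the
        parent equals the classic term-vs-universe hypergeometric test."""
        dag = flat_dag(3)
        genes = [f"g{i}" for i in range(12)]
        annotations = {g: {"GO:0000"} for g in genes}
        for i, g in enumerate(genes):
            annotations[g].add(f"GO:{(i % 3) + 1:04d}")
        universe = set(genes)
        study = {"g0", "g3", "g6", "g9", "g1"}
        results = {
            r.term_id: r
            for r in parent_child_fisher(dag, annotations, study, universe)
        }
        for term in ("GO:0001", "GO:0002", "GO:0003"):
            k = len({g for g in study if term in annotations[g]})
            K = len({g for g in genes if term in annotations[g]})
            classic = stats.hypergeom.sf(k - 1, len(universe), K, len(study))
            assert results[term].p == pytest.approx(classic, rel=1e-12)

    def test_term_equal_to_parent_gives_p_one(self):
        terms = DIAMOND + [
            ("GO:0005", "same as parent", "biological_process", ["GO:0004"])
        ]
        dag = load_go_dag(obo(terms))
        annotations = propagate_annotations(
            dag, {"g1": ["GO:0005"], "g2": ["GO:0005"], "g3": ["GO:0001"]}
        )
        universe = {"g1", "g2", "g3"}
        results = {
            r.term_id: r
            for r in parent_child_fisher(dag, annotations, {"g1"}, universe)
        }
        # genes(GO:0005) == genes(GO:0004): no enrichment is possible
        assert results["GO:0005"].p == pytest.approx(1.0)

    def test_root_term_gets_p_one(self):
        dag = flat_dag(1)
        annotations = {"g1": {"GO:0000", "GO:0001"}, "g2": {"GO:0000"}}
        results = {
            r.term_id: r
            for r in parent_child_fisher(dag, annotations, {"g1"}, {"g1", "g2"})
        }
        assert results["GO:0000"].p == 1.0

    def test_worked_fixture_matches_exhaustive_enumeration(self):
        """8 genes, 4 terms: the hypergeometric tail equals brute-force
        enumeration over all equally likely study draws from the parent
        pool."""
        dag = load_go_dag(obo(DIAMOND))
        genes = [f"g{i}" for i in range(8)]
        raw = {
            "g0": ["GO:0004"], "g1": ["GO:0004"], "g2": ["GO:0004"],
            "g3": ["GO:0002"], "g4": ["GO:0002"], "g5": ["GO:0003"],
            "g6": ["GO:0003"], "g7": ["GO:0001"],
        }
        closed = propagate_annotations(dag, raw)
        universe = set(genes)
        study = {"g0", "g1", "g3", "g5"}
        results = {
            r.term_id: r
            for r in parent_child_fisher(dag, closed, study, universe)
        }
        r = results["GO:0004"]
        # parent pool = genes of GO:0002 union GO:0003 = g0..g6
        pool = sorted(g for g in genes if closed[g] & {"GO:0002", "GO:0003"})
        assert r.parent_population_count == len(pool) == 7
        drawn = study & set(pool)
        successes = {g for g in pool if "GO:0004" in closed[g]}
        k_obs = len(study & successes)
        total = hits = 0
        for draw in combinations(pool, len(drawn)):
            total += 1
            if len(set(draw) & successes) >= k_obs:
                hits += 1
        assert r.p == pytest.approx(hits / total, rel=1e-12)

    def test_study_outside_universe_rejected(self):
        dag = flat_dag(1)
        with pytest.raises(ValueError, match="zz"):
            parent_child_fisher(dag, {"g1": {"GO:0000"}}, {"zz"}, {"g1"})

    def test_gene_relabeling_invariance(self):
        dag = load_go_dag(obo(DIAMOND))
        raw = {"g0": ["GO:0004"], "g1": ["GO:0002"], "g2": ["GO:0003"],
               "g3": ["GO:0001"]}
        closed = propagate_annotations(dag, raw)
        p1 = {
            r.term_id: r.p
            for r in parent_child_fisher(dag, closed, {"g0", "g1"},
                                         set(raw))
        }
        relabel = {f"g{i}": f"x{i}" for i in range(4)}
        closed2 = {relabel[g]: t for g, t in closed.items()}
        p2 = {
            r.term_id: r.p
            for r in parent_child_fisher(dag, closed2, {"x0", "x1"},
                                         set(closed2))
        }
        assert p1 == p2


class TestFilterEnriched:
    def result(self, p):
        return GOEnrichmentResult("GO:1", "t", 1, 1, 1, 1, p)

    def test_boundary_p_kept(self):
        assert len(filter_enriched([self.result(0.05)])) == 1

    def test_just_above_alpha_dropped(self):
        assert filter_enriched([self.result(0.051)]) == []

    def test_sorted_ascending_and_empty_ok(self):
        out = filter_enriched([self.result(0.04), self.result(0.001)])
        assert [r.p for r in out] == [0.001, 0.04]
        assert filter_enriched([]) == []
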