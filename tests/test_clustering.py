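"""Tests of BHR computation, pre-clustering and UPGMA refinement."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panclog.clustering import (
    BHRGraph,
    CLOG,
    CLOGSet,
    build_clogs,
    compute_bhr,
    precluster,
    upgma_refine,
)
from panclog.model import Gene
from panclog.scoring import SimilarityTable


def make_graph(edges: dict, strain_of: dict | None = None) -> BHRGraph:
    genes = {g for pair in edges for g in pair}
    if strain_of is None:
        strain_of = {g: f"strain_{g}" for g in genes}
    return BHRGraph(edges, strain_of)


class TestComputeBHR:
    def test_mutual_best_hits_give_unity(self):
        # a and b are each other's only (hence best) cross-genome hit
        table = SimilarityTable(
            {("a", "b"): 80.0, ("b", "a"): 80.0},
            {"a": "A", "b": "B"},
        )
        graph = compute_bhr(table)
        assert graph.bhr("a", "b") == 1.0

    def test_direct_formula_substitution(self):
        # S(a,b)=80, best(b, A)=100 (via a2), S(b,a)=90, best(a, B)=90 (via b2)
        entries = {
            ("a", "b"): 80.0,
            ("b", "a"): 90.0,
            ("b", "a2"): 100.0,
            ("a2", "b"): 60.0,
            ("a", "b2"): 90.0,
            ("b2", "a"): 60.0,
        }
        table = SimilarityTable(entries, {"a": "A", "a2": "A", "b": "B", "b2": "B"})
        graph = compute_bhr(table)
        assert graph.bhr("a", "b") == pytest.approx((80 / 100) * (90 / 90))

    def test_same_genome_pair_capped(self):
        # recent duplicates p, q in one genome are mutual best hits (BHR 1)
        table = SimilarityTable(
            {("p", "q"): 120.0, ("q", "p"): 120.0},
            {"p": "A", "q": "A"},
        )
        graph = compute_bhr(table)
        assert graph.bhr("p", "q") == 0.95

    def test_pair_missing_one_direction_absent(self):
        table = SimilarityTable({("a", "b"): 80.0}, {"a": "A", "b": "B"})
        graph = compute_bhr(table)
        assert graph.bhr("a", "b") == 0.0
        assert ("a", "b") not in graph.edges

    def test_bounds_on_fixture(self, fixture5, clogs5):
        from panclog.scoring import score_all_pairs

        table = score_all_pairs(fixture5.proteomes)
        graph = compute_bhr(table)
        for (a, b), v in graph.edges.items():
            assert 0.0 <= v <= 1.0
            if graph.strain_of(a) == graph.strain_of(b):
                assert v <= 0.95


class TestPrecluster:
    def test_transitive_merge_at_threshold(self):
        graph = make_graph({("a", "b"): 0.96, ("b", "c"): 0.95, ("a", "c"): 0.20})
        assert precluster(graph) == [{"a", "b", "c"}]

    def test_all_singletons_below_threshold(self):
        graph = make_graph({("a", "b"): 0.94, ("b", "c"): 0.5})
        assert precluster(graph) == [{"a"}, {"b"}, {"c"}]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_components_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        edges = {}
        for a, b in itertools.combinations(genes, 2):
            if rng.random() < 0.08:
                edges[(a, b)] = float(rng.random())
        graph = make_graph(edges, strain_of={g: f"strain_{g}" for g in genes})
        # independent union-find oracle
        parent = {g: g for g in genes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (a, b), v in edges.items():
            if v >= 0.95:
                parent[find(a)] = find(b)
        expected = {}
        for g in genes:
            expected.setdefault(find(g), set()).add(g)
        assert sorted(precluster(graph), key=min) == sorted(
            expected.values(), key=min
        )

    def test_raising_threshold_never_grows_components(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        edges = {
            (a, b): float(rng.random())
            for a, b in itertools.combinations(genes, 2)
            if rng.random() < 0.3
        }
        graph = make_graph(edges)
        lo = precluster(graph, ortholog_threshold=0.5)
        hi = precluster(graph, ortholog_threshold=0.9)
        # every high-threshold component is contained in a low-threshold one
        for comp in hi:
            assert any(comp <= big for big in lo)


def upgma_oracle(genes, graph, min_bhr=0.75):
    """Independent agglomeration: inter-entity similarity recomputed from
    scratch as the plain mean of all cross gene-pair BHRs (missing pairs
    count 0), rather than by incremental size-weighted updates."""
    entities = [frozenset([g]) for g in sorted(genes)]
    while len(entities) > 1:
        best = None
        for x, y in itertools.combinations(entities, 2):
            s = sum(graph.bhr(a, b) for a in x for b in y) / (len(x) * len(y))
            key = tuple(sorted(x | y))
            if best is None or s > best[0] + 1e-12 or (
                abs(s - best[0]) <= 1e-12 and key < best[3]
            ):
                best = (s, x, y, key)
        if best[0] < min_bhr:
            break
        s, x, y, _ = best
        entities = [e for e in entities if e not in (x, y)] + [x | y]
    return sorted(entities, key=min)


class TestUpgmaRefine:
    def test_weak_third_gene_link_is_split(self):
        graph = make_graph({("a", "b"): 0.96, ("b", "c"): 0.95, ("a", "c"): 0.20})
        result = upgma_refine({"a", "b", "c"}, graph)
        # merge a,b first (0.96); BHR({a,b},c) = (0.20 + 0.95)/2 = 0.575 < 0.75
        assert result == [frozenset({"a", "b"}), frozenset({"c"})]

    def test_fully_connected_unity_merges_all(self):
        genes = ["a", "b", "c", "d"]
        graph = make_graph({p: 1.0 for p in itertools.combinations(genes, 2)})
        assert upgma_refine(genes, graph) == [frozenset(genes)]

    def test_singleton_identity(self):
        graph = make_graph({("x", "y"): 0.5})
        assert upgma_refine({"x"}, graph) == [frozenset({"x"})]

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        genes = [f"g{i}" for i in range(n)]
        edges = {
            (a, b): float(rng.random())
            for a, b in itertools.combinations(genes, 2)
            if rng.random() < 0.7
        }
        graph = make_graph(edges)
        assert upgma_refine(genes, graph) == upgma_oracle(genes, graph)


class TestBuildClogs:
    def test_two_identical_singleton_strains_form_one_clog(self):
        g = "MKTAYIAKQR" * 15
        proteomes = {"A": [Gene("a1", "A", g)], "B": [Gene("b1", "B", g)]}
        clogs = build_clogs(proteomes)
        assert len(clogs) == 1
        assert clogs.clogs[0].members == frozenset({"a1", "b1"})

    def test_unrelated_genes_stay_singletons(self):
        rng = np.random.default_rng(13)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        proteomes = {
            s: [Gene(f"{s}_g", s, "".join(rng.choice(aa, size=150)))]
            for s in ("A", "B", "C")
        }
        clogs = build_clogs(proteomes)
        assert len(clogs) == 3
        assert all(c.size == 1 for c in clogs)

    def test_partition_invariant_on_fixture(self, fixture5, clogs5):
        members = [g for c in clogs5 for g in c.members]
        assert len(members) == len(set(members)) == len(fixture5.records)

    def test_paralogs_join_family_clog_via_capped_bhr(self):
        from panclog import simulate as sim

        pg = sim.generate_pangenome(
            3, 6, 0, 0, 0.05, seed=21, paralog_fraction=1.0
        )
        records = sim.synthesize_gene_sequences(pg)
        assert len(records) > 18  # at least one extra copy somewhere
        clogs = build_clogs(sim.as_proteomes(records))
        truth = sim.truth_families(records)
        # every planted family, including its within-genome duplicates,
        # should land in a single CLOG
        membership = clogs.membership()
        for fam in {r.family_id for r in records}:
            fam_genes = [g for g, f in truth.items() if f == fam]
            assert len({membership[g] for g in fam_genes}) == 1


class TestCLOGSetValidation:
    def test_overlapping_clogs_rejected(self):
        clogs = [
            CLOG("c1", frozenset({"a"}), frozenset({"A"})),
            CLOG("c2", frozenset({"a", "b"}), frozenset({"A", "B"})),
        ]
        with pytest.raises(ValueError):
            CLOGSet(clogs, {"a": "A", "b": "B"})

    def test_unassigned_gene_rejected(self):
        clogs = [CLOG("c1", frozenset({"a"}), frozenset({"A"}))]
        with pytest.raises(ValueError):
            CLOGSet(clogs, {"a": "A", "b": "B"})
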