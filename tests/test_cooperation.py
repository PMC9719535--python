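from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncoop.cooperation import (
    CoopParams,
    candidate_pairs,
    characteristic_path_length,
    cpl_permutation_p,
    detect_cooperations,
    edge_switch,
    enrich_modules,
    hypergeom_overlap_p,
    min_distance_ok,
    random_ensemble,
)
from lncoop.io import GeneSetCollection
from lncoop.regression import RegulationRecord, TargetMap


def hypergeom_oracle(N, K, n, k):
    """Exact upper tail by direct enumeration of the hypergeometric pmf."""
    denom = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(n, K) + 1)) / denom


def make_target_map(target_sets: dict, n_mrna_tested: int, extra_mrnas=()):
    """TargetMap stub from lncRNA -> target-set dict."""
    records = []
    seen = set()
    for lnc, targets in target_sets.items():
        for m in targets:
            records.append(RegulationRecord(
                lncrna_id=lnc, mrna_id=m, beta0=0, beta_cnv=0, beta_meth=0,
                beta_lncrna=1.0, p_lncrna=1e-6, residual_sd=1.0, n_used=50))
            seen.add(m)
    universe = set(seen) | set(extra_mrnas)
    universe |= {f"bg{i}" for i in range(n_mrna_tested - len(universe))}
    return TargetMap(cancer_label="T", records=records,
                     n_tested_pairs=len(records), n_mrna_tested=n_mrna_tested,
                     tested_mrnas=frozenset(universe))


class TestHypergeometricTails:
    def test_worked_overlap_example(self):
        # N=10, two target sets of 5 overlapping completely
        assert hypergeom_overlap_p(10, 5, 5, 5) == pytest.approx(1 / 252, abs=1e-15)

    def test_worked_enrichment_example(self):
        # universe 20, term 5, shared 4, intersection 4
        assert hypergeom_overlap_p(20, 5, 4, 4) == pytest.approx(5 / 4845, abs=1e-15)

    def test_agrees_with_enumeration_oracle(self):
        """Spot grid against the exact oracle (full sweep in acceptance)."""
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(1, 26))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k_lo = max(0, n + K - N)
            k = int(rng.integers(k_lo, min(n, K) + 1))
            assert hypergeom_overlap_p(N, K, n, k) == pytest.approx(
                hypergeom_oracle(N, K, n, k), abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(2, 40).flatmap(
        lambda N: st.tuples(st.just(N), st.integers(0, N), st.integers(0, N))))
    def test_tail_monotone_decreasing_in_k(self, NKn):
        N, K, n = NKn
        tails = [hypergeom_overlap_p(N, K, n, k) for k in range(min(n, K) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))
        assert tails[0] == pytest.approx(1.0)


class TestCandidatePairs:
    def test_min_shared_rule(self):
        tm = make_target_map({"a": {"g1", "g2"}, "b": {"g1", "g2"}}, 10)
        assert candidate_pairs(tm, min_shared=3) == []

    def test_maximal_overlap_is_extreme_case(self):
        tm = make_target_map({"a": {"g1", "g2", "g3"}, "b": {"g1", "g2", "g3"}}, 12)
        [(pair, shared, p)] = candidate_pairs(tm)
        assert shared == frozenset({"g1", "g2", "g3"})
        # identical sets attain the minimum tail over k for these margins
        tails = [hypergeom_oracle(12, 3, 3, k) for k in range(4)]
        assert p == pytest.approx(min(tails), abs=1e-15)

    def test_overlap_p_matches_oracle(self):
        tm = make_target_map({"a": {"g1", "g2", "g3", "g4", "g5"},
                              "b": {"g1", "g2", "g3", "g6", "g7"}}, 15)
        [(_, shared, p)] = candidate_pairs(tm, alpha_overlap=1.1)
        assert len(shared) == 3
        assert p == pytest.approx(hypergeom_oracle(15, 5, 5, 3), abs=1e-12)


class TestEnrichModules:
    def _genesets(self):
        return GeneSetCollection(terms={
            "T1": ("d", frozenset({"g1", "g2", "g3", "g4", "g5"})),
            "T2": ("d", frozenset({"g9", "g10", "g11"})),
            "ABSENT": ("d", frozenset({"zz1", "zz2"})),
        })

    def test_enrichment_p_and_module_genes(self):
        universe = frozenset(f"g{i}" for i in range(1, 21))
        shared = frozenset({"g1", "g2", "g3", "g4"})
        with pytest.warns(UserWarning, match="ABSENT"):
            mods = enrich_modules(shared, self._genesets(), universe)
        [m] = [m for m in mods if m.go_term == "T1"]
        assert m.genes == shared
        assert m.enrich_p == pytest.approx(5 / 4845, abs=1e-14)

    def test_small_intersection_gives_no_module(self):
        universe = frozenset(f"g{i}" for i in range(1, 21))
        shared = frozenset({"g1", "g9", "g10", "g15"})
        with pytest.warns(UserWarning, match="ABSENT"):
            mods = enrich_modules(shared, self._genesets(), universe,
                                  alpha_enrich=1.1, min_module=3)
        assert all(m.go_term != "T1" for m in mods)  # intersection 1 < 3

    def test_saturated_term_not_enriched(self):
        universe = frozenset({"g1", "g2", "g3", "g4"})
        gs = GeneSetCollection(terms={"ALL": ("d", frozenset(universe))})
        mods = enrich_modules(frozenset({"g1", "g2", "g3"}), gs, universe,
                              alpha_enrich=1.1)
        assert mods[0].enrich_p == pytest.approx(1.0)


class TestTopologyCriteria:
    def setup_method(self):
        self.path = nx.path_graph(["a", "b", "c", "d"])

    def test_min_distance_examples(self):
        assert min_distance_ok({"a", "c", "d"}, self.path) is True
        assert min_distance_ok({"a", "d"}, self.path) is False
        assert min_distance_ok({"a", "zz"}, self.path) is False

    def test_strict_variant(self):
        # a-c distance 2, a-d distance 3: per-gene passes, strict fails
        assert min_distance_ok({"a", "c", "d"}, self.path, strict=True) is False
        assert min_distance_ok({"a", "b", "c"}, self.path, strict=True) is True

    def test_cpl_hand_examples(self):
        assert characteristic_path_length({"a", "c", "d"}, self.path) == pytest.approx(2.0)
        tri = nx.complete_graph(["x", "y", "z"])
        assert characteristic_path_length({"x", "y", "z"}, tri) == pytest.approx(1.0)

    def test_cpl_undefined_for_isolated(self):
        g = nx.empty_graph(["u", "v"])
        assert characteristic_path_length({"u", "v"}, g) is None

    def test_cpl_skips_disconnected_pairs(self):
        g = nx.Graph([("a", "b")])
        g.add_node("c")
        assert characteristic_path_length({"a", "b", "c"}, g) == pytest.approx(1.0)


class TestEdgeSwitch:
    def test_degree_sequence_preserved(self):
        for seed in range(10):
            g = nx.gnp_random_graph(30, 0.15, seed=seed)
            h = edge_switch(g, seed=seed)
            assert sorted(d for _, d in h.degree()) == \
                sorted(d for _, d in g.degree())
            assert nx.is_isomorphic(nx.Graph(h), h)  # stays simple

    def test_star_graph_is_fixed_point(self):
        """No legal double-edge swap exists on a star: every swap would
        need two edges with four distinct endpoints, but all edges share
        the hub, so the output equals the input."""
        g = nx.star_graph(4)
        h = edge_switch(g, n_swaps=500, seed=1)
        assert set(map(frozenset, h.edges())) == set(map(frozenset, g.edges()))

    def test_seeded_determinism(self):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        h1 = edge_switch(g, seed=7)
        h2 = edge_switch(g, seed=7)
        assert set(map(frozenset, h1.edges())) == set(map(frozenset, h2.edges()))

    def test_actually_randomises(self):
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        h = edge_switch(g, seed=7)
        assert set(map(frozenset, h.edges())) != set(map(frozenset, g.edges()))


class TestCplPermutation:
    def test_invariant_module_has_p_zero(self):
        """On a star every degree-preserving network is the star itself,
        so a leaf pair's CPL can never beat the real one (strict <)."""
        g = nx.star_graph(6)
        cpl, p = cpl_permutation_p({1, 2}, g, n_random=20, seed=0)
        assert cpl == pytest.approx(2.0)
        assert p == 0.0

    def test_planted_clique_significant(self):
        rng_graph = nx.gnp_random_graph(60, 0.05, seed=2)
        clique = [0, 1, 2, 3]
        for i, j in combinations(clique, 2):
            rng_graph.add_edge(i, j)
        cpl, p = cpl_permutation_p(set(clique), rng_graph, n_random=100, seed=5)
        assert cpl == pytest.approx(1.0)
        assert p < 0.05

    def test_matches_manual_count_on_shared_ensemble(self):
        """p equals the fraction of ensemble networks whose module CPL is
        strictly shorter, counted by hand over an explicit ensemble."""
        g = nx.gnp_random_graph(25, 0.12, seed=9)
        genes = {0, 5, 9, 13}
        ensemble = random_ensemble(g, n_random=30, seed=11)
        cpl_real, p = cpl_permutation_p(genes, g, ensemble=ensemble)
        manual = 0
        for h in ensemble:
            dists = []
            for a, b in combinations(sorted(genes), 2):
                try:
                    dists.append(nx.shortest_path_length(h, a, b))
                except nx.NetworkXNoPath:
                    pass
            if dists and sum(dists) / len(dists) < cpl_real:
                manual += 1
        assert p == pytest.approx(manual / 30)


def brute_force_detect(targets: TargetMap, genesets, ppi, params: CoopParams):
    """Exhaustive re-derivation of the accepted pair set for small inputs.

    Evaluates every unordered lncRNA pair and every GO term directly with
    enumeration-based hypergeometric tails and hand BFS distances, sharing
    the seeded ensemble definition with the pipeline.
    """
    index = targets.target_index()
    universe = set(targets.tested_mrnas)
    N = len(universe)
    ensemble = random_ensemble(ppi, n_random=params.n_random,
                               n_swaps=params.n_swaps, seed=params.seed)

    def bfs_dist(graph, src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in graph[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        return dist

    def cpl_of(genes, graph):
        ds = []
        genes = [g for g in genes if g in graph]
        for i, a in enumerate(genes):
            da = bfs_dist(graph, a)
            for b in genes[i + 1:]:
                if b in da:
                    ds.append(da[b])
        return sum(ds) / len(ds) if ds else None

    accepted = set()
    for a, b in combinations(sorted(index), 2):
        shared = index[a] & index[b]
        if len(shared) < params.min_shared:
            continue
        p_ov = hypergeom_oracle(N, len(index[a]), len(index[b]), len(shared))
        if params.require_overlap_test and p_ov >= params.alpha_overlap:
            continue
        for tid in genesets:
            term = genesets.genes(tid) & universe
            if not term:
                continue
            genes = shared & term
            p_en = hypergeom_oracle(N, len(term), len(shared), len(genes))
            if p_en >= params.alpha_enrich or len(genes) < params.min_module:
                continue
            if any(g not in ppi for g in genes):
                continue
            ok = True
            for g in genes:
                dg = bfs_dist(ppi, g)
                if not any(dg.get(h, 99) <= 2 for h in genes if h != g):
                    ok = False
                    break
            if not ok:
                continue
            real = cpl_of(genes, ppi)
            if real is None:
                continue
            shorter = sum(1 for h in ensemble
                          if (c := cpl_of(genes, h)) is not None and c < real)
            if shorter / len(ensemble) < params.alpha_cpl:
                accepted.add(frozenset((a, b)))
                break
    return accepted


class TestDetectCooperations:
    def _small_instance(self):
        target_sets = {
            "L1": {"g1", "g2", "g3", "g4"},
            "L2": {"g1", "g2", "g3", "g5"},
            "L3": {"g6", "g7", "g8"},
            "L4": {"g6", "g7", "g8"},
            "L5": {"g9"},
            "L6": {"g1", "g6", "g9"},
        }
        tm = make_target_map(target_sets, n_mrna_tested=30)
        gs = GeneSetCollection(terms={
            "GO_A": ("d", frozenset({"g1", "g2", "g3", "g10"})),
            "GO_B": ("d", frozenset({"g6", "g7", "g8"})),
            "GO_C": ("d", frozenset({"g4", "g5", "g9"})),
        })
        ppi = nx.Graph()
        for tri in (("g1", "g2", "g3"), ("g6", "g7", "g8")):
            for x, y in combinations(tri, 2):
                ppi.add_edge(x, y)
        extra = nx.gnp_random_graph(20, 0.12, seed=4)
        ppi.add_edges_from((f"bg{u}", f"bg{v}") for u, v in extra.edges())
        ppi.add_edge("g1", "bg0")
        ppi.add_edge("g6", "bg1")
        ppi.add_edge("g4", "bg2")
        ppi.add_edge("g5", "bg3")
        ppi.add_edge("g9", "bg4")
        return tm, gs, ppi

    def test_matches_brute_force_oracle(self):
        tm, gs, ppi = self._small_instance()
        params = CoopParams(n_random=60, seed=13)
        pipeline = {p.key for p in detect_cooperations(tm, gs, ppi, params)}
        oracle = brute_force_detect(tm, gs, ppi, params)
        assert pipeline == oracle
        assert pipeline  # the instance is constructed to accept something

    def test_empty_target_map(self):
        tm = TargetMap(cancer_label="E")
        assert detect_cooperations(tm, GeneSetCollection(
            terms={"T": ("d", frozenset({"g1"}))}), nx.Graph()) == []

    def test_label_symmetry(self):
        tm, gs, ppi = self._small_instance()
        params = CoopParams(n_random=40, seed=3)
        out = detect_cooperations(tm, gs, ppi, params)
        for p in out:
            assert p.lncrna_a < p.lncrna_b
            assert len(p.key) == 2

    def test_alpha_monotonicity(self):
        tm, gs, ppi = self._small_instance()
        tight = {p.key for p in detect_cooperations(
            tm, gs, ppi, CoopParams(n_random=40, seed=3,
                                    alpha_enrich=0.01, alpha_cpl=0.01))}
        loose = {p.key for p in detect_cooperations(
            tm, gs, ppi, CoopParams(n_random=40, seed=3,
                                    alpha_enrich=0.2, alpha_cpl=0.2))}
        assert tight <= loose
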