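"""Detection of functionally cooperative lncRNA pairs.

A pair of lncRNAs cooperates when it (1) shares at least ``min_shared``
target genes, significantly more than expected by hypergeometric chance;
(2) the shared targets are enriched in at least one GO BP term
(hypergeometric upper tail); and (3) the resulting candidate module —
shared targets annotated to the term — is compact in the protein
interaction network: every module gene lies within shortest-path distance
2 of another module gene, and the module's characteristic path length
(CPL) is significantly shorter than in degree-preserving random networks
generated by repeated double-edge switches.

The permutation p-value is the fraction of random networks in which the
same gene subset attains a strictly shorter CPL than in the real network;
the random ensemble is generated once per detection run and shared by all
candidate modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncoop.io import GeneSetCollection
from lncoop.regression import TargetMap

logger = logging.getLogger(__name__)

__all__ = [
    "CoopParams",
    "FunctionalModule",
    "CooperationPair",
    "candidate_pairs",
    "enrich_modules",
    "min_distance_ok",
    "characteristic_path_length",
    "edge_switch",
    "random_ensemble",
    "cpl_permutation_p",
    "detect_cooperations",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class CoopParams:
    """Thresholds and null-model settings for cooperation detection."""

    min_shared: int = 3
    alpha_overlap: float = 0.05
    alpha_enrich: float = 0.05
    alpha_cpl: float = 0.05
    min_module: int = 3
    n_random: int = 1000
    n_swaps: int | None = None  # default 10 * |E| attempted swaps
    seed: int = 0
    require_overlap_test: bool = True
    strict_min_dist: bool = False  # all pairwise distances <= 2 instead of per-gene
    adjust_enrichment: bool = False  # BH over GO terms


@dataclass
class FunctionalModule:
    """A candidate or accepted co-regulated module of one lncRNA pair."""

    lncrna_a: str
    lncrna_b: str
    go_term: str
    genes: frozenset
    enrich_p: float
    min_dist_ok: bool | None = None
    cpl_real: float | None = None
    cpl_p: float | None = None
    n_random: int = 0

    def accepted(self, params: CoopParams) -> bool:
        return (self.enrich_p < params.alpha_enrich
                and bool(self.min_dist_ok)
                and self.cpl_p is not None
                and self.cpl_p < params.alpha_cpl)


@dataclass
class CooperationPair:
    """A validated cooperative lncRNA pair with its accepted module(s)."""

    lncrna_a: str
    lncrna_b: str
    cancer_label: str
    n_shared: int
    overlap_p: float
    modules: list = field(default_factory=list)

    @property
    def key(self) -> frozenset:
        return frozenset((self.lncrna_a, self.lncrna_b))

    @property
    def go_terms(self) -> set:
        return {m.go_term for m in self.modules}


def hypergeom_overlap_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for overlap k of draws n against K successes in N."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def candidate_pairs(
    targets: TargetMap,
    min_shared: int = 3,
    alpha_overlap: float = 0.05,
    require_overlap_test: bool = True,
) -> list[tuple[frozenset, frozenset, float]]:
    """Candidate lncRNA pairs sharing targets.

    Returns (pair, shared target set, overlap_p) for every unordered pair
    with at least ``min_shared`` shared targets whose overlap is
    hypergeometrically significant against the universe of mRNAs tested
    in this cancer. Set ``require_overlap_test=False`` to keep every pair
    meeting the count threshold regardless of p.
    """
    index = targets.target_index()
    N = targets.n_mrna_tested
    out = []
    for a, b in combinations(sorted(index), 2):
        shared = index[a] & index[b]
        if len(shared) < min_shared:
            continue
        p = hypergeom_overlap_p(N, len(index[a]), len(index[b]), len(shared))
        if require_overlap_test and p >= alpha_overlap:
            continue
        out.append((frozenset((a, b)), frozenset(shared), p))
    return out


def enrich_modules(
    shared: frozenset,
    genesets: GeneSetCollection,
    universe: frozenset,
    alpha_enrich: float = 0.05,
    min_module: int = 3,
    adjust: bool = False,
    lncrna_a: str = "",
    lncrna_b: str = "",
) -> list[FunctionalModule]:
    """Hypergeometric GO enrichment of a shared-target set.

    Per term, successes are the term's genes within the tested-mRNA
    universe; a candidate module is the intersection of the shared set
    with the term, emitted when the upper-tail p clears ``alpha_enrich``
    (optionally BH-adjusted across terms) and the module keeps at least
    ``min_module`` genes.
    """
    shared = frozenset(shared) & universe
    N = len(universe)
    results = []
    for tid in genesets:
        term_genes = genesets.genes(tid) & universe
        if not term_genes:
            warnings.warn(f"term {tid!r} absent from universe, skipped", stacklevel=2)
            continue
        genes = shared & term_genes
        p = hypergeom_overlap_p(N, len(term_genes), len(shared), len(genes))
        results.append((tid, genes, p))
    if not results:
        return []
    pvals = np.array([p for _, _, p in results])
    adj = multipletests(pvals, method="fdr_bh")[1] if adjust else pvals
    modules = []
    for (tid, genes, _), p in zip(results, adj):
        if p < alpha_enrich and len(genes) >= min_module:
            modules.append(FunctionalModule(
                lncrna_a=lncrna_a, lncrna_b=lncrna_b,
                go_term=tid, genes=frozenset(genes), enrich_p=float(p)))
    return modules


def _subset_distances(genes: frozenset, graph: nx.Graph, cutoff=None) -> dict:
    """Pairwise shortest-path distances within ``genes`` in the full graph."""
    members = [g for g in genes if g in graph]
    dist: dict = {}
    for g in members:
        lengths = nx.single_source_shortest_path_length(graph, g, cutoff=cutoff)
        for h in members:
            if h != g and h in lengths:
                dist[frozenset((g, h))] = lengths[h]
    return dist


def min_distance_ok(genes: frozenset, ppi: nx.Graph, strict: bool = False) -> bool:
    """Within-module compactness criterion in the interaction network.

    Default reading: every gene has at least one other module gene at
    shortest-path distance <= 2. ``strict=True`` demands all pairwise
    distances <= 2. Genes absent from the network fail the criterion.
    """
    genes = frozenset(genes)
    if any(g not in ppi for g in genes):
        return False
    dist = _subset_distances(genes, ppi, cutoff=2)
    if strict:
        n = len(genes)
        return len(dist) == n * (n - 1) // 2
    for g in genes:
        if not any(g in pair for pair in dist):
            return False
    return True


def characteristic_path_length(genes: frozenset, ppi: nx.Graph) -> float | None:
    """Mean shortest-path distance over connected gene pairs of the module.

    Pairs with no connecting path (including genes absent from the
    network) are excluded from the mean; returns None when no pair is
    connected.
    """
    dist = _subset_distances(frozenset(genes), ppi)
    if not dist:
        return None
    return float(sum(dist.values()) / len(dist))


def edge_switch(
    ppi: nx.Graph,
    n_swaps: int | None = None,
    seed=None,
) -> nx.Graph:
    """Degree-preserving randomisation by attempted double-edge switches.

    Each attempt picks two distinct edges (a,b), (c,d) and proposes
    rewiring to (a,d), (c,b); attempts that would create a self-loop or a
    multi-edge are rejected. The degree sequence is invariant. ``seed``
    may be an int or a numpy Generator; default attempts = 10 * |E|.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges = [tuple(e) for e in ppi.edges()]
    m = len(edges)
    if m < 2:
        return ppi.copy()
    if n_swaps is None:
        n_swaps = 10 * m
    edge_set = {frozenset(e) for e in edges}
    idx = rng.integers(0, m, size=(n_swaps, 2))
    flips = rng.integers(0, 2, size=n_swaps)
    for (i, j), flip in zip(idx, flips):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flip:  # choose which orientation of the second edge to cross
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
    g = nx.Graph()
    g.add_nodes_from(ppi.nodes())
    g.add_edges_from(edges)
    return g


def random_ensemble(
    ppi: nx.Graph,
    n_random: int = 1000,
    n_swaps: int | None = None,
    seed: int = 0,
) -> list[nx.Graph]:
    """Generate the shared ensemble of degree-preserving random networks."""
    ss = np.random.SeedSequence(int(seed))
    return [edge_switch(ppi, n_swaps=n_swaps, seed=np.random.default_rng(child))
            for child in ss.spawn(n_random)]


def cpl_permutation_p(
    genes: frozenset,
    ppi: nx.Graph,
    n_random: int = 1000,
    seed: int = 0,
    ensemble: list[nx.Graph] | None = None,
) -> tuple[float | None, float | None]:
    """Permutation p for module compactness against edge-switch nulls.

    p = fraction of random networks in which the module's CPL is strictly
    shorter than in the real network (ties count as not-shorter; a random
    network where the module CPL is undefined also counts as not-shorter).
    Returns (cpl_real, p); (None, None) when CPL is undefined on the real
    network.
    """
    cpl_real = characteristic_path_length(genes, ppi)
    if cpl_real is None:
        return None, None
    if ensemble is None:
        ensemble = random_ensemble(ppi, n_random=n_random, seed=seed)
    shorter = 0
    for g in ensemble:
        cpl_rand = characteristic_path_length(genes, g)
        if cpl_rand is not None and cpl_rand < cpl_real:
            shorter += 1
    return cpl_real, shorter / len(ensemble)


def detect_cooperations(
    targets: TargetMap,
    genesets: GeneSetCollection,
    ppi: nx.Graph,
    params: CoopParams = CoopParams(),
) -> list[CooperationPair]:
    """Full cooperation pipeline: overlap, enrichment, topology filters.

    A pair is retained iff at least one candidate module passes the
    enrichment threshold, the within-module distance criterion and the
    CPL permutation test. Deterministic given ``params.seed``.
    """
    if not targets.records:
        return []
    universe_ids = _universe(targets)
    cands = candidate_pairs(targets, params.min_shared, params.alpha_overlap,
                            params.require_overlap_test)
    if not cands:
        return []
    ensemble = random_ensemble(ppi, n_random=params.n_random,
                               n_swaps=params.n_swaps, seed=params.seed)
    out = []
    for pair, shared, overlap_p in cands:
        a, b = sorted(pair)
        modules = enrich_modules(shared, genesets, universe_ids,
                                 alpha_enrich=params.alpha_enrich,
                                 min_module=params.min_module,
                                 adjust=params.adjust_enrichment,
                                 lncrna_a=a, lncrna_b=b)
        accepted = []
        for mod in modules:
            mod.min_dist_ok = min_distance_ok(mod.genes, ppi,
                                              strict=params.strict_min_dist)
            if not mod.min_dist_ok:
                continue
            mod.cpl_real, mod.cpl_p = cpl_permutation_p(
                mod.genes, ppi, ensemble=ensemble)
            mod.n_random = len(ensemble)
            if mod.accepted(params):
                accepted.append(mod)
        if accepted:
            out.append(CooperationPair(
                lncrna_a=a, lncrna_b=b, cancer_label=targets.cancer_label,
                n_shared=len(shared), overlap_p=overlap_p, modules=accepted))
    return out


def _universe(targets: TargetMap) -> frozenset:
    """The tested-mRNA universe used for both hypergeometric tests."""
    if targets.tested_mrnas:
        return targets.tested_mrnas
    # map built without universe bookkeeping: fall back to observed targets
    return frozenset(r.mrna_id for r in targets.records)


def pairs_to_frame(pairs: list[CooperationPair]) -> pd.DataFrame:
    """Flatten accepted pairs to one row per accepted module."""
    rows = []
    for p in pairs:
        for m in p.modules:
            rows.append((p.lncrna_a, p.lncrna_b, p.cancer_label, p.n_shared,
                         p.overlap_p, m.go_term, ",".join(sorted(m.genes)),
                         m.enrich_p, m.cpl_real, m.cpl_p))
    return pd.DataFrame(rows, columns=[
        "lncrna_a", "lncrna_b", "cancer", "n_shared", "overlap_p",
        "go_term", "module_genes", "enrich_p", "cpl", "cpl_p"])
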