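"""Cooperation-network construction and LICN analytics.

Builds the pan-cancer cooperation network (edges carry the cancers and GO
terms of their accepted modules), extracts per-cancer networks and the
immune cooperative subnetworks (LICNs: edges backed by at least one
immune-flagged module; their nodes are the IC-lncRNAs), identifies degree
hubs (top decile with tie extension), classifies pan-cancer hubs by how
many per-cancer LICNs they are hubs of, and summarises topology (degree
distribution, discrete power-law exponent, clustering against
degree-preserving nulls) and catalog counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from lncoop.cooperation import CooperationPair, random_ensemble

__all__ = [
    "NetworkSet",
    "HubClassification",
    "DEFAULT_IMMUNE_KEYWORDS",
    "flag_immune_terms",
    "build_networks",
    "identify_hubs",
    "classify_hubs",
    "summarize_topology",
    "summary_counts",
    "pct",
]

DEFAULT_IMMUNE_KEYWORDS = (
    "immune", "t cell", "t_cell", "b cell", "b_cell", "lymphocyte",
    "leukocyte", "cytokine", "interleukin", "interferon", "inflammat",
    "chemokine", "antigen", "natural killer", "natural_killer",
)


def flag_immune_terms(term_ids, keywords=DEFAULT_IMMUNE_KEYWORDS) -> set:
    """Keyword fallback for immune GO-term flagging (case-insensitive)."""
    out = set()
    for tid in term_ids:
        low = tid.lower().replace("-", "_")
        if any(k.replace(" ", "_") in low.replace(" ", "_") for k in keywords):
            out.add(tid)
    return out


@dataclass
class NetworkSet:
    """Pan-cancer and per-cancer cooperation networks with their LICNs."""

    pan: nx.Graph
    per_cancer: dict
    licn: dict
    pan_licn: nx.Graph

    @property
    def ic_lncrnas(self) -> set:
        return set(self.pan_licn.nodes())


@dataclass
class HubClassification:
    """Category of one pan-cancer hub by per-cancer hub memberships."""

    lncrna_id: str
    category: str  # common | specific | other
    memberships: frozenset = field(default_factory=frozenset)


def _add_pair(g: nx.Graph, pair: CooperationPair, immune_terms: set) -> None:
    a, b = pair.lncrna_a, pair.lncrna_b
    if not g.has_edge(a, b):
        g.add_edge(a, b, cancers=set(), terms=set(), immune=False)
    d = g.edges[a, b]
    d["cancers"].add(pair.cancer_label)
    d["terms"] |= pair.go_terms
    if pair.go_terms & immune_terms:
        d["immune"] = True


def _immune_subgraph(g: nx.Graph) -> nx.Graph:
    h = nx.Graph()
    for a, b, d in g.edges(data=True):
        if d["immune"]:
            h.add_edge(a, b, **{k: (set(v) if isinstance(v, set) else v)
                                for k, v in d.items()})
    return h


def build_networks(pairs: list[CooperationPair], immune_terms: set) -> NetworkSet:
    """Assemble pan-cancer/per-cancer cooperation networks and LICNs.

    An edge is immune iff at least one of its accepted modules' GO terms
    is in ``immune_terms``; the LICN keeps exactly the immune edges, and
    its nodes are the IC-lncRNAs.
    """
    immune_terms = set(immune_terms)
    pan = nx.Graph()
    per_cancer: dict = {}
    for p in pairs:
        _add_pair(pan, p, immune_terms)
        g = per_cancer.setdefault(p.cancer_label, nx.Graph())
        _add_pair(g, p, immune_terms)
    licn = {c: _immune_subgraph(g) for c, g in per_cancer.items()}
    return NetworkSet(pan=pan, per_cancer=per_cancer, licn=licn,
                      pan_licn=_immune_subgraph(pan))


def identify_hubs(network: nx.Graph, top_frac: float = 0.10) -> set:
    """Top-degree hubs: ceil(top_frac * |V|) nodes, extended across ties.

    Every node whose degree ties the last included node is a hub, so the
    hub set is deterministic and independent of node order.
    """
    if network.number_of_nodes() == 0:
        return set()
    degrees = dict(network.degree())
    k = math.ceil(top_frac * len(degrees))
    cutoff = sorted(degrees.values(), reverse=True)[k - 1]
    return {v for v, d in degrees.items() if d >= cutoff}


def classify_hubs(pan_hubs: set, per_cancer_hub_sets: dict) -> list[HubClassification]:
    """Partition pan-cancer hubs by per-cancer hub membership count.

    ``common``: hub of two or more per-cancer LICNs; ``specific``: hub of
    exactly one; ``other``: hub of none.
    """
    out = []
    for h in sorted(pan_hubs):
        member = frozenset(c for c, hubs in per_cancer_hub_sets.items() if h in hubs)
        if len(member) >= 2:
            cat = "common"
        elif len(member) == 1:
            cat = "specific"
        else:
            cat = "other"
        out.append(HubClassification(lncrna_id=h, category=cat, memberships=member))
    return out


def powerlaw_alpha(degrees, d_min: int = 1) -> float | None:
    """Discrete maximum-likelihood power-law exponent on degrees >= d_min.

    alpha = 1 + n / sum(ln(d / (d_min - 1/2))); descriptive only.
    """
    d = np.asarray([x for x in degrees if x >= d_min], dtype=float)
    if d.size == 0:
        return None
    denom = np.log(d / (d_min - 0.5)).sum()
    if denom <= 0:
        return None
    return float(1.0 + d.size / denom)


def summarize_topology(
    network: nx.Graph, n_random: int = 100, seed: int = 0
) -> dict:
    """Topology report: degrees, power-law fit, clustering vs nulls.

    The clustering comparison draws ``n_random`` edge-switch nulls and
    reports the empirical one-sided p that a null network's mean
    clustering coefficient reaches the observed one.
    """
    degrees = [d for _, d in network.degree()]
    hist = np.bincount(degrees) if degrees else np.array([], dtype=int)
    report = {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "degree_histogram": hist.tolist(),
        "powerlaw_alpha": powerlaw_alpha(degrees),
        "mean_clustering": None,
        "null_mean_clustering": None,
        "clustering_p": None,
        "modularity": None,
    }
    if network.number_of_edges() == 0:
        return report
    cc = nx.average_clustering(network)
    report["mean_clustering"] = float(cc)
    try:
        comms = nx.community.greedy_modularity_communities(network)
        report["modularity"] = float(nx.community.modularity(network, comms))
    except (nx.NetworkXError, ZeroDivisionError):
        pass
    nulls = [nx.average_clustering(g)
             for g in random_ensemble(network, n_random=n_random, seed=seed)]
    report["null_mean_clustering"] = float(np.mean(nulls))
    report["clustering_p"] = float(np.mean([c >= cc for c in nulls]))
    return report


def pct(numerator: float, denominator: float, digits: int = 2) -> float:
    """Percentage rounded to ``digits`` decimals (the catalog convention)."""
    return round(100.0 * numerator / denominator, digits)


def summary_counts(
    pairs: list[CooperationPair],
    networks: NetworkSet,
    n_lncrna_universe: int | None = None,
) -> dict:
    """Catalog arithmetic over the detected cooperation landscape.

    Reports totals plus the standard ratios: the fraction of cooperative
    lncRNAs active in two or more cancers, the fraction of cancer-specific
    edges, the IC-lncRNA share of cooperative lncRNAs, optionally the
    cooperative share of the full lncRNA universe, and pair counts per GO
    term.
    """
    pan = networks.pan
    lnc_cancers: dict = {}
    for a, b, d in pan.edges(data=True):
        for v in (a, b):
            lnc_cancers.setdefault(v, set()).update(d["cancers"])
    n_lnc = len(lnc_cancers)
    n_multi = sum(1 for s in lnc_cancers.values() if len(s) >= 2)
    edge_labels = [d["cancers"] for _, _, d in pan.edges(data=True)]
    n_specific = sum(1 for s in edge_labels if len(s) == 1)
    per_function: dict = {}
    for p in pairs:
        for t in p.go_terms:
            per_function[t] = per_function.get(t, 0) + 1
    report = {
        "n_pairs": pan.number_of_edges(),
        "n_pair_cancer_instances": len(pairs),
        "n_lncrnas": n_lnc,
        "n_ic_lncrnas": len(networks.ic_lncrnas),
        "pct_multi_cancer_lncrnas": pct(n_multi, n_lnc) if n_lnc else None,
        "pct_cancer_specific_edges": (pct(n_specific, len(edge_labels))
                                      if edge_labels else None),
        "pct_ic_of_cooperative": (pct(len(networks.ic_lncrnas), n_lnc)
                                  if n_lnc else None),
        "pairs_per_function": dict(sorted(per_function.items())),
    }
    if n_lncrna_universe:
        report["pct_cooperative_of_universe"] = pct(n_lnc, n_lncrna_universe)
    return report


def hubs_to_frame(network: nx.Graph, classifications: list[HubClassification]) -> pd.DataFrame:
    deg = dict(network.degree())
    rows = [(c.lncrna_id, deg.get(c.lncrna_id, 0), c.category,
             ",".join(sorted(c.memberships)))
            for c in classifications]
    return pd.DataFrame(rows, columns=["lncrna", "degree", "category", "memberships"])
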