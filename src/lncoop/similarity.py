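"""Cross-cancer similarity from immune cooperative networks.

Two complementary views are averaged: R1, the Jaccard coefficient of
IC-lncRNA membership between two cancers' LICNs, and R2, the Pearson
correlation of mean log2 expression of the shared pan-cancer IC-lncRNAs.
Cancers are then hierarchically clustered on distance 1 - (R1 + R2)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from lncoop.errors import ValidationError

__all__ = [
    "jaccard",
    "expression_similarity",
    "SimilarityMatrix",
    "build_similarity",
    "cluster_cancers",
]


def jaccard(set_a: set, set_b: set) -> float:
    """|A n B| / |A u B|; defined 0 (with a warning) when both are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets, returning 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def expression_similarity(
    mean_expr_a: pd.Series,
    mean_expr_b: pd.Series,
    shared_lncrnas,
) -> float | None:
    """Pearson r of per-lncRNA mean expression over a shared feature set.

    Returns None (undefined) with fewer than 3 shared features carrying
    finite means in both cancers.
    """
    shared = [l for l in shared_lncrnas
              if l in mean_expr_a.index and l in mean_expr_b.index]
    x = mean_expr_a[shared].to_numpy(dtype=float)
    y = mean_expr_b[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return None
    r, _ = stats.pearsonr(x[ok], y[ok])
    return float(r)


@dataclass
class SimilarityMatrix:
    """R1 (Jaccard), R2 (Pearson) and their mean, cancers x cancers."""

    r1: pd.DataFrame
    r2: pd.DataFrame
    combined: pd.DataFrame

    def validate(self) -> None:
        for name in ("r1", "r2", "combined"):
            m = getattr(self, name).to_numpy(dtype=float)
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValidationError(f"{name} matrix is not symmetric")


def build_similarity(
    licn_nodes: dict,
    mean_expr: dict,
    feature_set: set | None = None,
) -> SimilarityMatrix:
    """Assemble the similarity matrix over cancers.

    ``licn_nodes`` maps cancer -> IC-lncRNA set; ``mean_expr`` maps
    cancer -> per-lncRNA mean log2 expression. ``feature_set`` (default:
    the pan-cancer union of IC-lncRNAs) bounds R2's feature universe.
    Where R2 is undefined for a pair, the combined score falls back to R1
    alone; negative combined entries are flagged with a warning.
    """
    cancers = sorted(licn_nodes)
    if feature_set is None:
        feature_set = set().union(*licn_nodes.values()) if cancers else set()
    n = len(cancers)
    r1 = np.eye(n)
    r2 = np.full((n, n), np.nan)
    np.fill_diagonal(r2, 1.0)
    comb = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cancers[i], cancers[j]
            v1 = jaccard(licn_nodes[a], licn_nodes[b])
            v2 = expression_similarity(mean_expr[a], mean_expr[b], sorted(feature_set))
            c = v1 if v2 is None else (v1 + v2) / 2.0
            r1[i, j] = r1[j, i] = v1
            if v2 is not None:
                r2[i, j] = r2[j, i] = v2
            comb[i, j] = comb[j, i] = c
    if (comb < 0).any():
        warnings.warn("negative combined similarity entries present", stacklevel=2)
    idx = pd.Index(cancers, name="cancer")
    sim = SimilarityMatrix(
        r1=pd.DataFrame(r1, index=idx, columns=idx),
        r2=pd.DataFrame(r2, index=idx, columns=idx),
        combined=pd.DataFrame(comb, index=idx, columns=idx),
    )
    sim.validate()
    return sim


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.left, labels)
    right = _newick(node.right, labels)
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_cancers(
    similarity: SimilarityMatrix,
    linkage_method: str = "average",
    n_clusters: int | None = None,
    height: float | None = None,
) -> dict:
    """Agglomerative clustering of cancers on 1 - combined similarity.

    Returns the scipy linkage matrix, a Newick serialisation of the
    dendrogram, and flat cluster labels at the requested cut
    (``n_clusters`` takes precedence; default is a 2-cluster cut).
    """
    similarity.validate()
    comb = similarity.combined
    cancers = list(comb.index)
    dist = 1.0 - comb.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=linkage_method)
    tree = to_tree(Z)
    newick = _newick(tree, cancers) + ";"
    if n_clusters is None and height is None:
        n_clusters = 2
    if n_clusters is not None:
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        flat = fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(flat, index=pd.Index(cancers, name="cancer"), name="cluster")
    return {"linkage": Z, "newick": newick, "clusters": labels}
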