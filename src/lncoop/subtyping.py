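"""Immune subtype discovery by consensus clustering of IC-lncRNAs.

Feature selection follows three ordered filters — expressed (> 0) in more
than half the samples, top decile of expression variance, intersection
with the network hubs — then samples are consensus-clustered (Monti
resampling: repeated subsampling, inner hierarchical clustering with
1 - Pearson distance, co-clustering frequencies) into k groups. Subtypes
are compared on infiltration, immune scores (cytolytic activity, MHC,
mean immune z-score), checkpoint-gene expression and clinical indicators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from lncoop.errors import ValidationError
from lncoop.infiltration import wilcoxon_two_group

__all__ = [
    "select_subtype_features",
    "SubtypeAssignment",
    "consensus_cluster",
    "ImmuneGeneLists",
    "immune_scores",
    "compare_subtypes",
]

# overridable defaults; the cytolytic score follows the GZMA/PRF1 convention
DEFAULT_CYT_GENES = ("GZMA", "PRF1")
DEFAULT_MHC_GENES = ("HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2")
DEFAULT_CHECKPOINT_GENES = ("PDCD1", "CD274", "CTLA4")


def select_subtype_features(
    expr: pd.DataFrame,
    hub_set: set,
    min_expressed_frac: float = 0.5,
    top_var_frac: float = 0.10,
) -> list:
    """Ordered feature filters: expression, variance decile, hubs.

    Step 1 keeps lncRNAs expressed (> 0) in more than
    ``min_expressed_frac`` of samples; step 2 keeps the top
    ``top_var_frac`` by expression variance (ceil count, ties at the cut
    included); step 3 intersects with ``hub_set``. Order-stable: the
    result is sorted.
    """
    expressed = expr.loc[(expr > 0).mean(axis=1) > min_expressed_frac]
    if expressed.empty:
        raise ValidationError("no lncRNA passes the expression filter; relax thresholds")
    var = expressed.var(axis=1, ddof=1)
    k = math.ceil(top_var_frac * len(var))
    cutoff = var.sort_values(ascending=False).iloc[k - 1]
    top = set(var.index[var >= cutoff])
    selected = sorted(top & set(hub_set))
    if not selected:
        raise ValidationError(
            "no top-variance lncRNA is a hub; relax top_var_frac or the hub rule")
    return selected


@dataclass
class SubtypeAssignment:
    """Consensus-clustering result for one cohort."""

    labels: pd.Series  # sample -> 1..k
    consensus: pd.DataFrame  # samples x samples co-clustering frequency
    k: int
    features: list = field(default_factory=list)

    def validate(self) -> None:
        c = self.consensus.to_numpy(dtype=float)
        if not np.allclose(c, c.T):
            raise ValidationError("consensus matrix not symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValidationError("consensus diagonal must be 1")
        if c.min() < 0 or c.max() > 1 + 1e-12:
            raise ValidationError("consensus entries outside [0, 1]")


def _cluster_samples(mat: np.ndarray, k: int) -> np.ndarray:
    """Inner clusterer: hierarchical, 1 - Pearson distance, average linkage.

    ``mat`` is samples x features; returns integer labels 1..k.
    """
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    expr_features: pd.DataFrame,
    k: int = 2,
    n_resample: int = 1000,
    sample_frac: float = 0.8,
    seed: int = 0,
) -> SubtypeAssignment:
    """Monti-style consensus clustering of samples.

    Per resample, ``floor(sample_frac * n)`` samples are drawn without
    replacement and clustered into ``k`` groups; consensus(i, j) is the
    co-cluster count over the co-sample count (pairs never co-sampled are
    imputed 0 with a warning). Final labels come from hierarchically
    clustering 1 - consensus into ``k`` groups. Fully seeded.
    """
    samples = list(expr_features.columns)
    n = len(samples)
    if expr_features.shape[0] < 2 or n < 2 * k:
        raise ValidationError("need >= 2 features and >= 2k samples")
    mat = expr_features.to_numpy(dtype=float).T  # samples x features
    rng = np.random.default_rng(seed)
    m = int(sample_frac * n)
    together = np.zeros((n, n))
    cosampled = np.zeros((n, n))
    for _ in range(n_resample):
        idx = rng.choice(n, size=m, replace=False)
        labels = _cluster_samples(mat[idx], k)
        cosampled[np.ix_(idx, idx)] += 1
        for lab in range(1, k + 1):
            grp = idx[labels == lab]
            together[np.ix_(grp, grp)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
    if (cosampled == 0).any():
        warnings.warn("some sample pairs never co-sampled; consensus imputed 0",
                      stacklevel=2)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    dist = np.maximum(1.0 - consensus, 0.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    idx_s = pd.Index(samples, name="sample_id")
    assignment = SubtypeAssignment(
        labels=pd.Series(labels, index=idx_s, name="subtype"),
        consensus=pd.DataFrame(consensus, index=idx_s, columns=idx_s),
        k=k,
        features=list(expr_features.index),
    )
    assignment.validate()
    return assignment


@dataclass(frozen=True)
class ImmuneGeneLists:
    """Gene lists behind the per-sample immune scores (all overridable)."""

    cyt_genes: tuple = DEFAULT_CYT_GENES
    mhc_genes: tuple = DEFAULT_MHC_GENES
    immune_genes: tuple = ()


def immune_scores(
    expr_log2: pd.DataFrame,
    gene_lists: ImmuneGeneLists,
    cyt_offset: float = 1.0,
) -> pd.DataFrame:
    """Per-sample CYT, MHC and immune scores from log2 expression.

    CYT is the geometric mean of linear-scale (2**log2) expression of the
    cytolytic genes plus ``cyt_offset``; MHC is the mean log2 expression
    of the MHC genes; the immune score is the mean per-gene z-score of
    the immune gene list. Missing genes are dropped with a warning; a
    score with no surviving genes is NaN.
    """
    out = pd.DataFrame(index=expr_log2.columns)

    def _present(genes, label):
        have = [g for g in genes if g in expr_log2.index]
        missing = set(genes) - set(have)
        if missing:
            warnings.warn(f"{label}: missing genes {sorted(missing)}", stacklevel=3)
        return have

    cyt = _present(gene_lists.cyt_genes, "cyt")
    if cyt:
        linear = 2.0 ** expr_log2.loc[cyt].to_numpy(dtype=float)
        out["cyt"] = np.exp(np.log(linear + cyt_offset).mean(axis=0))
    else:
        out["cyt"] = np.nan
    mhc = _present(gene_lists.mhc_genes, "mhc")
    out["mhc"] = expr_log2.loc[mhc].mean(axis=0) if mhc else np.nan
    imm = _present(gene_lists.immune_genes, "immune_score")
    if imm:
        sub = expr_log2.loc[imm].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        z = (sub - sub.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
        out["immune_score"] = z.mean(axis=0)
    else:
        out["immune_score"] = np.nan
    return out


def _two_group(values: pd.Series, g1, g2, test: str) -> tuple[float, float]:
    x = values.reindex(g1).dropna().to_numpy(dtype=float)
    y = values.reindex(g2).dropna().to_numpy(dtype=float)
    if test == "wilcoxon":
        return wilcoxon_two_group(x, y)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def compare_subtypes(
    assignment: SubtypeAssignment,
    infiltration: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
    checkpoint_expr: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
    feature_expr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-subtype comparison report.

    Wilcoxon-Mann-Whitney for infiltration fractions, immune scores,
    checkpoint genes and the clinical depth/proliferation indicators;
    Welch t for the subtype-defining lncRNAs; plus Pearson correlations
    between feature lncRNAs and checkpoint genes. Rows: variable, family,
    test, n per group, group means, statistic, p.
    """
    if assignment.k != 2:
        raise ValidationError("comparison is defined for exactly two subtypes")
    lab = assignment.labels
    g1 = list(lab.index[lab == 1])
    g2 = list(lab.index[lab == 2])
    if len(g1) < 5 or len(g2) < 5:
        raise ValidationError("need >= 5 samples per subtype")
    rows = []

    def _block(df: pd.DataFrame | None, family: str, test: str, by_row: bool):
        if df is None:
            return
        it = df.index if by_row else df.columns
        for var in it:
            vals = df.loc[var] if by_row else df[var]
            vals = pd.to_numeric(vals, errors="coerce")
            if vals.reindex(g1 + g2).notna().sum() == 0:
                warnings.warn(f"{var!r}: all missing, skipped", stacklevel=3)
                continue
            stat, p = _two_group(vals, g1, g2, test)
            rows.append((str(var), family, test, len(g1), len(g2),
                         float(vals.reindex(g1).mean()),
                         float(vals.reindex(g2).mean()), stat, p))

    _block(infiltration, "infiltration", "wilcoxon", by_row=False)
    _block(scores, "immune_score", "wilcoxon", by_row=False)
    _block(checkpoint_expr, "checkpoint", "wilcoxon", by_row=True)
    if clinical is not None:
        clin_cols = [c for c in ("breslow_depth", "mitotic_rate") if c in clinical]
        _block(clinical[clin_cols], "clinical", "wilcoxon", by_row=False)
    _block(feature_expr, "feature_lncrna", "t", by_row=True)

    if feature_expr is not None and checkpoint_expr is not None:
        shared = [s for s in feature_expr.columns if s in checkpoint_expr.columns]
        for lnc in feature_expr.index:
            for gene in checkpoint_expr.index:
                r, p = stats.pearsonr(
                    feature_expr.loc[lnc, shared].astype(float),
                    checkpoint_expr.loc[gene, shared].astype(float))
                rows.append((f"{lnc}~{gene}", "correlation", "pearson",
                             len(shared), len(shared), np.nan, np.nan,
                             float(r), float(p)))
    return pd.DataFrame(rows, columns=[
        "variable", "family", "test", "n1", "n2",
        "mean1", "mean2", "statistic", "p"])
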