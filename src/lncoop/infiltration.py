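"""lncRNA expression versus immune-cell infiltration.

Spearman correlation screening against TIMER-style per-sample infiltration
fractions (pass when |rho| > 0.3 and p < 0.05), differential expression
between patient groups split at the median infiltration of a cell type
(geometric fold change on log2 expression, Welch t test, BH FDR), and
Fisher's exact enrichment of a differential set within the IC-lncRNA set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncoop.errors import ValidationError

__all__ = [
    "correlate_infiltration",
    "median_split_de",
    "fisher_overlap",
    "OverlapResult",
    "wilcoxon_two_group",
]


def correlate_infiltration(
    expr: pd.DataFrame,
    infiltration: pd.DataFrame,
    r_cut: float = 0.3,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho of each lncRNA against each infiltration cell type.

    ``expr`` is features x samples, ``infiltration`` samples x cell
    types; shared samples (>= 10 required) are used. Constant expression
    vectors are skipped with a warning. Returns a table with columns
    lncrna, cell_type, spearman_r, p, passes.
    """
    shared = [s for s in expr.columns if s in infiltration.index]
    if len(shared) < 10:
        raise ValidationError(f"only {len(shared)} shared samples, need >= 10")
    rows = []
    for lnc in expr.index:
        x = expr.loc[lnc, shared].to_numpy(dtype=float)
        if np.ptp(x[np.isfinite(x)]) == 0:
            warnings.warn(f"constant expression for {lnc!r}, skipped", stacklevel=2)
            continue
        for ct in infiltration.columns:
            y = infiltration.loc[shared, ct].to_numpy(dtype=float)
            rho, p = stats.spearmanr(x, y, nan_policy="omit")
            passes = bool(abs(rho) > r_cut and p < p_cut)
            rows.append((lnc, ct, float(rho), float(p), passes))
    return pd.DataFrame(rows, columns=["lncrna", "cell_type", "spearman_r", "p", "passes"])


def median_split_de(
    expr: pd.DataFrame,
    infiltration: pd.DataFrame,
    cell_type: str,
    fc_cut: float = 2.0,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Differential lncRNAs between high and low infiltration halves.

    Samples above the median infiltration of ``cell_type`` form the high
    group (ties go low). Per lncRNA on log2 expression: fold change
    ``2**(mean_high - mean_low)``, Welch two-sided t test, BH FDR over
    all lncRNAs. Differential iff FC > ``fc_cut`` or FC < 1/``fc_cut``,
    and FDR < ``fdr_cut``.
    """
    shared = [s for s in expr.columns if s in infiltration.index]
    score = infiltration.loc[shared, cell_type].astype(float)
    med = score.median()
    high = [s for s in shared if score[s] > med]
    low = [s for s in shared if score[s] <= med]
    if len(high) < 5 or len(low) < 5:
        raise ValidationError(
            f"median split on {cell_type!r} leaves groups of "
            f"{len(high)}/{len(low)} samples (need >= 5 each)")
    hi = expr[high].to_numpy(dtype=float)
    lo = expr[low].to_numpy(dtype=float)
    log2_fc = hi.mean(axis=1) - lo.mean(axis=1)
    t, p = stats.ttest_ind(hi, lo, axis=1, equal_var=False)
    fdr = multipletests(p, method="fdr_bh")[1]
    fc = 2.0 ** log2_fc
    de = ((fc > fc_cut) | (fc < 1.0 / fc_cut)) & (fdr < fdr_cut)
    return pd.DataFrame({
        "lncrna": expr.index,
        "fc": fc,
        "log2_fc": log2_fc,
        "t": t,
        "p": p,
        "fdr": fdr,
        "de": de,
    }).set_index("lncrna")


@dataclass(frozen=True)
class OverlapResult:
    """Fisher's exact overlap of two sets within a universe."""

    table: tuple  # (both, de_only, ic_only, neither)
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool  # Haldane 0.5 continuity correction applied


def fisher_overlap(de_set: set, ic_set: set, universe: set) -> OverlapResult:
    """Two-sided Fisher's exact test for overlap of two sets.

    The odds ratio is the sample (ad/bc) estimate with a Woolf-logit 95%
    CI; when any cell is zero, all four cells take the Haldane 0.5
    continuity correction for the estimate and CI (flagged), while the p
    value remains the exact one on the raw table.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    de = set(de_set) & universe
    ic = set(ic_set) & universe
    a = len(de & ic)
    b = len(de - ic)
    c = len(ic - de)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if corrected
                      else (a, b, c, d))
    odds = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = float(np.exp(np.log(odds) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(odds) + 1.959963984540054 * se))
    return OverlapResult(table=(a, b, c, d), odds_ratio=float(odds),
                         ci_low=lo, ci_high=hi, p=float(p), corrected=corrected)


def wilcoxon_two_group(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns (U, p)."""
    u, p = stats.mannwhitneyu(np.asarray(x, dtype=float),
                              np.asarray(y, dtype=float),
                              alternative="two-sided")
    return float(u), float(p)
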