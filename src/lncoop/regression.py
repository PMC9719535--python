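"""Cancer-context lncRNA-target discovery by multivariable linear regression.

Each candidate (lncRNA, mRNA) pair is fit as

    mRNA = b0 + b_cnv * CNV + b_meth * METH + b_lncrna * LNCRNA + eps

with gene-level copy number and promoter methylation of the mRNA as
covariates. Significance attaches to the lncRNA coefficient only (two-sided
t test, n - 4 degrees of freedom). Multiplicity is handled per cancer over
all tested pairs: Benjamini-Hochberg FDR < ``fdr_cut`` and Bonferroni
< ``bonf_cut`` must both hold for a regulation to be retained.

``screen_targets`` uses a Frisch-Waugh-Lovell factorisation: per mRNA, the
response and every lncRNA are residualised on [1, CNV, METH], and the
lncRNA coefficient, its t statistic and p-value follow from the residual
regression with the full-model degrees of freedom. Retained pairs are
refit with the explicit four-parameter model so reported coefficients come
from the canonical fit; a unit test pins the two routes to each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lncoop.errors import DegenerateFitError
from lncoop.io import OmicsBundle

logger = logging.getLogger(__name__)

__all__ = ["RegulationRecord", "TargetMap", "fit_pair", "screen_targets"]

_N_PARAMS = 4  # intercept + CNV + methylation + lncRNA


@dataclass
class RegulationRecord:
    """One fitted lncRNA->mRNA regulation."""

    lncrna_id: str
    mrna_id: str
    beta0: float
    beta_cnv: float
    beta_meth: float
    beta_lncrna: float
    p_lncrna: float
    residual_sd: float
    n_used: int
    fdr: float = np.nan
    bonferroni: float = np.nan


@dataclass
class TargetMap:
    """Significant regulations of one cancer, indexed both directions."""

    cancer_label: str
    records: list = field(default_factory=list)
    n_tested_pairs: int = 0
    n_mrna_tested: int = 0
    n_lncrna_tested: int = 0
    tested_mrnas: frozenset = frozenset()

    def targets_of(self, lncrna_id: str) -> set:
        return {r.mrna_id for r in self.records if r.lncrna_id == lncrna_id}

    def regulators_of(self, mrna_id: str) -> set:
        return {r.lncrna_id for r in self.records if r.mrna_id == mrna_id}

    @property
    def lncrnas(self) -> set:
        return {r.lncrna_id for r in self.records}

    @property
    def pairs(self) -> set:
        return {(r.lncrna_id, r.mrna_id) for r in self.records}

    def target_index(self) -> dict:
        idx: dict = {}
        for r in self.records:
            idx.setdefault(r.lncrna_id, set()).add(r.mrna_id)
        return idx

    def to_frame(self) -> pd.DataFrame:
        cols = ["lncrna", "mrna", "beta0", "beta_cnv", "beta_meth",
                "beta_lncrna", "p", "fdr", "bonferroni", "n"]
        rows = [(r.lncrna_id, r.mrna_id, r.beta0, r.beta_cnv, r.beta_meth,
                 r.beta_lncrna, r.p_lncrna, r.fdr, r.bonferroni, r.n_used)
                for r in self.records]
        return pd.DataFrame(rows, columns=cols)

    def __len__(self) -> int:
        return len(self.records)


def fit_pair(
    y: np.ndarray,
    x_cnv: np.ndarray,
    x_meth: np.ndarray,
    x_lnc: np.ndarray,
    lncrna_id: str = "",
    mrna_id: str = "",
) -> RegulationRecord:
    """Ordinary-least-squares fit of one pair, pairwise-complete.

    Raises :class:`DegenerateFitError` for < 5 complete observations, a
    constant lncRNA vector, or a rank-deficient design.
    """
    y = np.asarray(y, dtype=float)
    x_cnv = np.asarray(x_cnv, dtype=float)
    x_meth = np.asarray(x_meth, dtype=float)
    x_lnc = np.asarray(x_lnc, dtype=float)
    mask = np.isfinite(y) & np.isfinite(x_cnv) & np.isfinite(x_meth) & np.isfinite(x_lnc)
    y, x_cnv, x_meth, x_lnc = y[mask], x_cnv[mask], x_meth[mask], x_lnc[mask]
    n = y.size
    if n < 5:
        raise DegenerateFitError(f"{lncrna_id}/{mrna_id}: only {n} complete samples")
    if np.ptp(x_lnc) == 0:
        raise DegenerateFitError(f"{lncrna_id}/{mrna_id}: constant lncRNA covariate")
    X = np.column_stack([np.ones(n), x_cnv, x_meth, x_lnc])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < _N_PARAMS:
        raise DegenerateFitError(f"{lncrna_id}/{mrna_id}: rank-deficient design")
    resid = y - X @ beta
    dof = n - _N_PARAMS
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_lnc = np.sqrt(sigma2 * xtx_inv[3, 3])
    if se_lnc == 0:
        p = 0.0 if beta[3] != 0 else 1.0
    else:
        t = beta[3] / se_lnc
        p = 2.0 * stats.t.sf(abs(t), dof)
    return RegulationRecord(
        lncrna_id=lncrna_id, mrna_id=mrna_id,
        beta0=float(beta[0]), beta_cnv=float(beta[1]),
        beta_meth=float(beta[2]), beta_lncrna=float(beta[3]),
        p_lncrna=float(p), residual_sd=float(np.sqrt(sigma2)), n_used=int(n),
    )


def _expressed_filter(mat: pd.DataFrame, min_frac: float) -> pd.DataFrame:
    keep = (mat > 0).mean(axis=1) >= min_frac
    return mat.loc[keep]


def screen_targets(
    bundle: OmicsBundle,
    fdr_cut: float = 0.01,
    bonf_cut: float = 0.1,
    expressed_frac: float | None = 0.2,
) -> TargetMap:
    """Screen every (lncRNA, mRNA) pair of a bundle for regulation.

    Features expressed (> 0) in fewer than ``expressed_frac`` of samples
    are dropped first (pass ``None`` to disable). Both adjustments are
    computed over all tested pairs of the cancer; a pair is retained iff
    FDR < ``fdr_cut`` and Bonferroni-adjusted p < ``bonf_cut``.
    """
    bundle.validate()
    lnc = bundle.lncrna_expr
    mrna = bundle.mrna_expr
    if expressed_frac is not None:
        lnc = _expressed_filter(lnc, expressed_frac)
        mrna = _expressed_filter(mrna, expressed_frac)
    mrna = mrna.loc[mrna.index.intersection(bundle.cnv.index)
                    .intersection(bundle.meth.index)]

    L = lnc.to_numpy(dtype=float)  # n_lnc x n_samples
    lnc_ok = np.ptp(L, axis=1) > 0
    if not lnc_ok.all():
        logger.info("screen_targets: skipping %d constant lncRNAs",
                    int((~lnc_ok).sum()))
    L = L[lnc_ok]
    lnc_ids = list(lnc.index[lnc_ok])
    n = L.shape[1]
    dof = n - _N_PARAMS
    if dof < 1 or L.size == 0 or len(mrna) == 0:
        warnings.warn("screen_targets: nothing to test", stacklevel=2)
        return TargetMap(cancer_label=bundle.cancer_label)

    has_na = (np.isnan(L).any() or mrna.isna().any().any()
              or bundle.cnv.isna().any().any() or bundle.meth.isna().any().any())

    pvals, betas, keys = [], [], []
    for mid in mrna.index:
        y = mrna.loc[mid].to_numpy(dtype=float)
        z_cnv = bundle.cnv.loc[mid].to_numpy(dtype=float)
        z_meth = bundle.meth.loc[mid].to_numpy(dtype=float)
        if has_na:
            for i, lid in enumerate(lnc_ids):
                try:
                    rec = fit_pair(y, z_cnv, z_meth, L[i], lid, mid)
                except DegenerateFitError:
                    continue
                pvals.append(rec.p_lncrna)
                betas.append(rec.beta_lncrna)
                keys.append((lid, mid))
            continue
        Z = np.column_stack([np.ones(n), z_cnv, z_meth])
        coef, _, z_rank, _ = np.linalg.lstsq(Z, np.column_stack([y, L.T]), rcond=None)
        if z_rank < 3:
            logger.info("screen_targets: collinear covariates for %s, skipped", mid)
            continue
        resid = np.column_stack([y, L.T]) - Z @ coef
        ry, RX = resid[:, 0], resid[:, 1:]
        rxx = np.einsum("ij,ij->j", RX, RX)
        valid = rxx > 0  # lncRNA collinear with covariates otherwise
        rxy = ry @ RX
        b = np.where(valid, rxy / np.where(valid, rxx, 1.0), np.nan)
        rss = ry @ ry - np.where(valid, b * rxy, 0.0)
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / dof / np.where(valid, rxx, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, b / se, np.where(b != 0, np.inf, 0.0))
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        for i, lid in enumerate(lnc_ids):
            if not valid[i]:
                continue
            pvals.append(float(p[i]))
            betas.append(float(b[i]))
            keys.append((lid, mid))

    m = len(pvals)
    tm = TargetMap(cancer_label=bundle.cancer_label, n_tested_pairs=m,
                   n_mrna_tested=len(mrna), n_lncrna_tested=len(lnc_ids),
                   tested_mrnas=frozenset(mrna.index))
    if m == 0:
        warnings.warn("screen_targets: zero tested pairs", stacklevel=2)
        return tm
    parr = np.asarray(pvals)
    fdr = multipletests(parr, method="fdr_bh")[1]
    bonf = np.minimum(parr * m, 1.0)
    keep = (fdr < fdr_cut) & (bonf < bonf_cut)
    for i in np.flatnonzero(keep):
        lid, mid = keys[i]
        rec = fit_pair(
            mrna.loc[mid].to_numpy(dtype=float),
            bundle.cnv.loc[mid].to_numpy(dtype=float),
            bundle.meth.loc[mid].to_numpy(dtype=float),
            lnc.loc[lid].to_numpy(dtype=float),
            lid, mid,
        )
        tm.records.append(replace(rec, fdr=float(fdr[i]), bonferroni=float(bonf[i])))
    return tm
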