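"""Cox modelling, risk scores and Kaplan-Meier comparisons of IC-lncRNAs.

Univariate Cox screens each lncRNA against overall survival; candidates
with p < 0.05 enter a bidirectional (add/drop) AIC-stepwise multivariate
Cox model whose coefficients define the per-sample risk score
``sum_j beta_j * expr_j``. Patients split at the median risk score are
compared by the log-rank test; an optimal expression cutpoint maximises
the standardised log-rank statistic over candidate thresholds between
expression quantiles (the surv_cutpoint convention). Ties in the partial
likelihood are handled by Efron's method (the lifelines default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test

from lncoop.errors import DegenerateFitError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "RiskModel",
    "univariate_cox",
    "univariate_screen",
    "stepwise_cox",
    "risk_score",
    "km_logrank",
    "optimal_cutpoint",
    "median_split_survival",
]


@dataclass(frozen=True)
class CoxResult:
    """Univariate proportional-hazards fit for one covariate."""

    covariate: str
    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int


@dataclass
class RiskModel:
    """Multivariate Cox coefficients defining the linear risk score."""

    lncrnas: list
    betas: dict  # lncrna -> log-hazard coefficient
    n_samples: int = 0
    n_events: int = 0
    aic: float = np.nan

    def __post_init__(self) -> None:
        if any(not np.isfinite(b) for b in self.betas.values()):
            raise ValidationError("non-finite Cox coefficient")


def _surv_frame(values: pd.Series, clinical: pd.DataFrame, name: str) -> pd.DataFrame:
    shared = [s for s in values.index if s in clinical.index]
    df = pd.DataFrame({
        name: values.reindex(shared).astype(float),
        "os_time": clinical.loc[shared, "os_time"].astype(float),
        "os_event": clinical.loc[shared, "os_event"].astype(int),
    }).dropna()
    return df


def univariate_cox(
    expr_vector: pd.Series, clinical: pd.DataFrame, min_events: int = 10
) -> CoxResult:
    """Single-covariate Cox fit: HR, Wald 95% CI and p.

    Requires at least ``min_events`` events; a constant covariate or a
    non-converging fit raises :class:`DegenerateFitError`.
    """
    name = str(expr_vector.name or "x")
    df = _surv_frame(expr_vector, clinical, name)
    n_events = int(df["os_event"].sum())
    if n_events < min_events:
        raise DegenerateFitError(f"{name}: {n_events} events < {min_events}")
    if np.ptp(df[name].to_numpy()) == 0:
        raise DegenerateFitError(f"{name}: constant covariate")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="os_time", event_col="os_event")
    except ConvergenceError as err:
        raise DegenerateFitError(f"{name}: Cox fit did not converge") from err
    s = cph.summary.loc[name]
    return CoxResult(
        covariate=name, log_hr=float(s["coef"]), hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]), n=len(df), n_events=n_events,
    )


def univariate_screen(
    expr_matrix: pd.DataFrame, clinical: pd.DataFrame, p_cut: float = 0.05
) -> tuple[list, pd.DataFrame]:
    """Univariate Cox over all lncRNAs; candidates have raw p < ``p_cut``."""
    rows, candidates = [], []
    for lnc in expr_matrix.index:
        try:
            res = univariate_cox(expr_matrix.loc[lnc], clinical)
        except DegenerateFitError as err:
            logger.info("univariate_screen: %s", err)
            continue
        rows.append((lnc, res.log_hr, res.hr, res.ci_low, res.ci_high, res.p))
        if res.p < p_cut:
            candidates.append(lnc)
    table = pd.DataFrame(rows, columns=["lncrna", "log_hr", "hr",
                                        "ci_low", "ci_high", "p"])
    return candidates, table


def _fit_multivariate(df: pd.DataFrame, covariates: list) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=1e-6)  # tiny ridge stabilises near-collinear fits
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[covariates + ["os_time", "os_event"]],
                duration_col="os_time", event_col="os_event")
    return cph


def _aic(cph: CoxPHFitter, n_covariates: int) -> float:
    return -2.0 * float(cph.log_likelihood_) + 2.0 * n_covariates


def stepwise_cox(
    expr_matrix: pd.DataFrame,
    candidates: list,
    clinical: pd.DataFrame,
) -> RiskModel:
    """Bidirectional AIC-stepwise multivariate Cox selection.

    Starts from the full candidate model and repeatedly applies the
    single add/drop move that lowers AIC most, until no move improves.
    The empty model's AIC uses the null partial likelihood. Returns the
    surviving coefficients (possibly an empty model).
    """
    shared = [s for s in expr_matrix.columns if s in clinical.index]
    df = pd.concat([
        expr_matrix.loc[candidates, shared].T.astype(float),
        clinical.loc[shared, ["os_time", "os_event"]].astype(float),
    ], axis=1).dropna()
    if df.empty or not candidates:
        return RiskModel(lncrnas=[], betas={})

    def _score(current: list) -> tuple[float, CoxPHFitter | None]:
        if not current:
            return null_aic, None
        try:
            cph = _fit_multivariate(df, current)
        except (ConvergenceError, ValueError):
            return np.inf, None
        return _aic(cph, len(current)), cph

    # null partial log-likelihood via any single-covariate fit's LR test
    probe = _fit_multivariate(df, [candidates[0]])
    ll_null = float(probe.log_likelihood_) - probe.log_likelihood_ratio_test().test_statistic / 2.0
    null_aic = -2.0 * ll_null

    current = list(candidates)
    best_aic, best_fit = _score(current)
    improved = True
    while improved:
        improved = False
        moves = [("drop", v) for v in current]
        moves += [("add", v) for v in candidates if v not in current]
        for kind, v in moves:
            trial = ([x for x in current if x != v] if kind == "drop"
                     else current + [v])
            aic, fit = _score(trial)
            if aic < best_aic - 1e-9:
                best_aic, best_fit, current = aic, fit, trial
                improved = True
    if not current:
        warnings.warn("stepwise_cox: no covariate survives selection", stacklevel=2)
        return RiskModel(lncrnas=[], betas={}, n_samples=len(df),
                         n_events=int(df["os_event"].sum()), aic=best_aic)
    betas = {v: float(best_fit.params_[v]) for v in current}
    return RiskModel(lncrnas=sorted(current), betas=betas,
                     n_samples=len(df), n_events=int(df["os_event"].sum()),
                     aic=best_aic)


def risk_score(model: RiskModel, expr_matrix: pd.DataFrame) -> pd.Series:
    """Per-sample linear risk score sum_j beta_j * expr_j."""
    missing = [l for l in model.lncrnas if l not in expr_matrix.index]
    if missing:
        raise ValidationError(f"expression matrix lacks model lncRNAs: {missing}")
    score = pd.Series(0.0, index=expr_matrix.columns, name="risk_score")
    for lnc in model.lncrnas:
        score += model.betas[lnc] * expr_matrix.loc[lnc].astype(float)
    return score


def km_logrank(groups: pd.Series, clinical: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per group plus the log-rank p.

    ``groups`` maps sample -> group label (>= 2 non-empty groups). A
    group without events is kept with a warning. Two groups use the
    two-sample log-rank test; more use its multivariate form.
    """
    shared = [s for s in groups.index if s in clinical.index]
    g = groups.reindex(shared)
    t = clinical.loc[shared, "os_time"].astype(float)
    e = clinical.loc[shared, "os_event"].astype(int)
    labels = sorted(g.dropna().unique())
    if len(labels) < 2:
        raise ValidationError("need >= 2 non-empty groups")
    curves = {}
    for lab in labels:
        mask = (g == lab).to_numpy()
        if e[mask].sum() == 0:
            warnings.warn(f"group {lab!r} has zero events", stacklevel=2)
        km = KaplanMeierFitter()
        km.fit(t[mask], e[mask], label=str(lab))
        curves[lab] = km.survival_function_
    if len(labels) == 2:
        m0, m1 = (g == labels[0]).to_numpy(), (g == labels[1]).to_numpy()
        res = logrank_test(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    else:
        res = multivariate_logrank_test(t, g, e)
    return {"curves": curves, "statistic": float(res.test_statistic),
            "p": float(res.p_value), "groups": {lab: int((g == lab).sum())
                                                for lab in labels}}


def optimal_cutpoint(
    expr_vector: pd.Series,
    clinical: pd.DataFrame,
    min_group_frac: float = 0.1,
) -> dict:
    """Maximally selected rank statistic cutpoint for one lncRNA.

    Scans every observed expression value between the ``min_group_frac``
    and ``1 - min_group_frac`` quantiles as a high/low threshold
    (high = expression > threshold) and returns the one maximising the
    standardised two-sample log-rank statistic. The associated p-value is
    selection-biased (maximum over many tests) and is reported with that
    caveat; no maxstat correction is applied.
    """
    name = str(expr_vector.name or "x")
    df = _surv_frame(expr_vector, clinical, name)
    if len(df) < 20:
        raise ValidationError(f"{name}: need >= 20 samples, have {len(df)}")
    x = df[name].to_numpy()
    if np.ptp(x) == 0:
        raise DegenerateFitError(f"{name}: all expression values equal")
    lo, hi = np.quantile(x, [min_group_frac, 1.0 - min_group_frac])
    cands = [v for v in np.unique(x) if lo <= v <= hi and (x > v).any()]
    if not cands:
        raise DegenerateFitError(f"{name}: no admissible threshold")
    t = df["os_time"].to_numpy()
    e = df["os_event"].to_numpy()
    best = None
    for c in cands:
        high = x > c
        res = logrank_test(t[high], t[~high],
                           event_observed_A=e[high], event_observed_B=e[~high])
        z = float(np.sqrt(res.test_statistic))
        if best is None or z > best[1] + 1e-12:
            best = (float(c), z, float(res.p_value))
    threshold, stat, p = best
    warnings.warn("optimal_cutpoint p-value is selection-biased "
                  "(maximum over scanned thresholds)", stacklevel=2)
    return {"threshold": threshold, "statistic": stat, "p": p,
            "n_candidates": len(cands)}


def median_split_survival(scores: pd.Series, clinical: pd.DataFrame) -> dict:
    """Median split of risk scores (ties to low risk) + log-rank comparison."""
    s = scores.dropna()
    if len(s) < 10:
        raise ValidationError("need >= 10 scored samples")
    med = float(s.median())
    groups = pd.Series(np.where(s > med, "high", "low"), index=s.index, name="risk_group")
    n_low, n_high = int((groups == "low").sum()), int((groups == "high").sum())
    if n_low > n_high:
        logger.info("median_split_survival: ties at the median enlarge the "
                    "low-risk group (%d vs %d)", n_low, n_high)
    out = km_logrank(groups, clinical)
    out["groups_series"] = groups
    out["median"] = med
    return out
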