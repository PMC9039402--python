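"""Survival analysis: univariate Cox fits, risk scores, KM / log-rank, ROC.

The risk score of a sample is the linear combination RiskScore = Σ_i β_i ·
Exp(i), where β_i is the univariate Cox proportional-hazards coefficient of
feature i and Exp(i) its (log2) expression in the sample.  Patients are split
at the arithmetic mean of the scores (samples exactly at the mean go to the
low-risk group) and the two groups are compared by Kaplan–Meier curves and
the log-rank test.  The Cox fitter maximizes the Breslow partial likelihood
by Newton iteration with step halving; Wald standard errors and p-values come
from the observed information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score

from .ingest import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "RiskModel",
    "Stratification",
    "KMResult",
    "cox_univariate",
    "breslow_partial_loglik",
    "fit_risk_model",
    "risk_score",
    "km_logrank",
    "roc_auc",
]

_BETA_CAP = 20.0
# |beta| (standardized scale) beyond which a fit is treated as monotone
# likelihood (separation): the partial likelihood is flat at its supremum
_SEPARATION_BOUND = 10.0


@dataclass
class CoxFit:
    feature_id: str
    beta: float
    se: float
    p_value: float
    converged: bool


@dataclass
class RiskModel:
    features: list[str]
    betas: list[float]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.betas) or not self.features:
            raise ValueError("features and betas must be equal-length and non-empty")


@dataclass
class Stratification:
    scores: pd.Series  # per-sample risk score
    cutoff: float
    groups: pd.Series  # "high" / "low"
    degenerate: bool = False


@dataclass
class KMResult:
    curves: dict  # group label -> DataFrame(time, survival, at_risk)
    logrank_chi2: float
    logrank_p: float


def breslow_partial_loglik(beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray):
    """Breslow log partial likelihood with gradient and Hessian.

    Every event at time t contributes βx − log Σ_{j: t_j ≥ t} exp(βx_j);
    tied events share the same risk-set denominator.
    """
    order = np.argsort(-time, kind="stable")
    t, d, xv = time[order], event[order], x[order]
    ex = np.exp(beta * xv)  # exponentials guarded by the beta cap
    s0 = np.cumsum(ex)
    s1 = np.cumsum(xv * ex)
    s2 = np.cumsum(xv * xv * ex)
    ll = grad = hess = 0.0
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        # risk set for time t[i] = subjects with index <= j (times >= t[i])
        S0, S1, S2 = s0[j], s1[j], s2[j]
        for k in range(i, j + 1):
            if d[k]:
                ll += beta * xv[k] - np.log(S0)
                grad += xv[k] - S1 / S0
                hess -= S2 / S0 - (S1 / S0) ** 2
        i = j + 1
    return ll, grad, hess


def cox_univariate(
    expr: np.ndarray | pd.Series,
    clinical: ClinicalTable,
    feature_id: str = "feature",
) -> CoxFit:
    """Newton maximization of the univariate Breslow partial likelihood.

    ``expr`` must be aligned with ``clinical.table`` rows.  Constant
    covariates give β = 0 flagged non-converged; monotone-likelihood
    separation is capped at |β| = 20 with a warning.
    """
    x = np.asarray(expr, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("expression values must be finite")
    time = clinical.table["time"].to_numpy(dtype=float)
    event = clinical.table["event"].to_numpy(dtype=int)
    if len(x) != len(time):
        raise ValueError("expression and clinical table lengths differ")
    if event.sum() == 0:
        raise ValueError("no events in clinical table")
    if np.ptp(x) == 0:
        return CoxFit(feature_id, 0.0, float("inf"), 1.0, converged=False)
    # center+scale for numerical stability; back-transform beta
    mu, sd = x.mean(), x.std()
    z = (x - mu) / sd

    beta = 0.0
    ll, grad, hess = breslow_partial_loglik(beta, time, event, z)
    converged = False
    for _ in range(60):
        if hess >= -1e-12:
            break
        step = -grad / hess
        new = beta + step
        # step-halve until the likelihood does not decrease
        for _ in range(30):
            if abs(new) > _BETA_CAP:
                new = np.sign(new) * _BETA_CAP
            nll = breslow_partial_loglik(new, time, event, z)[0]
            if nll >= ll - 1e-12:
                break
            new = (beta + new) / 2
        beta = new
        ll, grad, hess = breslow_partial_loglik(beta, time, event, z)
        if abs(grad) < 1e-9:
            converged = True
            break
        if abs(beta) >= _BETA_CAP:
            break
    if abs(beta) >= _SEPARATION_BOUND:
        logger.warning(
            "%s: monotone likelihood (separation), beta unreliable", feature_id
        )
        converged = False
    info = -hess
    se_z = 1.0 / np.sqrt(info) if info > 0 else float("inf")
    beta_x = beta / sd
    se_x = se_z / sd
    wald = beta_x / se_x if np.isfinite(se_x) and se_x > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(wald)))
    return CoxFit(feature_id, float(beta_x), float(se_x), max(p, np.finfo(float).tiny), converged)


def fit_risk_model(
    features: list[str], expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[RiskModel, list[CoxFit]]:
    """Univariate Cox fit per feature; β_i of the fits define the risk model."""
    clin = clinical.aligned(expr.sample_ids)
    fits = []
    for f in features:
        if f not in expr.values.index:
            raise KeyError(f"feature {f!r} missing from expression matrix")
        fits.append(cox_univariate(expr.values.loc[f].to_numpy(), clin, f))
    return RiskModel([f.feature_id for f in fits], [f.beta for f in fits]), fits


def risk_score(model: RiskModel, expr: ExpressionMatrix) -> Stratification:
    """Per-sample RiskScore = Σ β_i·Exp(i); split at the mean score.

    Samples with score strictly above the mean are high-risk; samples exactly
    at the mean go to the low-risk group.  An all-equal score vector (e.g.
    every β = 0) is flagged degenerate with every sample low-risk.
    """
    missing = [f for f in model.features if f not in expr.values.index]
    if missing:
        raise KeyError(f"features missing from expression matrix: {missing}")
    mat = expr.values.loc[model.features].to_numpy(dtype=float)
    scores = pd.Series(
        np.asarray(model.betas, dtype=float) @ mat, index=expr.sample_ids, name="risk_score"
    )
    cutoff = float(scores.mean())
    groups = pd.Series(
        np.where(scores.to_numpy() > cutoff, "high", "low"),
        index=scores.index,
        name="risk_group",
    )
    return Stratification(
        scores=scores,
        cutoff=cutoff,
        groups=groups,
        degenerate=bool(np.ptp(scores.to_numpy()) == 0),
    )


def km_logrank(clinical: ClinicalTable, groups: pd.Series | dict) -> KMResult:
    """Kaplan–Meier curve per group and the two-group log-rank test."""
    groups = pd.Series(groups)
    tab = clinical.table.set_index("sample_id")
    shared = [s for s in groups.index if s in tab.index]
    if not shared:
        raise ValueError("no shared samples between clinical table and groups")
    groups = groups.loc[shared]
    tab = tab.loc[shared]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    masks = {lv: (groups == lv).to_numpy() for lv in labels}
    if any(m.sum() == 0 for m in masks.values()):
        raise ValueError("both groups must be non-empty")

    curves = {}
    for lv in labels:
        kmf = KaplanMeierFitter()
        kmf.fit(tab["time"][masks[lv]], tab["event"][masks[lv]], label=str(lv))
        sf = kmf.survival_function_
        curves[lv] = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": kmf.event_table["at_risk"].reindex(sf.index).to_numpy(),
            }
        )
    if tab["event"].sum() == 0:
        logger.warning("no events in either group; log-rank undefined, p = 1")
        return KMResult(curves, 0.0, 1.0)
    res = logrank_test(
        tab["time"][masks[labels[0]]],
        tab["time"][masks[labels[1]]],
        event_observed_A=tab["event"][masks[labels[0]]],
        event_observed_B=tab["event"][masks[labels[1]]],
    )
    return KMResult(curves, float(res.test_statistic), float(res.p_value))


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both label classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
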