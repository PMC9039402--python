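"""Two-group differential expression on count matrices.

The test is a conditioned negative-binomial exact test with a single common
dispersion estimated by the method of moments — the classic exact-test idea
for sequencing counts, kept deliberately small.  Samples are normalized by
median-of-ratios size factors (robust to composition bias when a substantial
fraction of features is differentially expressed; plain total-count scaling
is available via ``normalization="total_count"``) before group means and fold
changes are computed; when the common dispersion estimate is zero the test
reduces to the two-sided exact binomial test on the conditional of one
group's total given the overall total.

Selection follows the conventional rule |FC| > 2 and raw p < 0.05 (both
configurable); p-values are not multiplicity-adjusted by default, a
Benjamini–Hochberg option is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .ingest import ExpressionMatrix

__all__ = ["DEResult", "de_test", "select_de", "estimate_common_dispersion"]


@dataclass
class DEResult:
    feature_id: str
    mean_a: float
    mean_b: float
    log2fc: float  # log2(mean_b / mean_a)
    p_value: float
    is_de: bool


def _check_counts(values: np.ndarray) -> None:
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(values, np.round(values)):
        raise ValueError("counts must be integers")


def size_factors(values: np.ndarray, method: str = "median_ratio") -> np.ndarray:
    """Per-sample normalization factors (geometric mean scaled to 1).

    ``median_ratio``: median, over features positive in every sample, of the
    ratio of the sample's count to the feature's geometric mean — robust to
    composition shifts caused by strongly differential features.  Falls back
    to total-count scaling when no feature is everywhere positive.
    ``total_count``: library-size ratios.
    """
    lib = values.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("a sample has zero total counts")
    if method == "total_count":
        factors = lib / np.exp(np.mean(np.log(lib)))
        return factors
    if method != "median_ratio":
        raise ValueError(f"unknown normalization {method!r}")
    pos = (values > 0).all(axis=1)
    if not pos.any():
        return size_factors(values, "total_count")
    sub = values[pos]
    log_ref = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_ref, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def estimate_common_dispersion(norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    """Method-of-moments common NB dispersion φ (variance = μ + φμ²).

    Pooled over features and groups, weighted by within-group degrees of
    freedom; clipped at zero.
    """
    num = 0.0
    den = 0.0
    for idx in (idx_a, idx_b):
        if idx.sum() < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = idx.sum() - 1
        keep = m > 0
        num += w * float(np.sum(v[keep] - m[keep]))
        den += w * float(np.sum(m[keep] ** 2))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_nb_pvalue(y_a: int, s: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for group-A total y_a given overall total s.

    Group totals are NB with shapes n_a/φ and n_b/φ and a common success
    probability; conditionally on the sum, P(Y_a = x) ∝ C(x+r_a−1, x)
    C(s−x+r_b−1, s−x).  Two-sided by the minimum-likelihood rule (sum of all
    outcomes no more probable than the observed one).
    """
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    r_a, r_b = n_a / phi, n_b / phi
    logw = (
        gammaln(x + r_a)
        - gammaln(x + 1)
        + gammaln(s - x + r_b)
        - gammaln(s - x + 1)
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p = float(probs[probs <= probs[y_a] * (1 + 1e-12)].sum())
    return min(1.0, p)


def de_test(
    counts: ExpressionMatrix,
    groups: pd.Series | dict,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    dispersion: float | None = None,
    normalization: str = "median_ratio",
) -> list[DEResult]:
    """NB exact test per feature between the two levels of ``groups``.

    ``groups`` maps sample id → label; the two labels sorted lexicographically
    define groups A and B, and log2fc = log2(mean_B / mean_A) on size-factor
    normalized counts.  ``dispersion`` overrides the pooled method-of-moments
    estimate (0 forces the exact binomial-conditional test).
    """
    if counts.scale != "raw":
        raise ValueError("de_test requires raw counts")
    groups = pd.Series(groups)
    groups = groups.loc[[s for s in counts.sample_ids if s in groups.index]]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    values = counts.values.loc[:, groups.index].to_numpy(dtype=float)
    _check_counts(values)

    factors = size_factors(values, normalization)
    idx_a = (groups == levels[0]).to_numpy()
    idx_b = (groups == levels[1]).to_numpy()
    if idx_a.sum() == 0 or idx_b.sum() == 0:
        raise ValueError("each group needs at least one sample")
    for idx, lv in ((idx_a, levels[0]), (idx_b, levels[1])):
        if values[:, idx].sum() == 0:
            raise ValueError(f"group {lv!r} has zero total counts")

    norm = values / factors
    if dispersion is None:
        phi = estimate_common_dispersion(norm, idx_a, idx_b)
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be >= 0")

    n_a, n_b = int(idx_a.sum()), int(idx_b.sum())
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    y_a = np.rint(norm[:, idx_a].sum(axis=1)).astype(np.int64)
    y_b = np.rint(norm[:, idx_b].sum(axis=1)).astype(np.int64)

    results: list[DEResult] = []
    lfc_cut = np.log2(fc_threshold)
    for i, fid in enumerate(counts.feature_ids):
        s = int(y_a[i] + y_b[i])
        if s == 0:
            p = 1.0
        elif phi == 0.0:
            p = float(binomtest(int(y_a[i]), s, n_a / (n_a + n_b)).pvalue)
        else:
            p = _conditional_nb_pvalue(int(y_a[i]), s, n_a, n_b, phi)
        ma, mb = float(mean_a[i]), float(mean_b[i])
        if ma > 0 and mb > 0:
            lfc = float(np.log2(mb / ma))
        elif ma == 0 and mb == 0:
            lfc = 0.0
        else:  # pseudo-count only in the degenerate all-zero-group case
            lfc = float(np.log2((mb + 0.5) / (ma + 0.5)))
        results.append(
            DEResult(
                feature_id=fid,
                mean_a=ma,
                mean_b=mb,
                log2fc=lfc,
                p_value=p,
                is_de=bool(abs(lfc) > lfc_cut and p < p_threshold),
            )
        )
    return results


def select_de(
    results: list[DEResult],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    adjust: bool = False,
) -> set[str]:
    """Features with |log2fc| > log2(fc_threshold) and p < p_threshold (strict).

    With ``adjust=True`` the p condition applies to BH-adjusted p-values.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if not results:
        return set()
    pvals = np.array([r.p_value for r in results])
    if adjust:
        pvals = multipletests(pvals, method="fdr_bh")[1]
    cut = np.log2(fc_threshold)
    return {
        r.feature_id
        for r, p in zip(results, pvals)
        if abs(r.log2fc) > cut and p < p_threshold
    }


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    """Tabular view of DE results (one row per feature)."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "is_de": [r.is_de for r in results],
        }
    )
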