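"""Downstream association utilities: lncRNA–immune-infiltration correlation
and generic gene-set over-representation (hypergeometric + BH)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cerna import hypergeom_shared
from .ingest import ExpressionMatrix

__all__ = ["OraResult", "infiltration_correlation", "ora"]


@dataclass
class OraResult:
    set_id: str
    overlap: int
    p_value: float
    bh_adjusted_p: float


def infiltration_correlation(
    lnc_expr: ExpressionMatrix, infiltration: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r (and test p) between each lncRNA and each cell-type score.

    ``infiltration`` is samples × cell types.  Samples are intersected and
    ordered identically; at least 3 shared samples are required.  Entries with
    a zero-variance side are NaN.
    """
    shared = [s for s in lnc_expr.sample_ids if s in infiltration.index]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(shared)}")
    X = lnc_expr.values.loc[:, shared].to_numpy(dtype=float)
    Y = infiltration.loc[shared].to_numpy(dtype=float)
    lnc_ids = lnc_expr.feature_ids
    cells = list(infiltration.columns)
    r = np.full((len(lnc_ids), len(cells)), np.nan)
    p = np.full_like(r, np.nan)
    for i in range(len(lnc_ids)):
        if np.ptp(X[i]) == 0:
            continue
        for j in range(len(cells)):
            if np.ptp(Y[:, j]) == 0:
                continue
            r[i, j], p[i, j] = stats.pearsonr(X[i], Y[:, j])
    return (
        pd.DataFrame(r, index=lnc_ids, columns=cells),
        pd.DataFrame(p, index=lnc_ids, columns=cells),
    )


def ora(
    query: set[str], collections: dict[str, set[str]], universe: set[str]
) -> list[OraResult]:
    """Over-representation of ``query`` in each named set, BH-adjusted.

    Upper-tail hypergeometric on the overlap between the query and each
    collection restricted to the universe; query must be a subset of the
    universe.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    names = sorted(collections)
    pvals = []
    overlaps = []
    for name in names:
        s = collections[name] & universe
        k = len(query & s)
        pvals.append(hypergeom_shared(k, len(s), len(query), len(universe)))
        overlaps.append(k)
    if not names:
        return []
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [
        OraResult(name, ov, float(p), float(a))
        for name, ov, p, a in zip(names, overlaps, pvals, adj)
    ]
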