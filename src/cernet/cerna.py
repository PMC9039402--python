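"""Competing-endogenous-RNA (ceRNA) network construction.

Two transcripts that carry response elements for the same miRNAs compete for
them; a lncRNA–mRNA pair is a ceRNA candidate when the two share at least one
miRNA neighbor across the miRNA–mRNA and miRNA–lncRNA networks.  Candidates
whose log2 expression profiles are strongly positively correlated
(PCC > 0.9 by default, strict) form the ceRNA network; each retained pair
contributes one (lncRNA, miRNA, mRNA) triplet per shared miRNA.  A
hypergeometric shared-miRNA p-value is reported per pair for symmetry with
the TF–lncRNA procedure (filtering on it is optional and off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .ingest import ExpressionMatrix

__all__ = ["SharedMirnaPair", "CeRNATriplet", "shared_pairs", "hypergeom_shared", "cerna_network"]


@dataclass
class SharedMirnaPair:
    lncrna_id: str
    mrna_id: str
    shared_mirnas: set
    n_shared: int
    hyper_p: float
    pcc: float = float("nan")


@dataclass
class CeRNATriplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    provenance: tuple = ()


def hypergeom_shared(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    ``K`` miRNA partners of one transcript, ``n`` of the other, out of ``N``
    miRNAs overall, sharing ``k``.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _partners(net: nx.Graph, node_class: str) -> dict[str, set]:
    """miRNA neighbor sets of every node of the given class."""
    out: dict[str, set] = {}
    for n, d in net.nodes(data=True):
        if d.get("node_class") != node_class:
            continue
        out[n] = {
            nb for nb in net.neighbors(n) if net.nodes[nb].get("node_class") == "miRNA"
        }
    return out


def mirna_universe(*nets: nx.Graph) -> set:
    u: set = set()
    for net in nets:
        u |= {n for n, d in net.nodes(data=True) if d.get("node_class") == "miRNA"}
    return u


def shared_pairs(mir_mrna_net: nx.Graph, mir_lnc_net: nx.Graph) -> list[SharedMirnaPair]:
    """All (lncRNA, mRNA) pairs sharing at least one miRNA neighbor.

    The hypergeometric universe N is the number of distinct miRNAs in the
    union of the two networks.
    """
    lnc_partners = _partners(mir_lnc_net, "lncRNA")
    mrna_partners = _partners(mir_mrna_net, "mRNA")
    N = len(mirna_universe(mir_mrna_net, mir_lnc_net))
    pairs: list[SharedMirnaPair] = []
    for lnc in sorted(lnc_partners):
        lp = lnc_partners[lnc]
        if not lp:
            continue
        for mr in sorted(mrna_partners):
            mp = mrna_partners[mr]
            shared = lp & mp
            if shared:
                pairs.append(
                    SharedMirnaPair(
                        lncrna_id=lnc,
                        mrna_id=mr,
                        shared_mirnas=shared,
                        n_shared=len(shared),
                        hyper_p=hypergeom_shared(len(shared), len(lp), len(mp), N),
                    )
                )
    return pairs


def cerna_network(
    pairs: list[SharedMirnaPair],
    lnc_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    pcc_threshold: float = 0.9,
    hyper_p_threshold: float | None = None,
) -> tuple[nx.Graph, list[CeRNATriplet], list[SharedMirnaPair]]:
    """Retain shared-miRNA pairs with PCC strictly above ``pcc_threshold``.

    Returns the lncRNA–mRNA co-expression network, the triplet list (one per
    retained pair per shared miRNA) and the retained pairs with their PCC.
    """
    if lnc_expr.sample_ids != mrna_expr.sample_ids:
        raise ValueError("expression matrices must share the identical ordered samples")
    net = nx.Graph()
    retained: list[SharedMirnaPair] = []
    triplets: list[CeRNATriplet] = []
    for pair in pairs:
        if pair.lncrna_id not in lnc_expr.values.index:
            continue
        if pair.mrna_id not in mrna_expr.values.index:
            continue
        x = lnc_expr.values.loc[pair.lncrna_id].to_numpy(dtype=float)
        y = mrna_expr.values.loc[pair.mrna_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = float(stats.pearsonr(x, y)[0])
        pair.pcc = r
        if r <= pcc_threshold:
            continue
        if hyper_p_threshold is not None and pair.hyper_p >= hyper_p_threshold:
            continue
        retained.append(pair)
        net.add_node(pair.lncrna_id, node_class="lncRNA")
        net.add_node(pair.mrna_id, node_class="mRNA")
        net.add_edge(pair.lncrna_id, pair.mrna_id, pcc=r)
        for mir in sorted(pair.shared_mirnas):
            triplets.append(
                CeRNATriplet(
                    lncrna_id=pair.lncrna_id,
                    mirna_id=mir,
                    mrna_id=pair.mrna_id,
                    provenance=((mir, pair.lncrna_id), (mir, pair.mrna_id)),
                )
            )
    return net, triplets, retained


def pairs_frame(pairs: list[SharedMirnaPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [p.lncrna_id for p in pairs],
            "mrna_id": [p.mrna_id for p in pairs],
            "n_shared": [p.n_shared for p in pairs],
            "shared_mirnas": [",".join(sorted(p.shared_mirnas)) for p in pairs],
            "hyper_p": [p.hyper_p for p in pairs],
            "pcc": [p.pcc for p in pairs],
        }
    )


def triplets_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [t.lncrna_id for t in triplets],
            "mirna_id": [t.mirna_id for t in triplets],
            "mrna_id": [t.mrna_id for t in triplets],
        }
    )
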