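"""Candidate regulator→target edges and the negative-correlation filter.

miRNA–mRNA candidates come from a curated interaction table restricted to
differentially expressed endpoints; miRNA–lncRNA candidates come from
canonical seed matching on sequences (6mer / 7mer-A1 / 7mer-m8 / 8mer site
classes).  Candidate edges are then filtered on expression: only pairs whose
log2 profiles are negatively Pearson-correlated (optionally requiring the
correlation-test p < 0.05) are kept, reflecting miRNA repression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import ExpressionMatrix

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")
DNA_ALPHABET = set("ACGT")
_DNA_COMP = str.maketrans("ACGT", "TGCA")
# complement of an RNA base, written in DNA letters (target side)
_RNA_TO_DNA_COMP = {"A": "T", "C": "G", "G": "C", "U": "A"}


@dataclass
class InteractionTable:
    """Curated (regulator, target) edge list with a source tag."""

    edges: pd.DataFrame  # columns: regulator_id, target_id, source

    def __post_init__(self) -> None:
        required = {"regulator_id", "target_id"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"InteractionTable needs columns {sorted(required)}")
        if "source" not in self.edges.columns:
            self.edges = self.edges.assign(source="unknown")
        before = len(self.edges)
        self.edges = self.edges.drop_duplicates(
            subset=["regulator_id", "target_id"]
        ).reset_index(drop=True)
        if len(self.edges) < before:
            logger.info("dropped %d duplicate edges", before - len(self.edges))

    def __len__(self) -> int:
        return len(self.edges)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


@dataclass
class WeightedEdge:
    regulator_id: str
    target_id: str
    pcc: float
    pcc_p: float


@dataclass
class SeedHit:
    """A canonical miRNA seed-site occurrence on a target sequence."""

    mirna_id: str
    target_id: str
    site_offset: int  # 0-based start of the site on the target
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer


def map_de_edges(
    table: InteractionTable, de_regulators: set[str], de_targets: set[str]
) -> InteractionTable:
    """Edges of ``table`` whose regulator AND target are differentially expressed."""
    e = table.edges
    keep = e["regulator_id"].isin(de_regulators) & e["target_id"].isin(de_targets)
    return InteractionTable(e.loc[keep].reset_index(drop=True))


def _validate_seq(seq: str, alphabet: set[str], label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(f"invalid {label} character {ch!r} at position {i}")
    return seq


def seed_scan(
    mirna_seq: str, target_seq: str, mirna_id: str = "miRNA", target_id: str = "target"
) -> list[SeedHit]:
    """Find canonical seed sites of a miRNA on a target sequence.

    The 6mer core is the reverse complement (in DNA letters) of miRNA
    positions 2–7 (1-based, 5'→3').  Extensions classify the site: a match to
    position 8 immediately 5' of the core on the target, and/or a literal A
    opposite position 1 immediately 3' of the core, give 7mer-m8 / 7mer-A1 /
    8mer.  Offsets are 0-based starts of the full site on the target.
    """
    m = _validate_seq(mirna_seq, RNA_ALPHABET, "miRNA")
    t = _validate_seq(target_seq, DNA_ALPHABET, "target")
    if len(m) < 8:
        raise ValueError("miRNA shorter than 8 nt")

    core = "".join(_RNA_TO_DNA_COMP[b] for b in reversed(m[1:7]))  # positions 2-7
    p8_comp = _RNA_TO_DNA_COMP[m[7]]
    hits: list[SeedHit] = []
    start = t.find(core)
    while start != -1:
        m8 = start >= 1 and t[start - 1] == p8_comp
        a1 = start + 6 < len(t) and t[start + 6] == "A"
        if m8 and a1:
            hits.append(SeedHit(mirna_id, target_id, start - 1, "8mer"))
        elif m8:
            hits.append(SeedHit(mirna_id, target_id, start - 1, "7mer-m8"))
        elif a1:
            hits.append(SeedHit(mirna_id, target_id, start, "7mer-A1"))
        else:
            hits.append(SeedHit(mirna_id, target_id, start, "6mer"))
        start = t.find(core, start + 1)
    return hits


def seed_edges(
    mirna_seqs: dict[str, str], target_seqs: dict[str, str], source: str = "seed"
) -> InteractionTable:
    """All (miRNA, target) pairs with at least one canonical seed site."""
    rows = []
    for mid, mseq in mirna_seqs.items():
        for tid, tseq in target_seqs.items():
            if seed_scan(mseq, tseq, mid, tid):
                rows.append((mid, tid, source))
    return InteractionTable(
        pd.DataFrame(rows, columns=["regulator_id", "target_id", "source"])
    )


def correlation_filter(
    edges: InteractionTable,
    regulator_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    p_threshold: float | None = 0.05,
) -> list[WeightedEdge]:
    """Retain edges whose endpoints are negatively correlated across samples.

    Pearson r is computed per edge on the two log2 matrices, which must share
    the identical ordered sample set.  An edge is kept when r < 0 and (unless
    ``p_threshold`` is None, the pure-negativity mode) the correlation-test
    p-value is below ``p_threshold``.  Edges with a missing or zero-variance
    endpoint are skipped with a logged warning.
    """
    if regulator_expr.sample_ids != target_expr.sample_ids:
        raise ValueError("expression matrices must share the identical ordered samples")
    if regulator_expr.scale != "log2" or target_expr.scale != "log2":
        raise ValueError("correlation_filter expects log2-scale matrices")

    out: list[WeightedEdge] = []
    rvals = regulator_expr.values
    tvals = target_expr.values
    for reg, tgt in edges.edges[["regulator_id", "target_id"]].itertuples(index=False):
        if reg not in rvals.index or tgt not in tvals.index:
            logger.warning("edge (%s, %s) endpoint missing from expression; skipped", reg, tgt)
            continue
        x = rvals.loc[reg].to_numpy(dtype=float)
        y = tvals.loc[tgt].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("edge (%s, %s) has a zero-variance endpoint; skipped", reg, tgt)
            continue
        r, p = stats.pearsonr(x, y)
        if r < 0 and (p_threshold is None or p < p_threshold):
            out.append(WeightedEdge(reg, tgt, float(r), float(p)))
    return out
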