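"""TF–lncRNA crosstalk: shared-miRNA pairing, promoter/enhancer windows and
position-weight-matrix scanning with an exact null distribution.

The motif scanner scores every window on both strands with the log-odds
log2(P(window|PWM) / P(window|background)) and converts scores to p-values
with the exact distribution of the discretized score under the background
model, computed by dynamic programming (discretization step 1/1000 bit).
A TF is called "binding" a lncRNA when at least one hit passes the p-value
threshold inside the ±2 kb promoter window or an assigned enhancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cerna import SharedMirnaPair, hypergeom_shared, mirna_universe

DNA = "ACGT"
_IDX = {b: i for i, b in enumerate(DNA)}
_COMP = str.maketrans("ACGT", "TGCA")

# 1/1000 of a bit, as in exact-p-value motif scanners
SCORE_STEP = 1e-3
# floor on matrix probabilities so log-odds stay finite
PROB_FLOOR = 1e-10


@dataclass
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PWM:
    """Per-position base-probability model of a TF binding motif (A,C,G,T rows)."""

    motif_id: str
    probabilities: np.ndarray  # 4 × width

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[0] != 4:
            raise ValueError("PWM needs a 4 × width probability matrix")
        if self.width < 1:
            raise ValueError("PWM width must be >= 1")
        if not np.allclose(self.probabilities.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.probabilities.argmax(axis=0))

    def information_content(self, background: np.ndarray | None = None) -> float:
        """Total information content in bits relative to the background."""
        q = _background(background)
        p = np.clip(self.probabilities, PROB_FLOOR, 1.0)
        return float(np.sum(p * np.log2(p / q[:, None])))


@dataclass
class MotifHit:
    motif_id: str
    sequence_id: str
    offset: int  # 0-based on the forward strand
    strand: str
    score: float  # log-odds in bits
    p_value: float


def _background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    q = np.asarray(background, dtype=float)
    if q.shape != (4,) or not np.isclose(q.sum(), 1.0, atol=1e-6) or (q <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    return q


def _int_score_matrix(pwm: PWM, q: np.ndarray) -> np.ndarray:
    """Log-odds per (base, position) discretized to integer multiples of SCORE_STEP."""
    p = np.clip(pwm.probabilities, PROB_FLOOR, 1.0)
    bits = np.log2(p / q[:, None])
    return np.rint(bits / SCORE_STEP).astype(np.int64)


def score_pvalue_table(pwm: PWM, background: np.ndarray | None = None):
    """Exact null distribution of the discretized window score.

    Returns ``(int_scores, tail)`` where ``tail[s - smin]`` is
    P(score ≥ s·SCORE_STEP) for a random background window, computed by DP
    convolution over positions.
    """
    q = _background(background)
    S = _int_score_matrix(pwm, q)
    lo = int(S.min(axis=0).sum())
    hi = int(S.max(axis=0).sum())
    dist = np.zeros(hi - lo + 1)
    # running support starts at the sum of per-position minima
    cur = np.array([1.0])
    cur_lo = 0
    mins = S.min(axis=0)
    for j in range(pwm.width):
        width_j = int(S[:, j].max() - mins[j])
        new = np.zeros(len(cur) + width_j)
        for b in range(4):
            shift = int(S[b, j] - mins[j])
            new[shift : shift + len(cur)] += q[b] * cur
        cur = new
        cur_lo += int(mins[j])
    assert cur_lo == lo and len(cur) == hi - lo + 1
    dist[:] = cur
    tail = np.cumsum(dist[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return S, lo, tail


def pwm_scan(
    seq: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: np.ndarray | None = None,
    sequence_id: str = "seq",
    both_strands: bool = True,
) -> list[MotifHit]:
    """Log-odds scan of a DNA sequence; hits with exact p < ``p_threshold``.

    Offsets are 0-based on the forward strand for both orientations; the
    reported score is in bits (discretized to 1/1000 bit).
    """
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in _IDX:
            raise ValueError(f"invalid DNA character {ch!r} at position {i}")
    w = pwm.width
    if len(seq) < w:
        raise ValueError("sequence shorter than motif width")
    S, lo, tail = score_pvalue_table(pwm, background)

    codes = np.fromiter((_IDX[c] for c in seq), dtype=np.int64, count=len(seq))
    hits: list[MotifHit] = []

    def scan_strand(codes_arr: np.ndarray, strand: str):
        n_win = len(codes_arr) - w + 1
        win = np.lib.stride_tricks.sliding_window_view(codes_arr, w)
        scores = S[win, np.arange(w)].sum(axis=1)
        pvals = tail[scores - lo]
        for off in range(n_win):
            if pvals[off] < p_threshold:
                orig = off if strand == "+" else len(seq) - w - off
                hits.append(
                    MotifHit(
                        motif_id=pwm.motif_id,
                        sequence_id=sequence_id,
                        offset=int(orig),
                        strand=strand,
                        score=float(scores[off] * SCORE_STEP),
                        p_value=float(pvals[off]),
                    )
                )

    scan_strand(codes, "+")
    if both_strands:
        rc = np.fromiter((_IDX[c] for c in seq.translate(_COMP)[::-1]), dtype=np.int64)
        scan_strand(rc, "-")
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def promoter_window(
    tss: int, strand: str = "+", chrom: str = "chr1", flank: int = 2000, name: str = ""
) -> GenomicInterval:
    """Symmetric basal promoter window [tss − flank, tss + flank), clipped at 0.

    The strand determines which gene coordinate the caller takes as the TSS;
    the window itself is symmetric.
    """
    if tss < 0:
        raise ValueError("tss must be >= 0")
    return GenomicInterval(chrom, max(0, tss - flank), tss + flank, strand, name)


def assign_enhancers(
    enhancers: list[GenomicInterval],
    tss: int,
    flank: int = 2000,
    chrom: str | None = None,
) -> list[GenomicInterval]:
    """Enhancers overlapping the ±flank window around the TSS.

    Interpreted as "within ±2 kb of the TSS" (the common reading of basal
    regulatory domains); see the methods note on this convention.
    """
    win_start, win_end = max(0, tss - flank), tss + flank
    out = []
    for e in enhancers:
        if chrom is not None and e.chrom != chrom:
            continue
        if e.start < win_end and win_start < e.end:
            out.append(e)
    return out


def tf_lncrna_pairs(
    mir_mrna_net: nx.Graph,
    mir_lnc_net: nx.Graph,
    tf_list: set[str],
    p_threshold: float = 0.05,
) -> list[SharedMirnaPair]:
    """TF–lncRNA pairs sharing significantly many miRNAs (hypergeometric).

    The mRNA side of the miRNA–mRNA network is restricted to TFs; each
    (TF, lncRNA) pair with at least one shared miRNA is tested against the
    miRNA universe of the two networks and retained at p < ``p_threshold``.
    The TF occupies the ``mrna_id`` field of the returned pairs.
    """
    N = len(mirna_universe(mir_mrna_net, mir_lnc_net))
    tf_partners = {
        n: {nb for nb in mir_mrna_net.neighbors(n)
            if mir_mrna_net.nodes[nb].get("node_class") == "miRNA"}
        for n, d in mir_mrna_net.nodes(data=True)
        if d.get("node_class") in ("mRNA", "TF") and n in tf_list
    }
    lnc_partners = {
        n: {nb for nb in mir_lnc_net.neighbors(n)
            if mir_lnc_net.nodes[nb].get("node_class") == "miRNA"}
        for n, d in mir_lnc_net.nodes(data=True)
        if d.get("node_class") == "lncRNA"
    }
    out: list[SharedMirnaPair] = []
    for tf in sorted(tf_partners):
        tp = tf_partners[tf]
        if not tp:
            continue
        for lnc in sorted(lnc_partners):
            lp = lnc_partners[lnc]
            shared = tp & lp
            if not shared:
                continue
            p = hypergeom_shared(len(shared), len(tp), len(lp), N)
            if p < p_threshold:
                out.append(
                    SharedMirnaPair(
                        lncrna_id=lnc,
                        mrna_id=tf,
                        shared_mirnas=shared,
                        n_shared=len(shared),
                        hyper_p=p,
                    )
                )
    return out


def binding_calls(
    pairs: list[SharedMirnaPair],
    pwms: dict[str, PWM],
    promoter_seqs: dict[str, str],
    enhancer_seqs: dict[str, list[tuple[str, str]]] | None = None,
    p_threshold: float = 1e-4,
) -> list[dict]:
    """Motif-supported TF→lncRNA binding calls over promoters and enhancers.

    ``pwms`` maps TF id → PWM; ``promoter_seqs`` maps lncRNA id → promoter
    sequence; ``enhancer_seqs`` maps lncRNA id → [(enhancer id, sequence)].
    One record per (TF, lncRNA, region) with at least one passing hit.
    """
    calls = []
    for pair in pairs:
        tf, lnc = pair.mrna_id, pair.lncrna_id
        if tf not in pwms:
            continue
        pwm = pwms[tf]
        regions: list[tuple[str, str, str]] = []
        if lnc in promoter_seqs:
            regions.append(("promoter", f"{lnc}|promoter", promoter_seqs[lnc]))
        for enh_id, seq in (enhancer_seqs or {}).get(lnc, []):
            regions.append(("enhancer", enh_id, seq))
        for region_type, region_id, seq in regions:
            if len(seq) < pwm.width:
                continue
            hits = pwm_scan(seq, pwm, p_threshold, sequence_id=region_id)
            if hits:
                best = min(hits, key=lambda h: h.p_value)
                calls.append(
                    {
                        "tf": tf,
                        "lncrna": lnc,
                        "region_type": region_type,
                        "region_id": region_id,
                        "n_hits": len(hits),
                        "best_p": best.p_value,
                        "best_offset": best.offset,
                        "best_strand": best.strand,
                    }
                )
    return calls
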