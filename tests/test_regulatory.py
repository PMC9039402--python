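import itertools

import networkx as nx
import numpy as np
import pytest

from cernet.cerna import hypergeom_shared
from cernet.regulatory import (
    SCORE_STEP,
    GenomicInterval,
    PWM,
    assign_enhancers,
    promoter_window,
    pwm_scan,
    score_pvalue_table,
    tf_lncrna_pairs,
)

DNA = "ACGT"


def _pwm(cols, motif_id="M"):
    """cols: list of length-4 probability columns (A,C,G,T)."""
    return PWM(motif_id, np.array(cols, dtype=float).T)


def strong_pwm(consensus, p=0.91, motif_id="M"):
    cols = []
    for b in consensus:
        col = [0.03] * 4
        col[DNA.index(b)] = p
        cols.append(col)
    return _pwm(cols, motif_id)


def enumerate_pvalues(pwm, q=None):
    """Oracle: exhaustive 4^w enumeration of the discretized score null."""
    q = q if q is not None else np.full(4, 0.25)
    S = np.rint(
        np.log2(np.clip(pwm.probabilities, 1e-10, 1.0) / q[:, None]) / SCORE_STEP
    ).astype(np.int64)
    w = pwm.width
    table = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(S[b, j] for j, b in enumerate(word)))
        pr = float(np.prod([q[b] for b in word]))
        table[s] = table.get(s, 0.0) + pr
    scores = sorted(table)
    pvals = {}
    acc = 0.0
    for s in reversed(scores):
        acc += table[s]
        pvals[s] = acc
    return S, pvals


class TestWindows:
    def test_promoter_window_arithmetic(self):
        iv = promoter_window(10_000)
        assert (iv.start, iv.end) == (8000, 12_000)

    def test_promoter_window_clipped_at_origin(self):
        iv = promoter_window(500)
        assert (iv.start, iv.end) == (0, 2500)

    def test_strand_recorded_window_symmetric(self):
        plus = promoter_window(10_000, "+")
        minus = promoter_window(10_000, "-")
        assert (minus.start, minus.end) == (plus.start, plus.end)
        assert minus.strand == "-"

    def test_negative_tss_rejected(self):
        with pytest.raises(ValueError):
            promoter_window(-1)

    def test_enhancer_assignment_examples(self):
        tss = 10_000
        far = GenomicInterval("chr1", tss + 3000, tss + 3500)
        near = GenomicInterval("chr1", tss - 100, tss + 100)
        got = assign_enhancers([far, near], tss)
        assert got == [near]

    def test_enhancer_assignment_matches_brute_force(self):
        rng = np.random.default_rng(12)
        tss, flank = 50_000, 2000
        ivs = []
        for _ in range(20):
            start = int(rng.integers(40_000, 60_000))
            ivs.append(GenomicInterval("chr1", start, start + int(rng.integers(50, 900))))
        got = assign_enhancers(ivs, tss, flank)
        expected = [
            iv
            for iv in ivs
            if iv.start < tss + flank and tss - flank < iv.end
        ]
        assert got == expected

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)


class TestPwmScan:
    def test_pwm_validation(self):
        with pytest.raises(ValueError):
            _pwm([[0.5, 0.5, 0.5, 0.5]])

    def test_consensus_is_best_hit(self):
        pwm = strong_pwm("ACGTAC")
        hits = pwm_scan("GGGG" + pwm.consensus + "GGGG", pwm, p_threshold=1e-3)
        fwd = [h for h in hits if h.strand == "+"]
        assert any(h.offset == 4 for h in fwd)
        best = min(hits, key=lambda h: h.p_value)
        assert best.offset == 4
        assert best.score == pytest.approx(6 * np.log2(0.91 / 0.25), abs=0.01)

    def test_uniform_pwm_scores_zero(self):
        pwm = _pwm([[0.25] * 4] * 3)
        _, lo, tail = score_pvalue_table(pwm)
        assert lo == 0 and tail[0] == pytest.approx(1.0)  # p(score >= 0) = 1
        assert pwm_scan("ACGTACGTAC", pwm, p_threshold=0.99) == []

    def test_pvalues_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        raw = rng.dirichlet([1, 1, 1, 1], size=4)  # width-4 random PWM
        pwm = PWM("W4", raw.T)
        S, oracle = enumerate_pvalues(pwm)
        Simpl, lo, tail = score_pvalue_table(pwm)
        assert np.array_equal(S, Simpl)
        seq = "ACGTACGTAC"
        codes = [DNA.index(c) for c in seq]
        for off in range(len(seq) - 4 + 1):
            s = int(sum(S[codes[off + j], j] for j in range(4)))
            assert tail[s - lo] == pytest.approx(oracle[s], abs=1e-9)

    @pytest.mark.parametrize("width", [3, 5, 6])
    def test_dp_equals_enumeration_all_scores(self, width):
        rng = np.random.default_rng(width)
        pwm = PWM(f"W{width}", rng.dirichlet([0.8] * 4, size=width).T)
        S, oracle = enumerate_pvalues(pwm)
        _, lo, tail = score_pvalue_table(pwm)
        for s, p in oracle.items():
            assert tail[s - lo] == pytest.approx(p, abs=1e-9)

    def test_pvalue_monotone_in_score(self):
        pwm = strong_pwm("ACGTACG")
        _, lo, tail = score_pvalue_table(pwm)
        assert np.all(np.diff(tail) <= 1e-15)  # tail nonincreasing in score

    def test_reverse_strand_hit_reported_on_forward_coordinates(self):
        pwm = strong_pwm("AACGTT"[:6].replace("N", "A"))
        cons = pwm.consensus
        rc = cons.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = "GGGGG" + rc + "GGGGG"
        hits = pwm_scan(seq, pwm, p_threshold=1e-3)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.offset == 5 for h in minus)

    def test_planted_consensus_recovered_at_default_threshold(self):
        # >= 8 bits information content guarantees recovery at p < 1e-4
        pwm = strong_pwm("ACGTACGT")
        assert pwm.information_content() >= 8
        rng = np.random.default_rng(3)
        seq = "".join(DNA[i] for i in rng.integers(0, 4, 300))
        seq = seq[:100] + pwm.consensus + seq[108:]
        hits = pwm_scan(seq, pwm, p_threshold=1e-4)
        assert any(h.offset == 100 and h.strand == "+" for h in hits)

    def test_alphabet_violation(self):
        with pytest.raises(ValueError, match="position"):
            pwm_scan("ACGTN", strong_pwm("ACG"))


class TestTfLncrnaPairs:
    def _nets(self, mm_edges, ml_edges):
        mm = nx.Graph()
        for m, g in mm_edges:
            mm.add_node(m, node_class="miRNA")
            mm.add_node(g, node_class="mRNA")
            mm.add_edge(m, g)
        ml = nx.Graph()
        for m, l in ml_edges:
            ml.add_node(m, node_class="miRNA")
            ml.add_node(l, node_class="lncRNA")
            ml.add_edge(m, l)
        return mm, ml

    def test_disjoint_tf_list(self):
        mm, ml = self._nets([("m1", "g1")], [("m1", "l1")])
        assert tf_lncrna_pairs(mm, ml, {"other"}) == []

    def test_full_overlap_minimal_p(self):
        # when every one of the TF's and the lncRNA's partners coincide and the
        # universe is larger, the upper-tail p is the single-configuration term
        mirnas = [f"m{i}" for i in range(10)]
        mm, ml = self._nets(
            [(m, "tf") for m in mirnas[:3]] + [(m, "gx") for m in mirnas[3:]],
            [(m, "l1") for m in mirnas[:3]],
        )
        pairs = tf_lncrna_pairs(mm, ml, {"tf"})
        assert [(p.mrna_id, p.lncrna_id) for p in pairs] == [("tf", "l1")]
        import math

        assert pairs[0].hyper_p == pytest.approx(1 / math.comb(10, 3))
        # K = n = N is degenerate: the overlap is forced and p = 1, not retained
        mm_deg, ml_deg = self._nets([(m, "tf") for m in mirnas], [(m, "l1") for m in mirnas])
        assert tf_lncrna_pairs(mm_deg, ml_deg, {"tf"}) == []
        # with extra miRNAs diluting the universe the overlap becomes significant
        mm2, ml2 = self._nets(
            [(m, "tf") for m in mirnas[:3]] + [("mx", "gx"), ("my", "gy")],
            [(m, "l1") for m in mirnas[:3]] + [("mz", "l2"), ("mw", "l2")],
        )
        pairs2 = tf_lncrna_pairs(mm2, ml2, {"tf"})
        assert [(p.mrna_id, p.lncrna_id) for p in pairs2] == [("tf", "l1")]
        assert pairs2[0].hyper_p < 0.05

    def test_fixture_matches_enumeration(self):
        rng = np.random.default_rng(42)
        mirnas = [f"m{i}" for i in range(8)]
        tfs = [f"tf{i}" for i in range(4)]
        lncs = [f"l{i}" for i in range(5)]
        mm_edges = [(m, t) for m in mirnas for t in tfs if rng.random() < 0.4]
        ml_edges = [(m, l) for m in mirnas for l in lncs if rng.random() < 0.4]
        mm, ml = self._nets(mm_edges, ml_edges)
        got = {(p.mrna_id, p.lncrna_id): p.hyper_p for p in tf_lncrna_pairs(mm, ml, set(tfs))}
        N = len({m for m, _ in mm_edges} | {m for m, _ in ml_edges})
        expected = {}
        for tf in tfs:
            tp = {m for m, t in mm_edges if t == tf}
            for l in lncs:
                lp = {m for m, x in ml_edges if x == l}
                k = len(tp & lp)
                if k == 0 or not tp:
                    continue
                p = hypergeom_shared(k, len(tp), len(lp), N)
                if p < 0.05:
                    expected[(tf, l)] = p
        assert got.keys() == expected.keys()
        for key in got:
            assert got[key] == pytest.approx(expected[key], rel=1e-12)
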