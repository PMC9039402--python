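import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.ingest import ExpressionMatrix
from cernet.interactions import (
    InteractionTable,
    correlation_filter,
    map_de_edges,
    seed_edges,
    seed_scan,
)

RC = {"A": "T", "C": "G", "G": "C", "U": "A"}


def _revcomp_rna_to_dna(rna: str) -> str:
    return "".join(RC[b] for b in reversed(rna))


def _table(pairs):
    return InteractionTable(
        pd.DataFrame(pairs, columns=["regulator_id", "target_id"]).assign(source="t")
    )


class TestMapDeEdges:
    def test_empty_de_sets(self):
        t = _table([("m1", "g1")])
        assert len(map_de_edges(t, set(), {"g1"})) == 0
        assert len(map_de_edges(t, {"m1"}, set())) == 0

    def test_all_de_identity(self):
        t = _table([("m1", "g1"), ("m2", "g2")])
        out = map_de_edges(t, {"m1", "m2"}, {"g1", "g2"})
        assert len(out) == 2

    def test_fixture_matches_brute_force(self):
        pairs = [(f"m{i % 5}", f"g{i % 4}") for i in range(10)]
        t = _table(pairs)
        de_m, de_g = {"m0", "m2", "m4"}, {"g1", "g3"}
        out = map_de_edges(t, de_m, de_g)
        expected = {
            (r, g)
            for r, g in t.edges[["regulator_id", "target_id"]].itertuples(index=False)
            if r in de_m and g in de_g
        }
        got = set(out.edges[["regulator_id", "target_id"]].itertuples(index=False, name=None))
        assert got == expected

    def test_duplicates_collapse_on_load(self):
        t = _table([("m1", "g1"), ("m1", "g1")])
        assert len(t) == 1


class TestSeedScan:
    MIRNA = "UGAGGUAGUAGGUUGUAUAGUU"  # position 1 is U

    def test_planted_8mer(self):
        # target = reverse complement of miRNA positions 1-8 (pos 1 = U -> A at 3')
        site = _revcomp_rna_to_dna(self.MIRNA[:8])
        target = "GGGG" + site + "GGGG"
        hits = seed_scan(self.MIRNA, target)
        assert len(hits) == 1
        assert hits[0].site_type == "8mer"
        assert hits[0].site_offset == 4

    def test_no_site(self):
        assert seed_scan(self.MIRNA, "G" * 40) == []

    def test_three_planted_sites_classified(self):
        m = self.MIRNA
        core6 = _revcomp_rna_to_dna(m[1:7])
        p8 = RC[m[7]]
        # 8mer = p8-match + core + A ; 7mer-m8 = p8-match + core + non-A ;
        # 6mer = no p8 match, no A
        s8 = p8 + core6 + "A"
        s7m8 = p8 + core6 + "C"
        s6 = ("C" if p8 != "C" else "G") + core6 + "C"
        spacer = "GGGGG"
        target = spacer + s8 + spacer + s7m8 + spacer + s6 + spacer
        assert len(target) >= 40
        hits = seed_scan(m, target)
        types = [(h.site_offset, h.site_type) for h in hits]
        assert types == [
            (len(spacer), "8mer"),
            (2 * len(spacer) + 8, "7mer-m8"),
            (3 * len(spacer) + 17, "6mer"),
        ]
        # brute-force check: every core occurrence is reported exactly once
        starts = [i for i in range(len(target) - 5) if target[i : i + 6] == core6]
        assert len(starts) == len(hits)

    def test_7mer_a1(self):
        m = self.MIRNA
        core6 = _revcomp_rna_to_dna(m[1:7])
        bad_p8 = "C" if RC[m[7]] != "C" else "G"
        target = "GG" + bad_p8 + core6 + "A" + "GG"
        hits = seed_scan(m, target)
        assert [h.site_type for h in hits] == ["7mer-A1"]
        assert hits[0].site_offset == 3

    def test_invalid_alphabet_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            seed_scan(self.MIRNA, "GGXGGGGG")
        with pytest.raises(ValueError, match="miRNA"):
            seed_scan("ACGT" * 6, "GGGGGGGG")  # T invalid in RNA

    def test_seed_edges_table(self):
        m = self.MIRNA
        site = _revcomp_rna_to_dna(m[:8])
        table = seed_edges(
            {"mir": m}, {"hit": "GG" + site + "GG", "miss": "G" * 30}
        )
        assert set(
            table.edges[["regulator_id", "target_id"]].itertuples(index=False, name=None)
        ) == {("mir", "hit")}


class TestCorrelationFilter:
    def _mats(self, x, y, samples=None):
        samples = samples or [f"s{i}" for i in range(len(x))]
        reg = ExpressionMatrix(
            pd.DataFrame([x], index=["r"], columns=samples), "miRNA", "log2"
        )
        tgt = ExpressionMatrix(
            pd.DataFrame([y], index=["t"], columns=samples), "mRNA", "log2"
        )
        return reg, tgt

    def test_perfect_anticorrelation_retained(self):
        reg, tgt = self._mats([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        out = correlation_filter(_table([("r", "t")]), reg, tgt)
        assert len(out) == 1 and out[0].pcc == pytest.approx(-1.0)

    def test_positive_correlation_dropped(self):
        reg, tgt = self._mats([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert correlation_filter(_table([("r", "t")]), reg, tgt) == []

    def test_hand_computed_pearson(self):
        x, y = [3, 1, 4, 1, 5], [2, 7, 1, 8, 2]
        xa, ya = np.array(x, float), np.array(y, float)
        r_hand = float(
            np.sum((xa - xa.mean()) * (ya - ya.mean()))
            / np.sqrt(np.sum((xa - xa.mean()) ** 2) * np.sum((ya - ya.mean()) ** 2))
        )
        reg, tgt = self._mats(x, y)
        out = correlation_filter(_table([("r", "t")]), reg, tgt, p_threshold=None)
        assert r_hand < 0  # this fixture is anticorrelated
        assert len(out) == 1
        assert out[0].pcc == pytest.approx(r_hand, abs=1e-12)
        # with the significance condition the same edge is decided by the test p
        p = stats.pearsonr(xa, ya)[1]
        strict = correlation_filter(_table([("r", "t")]), reg, tgt, p_threshold=0.05)
        assert (len(strict) == 1) == (p < 0.05)

    def test_output_subset_of_input(self, small_bundle):
        from cernet.ingest import log2_standardize

        mir = log2_standardize(small_bundle.mirna)
        mrna = log2_standardize(small_bundle.mrna)
        out = correlation_filter(small_bundle.interactions, mir, mrna)
        inset = set(
            small_bundle.interactions.edges[["regulator_id", "target_id"]].itertuples(
                index=False, name=None
            )
        )
        assert {(e.regulator_id, e.target_id) for e in out} <= inset

    def test_recovery_improves_with_edge_effect(self):
        # Jaccard overlap of retained edges with planted truth grows with the
        # regulation strength (log2fc_de = 0 isolates the latent channel)
        from cernet.ingest import log2_standardize
        from cernet.synthdata import SynthConfig, generate_study

        jaccards = []
        for effect in (0.2, 0.5, 0.9):
            vals = []
            for seed in range(6):
                cfg = SynthConfig(
                    n_tumor=15, n_normal=15, n_mirna=20, n_lncrna=15, n_mrna=40,
                    n_true_edges=25, n_triplets=2, edge_effect=effect,
                    log2fc_de=0.0, seed=60 + seed,
                )
                b = generate_study(cfg)
                got = {
                    (e.regulator_id, e.target_id)
                    for e in correlation_filter(
                        b.interactions,
                        log2_standardize(b.mirna),
                        log2_standardize(b.mrna),
                    )
                }
                planted = {
                    e for e in map(tuple, b.truth.true_edges) if e[1].startswith("GENE")
                }
                vals.append(len(got & planted) / len(got | planted))
            jaccards.append(np.mean(vals))
        assert jaccards[0] < jaccards[1] < jaccards[2]

    def test_mismatched_samples_error(self):
        reg, _ = self._mats([1, 2, 3], [1, 2, 3], samples=["a", "b", "c"])
        _, tgt = self._mats([1, 2, 3], [1, 2, 3], samples=["a", "b", "d"])
        with pytest.raises(ValueError, match="sample"):
            correlation_filter(_table([("r", "t")]), reg, tgt)

    def test_zero_variance_edge_skipped(self):
        reg, tgt = self._mats([1, 1, 1, 1, 1], [5, 4, 3, 2, 1])
        assert correlation_filter(_table([("r", "t")]), reg, tgt) == []
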