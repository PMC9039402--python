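import numpy as np
import pandas as pd
import pytest

from cernet.ingest import ClinicalTable, ExpressionMatrix
from cernet.survival import (
    RiskModel,
    breslow_partial_loglik,
    cox_univariate,
    km_logrank,
    risk_score,
    roc_auc,
)


def grid_search_beta(time, event, x, lo=-5, hi=5):
    """Oracle: brute-force maximization of the Breslow partial likelihood."""
    grid = np.linspace(lo, hi, 2001)
    lls = [breslow_partial_loglik(b, time, event, x)[0] for b in grid]
    b = grid[int(np.argmax(lls))]
    # refine
    grid2 = np.linspace(b - 0.01, b + 0.01, 2001)
    lls2 = [breslow_partial_loglik(b2, time, event, x)[0] for b2 in grid2]
    return float(grid2[int(np.argmax(lls2))])


def _clin(times, events):
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"p{i}" for i in range(len(times))],
                "time": times,
                "event": events,
            }
        )
    )


class TestCoxUnivariate:
    def test_constant_covariate_degenerate(self, toy_clinical):
        fit = cox_univariate([1.0, 1.0, 1.0, 1.0], toy_clinical)
        assert fit.beta == 0.0
        assert not fit.converged

    def test_four_subject_fixture_matches_grid_search(self, toy_clinical):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        t = toy_clinical.table["time"].to_numpy()
        d = toy_clinical.table["event"].to_numpy()
        fit = cox_univariate(x, toy_clinical)
        assert fit.converged
        assert abs(fit.beta - grid_search_beta(t, d, x)) < 1e-4

    def test_monotone_covariate_four_subjects_is_separated(self, toy_clinical):
        # the covariate perfectly orders the (uncensored) event sequence, so
        # the partial likelihood is monotone in beta and no finite MLE exists
        fit = cox_univariate(np.array([1.0, 1.0, 0.0, 0.0]), toy_clinical)
        assert not fit.converged

    @pytest.mark.parametrize(
        "times,events,x",
        [
            ([2, 4, 1, 5, 3], [1, 0, 1, 1, 1], [0.2, -1.0, 1.5, 0.0, 0.7]),
            ([1, 1, 2, 3, 5, 8], [1, 1, 0, 1, 1, 0], [1, 0, 1, 0, 1, 0]),
        ],
    )
    def test_small_fixtures_match_grid_search(self, times, events, x):
        clin = _clin([float(t) for t in times], events)
        xa = np.asarray(x, float)
        fit = cox_univariate(xa, clin)
        oracle = grid_search_beta(
            clin.table["time"].to_numpy(), clin.table["event"].to_numpy(), xa
        )
        assert abs(fit.beta - oracle) < 1e-4

    def test_no_events_rejected(self):
        clin = _clin([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="event"):
            cox_univariate([1.0, 2.0], clin)

    def test_separation_flagged(self):
        # covariate perfectly orders events first -> monotone likelihood
        clin = _clin([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 1, 0, 0, 0])
        fit = cox_univariate([10.0, 9.0, 8.0, 0.1, 0.05, 0.0], clin)
        assert not fit.converged


class TestRiskScore:
    def _expr(self):
        return ExpressionMatrix(
            pd.DataFrame(
                [[1.0, 2.0, 3.0, 4.0], [2.0, 0.0, 1.0, 5.0], [0.5, 0.5, 1.5, 0.0]],
                index=["f1", "f2", "f3"],
                columns=["p1", "p2", "p3", "p4"],
            ),
            "mRNA",
            "log2",
        )

    def test_zero_betas_degenerate_all_low(self):
        strat = risk_score(RiskModel(["f1"], [0.0]), self._expr())
        assert strat.degenerate
        assert (strat.groups == "low").all()

    def test_single_feature_identity(self):
        expr = self._expr()
        strat = risk_score(RiskModel(["f1"], [1.0]), expr)
        assert np.allclose(strat.scores.to_numpy(), expr.values.loc["f1"].to_numpy())
        assert strat.cutoff == pytest.approx(2.5)
        assert strat.groups.tolist() == ["low", "low", "high", "high"]

    def test_hand_computed_dot_products(self):
        betas = [0.5, -1.0, 2.0]
        expr = self._expr()
        strat = risk_score(RiskModel(["f1", "f2", "f3"], betas), expr)
        expected = (
            0.5 * expr.values.loc["f1"] - 1.0 * expr.values.loc["f2"] + 2.0 * expr.values.loc["f3"]
        )
        assert np.allclose(strat.scores.to_numpy(), expected.to_numpy())

    def test_group_assignment_invariant_under_constant_shift(self):
        expr = self._expr()
        strat = risk_score(RiskModel(["f1"], [1.0]), expr)
        shifted = ExpressionMatrix(expr.values + 100.0, "mRNA", "log2")
        strat2 = risk_score(RiskModel(["f1"], [1.0]), shifted)
        assert strat.groups.tolist() == strat2.groups.tolist()

    def test_missing_feature_named(self):
        with pytest.raises(KeyError, match="nope"):
            risk_score(RiskModel(["nope"], [1.0]), self._expr())


def logrank_oracle(time, event, group):
    """Hand-style oracle: observed/expected event table per distinct event time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = sorted(set(group))
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        n1 = (at_risk & (group == labels[0])).sum()
        d1 = ((time == t) & (event == 1) & (group == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKmLogrank:
    def test_identical_event_patterns(self):
        clin = _clin([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [1, 1, 0, 1, 1, 0])
        groups = pd.Series(
            ["a", "a", "a", "b", "b", "b"], index=clin.table["sample_id"]
        )
        res = km_logrank(clin, groups)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        clin = _clin(times, [1] * 6)
        groups = pd.Series(
            ["a", "a", "a", "b", "b", "b"], index=clin.table["sample_id"]
        )
        res = km_logrank(clin, groups)
        curve = res.curves["a"].set_index("time")["survival"]
        # empirical survivor function of group a: times 1,2,3
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(1 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    def test_ten_subject_fixture_matches_hand_table(self):
        times = [3.0, 5.0, 7.0, 2.0, 18.0, 12.0, 19.0, 16.0, 6.0, 9.0]
        events = [1, 1, 1, 1, 0, 1, 0, 1, 1, 1]
        group = ["a"] * 5 + ["b"] * 5
        clin = _clin(times, events)
        groups = pd.Series(group, index=clin.table["sample_id"])
        res = km_logrank(clin, groups)
        assert res.logrank_chi2 == pytest.approx(
            logrank_oracle(times, events, group), rel=1e-9
        )

    def test_symmetric_under_label_swap(self):
        times = [3.0, 5.0, 7.0, 2.0, 18.0, 12.0]
        events = [1, 1, 0, 1, 1, 1]
        clin = _clin(times, events)
        g1 = pd.Series(["a", "a", "a", "b", "b", "b"], index=clin.table["sample_id"])
        g2 = g1.map({"a": "b", "b": "a"})
        assert km_logrank(clin, g1).logrank_chi2 == pytest.approx(
            km_logrank(clin, g2).logrank_chi2
        )

    def test_no_events_warns_p_one(self):
        clin = _clin([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        groups = pd.Series(["a", "a", "b", "b"], index=clin.table["sample_id"])
        res = km_logrank(clin, groups)
        assert res.logrank_p == 1.0

    def test_empty_group_rejected(self):
        clin = _clin([1.0, 2.0], [1, 1])
        groups = pd.Series(["a", "a"], index=clin.table["sample_id"])
        with pytest.raises(ValueError):
            km_logrank(clin, groups)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_tie_handling_matches_pairwise_count(self):
        scores = [0.1, 0.4, 0.4, 0.6, 0.7, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        # brute force over all (positive, negative) pairs with 0.5 for ties
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        total = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
        assert roc_auc(scores, labels) == pytest.approx(total / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])
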