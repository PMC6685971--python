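"""Weighted vote fusion, cohort classification, metrics and ablation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from awakeosa.features import FeatureTable
from awakeosa.training import OutlierFences, SubsetModel, SubsetSpec
from awakeosa.voting import (
    VotingEnsemble,
    classify_cohort,
    combination_ahi_correlation,
    evaluate,
    subset_ablation,
    subset_vote,
    weighted_decision,
)


def make_model(name="m", features=("f",), sens=1.0, spec=1.0, positive_if=0.5, seed=0):
    """A subset model whose forest calls OSA iff the first feature > positive_if."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(60, len(features)))
    y = X[:, 0] > positive_if
    forest = RandomForestClassifier(n_estimators=25, random_state=0).fit(X, y)
    return SubsetModel(
        spec=SubsetSpec(name, "bmi", "<", 35),
        combination=tuple(features),
        fences=OutlierFences({f: (0.0, 1.0) for f in features}),
        forest=forest,
        oob_accuracy=(sens + spec) / 2,
        oob_sensitivity=sens,
        oob_specificity=spec,
    )


class TestSubsetVote:
    def test_osa_vote_weighted_by_sensitivity(self):
        m = make_model(sens=0.84, spec=0.9)
        assert subset_vote(m, {"f": 0.9}) == pytest.approx(0.84)

    def test_non_osa_vote_weighted_by_specificity(self):
        m = make_model(sens=0.84, spec=0.875)
        assert subset_vote(m, {"f": 0.1}) == pytest.approx(-0.875)

    def test_missing_or_fenced_feature_abstains(self):
        m = make_model()
        assert subset_vote(m, {"f": float("nan")}) is None
        assert subset_vote(m, {"f": 1.7}) is None  # outside (0, 1) fence
        assert subset_vote(m, {}) is None


class TestWeightedDecision:
    def test_unanimous_osa_with_perfect_weights_gives_one(self):
        d = weighted_decision([1.0] * 6)
        assert d.d == 1.0 and d.call == "osa" and d.high_confidence

    def test_unanimous_non_osa_with_perfect_weights_gives_minus_one(self):
        d = weighted_decision([-1.0] * 6)
        assert d.d == -1.0 and d.call == "non_osa" and d.high_confidence

    def test_hand_computed_mixed_vote(self):
        d = weighted_decision([0.84, -0.875, 0.80])
        assert d.d == pytest.approx((0.84 - 0.875 + 0.80) / 3)
        assert d.call == "osa" and not d.high_confidence

    def test_skip_policy_ignores_abstentions(self):
        d = weighted_decision([0.8, None, None])
        assert d.d == pytest.approx(0.8)

    def test_all_abstain_unclassifiable(self):
        d = weighted_decision([None, None])
        assert d.call == "unclassifiable" and np.isnan(d.d)

    def test_exact_zero_called_non_osa_with_tie_flag(self):
        d = weighted_decision([0.5, -0.5])
        assert d.call == "non_osa" and d.tie

    def test_invariant_to_vote_order(self):
        votes = [0.3, -0.9, 0.7, None]
        assert weighted_decision(votes).d == pytest.approx(weighted_decision(votes[::-1]).d)

    def test_bounded_by_largest_weight(self):
        votes = [0.84, -0.875, 0.8]
        assert abs(weighted_decision(votes).d) <= 0.875


def table_for(models, values):
    cols = sorted({f for m in models for f in m.combination})
    df = pd.DataFrame(values, columns=cols)
    df.index = [f"s{i}" for i in range(len(df))]
    return FeatureTable(df, provenance="scaled", scaling={c: (0, 1) for c in cols})


class TestClassifyCohort:
    def test_single_model_decision_equals_its_vote(self):
        m = make_model(sens=0.9, spec=0.8)
        table = table_for([m], [[0.9], [0.1]])
        dec = classify_cohort(VotingEnsemble([m]), table)
        assert dec.loc["s0", "d"] == pytest.approx(0.9)
        assert dec.loc["s1", "d"] == pytest.approx(-0.8)

    def test_unscaled_table_rejected(self):
        m = make_model()
        table = FeatureTable(pd.DataFrame({"f": [0.5]}, index=["s0"]))
        with pytest.raises(ValueError, match="scaled"):
            classify_cohort(VotingEnsemble([m]), table)

    def test_all_abstain_listed_unclassifiable(self):
        m = make_model()
        table = table_for([m], [[np.nan]])
        dec = classify_cohort(VotingEnsemble([m]), table)
        assert dec.loc["s0", "call"] == "unclassifiable"

    def test_zero_weight_model_never_changes_call(self):
        strong = make_model("strong", ("f",), sens=0.9, spec=0.9)
        null = make_model("null", ("f",), sens=0.0, spec=0.0)
        table = table_for([strong], [[0.9], [0.1], [0.7]])
        a = classify_cohort(VotingEnsemble([strong]), table)
        b = classify_cohort(VotingEnsemble([strong, null]), table)
        assert (a["call"] == b["call"]).all()


class TestEvaluate:
    def test_perfect_predictions(self):
        dec = pd.DataFrame({"call": ["osa", "non_osa"], "d": [1, -1]}, index=["a", "b"])
        m = evaluate(dec, pd.Series({"a": True, "b": False}))
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_confusion_count_arithmetic(self):
        calls = ["osa"] * 8 + ["non_osa"] * 2 + ["non_osa"] * 7 + ["osa"] * 3
        labels = [True] * 10 + [False] * 10
        idx = [f"s{i}" for i in range(20)]
        dec = pd.DataFrame({"call": calls}, index=idx)
        m = evaluate(dec, pd.Series(labels, index=idx))
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.7)
        assert m.accuracy == pytest.approx(0.75)

    def test_all_osa_predictor_on_balanced_data(self):
        dec = pd.DataFrame({"call": ["osa"] * 10}, index=[f"s{i}" for i in range(10)])
        labels = pd.Series([True] * 5 + [False] * 5, index=dec.index)
        m = evaluate(dec, labels)
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_unclassifiable_counts_as_error(self):
        dec = pd.DataFrame({"call": ["osa", "unclassifiable"]}, index=["a", "b"])
        m = evaluate(dec, pd.Series({"a": True, "b": True}))
        assert m.accuracy == 0.5 and m.n_unclassifiable == 1

    def test_empty_report_is_error(self):
        with pytest.raises(ValueError):
            evaluate(pd.DataFrame(columns=["call"]), pd.Series(dtype=bool))


class TestAblation:
    def test_zero_weight_model_removal_zero_delta(self):
        strong = make_model("strong", ("f",), sens=0.9, spec=0.9)
        null = make_model("null", ("f",), sens=0.0, spec=0.0)
        table = table_for([strong], [[0.9], [0.1]])
        labels = pd.Series({"s0": True, "s1": False})
        deltas = subset_ablation(VotingEnsemble([strong, null]), table, labels)
        assert deltas.loc["null", "delta_accuracy"] == 0.0

    def test_informative_model_removal_hurts(self):
        informative = make_model("inf", ("f",), sens=1.0, spec=1.0)
        contrarian = make_model("con", ("f",), sens=0.4, spec=0.4, positive_if=1.1)
        table = table_for([informative], [[0.9], [0.8], [0.1], [0.2]])
        labels = pd.Series({"s0": True, "s1": True, "s2": False, "s3": False})
        ens = VotingEnsemble([informative, contrarian])
        deltas = subset_ablation(ens, table, labels)
        assert deltas.loc["inf", "delta_accuracy"] > 0

    def test_reproducible(self):
        m1 = make_model("a", ("f",), 0.9, 0.8)
        m2 = make_model("b", ("f",), 0.7, 0.6, positive_if=0.3)
        table = table_for([m1], [[0.9], [0.4], [0.1]])
        labels = pd.Series({"s0": True, "s1": False, "s2": False})
        ens = VotingEnsemble([m1, m2])
        pd.testing.assert_frame_equal(
            subset_ablation(ens, table, labels), subset_ablation(ens, table, labels)
        )

    def test_single_model_is_error(self):
        m = make_model()
        table = table_for([m], [[0.5]])
        with pytest.raises(ValueError):
            subset_ablation(VotingEnsemble([m]), table, pd.Series({"s0": True}))


class TestAhiCorrelation:
    def test_exact_linear_response_correlates_perfectly(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        ahi = 2 + X @ np.array([1.0, -2.0, 0.5])
        r = combination_ahi_correlation(X, ["a", "b", "c"], ahi)
        assert r == pytest.approx(1.0)

    def test_null_response_low_correlation(self):
        # multiple-R under the null: R^2 ~ chi2_3 / 199, so P(R < 0.2) ~ 0.95;
        # assert within binomial noise of that rate over 100 runs
        rs = []
        for s in range(100):
            r = np.random.default_rng(s)
            X = pd.DataFrame(r.normal(size=(200, 3)), columns=list("abc"))
            ahi = pd.Series(r.uniform(1, 60, 200), index=X.index)
            rs.append(combination_ahi_correlation(X, list("abc"), ahi))
        assert np.mean(np.array(rs) < 0.2) >= 0.90

    def test_log_link_favors_log_scale(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 2)), columns=list("ab"))
        log_ahi = 1.5 + X["a"] - 0.8 * X["b"] + 0.1 * rng.normal(size=120)
        ahi = np.exp(log_ahi)
        r_lin = combination_ahi_correlation(X, list("ab"), ahi, scale="linear")
        r_log = combination_ahi_correlation(X, list("ab"), ahi, scale="log")
        assert r_log > r_lin

    def test_zero_ahi_dropped_under_log(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=list("ab"))
        ahi = pd.Series(np.r_[0.0, rng.uniform(1, 30, 11)], index=X.index)
        with pytest.warns(UserWarning, match="AHI"):
            combination_ahi_correlation(X, list("ab"), ahi, scale="log")
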