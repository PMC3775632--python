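import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from bdfunc.cohort import (
    classify,
    classify_matrix,
    group_anova,
    anova_table,
    score_samples,
    summarize_boxplot,
)
from bdfunc.engine import enrich_profile, make_profile
from bdfunc.signatures import BidirectionalSignature
from bdfunc.synthdata import PlantSpec, simulate_cohort


def brute_force_auc(pos, neg):
    """Pair-counting probability: (wins + ties/2) / (n_pos * n_neg)."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


@pytest.fixture
def cohort():
    spec = PlantSpec(n_activated=20, n_inhibited=20, n_background=60,
                     effect=1.5, n_pos=6, n_neg=6, seed=11)
    return simulate_cohort(spec)


class TestScoreSamples:
    def test_single_column_matches_enrich_profile(self, cohort):
        table, groups, sig, _ = cohort
        sm = score_samples(table, groups, [sig])
        col = table.columns[0]
        profile = make_profile(table[col], label=col)
        ref = enrich_profile(profile, [sig]).scores.iloc[0]
        assert sm.scores.loc[sig.name, col] == pytest.approx(ref["statistic"])

    def test_planted_activation_scores_positive(self, cohort):
        table, groups, sig, truth = cohort
        sm = score_samples(table, groups, [sig])
        pos = sm.scores.loc[sig.name, truth["positive_samples"]]
        neg = sm.scores.loc[sig.name, truth["negative_samples"]]
        assert pos.median() > neg.median()
        assert (pos > 2).all()

    def test_identical_columns_get_identical_scores(self, cohort):
        table, groups, sig, _ = cohort
        dup = table.copy()
        dup["COPY"] = dup[dup.columns[0]]
        groups2 = pd.concat([groups, pd.Series({"COPY": groups.iloc[0]})])
        sm = score_samples(dup, groups2, [sig])
        assert sm.scores.loc[sig.name, "COPY"] == sm.scores.loc[sig.name, dup.columns[0]]

    def test_unscoreable_signature_row_omitted(self, cohort):
        table, groups, sig, _ = cohort
        ghost = BidirectionalSignature.from_gene_lists(
            "GHOST", ["NO1", "NO2", "NO3"], ["NO4", "NO5", "NO6"]
        )
        sm = score_samples(table, groups, [sig, ghost])
        assert list(sm.scores.index) == [sig.name]
        assert sm.skipped[0][0] == "GHOST"


class TestGroupAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        cmp = group_anova([1, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        assert cmp.f_statistic == pytest.approx(0.0)
        assert cmp.anova_p == pytest.approx(1.0)

    def test_hand_worked_two_group_case(self):
        # groups [1,2] vs [3,4]: SSB = 4, SSW = 1, df (1, 2) -> F = 8
        cmp = group_anova([1, 2, 3, 4], ["A", "A", "B", "B"])
        assert cmp.f_statistic == pytest.approx(8.0, abs=1e-12)
        assert cmp.anova_p == pytest.approx(0.10557, abs=1e-5)

    def test_matches_scipy_and_shift_invariant(self, rng):
        for _ in range(100):
            sizes = rng.integers(2, 8, size=3)
            groups = np.repeat(["a", "b", "c"], sizes)
            vals = rng.normal(size=sizes.sum())
            cmp = group_anova(vals, groups)
            f, p = stats.f_oneway(*(vals[groups == g] for g in "abc"))
            assert cmp.f_statistic == pytest.approx(f, abs=1e-9)
            assert cmp.anova_p == pytest.approx(p, abs=1e-9)
            shifted = group_anova(vals + 17.3, groups)
            assert shifted.anova_p == pytest.approx(cmp.anova_p, abs=1e-9)

    def test_two_group_anova_equals_pooled_t(self, rng):
        vals = rng.normal(size=12)
        groups = ["x"] * 5 + ["y"] * 7
        cmp = group_anova(vals, groups)
        t, p = stats.ttest_ind(vals[:5], vals[5:], equal_var=True)
        assert cmp.f_statistic == pytest.approx(t**2, abs=1e-9)
        assert cmp.anova_p == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize(
        "scores, groups",
        [
            ([1, 2, 3], ["A", "A", "A"]),            # one group only
            ([1, 2, 3], ["A", "A", "B"]),            # a group with < 2 samples
        ],
    )
    def test_degenerate_grouping_rejected(self, scores, groups):
        with pytest.raises(ValueError):
            group_anova(scores, groups)

    def test_unlabelled_samples_excluded(self):
        cmp = group_anova([1, 2, 3, 4, 99], ["A", "A", "B", "B", None])
        assert cmp.group_ns == {"A": 2, "B": 2}


class TestBoxplotSummary:
    @pytest.mark.parametrize(
        "shift, color", [(3.1, "red"), (-2.5, "green"), (0.4, "grey")]
    )
    def test_median_color_rule(self, cohort, shift, color):
        table, groups, sig, _ = cohort
        sm = score_samples(table, groups, [sig])
        forced = sm.scores.copy()
        forced.loc[sig.name, :] = shift + np.linspace(-0.1, 0.1, forced.shape[1])
        summary = summarize_boxplot(
            type(sm)(scores=forced, groups=sm.groups, method=sm.method, flags=sm.flags)
        )
        assert (summary["color"] == color).all()

    def test_quartiles_linear_interpolation(self, cohort):
        table, groups, sig, _ = cohort
        sm = score_samples(table, groups, [sig])
        summary = summarize_boxplot(sm).set_index("group")
        pos = sm.scores.loc[sig.name, groups[groups == "positive"].index]
        assert summary.loc["positive", "q1"] == pytest.approx(
            np.percentile(pos, 25)  # numpy default = linear (type 7)
        )


class TestClassify:
    def test_worked_example_auc(self):
        # pos [3,1] vs neg [2,0]: 3 wins of 4 pairs -> 0.75
        scores = [3, 1, 2, 0]
        labels = ["positive", "positive", "negative", "negative"]
        res = classify(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc([3, 1], [2, 0]))
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = classify([5, 4, 1, 0], ["positive", "positive", "negative", "negative"])
        assert res.auc == 1.0

    def test_cutoff_rule(self):
        res = classify([2.5, 1.0], ["positive", "negative"], cutoff=2)
        assert (res.accuracy, res.sensitivity, res.specificity) == (1.0, 1.0, 1.0)
        # strict rule: a positive scoring exactly at the cutoff is missed
        res2 = classify([2.0, 1.0], ["positive", "negative"], cutoff=2)
        assert res2.sensitivity == 0.0

    def test_roc_curve_monotone_with_unit_endpoints(self, rng):
        scores = rng.normal(size=40)
        labels = rng.permutation(["positive"] * 18 + ["negative"] * 22)
        res = classify(scores, labels)
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()

    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=15),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=15),
    )
    def test_trapezoid_auc_equals_pair_counting(self, pos, neg):
        """Tied scores included: trapezoid AUC = (wins + ties/2) / (np*nn)."""
        scores = pos + neg
        labels = ["positive"] * len(pos) + ["negative"] * len(neg)
        res = classify(scores, labels)
        assert res.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    @given(
        pos=st.lists(st.floats(-5, 5, allow_nan=False, width=32), min_size=1, max_size=12),
        neg=st.lists(st.floats(-5, 5, allow_nan=False, width=32), min_size=1, max_size=12),
    )
    def test_auc_of_negated_scores_complements(self, pos, neg):
        scores = pos + neg
        labels = ["positive"] * len(pos) + ["negative"] * len(neg)
        a = classify(scores, labels).auc
        b = classify([-s for s in scores], labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_invert_flag_flips_orientation(self):
        scores = [0, 1, 2, 3]
        labels = ["positive", "positive", "negative", "negative"]
        assert classify(scores, labels).auc == 0.0
        assert classify(scores, labels, invert=True).auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify([1, 2], ["positive", "positive"])

    def test_null_labels_give_auc_near_half(self, rng):
        aucs = []
        for _ in range(200):
            scores = rng.normal(size=30)
            labels = rng.permutation(["positive"] * 15 + ["negative"] * 15)
            aucs.append(classify(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


class TestEndToEnd:
    def test_cohort_recovery_with_planted_effect(self):
        """Positive group median exceeds negative and ANOVA fires, across seeds."""
        n_median, n_anova, n_runs = 0, 0, 60
        for seed in range(n_runs):
            spec = PlantSpec(n_activated=40, n_inhibited=40, n_background=120,
                             effect=1.0, n_pos=10, n_neg=10, seed=seed)
            table, groups, sig, truth = simulate_cohort(spec)
            sm = score_samples(table, groups, [sig])
            pos = sm.scores.loc[sig.name, truth["positive_samples"]]
            neg = sm.scores.loc[sig.name, truth["negative_samples"]]
            n_median += pos.median() > neg.median()
            cmp = group_anova(sm.scores.loc[sig.name], groups, signature=sig.name)
            n_anova += cmp.anova_p < 0.01
        assert n_median == n_runs
        assert n_anova / n_runs >= 0.95

    def test_matrix_helpers_cover_all_signatures(self, cohort):
        table, groups, sig, _ = cohort
        sm = score_samples(table, groups, [sig])
        at = anova_table(sm)
        assert list(at["signature"]) == [sig.name]
        results = classify_matrix(sm)
        assert results[0].signature == sig.name
        assert results[0].auc > 0.9
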