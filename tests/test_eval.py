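"""Classifier-evaluation engine: stratified splits, Mann-Whitney AUC,
Youden operating point, repeated-split harness and group t-tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import kcscreen as kc
from kcscreen.evaluate import ClassifierSpec, operating_point, roc_auc, stratified_split

import oracles


class TestStratifiedSplit:
    def test_study_split_counts(self):
        labels = np.array(["normal"] * 50 + ["subKC"] * 33)
        train, val = stratified_split(labels, 0.7, np.random.default_rng(0))
        assert len(train) == 35 + 23
        assert len(val) == 83 - 58
        # per-class proportions preserved
        assert (labels[train] == "normal").sum() == 35
        assert (labels[val] == "subKC").sum() == 10

    def test_parts_partition_all_rows(self):
        labels = np.repeat(["a", "b"], [20, 12])
        train, val = stratified_split(labels, 0.7, np.random.default_rng(1))
        assert len(np.intersect1d(train, val)) == 0
        assert sorted(np.concatenate([train, val])) == list(range(32))

    def test_identical_rng_state_gives_identical_split(self):
        labels = np.repeat([0, 1], [30, 20])
        t1, v1 = stratified_split(labels, 0.7, np.random.default_rng(42))
        t2, v2 = stratified_split(labels, 0.7, np.random.default_rng(42))
        assert np.array_equal(t1, t2) and np.array_equal(v1, v2)

    def test_extreme_fraction_rejected(self):
        labels = np.repeat([0, 1], [10, 10])
        with pytest.raises(ValueError):
            stratified_split(labels, 0.999, np.random.default_rng(0))
        with pytest.raises(ValueError):
            stratified_split(labels, 1.2, np.random.default_rng(0))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_interleaved(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_exhaustive_pair_counting_oracle_small_n(self):
        rng = np.random.default_rng(7)
        for n in range(2, 9):
            scores = rng.integers(0, 4, size=n).astype(float)  # forces ties
            for labels in itertools.product([0, 1], repeat=n):
                labels = np.array(labels)
                if labels.sum() in (0, n):
                    continue
                assert roc_auc(scores, labels) == pytest.approx(
                    oracles.naive_pairwise_auc(scores, labels))

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.sum() in (0, 40):
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        base = roc_auc(scores, labels)
        for f in (np.exp, lambda s: s**3, lambda s: 5 * s - 2):
            assert roc_auc(f(scores), labels) == pytest.approx(base)


class TestOperatingPoint:
    def test_perfect_separation(self):
        assert operating_point([1, 2, 3, 4], [0, 0, 1, 1]) == (1.0, 1.0)

    def test_tie_resolved_toward_sensitivity(self):
        # J = 0.5 at both (1.0, 0.5) and (0.5, 1.0); sensitivity wins
        assert operating_point([1, 2, 3, 4], [0, 1, 0, 1]) == (1.0, 0.5)

    def test_youden_value_preserved_under_score_negation_with_label_swap(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        s1, p1 = operating_point(scores, labels)
        s2, p2 = operating_point(-scores, 1 - labels)
        assert s1 + p1 == pytest.approx(s2 + p2)

    def test_never_worse_than_chance(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            scores = rng.normal(size=20)
            labels = rng.integers(0, 2, size=20)
            if labels.sum() in (0, 20):
                continue
            sens, spec = operating_point(scores, labels)
            assert sens + spec - 1.0 >= -1e-12


class TestTrainClassifier:
    def test_deterministic_given_seed(self, table):
        sub = table.subset_classes(["normal", "subKC"])
        X = kc.fit_normalizer(sub).transform(sub.features).to_numpy()
        y = (sub.labels == "subKC").to_numpy().astype(int)
        spec = ClassifierSpec(kind="neural_network")
        f1, _ = kc.train_classifier(spec, X, y, seed=5)
        f2, _ = kc.train_classifier(spec, X, y, seed=5)
        assert np.array_equal(f1(X), f2(X))

    def test_scores_are_probabilities(self, table):
        sub = table.subset_classes(["normal", "KC"])
        X = kc.fit_normalizer(sub).transform(sub.features).to_numpy()
        y = (sub.labels == "KC").to_numpy().astype(int)
        for kind in ("logistic_regression", "neural_network"):
            f, _ = kc.train_classifier(ClassifierSpec(kind=kind), X, y, seed=1)
            s = f(X)
            assert np.all((s >= 0) & (s <= 1))

    def test_separable_1d_scores_perfectly(self):
        X = np.concatenate([np.linspace(-3, -1, 10), np.linspace(1, 3, 10)])[:, None]
        y = np.repeat([0, 1], 10)
        f, _ = kc.train_classifier(ClassifierSpec(kind="logistic_regression"), X, y)
        assert roc_auc(f(X), y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            kc.train_classifier(ClassifierSpec(), np.zeros((4, 2)), np.zeros(4))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(kind="random_forest")
        with pytest.raises(ValueError):
            ClassifierSpec(feature_subset="elevation_only")
        with pytest.raises(ValueError):
            ClassifierSpec(kind="neural_network", hidden_units=0)


class TestRepeatedSplitEval:
    def test_reproducible_from_master_seed(self, table):
        spec = ClassifierSpec(kind="logistic_regression")
        r1 = kc.repeated_split_eval(table, spec, ("normal", "KC"), repeats=5,
                                    master_seed=3)
        r2 = kc.repeated_split_eval(table, spec, ("normal", "KC"), repeats=5,
                                    master_seed=3)
        assert r1.per_repeat.equals(r2.per_repeat)

    def test_single_repeat_summary_matches_repeat(self, table):
        spec = ClassifierSpec(kind="logistic_regression")
        res = kc.repeated_split_eval(table, spec, ("normal", "KC"), repeats=1,
                                     master_seed=2)
        assert res.summary["mean_auc"] == res.per_repeat.loc[0, "auc"]
        assert res.summary["sd_auc"] == 0.0
        assert res.summary["n_repeats"] == 1

    def test_metrics_bounded(self, table):
        spec = ClassifierSpec(kind="neural_network", feature_subset="oct_only")
        res = kc.repeated_split_eval(table, spec, ("normal", "subKC"), repeats=10,
                                     master_seed=4)
        pr = res.per_repeat
        for col in ("auc", "sensitivity", "specificity"):
            assert ((pr[col] >= 0) & (pr[col] <= 1)).all()

    def test_label_permutation_null_auc_near_half(self, table):
        # destroying the label-feature link must drop performance to chance
        df = table.subset_classes(["normal", "subKC"]).df.copy()
        rng = np.random.default_rng(23)
        df["group"] = rng.permutation(df["group"].to_numpy())
        null = kc.FeatureTable(df)
        res = kc.repeated_split_eval(null, ClassifierSpec(kind="logistic_regression"),
                                     ("normal", "subKC"), repeats=100, master_seed=5)
        assert 0.4 <= res.summary["mean_auc"] <= 0.6

    def test_kc_discrimination_easier_than_subclinical(self, config):
        # the clinical severity gradient must be visible for every spec;
        # checked on a cohort large enough that a single atypical eye
        # cannot mask the population ordering
        cohort = kc.generate_cohort(config, 150, 100, 100, seed=21)
        big = kc.assemble_table(cohort, kc.build_normative_pattern(cohort))
        for kind in ("logistic_regression", "neural_network"):
            for subset in ("pentacam_only", "oct_only", "combined"):
                spec = ClassifierSpec(kind=kind, feature_subset=subset)
                sub = kc.repeated_split_eval(big, spec, ("normal", "subKC"),
                                             repeats=10, master_seed=6)
                hard = kc.repeated_split_eval(big, spec, ("normal", "KC"),
                                              repeats=10, master_seed=6)
                assert hard.summary["mean_auc"] > sub.summary["mean_auc"]


class TestGroupTtests:
    def test_matches_scipy_closed_form(self, table):
        out = kc.group_ttests(table, ["EPV", "ISV"]).set_index("feature")
        normal = table.df[table.df["group"] == "normal"]["EPV"]
        sub = table.df[table.df["group"] == "subKC"]["EPV"]
        t, p = sps.ttest_ind(normal, sub, equal_var=True)
        assert out.loc["EPV", "t_normal_vs_subKC"] == pytest.approx(t)
        assert out.loc["EPV", "p_normal_vs_subKC"] == pytest.approx(p)

    def test_hand_formula(self):
        a = np.array([0.0, 0.0, 1.0, 1.0])
        b = np.array([10.0, 10.0, 11.0, 11.0])
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        t_scipy, _ = sps.ttest_ind(a, b, equal_var=True)
        assert t_scipy == pytest.approx(t_hand)

    def test_equal_means_give_zero_t(self, table):
        df = table.df.copy()
        df["EPV"] = np.tile([1.0, 2.0], 61)[:121]  # same pattern in every group
        out = kc.group_ttests(kc.FeatureTable(df), ["EPV"]).set_index("feature")
        assert abs(out.loc["EPV", "t_normal_vs_KC"]) < 0.5
        assert out.loc["EPV", "p_normal_vs_KC"] > 0.5

    def test_epv_separates_normal_from_subkc(self, table):
        out = kc.group_ttests(table, ["EPV"]).set_index("feature")
        assert out.loc["EPV", "p_normal_vs_subKC"] < 0.001
        assert bool(out.loc["EPV", "significant_normal_vs_subKC"])

    def test_missing_group_rejected(self, table):
        with pytest.raises(ValueError, match="absent"):
            kc.group_ttests(table.subset_classes(["normal", "KC"]), ["EPV"])
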