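"""Fusion contracts and the six-classifier evaluation harness."""

import numpy as np
import pytest

from urisedclass import (ClassifierSpec, EvalScheme, FeatureMatrix,
                         SelectionResult, fuse, make_classifier, overall_accuracy,
                         subselect, train_eval)
from urisedclass.classify import CLASSIFIER_KINDS
from .conftest import make_feature_matrix


def gaussian_blobs(rng, n_per_class=50, n_classes=2, f=10, sep=6.0):
    """Well-separated Gaussian classes."""
    X, labels = [], []
    for c in range(n_classes):
        centre = np.zeros(f)
        centre[c % f] = sep * c
        X.append(rng.normal(size=(n_per_class, f)) + centre)
        labels += [f"c{c}"] * n_per_class
    X = np.vstack(X)
    return FeatureMatrix(X, [f"s{i}" for i in range(len(labels))], labels,
                         [f"f{j}" for j in range(f)])


class TestSubselect:
    def test_reorders_columns(self, rng):
        fm = make_feature_matrix(rng, n=10, f=6)
        sel = SelectionResult([4, 1], "MID", np.zeros(6), [0.0, 0.1])
        out = subselect(fm, sel)
        np.testing.assert_array_equal(out.values, fm.values[:, [4, 1]])
        assert out.feature_names == [fm.feature_names[4], fm.feature_names[1]]

    def test_identity_selection(self, rng):
        fm = make_feature_matrix(rng, n=8, f=4)
        sel = SelectionResult(list(range(4)), "MID", np.zeros(4), [0.0] * 4)
        np.testing.assert_array_equal(subselect(fm, sel).values, fm.values)

    def test_out_of_range_fatal(self, rng):
        fm = make_feature_matrix(rng, n=8, f=4)
        sel = SelectionResult([0, 9], "MID", np.zeros(4), [0.0, 0.0])
        with pytest.raises(ValueError, match="out of range"):
            subselect(fm, sel)

    def test_duplicate_index_fatal(self):
        with pytest.raises(ValueError, match="unique"):
            SelectionResult([1, 1], "MID", np.zeros(4), [0.0, 0.0])


class TestFuse:
    def test_concatenates_blocks(self, rng):
        fm = make_feature_matrix(rng, n=12, f=5)
        other = FeatureMatrix(rng.normal(size=(12, 3)), fm.sample_ids,
                              fm.labels, ["g0", "g1", "g2"])
        fused = fuse(fm, other)
        assert fused.values.shape == (12, 8)
        assert fused.feature_names == fm.feature_names + other.feature_names

    def test_empty_block_identity(self, rng):
        fm = make_feature_matrix(rng, n=6, f=4)
        empty = FeatureMatrix(np.empty((6, 0)), fm.sample_ids, fm.labels, [])
        np.testing.assert_array_equal(fuse(fm, empty).values, fm.values)

    def test_row_order_mismatch_fatal(self, rng):
        fm = make_feature_matrix(rng, n=6, f=4)
        shuffled = FeatureMatrix(fm.values[::-1], fm.sample_ids[::-1],
                                 fm.labels[::-1], fm.feature_names)
        with pytest.raises(ValueError, match="sample_id mismatch at row 0"):
            fuse(fm, shuffled)


class TestClassifierSpecs:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_all_six_build_and_fit(self, rng, kind):
        fm = gaussian_blobs(rng, n_per_class=20)
        clf = make_classifier(ClassifierSpec(kind=kind, seed=0))
        clf.fit(fm.values, fm.labels)
        assert set(clf.predict(fm.values)) <= {"c0", "c1"}

    def test_unknown_kind_or_hyperparam_fatal(self):
        with pytest.raises(ValueError):
            ClassifierSpec(kind="random_forest")
        with pytest.raises(ValueError, match="unknown hyperparams"):
            ClassifierSpec(kind="svm", hyperparams={"gamma": 1.0})


class TestTrainEval:
    def test_separated_gaussians_perfect_cv(self, rng):
        fm = gaussian_blobs(rng, n_per_class=100, sep=6.0)
        pooled, folds = train_eval(fm, ClassifierSpec("svm", seed=0),
                                   EvalScheme(mode="kfold_cv", folds=5, seed=0))
        assert overall_accuracy(pooled) == 100.0
        assert len(folds) == 5

    def test_count_conservation_cv_and_holdout(self, rng):
        fm = make_feature_matrix(rng, n=60, f=5)
        pooled, _ = train_eval(fm, ClassifierSpec("knn", seed=0),
                               EvalScheme(mode="kfold_cv", folds=3, seed=0))
        assert pooled.total == 60

    def test_holdout_counts_match_split_rule(self, rng):
        fm = make_feature_matrix(rng, n=100, f=4, n_classes=2)
        counts = {c: fm.labels.count(c) for c in fm.class_names}
        expected_test = sum(n - int(np.floor(0.8 * n + 0.5))
                            for n in counts.values())
        held, _ = train_eval(fm, ClassifierSpec("fine_tree", seed=0),
                             EvalScheme(mode="holdout", train_fraction=0.8, seed=0))
        assert held.total == expected_test

    def test_permuted_labels_at_chance(self):
        # 8 balanced classes, pure-noise features: pooled accuracy within
        # 3 standard errors of 12.5%
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 800
            labels = [f"c{i}" for i in rng.permutation(np.repeat(np.arange(8), n // 8))]
            fm = FeatureMatrix(rng.normal(size=(n, 10)),
                               [f"s{i}" for i in range(n)], labels,
                               [f"f{j}" for j in range(10)])
            pooled, _ = train_eval(fm, ClassifierSpec("linear_discriminant"),
                                   EvalScheme(mode="kfold_cv", folds=5, seed=seed))
            accs.append(overall_accuracy(pooled))
        se = 100 * np.sqrt(0.125 * 0.875 / (800 * len(accs)))
        assert abs(np.mean(accs) - 12.5) < 3 * se + 1.0

    def test_determinism(self, rng):
        fm = make_feature_matrix(rng, n=60, f=6)
        run = lambda: train_eval(fm, ClassifierSpec("ensemble_bagged_trees", seed=7),
                                 EvalScheme(mode="kfold_cv", folds=4, seed=7))[0]
        np.testing.assert_array_equal(run().counts, run().counts)

    def test_column_permutation_leaves_scalefree_results(self, rng):
        fm = gaussian_blobs(rng, n_per_class=30, f=6, sep=3.0)
        perm = rng.permutation(6)
        permuted = FeatureMatrix(fm.values[:, perm], fm.sample_ids, fm.labels,
                                 [fm.feature_names[j] for j in perm])
        for kind in ("knn", "gaussian_naive_bayes", "linear_discriminant"):
            a, _ = train_eval(fm, ClassifierSpec(kind, seed=0),
                              EvalScheme(mode="kfold_cv", folds=3, seed=0))
            b, _ = train_eval(permuted, ClassifierSpec(kind, seed=0),
                              EvalScheme(mode="kfold_cv", folds=3, seed=0))
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_class_smaller_than_folds_fatal(self, rng):
        fm = make_feature_matrix(rng, n=12, f=3, n_classes=3)
        with pytest.raises(ValueError, match="fewer samples than folds"):
            train_eval(fm, ClassifierSpec("svm"),
                       EvalScheme(mode="kfold_cv", folds=10, seed=0))

    def test_fusion_never_below_worse_block(self, rng):
        # fused features at least as good as the worse single block
        # (mean over seeds), on partially-informative synthetic blocks
        diffs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = r.integers(0, 2, 80)
            a_vals = r.normal(size=(80, 5))
            a_vals[:, 0] += 1.5 * y
            b_vals = r.normal(size=(80, 5))
            b_vals[:, 1] += 0.5 * y
            ids = [f"s{i}" for i in range(80)]
            labels = [f"c{v}" for v in y]
            names = lambda p: [f"{p}{j}" for j in range(5)]
            a = FeatureMatrix(a_vals, ids, labels, names("a"))
            b = FeatureMatrix(b_vals, ids, labels, names("b"))
            accs = {}
            for name, fm in (("a", a), ("b", b), ("ab", fuse(a, b))):
                pooled, _ = train_eval(fm, ClassifierSpec("svm", seed=0),
                                       EvalScheme(mode="kfold_cv", folds=5, seed=0))
                accs[name] = overall_accuracy(pooled)
            diffs.append(accs["ab"] - min(accs["a"], accs["b"]))
        assert np.mean(diffs) >= 0.0
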