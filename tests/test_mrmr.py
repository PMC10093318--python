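"""mRMR selection: MI/F primitives, greedy rule, oracle equivalence."""

import numpy as np
import pytest
from scipy.stats import f_oneway
from sklearn.metrics import mutual_info_score

from urisedclass import (FeatureMatrix, MRMRSelector, discretize_equal_width,
                         f_statistic, mrmr_select, mutual_information)
from urisedclass.mrmr import CRITERIA
from .conftest import make_feature_matrix


def argmax_tie_lowest(scores):
    """Shared tie rule: scores within 1e-9 (relative) of the maximum are
    tied up to float summation order; the lowest index wins."""
    scores = np.asarray(scores, dtype=float)
    m = scores.max()
    if not np.isfinite(m):
        return int(np.argmax(scores))
    tol = 1e-9 * max(1.0, abs(m))
    return int(np.flatnonzero(scores >= m - tol)[0])


def brute_force_mrmr(X, y, k, criterion, bins=10):
    """Independent re-implementation: recompute every statistic from scratch
    at every step with plain loops (no caching, no incremental updates)."""
    n, F = X.shape
    if criterion in ("MID", "MIQ"):
        Xd = [discretize_equal_width(X[:, j], bins) for j in range(F)]
        rel = [mutual_information(Xd[j], y) for j in range(F)]
        pair = lambda a, b: mutual_information(Xd[a], Xd[b])
    else:
        rel = [f_statistic(X[:, j], y) for j in range(F)]
        pair = lambda a, b: abs(np.corrcoef(X[:, a], X[:, b])[0, 1])
    selected = [argmax_tie_lowest(rel)]
    while len(selected) < k:
        scores = np.full(F, -np.inf)
        for j in range(F):
            if j in selected:
                continue
            red = np.mean([pair(j, s) for s in selected])
            if criterion in ("MID", "FCD"):
                scores[j] = rel[j] - red
            else:
                scores[j] = rel[j] / max(red, 1e-12)
        selected.append(argmax_tie_lowest(scores))
    return selected


class TestDiscretize:
    def test_midpoint_goes_to_upper_bin(self):
        np.testing.assert_array_equal(
            discretize_equal_width([0.0, 0.5, 1.0], 2), [0, 1, 1])

    def test_constant_vector_all_zeros(self):
        np.testing.assert_array_equal(
            discretize_equal_width([3.3] * 5, 7), [0] * 5)

    def test_uniform_grid_balanced(self):
        codes = discretize_equal_width(np.linspace(0, 1, 10), 5)
        assert all((codes == b).sum() == 2 for b in range(5))

    def test_non_finite_fatal(self):
        with pytest.raises(ValueError):
            discretize_equal_width([0.0, np.nan], 4)


class TestMutualInformation:
    def test_identity_uniform_four_symbols(self):
        x = np.repeat(np.arange(4), 5)
        assert mutual_information(x, x) == pytest.approx(2.0)

    def test_constant_gives_zero(self, rng):
        y = rng.integers(0, 3, 30)
        assert mutual_information(np.zeros(30), y) == pytest.approx(0.0)

    def test_brute_force_2x2_table(self):
        # joint counts ((2,1),(1,2)) over 6 samples
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        expected = 0.0
        for a, b, cnt in [(0, 0, 2), (0, 1, 1), (1, 0, 1), (1, 1, 2)]:
            p = cnt / 6
            expected += p * np.log2(p / (0.5 * 0.5))
        assert mutual_information(x, y) == pytest.approx(expected)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, 50)
            y = rng.integers(0, 3, 50)
            mi = mutual_information(x, y)
            assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
            assert mi >= -1e-12

    def test_agrees_with_sklearn(self, rng):
        x = rng.integers(0, 5, 200)
        y = rng.integers(0, 3, 200)
        assert mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y) / np.log(2))

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 2])


class TestFStatistic:
    def test_no_between_class_signal(self, rng):
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(0, 1, 500)])
        y = np.repeat([0, 1], 500)
        assert f_statistic(x, y) < 4.0  # ~F(1, 998) under the null

    def test_zero_within_variance_sentinel(self):
        assert f_statistic([0.0, 0.0, 1.0, 1.0], [0, 0, 1, 1]) == np.inf

    def test_two_group_textbook_example(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert f_statistic(x, y) == pytest.approx(13.5)

    def test_agrees_with_scipy(self, rng):
        x = rng.normal(size=60)
        y = rng.integers(0, 3, 60)
        expected = f_oneway(*(x[y == c] for c in range(3))).statistic
        assert f_statistic(x, y) == pytest.approx(expected)


class TestGreedySelection:
    @pytest.mark.parametrize("criterion", CRITERIA)
    def test_first_pick_is_argmax_relevance(self, rng, criterion):
        fm = make_feature_matrix(rng, n=60, f=10, informative=(4,))
        res = mrmr_select(fm, 1, criterion)
        assert res.selected == [int(np.argmax(res.relevance))]

    def test_label_copy_selected_first(self, rng):
        fm = make_feature_matrix(rng, n=200, f=21, informative=(5,))
        res = mrmr_select(fm, 3, "MID")
        assert res.selected[0] == 5

    @pytest.mark.parametrize("criterion", CRITERIA)
    def test_matches_brute_force_oracle(self, rng, criterion):
        # <=12-feature instances, full selection order
        for trial in range(3):
            fm = make_feature_matrix(rng, n=80, f=12, n_classes=3,
                                     informative=(2, 7))
            res = mrmr_select(fm, 12, criterion)
            expected = brute_force_mrmr(fm.values, fm.encoded_labels(),
                                        12, criterion)
            assert res.selected == expected

    def test_greedy_prefix_property(self, rng):
        fm = make_feature_matrix(rng, n=100, f=15, informative=(3,))
        full = mrmr_select(fm, 10, "MID").selected
        for j in (1, 4, 7):
            assert mrmr_select(fm, j, "MID").selected == full[:j]

    def test_determinism(self, rng):
        fm = make_feature_matrix(rng, n=50, f=20)
        a = mrmr_select(fm, 8, "MIQ")
        b = mrmr_select(fm, 8, "MIQ")
        assert a.selected == b.selected
        np.testing.assert_array_equal(a.relevance, b.relevance)

    def test_result_contract(self, rng):
        fm = make_feature_matrix(rng, n=50, f=20, informative=(0,))
        res = mrmr_select(fm, 6, "FCQ")
        assert len(res.selected) == 6
        assert len(set(res.selected)) == 6
        assert len(res.redundancy_trace) == 6
        assert res.redundancy_trace[0] == 0.0
        assert res.bins is None  # F-criteria do not discretize

    def test_planted_features_recovered(self):
        # 5 informative among 100 noise, d=2, n=300: all 5 in the MID top 10
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, 300)
            X = rng.normal(size=(300, 105))
            X[:, :5] += 2.0 * y[:, None]
            fm = FeatureMatrix(X, [f"s{i}" for i in range(300)],
                               [str(v) for v in y],
                               [f"f{j}" for j in range(105)])
            top10 = set(mrmr_select(fm, 10, "MID").selected)
            hits += set(range(5)) <= top10
        assert hits >= 4

    def test_invalid_inputs_fatal(self, rng):
        fm = make_feature_matrix(rng, n=30, f=5)
        with pytest.raises(ValueError):
            mrmr_select(fm, 6, "MID")  # k > n_features
        with pytest.raises(ValueError):
            mrmr_select(fm, 2, "XYZ")
        single = FeatureMatrix(rng.normal(size=(10, 3)),
                               [f"s{i}" for i in range(10)],
                               ["only"] * 10, ["a", "b", "c"])
        with pytest.raises(ValueError, match="2 classes"):
            mrmr_select(single, 2, "MID")


class TestSelectorEstimator:
    def test_sklearn_contract(self, rng):
        X = rng.normal(size=(60, 12))
        y = rng.integers(0, 2, 60)
        X[:, 3] = y
        sel = MRMRSelector(k=4).fit(X, y)
        assert sel.transform(X).shape == (60, 4)
        assert sel.selected_[0] == 3
        assert sel.get_support().sum() == 4

    def test_composes_in_pipeline(self, rng):
        from sklearn.pipeline import Pipeline
        from sklearn.svm import SVC
        X = rng.normal(size=(80, 10))
        y = rng.integers(0, 2, 80)
        X[:, 2] += 3 * y
        pipe = Pipeline([("sel", MRMRSelector(k=3)), ("svm", SVC())])
        assert pipe.fit(X, y).score(X, y) > 0.9
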