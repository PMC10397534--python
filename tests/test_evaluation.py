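"""Split hygiene, metric oracles, grid search and model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import average_precision_score

from combosyn import evaluation as ev
from combosyn.datasets import SynergySample


def toy_samples(cells):
    return [SynergySample("a", "b", c, 0.0, 0) for c in cells]


class TestKFold:
    def test_five_folds_partition_ten_samples(self):
        plan = ev.make_kfold(10, k=5, seed=0)
        tests = [set(te) for _, te in plan]
        assert all(len(t) == 2 for t in tests)
        assert set().union(*tests) == set(range(10))
        for i, t in enumerate(tests):
            for j, u in enumerate(tests):
                if i != j:
                    assert not (t & u)

    def test_remainder_distribution(self):
        plan = ev.make_kfold(11, k=5, seed=0)
        sizes = sorted(len(te) for _, te in plan)
        assert sizes == [2, 2, 2, 2, 3]

    def test_reproducible_under_seed(self):
        p1 = ev.make_kfold(50, k=5, seed=3)
        p2 = ev.make_kfold(50, k=5, seed=3)
        for (a, b), (c, d) in zip(p1, p2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            ev.make_kfold(3, k=5)

    @given(n=st.integers(10, 300), k=st.integers(2, 10), seed=st.integers(0, 99))
    @settings(max_examples=100, deadline=None)
    def test_split_hygiene_randomised(self, n, k, seed):
        if k > n:
            return
        plan = ev.make_kfold(n, k=k, seed=seed)
        all_test = []
        sizes = []
        for tr, te in plan:
            assert not (set(tr) & set(te))
            assert len(tr) + len(te) == n
            all_test.extend(te)
            sizes.append(len(te))
        assert sorted(all_test) == list(range(n))
        assert max(sizes) - min(sizes) <= 1


class TestLoco:
    def test_one_fold_per_cell_with_exact_membership(self):
        samples = toy_samples(["A"] * 3 + ["B"] * 2)
        plan = ev.make_loco(samples)
        assert len(plan) == 2
        sizes = sorted(len(te) for _, te in plan)
        assert sizes == [2, 3]
        for (tr, te), cell in zip(plan, plan.fold_names):
            assert all(samples[i].cell_id == cell for i in te)
            assert all(samples[i].cell_id != cell for i in tr)

    def test_union_of_test_sets_covers_everything(self):
        rng = np.random.default_rng(0)
        samples = toy_samples(rng.choice(list("ABCD"), size=40))
        plan = ev.make_loco(samples)
        covered = sorted(np.concatenate([te for _, te in plan]).tolist())
        assert covered == list(range(40))

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            ev.make_loco(toy_samples(["A", "A"]))


class TestMetrics:
    def test_hand_confusion_arithmetic(self):
        # TP=3, FP=1, FN=1, TN=5
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.1, 0.2, 0.3])
        rep = ev.evaluate_predictions(labels, scores)
        assert rep.acc == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(0.75)

    def test_perfect_ranking_gives_unit_aucs(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        rep = ev.evaluate_predictions(labels, scores)
        assert rep.auc_roc == pytest.approx(1.0)
        assert rep.auc_pr == pytest.approx(1.0)

    def test_constant_scorer_gives_half_auc(self):
        labels = np.array([0, 1, 0, 1, 1])
        rep = ev.evaluate_predictions(labels, np.full(5, 0.6))
        assert rep.auc_roc == pytest.approx(0.5)

    def test_single_class_aucs_missing_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            rep = ev.evaluate_predictions(np.ones(4), np.random.rand(4))
        assert rep.auc_roc is None and rep.auc_pr is None

    @given(seed=st.integers(0, 200))
    @settings(max_examples=40, deadline=None)
    def test_auc_roc_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.uniform(size=n), 2)  # coarse grid forces ties
        rep = ev.evaluate_predictions(labels, scores)
        brute = ev.auc_roc_brute_force(labels, scores)
        assert rep.auc_roc == pytest.approx(brute, abs=1e-9)

    def test_auc_pr_step_matches_average_precision(self, rng):
        labels = rng.integers(0, 2, size=100)
        scores = rng.uniform(size=100)
        assert ev.auc_pr_step(labels, scores) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )


class TestCompareModels:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = ev.compare_models([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
        assert (t, p) == (0.0, 1.0)

    def test_constant_improvement_with_jitter_significant(self):
        a = np.array([0.81, 0.79, 0.80, 0.82, 0.78])
        b = a - 0.1 + np.array([1e-3, -1e-3, 2e-3, -2e-3, 0.0])
        t, p = ev.compare_models(a, b)
        # closed-form paired t on the differences
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p < 0.05

    def test_swapping_negates_t_preserves_p(self, rng):
        a = rng.uniform(size=5)
        b = rng.uniform(size=5)
        t1, p1 = ev.compare_models(a, b)
        t2, p2 = ev.compare_models(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_reference(self, rng):
        a = rng.uniform(size=6)
        b = rng.uniform(size=6)
        t, p = ev.compare_models(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert (t, p) == (pytest.approx(t_ref), pytest.approx(p_ref))


class TestGridSearch:
    def test_two_point_grid_two_rows_and_argmax(self):
        grid = ev.GridSpec(patch_size=(20, 40))
        best, table = ev.grid_search(
            lambda pt: 1.0 if pt["patch_size"] == 40 else 0.5,
            grid, ["patch_size"],
        )
        assert len(table) == 2
        assert best == {"patch_size": 40}
        assert max(r["criterion"] for r in table) == 1.0

    def test_patch_by_overlap_sweep_has_table_shape(self):
        grid = ev.GridSpec()
        pts = grid.points(["patch_size", "overlap_ratio"])
        assert len(pts) == 20  # 5 x 4 printed grid
        assert {p["patch_size"] for p in pts} == {20, 30, 40, 50, 60}
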