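"""Evaluation harness tests: metric oracles, statistics, calibration."""

import itertools
import math

import numpy as np
import pytest

from vadistill.errors import InvalidArgumentError
from vadistill.evaluate import (
    auc_score,
    bootstrap_median_ci,
    compare_methods,
    f1_score,
    mann_whitney_u,
    playback_report,
)


class TestF1:
    def test_perfect(self):
        assert f1_score([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_closed_form(self):
        # TP=8, FP=2, FN=2 -> F1 = 2*8 / (2*8 + 2 + 2) = 0.8
        labels = [1] * 10 + [0] * 10
        preds = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        assert f1_score(labels, preds) == pytest.approx(0.8)

    def test_degenerate_all_negative(self):
        assert f1_score([1, 1, 0], [0, 0, 0]) == 0.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 50)
        preds = rng.integers(0, 2, 50)
        perm = rng.permutation(50)
        assert f1_score(labels, preds) == f1_score(labels[perm], preds[perm])

    def test_matches_sklearn(self):
        from sklearn.metrics import f1_score as sk_f1

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 100)
        preds = rng.integers(0, 2, 100)
        assert f1_score(labels, preds) == pytest.approx(sk_f1(labels, preds))


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_half(self):
        assert auc_score([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_enumeration_oracle(self):
        # pairs: (0.4 vs 0.1) win, (0.4 vs 0.8) loss, (0.9 vs 0.1) win, (0.9 vs 0.8) win
        assert auc_score([0, 0, 1, 1], [0.1, 0.8, 0.4, 0.9]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            auc_score([1, 1], [0.1, 0.2])

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 200)
        scores = rng.random(200)
        assert auc_score(labels, scores) == pytest.approx(roc_auc_score(labels, scores))

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 60)
        scores = rng.random(60)
        perm = rng.permutation(60)
        assert auc_score(labels, scores) == pytest.approx(auc_score(labels[perm], scores[perm]))

    def test_equals_normalized_u_statistic(self):
        # cross-check between the two operations on tie-free data
        rng = np.random.default_rng(4)
        labels = np.array([1] * 12 + [0] * 15)
        scores = rng.permutation(np.linspace(0, 1, 27))
        u, _ = mann_whitney_u(scores[labels == 1], scores[labels == 0])
        assert auc_score(labels, scores) == pytest.approx(u / (12 * 15))


class TestBootstrap:
    def test_constant_collapses_to_point(self):
        lo, hi = bootstrap_median_ci([3.3] * 10, seed=0)
        assert lo == hi == 3.3

    def test_contains_sample_median(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            vals = rng.normal(size=15)
            lo, hi = bootstrap_median_ci(vals, seed=trial)
            assert lo <= np.median(vals) <= hi

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bootstrap_median_ci([])

    def test_coverage_monte_carlo(self):
        # ~95% of intervals should cover the true median (0.5) of U(0,1), n=20
        rng = np.random.default_rng(6)
        hits = 0
        n_sim = 500
        for i in range(n_sim):
            vals = rng.random(20)
            lo, hi = bootstrap_median_ci(vals, n_boot=1000, seed=i)
            hits += lo <= 0.5 <= hi
        assert 0.92 <= hits / n_sim <= 0.98


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_extreme_exact_case(self):
        # enumeration over C(6,3) = 20 labelings: only the two extreme
        # labelings are as extreme as U = 0 -> p = 2/20 = 0.1
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_enumeration_oracle_matches_direct_count(self):
        a, b = np.array([1.0, 5.0, 7.0]), np.array([2.0, 4.0, 9.0, 11.0])
        u_a, p = mann_whitney_u(a, b)
        # independent oracle: enumerate all C(7,3) subsets
        pooled = np.concatenate([a, b])
        n_a = 3
        mu = n_a * (pooled.size - n_a) / 2
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        count = total = 0
        for combo in itertools.combinations(range(pooled.size), n_a):
            u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2
            count += abs(u - mu) >= abs(u_a - mu) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_swap_symmetry_and_u_identity(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=6), rng.normal(size=5)
        u_a, p_ab = mann_whitney_u(a, b)
        u_b, p_ba = mann_whitney_u(b, a)
        assert p_ab == pytest.approx(p_ba)
        assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_matches_scipy_large_samples(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        a, b = rng.normal(size=15), rng.normal(0.5, 1, size=12)
        u, p = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mann_whitney_u([], [1.0])

    def test_null_calibration(self):
        # type-I error rate at alpha = 0.05 under a simulated null, n=10 each
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a, b = rng.normal(size=10), rng.normal(size=10)
            _, p = mann_whitney_u(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class FixedScoreModel:
    """Deterministic stand-in classifier for report tests."""

    def __init__(self, score_fn):
        self.score_fn = score_fn

    def eval(self):
        return self

    def __call__(self, x):
        from vadistill.nn.tensor import Tensor

        return Tensor(np.array([self.score_fn(g) for g in x.data], dtype=np.float64))


@pytest.fixture(scope="module")
def playback(small_pools, tmp_path_factory):
    from vadistill.dataset_builder import build_playback_set

    out = tmp_path_factory.mktemp("pb")
    return build_playback_set(small_pools, n_per_cell=1, seed=2, outdir=out)


class TestPlaybackReport:
    def test_perfect_classifier_f1_one(self, playback):
        labels = {r.path: r.label for r in playback}
        paths = [r.path for r in playback]
        it = iter(paths)

        # grids are loaded per distance group in record order; recover labels
        # by path order via a loader shim
        class Oracle(FixedScoreModel):
            def __init__(self):
                self.i = 0

        def loader(path):
            # encode the label in the grid mean so the "model" can read it
            g = np.full((1, 128, 128), float(labels[path]), dtype=np.float32)
            return g

        model = FixedScoreModel(lambda g: 20.0 if g.mean() > 0.5 else -20.0)
        report = playback_report(model, playback, data_loader=loader)
        assert all(f == 1.0 for f in report.per_distance_f1.values())
        assert report.overall_f1 == 1.0

    def test_schema_four_distances_plus_overall(self, playback):
        model = FixedScoreModel(lambda g: 1.0)
        report = playback_report(model, playback, data_loader=lambda p: np.zeros((1, 128, 128), np.float32))
        frame = report.to_frame()
        assert len(frame) == 5
        assert set(report.per_distance_f1) == {1.0, 5.0, 10.0, 20.0}

    def test_score_decay_with_distance_non_increasing_f1(self, small_pools, tmp_path):
        from vadistill.dataset_builder import build_playback_set

        records = build_playback_set(small_pools, n_per_cell=4, seed=3, outdir=tmp_path / "pb")
        labels = {r.path: r.label for r in records}
        dists = {r.path: r.distance_m for r in records}
        rng = np.random.default_rng(0)

        def loader(path):
            g = np.zeros((1, 128, 128), dtype=np.float32)
            g[0, 0, 0] = labels[path]
            g[0, 0, 1] = dists[path]
            return g

        def score(g):
            label, dist = g[0, 0, 0], g[0, 0, 1]
            # label-correlated score minus distance-proportional noise
            noise = rng.normal(0, 0.02 * dist)
            return 8.0 * (label - 0.5) - 0.35 * dist * label + noise

        report = playback_report(FixedScoreModel(score), records, data_loader=loader)
        f1s = [report.per_distance_f1[d] for d in (1.0, 5.0, 10.0, 20.0)]
        assert all(a >= b for a, b in zip(f1s, f1s[1:]))

    def test_missing_stratum_rejected(self, playback):
        subset = [r for r in playback if r.distance_m != 10.0]
        with pytest.raises(InvalidArgumentError):
            playback_report(FixedScoreModel(lambda g: 1.0), subset,
                            data_loader=lambda p: np.zeros((1, 128, 128), np.float32))


class TestCompareMethods:
    def test_identical_score_lists_p_one(self):
        runs = {"auc": {"a": [0.9, 0.92, 0.91], "b": [0.9, 0.92, 0.91]}}
        report = compare_methods(runs, seed=0)
        assert report.pvalues["auc"][("a", "b")] == pytest.approx(1.0)

    def test_three_methods_three_pairs(self):
        runs = {"auc": {m: [0.9 + i * 0.01, 0.91] for i, m in enumerate("abc")}}
        report = compare_methods(runs, seed=0)
        assert len(report.pvalues["auc"]) == 3

    def test_medians_match_oracle(self):
        rng = np.random.default_rng(10)
        runs = {"f1": {m: list(rng.random(5)) for m in ("soft", "feat", "rel")}}
        report = compare_methods(runs, seed=0)
        for m, vals in runs["f1"].items():
            assert report.medians["f1"][m] == pytest.approx(float(np.median(vals)))

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(11)
        runs = {"auc": {"a": list(rng.random(8)), "b": list(rng.random(8))}}
        report = compare_methods(runs, seed=0)
        for m in ("a", "b"):
            lo, hi = report.cis["auc"][m]
            assert lo <= report.medians["auc"][m] <= hi

    def test_single_run_rejected(self):
        with pytest.raises(InvalidArgumentError):
            compare_methods({"auc": {"a": [0.9], "b": [0.8, 0.9]}})
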