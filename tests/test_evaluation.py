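"""Tests for AUC, bootstrap intervals, model selection, feature selection,
and the Kruskal-Wallis comparison — each against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hncnet.errors import ConfigurationError
from hncnet.evaluation import (
    SelectionCriterion,
    UndefinedMetricError,
    bootstrap_ci,
    forward_feature_selection,
    kruskal_wallis,
    roc_auc,
    run_cv,
    select_model,
)


def pair_counting_auc(labels, scores):
    """Exhaustive Mann-Whitney oracle: all (pos, neg) pairs, ties count 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_documented_example(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.7, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_pair_counting_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # coarse grid provokes ties
            assert roc_auc(labels, scores) == pytest.approx(
                pair_counting_auc(labels, scores), abs=1e-12)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        scores = rng.permutation(np.linspace(0, 1, 30))
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_invariance_under_increasing_transform(self, a, b):
        rng = np.random.default_rng(2)
        labels = np.array([0, 1] * 10)
        scores = rng.random(20)
        assert roc_auc(labels, a * scores + b) == pytest.approx(roc_auc(labels, scores))


class TestBootstrapCI:
    def test_perfect_separation_degenerate_interval(self):
        labels = np.array([0] * 10 + [1] * 10)
        scores = np.concatenate([np.linspace(0, 0.4, 10), np.linspace(0.6, 1, 10)])
        assert bootstrap_ci(labels, scores, seed=0) == (1.0, 1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        assert bootstrap_ci(labels, scores, seed=9) == bootstrap_ci(labels, scores, seed=9)

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        labels = np.array([0, 1] * 40)
        scores = rng.random(80) + 0.3 * labels
        lo, hi = bootstrap_ci(labels, scores, seed=0)
        assert lo <= roc_auc(labels, scores) <= hi

    def test_width_shrinks_with_sample_size(self):
        mu = np.sqrt(2) * stats.norm.ppf(0.8)
        widths = []
        for n in (50, 200, 800):
            w = []
            for rep in range(8):
                rng = np.random.default_rng(100 * n + rep)
                scores = np.concatenate([rng.standard_normal(n // 2),
                                         rng.standard_normal(n // 2) + mu])
                labels = np.array([0] * (n // 2) + [1] * (n // 2))
                lo, hi = bootstrap_ci(labels, scores, n_resamples=400, seed=rep)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]


def brute_force_select(trace, initial, step):
    """Enumeration oracle for the gap-constrained criterion."""
    gaps = [tr - va for tr, va in trace]
    threshold = initial
    while True:
        eligible = [i for i, g in enumerate(gaps) if g <= threshold + 1e-9]
        if eligible:
            best = max(eligible, key=lambda i: (trace[i][1], -i))
            return best + 1, threshold
        threshold += step


class TestSelectModel:
    def test_documented_example(self):
        logs = [(0.90, 0.70), (0.85, 0.82), (0.80, 0.79)]
        epoch, threshold = select_model(logs)
        assert epoch == 2 and threshold == pytest.approx(0.05)

    def test_escalation_example(self):
        logs = [(0.95, 0.80), (0.99, 0.85)]
        epoch, threshold = select_model(logs)
        assert epoch == 2 and threshold == pytest.approx(0.14)

    def test_single_epoch_negative_gap(self):
        epoch, threshold = select_model([(0.6, 0.7)])
        assert epoch == 1 and threshold == pytest.approx(0.05)

    def test_empty_logs_rejected(self):
        with pytest.raises(ConfigurationError):
            select_model([])

    def test_matches_enumeration_oracle_on_random_traces(self):
        rng = np.random.default_rng(5)
        crit = SelectionCriterion()
        for _ in range(500):
            n = int(rng.integers(1, 40))
            trace = [(round(float(rng.uniform(0.4, 1.0)), 3),
                      round(float(rng.uniform(0.3, 1.0)), 3)) for _ in range(n)]
            assert select_model(trace, crit) == pytest.approx(
                brute_force_select(trace, 0.05, 0.01))

    def test_chosen_gap_never_exceeds_final_threshold(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            trace = [(float(rng.uniform(0.4, 1)), float(rng.uniform(0.3, 1)))
                     for _ in range(n)]
            epoch, threshold = select_model(trace)
            tr, va = trace[epoch - 1]
            assert tr - va <= threshold + 1e-9
            assert threshold >= 0.05 - 1e-12

    def test_higher_threshold_never_decreases_selected_val_auc(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            trace = [(float(rng.uniform(0.4, 1)), float(rng.uniform(0.3, 1)))
                     for _ in range(15)]
            chosen = []
            for thr in (0.02, 0.05, 0.2, 1.0):
                e, _ = select_model(trace, SelectionCriterion(initial_gap_threshold=thr))
                chosen.append(trace[e - 1][1])
            assert all(b >= a - 1e-12 for a, b in zip(chosen, chosen[1:]))

    def test_best_val_auc_mode(self):
        logs = [(0.9, 0.70), (0.95, 0.88), (0.99, 0.80)]
        crit = SelectionCriterion(mode="best_val_auc")
        assert select_model(logs, crit)[0] == 2

    def test_lowest_val_loss_mode(self):
        logs = [(0.9, 0.7, 0.6), (0.95, 0.8, 0.4), (0.99, 0.75, 0.5)]
        crit = SelectionCriterion(mode="lowest_val_loss")
        assert select_model(logs, crit)[0] == 2


class TestForwardFeatureSelection:
    def test_single_improving_candidate(self):
        selected = forward_feature_selection(["a"], lambda s: 0.7 if s else 0.5)
        assert selected == ["a"]

    def test_pure_noise_gives_empty_subset(self):
        assert forward_feature_selection(["a", "b", "c"], lambda s: 0.5) == []

    def test_additive_gains_recovered_in_order(self):
        gains = {"A": 0.05, "B": 0.02, "C": 0.0}

        def eval_fn(subset):
            return 0.6 + sum(gains[f] for f in subset)

        assert forward_feature_selection(["C", "B", "A"], eval_fn) == ["A", "B"]

    def test_tie_breaks_to_declared_order(self):
        def eval_fn(subset):
            return 0.6 + 0.1 * len(subset)  # every candidate equally good

        selected = forward_feature_selection(["x", "y"], eval_fn)
        assert selected[0] == "x"


class TestKruskalWallis:
    def test_hand_computed_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        # ranks 1..9: rank sums 6/15/24 -> H = 12/(9*10) * sum(R^2/3) - 3*10 = 7.2
        assert h == pytest.approx(7.2)
        assert 0 < p < 0.05

    def test_identical_groups(self):
        h, p = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert h == 0.0 and p == 1.0

    def test_two_groups_match_rank_sum_statistic(self):
        rng = np.random.default_rng(8)
        a = rng.random(12)
        b = rng.random(15) + 0.3
        h, _ = kruskal_wallis([a, b])
        # rank-sum oracle: H equals the squared standardized rank sum
        n1, n2 = len(a), len(b)
        n = n1 + n2
        ranks = stats.rankdata(np.concatenate([a, b]))
        r1 = ranks[:n1].sum()
        z = (r1 - n1 * (n + 1) / 2) / np.sqrt(n1 * n2 * (n + 1) / 12.0)
        assert h == pytest.approx(z**2, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            kruskal_wallis([[1, 2]])
        with pytest.raises(ConfigurationError):
            kruskal_wallis([[1], []])


class TestRunCV:
    def _features(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, 5)).astype(np.float32)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x[:, 0]))).astype(int)
        return x, y

    def test_structure_and_determinism(self):
        from hncnet.models import build_ann
        from hncnet.training import TrainConfig

        x, y = self._features(80)
        xt, yt = self._features(40, seed=1)
        cfg = TrainConfig(max_epochs=5, batch_size=16, seed=0, augmentation=False)
        kwargs = dict(k=5, build_fn=lambda seed: build_ann(5, seed=seed),
                      train_cfg=cfg, seed=3)
        rep1 = run_cv(x, y, xt, yt, **kwargs)
        rep2 = run_cv(x, y, xt, yt, **kwargs)
        assert len(rep1.fold_auc["test"]) == 5
        assert len(rep1.selection) == 5
        assert rep1.to_json() == rep2.to_json()
        lo, hi = rep1.fold_range["test"]
        assert lo <= rep1.fold_mean["test"] <= hi
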