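"""Confusion metrics, ROC/AUC, and the cross-validation schemes."""

import numpy as np
import pytest

from gpspbs.data_model import BenchmarkDataset
from gpspbs.evaluation import (
    ConfusionCounts,
    confusion_metrics,
    cross_validate,
    roc_auc,
    select_scheme,
    stratified_folds,
)
from gpspbs.synthetic import MotifSpec, generate_benchmark


def mann_whitney_auc(scores, labels):
    """Brute-force pair counting with half credit for ties: the AUC oracle."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(5, 0, 5, 0))
        assert m["ac"] == m["sn"] == m["sp"] == m["mcc"] == 1.0

    def test_hand_computed_example(self):
        m = confusion_metrics(ConfusionCounts(tp=8, fp=10, tn=90, fn=2))
        assert m["sn"] == pytest.approx(0.8)
        assert m["sp"] == pytest.approx(0.9)
        assert m["ac"] == pytest.approx(98 / 110)
        # (8*90 - 2*10) / sqrt(10 * 100 * 18 * 92)
        assert m["mcc"] == pytest.approx(700 / np.sqrt(1_656_000))
        assert m["ppv"] == pytest.approx(8 / 18)
        assert m["npv"] == pytest.approx(90 / 92)

    def test_undefined_metric_flagged_not_thrown(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m["ppv"] is None
        assert m["sp"] == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)

    def test_mcc_invariant_under_class_swap(self):
        a = confusion_metrics(ConfusionCounts(7, 3, 50, 6))["mcc"]
        b = confusion_metrics(ConfusionCounts(50, 6, 7, 3))["mcc"]
        assert a == pytest.approx(b)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, points = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert points[0].tolist() == [0.0, 0.0]
        assert points[-1].tolist() == [1.0, 1.0]

    def test_chance_level_on_identical_distributions(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = np.r_[np.ones(2000, int), np.zeros(2000, int)]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_ties_match_pair_counting_oracle(self):
        scores = [0.9, 0.5, 0.5, 0.5, 0.3, 0.1]
        labels = [1, 1, 0, 1, 0, 0]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels))

    def test_trapezoid_equals_mann_whitney_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            scores = np.round(rng.normal(size=40), 1)  # induce ties
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels),
                                        abs=1e-12)

    def test_roc_point_count(self):
        scores = [0.9, 0.5, 0.5, 0.3, 0.1, 0.1]
        labels = [1, 1, 0, 1, 0, 0]
        _, points = roc_auc(scores, labels)
        assert len(points) == len(set(scores)) + 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestSchemes:
    def test_loo_forced_below_thirty_positives(self):
        assert select_scheme(12, "auto") == "loo"
        assert select_scheme(30, "auto") == "10-fold"

    def test_invalid_fold_counts(self):
        with pytest.raises(ValueError):
            select_scheme(100, 5)
        with pytest.raises(ValueError):
            select_scheme(8, 10)

    def test_stratified_partition(self):
        labels = np.r_[np.ones(200, int), np.zeros(400, int)]
        folds = stratified_folds(labels, 10, seed=1)
        # every positive appears in exactly one test fold
        assert np.bincount(folds[:200]).sum() == 200
        for f in range(10):
            assert np.sum(folds[:200] == f) == 20


@pytest.fixture(scope="module")
def benchmark():
    spec = MotifSpec("cv", "S", {-3: ("R", 0.95), +2: ("P", 0.9)})
    return generate_benchmark(spec, 40, 4.0, m=5, n=5, seed=2)


class TestCrossValidate:
    @staticmethod
    def score_trainer(train_benchmark):
        """A cheap reference pipeline: unweighted group similarity score,
        squashed to [0, 1]."""
        from gpspbs.scoring import (PositionWeights, PositiveProfile,
                                    SubstitutionMatrix)
        from gpspbs.alphabet import encode_peptides

        matrix = SubstitutionMatrix.blosum62()
        profile = PositiveProfile(train_benchmark.positives)
        k = profile.k

        def scorer(items):
            codes = encode_peptides([it.peptide for it in items])
            s = profile.per_position_scores(codes, matrix).sum(axis=1)
            return 1.0 / (1.0 + np.exp(-s / k))

        return scorer

    def test_kfold_partitions_and_reports(self, benchmark):
        report = cross_validate(benchmark, self.score_trainer, k=4, seed=0)
        assert report.scheme == "4-fold"
        assert 0.8 <= report.auc <= 1.0
        assert len(report.scores) == len(benchmark.items)

    def test_auto_selects_loo_for_small_nodes(self):
        spec = MotifSpec("small", "S", {-3: ("R", 1.0)})
        bench = generate_benchmark(spec, 12, 3.0, m=4, n=4, seed=3)
        report = cross_validate(bench, self.score_trainer, k="auto", seed=0)
        assert report.scheme == "loo"
        assert report.auc > 0.8

    def test_fold_choice_barely_matters_on_separable_data(self, benchmark):
        aucs = [cross_validate(benchmark, self.score_trainer, k=k, seed=0).auc
                for k in (4, 10)]
        assert min(aucs) >= 0.85
        assert abs(aucs[0] - aucs[1]) < 0.05
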