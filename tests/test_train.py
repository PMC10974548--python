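import numpy as np
import pytest

from efnet.model import reduced_config, build_efnet
from efnet.splits import semidependent_split
from efnet.train import (
    MetricsReport,
    TrainingConfig,
    aggregate_reports,
    compute_metrics,
    evaluate,
    train_model,
)


def brute_force_metrics(y, scores, thr=0.5):
    """Independent oracle: explicit confusion counts and pairwise-rank AUROC."""
    y = np.asarray(y)
    scores = np.asarray(scores)
    pred = (scores >= thr).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / y.size
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        auroc = None
    else:
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        auroc = wins / (len(pos) * len(neg))
    return acc, prec, rec, f1, auroc


class TestMetrics:
    def test_hand_computed_confusion_example(self):
        # labels [1,1,0,0], predicted classes [1,0,0,0]
        rep = compute_metrics([1, 1, 0, 0], [0.9, 0.1, 0.2, 0.3])
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision == pytest.approx(1.0)
        assert rep.recall == pytest.approx(0.5)
        assert rep.f1 == pytest.approx(2 / 3, abs=1e-9)

    def test_perfect_scores(self):
        rep = compute_metrics([1, 0, 1], [0.99, 0.01, 0.98])
        for name in ("accuracy", "precision", "recall", "f1", "auroc"):
            assert getattr(rep, name) == pytest.approx(1.0)

    def test_single_class_auroc_missing(self):
        rep = compute_metrics([1, 1, 1], [0.9, 0.8, 0.7])
        assert rep.auroc is None
        assert rep.accuracy == pytest.approx(1.0)

    def test_agreement_with_brute_force_oracle(self):
        rng = np.random.default_rng(12345)
        for _ in range(300):
            n = rng.integers(2, 50)
            y = rng.integers(0, 2, size=n)
            scores = np.round(rng.random(n), 2)  # rounding forces score ties
            rep = compute_metrics(y, scores)
            acc, prec, rec, f1, auroc = brute_force_metrics(y, scores)
            assert rep.accuracy == pytest.approx(acc)
            assert rep.precision == pytest.approx(prec)
            assert rep.recall == pytest.approx(rec)
            assert rep.f1 == pytest.approx(f1)
            if auroc is None:
                assert rep.auroc is None
            else:
                assert rep.auroc == pytest.approx(auroc)

    def test_random_scores_near_chance_auroc(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=4000)
        rep = compute_metrics(y, rng.random(4000))
        assert 0.45 <= rep.auroc <= 0.55


class TestAggregation:
    def test_mean_and_population_std(self):
        reports = [
            MetricsReport(accuracy=a, precision=a, recall=a, f1=a, auroc=a, n_test=10)
            for a in (0.9, 0.8, 1.0)
        ]
        agg = aggregate_reports(reports)
        assert agg["accuracy"]["mean"] == pytest.approx(90.0)
        assert agg["accuracy"]["std"] == pytest.approx(
            float(np.std([90.0, 80.0, 100.0])))

    def test_missing_auroc_propagates(self):
        reports = [MetricsReport(0.5, 0.5, 0.5, 0.5, None, 5)]
        agg = aggregate_reports(reports)
        assert agg["auroc"]["mean"] is None


@pytest.fixture(scope="module")
def small_setup(tiny_bundle):
    return tiny_bundle, semidependent_split(tiny_bundle, seed=38)


class TestTrainingLoop:

    def test_same_seed_reproduces_history(self, small_setup):
        bundle, split = small_setup
        histories = []
        for _ in range(2):
            spec = build_efnet(reduced_config("fnirs"), init_seed=38)
            cfg = TrainingConfig(max_epochs=2, seed=38, learning_rate=3e-3)
            res = train_model(spec, bundle, split, cfg)
            histories.append(res.history)
        assert histories[0]["loss"] == histories[1]["loss"]
        assert histories[0]["test_accuracy"] == histories[1]["test_accuracy"]

    def test_loss_decreases(self, small_setup):
        bundle, split = small_setup
        spec = build_efnet(reduced_config("fnirs"), init_seed=1)
        cfg = TrainingConfig(max_epochs=4, seed=1, learning_rate=3e-3)
        res = train_model(spec, bundle, split, cfg)
        assert res.history["loss"][-1] < res.history["loss"][0]

    def test_faithful_rule_maximizes_test_accuracy_over_epochs(self, small_setup):
        bundle, split = small_setup
        spec = build_efnet(reduced_config("fnirs"), init_seed=2)
        cfg = TrainingConfig(max_epochs=4, seed=2, learning_rate=3e-3,
                             checkpoint_rule="best-test-accuracy")
        res = train_model(spec, bundle, split, cfg)
        best = max(res.history["test_accuracy"])
        assert res.history["test_accuracy"][res.best_epoch] == best
        rep = evaluate(spec, _normalized(bundle, res), split.test_idx)
        assert rep.accuracy == pytest.approx(best)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(batch_size=0).validate()
        with pytest.raises(ValueError):
            TrainingConfig(checkpoint_rule="best-train").validate()


def _normalized(bundle, result):
    from efnet.preprocess import apply_normalizer

    if result.normalizer_state is None:
        return bundle
    return apply_normalizer(result.normalizer_state, bundle)
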