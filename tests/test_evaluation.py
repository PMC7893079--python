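"""Metrics, folds, training loop contracts, and protocol audit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adspeech.evaluation import (
    TrainConfig,
    class_metrics,
    confusion_from_recalls,
    metrics_from_confusion,
    prediction_similarity,
    roc_auc,
    run_protocol,
    stratified_kfold,
    train_model,
)
from adspeech.models import ModelConfig, build_model


def brute_force_metrics(probs, labels, threshold=0.5):
    """Oracle: explicit loop over predictions, AD positive."""
    tp = fp = fn = tn = 0
    for p, y in zip(probs, labels):
        pred = 1 if p >= threshold else 0
        if pred == 1 and y == 1:
            tp += 1
        elif pred == 1 and y == 0:
            fp += 1
        elif pred == 0 and y == 1:
            fn += 1
        else:
            tn += 1
    def safe(num, den):
        return num / den if den else 0.0
    rec, prec = safe(tp, tp + fn), safe(tp, tp + fp)
    f1 = safe(2 * prec * rec, prec + rec)
    return tp, fp, fn, tn, rec, prec, f1


def pair_counting_auc(probs, labels):
    """Oracle: fraction of (positive, negative) pairs correctly ordered,
    ties counted half (the Mann-Whitney statistic)."""
    pos = [p for p, y in zip(probs, labels) if y == 1]
    neg = [p for p, y in zip(probs, labels) if y == 0]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestClassMetrics:
    def test_all_correct(self):
        r = class_metrics([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0])
        for cls in ("AD", "non-AD"):
            m = r.per_class[cls]
            assert m.recall == m.precision == m.f1 == 1.0
        assert r.accuracy == 1.0

    def test_zero_denominator_flagged(self):
        r = class_metrics([0.1, 0.2], [1, 1])    # no AD predictions: tp=fp=0
        m = r.per_class["AD"]
        assert m.precision == 0.0 and m.f1 == 0.0 and m.zero_denominator

    def test_tie_at_threshold_predicts_ad(self):
        r = class_metrics([0.5], [1])
        assert r.confusion.tp == 1

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 40))
            probs = rng.random(n)
            labels = rng.integers(0, 2, n)
            r = class_metrics(probs, labels, with_roc=False)
            tp, fp, fn, tn, rec, prec, f1 = brute_force_metrics(probs, labels)
            assert (r.confusion.tp, r.confusion.fp,
                    r.confusion.fn, r.confusion.tn) == (tp, fp, fn, tn)
            assert r.per_class["AD"].recall == pytest.approx(rec)
            assert r.per_class["AD"].precision == pytest.approx(prec)
            assert r.per_class["AD"].f1 == pytest.approx(f1)
            assert r.accuracy == pytest.approx((tp + tn) / n)

    def test_swap_convention(self, rng):
        """Non-AD row equals the AD row computed on inverted labels/scores."""
        probs = rng.random(30)
        labels = rng.integers(0, 2, 30)
        r = class_metrics(probs, labels, with_roc=False)
        flipped = class_metrics(1 - probs - 1e-9, 1 - labels, with_roc=False)
        assert r.per_class["non-AD"].recall == pytest.approx(
            flipped.per_class["AD"].recall)
        assert r.per_class["non-AD"].precision == pytest.approx(
            flipped.per_class["AD"].precision)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            class_metrics([0.5], ["MCI"])

    @given(st.lists(st.tuples(st.floats(0, 1), st.integers(0, 1)),
                    min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_accuracy_identity(self, pairs):
        probs = [p for p, _ in pairs]
        labels = [y for _, y in pairs]
        r = class_metrics(probs, labels, with_roc=False)
        c = r.confusion
        assert c.total == len(pairs)
        assert r.accuracy == pytest.approx((c.tp + c.tn) / c.total)


class TestConfusionFromRecalls:
    def test_reconstruction_arithmetic(self):
        c = confusion_from_recalls(0.9167, 0.5416, 24)
        assert (c.tp, c.tn, c.fn, c.fp) == (13, 22, 11, 2)
        assert c.accuracy == pytest.approx(35 / 48)

    def test_perfect_recalls(self):
        c = confusion_from_recalls(1.0, 1.0, 24)
        assert (c.tp, c.tn, c.fn, c.fp) == (24, 24, 0, 0)

    def test_derived_precision(self):
        r = metrics_from_confusion(confusion_from_recalls(0.8333, 0.6250, 24))
        assert r.per_class["AD"].precision == pytest.approx(15 / 19)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confusion_from_recalls(1.2, 0.5, 24)
        with pytest.raises(ValueError):
            confusion_from_recalls(0.5, 0.5, 0)


class TestPredictionSimilarity:
    def test_identical_and_complementary(self):
        a = np.array([1, 0, 1, 1])
        assert prediction_similarity(a, a) == 1.0
        assert prediction_similarity(a, 1 - a) == 0.0

    def test_fraction_of_matches(self):
        a = np.zeros(48, dtype=int)
        b = np.zeros(48, dtype=int)
        b[:16] = 1
        assert prediction_similarity(a, b) == pytest.approx(32 / 48)

    def test_threshold_binarization(self):
        assert prediction_similarity([0.9, 0.2], [0.6, 0.1], threshold=0.5) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            prediction_similarity([1, 0], [1])


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_constant_scores(self):
        _, auc = roc_auc([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_hand_counted_pairs(self):
        # AD scores [0.9, 0.4] vs non-AD [0.6, 0.1]: 3 of 4 pairs ordered
        _, auc = roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_agrees_with_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            probs = np.round(rng.random(n), 2)     # induce some ties
            _, auc = roc_auc(probs, labels)
            assert auc == pytest.approx(pair_counting_auc(probs, labels))

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        probs = rng.random(30)
        _, a1 = roc_auc(probs, labels)
        _, a2 = roc_auc(np.exp(3 * probs), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.5, 0.6], [1, 1])


class TestStratifiedKfold:
    def test_balanced_cohort_fold_arithmetic(self):
        labels = np.array([1] * 54 + [0] * 54)
        folds = stratified_kfold(labels, k=5, seed=3)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [21, 21, 22, 22, 22]
        for f in folds:
            assert labels[f].sum() in (10, 11)

    def test_deterministic_and_partitioning(self):
        labels = np.array([1] * 20 + [0] * 20)
        a = stratified_kfold(labels, k=5, seed=7)
        b = stratified_kfold(labels, k=5, seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)
        allidx = np.concatenate(a)
        assert sorted(allidx.tolist()) == list(range(40))

    def test_k_exceeding_class_size_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold([1, 1, 0, 0], k=3)


class TestTraining:
    def _toy(self, rng, n=16, n_feat=5, t=6, sep=3.0):
        labels = np.array([0, 1] * (n // 2))
        speech = rng.normal(size=(n, t, n_feat))
        speech[labels == 1] += sep
        return {"speech": speech,
                "speech_mask": np.ones((n, t), dtype=bool)}, labels

    def test_early_stopping_stops_before_max(self, rng):
        batch, labels = self._toy(rng)
        # validation with inverted labels never improves for long
        model = build_model(ModelConfig(kind="B0", n_acoustic_features=5,
                                        gru_width=4), seed=0)
        cfg = TrainConfig(seed=0, max_epochs=200, patience=3,
                          learning_rate=0.05)
        hist = train_model(model, batch, labels, cfg, batch, 1 - labels)
        assert hist["stopped_epoch"] < 199
        assert hist["best_epoch"] <= hist["stopped_epoch"]

    def test_loss_decreases_on_separable_toy(self, rng):
        batch, labels = self._toy(rng)
        model = build_model(ModelConfig(kind="B0", n_acoustic_features=5,
                                        gru_width=4), seed=0)
        cfg = TrainConfig(seed=0, max_epochs=12, patience=12,
                          learning_rate=0.05)
        hist = train_model(model, batch, labels, cfg)
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_fixed_seed_reproduces_history(self, rng):
        batch, labels = self._toy(rng)
        hists = []
        for _ in range(2):
            model = build_model(ModelConfig(kind="B0", n_acoustic_features=5,
                                            gru_width=4), seed=1)
            cfg = TrainConfig(seed=5, max_epochs=5, patience=5)
            hists.append(train_model(model, batch, labels, cfg))
        assert hists[0]["train_loss"] == hists[1]["train_loss"]

    def test_restores_best_epoch_weights(self, rng):
        batch, labels = self._toy(rng)
        model = build_model(ModelConfig(kind="B0", n_acoustic_features=5,
                                        gru_width=4), seed=0)
        cfg = TrainConfig(seed=0, max_epochs=30, patience=2,
                          learning_rate=0.05)
        hist = train_model(model, batch, labels, cfg, batch, 1 - labels)
        # monitored value of restored weights equals the recorded best
        from adspeech.nn import bce_with_logits
        val_loss = float(bce_with_logits(model.logits(batch),
                                         (1 - labels).astype(float)).data)
        assert val_loss == pytest.approx(min(hist["val_loss"]))


class TestProtocol:
    def test_reports_shape_and_determinism(self, tiny_data):
        cfg = ModelConfig(kind="B0", gru_width=8)
        tc = TrainConfig(seed=2, k_folds=2, max_epochs=4, patience=2)
        r1 = run_protocol(tiny_data, cfg, tc)
        r2 = run_protocol(tiny_data, cfg, tc)
        assert len(r1.cv.folds) == 2
        assert "accuracy" in r1.cv.mean and "accuracy" in r1.cv.sd
        assert r1.test.fold == "test"
        np.testing.assert_array_equal(r1.test_probabilities,
                                      r2.test_probabilities)
        assert r1.cv.mean == r2.cv.mean

    def test_test_labels_never_seen_during_fit(self, tiny_data, monkeypatch):
        """Audit: training only ever receives train-split rows."""
        from adspeech import evaluation as ev
        n_train = len(tiny_data.train_labels)
        seen = []
        original = ev.train_model

        def spy(model, batch, labels, *args, **kw):
            seen.append(len(labels))
            return original(model, batch, labels, *args, **kw)

        monkeypatch.setattr(ev, "train_model", spy)
        tc = TrainConfig(seed=0, k_folds=2, max_epochs=2, patience=2)
        ev.run_protocol(tiny_data, ModelConfig(kind="B0", gru_width=4), tc)
        assert max(seen) <= n_train
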