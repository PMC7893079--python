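"""Training protocol and evaluation metrics.

The protocol mirrors the study design: stratified 5-fold cross-validation on
the 108-participant train split (AdaGrad, learning rate 0.001, up to 200
epochs with early stopping, classification threshold 0.5), then a single fit
on the complete train split evaluated once on the held-out test split.

AD is the positive class. Per-class precision/recall/F1 are computed from the
confusion counts with the class roles swapped for the non-AD row; accuracy is
(tp+tn)/n. Metrics with a zero denominator are defined as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .acoustic_features import (
    apply_filter,
    duration_correlation_filter,
    pad_segment_sequences,
    standardize,
)
from .corpus_io import Cohort
from .models import Model, ModelConfig, build_model, slice_batch
from .nn import AdaGrad, bce_with_logits
from .targeted_speech_features import targeted_speech_vector
from .text_features import (
    EmbeddingTable,
    PsycholinguisticLexicon,
    build_targeted_text_vector,
    encode_text_inputs,
    lexicon_sentiment_scorer,
    rule_pos_tagger,
)
from .targeted_speech_features import heuristic_dependency_parser

POSITIVE_LABEL = "AD"


# ---------------------------------------------------------------------------
# Configuration and report containers
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    optimizer: str = "adagrad"
    learning_rate: float = 0.001
    max_epochs: int = 200
    patience: int = 10
    monitor: str = "val_loss"
    threshold: float = 0.5
    seed: int = 0
    k_folds: int = 5
    batch_size: int = 16

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.optimizer.lower() != "adagrad":
            raise ValueError("only the AdaGrad optimizer is supported")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class ClassMetrics:
    recall: float
    precision: float
    f1: float
    zero_denominator: bool = False


@dataclass
class EvalReport:
    per_class: dict[str, ClassMetrics]
    accuracy: float
    confusion: ConfusionCounts
    roc_points: np.ndarray | None = None     # (n, 2) of (fpr, tpr)
    auc: float | None = None
    fold: str = "test"

    def metric(self, cls: str, name: str) -> float:
        return getattr(self.per_class[cls], name)


@dataclass
class CVReport:
    folds: list[EvalReport]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_folds(cls, folds: list[EvalReport]) -> "CVReport":
        keys = [(c, m) for c in ("non-AD", "AD")
                for m in ("recall", "precision", "f1")]
        mean, sd = {}, {}
        for c, m in keys:
            vals = np.array([f.metric(c, m) for f in folds])
            mean[f"{c}.{m}"] = float(vals.mean())
            sd[f"{c}.{m}"] = float(vals.std(ddof=1))
        accs = np.array([f.accuracy for f in folds])
        mean["accuracy"] = float(accs.mean())
        sd["accuracy"] = float(accs.std(ddof=1))
        return cls(folds, mean, sd)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _as_binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        bad = set(map(str, arr)) - {"AD", "non-AD"}
        if bad:
            raise ValueError(f"labels outside {{AD, non-AD}}: {sorted(bad)}")
        return (arr == "AD").astype(int)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"numeric labels must be 0/1 (1=AD), got {sorted(uniq)}")
    return arr.astype(int)


def class_metrics(probabilities, labels, threshold: float = 0.5,
                  fold: str = "test", with_roc: bool = True) -> EvalReport:
    """Per-class precision/recall/F1, accuracy, confusion and ROC/AUC.

    Predict AD iff probability >= threshold (closed boundary at the tie).
    """
    p = np.asarray(probabilities, dtype=float)
    y = _as_binary_labels(labels)
    if p.shape != y.shape or p.size == 0:
        raise ValueError("probabilities and labels must be equal-length, non-empty")
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    confusion = ConfusionCounts(tp, fp, fn, tn)

    def one_class(tp_, fp_, fn_) -> ClassMetrics:
        flag = False
        if tp_ + fn_ == 0:
            recall, flag = 0.0, True
        else:
            recall = tp_ / (tp_ + fn_)
        if tp_ + fp_ == 0:
            precision, flag = 0.0, True
        else:
            precision = tp_ / (tp_ + fp_)
        if precision + recall == 0:
            f1, flag = 0.0, True
        else:
            f1 = 2 * precision * recall / (precision + recall)
        return ClassMetrics(recall, precision, f1, flag)

    report = EvalReport(
        per_class={"AD": one_class(tp, fp, fn),
                   "non-AD": one_class(tn, fn, fp)},   # swapped roles
        accuracy=confusion.accuracy,
        confusion=confusion,
        fold=fold,
    )
    if with_roc and len(set(y.tolist())) == 2:
        points, auc = roc_auc(p, y)
        report.roc_points, report.auc = points, auc
    return report


def confusion_from_recalls(recall_neg: float, recall_pos: float,
                           n_per_class: int) -> ConfusionCounts:
    """Reconstruct confusion counts from per-class recalls on a balanced split.

    With n participants per class, tp = round(recall_pos * n) and
    tn = round(recall_neg * n); the remaining counts follow. Used to recover
    full metric sets from published per-class recall values.
    """
    if not (0 <= recall_neg <= 1 and 0 <= recall_pos <= 1):
        raise ValueError("recalls must lie in [0, 1]")
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    tp = round(recall_pos * n_per_class)
    tn = round(recall_neg * n_per_class)
    return ConfusionCounts(tp=tp, fp=n_per_class - tn,
                           fn=n_per_class - tp, tn=tn)


def metrics_from_confusion(confusion: ConfusionCounts) -> EvalReport:
    """Per-class metrics computed directly from confusion counts."""
    tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    probs = np.concatenate([np.ones(tp), np.zeros(fn),      # AD cases
                            np.ones(fp), np.zeros(tn)])     # non-AD cases
    labels = np.concatenate([np.ones(tp + fn), np.zeros(fp + tn)]).astype(int)
    return class_metrics(probs, labels, threshold=0.5, with_roc=False)


def prediction_similarity(preds_a, preds_b, threshold: float | None = None) -> float:
    """Fraction of positions where two prediction vectors agree.

    Pass ``threshold`` to binarize probability vectors first; otherwise the
    inputs are compared as the hard labels they already are.
    """
    a = np.asarray(preds_a)
    b = np.asarray(preds_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("prediction vectors must be equal-length and non-empty")
    if threshold is not None:
        a = (a.astype(float) >= threshold).astype(int)
        b = (b.astype(float) >= threshold).astype(int)
    return float(np.mean(a == b))


def roc_auc(probabilities, labels) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC points (fpr, tpr) and trapezoidal AUC."""
    y = _as_binary_labels(labels)
    p = np.asarray(probabilities, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(y, p)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# Folds and training
# ---------------------------------------------------------------------------

def stratified_kfold(labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified folds; returns k disjoint held-out index arrays."""
    y = _as_binary_labels(labels)
    counts = np.bincount(y, minlength=2)
    if (counts < k).any():
        raise ValueError(f"k={k} exceeds the size of the smallest class {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(y)), y)]


def train_model(model: Model, train_batch: dict, train_labels,
                config: TrainConfig,
                val_batch: dict | None = None, val_labels=None) -> dict:
    """Fit with AdaGrad + early stopping; restores best-epoch parameters.

    Monitors validation loss when a validation set is given, else training
    loss. Returns the history dict (per-epoch losses and accuracies).
    """
    y_train = _as_binary_labels(train_labels).astype(float)
    has_val = val_batch is not None
    y_val = _as_binary_labels(val_labels).astype(float) if has_val else None

    opt = AdaGrad(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n = len(y_train)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [],
                                       "val_accuracy": []}
    best = (np.inf, None, -1)       # monitored value, weights, epoch

    for epoch in range(config.max_epochs):
        model.set_training(True)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            mb = slice_batch(train_batch, idx)
            logits = model.logits(mb)
            loss = bce_with_logits(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={config.learning_rate}); aborting")
            model.zero_grad()
            loss.backward()
            opt.step()
        model.set_training(False)

        train_loss = float(bce_with_logits(model.logits(train_batch), y_train).data)
        history["train_loss"].append(train_loss)
        if has_val:
            val_logits = model.logits(val_batch)
            val_loss = float(bce_with_logits(val_logits, y_val).data)
            val_probs = 1.0 / (1.0 + np.exp(-val_logits.data))
            val_acc = float(np.mean((val_probs >= config.threshold) == y_val))
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(val_acc)
            monitored = val_loss
        else:
            monitored = train_loss

        if monitored < best[0] - 1e-12:
            best = (monitored, model.state_arrays(), epoch)
        elif epoch - best[2] >= config.patience:
            break
    if best[1] is not None:
        model.load_state_arrays(best[1])
    history["best_epoch"] = best[2]
    history["stopped_epoch"] = epoch
    return history


# ---------------------------------------------------------------------------
# Featurization glue: cohort -> model batches
# ---------------------------------------------------------------------------

@dataclass
class CohortResources:
    """External resources the feature extractors depend on (pluggable backends)."""

    embedding_table: EmbeddingTable
    lexicon: PsycholinguisticLexicon
    sentiment_scorer: object = None
    pos_tagger: object = None
    dependency_parser: object = None

    def __post_init__(self):
        self.sentiment_scorer = self.sentiment_scorer or lexicon_sentiment_scorer
        self.pos_tagger = self.pos_tagger or rule_pos_tagger
        self.dependency_parser = self.dependency_parser or heuristic_dependency_parser


@dataclass
class PreparedData:
    train_batch: dict
    train_labels: np.ndarray
    test_batch: dict
    test_labels: np.ndarray
    filter_result: object
    n_acoustic_features: int
    embedding_dim: int
    max_len: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def _zscore_rows(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mean) / sd, (test - mean) / sd


def prepare_inputs(cohort: Cohort, resources: CohortResources,
                   filter_threshold: float = 0.2, filter_scope: str = "all",
                   max_segments: int = 64, max_len: int = 128) -> PreparedData:
    """Run the full featurization pipeline and emit train/test model batches.

    Acoustic features pass the duration-correlation filter, are z-scored on
    train statistics and padded into masked sequences. Targeted vectors (text
    and speech) are z-scored on train statistics. Text inputs are padded
    embedding + POS-id streams from participant turns only.
    """
    train_ps, test_ps = cohort.train, cohort.test
    if not train_ps or not test_ps:
        raise ValueError("cohort must have both train and test participants")

    filt = duration_correlation_filter(cohort, threshold=filter_threshold,
                                       fit_scope=filter_scope)
    train_f = [apply_filter(p.acoustics, filt) for p in train_ps]
    test_f = [apply_filter(p.acoustics, filt) for p in test_ps]
    train_z, test_z, _, _ = standardize(train_f, test_f)

    def build(participants, sessions):
        padded = pad_segment_sequences(sessions, max_segments=max_segments)
        text = [encode_text_inputs(p.transcript, resources.embedding_table,
                                   max_len=max_len, tagger=resources.pos_tagger)
                for p in participants]
        t_text = np.stack([
            build_targeted_text_vector(p.transcript, resources.lexicon,
                                       scorer=resources.sentiment_scorer,
                                       age=p.age, gender=p.gender).to_array()
            for p in participants])
        t_speech = np.stack([
            targeted_speech_vector(p.transcript, p.acoustics.durations,
                                   parser=resources.dependency_parser)
            for p in participants])
        batch = {
            "speech": padded.tensor,
            "speech_mask": padded.mask,
            "text_emb": np.stack([e.embeddings for e in text]),
            "text_pos": np.stack([e.pos_ids for e in text]),
            "text_mask": np.stack([e.mask for e in text]),
        }
        return batch, t_text, t_speech

    train_batch, tt_train, ts_train = build(train_ps, train_z)
    test_batch, tt_test, ts_test = build(test_ps, test_z)
    train_batch["text_targeted"], test_batch["text_targeted"] = _zscore_rows(
        tt_train, tt_test)
    train_batch["speech_targeted"], test_batch["speech_targeted"] = _zscore_rows(
        ts_train, ts_test)

    return PreparedData(
        train_batch=train_batch, train_labels=cohort.labels(train_ps),
        test_batch=test_batch, test_labels=cohort.labels(test_ps),
        filter_result=filt,
        n_acoustic_features=train_z[0].matrix.shape[1],
        embedding_dim=resources.embedding_table.dim, max_len=max_len,
        train_ids=tuple(p.id for p in train_ps),
        test_ids=tuple(p.id for p in test_ps),
    )


# ---------------------------------------------------------------------------
# The full protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    cv: CVReport
    test: EvalReport
    test_probabilities: np.ndarray
    history: dict


def run_protocol(data: PreparedData, model_config: ModelConfig,
                 train_config: TrainConfig) -> ProtocolResult:
    """Stratified k-fold CV on train, then one full-train fit scored on test."""
    cfg = model_config
    if cfg.kind in ("B0", "B1", "C"):
        cfg = replace_field(cfg, n_acoustic_features=data.n_acoustic_features)
    if cfg.kind in ("A0", "A1", "C"):
        cfg = replace_field(cfg, embedding_dim=data.embedding_dim)

    folds = stratified_kfold(data.train_labels, k=train_config.k_folds,
                             seed=train_config.seed)
    all_idx = np.arange(len(data.train_labels))
    fold_reports: list[EvalReport] = []
    for i, held in enumerate(folds):
        fit_idx = np.setdiff1d(all_idx, held)
        model = build_model(cfg, seed=train_config.seed + i)
        train_model(model,
                    slice_batch(data.train_batch, fit_idx),
                    data.train_labels[fit_idx], train_config,
                    slice_batch(data.train_batch, held),
                    data.train_labels[held])
        probs = model.forward(slice_batch(data.train_batch, held))
        fold_reports.append(class_metrics(probs, data.train_labels[held],
                                          threshold=train_config.threshold,
                                          fold=f"fold{i}"))
    cv = CVReport.from_folds(fold_reports)

    final, history = fit_final(data.train_batch, data.train_labels, cfg,
                               train_config)
    test_probs = final.forward(data.test_batch)
    test_report = class_metrics(test_probs, data.test_labels,
                                threshold=train_config.threshold, fold="test")
    return ProtocolResult(cv=cv, test=test_report,
                          test_probabilities=test_probs, history=history)


def fit_final(train_batch: dict, train_labels, model_config: ModelConfig,
              train_config: TrainConfig) -> tuple[Model, dict]:
    """Fit on the complete train split with early stopping.

    Early stopping needs a monitored held-out quantity, so the stopping epoch
    is first selected on a stratified validation split (one fold's worth of
    the train data); the model is then retrained from scratch on the full
    train split for exactly that many epochs. This keeps the final parameters
    trained on every train participant while retaining data-driven stopping.
    """
    labels = _as_binary_labels(train_labels)
    val_idx = stratified_kfold(labels, k=train_config.k_folds,
                               seed=train_config.seed)[0]
    fit_idx = np.setdiff1d(np.arange(len(labels)), val_idx)
    probe = build_model(model_config, seed=train_config.seed)
    probe_hist = train_model(probe, slice_batch(train_batch, fit_idx),
                             labels[fit_idx], train_config,
                             slice_batch(train_batch, val_idx), labels[val_idx])
    n_epochs = probe_hist["best_epoch"] + 1

    from dataclasses import replace
    final_cfg = replace(train_config, max_epochs=n_epochs,
                        patience=train_config.max_epochs)   # run to n_epochs
    final = build_model(model_config, seed=train_config.seed)
    history = train_model(final, train_batch, labels, final_cfg)
    history["probe_best_epoch"] = probe_hist["best_epoch"]
    history["probe_stopped_epoch"] = probe_hist["stopped_epoch"]
    return final, history


def replace_field(cfg: ModelConfig, **kw) -> ModelConfig:
    from dataclasses import replace
    return replace(cfg, **kw)
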