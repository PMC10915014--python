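"""LSTM/CNN training, hybrid fusion and the blocked cross-validation protocol.

The locomotion branch feeds sequences of ``seq_len`` consecutive transformed
feature rows to a single-layer LSTM; the localization branch feeds each
transformed row to a small 1-D CNN.  Cross-validation splits the time-ordered
rows into k contiguous, approximately equal blocks; each block is the test
set exactly once and the Yeo-Johnson parameters are refitted on the training
rows of every fold (no leakage, asserted by the recorded fold instrumentation).
Hybrid fusion concatenates the handcrafted row with the trained network's
penultimate activations and retrains a softmax (multinomial logistic) head.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._nn import CNNClassifier, LSTMClassifier
from .errors import ValidationError
from .evaluate import EvaluationReport, make_report
from .io_formats import FeatureMatrix
from .transform import TransformParams, apply_transform, fit_transform_matrix

log = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters for one task branch."""

    task: str = "locomotion"                 # locomotion | localization
    arch: str = "lstm"                       # lstm | cnn | hybrid
    seq_len: int = 5                         # LSTM: segments per instance
    hidden: int = 64
    filters: int = 32
    kernel: int = 3
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.seq_len < 1:
            raise ValidationError("seq_len must be >= 1")


@dataclass
class FoldPlan:
    """Contiguous time-block partition for blocked k-fold CV."""

    k: int
    test_blocks: list[np.ndarray]    # row indices per fold

    def train_indices(self, fold: int) -> np.ndarray:
        test = set(self.test_blocks[fold].tolist())
        n = sum(len(b) for b in self.test_blocks)
        return np.asarray([i for i in range(n) if i not in test], dtype=int)


def make_fold_plan(n_rows: int, k: int = 5, row_times=None) -> FoldPlan:
    """Split time-ordered rows into k contiguous blocks, sizes differing by
    at most one; each block serves as the test set exactly once."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n_rows:
        raise ValidationError(f"k = {k} exceeds row count {n_rows}")
    if row_times is not None:
        row_times = np.asarray(row_times)
        if np.any(np.diff(row_times) < 0):
            raise ValidationError("rows must be time-ordered for blocked CV")
    blocks = np.array_split(np.arange(n_rows), k)
    return FoldPlan(k=k, test_blocks=[b.copy() for b in blocks])


# ---------------------------------------------------------------------------
# Sequence construction for the LSTM branch
# ---------------------------------------------------------------------------

def build_sequences(X: np.ndarray, labels: np.ndarray, seq_len: int):
    """Sliding windows of ``seq_len`` consecutive rows with majority labels.

    Returns (instances (n, T, d), instance_labels, end_row_indices).  The
    majority tie-break is the class occurring earliest within the window.
    Rows are assumed time-ordered; windows never cross the array boundary.
    """
    n = len(X)
    if n < seq_len:
        log.warning("only %d rows for seq_len %d: no sequence instances", n, seq_len)
        return np.empty((0, seq_len, X.shape[1])), np.empty(0, dtype=labels.dtype), np.empty(0, dtype=int)
    instances = []
    inst_labels = []
    ends = []
    for start in range(0, n - seq_len + 1):
        window = labels[start:start + seq_len]
        values, counts = np.unique(window, return_counts=True)
        best = counts.max()
        majority = next(v for v in window if counts[list(values).index(v)] == best)
        instances.append(X[start:start + seq_len])
        inst_labels.append(majority)
        ends.append(start + seq_len - 1)
    return np.asarray(instances), np.asarray(inst_labels), np.asarray(ends, dtype=int)


def train_lstm(features: FeatureMatrix, cfg: ModelConfig) -> LSTMClassifier:
    """Train the locomotion LSTM on a (transformed) feature matrix."""
    if cfg.task != "locomotion":
        raise ValidationError("train_lstm expects cfg.task == 'locomotion'")
    X, y, _ = build_sequences(features.to_array(), features.labels, cfg.seq_len)
    if len(X) == 0:
        raise ValidationError("no sequence instances could be built")
    model = LSTMClassifier(hidden=cfg.hidden, epochs=cfg.epochs,
                           batch_size=cfg.batch_size, lr=cfg.learning_rate,
                           seed=cfg.seed)
    return model.fit(X, y)


def train_cnn(features: FeatureMatrix, cfg: ModelConfig) -> CNNClassifier:
    """Train the localization CNN on a (transformed) feature matrix."""
    if cfg.task != "localization":
        raise ValidationError("train_cnn expects cfg.task == 'localization'")
    model = CNNClassifier(filters=cfg.filters, kernel=cfg.kernel, hidden=cfg.hidden,
                          epochs=cfg.epochs, batch_size=cfg.batch_size,
                          lr=cfg.learning_rate, seed=cfg.seed)
    return model.fit(features.to_array(), features.labels)


# ---------------------------------------------------------------------------
# Hybrid fusion
# ---------------------------------------------------------------------------

def hybrid_features(model, features: FeatureMatrix, seq_len: int | None = None) -> FeatureMatrix:
    """Concatenate handcrafted rows with the model's penultimate activations.

    For an LSTM the activation belongs to the sequence ending at a row, and
    the handcrafted part is that end row; for a CNN the mapping is row-wise.
    Column provenance is recorded via ``hand__`` / ``deep__`` prefixes.
    """
    X = features.to_array()
    if isinstance(model, LSTMClassifier):
        if seq_len is None:
            raise ValidationError("seq_len required for LSTM hybrid features")
        seqs, seq_labels, ends = build_sequences(X, features.labels, seq_len)
        deep = model.penultimate(seqs)
        hand = X[ends]
        labels = features.labels[ends]
    else:
        deep = model.penultimate(X)
        hand = X
        labels = features.labels
    if len(deep) != len(hand):
        raise ValidationError("handcrafted and deep feature counts disagree")
    cols = {f"hand__{c}": hand[:, i] for i, c in enumerate(features.columns)}
    cols.update({f"deep__{j}": deep[:, j] for j in range(deep.shape[1])})
    return FeatureMatrix(values=pd.DataFrame(cols), labels=labels, branch=features.branch)


def fit_softmax_head(X: np.ndarray, y: np.ndarray, seed: int = 0) -> LogisticRegression:
    """Multinomial logistic head used for hybrid fusion and ablations."""
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(X, y)
    return clf


def hybrid_ablation(features: FeatureMatrix, cfg: ModelConfig,
                    train_frac: float = 0.7) -> dict[str, float]:
    """Compare handcrafted-only, deep-only and hybrid accuracy on one
    contiguous train/test split (fold hygiene preserved: the transform and
    every model see training rows only).

    Returns test accuracies keyed ``handcrafted``, ``deep`` and ``hybrid``;
    all three are evaluated on the same sequence-aligned test instances.
    """
    n = features.n_rows
    cut = int(round(train_frac * n))
    train_fm = _subset(features, np.arange(cut))
    test_fm = _subset(features, np.arange(cut, n))
    train_t, params = fit_transform_matrix(train_fm)
    test_t = apply_transform(test_fm, params)

    model = train_lstm(train_t, cfg) if cfg.task == "locomotion" else train_cnn(train_t, cfg)
    seq_len = cfg.seq_len if cfg.task == "locomotion" else None

    hyb_train = hybrid_features(model, train_t, seq_len=seq_len)
    hyb_test = hybrid_features(model, test_t, seq_len=seq_len)
    hand_cols = [c for c in hyb_train.columns if c.startswith("hand__")]
    deep_cols = [c for c in hyb_train.columns if c.startswith("deep__")]

    accs: dict[str, float] = {}
    y_train, y_test = hyb_train.labels, hyb_test.labels
    for name, cols in (("handcrafted", hand_cols), ("hybrid", hyb_train.columns)):
        head = fit_softmax_head(hyb_train.values[cols].to_numpy(), y_train, seed=cfg.seed)
        accs[name] = float(np.mean(head.predict(hyb_test.values[cols].to_numpy()) == y_test))
    if cfg.task == "locomotion":
        seqs, seq_labels, _ = build_sequences(test_t.to_array(), test_t.labels, cfg.seq_len)
        accs["deep"] = float(np.mean(model.predict(seqs) == seq_labels))
    else:
        accs["deep"] = float(np.mean(model.predict(test_t.to_array()) == test_t.labels))
    return accs


# ---------------------------------------------------------------------------
# Blocked cross-validation
# ---------------------------------------------------------------------------

# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path, cfg: ModelConfig | None = None) -> None:
    """Save weights to a single ``.npz`` plus a JSON sidecar of metadata."""
    path = Path(path)
    np.savez(path, **model.params)
    kind = "lstm" if isinstance(model, LSTMClassifier) else "cnn"
    meta = {
        "kind": kind,
        "classes": [str(c) for c in model.classes_],
        "hidden": model.hidden,
        "seed": model.seed,
    }
    if kind == "cnn":
        meta.update(filters=model.filters, kernel=model.kernel)
    if cfg is not None:
        meta["model_config"] = asdict(cfg)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_model(path: str | Path):
    """Load a checkpoint saved by :func:`save_model`."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    sidecar = npz_path.with_suffix(".json")
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    if meta["kind"] == "lstm":
        model = LSTMClassifier(hidden=meta["hidden"], seed=meta.get("seed", 0))
    else:
        model = CNNClassifier(filters=meta["filters"], kernel=meta["kernel"],
                              hidden=meta["hidden"], seed=meta.get("seed", 0))
    with np.load(npz_path) as data:
        model.params = {k: data[k].copy() for k in data.files}
    model.classes_ = np.asarray(meta["classes"])
    return model


@dataclass
class FoldRecord:
    """Instrumentation: exactly which rows each fitted object saw."""

    fold: int
    train_rows: np.ndarray
    test_rows: np.ndarray
    transform_fit_rows: np.ndarray
    model_fit_rows: np.ndarray
    transform_params: TransformParams
    missing_train_classes: list[str]


@dataclass
class CVResult:
    fold_plan: FoldPlan
    fold_reports: list[EvaluationReport]
    pooled: EvaluationReport
    records: list[FoldRecord]


def _subset(fm: FeatureMatrix, rows: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        values=fm.values.iloc[rows].reset_index(drop=True),
        labels=fm.labels[rows],
        branch=fm.branch,
    )


def run_cv(features: FeatureMatrix, cfg: ModelConfig, k: int = 5) -> CVResult:
    """Blocked k-fold: per fold, fit Yeo-Johnson on the training rows only,
    train the configured architecture, evaluate on the held-out block, and
    pool the confusion matrices over folds."""
    n = features.n_rows
    plan = make_fold_plan(n, k)
    class_order = sorted(np.unique(features.labels).tolist())
    pooled_conf = np.zeros((len(class_order), len(class_order)), dtype=int)
    fold_reports: list[EvaluationReport] = []
    records: list[FoldRecord] = []
    all_true: list = []
    all_pred: list = []
    all_scores: list[np.ndarray] = []

    for fold in range(k):
        test_rows = plan.test_blocks[fold]
        train_rows = plan.train_indices(fold)
        train_fm = _subset(features, train_rows)
        test_fm = _subset(features, test_rows)
        missing = sorted(set(class_order) - set(np.unique(train_fm.labels)))
        if missing:
            log.warning("fold %d: classes %s absent from training block", fold, missing)

        train_t, params = fit_transform_matrix(train_fm)
        test_t = apply_transform(test_fm, params)

        if cfg.arch == "cnn" or cfg.task == "localization":
            model = train_cnn(train_t, cfg)
            test_X = test_t.to_array()
            test_y = test_t.labels
            probs = model.predict_proba(test_X)
            preds = model.predict(test_X)
            model_rows = train_rows
        else:
            model = train_lstm(train_t, cfg)
            seqs, seq_labels, ends = build_sequences(
                test_t.to_array(), test_t.labels, cfg.seq_len
            )
            if len(seqs) == 0:
                log.warning("fold %d: test block too short for sequences", fold)
                continue
            probs = model.predict_proba(seqs)
            preds = model.predict(seqs)
            test_y = seq_labels
            model_rows = train_rows

        # scores aligned to the global class order (model may have seen fewer)
        scores = np.zeros((len(preds), len(class_order)))
        for j, cls in enumerate(model.classes_):
            scores[:, class_order.index(cls)] = probs[:, j]

        cm_fold = make_report(test_y, preds, class_order, scores)
        fold_reports.append(cm_fold)
        pooled_conf += cm_fold.confusion
        all_true.extend(test_y.tolist())
        all_pred.extend(preds.tolist())
        all_scores.append(scores)
        records.append(
            FoldRecord(
                fold=fold,
                train_rows=train_rows,
                test_rows=test_rows,
                transform_fit_rows=train_rows.copy(),
                model_fit_rows=model_rows.copy(),
                transform_params=params,
                missing_train_classes=missing,
            )
        )

    pooled = make_report(
        np.asarray(all_true), np.asarray(all_pred), class_order,
        np.vstack(all_scores) if all_scores else None,
    )
    return CVResult(fold_plan=plan, fold_reports=fold_reports, pooled=pooled,
                    records=records)
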