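"""Loss, the optimization loop, and ranking metrics (AUROC / AUPRC).

AUROC is computed through the Mann-Whitney identity with midrank tie handling:
it equals P(score_pos > score_neg) + 0.5 P(tie) over all positive-negative
pairs.  AUPRC is average precision with tied score blocks treated jointly:
the sum over descending unique thresholds of precision times the recall
increment.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .datasets import LabeledExample
from .network import SSBModel
from .network import autodiff as ad
from .seqcore import one_hot_encode


class UndefinedMetricError(ValueError):
    """AUROC/AUPRC need at least one example of each class."""


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 256
    max_epochs: int = 20
    learning_rate: float = 1e-3
    early_stop_patience: int = 3  # epochs without a validation-AUPRC improvement
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.early_stop_patience) < 1:
            raise ValueError("batch_size, max_epochs and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass(frozen=True)
class EvalResult:
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int


def binary_cross_entropy(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean of -[y ln p + (1-y) ln(1-p)] with p clamped to [1e-7, 1 - 1e-7]."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if scores.shape != labels.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {labels.shape}")
    p = np.clip(scores, 1e-7, 1.0 - 1e-7)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def _bce_loss(scores: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    """Differentiable BCE on a score tensor (same clamping as the scalar form)."""
    y = labels.astype(np.float32)
    p = ad.clip(scores, 1e-7, 1.0 - 1e-7)
    pos = ad.mul(ad.log(p), y)
    neg = ad.mul(ad.log(ad.add(ad.mul(p, -1.0), 1.0)), 1.0 - y)
    return ad.mul(ad.mean(ad.add(pos, neg)), -1.0)


def evaluate_auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via midranks (ties counted half)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs both classes present")
    ranks = rankdata(scores)  # midranks
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def evaluate_auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision; tied blocks contribute a single (precision, recall) step."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUPRC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], (labels[order] == 1).astype(np.int64)
    tp = np.cumsum(y)
    rank = np.arange(1, len(y) + 1)
    # keep only the last index of every tied block (threshold boundaries)
    boundary = np.nonzero(np.append(np.diff(s) != 0, True))[0]
    tp_b = tp[boundary]
    precision = tp_b / rank[boundary]
    recall_inc = np.diff(np.concatenate([[0], tp_b])) / n_pos
    return float(np.sum(precision * recall_inc))


def evaluate(scores: Sequence[float], labels: Sequence[int]) -> EvalResult:
    labels_arr = np.asarray(labels)
    return EvalResult(
        auroc=evaluate_auroc(scores, labels),
        auprc=evaluate_auprc(scores, labels),
        n_pos=int((labels_arr == 1).sum()),
        n_neg=int((labels_arr == 0).sum()),
    )


# ---------------------------------------------------------------------------
# Encoding examples into arrays and the Adam loop
# ---------------------------------------------------------------------------


def encode_examples(examples: Sequence[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack one-hot windows into (N, 4, L) plus a (N,) label vector."""
    if not examples:
        raise ValueError("empty example list")
    X = np.stack([one_hot_encode(ex.sequence).matrix for ex in examples])
    y = np.array([ex.label for ex in examples], dtype=np.int64)
    return X, y


def stratified_validation_split(
    examples: Sequence[LabeledExample], fraction: float = 0.1, seed: int = 0
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Label-stratified (train, validation) split; at least one per class in each."""
    rng = np.random.default_rng(seed)
    train: list[LabeledExample] = []
    val: list[LabeledExample] = []
    for label in (0, 1):
        idx = [i for i, ex in enumerate(examples) if ex.label == label]
        rng.shuffle(idx)
        n_val = max(1, int(round(fraction * len(idx)))) if idx else 0
        val.extend(examples[i] for i in idx[:n_val])
        train.extend(examples[i] for i in idx[n_val:])
    return train, val


class Adam:
    def __init__(self, params: list[ad.Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_auroc: float
    val_auprc: float


def train_model(
    model: SSBModel,
    train_examples: Sequence[LabeledExample],
    val_examples: Sequence[LabeledExample],
    config: TrainConfig,
) -> tuple[SSBModel, list[EpochRecord]]:
    """Adam-optimized BCE training with best-validation-AUPRC model selection.

    Early stopping triggers after ``early_stop_patience`` epochs without a
    strict validation-AUPRC improvement.  Fully reproducible for fixed
    (TrainConfig.seed, ModelConfig.seed) and data order.
    """
    if not train_examples:
        raise ValueError("empty train set")
    if not val_examples:
        raise ValueError("empty validation set")
    val_labels = np.array([ex.label for ex in val_examples])
    if len(set(val_labels.tolist())) < 2:
        raise UndefinedMetricError("validation set must contain both classes")

    X_train, y_train = encode_examples(train_examples)
    X_val, _ = encode_examples(val_examples)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)

    history: list[EpochRecord] = []
    best_auprc = -np.inf
    best_weights = model.get_weights()
    epochs_since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_examples))
        losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch = ad.constant(X_train[idx])
            logits = model.forward_logits(batch, train=True, rng=rng)
            loss = ad.bce_with_logits(logits, y_train[idx])
            model.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))

        val_scores = model.predict(X_val, batch_size=config.batch_size)
        result = evaluate(val_scores, val_labels)
        history.append(EpochRecord(epoch, float(np.mean(losses)),
                                   result.auroc, result.auprc))
        if result.auprc > best_auprc:
            best_auprc = result.auprc
            best_weights = model.get_weights()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.early_stop_patience:
                break

    model.set_weights(best_weights)
    return model, history


def write_history_tsv(history: Sequence[EpochRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_auroc\tval_auprc\n")
        for rec in history:
            fh.write(f"{rec.epoch}\t{rec.train_loss:.6f}\t{rec.val_auroc:.6f}\t{rec.val_auprc:.6f}\n")
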