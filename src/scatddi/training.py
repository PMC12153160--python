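"""Loss, optimisation, metrics and cross-validation around the classifier.

The public face is :class:`ScatClassifier`, a scikit-learn-style estimator:
``fit`` runs mini-batch Adam on the categorical cross-entropy, ``predict`` /
``predict_proba`` run chunked eval-mode forwards.  ``train`` and ``kfold_cv``
are thin functional wrappers.

Evaluation follows the DDI-corpus convention: micro-averaged precision,
recall and F1 from per-class TP/FP/FN counts summed over the positive
interaction classes (effect, mechanism, advice, int); accuracy is computed
over all instances.  An all-classes scope is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor
from .config import POSITIVE_CLASSES, ScatConfig, TrainConfig
from .model import ScatModel

__all__ = [
    "ScatClassifier", "cross_entropy_loss", "evaluate_metrics",
    "MetricsReport", "train", "kfold_cv", "AdamOptimizer",
]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_entropy_loss(p, labels, reduction: str = "sum",
                       class_weights=None) -> float:
    """Categorical cross-entropy -sum(log p[true label]) over a batch.

    ``p`` is an (M, C) array of class probabilities; probabilities of zero at
    the true label are clamped at 1e-12 with a warning.  ``reduction`` is
    ``"sum"`` (default) or ``"mean"``.
    """
    p = np.asarray(p, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if p.ndim != 2 or len(labels) != p.shape[0]:
        raise ValueError("p must be (M, C) with one label per row")
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= p.shape[1]:
        raise ValueError("labels out of range")
    picked = p[np.arange(len(labels)), labels]
    if np.any(picked <= 0):
        warnings.warn("zero probability at true label; clamping at 1e-12",
                      stacklevel=2)
        picked = np.clip(picked, 1e-12, None)
    losses = -np.log(picked)
    if class_weights is not None:
        losses = losses * np.asarray(class_weights)[labels]
    if reduction == "sum":
        return float(losses.sum())
    if reduction == "mean":
        return float(losses.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def _nll_from_logits(logits: Tensor, labels: np.ndarray,
                     weights: np.ndarray | None) -> Tensor:
    """Numerically stable mean cross-entropy on the autodiff graph."""
    onehot = np.zeros(logits.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    if weights is not None:
        onehot *= weights[labels][:, None]
    logp = logits.log_softmax(axis=-1)
    return -(logp * Tensor(onehot)).sum() / float(len(labels))


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class AdamOptimizer:
    """Adam with the usual default moments (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    counts: dict[str, tuple[int, int, int, int]]  # class -> (TP, FP, TN, FN)
    accuracy: float
    precision: float
    recall: float
    f1: float
    scope: str
    n: int = 0


def evaluate_metrics(pred, gold, scope: str = "positive") -> MetricsReport:
    """Micro-averaged P/R/F1 over the classes in scope; accuracy over all.

    ``scope="positive"`` restricts the count sums to the four interaction
    classes; ``scope="all"`` uses every observed class (in which case micro
    P = R = F1 = accuracy for single-label data).
    """
    pred, gold = list(pred), list(gold)
    if len(pred) != len(gold):
        raise ValueError("pred and gold must have equal length")
    if not pred:
        raise ValueError("empty input")
    observed = sorted(set(pred) | set(gold))
    if scope == "positive":
        classes = [c for c in observed if c in POSITIVE_CLASSES]
    elif scope == "all":
        classes = observed
    else:
        raise ValueError(f"unknown scope {scope!r}")
    counts = {}
    tp_sum = fp_sum = fn_sum = 0
    n = len(pred)
    for c in classes:
        tp = sum(1 for p, g in zip(pred, gold) if p == c and g == c)
        fp = sum(1 for p, g in zip(pred, gold) if p == c and g != c)
        fn = sum(1 for p, g in zip(pred, gold) if p != c and g == c)
        counts[c] = (tp, fp, n - tp - fp - fn, fn)
        tp_sum, fp_sum, fn_sum = tp_sum + tp, fp_sum + fp, fn_sum + fn
    precision = tp_sum / (tp_sum + fp_sum) if tp_sum + fp_sum else 0.0
    recall = tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = sum(1 for p, g in zip(pred, gold) if p == g) / n
    return MetricsReport(counts, accuracy, precision, recall, f1, scope, n)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class ScatClassifier(BaseEstimator, ClassifierMixin):
    """Cross-attention DDI classifier with a scikit-learn interface.

    Parameters
    ----------
    config : ScatConfig, optional
        Architecture hyperparameters (defaults to published operating point).
    train_config : TrainConfig, optional
        Optimisation hyperparameters.
    validation : float, default 0.0
        Fraction of the training set held out for periodic metric traces.

    Each sample in ``X`` is a pair ``(E1, E2)`` of fused modality sequences,
    arrays of shape (T_i, d_w + d_d + d_g).  ``y`` holds class labels.

    Attributes
    ----------
    model_ : ScatModel
        The fitted network.
    classes_ : ndarray
        Sorted class labels.
    loss_trace_ : list of float
        Per-step training loss.
    metric_trace_ : list of dict
        Validation metrics every ``eval_every`` steps (when validation > 0).
    """

    def __init__(self, config: ScatConfig | None = None,
                 train_config: TrainConfig | None = None,
                 validation: float = 0.0):
        self.config = config
        self.train_config = train_config
        self.validation = validation

    def _check_X(self, X):
        pairs = []
        for i, pair in enumerate(X):
            if len(pair) != 2:
                raise ValueError(f"sample {i} is not an (E1, E2) pair")
            pairs.append((np.asarray(pair[0], float), np.asarray(pair[1], float)))
        return pairs

    def fit(self, X, y):
        cfg = self.config or ScatConfig()
        tcfg = self.train_config or TrainConfig()
        pairs = self._check_X(X)
        y = np.asarray(y)
        if len(pairs) != len(y) or not len(pairs):
            raise ValueError("X and y must be equal-length and non-empty")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) == 1:
            warnings.warn("single-class training set; metrics are degenerate",
                          stacklevel=2)
        if len(self.classes_) != cfg.n_classes:
            cfg = replace(cfg, n_classes=max(2, len(self.classes_)))
        self._fitted_config_ = cfg
        self.model_ = ScatModel(cfg)
        rng = np.random.Generator(np.random.PCG64(tcfg.seed))

        # optional validation split (stratified where possible)
        idx = np.arange(len(pairs))
        val_idx = np.array([], dtype=int)
        if self.validation > 0 and len(pairs) >= 10:
            perm = rng.permutation(idx)
            n_val = max(1, int(round(self.validation * len(pairs))))
            val_idx, idx = perm[:n_val], perm[n_val:]
        train_pairs = [pairs[i] for i in idx]
        train_y = y_idx[idx]

        weights = None
        if tcfg.class_weighting == "inverse-frequency":
            freq = np.bincount(train_y, minlength=cfg.n_classes).astype(float)
            freq[freq == 0] = 1.0
            weights = len(train_y) / (cfg.n_classes * freq)

        opt = AdamOptimizer(self.model_.params, tcfg.learning_rate)
        self.loss_trace_, self.metric_trace_ = [], []
        order = rng.permutation(len(train_pairs))
        cursor = 0
        best_val, patience_left = np.inf, tcfg.patience
        for step in range(tcfg.max_iterations):
            if cursor + tcfg.mini_batch > len(order):
                order = rng.permutation(len(train_pairs))
                cursor = 0
            take = order[cursor:cursor + tcfg.mini_batch]
            cursor += tcfg.mini_batch
            E1 = [train_pairs[i][0] for i in take]
            E2 = [train_pairs[i][1] for i in take]
            labels = train_y[take]
            out = self.model_.forward_batch(E1, E2, train=True, rng=rng)
            loss = _nll_from_logits(out["logits"], labels, weights)
            self.model_.zero_grad()
            loss.backward()
            opt.step()
            self.loss_trace_.append(float(loss.data))
            if len(val_idx) and (step + 1) % tcfg.eval_every == 0:
                vp = self.predict([pairs[i] for i in val_idx])
                rep = evaluate_metrics(list(vp), list(y[val_idx]), scope="all")
                vloss = cross_entropy_loss(
                    self.predict_proba([pairs[i] for i in val_idx]),
                    np.searchsorted(self.classes_, y[val_idx]),
                    reduction="mean")
                self.metric_trace_.append(
                    {"step": step + 1, "val_accuracy": rep.accuracy,
                     "val_f1": rep.f1, "val_loss": vloss})
                if tcfg.early_stopping:
                    if vloss < best_val - 1e-6:
                        best_val, patience_left = vloss, tcfg.patience
                    else:
                        patience_left -= 1
                        if patience_left <= 0:
                            break
        self.n_iter_ = len(self.loss_trace_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        pairs = self._check_X(X)
        cap = (self.train_config or TrainConfig()).eval_batch
        chunks = []
        for lo in range(0, len(pairs), cap):
            batch = pairs[lo:lo + cap]
            out = self.model_.forward_batch(
                [p[0] for p in batch], [p[1] for p in batch], train=False)
            chunks.append(out["probs"])
        return np.concatenate(chunks, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train(X, y, config: ScatConfig | None = None,
          train_config: TrainConfig | None = None,
          validation: float = 0.1) -> ScatClassifier:
    """Fit a classifier, returning it with loss and metric traces attached."""
    clf = ScatClassifier(config=config, train_config=train_config,
                         validation=validation)
    return clf.fit(X, y)


def kfold_cv(X, y, k: int = 5, config: ScatConfig | None = None,
             train_config: TrainConfig | None = None,
             scope: str = "positive"):
    """Stratified k-fold cross-validation.

    Returns ``(fold_reports, summary)`` where the summary holds the mean and
    standard deviation of each metric plus the report on pooled out-of-fold
    predictions.  Classes with fewer than ``k`` members are merged into the
    nearest-size stratum for splitting only (their labels are untouched).
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(y) < k:
        raise ValueError("dataset smaller than k")
    seed = (train_config or TrainConfig()).seed
    strat = y.astype(object).copy()
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < k]
    if len(small):
        warnings.warn(
            f"classes {list(small)} have fewer than {k} members; merged into "
            "nearest-size stratum for fold assignment", stacklevel=2)
        big_classes = classes[counts >= k]
        if not len(big_classes):
            strat[:] = "all"
        else:
            for c in small:
                c_count = counts[list(classes).index(c)]
                big_counts = counts[counts >= k]
                target = big_classes[np.argmin(np.abs(big_counts - c_count))]
                strat[y == c] = target
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports, pooled_pred, pooled_gold = [], [None] * len(y), [None] * len(y)
    for train_idx, test_idx in skf.split(np.zeros(len(y)), strat):
        clf = ScatClassifier(config=config, train_config=train_config)
        clf.fit([X[i] for i in train_idx], y[train_idx])
        pred = clf.predict([X[i] for i in test_idx])
        for i, p in zip(test_idx, pred):
            pooled_pred[i], pooled_gold[i] = p, y[i]
        reports.append(evaluate_metrics(list(pred), list(y[test_idx]), scope))
    pooled = evaluate_metrics(pooled_pred, pooled_gold, scope)
    summary = {
        "mean": {m: float(np.mean([getattr(r, m) for r in reports]))
                 for m in ("accuracy", "precision", "recall", "f1")},
        "std": {m: float(np.std([getattr(r, m) for r in reports]))
                for m in ("accuracy", "precision", "recall", "f1")},
        "pooled": pooled,
    }
    return reports, summary
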