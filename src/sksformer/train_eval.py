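"""Training loop, stratified 5-fold cross-validation, and metrics.

Training follows the standard recipe for this model family: Adam at
learning rate 1e-3, batch size 64, categorical cross-entropy, with early
stopping (patience 10) on a 10% validation split and restoration of the
best-validation weights. Cross-validation is stratified and window-wise;
normalization statistics are fitted per fold on the training windows only,
so no validation information leaks into the transform.

Precision/recall/F1 are macro-averaged by default (per-class metrics
averaged with equal class weight); ``average="weighted"`` switches to
support-weighted averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn
from .model import ModelConfig, SKSTransformer
from .preprocess import NormStats, fit_normalizer


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")


@dataclass
class FoldMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def compute_metrics(y_true, y_pred, k: int, average: str = "macro") -> FoldMetrics:
    """Accuracy plus macro- (or weighted-) averaged precision/recall/F1."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, v in (("true", y_true), ("pred", y_pred)):
        if v.size and (v.min() < 0 or v.max() >= k):
            raise ValueError(f"{name} labels outside 0..{k - 1}")
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    total = conf.sum()
    accuracy = float(np.trace(conf)) / total if total else 0.0
    tp = np.diag(conf).astype(float)
    pred_count = conf.sum(axis=0).astype(float)
    true_count = conf.sum(axis=1).astype(float)
    absent = (pred_count == 0) & (true_count == 0)
    if absent.any():
        warnings.warn(
            f"classes {np.flatnonzero(absent).tolist()} absent from truth and "
            "prediction; they contribute 0 to averaged metrics", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_count > 0, tp / pred_count, 0.0)
        recall = np.where(true_count > 0, tp / true_count, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    if average == "macro":
        w = np.full(k, 1.0 / k)
    elif average == "weighted":
        w = true_count / max(total, 1)
    else:
        raise ValueError(f"unknown averaging scheme {average!r}")
    return FoldMetrics(accuracy=accuracy,
                       precision=float(precision @ w),
                       recall=float(recall @ w),
                       f1=float(f1 @ w),
                       confusion=conf)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def evaluate_model(model: SKSTransformer, x: np.ndarray, y: np.ndarray,
                   batch_size: int = 256) -> tuple[float, np.ndarray]:
    model.eval()
    preds = np.concatenate([model.predict(x[i:i + batch_size])
                            for i in range(0, len(x), batch_size)])
    return float(np.mean(preds == y)), preds


def train_model(x: np.ndarray, y: np.ndarray, model_cfg: ModelConfig,
                train_cfg: TrainConfig, model: SKSTransformer | None = None,
                verbose: bool = False):
    """Fit on normalized windows; returns (model, per-epoch log).

    The 10% validation split drives early stopping; the best-validation
    weights are restored before returning. A non-finite loss aborts with
    a diagnostic rather than training onwards from a poisoned state.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=int)
    if len(x) < 1:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(train_cfg.seed)
    n_val = int(round(train_cfg.val_fraction * len(x)))
    order = rng.permutation(len(x))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = order, order[:0]
    model = model if model is not None else SKSTransformer(model_cfg)
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate)
    log: list[dict] = []
    best_state, best_val, since_best = None, -np.inf, 0
    for epoch in range(train_cfg.epochs):
        model.train()
        losses, hits, count = [], 0, 0
        for batch in _batches(len(train_idx), train_cfg.batch_size, rng):
            bi = train_idx[batch]
            logits = model(x[bi])
            loss = nn.cross_entropy(logits, y[bi])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            hits += int((logits.data.argmax(axis=1) == y[bi]).sum())
            count += len(bi)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "train_accuracy": hits / max(count, 1)}
        if len(val_idx):
            val_acc, _ = evaluate_model(model, x[val_idx], y[val_idx])
            entry["val_accuracy"] = val_acc
            if val_acc >= best_val:
                # keep the latest among equally good epochs: more training
                # at the same validation score generalizes no worse
                if val_acc > best_val:
                    since_best = 0
                else:
                    since_best += 1
                best_val, best_state = val_acc, model.state_dict()
            else:
                since_best += 1
            if since_best >= train_cfg.patience:
                log.append(entry)
                break
        log.append(entry)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(
                f"{k}={v:.4f}" for k, v in entry.items() if k != "epoch"))
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, log


@dataclass
class CrossValResult:
    fold_metrics: list[FoldMetrics]
    fold_norm_stats: list[NormStats]
    logs: list[list] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.fold_metrics]))

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(m, name) for m in self.fold_metrics]))

    def summary(self) -> dict:
        return {name: self.mean(name)
                for name in ("accuracy", "precision", "recall", "f1")}


def run_cross_validation(x_raw: np.ndarray, y: np.ndarray,
                         model_cfg: ModelConfig, train_cfg: TrainConfig,
                         model_factory=None,
                         norm_scope: str = "train") -> CrossValResult:
    """Stratified k-fold CV on raw (unnormalized) windows.

    Per fold: fit z-score statistics on the training windows, transform
    both sides, train, evaluate on the held-out fold. Averages over folds
    are unweighted means. Deterministic given the config seeds.
    ``norm_scope="global"`` fits the statistics once on the whole dataset
    instead (leaks held-out values into the transform; provided only for
    compatibility experiments).
    """
    if norm_scope not in ("train", "global"):
        raise ValueError("norm_scope must be 'train' or 'global'")
    x_raw = np.asarray(x_raw, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=int(y.max()) + 1)
    for cls, c in enumerate(counts):
        if 0 < c < train_cfg.folds:
            raise ValueError(
                f"class {cls} has only {c} samples, fewer than {train_cfg.folds} folds")
    k = int(y.max()) + 1
    skf = StratifiedKFold(n_splits=train_cfg.folds, shuffle=True,
                          random_state=train_cfg.seed)
    global_stats = fit_normalizer(x_raw) if norm_scope == "global" else None
    result = CrossValResult(fold_metrics=[], fold_norm_stats=[])
    for fold, (tr, te) in enumerate(skf.split(x_raw, y)):
        stats = global_stats if global_stats is not None \
            else fit_normalizer(x_raw[tr])
        x_tr = (x_raw[tr] - stats.mean) / stats.std
        x_te = (x_raw[te] - stats.mean) / stats.std
        fold_mc = model_cfg.replace(seed=model_cfg.seed + fold)
        fold_tc = replace(train_cfg, seed=train_cfg.seed + 100 * (fold + 1))
        if model_factory is not None:
            model = model_factory(fold_mc)
            model, log = train_model(x_tr, y[tr], fold_mc, fold_tc, model=model)
        else:
            model, log = train_model(x_tr, y[tr], fold_mc, fold_tc)
        _, preds = evaluate_model(model, x_te.astype(np.float32), y[te])
        result.fold_metrics.append(compute_metrics(y[te], preds, k))
        result.fold_norm_stats.append(stats)
        result.logs.append(log)
    return result
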