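"""Training loop, stratified k-fold cross-validation and architecture grid search.

The loss is 2-class cross-entropy on the softmax outputs, minimized with
Adam (default lr 1e-3, batch 64) and early stopping on validation loss.
All randomness — parameter init, shuffling, dropout, fold assignment — is
driven by the single seed in TrainConfig, so runs are bit-reproducible on a
fixed device.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from kcrnet.network import KcrModel, ModelConfig, softmax, stage_shapes
from kcrnet.evaluation import MetricReport, evaluate

__all__ = ["TrainConfig", "FoldSplit", "TrainResult", "fit", "make_folds",
           "cross_validate", "grid_search"]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0
    class_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FoldSplit:
    """A stratified partition of 0..n-1 into k folds."""

    k: int
    assignments: np.ndarray  # (n,) fold id per index

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass
class TrainResult:
    model: KcrModel
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss, train_acc, val_acc
    best_epoch: int


def make_folds(n: int, labels: Sequence[int], k: int, seed: int = 0) -> FoldSplit:
    """Stratified folds: sizes differ by at most 1 and each class is spread
    as evenly as possible (per-class round-robin after a seeded shuffle)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=np.int64)
    # offset continues across classes so overall fold sizes stay balanced
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            assignments[i] = (offset + j) % k
        offset += len(idx)
    return FoldSplit(k=k, assignments=assignments)


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _SGD:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr

    def step(self):
        for p in self.params:
            p.value -= self.lr * p.grad


def _xent_and_grad(logits: np.ndarray, y: np.ndarray):
    p = softmax(logits)
    n = len(y)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), y] + eps))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n, p


def _epoch_eval(model: KcrModel, X: np.ndarray, y: np.ndarray, batch: int = 256):
    losses, correct = [], 0
    for i in range(0, len(X), batch):
        logits = model.forward_logits(X[i : i + batch], train=False)
        loss, _, p = _xent_and_grad(logits, y[i : i + batch])
        losses.append(loss * len(p))
        correct += int((p.argmax(axis=1) == y[i : i + batch]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def fit(
    X: np.ndarray,
    y: Sequence[int],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> TrainResult:
    """Train a model on an encoded dataset (X of shape (N, C, L), y in {0,1}).

    A stratified ``validation_fraction`` of the data is held out for early
    stopping; the weights from the best validation epoch are restored.
    """
    model_config = model_config or ModelConfig()
    cfg = train_config or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(X) == 0:
        raise ValueError("empty dataset")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    # stratified validation split via a k-fold assignment with k=1/fraction
    k = max(2, int(round(1.0 / cfg.validation_fraction)))
    split = make_folds(len(y), y, k=k, seed=cfg.seed)
    val_idx = split.test_indices(0)
    tr_idx = split.train_indices(0)
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    model = KcrModel(model_config, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = (_Adam if cfg.optimizer == "adam" else _SGD)(model.parameters(), cfg.learning_rate)

    best_val = np.inf
    best_epoch = -1
    best_state = None
    rows = []
    wait = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        ep_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            if len(sel) < 2:
                continue  # BN needs >= 2 samples
            model.zero_grad()
            logits = model.forward_logits(Xtr[sel], train=True, rng=rng)
            loss, dlogits, _ = _xent_and_grad(logits, ytr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            model.backward(dlogits)
            opt.step()
            ep_loss += loss * len(sel)
            seen += len(sel)
        train_loss, train_acc = _epoch_eval(model, Xtr, ytr)
        val_loss, val_acc = _epoch_eval(model, Xval, yval)
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
             "train_acc": train_acc, "val_acc": val_acc}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_state = [p.value.copy() for p in model.parameters()]
            best_bn = [(bn.running_mean.copy(), bn.running_var.copy())
                       for bn in model._bn_layers()]
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    if best_state is not None:
        for p, v in zip(model.parameters(), best_state):
            p.value[...] = v
        for bn, (rm, rv) in zip(model._bn_layers(), best_bn):
            bn.running_mean[...] = rm
            bn.running_var[...] = rv
    return TrainResult(model=model, history=pd.DataFrame(rows), best_epoch=best_epoch)


def cross_validate(
    X_windows,
    labels: Sequence[int],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    encoder=None,
) -> tuple[list[MetricReport], pd.DataFrame]:
    """k-fold cross-validation with per-fold encoding to avoid leakage.

    ``X_windows`` is either an already-encoded (N, C, L) array (then
    ``encoder`` is ignored) or a sequence of peptide windows together with an
    ``encoder`` callable ``(train_windows, all_windows) -> (N, C, L)`` that
    fits its embedding on the training portion only.
    Returns the per-fold reports and a summary frame (per-fold rows plus
    mean/sd rows).
    """
    cfg = train_config or TrainConfig()
    y = np.asarray(labels, dtype=np.int64)
    split = make_folds(len(y), y, k=k, seed=cfg.seed)
    reports: list[MetricReport] = []
    rows = []
    for fold in range(k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        if encoder is None:
            X = np.asarray(X_windows, dtype=np.float64)
            Xtr, Xte = X[tr], X[te]
        else:
            train_windows = [X_windows[i] for i in tr]
            Xall = encoder(train_windows, X_windows)
            Xtr, Xte = Xall[tr], Xall[te]
        res = fit(Xtr, y[tr], model_config, cfg)
        scores = res.model.predict_proba(Xte)[:, 1]
        rep = evaluate(scores, y[te], threshold=cfg.class_threshold)
        reports.append(rep)
        rows.append({"fold": fold, **rep.to_dict()})
    df = pd.DataFrame(rows)
    metric_cols = ["sn", "sp", "acc", "mcc", "auc"]
    mean_row = {"fold": "mean", **df[metric_cols].mean().to_dict()}
    sd_row = {"fold": "sd", **df[metric_cols].std(ddof=1).to_dict()}
    summary = pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)
    return reports, summary


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    blocks_grid: Sequence[int],
    layers_grid: Sequence[int],
    train_config: TrainConfig | None = None,
    base_config: ModelConfig | None = None,
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Evaluate every (n_blocks, layers_per_block) combination on a held-out
    split; the best feasible row (Acc, then MCC, then fewer parameters) is
    flagged in the ``best`` column.  A combination whose transitions would
    shrink the length below 1 is marked infeasible, not an error.
    """
    if not blocks_grid or not layers_grid:
        raise ValueError("grids must be non-empty")
    cfg = train_config or TrainConfig()
    base = base_config or ModelConfig()
    y = np.asarray(y, dtype=np.int64)
    X = np.asarray(X, dtype=np.float64)
    k = max(2, int(round(1.0 / test_fraction)))
    split = make_folds(len(y), y, k=k, seed=cfg.seed)
    te, tr = split.test_indices(0), split.train_indices(0)

    rows = []
    for nb in blocks_grid:
        for nl in layers_grid:
            row = {"n_blocks": nb, "layers_per_block": nl}
            if base.input_length < 2 ** (nb - 1):
                row.update({"feasible": False, "sn": np.nan, "sp": np.nan,
                            "acc": np.nan, "mcc": np.nan, "auc": np.nan,
                            "n_parameters": np.nan})
                rows.append(row)
                continue
            mc = ModelConfig(**{**asdict(base), "n_blocks": nb, "layers_per_block": nl})
            res = fit(X[tr], y[tr], mc, cfg)
            scores = res.model.predict_proba(X[te])[:, 1]
            rep = evaluate(scores, y[te], threshold=cfg.class_threshold)
            row.update({"feasible": True, **rep.to_dict(),
                        "n_parameters": res.model.n_parameters})
            rows.append(row)
    df = pd.DataFrame(rows)
    df["best"] = False
    feas = df[df["feasible"]]
    if len(feas):
        ranked = feas.sort_values(
            by=["acc", "mcc", "n_parameters"], ascending=[False, False, True]
        )
        df.loc[ranked.index[0], "best"] = True
    return df
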