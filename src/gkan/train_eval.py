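"""Training, five-fold evaluation and ablation sweeps.

The classifier is optimized with AdamW on cross-entropy plus the KAN
sparsity penalty, optionally tracking an exponential moving average (EMA)
of the weights that is swapped in for evaluation.  Metrics follow the
standard binary panel — MCC (the headline metric), accuracy, ROC-AUC,
precision, recall, F1 — reported per fold and as mean ± std.

The ablation sweep retrains the LKAN classifier over a grid of
(spline grid size G, number of replaced blocks N) and tabulates F1,
parameter count, train-vs-test gap and per-batch wall time; the parameter
column grows linearly in G, the timing column is hardware-dependent and
reported for orientation only.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .architectures import (GANConfig, ModelConfig, build_classifier,
                            build_gan, softmax_channels, wgan_train_step)
from .autograd import Tensor, no_grad
from .kan_layers import ConvKAN, LinearKAN, kan_regularization
from .nn import Module
from .optim import EMA, AdamW
from .synthetic_data import LabeledSequenceSet, one_hot_encode

__all__ = [
    "TrainConfig", "MetricsReport", "TrainingDivergence", "compute_metrics",
    "train_classifier", "cross_validate", "ablation_sweep", "predict_proba",
    "train_wgan",
]


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 64
    learning_rate: float = 3e-3
    weight_decay: float = 0.0
    kan_l1_weight: float = 0.0
    kan_entropy_weight: float = 0.0
    ema_decay: float = 0.0  # 0 disables the shadow's lag entirely
    use_ema: bool = False
    early_stop_patience: int | None = None
    stop_at_val_mcc: float | None = None  # stop once validation MCC reaches this
    validation_fraction: float = 0.1
    seed: int = 0

    def validate(self):
        for name in ("learning_rate", "weight_decay", "kan_l1_weight",
                     "kan_entropy_weight"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("ema_decay must be in [0, 1)")


class TrainingDivergence(RuntimeError):
    """Raised when the loss goes non-finite; carries the last good weights."""

    def __init__(self, message: str, last_good_state: dict | None = None):
        super().__init__(message)
        self.last_good_state = last_good_state


@dataclass
class MetricsReport:
    """Per-fold metric rows plus mean/std aggregation."""

    per_fold: list[dict] = field(default_factory=list)

    METRICS = ("mcc", "accuracy", "roc_auc", "precision", "recall", "f1")

    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for m in self.METRICS:
            vals = [row[m] for row in self.per_fold if row.get(m) is not None]
            if vals:
                out[m] = (float(np.mean(vals)), float(np.std(vals)))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_fold)

    def summary(self) -> str:
        agg = self.aggregate()
        return "  ".join(f"{m}={mu:.3f}±{sd:.3f}" for m, (mu, sd) in agg.items())


def matthews_corrcoef(tp: int, fn: int, fp: int, tn: int) -> float:
    """MCC from confusion counts; 0 when any marginal is empty."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(float(denom)))


def compute_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Binary metric panel from true labels and positive-class scores.

    ROC-AUC is rank-based and threshold-free; with a single class present it
    is undefined and reported as None (never silently 0.5).  MCC uses the
    degenerate-denominator convention MCC = 0.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    preds = (scores >= threshold).astype(int)
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    n = len(labels)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    auc = None
    if len(np.unique(labels)) == 2:
        auc = float(roc_auc_score(labels, scores))
    return {
        "mcc": matthews_corrcoef(tp, fn, fp, tn),
        "accuracy": (tp + tn) / n,
        "roc_auc": auc,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
    }


# -- classifier training ----------------------------------------------------

def _cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    shifted = logits - logits.max(axis=1, keepdims=True)
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    ll = shifted[np.arange(len(y)), y] - lse.reshape(len(y))
    return -ll.mean()


def _kan_penalty(model: Module, l1: float, ent: float) -> Tensor | None:
    if l1 == 0 and ent == 0:
        return None
    total = None
    for _, m in model.named_modules():
        if isinstance(m, (LinearKAN, ConvKAN)):
            term = kan_regularization(m, l1, ent)
            total = term if total is None else total + term
    return total


def predict_proba(model: Module, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Positive-class probability for one-hot inputs (n, 4, L)."""
    model.eval()
    out = []
    with no_grad():
        for s in range(0, len(x), batch_size):
            logits = model(Tensor(x[s:s + batch_size])).data
            z = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            out.append(p[:, 1])
    model.train()
    return np.concatenate(out)


def train_classifier(model: Module, data: LabeledSequenceSet, fold: int,
                     config: TrainConfig) -> tuple[Module, dict]:
    """Train on all folds but ``fold``; returns (model, history).

    A stratified ``validation_fraction`` of the training split is held out
    for the per-epoch validation loss used by early stopping; with EMA
    enabled, validation and final weights come from the shadow copy.
    """
    config.validate()
    train_idx, _ = data.fold_split(fold)
    rng = np.random.default_rng(config.seed)
    y_all = data.labels[train_idx]
    val_idx, fit_idx = [], []
    for lab in np.unique(y_all):
        idx = train_idx[y_all == lab]
        idx = rng.permutation(idx)
        n_val = max(1, int(round(len(idx) * config.validation_fraction)))
        val_idx.extend(idx[:n_val])
        fit_idx.extend(idx[n_val:])
    fit_idx, val_idx = np.array(fit_idx), np.array(val_idx)
    x_fit = one_hot_encode([data.sequences[i] for i in fit_idx])
    y_fit = data.labels[fit_idx]
    x_val = one_hot_encode([data.sequences[i] for i in val_idx])
    y_val = data.labels[val_idx]

    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    ema = EMA(model, config.ema_decay) if config.use_ema else None
    history = {"train_loss": [], "val_loss": [], "val_mcc": []}
    best_val, since_best = np.inf, 0
    last_good = model.state_dict()
    for epoch in range(config.epochs):
        order = rng.permutation(len(fit_idx))
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, len(order), config.batch_size):
            sel = order[s:s + config.batch_size]
            logits = model(Tensor(x_fit[sel]))
            loss = _cross_entropy(logits, y_fit[sel])
            penalty = _kan_penalty(model, config.kan_l1_weight,
                                   config.kan_entropy_weight)
            if penalty is not None:
                loss = loss + penalty
            if not np.isfinite(loss.item()):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch}", last_good)
            model.zero_grad()
            loss.backward()
            opt.step()
            if ema is not None:
                ema.update()
            epoch_loss += loss.item()
            n_batches += 1
        backup = ema.swap_in() if ema is not None else None
        scores = predict_proba(model, x_val)
        val = compute_metrics(y_val, scores)
        val_loss = _val_loss(y_val, scores)
        if backup is not None:
            ema.swap_out(backup)
        history["train_loss"].append(epoch_loss / max(1, n_batches))
        history["val_loss"].append(val_loss)
        history["val_mcc"].append(val["mcc"])
        last_good = model.state_dict()
        if (config.stop_at_val_mcc is not None
                and val["mcc"] >= config.stop_at_val_mcc):
            break
        if val_loss < best_val - 1e-6:
            best_val, since_best = val_loss, 0
        else:
            since_best += 1
            if (config.early_stop_patience is not None
                    and since_best > config.early_stop_patience):
                break
    if ema is not None and config.epochs > 0:
        model.load_state_dict(ema.shadow)  # parameters only; buffers stay
    return model, history


def _val_loss(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def evaluate_fold(model: Module, data: LabeledSequenceSet, fold: int) -> dict:
    _, test_idx = data.fold_split(fold)
    x = one_hot_encode([data.sequences[i] for i in test_idx])
    y = data.labels[test_idx]
    scores = predict_proba(model, x)
    row = compute_metrics(y, scores)
    row["fold"] = fold
    return row


def cross_validate(model_config: ModelConfig, data: LabeledSequenceSet,
                   train_config: TrainConfig) -> MetricsReport:
    """Train one model per fold (fresh seed = seed + fold); aggregate panel."""
    n_folds = int(data.fold_ids.max()) + 1
    report = MetricsReport()
    for fold in range(n_folds):
        cfg = dataclasses.replace(model_config, seed=model_config.seed + fold)
        tcfg = dataclasses.replace(train_config, seed=train_config.seed + fold)
        model = build_classifier(cfg)
        model, history = train_classifier(model, data, fold, tcfg)
        row = evaluate_fold(model, data, fold)
        row["train_loss_final"] = history["train_loss"][-1] if history["train_loss"] else None
        report.per_fold.append(row)
    return report


def ablation_sweep(base_config: ModelConfig, grid_sizes: list[int],
                   replaced_counts: list[int], data: LabeledSequenceSet,
                   train_config: TrainConfig, fold: int = 0) -> pd.DataFrame:
    """F1 / parameter-count / overfit-gap table over (grid size, replaced blocks).

    One row per (G, N) cell, trained on the given fold.  N = 0 cells are the
    baseline architecture (zero replacements); the parameter column grows
    strictly with G whenever N > 0.  Per-batch time is wall-clock and
    hardware-dependent — reported for the scaling curve, not for comparison
    across machines.
    """
    from .kan_layers import count_parameters

    rows = []
    for g in grid_sizes:
        for n_repl in replaced_counts:
            if not 0 <= n_repl <= base_config.num_blocks:
                raise ValueError(f"replaced count {n_repl} out of range")
            cfg = dataclasses.replace(base_config, variant="lkan",
                                      grid_size=g, replaced_blocks=n_repl)
            model = build_classifier(cfg)
            t0 = time.perf_counter()
            model, history = train_classifier(model, data, fold, train_config)
            elapsed = time.perf_counter() - t0
            test_row = evaluate_fold(model, data, fold)
            train_idx, _ = data.fold_split(fold)
            x_tr = one_hot_encode([data.sequences[i] for i in train_idx])
            train_row = compute_metrics(data.labels[train_idx],
                                        predict_proba(model, x_tr))
            n_steps = max(1, len(history["train_loss"])) * max(
                1, int(np.ceil(len(train_idx) * 0.9 / train_config.batch_size)))
            rows.append({
                "grid_size": g,
                "replaced_blocks": n_repl,
                "f1": test_row["f1"],
                "mcc": test_row["mcc"],
                "train_f1": train_row["f1"],
                "overfit_gap": train_row["f1"] - test_row["f1"],
                "params": count_parameters(model),
                "sec_per_batch": elapsed / n_steps,
            })
    return pd.DataFrame(rows)


# -- GAN training -----------------------------------------------------------

def train_wgan(onehot_data: np.ndarray, config: GANConfig, n_steps: int,
               batch_size: int = 32, lr: float = 1e-4,
               seed: int = 0, log_every: int = 50) -> tuple:
    """Adversarial training on one-hot sequences; returns (gen, critic, history)."""
    gen, critic = build_gan(config)
    opt_g = AdamW(gen.parameters(), lr=lr, betas=(0.5, 0.9))
    opt_c = AdamW(critic.parameters(), lr=lr, betas=(0.5, 0.9))
    rng = np.random.default_rng(seed)
    history = []
    n = len(onehot_data)
    for step in range(n_steps):
        sel = rng.choice(n, size=min(batch_size, n), replace=False)
        record = wgan_train_step(gen, critic, onehot_data[sel], config, rng,
                                 opt_g, opt_c)
        if step % log_every == 0 or step == n_steps - 1:
            history.append({"step": step, **record})
    return gen, critic, history
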