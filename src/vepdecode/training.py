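"""Training protocol, data splits, cross-validation and evaluation reports.

Training minimises cross-entropy with AdamW (Adam + decoupled weight decay)
under a one-cycle learning-rate schedule.  Per subject, the recording with
the fewest missing trials is the hold-out test set, one further recording is
the validation set, and models are finally retrained on train+validation
before the single test-set evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import nn
from .models import EEGNetConfig, ModelHandle, build_eegnet, build_eegnet_plus
from .nn import Tensor, cross_entropy_logits
from .nn.optim import AdamW, one_cycle_lr
from .preprocessing import EpochSet


@dataclass
class TrainConfig:
    max_lr: float = 2e-3
    weight_decay: float = 1e-2
    one_cycle: bool = True
    epochs: int = 30
    batch_size: int = 128
    seed: int = 0
    warmup_frac: float = 0.3
    div_factor: float = 25.0
    final_div_factor: float = 1e4

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.max_lr <= 0:
            raise ValueError("max_lr must be positive")


@dataclass
class TrainHistory:
    epoch: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1

    def to_csv(self, path: str | Path):
        pd.DataFrame({k: getattr(self, k) for k in
                      ("epoch", "train_loss", "train_acc",
                       "val_loss", "val_acc", "lr")}).to_csv(path, index=False)


def _eval_loss_acc(handle: ModelHandle, data: np.ndarray, labels: np.ndarray,
                   batch_size: int = 256) -> tuple[float, float]:
    logits = handle.logits(data, batch_size=batch_size)
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1)) - z[np.arange(len(labels)), labels]
    return float(lse.mean()), float((logits.argmax(axis=1) == labels).mean())


def train_classifier(handle: ModelHandle, train: EpochSet, val: EpochSet | None,
                     cfg: TrainConfig) -> tuple[ModelHandle, TrainHistory]:
    """Train in place; returns the handle restored to its best-validation
    epoch (final weights when no validation set is given) plus the history."""
    x = np.asarray(train.retained_data(), dtype=nn.DTYPE)
    y = train.retained_labels().astype(np.int64)
    if len(x) == 0:
        raise ValueError("empty training split")
    if val is not None and val.n_retained == 0:
        raise ValueError("empty validation split")
    rng = np.random.default_rng(cfg.seed)
    handle.network.seed_rng(cfg.seed + 1)
    net = handle.network
    opt = AdamW(net.parameters(), lr=cfg.max_lr, weight_decay=cfg.weight_decay)
    n = len(x)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    total_steps = steps_per_epoch * cfg.epochs
    history = TrainHistory()
    best_state, best_val, best_epoch = None, -np.inf, -1
    step = 0
    for epoch in range(cfg.epochs):
        net.train()
        order = rng.permutation(n)
        losses, hits = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = Tensor(x[idx, None, :, :])
            if cfg.one_cycle:
                opt.lr = one_cycle_lr(step, total_steps, cfg.max_lr,
                                      warmup_frac=cfg.warmup_frac,
                                      div_factor=cfg.div_factor,
                                      final_div_factor=cfg.final_div_factor)
            logits = net(xb)
            loss = cross_entropy_logits(logits, y[idx])
            net.zero_grad()
            loss.backward()
            opt.step()
            step += 1
            losses.append(loss.item())
            hits += int((logits.data.argmax(axis=1) == y[idx]).sum())
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.train_acc.append(hits / n)
        history.lr.append(opt.lr)
        if val is not None:
            vl, va = _eval_loss_acc(handle, val.retained_data(),
                                    val.retained_labels().astype(np.int64))
            history.val_loss.append(vl)
            history.val_acc.append(va)
            if va > best_val:
                best_val, best_epoch = va, epoch
                best_state = net.state_dict()
        else:
            history.val_loss.append(np.nan)
            history.val_acc.append(np.nan)
    if best_state is not None:
        net.load_state_dict(best_state)
        history.best_epoch = best_epoch
    else:
        history.best_epoch = cfg.epochs - 1
    return handle, history


@dataclass
class SplitPlan:
    train_idx: list[int]
    val_idx: int
    test_idx: int

    def __post_init__(self):
        all_idx = set(self.train_idx) | {self.val_idx, self.test_idx}
        if len(all_idx) != len(self.train_idx) + 2:
            raise ValueError("train/val/test must be pairwise disjoint")


def make_split(recordings: list[EpochSet]) -> SplitPlan:
    """Test = recording with the fewest missing trials (ties: lowest session
    index); validation = next fewest; the rest train."""
    if len(recordings) < 3:
        raise ValueError("need at least 3 recordings per subject")
    drops = [r.n_dropped for r in recordings]
    test = int(np.argmin(drops))                      # argmin takes lowest index on ties
    rest = [i for i in range(len(recordings)) if i != test]
    val = min(rest, key=lambda i: (drops[i], i))
    train = [i for i in rest if i != val]
    return SplitPlan(train_idx=train, val_idx=val, test_idx=test)


def merge_epochs(recordings: list[EpochSet]) -> EpochSet:
    return EpochSet(
        data=np.concatenate([r.data for r in recordings]),
        labels=np.concatenate([r.labels for r in recordings]),
        retained=np.concatenate([r.retained for r in recordings]),
        session_id="+".join(r.session_id for r in recordings),
        fs_hz=recordings[0].fs_hz,
        image_ids=None,
        normalized=all(r.normalized for r in recordings),
        provenance=["merged"])


@dataclass
class EvaluationReport:
    accuracy: float                          # fraction in [0, 1]
    per_class_accuracy: np.ndarray
    confusion: np.ndarray                    # rows = truth, cols = prediction

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps({
            "accuracy_pct": self.accuracy_pct,
            "per_class_accuracy_pct": (100 * self.per_class_accuracy).tolist(),
        }, indent=2))

    def confusion_csv(self, path: str | Path):
        pd.DataFrame(self.confusion).to_csv(path, index=False)


def evaluate(handle: ModelHandle, test: EpochSet,
             n_classes: int | None = None) -> EvaluationReport:
    if test.n_retained == 0:
        raise ValueError("empty test set")
    n_classes = n_classes or handle.config.n_classes
    y = test.retained_labels().astype(np.int64)
    pred = handle.predict(test.retained_data())
    cm = confusion_matrix(y, pred, labels=np.arange(n_classes))
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_sums > 0, cm.diagonal() / row_sums, np.nan)
    return EvaluationReport(accuracy=float(cm.trace() / cm.sum()),
                            per_class_accuracy=per_class, confusion=cm)


def grid_search(grid: list[EEGNetConfig], recordings: list[EpochSet],
                split: SplitPlan, cfg: TrainConfig, kind: str = "eegnet"
                ) -> tuple[EEGNetConfig, ModelHandle, pd.DataFrame]:
    """Pick the config with the best validation accuracy (ties: fewer
    parameters), then retrain it on train+validation."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    train = merge_epochs([recordings[i] for i in split.train_idx])
    val = recordings[split.val_idx]
    rows = []
    builder = build_eegnet if kind == "eegnet" else build_eegnet_plus
    for j, config in enumerate(grid):
        handle = builder(config, seed=cfg.seed + j)
        handle, _ = train_classifier(handle, train, val, cfg)
        _, va = _eval_loss_acc(handle, val.retained_data(),
                               val.retained_labels().astype(np.int64))
        rows.append({"config_index": j, "val_accuracy": va,
                     "n_parameters": handle.n_parameters})
    table = pd.DataFrame(rows)
    best_j = int(table.sort_values(
        ["val_accuracy", "n_parameters", "config_index"],
        ascending=[False, True, True]).iloc[0]["config_index"])
    final = builder(grid[best_j], seed=cfg.seed + best_j)
    final, _ = train_classifier(final, merge_epochs([train, val]), None, cfg)
    return grid[best_j], final, table


def cross_validate(cfg: TrainConfig, recordings: list[EpochSet],
                   config: EEGNetConfig | None = None,
                   split: SplitPlan | None = None, kind: str = "eegnet"
                   ) -> tuple[np.ndarray, float]:
    """Leave-one-recording-out over the non-test recordings (fold order =
    session index); returns per-fold accuracies and their mean."""
    split = split or make_split(recordings)
    fold_idx = sorted(split.train_idx + [split.val_idx])
    if len(fold_idx) < 2:
        raise ValueError("need at least 2 non-test recordings")
    builder = build_eegnet if kind == "eegnet" else build_eegnet_plus
    accs = []
    for held in fold_idx:
        train = merge_epochs([recordings[i] for i in fold_idx if i != held])
        handle = builder(config or EEGNetConfig(), seed=cfg.seed)
        handle, _ = train_classifier(handle, train, None, cfg)
        accs.append(evaluate(handle, recordings[held]).accuracy)
    accs = np.asarray(accs)
    return accs, float(accs.mean())


def chance_level(n_classes: int) -> float:
    """Expected accuracy (fraction) of a uniform-random predictor on a
    class-balanced set."""
    return 1.0 / n_classes
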