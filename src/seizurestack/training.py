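"""Two-phase training: population base models, then patient fine-tuning.

Phase 1 trains each backbone on every patient *except* the target, to
learn transferable seizure patterns.  Phase 2 continues from the base
weights on the target patient's own training split with a reduced
learning rate (``finetune_lr_factor``, default 0.1), adapting the model
to that patient's EEG without destroying the population weights.

Optimization: Adam on the mean binary cross-entropy with L2 weight decay,
validation loss (and accuracy/precision/recall/F1/AUC) evaluated every
epoch, early stopping on the validation loss with a patience counter, and
the best-validation-loss weights retained in the returned checkpoint.
"""

from __future__ import annotations

import copy
import csv
import json
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .ensemble import confusion, metrics_from_confusion, roc_auc
from .io import SpectrogramDataset
from .models import ModelConfig, build_model
from .types import ValidationError

__all__ = [
    "TrainConfig",
    "EarlyStopState",
    "Checkpoint",
    "LabeledImages",
    "CohortSplits",
    "split_cohort",
    "split_train_val",
    "train",
    "early_stop_update",
    "personalize",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 200
    patience: int = 20
    base_lr: float = 1e-3
    finetune_lr_factor: float = 0.1
    batch_size: int = 32
    weight_decay: float = 1e-4
    seed: int = 0
    val_fraction: float = 0.15
    test_fraction: float = 0.15
    pos_weight: float | None = None  # optional imbalance correction, off by default

    def __post_init__(self):
        if self.max_epochs > 0 and not self.patience < self.max_epochs:
            raise ValidationError("patience must be smaller than max_epochs")
        if not 0.0 < self.finetune_lr_factor < 1.0:
            raise ValidationError("finetune_lr_factor must be in (0, 1)")
        for name in ("val_fraction", "test_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")
        if self.val_fraction + self.test_fraction >= 1.0:
            raise ValidationError("val_fraction + test_fraction must be < 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass
class EarlyStopState:
    best_val_loss: float = np.inf
    best_epoch: int = 0
    epochs_since_improve: int = 0
    epoch: int = 0
    stopped: bool = False


def early_stop_update(state: EarlyStopState, val_loss: float,
                      patience: int) -> EarlyStopState:
    """Advance the early-stopping state by one epoch.

    Improvement means a *strict* decrease of the best validation loss;
    ties and NaNs count toward the patience counter (NaN with a warning).
    ``stopped`` becomes true exactly when the counter reaches ``patience``.
    """
    s = copy.copy(state)
    s.epoch += 1
    if np.isnan(val_loss):
        warnings.warn(f"epoch {s.epoch}: validation loss is NaN; treated as no improvement")
        improved = False
    else:
        improved = val_loss < s.best_val_loss
    if improved:
        s.best_val_loss = float(val_loss)
        s.best_epoch = s.epoch
        s.epochs_since_improve = 0
    else:
        s.epochs_since_improve += 1
    s.stopped = s.epochs_since_improve >= patience
    return s


@dataclass
class LabeledImages:
    """A stack of spectrogram images with binary labels."""

    X: np.ndarray  # [n, H, W]
    y: np.ndarray  # [n] in {0,1}

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.X) != len(self.y):
            raise ValidationError("images and labels differ in length")

    def __len__(self):
        return len(self.y)

    @classmethod
    def from_dataset(cls, ds: SpectrogramDataset) -> "LabeledImages":
        return cls(ds.stacked(), ds.labels)


@dataclass
class Checkpoint:
    """Best-validation weights plus the run's full per-epoch history."""

    state: dict[str, np.ndarray]
    model_config: ModelConfig
    train_config: TrainConfig
    history: list[dict]  # per epoch: train/val loss + val metrics
    best_epoch: int
    phase: str = "base"  # "base" or "personalized"


@dataclass
class CohortSplits:
    base_train: SpectrogramDataset
    target_train: SpectrogramDataset
    target_val: SpectrogramDataset
    target_test: SpectrogramDataset


def _allocate_per_class(counts: dict[int, int], total: int) -> dict[int, int]:
    """Largest-remainder proportional allocation of `total` across classes."""
    n = sum(counts.values())
    quota = {c: total * m / n for c, m in counts.items()}
    alloc = {c: int(np.floor(q)) for c, q in quota.items()}
    rem = total - sum(alloc.values())
    for c in sorted(counts, key=lambda c: quota[c] - alloc[c], reverse=True):
        if rem <= 0:
            break
        alloc[c] += 1
        rem -= 1
    return alloc


def split_cohort(dataset: SpectrogramDataset, target_patient: str,
                 cfg: TrainConfig) -> CohortSplits:
    """Leave-one-patient-out split plus chronologically-stratified target
    splits.

    base_train holds every window of every non-target patient.  The
    target's windows are split into train / validation / test with
    floor(test_fraction*n) test and floor(val_fraction*n) validation
    windows, allocated across the two classes proportionally (largest
    remainder, at least one window of each class where possible).  Within
    each class the *latest* windows form the test set and the preceding
    ones the validation set, so overlapping neighbours never straddle
    splits in the optimistic direction (adjacent 8 s / 4 s windows share
    samples).
    """
    pids = np.asarray(dataset.patient_ids)
    if target_patient not in pids:
        raise ValidationError(f"target patient {target_patient!r} not in dataset")
    if len(set(dataset.patient_ids)) < 2:
        raise ValidationError("cohort must contain at least 2 patients")
    base_idx = np.flatnonzero(pids != target_patient)
    tgt_idx = np.flatnonzero(pids == target_patient)
    order = np.argsort(dataset.window_starts[tgt_idx], kind="stable")
    tgt_idx = tgt_idx[order]
    labels = dataset.labels[tgt_idx]
    n = len(tgt_idx)
    n_test = int(np.floor(cfg.test_fraction * n))
    n_val = int(np.floor(cfg.val_fraction * n))
    counts = {int(c): int(m) for c, m in zip(*np.unique(labels, return_counts=True))}
    test_alloc = _allocate_per_class(counts, n_test)
    val_alloc = _allocate_per_class(counts, n_val)
    # both classes should appear in val and test where the class has spares
    for alloc, other in ((test_alloc, val_alloc), (val_alloc, test_alloc)):
        for c in counts:
            spare = counts[c] - other[c]
            if alloc[c] == 0 and spare >= 1 and sum(alloc.values()) >= 2:
                donor = max((d for d in counts if d != c and alloc[d] >= 1),
                            key=lambda d: alloc[d], default=None)
                if donor is not None:
                    alloc[donor] -= 1
                    alloc[c] += 1
    train_i, val_i, test_i = [], [], []
    for c, m in counts.items():
        cls = tgt_idx[labels == c]  # already chronological
        t, v = test_alloc.get(c, 0), val_alloc.get(c, 0)
        train_i.extend(cls[:m - v - t])
        val_i.extend(cls[m - v - t:m - t])
        test_i.extend(cls[m - t:])
    return CohortSplits(
        base_train=dataset.subset(base_idx),
        target_train=dataset.subset(np.sort(train_i)),
        target_val=dataset.subset(np.sort(val_i)),
        target_test=dataset.subset(np.sort(test_i)),
    )


def split_train_val(ds: SpectrogramDataset, val_fraction: float
                    ) -> tuple[SpectrogramDataset, SpectrogramDataset]:
    """Chronological train/val split within each patient (for phase 1)."""
    pids = np.asarray(ds.patient_ids)
    train_idx, val_idx = [], []
    for pid in sorted(set(ds.patient_ids)):
        idx = np.flatnonzero(pids == pid)
        idx = idx[np.argsort(ds.window_starts[idx], kind="stable")]
        n_val = int(np.floor(val_fraction * len(idx)))
        cut = len(idx) - n_val
        train_idx.extend(idx[:cut])
        val_idx.extend(idx[cut:])
    return ds.subset(np.asarray(train_idx)), ds.subset(np.asarray(val_idx))


def _eval_split(model: nn.Module, data: LabeledImages, batch_size: int,
                pos_weight: float | None) -> tuple[float, np.ndarray]:
    model.eval()
    losses, probs = [], []
    for i in range(0, len(data), batch_size):
        xb = nn.Tensor(data.X[i:i + batch_size, None])
        yb = data.y[i:i + batch_size]
        logits = model(xb)
        losses.append(
            nn.binary_cross_entropy_with_logits(logits, yb, pos_weight).item()
            * len(yb)
        )
        probs.append(1.0 / (1.0 + np.exp(-logits.data)))
    return float(np.sum(losses) / len(data)), np.concatenate(probs)


def _metric_row(y: np.ndarray, probs: np.ndarray) -> dict:
    cm = confusion(y, probs)
    row = metrics_from_confusion(cm).copy()
    row.pop("flags", None)
    if len(np.unique(y)) == 2:
        row["auc"] = roc_auc(y, probs)[0]
    else:
        row["auc"] = float("nan")
    return row


def train(model: nn.Module, train_set: LabeledImages, val_set: LabeledImages,
          cfg: TrainConfig, lr: float | None = None,
          val_loss_hook=None, phase: str = "base") -> Checkpoint:
    """Optimize a model and return the best-validation-loss checkpoint.

    ``val_loss_hook(epoch)`` optionally overrides the measured validation
    loss (diagnostics: lets scripted loss sequences exercise the early
    stopping logic end to end).  ``lr`` overrides cfg.base_lr (used by the
    fine-tuning phase).
    """
    if len(train_set) == 0:
        raise ValidationError("empty training set")
    for name, split in (("train", train_set), ("val", val_set)):
        if len(np.unique(split.y)) < 2:
            warnings.warn(f"{name} split contains a single class")

    rng = np.random.default_rng(cfg.seed)
    nn.seed_dropout(int(rng.integers(2 ** 31)))
    opt = nn.Adam(model.parameters(), lr=lr if lr is not None else cfg.base_lr,
                  weight_decay=cfg.weight_decay)
    es = EarlyStopState()
    history: list[dict] = []
    best_state = model.state_dict()
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        order = rng.permutation(len(train_set))
        tr_loss_sum = 0.0
        tr_probs = np.empty(len(train_set))
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            xb = nn.Tensor(train_set.X[sel][:, None])
            yb = train_set.y[sel]
            logits = model(xb)
            loss = nn.binary_cross_entropy_with_logits(logits, yb, cfg.pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            tr_loss_sum += loss.item() * len(sel)
            tr_probs[sel] = 1.0 / (1.0 + np.exp(-logits.data))
        val_loss, val_probs = _eval_split(model, val_set, cfg.batch_size,
                                          cfg.pos_weight)
        if val_loss_hook is not None:
            val_loss = float(val_loss_hook(epoch))
        row = {"epoch": epoch, "train_loss": tr_loss_sum / len(train_set),
               "val_loss": val_loss}
        row.update({f"train_{k}": v for k, v in
                    _metric_row(train_set.y, tr_probs).items()})
        row.update({f"val_{k}": v for k, v in
                    _metric_row(val_set.y, val_probs).items()})
        history.append(row)
        es = early_stop_update(es, val_loss, cfg.patience)
        if es.best_epoch == epoch:
            best_state = model.state_dict()
        if es.stopped:
            break
    model.load_state_dict(best_state)
    return Checkpoint(
        state=best_state,
        model_config=model.config,
        train_config=cfg,
        history=history,
        best_epoch=es.best_epoch,
        phase=phase,
    )


def personalize(base: Checkpoint, target_train: LabeledImages,
                target_val: LabeledImages, cfg: TrainConfig) -> Checkpoint:
    """Phase 2: fine-tune a base checkpoint on the target patient.

    Continues from the base weights with learning rate
    ``base_lr * finetune_lr_factor`` and the same early-stopping regime;
    all layers stay trainable.  ``max_epochs = 0`` returns the base
    weights unchanged.
    """
    model = build_model(base.model_config)
    model.load_state_dict(base.state)
    if cfg.max_epochs == 0:
        return Checkpoint(
            state=model.state_dict(),
            model_config=base.model_config,
            train_config=cfg,
            history=[],
            best_epoch=0,
            phase="personalized",
        )
    return train(model, target_train, target_val, cfg,
                 lr=cfg.base_lr * cfg.finetune_lr_factor, phase="personalized")


# ---------------------------------------------------------------------------
# checkpoint container (single .npz file with an embedded JSON header)
# ---------------------------------------------------------------------------

def save_checkpoint(ckpt: Checkpoint, path) -> None:
    meta = {
        "model_config": vars(ckpt.model_config).copy(),
        "train_config": vars(ckpt.train_config).copy(),
        "history": ckpt.history,
        "best_epoch": ckpt.best_epoch,
        "phase": ckpt.phase,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **ckpt.state)


def load_checkpoint(path, expect_config: ModelConfig | None = None) -> Checkpoint:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    mc = ModelConfig(**meta["model_config"])
    if expect_config is not None and mc != expect_config:
        raise ValidationError(
            f"checkpoint config {mc} does not match expected {expect_config}"
        )
    return Checkpoint(
        state=state,
        model_config=mc,
        train_config=TrainConfig(**meta["train_config"]),
        history=meta["history"],
        best_epoch=meta["best_epoch"],
        phase=meta.get("phase", "base"),
    )


def history_to_csv(ckpt: Checkpoint, path) -> None:
    """Export the per-epoch metric series (loss/accuracy/.../AUC) as CSV."""
    if not ckpt.history:
        with open(path, "w") as fh:
            fh.write("")
        return
    keys = list(ckpt.history[0].keys())
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=keys)
        w.writeheader()
        for row in ckpt.history:
            w.writerow(row)
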