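"""Two-phase training: splits, early stopping, checkpoints, personalization."""

import numpy as np
import pytest

from seizurestack.experiments import cohort_dataset
from seizurestack.io import SpectrogramDataset
from seizurestack.models import ModelConfig, build_model
from seizurestack.synthetic import SyntheticConfig
from seizurestack.training import (
    EarlyStopState,
    LabeledImages,
    TrainConfig,
    early_stop_update,
    load_checkpoint,
    personalize,
    save_checkpoint,
    split_cohort,
    split_train_val,
    train,
)
from seizurestack.types import SpectrogramImage, ValidationError


def _fast_cfg(**kw):
    kw.setdefault("max_epochs", 3)
    kw.setdefault("patience", 2)
    kw.setdefault("seed", 0)
    return TrainConfig(**kw)


def _toy_dataset(n_per_patient=40, patients=("P1", "P2", "P3")):
    rng = np.random.default_rng(0)
    images, labels, pids, starts = [], [], [], []
    for pid in patients:
        for i in range(n_per_patient):
            label = int(rng.random() < 0.3)
            vals = rng.random((9, 8)) + 2.0 * label
            images.append(SpectrogramImage(
                values=vals, freq_axis=np.arange(9.0),
                time_axis=np.arange(8.0), log_scaled=True))
            labels.append(label)
            pids.append(pid)
            starts.append(4.0 * i)
    return SpectrogramDataset(images=images, labels=np.asarray(labels),
                              patient_ids=pids,
                              window_starts=np.asarray(starts),
                              manifest={})


# -- early stopping ---------------------------------------------------------

def _run_sequence(losses, patience):
    s = EarlyStopState()
    for v in losses:
        s = early_stop_update(s, v, patience)
        if s.stopped:
            break
    return s


def test_improving_sequence_never_stops():
    s = _run_sequence([1.0, 0.9, 0.8], patience=2)
    assert not s.stopped and s.best_epoch == 3 and s.best_val_loss == 0.8


def test_ties_count_toward_patience():
    """Equal loss is no improvement: 20 repeats of the best value stop at
    patience 20."""
    s = _run_sequence([0.5] + [0.5] * 20, patience=20)
    assert s.stopped and s.epoch == 21 and s.best_epoch == 1


def test_patience_one_stops_at_second_epoch():
    s = _run_sequence([0.5, 0.6], patience=1)
    assert s.stopped and s.epoch == 2 and s.best_epoch == 1


def test_scripted_patience_two_semantics():
    s = _run_sequence([0.5, 0.6, 0.6], patience=2)
    assert s.stopped and s.epoch == 3 and s.best_epoch == 1


def test_nan_loss_warns_and_counts_as_no_improvement():
    s = EarlyStopState()
    s = early_stop_update(s, 0.5, patience=2)
    with pytest.warns(UserWarning):
        s = early_stop_update(s, float("nan"), patience=2)
    assert s.epochs_since_improve == 1 and s.best_epoch == 1


# -- config validation ------------------------------------------------------

def test_train_config_invariants():
    with pytest.raises(ValidationError):
        TrainConfig(finetune_lr_factor=1.0)
    with pytest.raises(ValidationError):
        TrainConfig(patience=20, max_epochs=10)
    with pytest.raises(ValidationError):
        TrainConfig(val_fraction=0.6, test_fraction=0.5)


# -- splits -----------------------------------------------------------------

def test_split_cohort_partitions_by_patient():
    ds = _toy_dataset()
    cfg = _fast_cfg()
    splits = split_cohort(ds, "P3", cfg)
    assert set(splits.base_train.patient_ids) == {"P1", "P2"}
    for part in (splits.target_train, splits.target_val, splits.target_test):
        assert set(part.patient_ids) <= {"P3"}
    n = 40
    assert len(splits.target_test) == int(np.floor(0.15 * n))
    assert len(splits.target_val) == int(np.floor(0.15 * n))
    total = (len(splits.target_train) + len(splits.target_val)
             + len(splits.target_test))
    assert total == n  # no window lost or duplicated


def test_split_cohort_hundred_windows_fifteen_test():
    ds = _toy_dataset(n_per_patient=100, patients=("P1", "P2"))
    splits = split_cohort(ds, "P2", _fast_cfg())
    assert len(splits.target_test) == 15


def test_split_cohort_is_chronological_within_class():
    ds = _toy_dataset(n_per_patient=40, patients=("P1", "P2"))
    splits = split_cohort(ds, "P2", _fast_cfg())
    for label in (0, 1):
        bounds = []
        for part in (splits.target_train, splits.target_val, splits.target_test):
            mask = part.labels == label
            if mask.any():
                bounds.append((part.window_starts[mask].min(),
                               part.window_starts[mask].max()))
        for (_, hi), (lo, _) in zip(bounds, bounds[1:]):
            assert hi < lo  # later split -> strictly later windows


def test_split_cohort_val_and_test_contain_both_classes():
    ds = _toy_dataset(n_per_patient=60, patients=("P1", "P2"))
    splits = split_cohort(ds, "P2", _fast_cfg())
    for part in (splits.target_val, splits.target_test):
        assert set(np.unique(part.labels)) == {0, 1}


def test_split_cohort_errors():
    ds = _toy_dataset()
    with pytest.raises(ValidationError):
        split_cohort(ds, "P9", _fast_cfg())
    solo = _toy_dataset(patients=("P1",))
    with pytest.raises(ValidationError):
        split_cohort(solo, "P1", _fast_cfg())


def test_split_train_val_per_patient():
    ds = _toy_dataset(n_per_patient=20, patients=("P1", "P2"))
    tr, val = split_train_val(ds, 0.25)
    assert len(val) == 10 and len(tr) == 30
    assert set(val.patient_ids) == {"P1", "P2"}


# -- train ------------------------------------------------------------------

def _tiny_model(seed=0):
    return build_model(ModelConfig(arch="custom2dcnn", width_scale=1 / 16, seed=seed))


def _labeled(n=24, seed=0, h=9, w=8):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(int)
    X = rng.random((n, h, w)) + 2.0 * y[:, None, None]
    return LabeledImages(X, y)


def test_train_scripted_losses_stop_and_best_epoch():
    """Scripted validation losses [0.5, 0.6, 0.6] with patience 2 stop
    after epoch 3 with best epoch 1."""
    losses = {1: 0.5, 2: 0.6, 3: 0.6, 4: 0.4}
    ckpt = train(_tiny_model(), _labeled(), _labeled(seed=1),
                 _fast_cfg(max_epochs=10, patience=2),
                 val_loss_hook=lambda e: losses[e])
    assert len(ckpt.history) == 3
    assert ckpt.best_epoch == 1


def test_train_runs_all_epochs_when_improving():
    ckpt = train(_tiny_model(), _labeled(), _labeled(seed=1),
                 _fast_cfg(max_epochs=4, patience=3),
                 val_loss_hook=lambda e: 1.0 / e)
    assert len(ckpt.history) == 4 and ckpt.best_epoch == 4


def test_train_empty_set_rejected():
    empty = LabeledImages(np.zeros((0, 9, 8)), np.zeros(0, dtype=int))
    with pytest.raises(ValidationError):
        train(_tiny_model(), empty, _labeled(), _fast_cfg())


def test_train_single_class_warns():
    ones = _labeled()
    ones.y[:] = 1
    with pytest.warns(UserWarning):
        train(_tiny_model(), ones, _labeled(seed=1),
              _fast_cfg(max_epochs=2, patience=1))


def test_train_reproducible_from_seed():
    cfg = _fast_cfg(max_epochs=2, patience=1, seed=5)
    h = []
    for _ in range(2):
        ckpt = train(_tiny_model(seed=3), _labeled(), _labeled(seed=1), cfg)
        h.append(ckpt)
    assert h[0].history == h[1].history
    for k in h[0].state:
        assert np.array_equal(h[0].state[k], h[1].state[k])


def test_train_separable_windows_reach_high_accuracy():
    """A tiny model on ~200 clearly separable synthetic windows should fit
    the training set almost perfectly within 20 epochs."""
    config = SyntheticConfig(n_patients=2, n_channels=2, duration_s=412.0,
                             seed=17)
    ds, _ = cohort_dataset(config)
    data = LabeledImages.from_dataset(ds)
    assert len(data) >= 200
    model = build_model(ModelConfig(arch="custom2dcnn", width_scale=0.25, seed=1))
    ckpt = train(model, data, data, TrainConfig(max_epochs=20, patience=19, seed=1))
    assert ckpt.history[-1]["train_accuracy"] >= 0.95


def test_checkpoint_history_tracks_best_weights():
    ckpt = train(_tiny_model(), _labeled(), _labeled(seed=1),
                 _fast_cfg(max_epochs=3, patience=2))
    assert len(ckpt.history) <= 3
    assert ckpt.best_epoch >= 1
    best_val = min(r["val_loss"] for r in ckpt.history)
    assert ckpt.history[ckpt.best_epoch - 1]["val_loss"] == best_val


# -- personalize ------------------------------------------------------------

def _base_checkpoint():
    return train(_tiny_model(), _labeled(), _labeled(seed=1),
                 _fast_cfg(max_epochs=2, patience=1))


def test_personalize_zero_epochs_returns_base_weights():
    base = _base_checkpoint()
    pers = personalize(base, _labeled(seed=2), _labeled(seed=3),
                       _fast_cfg(max_epochs=0))
    assert pers.phase == "personalized"
    for k in base.state:
        assert np.array_equal(base.state[k], pers.state[k])


def test_personalize_uses_reduced_learning_rate():
    base = _base_checkpoint()
    pers = personalize(base, _labeled(seed=2), _labeled(seed=3),
                       _fast_cfg(max_epochs=2, patience=1))
    assert pers.best_epoch >= 1
    changed = any(not np.array_equal(base.state[k], pers.state[k])
                  for k in base.state)
    assert changed


def test_personalization_does_not_hurt_target_auc(shift_runs):
    """After fine-tuning on a domain-shifted target, test AUC does not
    drop (allowing for noise) in at least 2 of 3 seeds, per backbone."""
    for arch in shift_runs[0].base_auc:
        ok = sum(r.personalized_auc[arch] >= r.base_auc[arch] - 0.02
                 for r in shift_runs)
        assert ok >= 2, f"{arch}: fine-tuning degraded the target AUC"


# -- checkpoint i/o ---------------------------------------------------------

def test_checkpoint_roundtrip(tmp_path):
    ckpt = _base_checkpoint()
    path = tmp_path / "ck.npz"
    save_checkpoint(ckpt, path)
    back = load_checkpoint(path)
    assert back.model_config == ckpt.model_config
    assert back.best_epoch == ckpt.best_epoch
    assert back.history == ckpt.history
    for k in ckpt.state:
        assert np.array_equal(back.state[k], ckpt.state[k])


def test_checkpoint_refuses_mismatched_config(tmp_path):
    ckpt = _base_checkpoint()
    path = tmp_path / "ck.npz"
    save_checkpoint(ckpt, path)
    other = ModelConfig(arch="resnet18", width_scale=1 / 16)
    with pytest.raises(ValidationError):
        load_checkpoint(path, expect_config=other)
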