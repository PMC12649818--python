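"""End-to-end synthetic experiments: cohort -> spectrograms -> two-phase
training -> stacking ensemble -> metrics.

These drivers tie the whole pipeline together on generated cohorts and
are what the acceptance checks and the reproduction script run.  The
default problem sizes are chosen so a full leave-one-patient-out run with
all three (width-scaled) backbones completes in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ensemble import fit_meta, roc_auc
from .io import SpectrogramDataset
from .models import ARCHS, ModelConfig, build_model
from .preprocessing import normalize, segment, spectrogram
from .synthetic import SyntheticConfig, draw_signatures, generate_cohort
from .training import (
    Checkpoint,
    LabeledImages,
    TrainConfig,
    personalize,
    split_cohort,
    split_train_val,
    train,
)
from .types import StftParams
from . import nn

__all__ = [
    "cohort_dataset",
    "batched_probability",
    "batched_features",
    "run_two_phase_pipeline",
]

DEFAULT_STFT = StftParams(N=256, R=256)


def cohort_dataset(config: SyntheticConfig,
                   stft_params: StftParams = DEFAULT_STFT,
                   window_s: float = 8.0, step_s: float = 4.0,
                   label_threshold: float = 0.5,
                   target_shift_hz: float = 0.0,
                   log_scaled: bool = True, collapse: str = "mean",
                   ) -> tuple[SpectrogramDataset, str]:
    """Generate a cohort and preprocess it into a spectrogram dataset.

    The last patient is the personalization target; ``target_shift_hz``
    moves that patient's ictal frequency out of the base cohort's
    distribution (the domain-shift experiment).  Returns (dataset,
    target_patient_id).
    """
    signatures = draw_signatures(config)
    if target_shift_hz:
        tgt = signatures[-1]
        signatures[-1] = replace(tgt, ictal_freq_hz=tgt.ictal_freq_hz + target_shift_hz)
    cohort = generate_cohort(config, signatures)
    images, labels, pids, starts = [], [], [], []
    for recording, _sig in cohort:
        rec = normalize(recording)
        for seg in segment(rec, window_s, step_s, label_threshold):
            images.append(spectrogram(seg, stft_params, collapse, log_scaled))
            labels.append(seg.label)
            pids.append(seg.patient_id)
            starts.append(seg.start_s)
    manifest = {
        "window_s": window_s, "step_s": step_s, "fs": config.fs,
        "stft_N": stft_params.N, "stft_R": stft_params.R,
        "label_threshold": label_threshold,
        "log_scaled": log_scaled, "channel_collapse": collapse,
        "target_shift_hz": target_shift_hz, "seed": config.seed,
    }
    ds = SpectrogramDataset(images=images, labels=np.asarray(labels),
                            patient_ids=pids, window_starts=np.asarray(starts),
                            manifest=manifest)
    return ds, signatures[-1].patient_id


def batched_probability(model, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Eval-mode probabilities for an [n, H, W] stack, in memory-safe chunks."""
    model.eval()
    out = []
    for i in range(0, len(X), batch_size):
        out.append(model.probability(nn.Tensor(X[i:i + batch_size, None])).data)
    return np.concatenate(out)


def batched_features(model, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    model.eval()
    out = []
    for i in range(0, len(X), batch_size):
        out.append(model.features(nn.Tensor(X[i:i + batch_size, None])).data)
    return np.concatenate(out)


@dataclass
class PipelineResult:
    """Per-architecture and ensemble test-set AUCs of one full run."""

    target_patient: str
    n_windows: int
    n_test: int
    seizure_rate: float
    base_auc: dict[str, float]
    personalized_auc: dict[str, float]
    stack_auc: float
    average_auc: float
    base_checkpoints: dict[str, Checkpoint]
    personalized_checkpoints: dict[str, Checkpoint]


def run_two_phase_pipeline(seed: int,
                           n_patients: int = 4,
                           duration_s: float = 2004.0,
                           width_scale: float = 1.0 / 16.0,
                           max_epochs: int = 12,
                           patience: int = 5,
                           target_shift_hz: float = 0.0,
                           archs: tuple[str, ...] = ARCHS,
                           meta_l2: float = 1.0,
                           synthetic_overrides: dict | None = None,
                           ) -> PipelineResult:
    """One leave-one-patient-out, two-phase run on a synthetic cohort.

    Phase 1 trains each backbone on all patients except the target (with a
    chronological per-patient train/val split), phase 2 fine-tunes on the
    target's training split at a reduced learning rate.  The stacking
    meta-model is fit on the target validation split over the personalized
    models' concatenated features; AUCs are measured on the held-out
    target test split (the chronologically last 15% of windows).
    """
    syn_kwargs = dict(n_patients=n_patients, duration_s=duration_s, seed=seed)
    if synthetic_overrides:
        syn_kwargs.update(synthetic_overrides)
    config = SyntheticConfig(**syn_kwargs)
    dataset, target = cohort_dataset(config, target_shift_hz=target_shift_hz)

    tcfg = TrainConfig(max_epochs=max_epochs, patience=patience, seed=seed)
    splits = split_cohort(dataset, target, tcfg)
    base_tr_ds, base_val_ds = split_train_val(splits.base_train, tcfg.val_fraction)
    base_tr = LabeledImages.from_dataset(base_tr_ds)
    base_val = LabeledImages.from_dataset(base_val_ds)
    tgt_tr = LabeledImages.from_dataset(splits.target_train)
    tgt_val = LabeledImages.from_dataset(splits.target_val)
    tgt_test = LabeledImages.from_dataset(splits.target_test)

    rng = np.random.default_rng(seed)
    base_ckpts: dict[str, Checkpoint] = {}
    pers_ckpts: dict[str, Checkpoint] = {}
    base_auc: dict[str, float] = {}
    pers_auc: dict[str, float] = {}
    pers_models: dict[str, nn.Module] = {}
    for arch in archs:
        mcfg = ModelConfig(arch=arch, width_scale=width_scale,
                           seed=int(rng.integers(2 ** 31)))
        model = build_model(mcfg)
        base_ckpts[arch] = train(model, base_tr, base_val, tcfg)
        base_auc[arch] = roc_auc(tgt_test.y,
                                 batched_probability(model, tgt_test.X))[0]
        pers_ckpts[arch] = personalize(base_ckpts[arch], tgt_tr, tgt_val, tcfg)
        pers_model = build_model(mcfg)
        pers_model.load_state_dict(pers_ckpts[arch].state)
        pers_models[arch] = pers_model
        pers_auc[arch] = roc_auc(tgt_test.y,
                                 batched_probability(pers_model, tgt_test.X))[0]

    stack_auc = float("nan")
    average_auc = float("nan")
    if set(archs) == set(ARCHS):
        val_feats = np.concatenate(
            [batched_features(pers_models[a], tgt_val.X) for a in ARCHS], axis=1)
        meta = fit_meta(val_feats, tgt_val.y, l2=meta_l2)
        test_feats = np.concatenate(
            [batched_features(pers_models[a], tgt_test.X) for a in ARCHS], axis=1)
        stack_auc = roc_auc(tgt_test.y, meta.predict_proba(test_feats))[0]
        avg_probs = np.mean(
            [batched_probability(pers_models[a], tgt_test.X) for a in ARCHS], axis=0)
        average_auc = roc_auc(tgt_test.y, avg_probs)[0]

    return PipelineResult(
        target_patient=target,
        n_windows=len(dataset),
        n_test=len(tgt_test),
        seizure_rate=float(np.mean(dataset.labels)),
        base_auc=base_auc,
        personalized_auc=pers_auc,
        stack_auc=stack_auc,
        average_auc=average_auc,
        base_checkpoints=base_ckpts,
        personalized_checkpoints=pers_ckpts,
    )
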