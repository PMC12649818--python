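"""Meta-model, ensemble prediction and metric oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seizurestack.ensemble import (
    ConfusionMatrix,
    MetaModel,
    confusion,
    evaluate,
    fit_meta,
    metrics_from_confusion,
    predict_ensemble,
    roc_auc,
)
from seizurestack.models import ARCHS, ModelConfig, build_model
from seizurestack.types import ValidationError


def auc_bruteforce(labels, scores):
    """Mann-Whitney by explicit pair counting (the independent oracle)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


# -- meta-model -------------------------------------------------------------

def test_zero_meta_outputs_half():
    meta = MetaModel(weights=np.zeros(5), bias=0.0, l2=1.0)
    probs = meta.predict_proba(np.random.default_rng(0).normal(size=(7, 5)))
    assert np.allclose(probs, 0.5)


def test_monotone_feature_gives_perfect_training_auc():
    x = np.linspace(-1, 1, 40)[:, None]
    y = (x[:, 0] > 0).astype(int)
    meta = fit_meta(x, y, l2=1.0)
    auc, _ = roc_auc(y, meta.predict_proba(x))
    assert auc == 1.0


def test_duplicated_feature_splits_weight_under_l2():
    rng = np.random.default_rng(1)
    f = rng.normal(size=200)
    y = (f + 0.3 * rng.normal(size=200) > 0).astype(int)
    X = np.column_stack([f, f])
    meta = fit_meta(X, y, l2=10.0)
    w1, w2 = meta.weights
    assert w1 == pytest.approx(w2, rel=0.05)


def test_meta_single_class_rejected():
    with pytest.raises(ValidationError):
        fit_meta(np.zeros((4, 2)), np.ones(4), l2=1.0)


# -- ensemble prediction ----------------------------------------------------

def _tiny_models():
    return {a: build_model(ModelConfig(arch=a, width_scale=1 / 16, seed=i))
            for i, a in enumerate(ARCHS)}


def test_average_of_identical_probabilities():
    rng = np.random.default_rng(2)
    img = rng.normal(size=(33, 10))
    models = _tiny_models()
    m = models["custom2dcnn"]
    same = {a: m for a in ARCHS}
    from seizurestack.models import forward_probability
    p = forward_probability(m, img)
    out = predict_ensemble(same, None, img, mode="average")
    assert out == pytest.approx(p)


def test_stack_with_zeroed_meta_is_half():
    rng = np.random.default_rng(3)
    img = rng.normal(size=(33, 10))
    models = _tiny_models()
    dim = sum(m.head.weight.data.shape[0] for m in models.values())
    meta = MetaModel(weights=np.zeros(dim), bias=0.0, l2=1.0)
    out = predict_ensemble(models, meta, img, mode="stack")
    assert np.allclose(out, 0.5)


def test_stack_requires_all_models_and_meta():
    models = _tiny_models()
    models.pop("resnet18")
    with pytest.raises(ValidationError):
        predict_ensemble(models, MetaModel(np.zeros(3), 0.0, 1.0),
                         np.zeros((33, 10)), mode="stack")
    with pytest.raises(ValidationError):
        predict_ensemble(_tiny_models(), None, np.zeros((33, 10)), mode="stack")


def test_stack_auc_not_below_best_single(plain_runs):
    """Stacking matches or beats the best personalized backbone."""
    mean_stack = np.mean([r.stack_auc for r in plain_runs])
    mean_best = np.mean([max(r.personalized_auc.values()) for r in plain_runs])
    mean_avg = np.mean([r.average_auc for r in plain_runs])
    assert mean_stack >= mean_best - 0.01
    assert mean_stack >= mean_avg - 0.02


# -- confusion & metrics ----------------------------------------------------

def test_confusion_hand_tally():
    cm = confusion([1, 0, 1, 0], [0.9, 0.1, 0.2, 0.8])
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (1, 1, 1, 1)


def test_confusion_all_correct():
    cm = confusion([1, 0, 1], [0.9, 0.1, 0.8])
    assert cm.fp == 0 and cm.fn == 0


def test_confusion_threshold_zero_everything_positive():
    cm = confusion([1, 0, 1], [0.0, 0.0, 0.9], threshold=0.0)
    assert cm.tn == 0 and cm.fn == 0


def test_confusion_length_mismatch():
    with pytest.raises(ValidationError):
        confusion([1, 0], [0.5])


def test_metrics_perfect_matrix():
    m = metrics_from_confusion(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0))
    assert (m["accuracy"], m["precision"], m["recall"], m["f1"]) == (1, 1, 1, 1)


def test_metrics_zero_denominator_flagged():
    m = metrics_from_confusion(ConfusionMatrix(tp=0, tn=4, fp=0, fn=2))
    assert m["recall"] == 0.0
    assert m["precision"] == 0.0 and "precision_undefined" in m["flags"]
    with pytest.raises(ValidationError):
        metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_metrics_agree_with_direct_counting(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 60))
    y = rng.integers(0, 2, n)
    p = rng.random(n)
    cm = confusion(y, p)
    pred = (p >= 0.5).astype(int)
    assert cm.total == n
    m = metrics_from_confusion(cm)
    assert m["accuracy"] == pytest.approx(np.mean(pred == y))


# -- ROC / AUC --------------------------------------------------------------

def test_auc_perfect_and_ties():
    assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])[0] == 1.0
    assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])[0] == 0.5


def test_auc_hand_example():
    auc, _ = roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
    assert auc == pytest.approx(0.75)


def test_auc_single_class_rejected():
    with pytest.raises(ValidationError):
        roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_auc_matches_bruteforce_pair_count(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 50))
    y = rng.integers(0, 2, n)
    if len(np.unique(y)) < 2:
        y[0], y[1] = 0, 1
    s = np.round(rng.random(n), 2)  # coarse grid to exercise ties
    auc, _ = roc_auc(y, s)
    assert auc == pytest.approx(auc_bruteforce(y, s), abs=1e-12)


@given(st.integers(0, 2 ** 31 - 1))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    n = 30
    y = rng.integers(0, 2, n)
    if len(np.unique(y)) < 2:
        y[0], y[1] = 0, 1
    s = rng.normal(size=n)
    a1, _ = roc_auc(y, s)
    a2, _ = roc_auc(y, np.exp(2.0 * s) + 5.0)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_roc_points_monotone():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 50)
    y[0], y[1] = 0, 1
    _, pts = roc_auc(y, rng.random(50))
    assert np.all(np.diff(pts[:, 0]) >= 0)
    assert np.all(np.diff(pts[:, 1]) >= 0)


def test_evaluate_report_roundtrip():
    y = [0, 1, 0, 1, 1]
    p = [0.2, 0.8, 0.4, 0.6, 0.3]
    rep = evaluate(y, p, mode="stack")
    d = rep.to_dict()
    assert d["mode"] == "stack"
    assert 0.0 <= d["auc"] <= 1.0
    assert d["confusion"]["tp"] + d["confusion"]["fn"] == 3
    import json
    assert json.loads(rep.to_json())["accuracy"] == d["accuracy"]
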