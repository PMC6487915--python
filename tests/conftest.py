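"""Shared fixtures, including the multi-seed end-to-end staging experiment.

The experiment (5 simulated recordings x 200 epochs per seed, Q=25, 30
training epochs) is computed once per session and shared between the
training-behavior tests and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import sleepmt as smt
from sleepmt.estimator import MultiTaskSleepStager

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

STAGE_LABELS = np.array(smt.AASM5.labels)


@pytest.fixture(scope="session")
def gen_cfg():
    return smt.SignalGenConfig()


@pytest.fixture(scope="session")
def transition_model():
    return smt.default_transition_model()


@pytest.fixture(scope="session")
def small_recording(transition_model, gen_cfg):
    return smt.simulate_recording(30, transition_model, gen_cfg, seed=7)


def run_staging_experiment(seed: int) -> dict:
    """One seed of the desk-scale experiment.

    Five 200-epoch recordings; four go to the estimator (which holds one out
    for validation), the fifth is the test recording. Returns per-subtask and
    per-aggregation-scheme test accuracies.
    """
    cfg = smt.SignalGenConfig()
    tm = smt.default_transition_model()
    recs = [
        smt.simulate_recording(200, tm, cfg, seed * 100 + r, subject_id=f"S{r}")
        for r in range(5)
    ]
    feats = [smt.featurize_recording(rec) for rec in recs]
    Xtr = np.concatenate(feats[:4])
    ytr = STAGE_LABELS[np.concatenate([rec.stages.codes() for rec in recs[:4]])]
    gtr = np.concatenate([[i] * 200 for i in range(4)])
    est = MultiTaskSleepStager(
        Q=25,
        n_train_epochs=30,
        learning_rate=1e-3,
        validation_fraction=0.25,
        random_state=seed,
    )
    est.fit(Xtr, ytr, groups=gtr)

    Xte, yte = feats[4], recs[4].stages.codes()
    posts = est.posteriors(Xte)[0][1]
    probs = np.stack([p.probs for p in posts])
    cls_order = list(est.classes_)
    to_cls = np.array([cls_order.index(lab) for lab in STAGE_LABELS])
    yte_c = to_cls[yte]
    pred_sub = probs.argmax(axis=2)
    accs = {}
    for k, name in [(0, "left_prediction"), (1, "classification"), (2, "right_prediction")]:
        off = k - 1
        lo, hi = max(0, -off), len(yte_c) - max(0, off)
        accs[name] = float((pred_sub[lo:hi, k] == yte_c[lo + off : hi + off]).mean())
    for vote in ("none", "additive", "multiplicative"):
        est.vote = vote
        pred = est.predict(Xte)
        accs[vote] = float((pred == STAGE_LABELS[yte]).mean())
    return accs


@pytest.fixture(scope="session")
def directional_results():
    """Accuracies of the staging experiment over 5 seeds."""
    return [run_staging_experiment(seed) for seed in range(1, 6)]
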