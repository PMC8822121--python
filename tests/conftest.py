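"""Shared fixtures.

The expensive artifacts — the miniature synthetic subject, its gaze
timelines and a classifier trained on folds 1-3 — are session-scoped
and shared across test modules.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gazegrasp.classifier import (
    ClassMap,
    ModelSpec,
    TrainConfig,
    build_model,
    compute_class_weights,
    train,
)
from gazegrasp.emg import fit_scaler, tensorize, transform, window_segment
from gazegrasp.gaze import GazeConfig, annotate_stream
from gazegrasp.protocol import grasp_object_pairs, miniature_pairing, split_train_validation
from gazegrasp.synthetic import SynthConfig, generate_subject

MINI_SEED = 7


@pytest.fixture(scope="session")
def pairing():
    return grasp_object_pairs()


@pytest.fixture(scope="session")
def mini_pairing():
    return miniature_pairing()


@pytest.fixture(scope="session")
def mini_recording(mini_pairing):
    """Miniature protocol (2 grasps x 32 reps) at default noise."""
    return generate_subject(SynthConfig(seed=MINI_SEED), mini_pairing, subject="M01")


@pytest.fixture(scope="session")
def full_recording(pairing):
    """Full protocol: 10 grasps x 32 reps = 320 segments."""
    return generate_subject(SynthConfig(seed=3), pairing, subject="S001")


@pytest.fixture(scope="session")
def mini_timelines(mini_recording):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return annotate_stream(
            mini_recording.gaze,
            mini_recording.detections,
            mini_recording.trials,
            GazeConfig(),
            mini_recording.sampling,
        )


def segment_windows(recording, trials, scaler, class_map):
    xs, ys = [], []
    for t in trials:
        w, wl = window_segment(
            transform(recording.emg[t.start_sample : t.end_sample], scaler),
            recording.emg_labels[t.start_sample : t.end_sample],
        )
        if len(w):
            xs.append(w)
            ys.append(wl)
    return tensorize(np.concatenate(xs)), class_map.encode_labels(np.concatenate(ys))


@pytest.fixture(scope="session")
def trained_mini(mini_recording, mini_pairing):
    """Classifier trained on folds 1-3 of the miniature recording.

    Returns (model, scaler, class_map, heldout_fold_id).  16 filters and
    8 epochs suffice on the separable synthetic signatures.
    """
    class_map = ClassMap.from_pairing(mini_pairing)
    pool = [t for t in mini_recording.trials if t.fold_id != 4]
    train_trials, val_trials = split_train_validation(pool, seed=0)
    scaler = fit_scaler(
        [mini_recording.emg[t.start_sample : t.end_sample] for t in train_trials]
    )
    Xtr, ytr = segment_windows(mini_recording, train_trials, scaler, class_map)
    Xval, yval = segment_windows(mini_recording, val_trials, scaler, class_map)
    model = build_model(
        ModelSpec(convlstm_filters=16, output_units=class_map.n_classes), seed=0
    )
    cfg = TrainConfig(
        epochs=8, class_weights=compute_class_weights(ytr, class_map.n_classes), seed=0
    )
    train(model, Xtr, ytr, Xval, yval, cfg)
    return model, scaler, class_map, 4
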