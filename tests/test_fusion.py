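"""Fusion state machine: intent detection, target search, restricted argmax."""

import numpy as np
import pandas as pd
import pytest

from gazegrasp.classifier import ClassMap, ProbStream
from gazegrasp.fusion import (
    FusionConfig,
    detect_intent,
    find_target_object,
    fuse_decision,
    run_fusion,
)
from gazegrasp.protocol import GRASPS, grasp_object_pairs, miniature_pairing

FS = 1926.0


def prob_stream_from_classes(classes, n_classes, t0=200, stride=20, confidence=0.9):
    """A ProbStream whose argmax follows the given class sequence."""
    n = len(classes)
    p = np.full((n, n_classes), (1 - confidence) / (n_classes - 1))
    p[np.arange(n), classes] = confidence
    t = t0 + stride * np.arange(n)
    return ProbStream(t=t.astype(np.int64), p=p)


def timeline_of(entries):
    """entries: list of (t_seconds, label-or-None)."""
    return pd.DataFrame(
        {
            "t": [e[0] for e in entries],
            "looked_at": [e[1] for e in entries],
            "distance_px": 0.0,
            "frame_index": 0,
            "valid_instance": [e[1] is not None for e in entries],
        }
    )


class TestIntentDetection:
    def test_scan_oracle(self):
        stream = prob_stream_from_classes([0, 0, 1, 1, 0, 2], 3)
        assert detect_intent(stream) == [2, 5]

    def test_all_rest_no_events(self):
        stream = prob_stream_from_classes([0, 0, 0, 0], 3)
        assert detect_intent(stream) == []

    def test_stream_starting_non_rest_fires_at_first_step(self):
        stream = prob_stream_from_classes([1, 1, 0, 1], 3)
        assert detect_intent(stream) == [0, 3]


class TestTargetSearch:
    def test_recent_look_found_at_intent(self):
        intent = 10000
        t_look = (intent - 100) / FS  # ~52 ms before intent
        tl = timeline_of([(t_look - 0.05, None), (t_look, "mug")])
        obj, found = find_target_object(tl, intent)
        assert obj == "mug"
        assert found == intent

    def test_look_outside_480_sample_window_is_none(self):
        intent = 10000
        tl = timeline_of([((intent - 600) / FS, "mug")])
        obj, found = find_target_object(tl, intent)
        assert obj is None and found is None

    def test_forward_search_finds_late_look(self):
        intent = 10000
        t_look = intent / FS + 0.2  # 200 ms after intent
        tl = timeline_of([(t_look, "key")])
        obj, found = find_target_object(tl, intent)
        assert obj == "key"
        assert found == int(np.ceil(t_look * FS))

    def test_forward_search_expires_after_500ms(self):
        intent = 10000
        tl = timeline_of([(intent / FS + 0.6, "key")])
        obj, found = find_target_object(tl, intent)
        assert obj is None

    def test_most_recent_look_wins_lookback(self):
        intent = 10000
        tl = timeline_of(
            [((intent - 400) / FS, "mug"), ((intent - 100) / FS, "key")]
        )
        obj, _ = find_target_object(tl, intent)
        assert obj == "key"


class TestRestrictedArgmax:
    def test_bottle_restriction_selects_medium_wrap(self):
        # 11-class posterior: lateral most likely overall, but bottle only
        # pairs with medium wrap and tripod grasp
        cm = ClassMap(GRASPS)
        pairing = grasp_object_pairs()
        p = np.zeros(11)
        p[cm.index_of(2)] = 0.40  # lateral
        p[cm.index_of(1)] = 0.35  # medium wrap
        p[cm.index_of(4)] = 0.10  # tripod grasp
        allowed = [cm.index_of(g.id) for g in pairing.grasps_for("bottle")]
        assert fuse_decision(p, allowed) == cm.index_of(1)

    def test_noop_when_argmax_already_allowed(self):
        p = np.array([0.1, 0.2, 0.7])
        assert fuse_decision(p, [1, 2]) == 2

    def test_singleton_allowed_set_forces_that_grasp(self):
        p = np.array([0.8, 0.1, 0.1])
        assert fuse_decision(p, [2]) == 2

    def test_empty_or_rest_allowed_raises(self):
        with pytest.raises(ValueError):
            fuse_decision(np.array([0.5, 0.5]), [])
        with pytest.raises(ValueError):
            fuse_decision(np.array([0.5, 0.5]), [0, 1])


class TestStateMachine:
    def test_all_none_timeline_reduces_to_unimodal(self):
        cm = ClassMap.from_pairing(miniature_pairing())
        classes = [0, 0, 1, 1, 1, 0, 2, 2, 0]
        stream = prob_stream_from_classes(classes, cm.n_classes)
        tl = timeline_of([(0.01 * i, None) for i in range(200)])
        trace = run_fusion(stream, tl, miniature_pairing(), cm)
        assert trace["fused"].tolist() == classes
        assert trace["object"].isna().all()

    def test_restriction_soundness_and_reset(self, trained_mini, mini_recording, mini_timelines):
        from gazegrasp.evaluation import evaluate_trial

        model, scaler, cm, heldout = trained_mini
        pairing = miniature_pairing()
        test_idx = [i for i, t in enumerate(mini_recording.trials) if t.fold_id == heldout]
        for i in test_idx[:6]:
            ev = evaluate_trial(mini_recording, i, model, scaler, mini_timelines[i], pairing, cm)
            tr = ev.trace
            fused_rows = tr[tr.state == "FUSED"]
            for row in fused_rows.itertuples():
                if row.fused != 0:
                    allowed = {cm.index_of(g.id) for g in pairing.grasps_for(row.object)}
                    assert row.fused in allowed
            # reset correctness: a rest-classified step is never in FUSED state
            assert not ((tr.unimodal == 0) & (tr.state == "FUSED")).any()
            # rest steps pass through identically
            rest = tr[tr.unimodal == 0]
            assert (rest.fused == 0).all()

    def test_streamed_equals_offline_replay(self, trained_mini, mini_recording, mini_timelines):
        """The incremental machine matches an independent offline replay."""
        from gazegrasp.emg import transform
        from gazegrasp.classifier import predict_stream

        model, scaler, cm, heldout = trained_mini
        pairing = miniature_pairing()
        config = FusionConfig()
        test_idx = [i for i, t in enumerate(mini_recording.trials) if t.fold_id == heldout]
        fs = mini_recording.sampling.emg_rate
        for i in test_idx[:8]:
            trial = mini_recording.trials[i]
            lo = max(trial.onset_sample - int(2.0 * fs), trial.start_sample)
            hi = min(trial.onset_sample + int(3.5 * fs), trial.end_sample)
            stream = predict_stream(model, transform(mini_recording.emg[lo:hi], scaler), t_offset=lo)
            trace = run_fusion(stream, mini_timelines[i], pairing, cm, config)
            replay = _offline_replay(stream, mini_timelines[i], pairing, cm, config)
            assert trace["fused"].tolist() == replay

    def test_guaranteed_failure_when_object_excludes_true_grasp(self):
        # identified object pairs only with medium wrap; true grasp is tripod
        cm = ClassMap.from_pairing(miniature_pairing())
        tripod = cm.index_of(4)
        classes = [0, 0] + [tripod] * 10
        stream = prob_stream_from_classes(classes, cm.n_classes)
        intent_t = stream.t[2] / FS
        tl = timeline_of([(intent_t - 0.05, "can")])  # can -> {medium wrap} only
        trace = run_fusion(stream, tl, miniature_pairing(), cm)
        fused_steps = trace[(trace.state == "FUSED") & (trace.fused != 0)]
        assert len(fused_steps) == 10
        assert (fused_steps.fused != tripod).all()

    def test_dominance_under_correct_identification(self, trained_mini, mini_recording, mini_timelines):
        from gazegrasp.evaluation import evaluate_trial

        model, scaler, cm, heldout = trained_mini
        pairing = miniature_pairing()
        test_idx = [i for i, t in enumerate(mini_recording.trials) if t.fold_id == heldout]
        for i in test_idx:
            trial = mini_recording.trials[i]
            ev = evaluate_trial(mini_recording, i, model, scaler, mini_timelines[i], pairing, cm)
            tr = ev.trace
            correct_obj = tr.object == trial.object
            uni_correct = tr.unimodal.to_numpy() == ev.step_labels
            fused_correct = tr.fused.to_numpy() == ev.step_labels
            # wherever the object is right and the sEMG decision is right,
            # restriction cannot demote it
            mask = correct_obj.to_numpy() & uni_correct
            assert fused_correct[mask].all()


def _offline_replay(stream, timeline, pairing, cm, config):
    """Independent episode-wise reconstruction of the fusion output."""
    cls = stream.argmax
    n = len(cls)
    fused = [0] * n
    i = 0
    while i < n:
        if cls[i] == 0:
            fused[i] = 0
            i += 1
            continue
        j = i
        while j < n and cls[j] != 0:
            j += 1
        obj, found_at = find_target_object(timeline, int(stream.t[i]), config)
        for s in range(i, j):
            if obj is not None and found_at <= stream.t[s]:
                allowed = [cm.index_of(g.id) for g in pairing.grasps_for(obj)]
                fused[s] = fuse_decision(stream.p[s], allowed)
            else:
                fused[s] = int(cls[s])
        i = j
    return fused
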