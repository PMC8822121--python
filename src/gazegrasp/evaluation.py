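"""Metrics, nonparametric statistics and the cross-validation driver.

Accuracy is step-wise over every classification step of a trial's
analysis window, on all classes including rest.  The correct-object-
identification rate counts, per subject and condition, the trials whose
identified object at the intent event equals the ground-truth target.
Approach comparisons use the one-sided Wilcoxon signed-rank test (with
matched rank-biserial effect size); group comparisons use the
Mann-Whitney test (rank-biserial effect size), both applied to
per-subject averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import ClassMap, ModelSpec, TrainConfig, build_model, compute_class_weights, predict_stream, train
from .emg import WindowSpec, fit_scaler, tensorize, transform, window_label, window_segment
from .fusion import FusionConfig, detect_intent, find_target_object, run_fusion
from .gaze import GazeConfig, annotate_stream
from .protocol import Condition, GraspObjectMap, TrialMeta, split_train_validation
from .synthetic import SubjectRecording

__all__ = [
    "FoldResult",
    "ObjectIdResult",
    "TestResult",
    "accuracy",
    "confusion_matrix",
    "stream_step_labels",
    "object_id_rate",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "evaluate_trial",
    "crossval_driver",
    "CrossvalResult",
]

#: Exact-null sample-size ceiling for the signed-rank test; above it (or
#: with tied ranks) the normal approximation with continuity correction
#: is used.
WILCOXON_EXACT_N = 25


@dataclass
class FoldResult:
    """Per-fold step-wise accuracies and confusion matrices (%)."""

    fold_id: int
    unimodal_accuracy: float
    multimodal_accuracy: float
    confusion_unimodal: np.ndarray
    confusion_multimodal: np.ndarray
    heldout_window_accuracy: float
    n_steps: int


@dataclass
class ObjectIdResult:
    """Correct-object-identification rate per subject and condition."""

    subject: str
    condition: str  # "static" | "dynamic"
    rate: float  # %
    n_trials: int


@dataclass
class TestResult:
    test: str
    p_value: float
    effect_size: float  # magnitude
    alternative: str
    n: int


def accuracy(decisions: np.ndarray, labels: np.ndarray) -> float:
    """Percentage of steps where the decision equals the label."""
    decisions = np.asarray(decisions)
    labels = np.asarray(labels)
    if decisions.shape != labels.shape:
        raise ValueError(f"length mismatch: {decisions.shape} vs {labels.shape}")
    if len(decisions) == 0:
        raise ValueError("empty decision sequence")
    return float((decisions == labels).mean() * 100.0)


def confusion_matrix(decisions: np.ndarray, labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Rows = true class, columns = decision; row sums = class support."""
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (np.asarray(labels), np.asarray(decisions)), 1)
    return m


def stream_step_labels(
    emg_labels: np.ndarray, step_samples: np.ndarray, class_map: ClassMap, spec: WindowSpec = WindowSpec()
) -> np.ndarray:
    """Ground-truth class per streaming step.

    The label of step t is the majority label (ties toward rest) of the
    trailing window ending at t — the same rule used to label training
    windows.  ``step_samples`` are indices into ``emg_labels``.
    """
    out = np.empty(len(step_samples), dtype=np.int64)
    for i, t in enumerate(np.asarray(step_samples)):
        out[i] = window_label(emg_labels[t - spec.window_len : t])
    return class_map.encode_labels(out)


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float], alternative: str = "greater"
) -> TestResult:
    """Wilcoxon signed-rank test of b vs a on paired samples.

    ``alternative='greater'`` tests that b exceeds a.  Zero differences
    are dropped; at least 5 non-zero differences are required.  Exact
    null up to n = 25 without tied ranks, else normal approximation
    with continuity correction.  Effect size is the magnitude of the
    matched rank-biserial correlation (W+ - W-) / (W+ + W-).
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: effect size undefined")
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    effect = abs(w_plus - w_minus) / (w_plus + w_minus)
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= WILCOXON_EXACT_N and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method, correction=(method == "approx"))
    return TestResult("wilcoxon_signed_rank", float(res.pvalue), effect, alternative, n)


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test between independent groups.

    Exact null for small tie-free samples, otherwise the normal
    approximation with tie correction.  Effect size is the magnitude of
    the rank-biserial correlation 1 - 2U/(n_a * n_b).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= WILCOXON_EXACT_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    effect = abs(1.0 - 2.0 * float(res.statistic) / (len(a) * len(b)))
    return TestResult("mann_whitney", float(res.pvalue), effect, alternative, len(a) + len(b))


# ----------------------------------------------------------------------
# trial-level evaluation


@dataclass
class TrialEvaluation:
    trial_index: int
    step_labels: np.ndarray
    unimodal: np.ndarray
    fused: np.ndarray
    identified_object: str | None
    trace: pd.DataFrame


def _identification_at_grasp_onset(
    stream, timeline: pd.DataFrame, onset_sample: int, fusion_config: FusionConfig
) -> str | None:
    """The object recognized by the approach at the beginning of the grasp.

    The machine restarts at every rest classification, so a false-alarm
    episode that dies out before the true onset does not carry an
    identification into the grasp.  The scoring therefore uses the
    intent event of the first non-rest episode that reaches the onset;
    None when no such episode exists or its search fails.
    """
    cls = stream.argmax
    intents = detect_intent(stream)
    for k, s in enumerate(intents):
        e = s
        while e + 1 < len(cls) and cls[e + 1] != 0:
            e += 1
        if stream.t[e] >= onset_sample:
            obj, _ = find_target_object(timeline, int(stream.t[s]), fusion_config)
            return obj
    return None


def evaluate_trial(
    recording: SubjectRecording,
    trial_index: int,
    model,
    scaler,
    timeline: pd.DataFrame,
    pairing: GraspObjectMap,
    class_map: ClassMap,
    window: WindowSpec = WindowSpec(),
    gaze_config: GazeConfig = GazeConfig(),
    fusion_config: FusionConfig = FusionConfig(),
) -> TrialEvaluation:
    """Stream one trial's analysis window through both approaches.

    The window spans 2 s before to 3.5 s after the onset, clipped to the
    trial's segment so no neighbouring trial leaks in.  The identified
    object is the one resolved at the first intent event (None when no
    intent fires or the search fails).
    """
    trial = recording.trials[trial_index]
    fs = recording.sampling.emg_rate
    lo = max(trial.onset_sample - int(round(gaze_config.pre_window * fs)), trial.start_sample)
    hi = min(trial.onset_sample + int(round(gaze_config.post_window * fs)), trial.end_sample)
    emg_std = transform(recording.emg[lo:hi], scaler)
    stream = predict_stream(model, emg_std, window, t_offset=lo)
    trace = run_fusion(stream, timeline, pairing, class_map, fusion_config)
    labels = stream_step_labels(recording.emg_labels, stream.t, class_map, window)
    identified = _identification_at_grasp_onset(stream, timeline, trial.onset_sample, fusion_config)
    return TrialEvaluation(
        trial_index=trial_index,
        step_labels=labels,
        unimodal=trace["unimodal"].to_numpy(),
        fused=trace["fused"].to_numpy(),
        identified_object=identified,
        trace=trace,
    )


def object_id_rate(evaluations: Sequence[TrialEvaluation], trials: Sequence[TrialMeta], subject: str) -> list[ObjectIdResult]:
    """Correct-object-identification rate per condition.

    The static seated and standing repetitions merge into "static"; a
    missing identification counts as incorrect.
    """
    buckets: dict[str, list[bool]] = {"static": [], "dynamic": []}
    for ev in evaluations:
        trial = trials[ev.trial_index]
        cond = "dynamic" if trial.condition is Condition.dynamic else "static"
        buckets[cond].append(ev.identified_object == trial.object)
    return [
        ObjectIdResult(subject, cond, 100.0 * np.mean(hits) if hits else float("nan"), len(hits))
        for cond, hits in buckets.items()
        if hits
    ]


# ----------------------------------------------------------------------
# cross-validation driver


@dataclass
class CrossvalResult:
    subject: str
    fold_results: list[FoldResult]
    object_id_results: list[ObjectIdResult]
    audit_log: pd.DataFrame  # fold x role x trial index: proves no leakage

    @property
    def mean_unimodal(self) -> float:
        return float(np.mean([f.unimodal_accuracy for f in self.fold_results]))

    @property
    def mean_multimodal(self) -> float:
        return float(np.mean([f.multimodal_accuracy for f in self.fold_results]))


def crossval_driver(
    recording: SubjectRecording,
    pairing: GraspObjectMap,
    model_spec: ModelSpec | None = None,
    train_config: TrainConfig = TrainConfig(),
    window: WindowSpec = WindowSpec(),
    gaze_config: GazeConfig = GazeConfig(),
    fusion_config: FusionConfig = FusionConfig(),
) -> CrossvalResult:
    """4-fold cross-validated unimodal and multimodal evaluation.

    For each fold: the other three folds form the training pool, from
    which a validation repetition per (condition x grasp) is drawn
    (210/30 for the full protocol); the scaler and the classifier see
    training repetitions only; both approaches are then streamed over
    the held-out fold's analysis windows.  The audit log records every
    trial's role per fold so train/test disjointness is checkable.
    """
    class_map = ClassMap.from_pairing(pairing)
    if model_spec is None:
        model_spec = ModelSpec(output_units=class_map.n_classes)
    if model_spec.output_units != class_map.n_classes:
        raise ValueError("model output_units must match the taxonomy size")
    timelines = annotate_stream(
        recording.gaze, recording.detections, recording.trials, gaze_config, recording.sampling
    )
    trials = recording.trials
    fold_ids = sorted({t.fold_id for t in trials})
    fold_results: list[FoldResult] = []
    evaluations: list[TrialEvaluation] = []
    audit_rows = []

    for fold in fold_ids:
        test_idx = [i for i, t in enumerate(trials) if t.fold_id == fold]
        pool_idx = [i for i, t in enumerate(trials) if t.fold_id != fold]
        pool = [trials[i] for i in pool_idx]
        train_trials, val_trials = split_train_validation(pool, seed=train_config.seed + fold)
        # map back to recording indices (objects are unique per identity)
        by_id = {id(t): i for i, t in zip(pool_idx, pool)}
        train_idx = [by_id[id(t)] for t in train_trials]
        val_idx = [by_id[id(t)] for t in val_trials]
        for role, idxs in (("train", train_idx), ("validation", val_idx), ("test", test_idx)):
            audit_rows += [{"fold": fold, "role": role, "trial": i} for i in idxs]

        scaler = fit_scaler([recording.emg[trials[i].start_sample : trials[i].end_sample] for i in train_idx])

        def _windows(idxs):
            xs, ys = [], []
            for i in idxs:
                t = trials[i]
                seg = transform(recording.emg[t.start_sample : t.end_sample], scaler)
                labels = recording.emg_labels[t.start_sample : t.end_sample]
                w, wl = window_segment(seg, labels, window)
                if len(w):
                    xs.append(w)
                    ys.append(wl)
            X = tensorize(np.concatenate(xs), window)
            y = class_map.encode_labels(np.concatenate(ys))
            return X, y

        Xtr, ytr = _windows(train_idx)
        Xval, yval = _windows(val_idx)
        cfg = TrainConfig(
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            class_weights=compute_class_weights(ytr, class_map.n_classes),
            seed=train_config.seed + fold,
        )
        model = build_model(model_spec, seed=train_config.seed + fold, window=window,
                            n_channels=recording.sampling.n_electrodes)
        train(model, Xtr, ytr, Xval, yval, cfg)

        Xte, yte = _windows(test_idx)
        heldout_acc = accuracy(model.predict_proba(Xte).argmax(axis=1), yte)

        uni_dec, fused_dec, step_labs = [], [], []
        for i in test_idx:
            ev = evaluate_trial(
                recording, i, model, scaler, timelines[i], pairing, class_map,
                window, gaze_config, fusion_config,
            )
            evaluations.append(ev)
            uni_dec.append(ev.unimodal)
            fused_dec.append(ev.fused)
            step_labs.append(ev.step_labels)
        uni = np.concatenate(uni_dec)
        fused = np.concatenate(fused_dec)
        labs = np.concatenate(step_labs)
        fold_results.append(
            FoldResult(
                fold_id=fold,
                unimodal_accuracy=accuracy(uni, labs),
                multimodal_accuracy=accuracy(fused, labs),
                confusion_unimodal=confusion_matrix(uni, labs, class_map.n_classes),
                confusion_multimodal=confusion_matrix(fused, labs, class_map.n_classes),
                heldout_window_accuracy=heldout_acc,
                n_steps=len(labs),
            )
        )

    oid = object_id_rate(evaluations, trials, recording.subject_id)
    return CrossvalResult(
        subject=recording.subject_id,
        fold_results=fold_results,
        object_id_results=oid,
        audit_log=pd.DataFrame(audit_rows),
    )
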