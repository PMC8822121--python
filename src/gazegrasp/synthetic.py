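"""Protocol-faithful synthetic multimodal recordings.

Generates, per subject, the three time-aligned streams the pipeline
consumes — 12-channel sEMG at 1926 Hz with per-sample grasp labels, a
monocular gaze stream at 100 Hz, and per-video-frame (25 FPS) object
detections — together with ground-truth trial metadata, standing in for
a real multimodal grasping acquisition.

The sEMG model is deliberately simple: rest is zero-mean Gaussian noise
and a grasp adds a per-grasp 12-channel activation signature under a
smooth raised-cosine on/off envelope.  It reproduces the *structure* the
pipeline depends on (rest-grasp-rest segments, separable per-grasp
patterns, label alignment), not sEMG physiology.

Scenes are static per trial: the target object plus at least four
distractors placed as non-overlapping simple polygons in a 1920x1080 px
frame.  Gaze fixates the target from ``fixation_lead`` seconds before
the grasp onset (the pre-movement target fixation of natural eye-hand
coordination) and wanders across distractors otherwise; in the dynamic
condition it leaves the target shortly after the onset.  Detections
carry score jitter, missed and spurious instances, and contour jitter.
Detection frames are stored only inside each trial's analysis window
(2 s before to 3.5 s after the onset, clipped to the trial's segment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .protocol import (
    CONDITIONS,
    OBJECT_CLASSES,
    PERSON,
    REPS_PER_CELL,
    Condition,
    GraspObjectMap,
    GraspType,
    TrialMeta,
    assign_folds,
)

__all__ = [
    "SamplingSpec",
    "SynthConfig",
    "Instance",
    "DetectionFrame",
    "SubjectRecording",
    "generate_subject",
    "synthesize_emg_segment",
    "generate_scene_and_gaze",
    "default_signatures",
]


@dataclass(frozen=True)
class SamplingSpec:
    """Stream rates and channel count of the acquisition setup."""

    emg_rate: float = 1926.0
    gaze_rate: float = 100.0
    video_rate: float = 25.0
    n_electrodes: int = 12

    def __post_init__(self):
        if min(self.emg_rate, self.gaze_rate, self.video_rate) <= 0:
            raise ValueError("all rates must be positive")
        if self.n_electrodes != 12:
            raise ValueError("the electrode setup has 12 channels")


@dataclass(frozen=True)
class Instance:
    """One detected object instance in a video frame."""

    label: str
    score: float
    polygon: np.ndarray  # (k, 2) float32 pixel vertices

    def __eq__(self, other):
        return (
            isinstance(other, Instance)
            and self.label == other.label
            and self.score == other.score
            and np.array_equal(self.polygon, other.polygon)
        )


@dataclass(frozen=True)
class DetectionFrame:
    """Detections of one video frame."""

    frame_index: int
    timestamp: float
    instances: tuple[Instance, ...]


@dataclass
class SubjectRecording:
    """One subject's time-aligned multimodal recording with ground truth.

    All streams share the time origin t = 0 at the first sEMG sample.
    """

    subject_id: str
    population: str  # "amputee" | "able_bodied"
    sampling: SamplingSpec
    emg: np.ndarray  # (n_samples, 12) float32
    emg_labels: np.ndarray  # (n_samples,) int16 grasp id (0 = rest)
    gaze: pd.DataFrame  # columns t, x, y, valid
    detections: list[DetectionFrame]
    trials: list[TrialMeta]
    seed: int | None = None

    @property
    def duration(self) -> float:
        return len(self.emg) / self.sampling.emg_rate


@dataclass
class SynthConfig:
    """Generator parameters.

    Defaults realize the acquisition protocol: rest of at least 1 s on
    each side of a grasp, at least five objects in the scene, and a
    pre-onset target fixation.
    """

    seed: int = 0
    rest_range: tuple[float, float] = (1.0, 3.0)  # s, uniform
    grasp_range: tuple[float, float] = (1.5, 2.5)  # s, uniform
    envelope_ramp: float = 0.1  # s, raised-cosine on/off ramp
    signature_amplitude: float = 1.0
    signatures: np.ndarray | None = None  # (n_grasps, 12), rows pairwise distinct
    noise_sd: float = 0.25
    population: str = "able_bodied"
    amputee_noise_multiplier: float = 1.5  # variability-only population difference
    # vision / gaze
    frame_size: tuple[int, int] = (1920, 1080)
    distractor_count: int = 4  # extra objects beside the target (>= 4)
    fixation_lead: float = 1.0  # s gaze lands on target before onset
    fixation_hold: float = 0.25  # s gaze stays on target after onset (static)
    gaze_shift_delay: float = 0.3  # s after onset gaze leaves target (dynamic)
    gaze_jitter_px: float = 4.0
    gaze_invalid_rate: float = 0.02
    dwell_range: tuple[float, float] = (0.25, 0.6)  # s per saccade target
    # detection noise
    score_mean: float = 0.93
    score_sd: float = 0.05
    miss_prob: float = 0.05
    target_miss_prob: float | None = None  # None -> miss_prob
    spurious_prob: float = 0.02
    contour_jitter_px: float = 1.0
    person_prob: float = 0.3  # chance a scene contains a person instance
    min_separation_px: float = 50.0
    object_radius_range: tuple[float, float] = (60.0, 110.0)
    pre_window: float = 2.0  # analysis window around the onset, s
    post_window: float = 3.5

    def __post_init__(self):
        if self.rest_range[0] < 1.0:
            raise ValueError("rest duration minimum is 1 s by protocol")
        if self.distractor_count < 4:
            raise ValueError("scenes must contain at least 5 objects (>= 4 distractors)")

    def effective_noise_sd(self) -> float:
        if self.population == "amputee":
            return self.noise_sd * self.amputee_noise_multiplier
        return self.noise_sd


def default_signatures(n_grasps: int, n_channels: int = 12, amplitude: float = 1.0) -> np.ndarray:
    """Pairwise-distinct nonnegative activation signatures.

    Grasp ``g`` (0-based row) activates three channels offset by g with
    decaying amplitudes, so each grasp has a unique spatial pattern
    across the electrode ring.
    """
    sig = np.zeros((n_grasps, n_channels), dtype=np.float64)
    for g in range(n_grasps):
        for j, a in enumerate((1.0, 0.8, 0.6)):
            sig[g, (g + 4 * j) % n_channels] += a * amplitude
    return sig


def _raised_cosine_envelope(n_samples: int, ramp_samples: int) -> np.ndarray:
    env = np.ones(n_samples)
    r = min(ramp_samples, n_samples // 2)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def synthesize_emg_segment(
    grasp: GraspType,
    durations: tuple[float, float, float],
    config: SynthConfig,
    rng: np.random.Generator,
    signature: np.ndarray,
    sampling: SamplingSpec = SamplingSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """One rest-grasp-rest sEMG segment with per-sample labels.

    ``durations`` is (rest_before, grasp, rest_after) in seconds.  Rest
    is zero-mean Gaussian noise; the grasp adds ``signature`` under a
    raised-cosine envelope.  Labels mark the nominal grasp interval with
    the grasp id; rest is 0.
    """
    rest1, grasp_dur, rest2 = durations
    fs = sampling.emg_rate
    n1, ng, n2 = (int(round(d * fs)) for d in (rest1, grasp_dur, rest2))
    n = n1 + ng + n2
    noise_sd = config.effective_noise_sd()
    signal = rng.normal(0.0, noise_sd, size=(n, sampling.n_electrodes)) if noise_sd > 0 else np.zeros(
        (n, sampling.n_electrodes)
    )
    env = _raised_cosine_envelope(ng, int(round(config.envelope_ramp * fs)))
    signal[n1 : n1 + ng] += env[:, None] * signature[None, :]
    labels = np.zeros(n, dtype=np.int16)
    labels[n1 : n1 + ng] = grasp.id
    return signal.astype(np.float32), labels


def _make_polygon(center: np.ndarray, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Simple (star-shaped) polygon of 8-16 vertices around a center."""
    k = int(rng.integers(8, 17))
    base = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    angles = base + rng.uniform(-0.3, 0.3, size=k) * (2.0 * np.pi / k)
    radii = radius * (1.0 + rng.uniform(-0.15, 0.15, size=k))
    pts = center[None, :] + np.c_[np.cos(angles), np.sin(angles)] * radii[:, None]
    return pts.astype(np.float32)


def _place_scene(
    trial: TrialMeta,
    pairing: GraspObjectMap,
    config: SynthConfig,
    rng: np.random.Generator,
    max_tries: int = 500,
) -> list[tuple[str, np.ndarray]]:
    """Target + distractor polygons, pairwise separated, inside the frame."""
    w, h = config.frame_size
    rmin, rmax = config.object_radius_range
    placed: list[tuple[str, np.ndarray]] = []
    shapes: list[Polygon] = []

    other_objects = [o for o in pairing.objects if o != trial.object]
    labels = [trial.object]
    n_distr = config.distractor_count
    labels += [other_objects[int(rng.integers(len(other_objects)))] for _ in range(n_distr)]
    if rng.uniform() < config.person_prob:
        labels.append(PERSON)

    for i, label in enumerate(labels):
        radius = rng.uniform(rmin, rmax)
        for attempt in range(max_tries):
            if i == 0:  # target near the frame center, where gaze dwells
                center = np.array(
                    [rng.uniform(w * 0.3, w * 0.7), rng.uniform(h * 0.3, h * 0.7)]
                )
            else:
                center = np.array(
                    [rng.uniform(rmax, w - rmax), rng.uniform(rmax, h - rmax)]
                )
            poly = _make_polygon(center, radius, rng)
            shape = Polygon(poly)
            if all(shape.distance(s) > config.min_separation_px for s in shapes):
                placed.append((label, poly))
                shapes.append(shape)
                break
        else:
            raise RuntimeError(
                f"could not place object {label!r} after {max_tries} tries; "
                "reduce distractor_count or object size"
            )
    return placed


def _representative_point(poly: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = Polygon(poly).representative_point()
    return np.array([p.x, p.y])


def generate_scene_and_gaze(
    trial: TrialMeta,
    config: SynthConfig,
    rng: np.random.Generator,
    pairing: GraspObjectMap,
    sampling: SamplingSpec = SamplingSpec(),
) -> tuple[list[DetectionFrame], pd.DataFrame]:
    """Scene detections and gaze stream for one trial's segment.

    Gaze covers the whole segment at the gaze rate; detection frames are
    emitted only within the analysis window around the onset, clipped to
    the segment.  Timestamps are global (shared origin with the sEMG).
    """
    if trial.onset_sample < 0 or trial.start_sample < 0:
        raise ValueError("trial must carry onset and segment bounds")
    fs = sampling.emg_rate
    t_start = trial.start_sample / fs
    t_end = trial.end_sample / fs
    t_onset = trial.onset_sample / fs

    scene = _place_scene(trial, pairing, config, rng)
    target_point = _representative_point(scene[0][1], rng)
    distractor_points = [_representative_point(p, rng) for _, p in scene[1:]]

    # --- gaze ---------------------------------------------------------
    # Sample instants on the global gaze clock that fall in the segment.
    i0 = int(math.ceil(t_start * sampling.gaze_rate))
    i1 = int(math.ceil(t_end * sampling.gaze_rate))
    t = np.arange(i0, i1) / sampling.gaze_rate
    xy = np.empty((len(t), 2))

    fix_start = t_onset - config.fixation_lead
    if trial.condition is Condition.dynamic:
        fix_end = t_onset + config.gaze_shift_delay
    else:
        fix_end = t_onset + config.fixation_hold

    # wander schedule outside the fixation window: piecewise dwells
    def wander_point() -> np.ndarray:
        if distractor_points and rng.uniform() < 0.8:
            return distractor_points[int(rng.integers(len(distractor_points)))]
        w, h = config.frame_size
        return np.array([rng.uniform(0, w), rng.uniform(0, h)])

    cursor = t_start
    current = wander_point()
    dwell_until = cursor + rng.uniform(*config.dwell_range)
    for j, tj in enumerate(t):
        if fix_start <= tj <= fix_end:
            xy[j] = target_point
        else:
            if tj > dwell_until:
                current = wander_point()
                dwell_until = tj + rng.uniform(*config.dwell_range)
            xy[j] = current
    if config.gaze_jitter_px > 0:
        xy += rng.normal(0.0, config.gaze_jitter_px, size=xy.shape)
    w, h = config.frame_size
    xy[:, 0] = np.clip(xy[:, 0], 0, w - 1)
    xy[:, 1] = np.clip(xy[:, 1], 0, h - 1)
    valid = rng.uniform(size=len(t)) >= config.gaze_invalid_rate
    gaze = pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1], "valid": valid})

    # --- detections ---------------------------------------------------
    win_start = max(t_onset - config.pre_window, t_start)
    win_end = min(t_onset + config.post_window, t_end)
    f0 = int(math.ceil(win_start * sampling.video_rate))
    f1 = int(math.floor(win_end * sampling.video_rate))
    frames: list[DetectionFrame] = []
    target_miss = config.miss_prob if config.target_miss_prob is None else config.target_miss_prob
    for fi in range(f0, f1 + 1):
        instances: list[Instance] = []
        for k, (label, poly) in enumerate(scene):
            miss = target_miss if k == 0 else config.miss_prob
            if rng.uniform() < miss:
                continue
            score = float(np.clip(rng.normal(config.score_mean, config.score_sd), 0.0, 1.0))
            verts = poly
            if config.contour_jitter_px > 0:
                verts = poly + rng.normal(0.0, config.contour_jitter_px, size=poly.shape).astype(
                    np.float32
                )
            instances.append(Instance(label, score, verts.astype(np.float32)))
        if rng.uniform() < config.spurious_prob:
            center = np.array([rng.uniform(0, w), rng.uniform(0, h)])
            poly = _make_polygon(center, rng.uniform(20, 50), rng)
            label = OBJECT_CLASSES[int(rng.integers(len(OBJECT_CLASSES)))]
            score = float(np.clip(rng.normal(0.85, 0.1), 0.0, 1.0))
            instances.append(Instance(label, score, poly))
        frames.append(
            DetectionFrame(frame_index=fi, timestamp=fi / sampling.video_rate, instances=tuple(instances))
        )
    return frames, gaze


def _build_trial_plan(pairing: GraspObjectMap, subject: str) -> list[TrialMeta]:
    """Full protocol plan: per grasp, 12+12+8 repetitions in grasp blocks."""
    trials: list[TrialMeta] = []
    for grasp in pairing.grasps:
        objects = pairing.objects_for(grasp)
        for cond in CONDITIONS:
            cond_objects = objects if cond is not Condition.dynamic else objects[:2]
            for rep in range(REPS_PER_CELL):
                for obj in cond_objects:
                    trials.append(
                        TrialMeta(
                            subject=subject,
                            grasp=grasp,
                            object=obj,
                            condition=cond,
                            repetition_index=rep,
                        )
                    )
    return trials


def generate_subject(
    config: SynthConfig,
    pairing: GraspObjectMap,
    subject: str = "S001",
    sampling: SamplingSpec = SamplingSpec(),
) -> SubjectRecording:
    """Generate one subject's full-protocol multimodal recording.

    For the 10-grasp pairing this realizes 10 x 32 = 320 rest-grasp-rest
    segments; a miniature pairing scales the count accordingly.  All
    randomness is drawn from ``config.seed``, so equal seeds give
    bit-identical recordings.
    """
    rng = np.random.default_rng(config.seed)
    signatures = config.signatures
    if signatures is None:
        signatures = default_signatures(
            len(pairing.grasps), sampling.n_electrodes, config.signature_amplitude
        )
    sig_by_grasp = {g: signatures[i] for i, g in enumerate(pairing.grasps)}
    if len({tuple(np.round(s, 9)) for s in sig_by_grasp.values()}) != len(sig_by_grasp):
        raise ValueError("activation signatures must be pairwise distinct")

    min_grasp = config.grasp_range[0]
    if min_grasp * sampling.emg_rate < 200:
        raise ValueError("grasp duration shorter than one 200-sample window")

    plan = _build_trial_plan(pairing, subject)
    emg_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    gaze_parts: list[pd.DataFrame] = []
    detections: list[DetectionFrame] = []
    trials: list[TrialMeta] = []
    cursor = 0
    for t in plan:
        rest1 = rng.uniform(*config.rest_range)
        grasp_dur = rng.uniform(*config.grasp_range)
        rest2 = rng.uniform(*config.rest_range)
        signal, labels = synthesize_emg_segment(
            t.grasp, (rest1, grasp_dur, rest2), config, rng, sig_by_grasp[t.grasp], sampling
        )
        n1 = int(round(rest1 * sampling.emg_rate))
        trial = replace(
            t,
            start_sample=cursor,
            end_sample=cursor + len(signal),
            onset_sample=cursor + n1,
        )
        frames, gaze = generate_scene_and_gaze(trial, config, rng, pairing, sampling)
        emg_parts.append(signal)
        label_parts.append(labels)
        gaze_parts.append(gaze)
        detections.extend(frames)
        trials.append(trial)
        cursor += len(signal)

    trials = assign_folds(trials)
    return SubjectRecording(
        subject_id=subject,
        population=config.population,
        sampling=sampling,
        emg=np.concatenate(emg_parts),
        emg_labels=np.concatenate(label_parts),
        gaze=pd.concat(gaze_parts, ignore_index=True),
        detections=detections,
        trials=trials,
        seed=config.seed,
    )
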