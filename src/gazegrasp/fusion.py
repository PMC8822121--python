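"""Multimodal decision fusion.

The continuously running sEMG classifier doubles as intent detector:
the first non-rest classification after rest (or after stream start)
triggers a search for the target object — the last object looked at in
the previous 480 sEMG samples (~250 ms); if none, the search continues
until 500 ms after the intent.  Once an object is identified, the final
grasp is the classifier's highest-probability grasp *restricted to the
grasp types paired with that object*; if no object is found in time the
output stays purely sEMG-based.  The machine resets as soon as a sample
is classified as rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import ClassMap, ProbStream
from .protocol import GraspObjectMap

__all__ = ["FusionConfig", "FusionState", "detect_intent", "find_target_object", "fuse_decision", "run_fusion"]

REST_IDX = 0


@dataclass(frozen=True)
class FusionConfig:
    """Timing constants of the fusion state machine (sEMG sample clock)."""

    lookback: int = 480  # samples, ~250 ms at 1926 Hz
    forward_timeout: float = 0.5  # s after the intent
    stride: int = 20  # samples between classification steps
    emg_rate: float = 1926.0
    rest_debounce: int = 1  # consecutive rest steps required to reset

    def __post_init__(self):
        if min(self.lookback, self.forward_timeout, self.stride, self.emg_rate) <= 0:
            raise ValueError("all timing constants must be positive")

    @property
    def timeout_steps(self) -> int:
        """Forward-search budget in classification steps: ceil(0.5 s / stride)."""
        return int(math.ceil(self.forward_timeout * self.emg_rate / self.stride))


class FusionState(str, Enum):
    REST = "REST"
    SEARCHING = "SEARCHING"
    FUSED = "FUSED"
    EMG_ONLY = "EMG_ONLY"


def detect_intent(prob_stream: ProbStream) -> list[int]:
    """Step indices of grasp-intent events.

    An event fires at the first step whose argmax is non-rest following
    a rest step or the stream start; later non-rest steps of the same
    episode fire no event.
    """
    cls = prob_stream.argmax
    events = []
    prev_rest = True
    for i, c in enumerate(cls):
        if c != REST_IDX and prev_rest:
            events.append(i)
        prev_rest = c == REST_IDX
    return events


def _timeline_lookup(timeline: pd.DataFrame):
    t = timeline["t"].to_numpy(dtype=np.float64)
    labels = timeline["looked_at"].to_numpy(dtype=object)
    return t, labels


def find_target_object(
    timeline: pd.DataFrame, intent_sample: int, config: FusionConfig = FusionConfig()
) -> tuple[str | None, int | None]:
    """Offline target-object query for one intent event.

    Returns the most recent looked-at label in the half-open lookback
    window (intent - 480, intent] on the sEMG sample clock; failing
    that, the first label in the forward window (intent, intent +
    500 ms]; else (None, None).  The reported sample is where the
    object became known: the intent sample for lookback hits, the
    (sample-converted) gaze timestamp for forward hits.
    """
    t, labels = _timeline_lookup(timeline)
    fs = config.emg_rate
    lo = (intent_sample - config.lookback) / fs
    ti = intent_sample / fs
    back = np.flatnonzero((t > lo) & (t <= ti + 1e-12) & (labels != None))  # noqa: E711
    if len(back):
        return str(labels[back[-1]]), int(intent_sample)
    hi = ti + config.forward_timeout
    fwd = np.flatnonzero((t > ti + 1e-12) & (t <= hi + 1e-12) & (labels != None))  # noqa: E711
    if len(fwd):
        return str(labels[fwd[0]]), int(math.ceil(t[fwd[0]] * fs))
    return None, None


def fuse_decision(p: np.ndarray, allowed: Sequence[int]) -> int:
    """Argmax of the posterior restricted to the allowed class indices."""
    allowed = np.asarray(sorted(set(allowed)), dtype=np.int64)
    if len(allowed) == 0:
        raise ValueError("empty allowed class set")
    if REST_IDX in allowed:
        raise ValueError("rest cannot be in the allowed grasp set")
    return int(allowed[np.argmax(np.asarray(p)[allowed])])


def run_fusion(
    prob_stream: ProbStream,
    timeline: pd.DataFrame,
    pairing: GraspObjectMap,
    class_map: ClassMap,
    config: FusionConfig = FusionConfig(),
) -> pd.DataFrame:
    """Stream the fusion state machine over one analysis window.

    Per step: a rest classification outputs rest and resets; a non-rest
    classification after rest triggers the lookback query, then forward
    search (unimodal output while searching), then either restricted
    argmax over the identified object's paired grasps (FUSED) or the
    plain unimodal output after the 500 ms timeout (EMG_ONLY).

    Returns the trace: one row per step with columns t, state,
    unimodal, fused (class indices) and object.
    """
    t_steps = prob_stream.t
    probs = prob_stream.p
    unimodal = prob_stream.argmax
    tl_t, tl_labels = _timeline_lookup(timeline)
    fs = config.emg_rate

    state = FusionState.REST
    obj: str | None = None
    allowed: list[int] = []
    intent_sample = 0
    steps_since_intent = 0
    rest_run = 0
    rows = []
    for i in range(len(t_steps)):
        t = int(t_steps[i])
        u = int(unimodal[i])
        if u == REST_IDX:
            rest_run += 1
            if rest_run >= config.rest_debounce:
                state = FusionState.REST
                obj = None
            fused = u  # rest passes through identically in both approaches
        else:
            rest_run = 0
            if state is FusionState.REST:
                intent_sample = t
                steps_since_intent = 0
                lo = (t - config.lookback) / fs
                hit = np.flatnonzero(
                    (tl_t > lo) & (tl_t <= t / fs + 1e-12) & (tl_labels != None)  # noqa: E711
                )
                if len(hit):
                    obj = str(tl_labels[hit[-1]])
                    allowed = [class_map.index_of(g.id) for g in pairing.grasps_for(obj)]
                    state = FusionState.FUSED
                else:
                    state = FusionState.SEARCHING
            elif state is FusionState.SEARCHING:
                steps_since_intent += 1
                # hits count only within the 500 ms forward window even if
                # the step grid overshoots it
                hi = min(t / fs, intent_sample / fs + config.forward_timeout)
                hit = np.flatnonzero(
                    (tl_t > intent_sample / fs + 1e-12)
                    & (tl_t <= hi + 1e-12)
                    & (tl_labels != None)  # noqa: E711
                )
                if len(hit):
                    obj = str(tl_labels[hit[0]])
                    allowed = [class_map.index_of(g.id) for g in pairing.grasps_for(obj)]
                    state = FusionState.FUSED
                elif steps_since_intent >= config.timeout_steps:
                    state = FusionState.EMG_ONLY
            fused = _fused_or_unimodal(state, probs[i], allowed, u)
        rows.append(
            {
                "t": t,
                "state": state.value,
                "unimodal": u,
                "fused": fused,
                "object": obj if state is FusionState.FUSED else None,
            }
        )
    return pd.DataFrame(rows, columns=["t", "state", "unimodal", "fused", "object"])


def _fused_or_unimodal(state: FusionState, p: np.ndarray, allowed: list[int], u: int) -> int:
    if state is FusionState.FUSED:
        return fuse_decision(p, allowed)
    return u
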