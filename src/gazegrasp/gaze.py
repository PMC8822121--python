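"""Gaze-to-object association.

Identifies, per gaze sample, which detected object instance (if any)
the subject is looking at: detection instances are filtered by score
(>= 0.8) and the reserved person/background labels are excluded; an
object counts as looked at when the gaze point lies strictly closer
than 20 px (Euclidean) to its contour, with points inside the contour
at distance 0 by default.  The association is evaluated at the gaze
stream's native rate, only within the analysis window from 2 s before
to 3.5 s after each grasp onset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .protocol import BACKGROUND, PERSON, TrialMeta
from .synthetic import DetectionFrame, SamplingSpec

__all__ = [
    "GazeConfig",
    "filter_instances",
    "point_contour_distance",
    "looked_at_object",
    "annotate_stream",
    "timeline_to_csv",
    "timeline_from_csv",
]

TIMELINE_COLUMNS = ["t", "looked_at", "distance_px", "frame_index", "valid_instance"]


@dataclass(frozen=True)
class GazeConfig:
    """Association thresholds and analysis-window extent."""

    score_min: float = 0.8
    distance_max: float = 20.0  # px, strict
    pre_window: float = 2.0  # s before the grasp onset
    post_window: float = 3.5  # s after
    boundary_only: bool = False  # distance to the contour polyline even when inside

    def __post_init__(self):
        if min(self.score_min, self.distance_max, self.pre_window, self.post_window) <= 0:
            raise ValueError("thresholds and window extents must be positive")


def filter_instances(frame: DetectionFrame, config: GazeConfig = GazeConfig()) -> DetectionFrame:
    """Drop low-score (< score_min) and person/background instances.

    A score exactly at the threshold is kept ("lower than" is strict).
    """
    kept = tuple(
        inst
        for inst in frame.instances
        if inst.score >= config.score_min and inst.label not in (PERSON, BACKGROUND)
    )
    return DetectionFrame(frame.frame_index, frame.timestamp, kept)


def point_contour_distance(x: float, y: float, contour: np.ndarray, boundary_only: bool = False) -> float:
    """Euclidean distance in px from a point to an object contour.

    Points strictly inside the polygon are at distance 0 unless
    ``boundary_only`` is set, in which case the distance to the contour
    polyline is returned regardless of side.  Degenerate polygons
    (fewer than 3 vertices, non-finite or zero-area) raise.
    """
    contour = np.asarray(contour, dtype=np.float64)
    if contour.ndim != 2 or contour.shape[0] < 3 or contour.shape[1] != 2:
        raise ValueError(f"contour must be (k>=3, 2), got {contour.shape}")
    if not np.all(np.isfinite(contour)):
        raise ValueError("contour has non-finite vertices")
    poly = Polygon(contour)
    if poly.area == 0 or not poly.is_valid:
        raise ValueError("degenerate polygon")
    pt = Point(x, y)
    if boundary_only:
        return float(poly.exterior.distance(pt))
    return float(poly.distance(pt))  # 0 inside


def looked_at_object(
    x: float,
    y: float,
    valid: bool,
    frame: DetectionFrame,
    config: GazeConfig = GazeConfig(),
) -> tuple[str | None, float]:
    """The looked-at object label for one gaze sample, or None.

    Returns the label of the score-filtered instance minimizing the
    contour distance, provided that distance is strictly below
    ``distance_max``; None when the gaze sample is invalid, no filtered
    instance exists, or no instance is close enough.  Equidistant
    instances break toward the lower instance index in the frame.
    """
    if not valid:
        return None, math.nan
    kept = filter_instances(frame, config)
    if not kept.instances:
        return None, math.nan
    best_label, best_dist = None, math.inf
    for inst in kept.instances:
        d = point_contour_distance(x, y, inst.polygon, config.boundary_only)
        if d < best_dist:  # strict: first (lowest index) wins ties
            best_label, best_dist = inst.label, d
    if best_dist < config.distance_max:
        return best_label, best_dist
    return None, best_dist


def annotate_stream(
    gaze: pd.DataFrame,
    detections: Sequence[DetectionFrame],
    trials: Sequence[TrialMeta],
    config: GazeConfig = GazeConfig(),
    sampling: SamplingSpec = SamplingSpec(),
) -> dict[int, pd.DataFrame]:
    """Looked-at timeline per trial over the analysis window.

    For each trial, gaze samples with onset - pre_window <= t <
    onset + post_window (native gaze rate) are associated with the last
    started video frame (floor to the frame interval containing the
    timestamp) and labelled.  Windows extending beyond the recording
    are truncated with a warning.  Returns trial index -> DataFrame
    with columns t, looked_at (None when no object), distance_px,
    frame_index, valid_instance.
    """
    frames_by_index = {f.frame_index: f for f in detections}
    t_all = gaze["t"].to_numpy()
    timelines: dict[int, pd.DataFrame] = {}
    for ti, trial in enumerate(trials):
        t_on = trial.onset_sample / sampling.emg_rate
        lo, hi = t_on - config.pre_window, t_on + config.post_window
        if lo < t_all[0] - 1e-9 or hi > t_all[-1] + 1.0 / sampling.gaze_rate + 1e-9:
            warnings.warn(f"trial {ti}: analysis window [{lo:.2f}, {hi:.2f}] s truncated to recording")
        j0, j1 = np.searchsorted(t_all, [lo - 1e-9, hi - 1e-9])
        rows = []
        cached: dict[int, DetectionFrame] = {}
        for j in range(j0, j1):
            t = float(t_all[j])
            fi = int(math.floor(t * sampling.video_rate + 1e-9))
            frame = cached.get(fi)
            if frame is None:
                frame = filter_instances(
                    frames_by_index.get(fi, DetectionFrame(fi, fi / sampling.video_rate, ())), config
                )
                cached[fi] = frame
            x, y, valid = float(gaze["x"].iat[j]), float(gaze["y"].iat[j]), bool(gaze["valid"].iat[j])
            label, dist = looked_at_object(x, y, valid, frame, config)
            rows.append(
                {
                    "t": t,
                    "looked_at": label,
                    "distance_px": dist,
                    "frame_index": fi,
                    "valid_instance": valid and len(frame.instances) > 0,
                }
            )
        timelines[ti] = pd.DataFrame(rows, columns=TIMELINE_COLUMNS)
    return timelines


def timeline_to_csv(timeline: pd.DataFrame, path) -> None:
    timeline.to_csv(path, index=False)


def timeline_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    df["looked_at"] = df["looked_at"].where(df["looked_at"].notna(), None)
    return df[TIMELINE_COLUMNS]
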