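"""Recording bundles on disk.

A bundle is a directory holding one subject's streams in open formats:

    manifest.json     sampling spec, subject id, population, seed
    emg.h5            sEMG matrix + per-sample labels (HDF5)
    gaze.csv          t, x, y, valid
    detections.jsonl  one frame per line: frame_index, timestamp,
                      instances [{label, score, polygon: [[x, y], ...]}]
    trials.csv        trial metadata table

Round trips are bit-exact for all streams.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .protocol import trials_from_csv, trials_to_csv
from .synthetic import DetectionFrame, Instance, SamplingSpec, SubjectRecording

__all__ = ["write_bundle", "read_bundle"]

_FILES = ("manifest.json", "emg.h5", "gaze.csv", "detections.jsonl", "trials.csv")


def write_bundle(recording: SubjectRecording, path) -> dict:
    """Write a recording bundle; returns the manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_id": recording.subject_id,
        "population": recording.population,
        "seed": recording.seed,
        "sampling": {
            "emg_rate": recording.sampling.emg_rate,
            "gaze_rate": recording.sampling.gaze_rate,
            "video_rate": recording.sampling.video_rate,
            "n_electrodes": recording.sampling.n_electrodes,
        },
        "n_emg_samples": int(len(recording.emg)),
        "n_trials": len(recording.trials),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with h5py.File(path / "emg.h5", "w") as f:
        f.create_dataset("emg", data=recording.emg)
        f.create_dataset("labels", data=recording.emg_labels)
    recording.gaze.to_csv(path / "gaze.csv", index=False)
    with open(path / "detections.jsonl", "w") as f:
        for frame in recording.detections:
            f.write(
                json.dumps(
                    {
                        "frame_index": frame.frame_index,
                        "timestamp": frame.timestamp,
                        "instances": [
                            {
                                "label": i.label,
                                "score": i.score,
                                "polygon": np.asarray(i.polygon, dtype=np.float64).tolist(),
                            }
                            for i in frame.instances
                        ],
                    }
                )
                + "\n"
            )
    trials_to_csv(recording.trials, path / "trials.csv")
    return manifest


def read_bundle(path) -> SubjectRecording:
    """Read a bundle back into a :class:`SubjectRecording`.

    Raises descriptive errors on missing files, schema violations and
    manifest/stream rate mismatches.
    """
    path = Path(path)
    for name in _FILES:
        if not (path / name).exists():
            raise FileNotFoundError(f"bundle {path} is missing {name}")
    manifest = json.loads((path / "manifest.json").read_text())
    sampling = SamplingSpec(**manifest["sampling"])
    with h5py.File(path / "emg.h5", "r") as f:
        emg = f["emg"][:]
        labels = f["labels"][:]
    if emg.shape[1] != sampling.n_electrodes:
        raise ValueError(
            f"manifest declares {sampling.n_electrodes} electrodes but emg has {emg.shape[1]} channels"
        )
    if len(emg) != manifest["n_emg_samples"]:
        raise ValueError("manifest n_emg_samples does not match emg.h5")
    gaze = pd.read_csv(path / "gaze.csv", float_precision="round_trip")
    missing = {"t", "x", "y", "valid"} - set(gaze.columns)
    if missing:
        raise ValueError(f"gaze.csv missing columns {sorted(missing)}")
    # cadence check: median gaze interval must match the declared rate
    if len(gaze) > 1:
        dt = float(np.median(np.diff(gaze["t"].to_numpy())))
        if abs(dt * sampling.gaze_rate - 1.0) > 0.01:
            raise ValueError(
                f"gaze cadence {1.0 / dt:.1f} Hz does not match manifest rate {sampling.gaze_rate} Hz"
            )
    detections = []
    with open(path / "detections.jsonl") as f:
        for lineno, line in enumerate(f, 1):
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"detections.jsonl line {lineno}: invalid JSON ({e})") from e
            detections.append(
                DetectionFrame(
                    frame_index=int(raw["frame_index"]),
                    timestamp=float(raw["timestamp"]),
                    instances=tuple(
                        Instance(
                            label=i["label"],
                            score=float(i["score"]),
                            polygon=np.asarray(i["polygon"], dtype=np.float32),
                        )
                        for i in raw["instances"]
                    ),
                )
            )
    trials = trials_from_csv(path / "trials.csv")
    duration = len(emg) / sampling.emg_rate
    if len(gaze) and abs(len(gaze) / sampling.gaze_rate - duration) > 1.0 / sampling.video_rate + 0.5:
        raise ValueError("gaze and emg durations disagree by more than a frame period")
    return SubjectRecording(
        subject_id=manifest["subject_id"],
        population=manifest["population"],
        sampling=sampling,
        emg=emg,
        emg_labels=labels,
        gaze=gaze,
        detections=detections,
        trials=trials,
        seed=manifest.get("seed"),
    )
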