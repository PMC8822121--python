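"""The ConvLSTM grasp-type classifier: construction, training, inference.

Defaults follow the reference architecture and regime: ConvLSTM with 128
filters and a 1x3 kernel, dropout 0.5, dense layers of 200 and 50 ReLU
units, dropout 0.2, an 11-way softmax head (ten grasps plus rest),
categorical cross-entropy with balanced class weights, Adam with default
parameters, 150 epochs of batches of 32, and best-model selection on
validation accuracy.  Streaming inference re-classifies the trailing
200-sample window every 20 samples (~10 ms at 1926 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .convlstm import Adam, ConvLSTMNet
from .emg import WindowSpec, tensorize
from .protocol import GraspObjectMap, GraspType, REST

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "ClassMap",
    "ProbVector",
    "ProbStream",
    "build_model",
    "compute_class_weights",
    "train",
    "predict_stream",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters."""

    convlstm_filters: int = 128
    kernel: tuple[int, int] = (1, 3)
    dropout1: float = 0.5
    dense_units: tuple[int, int] = (200, 50)
    dropout2: float = 0.2
    output_units: int = 11

    def __post_init__(self):
        if self.kernel[0] != 1:
            raise ValueError("kernel height must be 1 for the 1-row tensor layout")


@dataclass
class TrainConfig:
    """Training regime parameters."""

    epochs: int = 150
    batch_size: int = 32
    class_weights: Mapping[int, float] | None = None  # class index -> weight
    seed: int = 0


class ClassMap:
    """Mapping between grasp ids and contiguous class indices.

    Class 0 is rest; grasps follow in ascending id order, so the full
    taxonomy yields 11 classes and a reduced taxonomy scales down.
    """

    def __init__(self, grasps: Sequence[GraspType]):
        self.grasps = tuple(sorted(grasps))
        self._idx = {REST.id: 0} | {g.id: i + 1 for i, g in enumerate(self.grasps)}
        self._gid = {v: k for k, v in self._idx.items()}

    @classmethod
    def from_pairing(cls, pairing: GraspObjectMap) -> "ClassMap":
        return cls(pairing.grasps)

    @property
    def n_classes(self) -> int:
        return len(self.grasps) + 1

    def index_of(self, grasp_id: int) -> int:
        return self._idx[grasp_id]

    def grasp_id_of(self, index: int) -> int:
        return self._gid[index]

    def encode_labels(self, grasp_ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(grasp_ids)
        lut = np.full(max(self._idx) + 1, -1, dtype=np.int64)
        for gid, idx in self._idx.items():
            lut[gid] = idx
        if np.any(ids < 0) or np.any(ids >= len(lut)):
            raise ValueError("labels contain grasp ids outside the class map")
        out = lut[ids]
        if np.any(out < 0):
            raise ValueError("labels contain grasp ids outside the class map")
        return out


@dataclass(frozen=True)
class ProbVector:
    """One posterior over the classes, emitted at sEMG sample index t."""

    t: int
    p: np.ndarray


@dataclass
class ProbStream:
    """Dense sequence of posteriors from strided streaming inference."""

    t: np.ndarray  # (n,) emitting sample indices (window end, inclusive count)
    p: np.ndarray  # (n, n_classes)

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[ProbVector]:
        return (ProbVector(int(ti), pi) for ti, pi in zip(self.t, self.p))

    @property
    def argmax(self) -> np.ndarray:
        return self.p.argmax(axis=1)


def build_model(
    spec: ModelSpec, seed: int, window: WindowSpec = WindowSpec(), n_channels: int = 12
) -> ConvLSTMNet:
    """Construct the network with seeded initial parameters."""
    return ConvLSTMNet(
        n_filters=spec.convlstm_filters,
        kernel_w=spec.kernel[1],
        dense_units=spec.dense_units,
        n_classes=spec.output_units,
        n_subseq=window.n_subseq,
        width=window.subseq_cols,
        channels=n_channels,
        dropout1=spec.dropout1,
        dropout2=spec.dropout2,
        seed=seed,
    )


def compute_class_weights(window_labels: np.ndarray, n_classes: int) -> dict[int, float]:
    """Balanced inverse-frequency weights: total / (n_classes * count).

    Counters the predominance of the rest class.  Every class must be
    present in the training windows.
    """
    labels = np.asarray(window_labels)
    counts = np.bincount(labels, minlength=n_classes)
    absent = np.flatnonzero(counts == 0).tolist()
    if absent:
        raise ValueError(f"classes absent from training windows: {absent}")
    total = counts.sum()
    return {c: float(total / (n_classes * counts[c])) for c in range(n_classes)}


def _accuracy(model: ConvLSTMNet, X: np.ndarray, y: np.ndarray) -> float:
    return float((model.predict_proba(X).argmax(axis=1) == y).mean())


def train(
    model: ConvLSTMNet,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig,
) -> pd.DataFrame:
    """Train with best-snapshot selection on validation accuracy.

    Runs the fixed number of epochs (no early stopping, no schedule);
    at the end the model carries the parameters of the epoch with the
    highest validation accuracy.  Returns the per-epoch training log.
    Raises on non-finite loss.
    """
    rng = np.random.default_rng(config.seed)
    if config.class_weights is not None:
        wlut = np.array([config.class_weights[c] for c in range(model.n_classes)])
        weights = wlut[train_y]
    else:
        weights = np.ones(len(train_y))
    opt = Adam(model.params)
    best_acc = -1.0
    best_params = model.copy_params()
    log = []
    n = len(train_X)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct, seen = [], 0, 0
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            loss, grads, probs = model.loss_and_grads(
                train_X[idx], train_y[idx], weights[idx], rng=rng, train=True
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {s // config.batch_size}")
            opt.step(model.params, grads)
            losses.append(loss)
            correct += int((probs.argmax(axis=1) == train_y[idx]).sum())
            seen += len(idx)
        val_probs = model.predict_proba(val_X)
        val_acc = float((val_probs.argmax(axis=1) == val_y).mean())
        py = np.clip(val_probs[np.arange(len(val_y)), val_y], 1e-12, None)
        val_loss = float(-np.log(py).mean())
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "train_acc": correct / seen,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_params = model.copy_params()
    model.set_params(best_params)
    return pd.DataFrame(log)


def predict_stream(
    model: ConvLSTMNet,
    standardized_emg: np.ndarray,
    spec: WindowSpec = WindowSpec(),
    t_offset: int = 0,
) -> ProbStream:
    """Strided streaming inference over a standardized-rectified stream.

    Emits one posterior per stride, at samples t = 200, 220, ...,
    classifying the trailing 200-sample window ending at t (causal).
    ``t_offset`` shifts the reported indices to the stream's global
    clock.  A stream shorter than one window yields an empty sequence.
    """
    x = np.asarray(standardized_emg)
    L = len(x)
    if L < spec.window_len:
        return ProbStream(t=np.empty(0, dtype=np.int64), p=np.empty((0, model.n_classes)))
    view = np.lib.stride_tricks.sliding_window_view(x, (spec.window_len, x.shape[1]))[:, 0]
    windows = view[:: spec.stride_inference]  # starts 0, 20, 40, ...
    tensor = tensorize(np.ascontiguousarray(windows), spec)
    probs = model.predict_proba(tensor)
    t = t_offset + spec.window_len + spec.stride_inference * np.arange(len(windows))
    return ProbStream(t=t.astype(np.int64), p=probs)


def save_model(model: ConvLSTMNet, path) -> None:
    """Checkpoint: npz parameter arrays plus embedded architecture JSON."""
    meta = {
        "n_filters": model.F,
        "kernel_w": model.k,
        "dense_units": list(model.dense_units),
        "n_classes": model.n_classes,
        "n_subseq": model.T,
        "width": model.W,
        "channels": model.C,
        "dropout1": model.dropout1,
        "dropout2": model.dropout2,
        "seed": model.seed,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_model(path) -> ConvLSTMNet:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    model = ConvLSTMNet(
        n_filters=meta["n_filters"],
        kernel_w=meta["kernel_w"],
        dense_units=tuple(meta["dense_units"]),
        n_classes=meta["n_classes"],
        n_subseq=meta["n_subseq"],
        width=meta["width"],
        channels=meta["channels"],
        dropout1=meta["dropout1"],
        dropout2=meta["dropout2"],
        seed=meta["seed"],
    )
    model.set_params({k: data[k] for k in model.params})
    return model
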