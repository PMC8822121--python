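"""Structure of the grasping acquisition protocol.

The protocol records a subject performing 10 grasp types on household
objects.  Each grasp type is paired with three objects and repeated 32
times: 12 repetitions seated (*static seated*), 12 standing (*static
standing*) and 8 while additionally manipulating the object (*dynamic*,
on two of the three paired objects).  Repetitions are partitioned into 4
folds of 8 repetitions per grasp (3 seated + 3 standing + 2 dynamic, on
different objects) for cross-validated training.

This module encodes the grasp taxonomy, the object catalog, the
grasp-object pairing table, trial bookkeeping, the fold partition and the
train/validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GraspType",
    "REST",
    "GRASPS",
    "OBJECT_CLASSES",
    "PERSON",
    "BACKGROUND",
    "Condition",
    "GraspObjectMap",
    "TrialMeta",
    "FoldPartition",
    "grasp_object_pairs",
    "miniature_pairing",
    "grasp_by_name",
    "grasp_by_id",
    "build_fold_partition",
    "split_train_validation",
    "trials_to_csv",
    "trials_from_csv",
]


@dataclass(frozen=True, order=True)
class GraspType:
    """One of the ten canonical grasp types, or the rest class (id 0)."""

    id: int
    name: str


#: The ten grasp types, ids 1-10. Labels are lowercase canonical names.
GRASPS: tuple[GraspType, ...] = tuple(
    GraspType(i + 1, name)
    for i, name in enumerate(
        [
            "medium wrap",
            "lateral",
            "parallel extension",
            "tripod grasp",
            "power sphere",
            "precision disk",
            "prismatic pinch",
            "index finger extension",
            "adducted thumb",
            "prismatic four finger",
        ]
    )
)

#: The rest (no-grasp) class, distinct from every grasp type.
REST = GraspType(0, "rest")

#: The 18 graspable household object classes, in catalog order.
OBJECT_CLASSES: tuple[str, ...] = (
    "bottle",
    "can",
    "door handle",
    "mug",
    "key",
    "pencil case",
    "plate",
    "book",
    "drawer",
    "ball",
    "bulb",
    "jar",
    "clothespin",
    "remote",
    "knife",
    "fork",
    "screwdriver",
    "wrench",
)

#: Reserved detector labels that are never graspable.
PERSON = "person"
BACKGROUND = "background"

_GRASP_BY_NAME = {g.name: g for g in GRASPS}
_GRASP_BY_ID = {g.id: g for g in GRASPS} | {0: REST}


def grasp_by_name(name: str) -> GraspType:
    """Look up a grasp type by its lowercase canonical name."""
    return _GRASP_BY_NAME[name.lower()]


def grasp_by_id(gid: int) -> GraspType:
    """Look up a grasp type (or REST, id 0) by id."""
    return _GRASP_BY_ID[gid]


class Condition(str, Enum):
    """Acquisition condition of a repetition."""

    static_seated = "static_seated"
    static_standing = "static_standing"
    dynamic = "dynamic"


CONDITIONS: tuple[Condition, ...] = (
    Condition.static_seated,
    Condition.static_standing,
    Condition.dynamic,
)

#: Repetitions per (grasp, condition, object) cell in one full protocol,
#: one per fold.
REPS_PER_CELL = 4
#: Per fold and grasp: 3 seated + 3 standing + 2 dynamic repetitions.
_FOLD_REPS = {Condition.static_seated: 3, Condition.static_standing: 3, Condition.dynamic: 2}
N_FOLDS = 4


class GraspObjectMap:
    """Immutable bidirectional pairing between grasp types and objects.

    Every grasp maps to exactly three objects; every object maps to at
    least one grasp.  The reserved ``person``/``background`` labels are
    rejected.
    """

    def __init__(self, pairs: Mapping[GraspType, Sequence[str]]):
        by_grasp: dict[GraspType, tuple[str, ...]] = {}
        by_object: dict[str, set[GraspType]] = {}
        for grasp, objects in pairs.items():
            objects = tuple(o.lower() for o in objects)
            if grasp == REST:
                raise ValueError("REST cannot be paired with objects")
            if len(objects) != 3 or len(set(objects)) != 3:
                raise ValueError(
                    f"grasp {grasp.name!r} must pair with exactly 3 distinct objects, "
                    f"got {objects}"
                )
            for obj in objects:
                if obj in (PERSON, BACKGROUND):
                    raise ValueError(f"{obj!r} is not a graspable object class")
                by_object.setdefault(obj, set()).add(grasp)
            by_grasp[grasp] = objects
        if not by_grasp:
            raise ValueError("empty pairing")
        self._by_grasp = by_grasp
        self._by_object = {o: frozenset(gs) for o, gs in by_object.items()}

    @property
    def grasps(self) -> tuple[GraspType, ...]:
        return tuple(sorted(self._by_grasp))

    @property
    def objects(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_object))

    def objects_for(self, grasp: GraspType) -> tuple[str, ...]:
        """The three objects a grasp is performed on, in table order."""
        return self._by_grasp[grasp]

    def grasps_for(self, obj: str) -> frozenset[GraspType]:
        """The non-empty set of grasp types admissible for an object."""
        return self._by_object[obj.lower()]

    def __contains__(self, pair: tuple[GraspType, str]) -> bool:
        grasp, obj = pair
        return grasp in self._by_grasp and obj.lower() in self._by_grasp[grasp]

    def __eq__(self, other) -> bool:
        return isinstance(other, GraspObjectMap) and self._by_grasp == other._by_grasp

    def __repr__(self) -> str:
        return f"GraspObjectMap({len(self._by_grasp)} grasps, {len(self._by_object)} objects)"


def grasp_object_pairs() -> GraspObjectMap:
    """The full protocol pairing table (10 grasps x 18 objects).

    Loaded from the versioned JSON resource shipped with the package.
    """
    text = resources.files("gazegrasp.data").joinpath("grasp_object_pairs.json").read_text()
    raw = json.loads(text)
    return GraspObjectMap({grasp_by_name(name): objs for name, objs in raw["pairs"].items()})


def miniature_pairing() -> GraspObjectMap:
    """A 2-grasp / 4-object pairing with the full protocol's structure.

    Used for fast end-to-end runs: medium wrap and tripod grasp each pair
    with three of {bottle, can, mug, drawer}, sharing bottle and mug, so
    the restricted-argmax fusion is non-trivial.
    """
    return GraspObjectMap(
        {
            grasp_by_name("medium wrap"): ("bottle", "can", "mug"),
            grasp_by_name("tripod grasp"): ("bottle", "mug", "drawer"),
        }
    )


@dataclass
class TrialMeta:
    """Metadata of one rest-grasp-rest repetition."""

    subject: str
    grasp: GraspType
    object: str
    condition: Condition
    repetition_index: int  # index within (grasp, condition, object), 0-based
    fold_id: int | None = None
    onset_sample: int = -1  # ground-truth grasp onset, sEMG sample clock
    start_sample: int = -1  # segment start (inclusive)
    end_sample: int = -1  # segment end (exclusive)


@dataclass(frozen=True)
class FoldPartition:
    """Disjoint total assignment of trials (by index) to folds 1-4."""

    assignment: Mapping[int, int]

    def fold(self, fold_id: int) -> list[int]:
        return sorted(i for i, f in self.assignment.items() if f == fold_id)

    @property
    def fold_ids(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.assignment.values())))


class ProtocolError(ValueError):
    """The trial list does not realize the full protocol structure."""


def build_fold_partition(trials: Sequence[TrialMeta]) -> FoldPartition:
    """Partition a complete protocol's trials into 4 folds.

    Each fold holds, per grasp, 3 static-seated + 3 static-standing + 2
    dynamic repetitions, performed on the grasp's distinct paired objects.
    Assignment is round-robin on the repetition index within each
    (grasp, condition, object) cell, hence deterministic given the trial
    ordering.

    Raises :class:`ProtocolError` naming the deficient (grasp, condition)
    cell when the protocol is incomplete.
    """
    cells: dict[tuple[GraspType, Condition, str], list[int]] = {}
    for i, t in enumerate(trials):
        cells.setdefault((t.grasp, t.condition, t.object), []).append(i)

    grasps = sorted({t.grasp for t in trials})
    assignment: dict[int, int] = {}
    for grasp in grasps:
        for cond in CONDITIONS:
            expected_objects = _FOLD_REPS[cond]  # objects per fold == reps per fold
            cell_keys = [k for k in cells if k[0] == grasp and k[1] == cond]
            if len(cell_keys) != expected_objects:
                raise ProtocolError(
                    f"({grasp.name}, {cond.value}): expected {expected_objects} distinct "
                    f"objects, found {len(cell_keys)}"
                )
            for key in cell_keys:
                idxs = sorted(cells[key], key=lambda i: trials[i].repetition_index)
                if len(idxs) != REPS_PER_CELL:
                    raise ProtocolError(
                        f"({grasp.name}, {cond.value}, {key[2]}): expected "
                        f"{REPS_PER_CELL} repetitions, found {len(idxs)}"
                    )
                for rank, i in enumerate(idxs):
                    assignment[i] = rank + 1
    return FoldPartition(assignment)


def assign_folds(trials: Sequence[TrialMeta]) -> list[TrialMeta]:
    """Return a copy of ``trials`` with ``fold_id`` filled in."""
    part = build_fold_partition(trials)
    return [replace(t, fold_id=part.assignment[i]) for i, t in enumerate(trials)]


def split_train_validation(
    training_trials: Sequence[TrialMeta], seed: int
) -> tuple[list[TrialMeta], list[TrialMeta]]:
    """Draw the validation set from a 3-fold training pool.

    One repetition per (condition x grasp) cell is drawn at random into
    the validation set (30 repetitions for the full protocol, leaving 210
    for training).  Reproducible under ``seed``.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    cells: dict[tuple[GraspType, Condition], list[int]] = {}
    for i, t in enumerate(training_trials):
        cells.setdefault((t.grasp, t.condition), []).append(i)
    grasps = sorted({t.grasp for t in training_trials})
    val_idx: set[int] = set()
    for grasp in grasps:
        for cond in CONDITIONS:
            cell = cells.get((grasp, cond), [])
            if not cell:
                raise ProtocolError(f"empty (condition, grasp) cell: ({cond.value}, {grasp.name})")
            val_idx.add(cell[int(rng.integers(len(cell)))])
    train = [t for i, t in enumerate(training_trials) if i not in val_idx]
    validation = [t for i, t in enumerate(training_trials) if i in val_idx]
    return train, validation


_CSV_COLUMNS = [
    "subject",
    "grasp",
    "object",
    "condition",
    "repetition",
    "fold",
    "onset_sample",
    "start_sample",
    "end_sample",
]


def trials_to_csv(trials: Iterable[TrialMeta], path) -> None:
    rows = [
        {
            "subject": t.subject,
            "grasp": t.grasp.name,
            "object": t.object,
            "condition": t.condition.value,
            "repetition": t.repetition_index,
            "fold": -1 if t.fold_id is None else t.fold_id,
            "onset_sample": t.onset_sample,
            "start_sample": t.start_sample,
            "end_sample": t.end_sample,
        }
        for t in trials
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def trials_from_csv(path) -> list[TrialMeta]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials table {path} missing columns: {sorted(missing)}")
    return [
        TrialMeta(
            subject=str(r.subject),
            grasp=grasp_by_name(r.grasp),
            object=str(r.object),
            condition=Condition(r.condition),
            repetition_index=int(r.repetition),
            fold_id=None if int(r.fold) < 0 else int(r.fold),
            onset_sample=int(r.onset_sample),
            start_sample=int(r.start_sample),
            end_sample=int(r.end_sample),
        )
        for r in df.itertuples()
    ]
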