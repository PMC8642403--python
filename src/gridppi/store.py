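"""HDF5 persistence of featurized complexes, selection streaming, and
complex-level grouped cross-validation splits.

File layout (one group per docking model)::

    /<model_id>/mapped_features/<channel>   3D float arrays
    /<model_id>/grid_points/{x,y,z}         axis coordinates
    /<model_id>/targets/<name>              scalar metrics / labels
    /<model_id>.attrs                       case_id, seed, config_hash
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import h5py
import numpy as np

from .gridmap import FeatureGrid, GridSpec

__all__ = [
    "DatasetEntry",
    "FoldAssignment",
    "StoreError",
    "SelectionError",
    "write_entries",
    "read_selection",
    "list_entries",
    "grouped_kfold",
]

_COMPARATORS = {"<": operator.lt, "<=": operator.le, ">": operator.gt,
                ">=": operator.ge, "=": operator.eq, "==": operator.eq}


class StoreError(RuntimeError):
    pass


class SelectionError(KeyError):
    pass


@dataclass
class DatasetEntry:
    model_id: str
    case_id: str
    grid: FeatureGrid
    targets: dict = field(default_factory=dict)
    seed: int = 0
    config_hash: str = ""

    def __post_init__(self):
        if not self.case_id:
            raise StoreError("case_id must be non-empty")


@dataclass
class FoldAssignment:
    k: int
    folds: list[tuple[list[str], list[str], list[str]]]  # (train, val, test)

    def __iter__(self):
        return iter(self.folds)


def write_entries(path, entries: Iterable[DatasetEntry],
                  compression: str | None = "gzip") -> None:
    """Append entries to an HDF5 file; duplicate model ids are rejected
    before anything is written for that entry."""
    with h5py.File(path, "a") as fh:
        for entry in entries:
            if entry.model_id in fh:
                raise StoreError(f"duplicate model_id {entry.model_id!r}")
            grp = fh.create_group(entry.model_id)
            grp.attrs["case_id"] = entry.case_id
            grp.attrs["seed"] = entry.seed
            grp.attrs["config_hash"] = entry.config_hash
            feats = grp.create_group("mapped_features")
            for name, arr in entry.grid.channels.items():
                feats.create_dataset(name, data=arr, compression=compression)
            pts = grp.create_group("grid_points")
            for axis, label in enumerate("xyz"):
                pts.create_dataset(label, data=entry.grid.spec.axis_coords(axis))
            tgt = grp.create_group("targets")
            for name, value in entry.targets.items():
                tgt.create_dataset(name, data=value)


def list_entries(path) -> list[str]:
    with h5py.File(path, "r") as fh:
        return sorted(fh.keys())


def _passes(value, target_filter) -> bool:
    name, op, bound = target_filter
    return _COMPARATORS[op](value, bound)


def read_selection(path, channel_names: list[str] | None = None,
                   target_name: str | None = None,
                   target_filter: tuple | None = None
                   ) -> Iterator[tuple[str, str, np.ndarray, object]]:
    """Stream ``(model_id, case_id, tensor, target)`` in sorted-id order.

    ``channel_names`` selects and orders the stacked channels (all stored
    channels, sorted order of the first entry, when omitted).  Entries
    failing ``target_filter = (name, comparator, value)`` are skipped.
    """
    with h5py.File(path, "r") as fh:
        ids = sorted(fh.keys())
        for model_id in ids:
            grp = fh[model_id]
            feats = grp["mapped_features"]
            names = channel_names if channel_names is not None else sorted(feats)
            for n in names:
                if n not in feats:
                    raise SelectionError(f"unknown channel {n!r} in {model_id!r}")
            if target_filter is not None:
                fname = target_filter[0]
                if fname not in grp["targets"]:
                    raise SelectionError(f"unknown target {fname!r} in {model_id!r}")
                if not _passes(grp["targets"][fname][()], target_filter):
                    continue
            target = None
            if target_name is not None:
                if target_name not in grp["targets"]:
                    raise SelectionError(
                        f"unknown target {target_name!r} in {model_id!r}")
                target = grp["targets"][target_name][()]
                if isinstance(target, bytes):
                    target = target.decode()
            tensor = np.stack([feats[n][()] for n in names]).astype(np.float32)
            yield model_id, grp.attrs["case_id"], tensor, target


def grouped_kfold(case_ids: list[str], k: int, n_val_cases: int,
                  seed: int) -> FoldAssignment:
    """Complex-level k-fold split with equal-size test blocks.

    Cases are shuffled by the seed and cut into k disjoint test blocks of
    floor(n/k) cases; leftover cases are never tested.  Per fold,
    ``n_val_cases`` validation cases are drawn from the non-test cases and
    the remainder trains.  With 142 cases and k=10 this yields the
    114/14/14 train/validation/test pattern covering 140 distinct test
    cases.
    """
    cases = list(case_ids)
    n = len(cases)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cases ({n})")
    block = n // k
    if n_val_cases > n - block:
        raise ValueError("not enough non-test cases for validation")
    rng = np.random.default_rng(seed)
    shuffled = [cases[i] for i in rng.permutation(n)]
    folds = []
    for f in range(k):
        test = shuffled[f * block:(f + 1) * block]
        rest = [c for c in shuffled if c not in test]
        order = rng.permutation(len(rest))
        val = [rest[i] for i in order[:n_val_cases]]
        train = [rest[i] for i in sorted(order[n_val_cases:])]
        folds.append((train, val, test))
    return FoldAssignment(k=k, folds=folds)
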