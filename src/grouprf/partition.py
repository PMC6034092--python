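"""Feature-to-group partitions.

A partition assigns each feature (column of the data matrix) to at most one
named group -- a brain region when features are voxels, an a-priori block of
variables otherwise.  Groups are disjoint and non-empty; features outside
every group are *unassigned*: they take part in forest fitting but never in
group scores.

Partitions can be built from a two-column mapping table or from a NIfTI
atlas label volume restricted to a binary brain mask.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

UNASSIGNED = -1
#: sentinel group id used in the table format for unassigned features
UNASSIGNED_LABEL = "__unassigned__"


class FeaturePartition:
    """Disjoint assignment of feature indices to named groups.

    Parameters
    ----------
    group_ids : sequence of str
        Group identifiers in their canonical order (the order used for
        ranking tie-breaks).
    assignment : array of int, shape (n_features,)
        For each feature, the index into ``group_ids`` of its group, or
        ``-1`` for unassigned features.
    meta : dict, optional
        Free-form provenance (e.g. voxel linearization order for atlases).
    """

    def __init__(self, group_ids: Sequence[str], assignment, meta: dict | None = None):
        self.group_ids = [str(g) for g in group_ids]
        self.assignment = np.asarray(assignment, dtype=np.intp)
        self.meta = dict(meta or {})
        self._validate()

    def _validate(self) -> None:
        if len(set(self.group_ids)) != len(self.group_ids):
            raise ValueError("duplicate group identifiers")
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be one-dimensional")
        g = len(self.group_ids)
        bad = (self.assignment < UNASSIGNED) | (self.assignment >= g)
        if bad.any():
            raise ValueError("assignment indices out of range")
        sizes = np.bincount(self.assignment[self.assignment >= 0], minlength=g)
        if g and sizes.min() < 1:
            empty = [self.group_ids[i] for i in np.flatnonzero(sizes == 0)]
            raise ValueError(f"empty groups: {empty}")
        self._sizes = sizes

    # ------------------------------------------------------------------ #
    @property
    def n_features(self) -> int:
        return self.assignment.size

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def sizes(self) -> np.ndarray:
        """Per-group feature counts, aligned with ``group_ids``."""
        return self._sizes.copy()

    @property
    def assigned_mask(self) -> np.ndarray:
        return self.assignment >= 0

    @property
    def n_unassigned(self) -> int:
        return int((self.assignment == UNASSIGNED).sum())

    def indices(self, group: str | int) -> np.ndarray:
        """Feature indices belonging to a group (by id or positional index)."""
        gi = group if isinstance(group, (int, np.integer)) else self.group_ids.index(str(group))
        return np.flatnonzero(self.assignment == gi)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeaturePartition)
            and self.group_ids == other.group_ids
            and np.array_equal(self.assignment, other.assignment)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FeaturePartition({self.n_groups} groups, {self.n_features} features, "
            f"{self.n_unassigned} unassigned)"
        )

    # ------------------------------ I/O ------------------------------- #
    def to_frame(self) -> pd.DataFrame:
        gid = np.array(self.group_ids + [UNASSIGNED_LABEL], dtype=object)
        return pd.DataFrame(
            {"feature_id": np.arange(self.n_features), "group_id": gid[self.assignment]}
        )

    def save(self, path) -> None:
        """Write the two-column tab-separated table ``feature_id<TAB>group_id``."""
        df = self.to_frame()
        df = df[df["group_id"] != UNASSIGNED_LABEL]
        df.to_csv(path, sep="\t", index=False)
        if self.meta:
            Path(str(path) + ".meta.json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def from_mapping(
        cls,
        mapping: Iterable[tuple[int, str]] | Mapping[int, str],
        expected_feature_count: int,
    ) -> "FeaturePartition":
        """Build a partition from ``(feature_id, group_id)`` records.

        Features absent from the mapping are unassigned.  Group order is
        first-appearance order in the mapping.
        """
        if expected_feature_count < 1:
            raise ValueError("expected_feature_count must be >= 1")
        items = list(mapping.items()) if isinstance(mapping, Mapping) else list(mapping)
        assignment = np.full(expected_feature_count, UNASSIGNED, dtype=np.intp)
        group_ids: list[str] = []
        index: dict[str, int] = {}
        seen: set[int] = set()
        for fid, gid in items:
            fid = int(fid)
            if fid in seen:
                raise ValueError(f"duplicate feature id {fid}")
            if not 0 <= fid < expected_feature_count:
                raise ValueError(
                    f"feature id {fid} outside [0, {expected_feature_count})"
                )
            seen.add(fid)
            gid = str(gid)
            if gid == UNASSIGNED_LABEL:
                continue
            if gid not in index:
                index[gid] = len(group_ids)
                group_ids.append(gid)
            assignment[fid] = index[gid]
        return cls(group_ids, assignment)

    @classmethod
    def load(cls, path, expected_feature_count: int | None = None) -> "FeaturePartition":
        """Read a partition table written by :meth:`save`."""
        df = pd.read_csv(path, sep="\t")
        if not {"feature_id", "group_id"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns feature_id, group_id")
        if expected_feature_count is None:
            expected_feature_count = int(df["feature_id"].max()) + 1
        return cls.from_mapping(
            zip(df["feature_id"].astype(int), df["group_id"].astype(str)),
            expected_feature_count,
        )


def partition_from_atlas(atlas, mask, pool_background: bool = False) -> FeaturePartition:
    """Build a partition from a labelled atlas volume and a brain mask.

    Features are the in-mask voxels, linearized in C order (last axis
    fastest); this order defines feature identity and is recorded in the
    partition metadata.  An in-mask voxel with atlas label ``L > 0`` joins
    group ``str(L)``; label 0 (background / outside the atlas) is
    unassigned unless ``pool_background`` pools those voxels into a single
    ``"background"`` group.

    Parameters
    ----------
    atlas, mask : array-like or nibabel image or path
        3-D integer label volume and binary mask of identical shape.
    """
    labels = _as_volume(atlas).astype(np.int64)
    mask_arr = _as_volume(mask)
    if labels.shape != mask_arr.shape:
        raise ValueError(f"atlas shape {labels.shape} != mask shape {mask_arr.shape}")
    if (labels < 0).any():
        raise ValueError("atlas labels must be non-negative integers")
    inmask = np.ravel(mask_arr, order="C") != 0
    if not inmask.any():
        raise ValueError("mask is empty")
    voxel_labels = np.ravel(labels, order="C")[inmask]

    present = np.unique(voxel_labels)
    present = present[present > 0]
    group_ids = [str(int(l)) for l in present]
    lookup = {int(l): i for i, l in enumerate(present)}
    assignment = np.array(
        [lookup.get(int(l), UNASSIGNED) for l in voxel_labels], dtype=np.intp
    )
    if pool_background and (voxel_labels == 0).any():
        group_ids.append("background")
        assignment[voxel_labels == 0] = len(group_ids) - 1
    return FeaturePartition(
        group_ids,
        assignment,
        meta={
            "source": "atlas",
            "linearization": "C order (last axis fastest), in-mask voxels only",
            "n_inmask_voxels": int(inmask.sum()),
            "pool_background": bool(pool_background),
        },
    )


def _as_volume(obj) -> np.ndarray:
    """Accept a numpy array, a nibabel image, or a NIfTI path."""
    if isinstance(obj, np.ndarray):
        return obj
    if isinstance(obj, (str, Path)):
        import nibabel as nib

        return np.asanyarray(nib.load(str(obj)).dataobj)
    if hasattr(obj, "dataobj"):  # nibabel image
        return np.asanyarray(obj.dataobj)
    return np.asarray(obj)
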