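"""Streamline geometry: voxel traversal and endpoint-to-node assignment.

Traversal is exact: each polyline segment is intersected with the voxel
grid analytically (crossings of the half-integer voxel boundary planes in
voxel coordinates), so no resampling step size is involved.  A streamline
contributes each traversed voxel once, no matter how many of its segments
pass through it — per-voxel counts downstream mean "number of streamlines",
not number of visits.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import VolumeGrid


class Edge(NamedTuple):
    """Unordered pair of gray-matter node ids, stored canonically as i < j."""

    i: int
    j: int

    @classmethod
    def make(cls, a: int, b: int) -> "Edge":
        a, b = int(a), int(b)
        if a == b:
            raise ValueError(f"self-edge ({a},{b}) is not a valid connection")
        return cls(a, b) if a < b else cls(b, a)


def voxels_traversed(streamline: np.ndarray, grid: VolumeGrid) -> set[tuple[int, int, int]]:
    """Unique in-bounds voxels intersected by the streamline polyline.

    A point exactly on a voxel boundary belongs to the voxel with the
    larger index (half-open convention).  Points and segments outside the
    grid contribute nothing.
    """
    pts = np.asarray(streamline, dtype=float)
    if pts.size == 0:
        raise ValueError("empty streamline")
    pts = pts.reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")

    vox = grid.world_to_voxel(pts)
    shape = grid.shape[:3]

    voxels: set[tuple[int, int, int]] = set()

    def add(idx: np.ndarray) -> None:
        i, j, k = int(idx[0]), int(idx[1]), int(idx[2])
        if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
            voxels.add((i, j, k))

    # every vertex's containing voxel counts (covers 1-point streamlines and
    # degenerate boundary touches)
    for p in vox:
        add(np.floor(p + 0.5))

    for a, b in zip(vox[:-1], vox[1:]):
        d = b - a
        if not np.any(d):
            continue
        ts = [np.array([0.0, 1.0])]
        for axis in range(3):
            if d[axis] == 0.0:
                continue
            lo, hi = (a[axis], b[axis]) if d[axis] > 0 else (b[axis], a[axis])
            # boundary planes m + 0.5 strictly inside (lo, hi)
            m_first = np.floor(lo - 0.5) + 1
            m_last = np.ceil(hi - 0.5) - 1
            if m_last < m_first:
                continue
            planes = np.arange(m_first, m_last + 1) + 0.5
            ts.append((planes - a[axis]) / d[axis])
        t = np.unique(np.clip(np.concatenate(ts), 0.0, 1.0))
        mids = a + np.outer((t[:-1] + t[1:]) / 2.0, d)
        for m in mids:
            add(np.floor(m + 0.5))
    return voxels


class LabelIndex:
    """Spatial index over the nonzero voxels of a label volume.

    Used for radius-based endpoint assignment: when a streamline terminates
    in background, the nearest labeled voxel centre within ``radius_mm`` (in
    world distance) supplies the label, ties broken by smallest node id.
    """

    def __init__(self, labels: VolumeGrid):
        data = np.asarray(labels.data)
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError("label volume must be integer-valued")
        if data.min() < 0:
            raise ValueError("label volume must be non-negative")
        self.grid = labels
        idx = np.argwhere(data > 0)
        self._labels = data[tuple(idx.T)] if len(idx) else np.empty(0, int)
        self._centers = labels.voxel_to_world(idx) if len(idx) else np.empty((0, 3))
        self._tree = cKDTree(self._centers) if len(idx) else None

    def label_at(self, point_mm: np.ndarray, radius_mm: float = 0.0) -> Optional[int]:
        data = self.grid.data
        vox = np.floor(self.grid.world_to_voxel(point_mm)[0] + 0.5).astype(int)
        if np.all(vox >= 0) and np.all(vox < np.asarray(data.shape[:3])):
            value = int(data[tuple(vox)])
            if value > 0:
                return value
        if radius_mm <= 0 or self._tree is None:
            return None
        hits = self._tree.query_ball_point(np.asarray(point_mm, float).reshape(3), radius_mm)
        if not hits:
            return None
        hits = np.asarray(hits)
        dists = np.linalg.norm(self._centers[hits] - np.asarray(point_mm, float), axis=1)
        dmin = dists.min()
        nearest = self._labels[hits[dists <= dmin + 1e-9]]
        return int(nearest.min())


def endpoint_labels(
    streamline: np.ndarray,
    labels: VolumeGrid,
    radius_mm: float = 0.0,
    index: LabelIndex | None = None,
) -> tuple[Optional[int], Optional[int]]:
    """Node labels at the two terminal points of a streamline (None if unlabeled)."""
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    pts = np.asarray(streamline, dtype=float).reshape(-1, 3)
    if pts.size == 0:
        raise ValueError("empty streamline")
    if index is None:
        index = LabelIndex(labels)
    return index.label_at(pts[0], radius_mm), index.label_at(pts[-1], radius_mm)


def assign_edge(
    streamline: np.ndarray,
    labels: VolumeGrid,
    radius_mm: float = 0.0,
    index: LabelIndex | None = None,
) -> Optional[Edge]:
    """Canonical edge connected by a streamline, or None.

    None when either endpoint is unlabeled or both endpoints carry the same
    label (self-connections are excluded from the connectome).
    """
    a, b = endpoint_labels(streamline, labels, radius_mm, index)
    if a is None or b is None or a == b:
        return None
    return Edge.make(a, b)
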