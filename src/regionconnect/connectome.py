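"""Connectome construction: streamline-pair counting and per-voxel edge counts.

The central intermediate is the :class:`EdgeCountField`: for every voxel it
records, sparsely, how many streamlines of each edge (i, j) traverse it —
S_ij(x, y, z).  From it derive the track-density map (TD, sum over edges),
per-edge track-density images, edge-density maps, and group-level
connectivity maps (e.g. lobar probability maps or winner-take-all
connectivity-based parcellation of a target structure).

Sparse voxel-major storage is deliberate: in real connectomes almost all
voxels carry only a handful of edges with streamlines, so a dense 4D array
over thousands of edges would be wasteful.
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Iterable, Mapping, Optional

import numpy as np

from .io_formats import VolumeGrid
from .tractogram_core import Edge, LabelIndex, assign_edge, voxels_traversed

Voxel = tuple[int, int, int]


@dataclasses.dataclass
class ConnectivityMatrix:
    """Symmetric node-by-node streamline-count matrix with zero diagonal."""

    node_ids: tuple[int, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = tuple(int(i) for i in self.node_ids)
        self.counts = np.asarray(self.counts)
        n = len(self.node_ids)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {self.counts.shape}")
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("connectivity matrix diagonal must be zero")
        self._index = {nid: k for k, nid in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edge_count(self, edge: Edge) -> int:
        return int(self.counts[self._index[edge.i], self._index[edge.j]])

    def edge_counts(self) -> dict[Edge, int]:
        """All nonzero edges of the upper triangle."""
        out: dict[Edge, int] = {}
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        for a, b in zip(iu, ju):
            c = int(self.counts[a, b])
            if c:
                out[Edge(self.node_ids[a], self.node_ids[b])] = c
        return out

    def total_streamlines(self) -> int:
        return int(np.triu(self.counts, k=1).sum())


@dataclasses.dataclass
class EdgeCountField:
    """Per-voxel sparse map edge -> streamline count S_ij(x, y, z)."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    counts: dict[Voxel, dict[Edge, int]]

    def grid_like(self, dtype=np.int32) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)

    def edges(self) -> set[Edge]:
        out: set[Edge] = set()
        for per_voxel in self.counts.values():
            out.update(per_voxel)
        return out

    def nodes(self) -> set[int]:
        return {n for e in self.edges() for n in e}


def build_edge_count_field(
    streamlines: Iterable[np.ndarray],
    labels: VolumeGrid,
    radius_mm: float = 0.0,
    node_ids: Optional[Iterable[int]] = None,
) -> tuple[EdgeCountField, ConnectivityMatrix]:
    """Combine a tractogram with gray-matter labels.

    Every streamline whose two endpoints map to two distinct node labels
    contributes: +1 to that edge's matrix cell, and +1 to the edge's count
    in each voxel the streamline traverses (once per voxel, regardless of
    revisits).  Streamlines with an unlabeled endpoint or a self-connection
    contribute to neither.

    ``node_ids`` fixes the matrix dimension (defaults to the labels present
    in the volume); an empty tractogram yields an empty field and a zero
    matrix.
    """
    data = np.asarray(labels.data)
    if node_ids is None:
        node_ids = np.unique(data[data > 0])
    node_ids = tuple(int(i) for i in sorted(node_ids))
    index = {nid: k for k, nid in enumerate(node_ids)}
    matrix = np.zeros((len(node_ids), len(node_ids)), dtype=np.int64)
    label_index = LabelIndex(labels)

    counts: dict[Voxel, dict[Edge, int]] = {}
    for sl in streamlines:
        edge = assign_edge(sl, labels, radius_mm, index=label_index)
        if edge is None:
            continue
        matrix[index[edge.i], index[edge.j]] += 1
        matrix[index[edge.j], index[edge.i]] += 1
        for vox in voxels_traversed(sl, labels):
            per_voxel = counts.setdefault(vox, {})
            per_voxel[edge] = per_voxel.get(edge, 0) + 1

    field = EdgeCountField(shape=tuple(data.shape[:3]), affine=labels.affine, counts=counts)
    return field, ConnectivityMatrix(node_ids=node_ids, counts=matrix)


def filter_edges(matrix: ConnectivityMatrix, fraction: float = 0.05) -> set[Edge]:
    """Strong edges: count >= fraction x the strongest edge's count.

    Edges *strictly below* the threshold are removed, so an edge exactly at
    the threshold survives.  "Strongest" refers to the matrix cell (the
    edge's streamline total), not any per-voxel count.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    edge_counts = matrix.edge_counts()
    if not edge_counts:
        raise ValueError("connectivity matrix has no nonzero edge")
    threshold = fraction * max(edge_counts.values())
    return {e for e, c in edge_counts.items() if c >= threshold}


def track_density_map(field: EdgeCountField) -> VolumeGrid:
    """TD(x, y, z): total streamlines through each voxel, summed over edges."""
    td = field.grid_like(np.int64)
    for vox, per_voxel in field.counts.items():
        td[vox] = sum(per_voxel.values())
    return VolumeGrid(data=td, affine=field.affine)


def edge_tdi(field: EdgeCountField, edge: Edge) -> VolumeGrid:
    """Track-density image of a single edge (all-zero if the edge is absent)."""
    tdi = field.grid_like(np.int64)
    for vox, per_voxel in field.counts.items():
        if edge in per_voxel:
            tdi[vox] = per_voxel[edge]
    return VolumeGrid(data=tdi, affine=field.affine)


def edge_density_map(field: EdgeCountField, edge_set: Iterable[Edge]) -> VolumeGrid:
    """Per voxel, the number of distinct edges from ``edge_set`` with S > 0."""
    edge_set = set(edge_set)
    density = field.grid_like(np.int32)
    for vox, per_voxel in field.counts.items():
        density[vox] = sum(1 for e in per_voxel if e in edge_set)
    return VolumeGrid(data=density, affine=field.affine)


def group_connectivity(
    field: EdgeCountField,
    grouping: Mapping[int, Hashable],
    mode: str = "probability",
    ignore_groups: frozenset = frozenset(),
):
    """Group-level connectivity maps from per-voxel edge counts.

    ``grouping`` maps every node id appearing in the field to a group id;
    an uncovered node is an error.  Groups listed in ``ignore_groups`` are
    valid assignments but produce no output map and do not compete in
    argmax — use this for the seed structure itself when parcellating a
    target region by its connectivity to the remaining groups.

    probability mode
        One map per group: per voxel, the fraction of the track density
        carried by edges touching that group.  An edge counts once per
        distinct group among its two endpoints (never twice for one group).

    argmax mode
        Winner-take-all parcellation: per voxel, the group with the largest
        streamline sum; ties go to the smallest group id, TD = 0 voxels get
        0.  Returns ``(VolumeGrid, code_to_group)``; positive-integer group
        ids are used directly as map codes, otherwise codes are assigned
        1..G in sorted group order.
    """
    if mode not in ("probability", "argmax"):
        raise ValueError(f"unknown mode {mode!r}")
    for node in sorted(field.nodes()):
        if node not in grouping:
            raise ValueError(f"grouping does not cover node {node}")
    groups = sorted(
        {g for g in grouping.values() if g not in ignore_groups}, key=lambda g: (str(type(g)), g)
    )

    # per voxel, streamline sum per (non-ignored) group, each edge counted
    # once per distinct group it touches
    group_sums: dict[Voxel, dict[Hashable, int]] = {}
    td: dict[Voxel, int] = {}
    for vox, per_voxel in field.counts.items():
        sums: dict[Hashable, int] = {}
        for edge, s in per_voxel.items():
            touched = {grouping[edge.i], grouping[edge.j]} - set(ignore_groups)
            for g in touched:
                sums[g] = sums.get(g, 0) + s
        group_sums[vox] = sums
        td[vox] = sum(per_voxel.values())

    if mode == "probability":
        out: dict[Hashable, VolumeGrid] = {}
        for g in groups:
            prob = field.grid_like(np.float64)
            for vox, sums in group_sums.items():
                if td[vox] > 0 and g in sums:
                    prob[vox] = sums[g] / td[vox]
            out[g] = VolumeGrid(data=prob, affine=field.affine)
        return out

    if all(isinstance(g, (int, np.integer)) and g > 0 for g in groups):
        codes = {g: int(g) for g in groups}
    else:
        codes = {g: k + 1 for k, g in enumerate(groups)}
    label = field.grid_like(np.int32)
    for vox, sums in group_sums.items():
        if td[vox] == 0 or not sums:
            continue
        best = max(sums.values())
        winner = min((g for g in groups if sums.get(g, 0) == best), key=lambda g: codes[g])
        label[vox] = codes[winner]
    return VolumeGrid(data=label, affine=field.affine), {v: k for k, v in codes.items()}
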