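"""The region query: rank the connections traversing a white-matter region.

Given a binary mask, the layered label/confidence volumes and the track
density map, the probability that a streamline passing through the region
belongs to edge (i, j) is the track-density-weighted average of the
per-voxel confidences,

    P_region(i, j) = sum_region P_ij(v) * TD(v) / sum_region TD(v),

which equals the total streamline count of the edge over the region divided
by the total track density there.  The denominator is the *full* track
density, including streamline mass whose labels were truncated out of the
stored layers, so the reported probabilities sum to at most 1 and the sum
is interpretable as coverage; no renormalization over the reported labels
is applied.  Runtime is linear in (edges present x masked voxels).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .connectome import EdgeCountField
from .io_formats import NodeLookup, VolumeGrid, require_same_grid
from .labels import MultiLayerLabels, decode_edge
from .tractogram_core import Edge


@dataclasses.dataclass
class RegionEntry:
    edge: Edge
    name_i: str
    name_j: str
    probability: float


@dataclasses.dataclass
class RegionResult:
    """Connections traversing a region, ranked by decreasing probability."""

    entries: list[RegionEntry]
    region_voxel_count: int
    region_td_sum: float

    def top(self, n: int) -> "RegionResult":
        return dataclasses.replace(self, entries=self.entries[: int(n)])

    def as_rows(self) -> list[dict]:
        return [
            {
                "rank": k + 1,
                "node_i": e.edge.i,
                "node_j": e.edge.j,
                "name_i": e.name_i,
                "name_j": e.name_j,
                "probability": e.probability,
            }
            for k, e in enumerate(self.entries)
        ]


def _mask_voxels(mask: VolumeGrid) -> np.ndarray:
    m = np.asarray(mask.data)
    if m.ndim != 3:
        raise ValueError(f"mask must be 3D, got {m.ndim}D")
    vox = np.argwhere(m != 0)
    if len(vox) == 0:
        raise ValueError("region mask is empty")
    return vox


def _rank(
    weights: dict[Edge, float], denom: float, lookup: NodeLookup,
    n_voxels: int,
) -> RegionResult:
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [
        RegionEntry(
            edge=e,
            name_i=lookup.name(e.i) if e.i in lookup else str(e.i),
            name_j=lookup.name(e.j) if e.j in lookup else str(e.j),
            probability=w / denom,
        )
        for e, w in ranked
        if w > 0
    ]
    return RegionResult(entries=entries, region_voxel_count=n_voxels, region_td_sum=denom)


def regionconnect(
    mask: VolumeGrid,
    labels4d: MultiLayerLabels,
    td: VolumeGrid,
    lookup: NodeLookup,
) -> RegionResult:
    """Aggregate layered labels over a mask and rank traversing connections.

    Any nonzero mask voxel belongs to the region (threshold statistical
    maps upstream).  Voxels with zero track density contribute to neither
    sum.  The mask, label volumes, and track-density map must share grid
    and affine exactly (within 1e-5); mismatched grids are a hard error —
    resample to atlas space externally, never silently here.
    """
    td_grid = VolumeGrid(np.asarray(td.data), td.affine)
    require_same_grid(mask, td_grid, "mask and track-density map")
    labels_grid = VolumeGrid(labels4d.code_layers, labels4d.affine)
    require_same_grid(mask, labels_grid, "mask and label volumes")

    vox = _mask_voxels(mask)
    idx = tuple(vox.T)
    td_vals = np.asarray(td_grid.data, dtype=float)[idx]
    denom = float(td_vals.sum())
    if denom <= 0:
        raise ValueError("region contains no traversed white matter (track density is 0)")

    codes = labels4d.code_layers[idx]          # (n_vox, n_layers)
    confs = labels4d.confidence_layers[idx].astype(float)
    weights_arr = confs * td_vals[:, None]     # P(v) * TD(v) per layer

    live = codes != 0
    flat_codes = codes[live]
    flat_weights = weights_arr[live]
    uniq, inverse = np.unique(flat_codes, return_inverse=True)
    sums = np.zeros(len(uniq))
    np.add.at(sums, inverse, flat_weights)

    weights = {decode_edge(c): float(s) for c, s in zip(uniq, sums)}
    return _rank(weights, denom, lookup, n_voxels=len(vox))


def regionconnect_direct(
    mask: VolumeGrid,
    field: EdgeCountField,
    lookup: NodeLookup,
) -> RegionResult:
    """Same query computed straight from per-voxel streamline counts.

    P_region(i, j) = sum_region S_ij / sum_region TD, with no layered 4D
    intermediate.  Serves as the exact reference for :func:`regionconnect`;
    the two agree whenever no voxel's edge list was truncated by the layer
    limit.
    """
    field_grid = VolumeGrid(np.zeros(field.shape, dtype=np.int8), field.affine)
    require_same_grid(mask, field_grid, "mask and edge-count field")
    vox = _mask_voxels(mask)

    sums: dict[Edge, float] = {}
    denom = 0.0
    for v in map(tuple, vox):
        per_voxel = field.counts.get(v)
        if not per_voxel:
            continue
        denom += sum(per_voxel.values())
        for edge, s in per_voxel.items():
            sums[edge] = sums.get(edge, 0.0) + s
    if denom <= 0:
        raise ValueError("region contains no traversed white matter (track density is 0)")
    return _rank(sums, denom, lookup, n_voxels=len(vox))
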