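"""Multi-layer, connectivity-based white-matter labels.

Each white-matter voxel may carry axons from many connections, so a single
label per voxel misrepresents connectivity.  Instead, every voxel gets an
ordered list of edge labels "i,j" ranked by decreasing confidence

    P_ij(x, y, z) = S_ij(x, y, z) / sum_kl S_kl(x, y, z),

the fraction of streamlines through the voxel that belong to edge (i, j).
The ranked lists are stored as two paired 4D grids — integer edge codes and
floating-point confidences — with the layer as the 4th axis, layer 0 most
probable.  The default depth of 60 layers is ample in practice: real
connectomes rarely put more than a few dozen edges through one voxel.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import EdgeCountField, Voxel
from .io_formats import VolumeGrid
from .tractogram_core import Edge

#: node-id limit of the human-readable code scheme code = i*1000 + j
MAX_NODE_ID = 999


def encode_edge(edge: Edge) -> int:
    """Pack edge (i, j), i < j, into the human-readable code i*1000 + j."""
    if not 1 <= edge.i < edge.j <= MAX_NODE_ID:
        raise ValueError(
            f"edge {tuple(edge)} outside encodable range 1 <= i < j <= {MAX_NODE_ID}"
        )
    return edge.i * 1000 + edge.j

def decode_edge(code: int) -> Edge:
    """Inverse of :func:`encode_edge`; 0 is reserved for 'no label'."""
    code = int(code)
    i, j = divmod(code, 1000)
    if not 1 <= i < j <= MAX_NODE_ID:
        raise ValueError(f"{code} is not a valid edge code")
    return Edge(i, j)


@dataclasses.dataclass
class MultiLayerLabels:
    """Paired 4D code/confidence grids, layer-ordered by decreasing confidence."""

    affine: np.ndarray
    code_layers: np.ndarray        # int32, shape (X, Y, Z, n_layers), 0 = empty
    confidence_layers: np.ndarray  # float32, same shape, P in [0, 1]
    code_table: dict[int, Edge]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.code_layers.shape[:3]

    @property
    def n_layers(self) -> int:
        return self.code_layers.shape[3]

    def voxel_layers(self, voxel: Voxel) -> list[tuple[Edge, float]]:
        """Non-empty (edge, confidence) layers of one voxel, top first."""
        codes = self.code_layers[voxel]
        confs = self.confidence_layers[voxel]
        return [(decode_edge(c), float(p)) for c, p in zip(codes, confs) if c != 0]


def voxel_probabilities(field: EdgeCountField, voxel: Voxel) -> dict[Edge, float]:
    """P(edge) = S(edge) / TD at one voxel; empty when no streamline passes."""
    voxel = tuple(int(v) for v in voxel)
    for v, n in zip(voxel, field.shape):
        if not 0 <= v < n:
            raise IndexError(f"voxel {voxel} outside grid {field.shape}")
    per_voxel = field.counts.get(voxel, {})
    td = sum(per_voxel.values())
    if td == 0:
        return {}
    return {edge: s / td for edge, s in per_voxel.items()}


def build_multilayer_labels(field: EdgeCountField, n_layers: int = 60) -> MultiLayerLabels:
    """Rank each voxel's edges by decreasing confidence and layer them.

    Ties in confidence are broken lexicographically by (i, j) — applied to
    the integer streamline counts, so the tie-break is exact and immune to
    floating-point rounding.  Voxels traversed by more than ``n_layers``
    edges keep only the top ``n_layers``; their kept confidences then sum
    to less than 1.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    shape = field.shape
    codes = np.zeros(shape + (n_layers,), dtype=np.int32)
    confs = np.zeros(shape + (n_layers,), dtype=np.float32)
    code_table: dict[int, Edge] = {}
    for vox, per_voxel in field.counts.items():
        td = sum(per_voxel.values())
        ranked = sorted(per_voxel.items(), key=lambda kv: (-kv[1], kv[0]))[:n_layers]
        for layer, (edge, s) in enumerate(ranked):
            code = encode_edge(edge)
            code_table[code] = edge
            codes[vox + (layer,)] = code
            confs[vox + (layer,)] = s / td
    return MultiLayerLabels(
        affine=np.asarray(field.affine, float),
        code_layers=codes,
        confidence_layers=confs,
        code_table=code_table,
    )


# ---------------------------------------------------------------------------
# on-disk form: two 4D NIfTIs + a code-table TSV


def save_multilayer(labels: MultiLayerLabels, codes_path, confidence_path, table_path) -> None:
    from .io_formats import write_volume

    write_volume(VolumeGrid(labels.code_layers, labels.affine), codes_path)
    write_volume(VolumeGrid(labels.confidence_layers, labels.affine), confidence_path)
    rows = sorted(labels.code_table.items())
    pd.DataFrame(
        {"code": [c for c, _ in rows],
         "node_i": [e.i for _, e in rows],
         "node_j": [e.j for _, e in rows]}
    ).to_csv(str(table_path), sep="\t", index=False)


def load_multilayer(codes_path, confidence_path, table_path=None) -> MultiLayerLabels:
    from .io_formats import read_volume

    codes = read_volume(codes_path, ndim=4)
    confs = read_volume(confidence_path, ndim=4)
    if codes.shape != confs.shape:
        raise ValueError("code and confidence volumes disagree in shape")
    if table_path is not None and Path(table_path).exists():
        df = pd.read_csv(str(table_path), sep="\t")
        table = {int(r.code): Edge(int(r.node_i), int(r.node_j)) for r in df.itertuples()}
    else:
        table = {int(c): decode_edge(c) for c in np.unique(codes.data) if c != 0}
    return MultiLayerLabels(
        affine=codes.affine,
        code_layers=np.asarray(codes.data, dtype=np.int32),
        confidence_layers=np.asarray(confs.data, dtype=np.float32),
        code_table=table,
    )
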