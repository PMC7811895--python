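"""Readers and writers for the standard formats the pipeline touches.

All volumes are NIfTI-1 (optionally gzipped); streamlines are TCK or TRK.
Internally every streamline point lives in world millimetres (RAS+); voxel
indices are obtained only through a grid affine, with the NIfTI convention
that voxel centres sit at integer indices and voxel ``(i, j, k)`` spans the
half-open cube ``[i-0.5, i+0.5) x [j-0.5, j+0.5) x [k-0.5, k+0.5)`` in
voxel coordinates.  TCK stores world mm natively; TRK stores its own
voxel-mm space and is transformed through its header on load, so both
formats yield identical in-memory coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd


class GridError(ValueError):
    """Raised for malformed volume grids (singular affine, bad dimensionality)."""


@dataclasses.dataclass
class VolumeGrid:
    """A scalar grid with a voxel-to-world-mm affine.

    ``data`` is integer for label/code volumes and floating point for
    confidence or density volumes.  The affine must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GridError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GridError("affine is singular (non-invertible)")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = self.inverse_affine
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, voxels: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(np.asarray(voxels, dtype=float))
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclasses.dataclass
class NodeLookup:
    """Ordered map from gray-matter node id to region name."""

    entries: dict[int, str]

    def __post_init__(self) -> None:
        entries = dict(self.entries)
        for node_id, name in entries.items():
            if int(node_id) < 1:
                raise ValueError(f"node ids must be positive, got {node_id}")
            if not str(name):
                raise ValueError(f"empty name for node {node_id}")
        self.entries = {int(k): str(v) for k, v in entries.items()}

    def name(self, node_id: int) -> str:
        try:
            return self.entries[int(node_id)]
        except KeyError:
            raise KeyError(f"node id {node_id} not in lookup") from None

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, node_id: int) -> bool:
        return int(node_id) in self.entries


def grids_compatible(a: VolumeGrid, b: VolumeGrid, atol: float = 1e-5) -> bool:
    return a.shape[:3] == b.shape[:3] and np.allclose(a.affine, b.affine, atol=atol)


def require_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "volumes") -> None:
    if not grids_compatible(a, b):
        raise GridError(
            f"{what} are not on the same grid: shapes {a.shape[:3]} vs {b.shape[:3]}, "
            f"affines\n{a.affine}\nvs\n{b.affine}\n"
            "resample to a common grid externally before calling this tool"
        )


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path: str | Path, ndim: int | None = None) -> VolumeGrid:
    """Read a NIfTI volume; ``ndim`` (3 or 4) enforces dimensionality."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if ndim == 3 and data.ndim > 3 else data
    if ndim is not None and data.ndim != ndim:
        raise GridError(f"{path}: expected a {ndim}D volume, got {data.ndim}D")
    return VolumeGrid(data=data, affine=img.affine)


def write_volume(grid: VolumeGrid, path: str | Path) -> None:
    data = grid.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32, copy=False)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32, copy=False)
    nib.save(nib.Nifti1Image(data, grid.affine), str(path))


# ---------------------------------------------------------------------------
# Streamlines (TCK / TRK)


def read_tractogram(path: str | Path) -> list[np.ndarray]:
    """Load streamlines as a list of (N, 3) float64 world-mm arrays."""
    path = Path(path)
    if path.suffix.lower() not in (".tck", ".trk"):
        raise ValueError(f"unknown tractogram extension: {path.suffix!r} (need .tck/.trk)")
    tf = nib.streamlines.load(str(path))  # applies header transform to world mm
    if path.suffix.lower() == ".trk":
        vox2ras = np.asarray(tf.header[nib.streamlines.trk.Field.VOXEL_TO_RASMM], float)
        if abs(np.linalg.det(vox2ras[:3, :3])) < 1e-12:
            raise ValueError(f"{path}: TRK header affine is degenerate")
    return [np.asarray(s, dtype=float) for s in tf.streamlines]


def write_tractogram(
    streamlines: Iterable[np.ndarray],
    path: str | Path,
    reference: VolumeGrid | None = None,
) -> None:
    """Write world-mm streamlines as TCK or TRK.

    TRK requires grid geometry in its header; ``reference`` supplies it
    (defaults to a 1 mm isotropic identity grid large enough to be harmless,
    since coordinates are stored relative to the header affine anyway).
    """
    path = Path(path)
    sl = [np.asarray(s, dtype=np.float32).reshape(-1, 3) for s in streamlines]
    tractogram = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    suffix = path.suffix.lower()
    if suffix == ".tck":
        nib.streamlines.save(tractogram, str(path))
    elif suffix == ".trk":
        Field = nib.streamlines.trk.Field
        if reference is not None:
            affine = reference.affine
            dims = np.asarray(reference.shape[:3], dtype=np.int16)
        else:
            affine = np.eye(4)
            dims = np.asarray((256, 256, 256), dtype=np.int16)
        header = {
            Field.VOXEL_TO_RASMM: affine.astype(np.float32),
            Field.VOXEL_SIZES: np.sqrt((affine[:3, :3] ** 2).sum(axis=0)).astype(np.float32),
            Field.DIMENSIONS: dims,
        }
        nib.streamlines.save(tractogram, str(path), header=header)
    else:
        raise ValueError(f"unknown tractogram extension: {path.suffix!r} (need .tck/.trk)")


# ---------------------------------------------------------------------------
# Connectome CSV and lookup TSV


def write_connectome_csv(matrix, lookup: NodeLookup, path: str | Path) -> None:
    """Write a symmetric streamline-count matrix as CSV with named header row/column."""
    counts = np.asarray(matrix.counts)
    if counts.shape[0] != counts.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.array_equal(counts, counts.T):
        raise ValueError("connectivity matrix must be symmetric")
    if len(matrix.node_ids) != len(lookup):
        raise ValueError(
            f"matrix has {len(matrix.node_ids)} nodes but lookup has {len(lookup)}"
        )
    names = [lookup.name(i) for i in matrix.node_ids]
    pd.DataFrame(counts, index=names, columns=names).to_csv(str(path))


def read_connectome_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), index_col=0)


def read_lookup(path: str | Path) -> NodeLookup:
    """Read a two-column (id, name) TSV."""
    df = pd.read_csv(str(path), sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "name" not in cols:
        raise ValueError(f"{path}: lookup TSV needs 'id' and 'name' columns")
    entries = dict(zip(df[cols["id"]].astype(int), df[cols["name"]].astype(str)))
    if len(entries) != len(df):
        raise ValueError(f"{path}: duplicate node ids in lookup")
    return NodeLookup(entries)


def write_lookup(lookup: NodeLookup, path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(lookup.entries), "name": list(lookup.entries.values())}
    ).to_csv(str(path), sep="\t", index=False)


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
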