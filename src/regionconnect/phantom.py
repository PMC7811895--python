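"""Deterministic synthetic phantoms: labeled blob volumes + geometric bundles.

A phantom is a small labeled grid (rectangular gray-matter "blobs", one
node id each) plus a tractogram of synthetic bundles running between blob
pairs, with the per-edge streamline counts known by construction.  This
gives every downstream stage — connectome construction, layered labels,
region queries, evaluation metrics — an exactly known ground truth without
any external imaging data.  Only geometry is simulated: no diffusion
signal, no fODFs, no anatomy.

Streamline paths are straight lines or single-waypoint arcs, resampled at
no more than half the smallest voxel size so traversal is dense (mirroring
1 mm stepping on a 1 mm grid), with a per-streamline lateral Gaussian
offset tapered to zero at the endpoints so that every endpoint stays
strictly inside its blob.  Identical spec + seed reproduces the phantom
bit for bit.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .io_formats import VolumeGrid
from .tractogram_core import Edge, voxels_traversed

#: default phantom seed, recorded in output metadata
DEFAULT_SEED = 20201016


@dataclasses.dataclass(frozen=True)
class Blob:
    """Axis-aligned box of voxels carrying one gray-matter node id."""

    node_id: int
    corner: tuple[int, int, int]   # voxel index of the low corner
    extent: tuple[int, int, int]   # box size in voxels


@dataclasses.dataclass(frozen=True)
class Bundle:
    """A synthetic fiber bundle between two blobs.

    ``waypoint_offset_mm`` bends the path through a quadratic arc whose
    control point is the midpoint shifted by this vector; None is straight.
    ``endpoint_spread`` scales how much of each blob the endpoints sample:
    1.0 fans endpoints over the whole blob interior, smaller values
    concentrate them around the blob centre so the bundle is a coherent
    tube (endpoints always stay strictly inside the blob).
    """

    node_a: int
    node_b: int
    n_streamlines: int
    waypoint_offset_mm: Optional[tuple[float, float, float]] = None
    points_per_streamline: int = 2
    jitter_sd_mm: float = 0.0
    endpoint_spread: float = 1.0


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    blobs: tuple[Blob, ...]
    bundles: tuple[Bundle, ...]
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        ids = [b.node_id for b in self.blobs]
        if len(set(ids)) != len(ids):
            raise ValueError("blob node ids must be distinct")
        if any(i < 1 for i in ids):
            raise ValueError("node ids must be >= 1")
        shape = np.asarray(self.grid_shape)
        if np.any(shape < 1) or any(s <= 0 for s in self.voxel_size):
            raise ValueError("grid shape and voxel size must be positive")
        occupied: dict[tuple[int, int, int], int] = {}
        for blob in self.blobs:
            corner, extent = np.asarray(blob.corner), np.asarray(blob.extent)
            if np.any(corner < 0) or np.any(corner + extent > shape):
                raise ValueError(f"blob {blob.node_id} extends outside the grid")
            for vox in np.ndindex(*extent):
                key = tuple(corner + vox)
                if key in occupied and occupied[key] != blob.node_id:
                    raise ValueError(
                        f"blobs {occupied[key]} and {blob.node_id} overlap at voxel {key}: "
                        "labels would be ambiguous"
                    )
                occupied[key] = blob.node_id
        by_id = {b.node_id: b for b in self.blobs}
        for bundle in self.bundles:
            if bundle.node_a == bundle.node_b:
                raise ValueError("bundle endpoints must differ")
            for nid in (bundle.node_a, bundle.node_b):
                if nid not in by_id:
                    raise ValueError(f"bundle references unknown node {nid}")
                if any(e <= 0 for e in by_id[nid].extent):
                    raise ValueError(f"bundle endpoint blob {nid} has zero extent")
            if bundle.n_streamlines < 1:
                raise ValueError("bundles need at least one streamline")


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth bundled with every phantom."""

    edge_counts: dict[Edge, int]
    crossing_voxels: set[tuple[int, int, int]]
    seed: int = DEFAULT_SEED


def _affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spec.voxel_size
    return aff


def _sample_in_blob(blob: Blob, rng: np.random.Generator, spread: float = 1.0) -> np.ndarray:
    """Uniform point strictly inside the blob's voxel box, in voxel coords.

    ``spread`` in (0, 1] shrinks the sampling box toward the blob centre.
    """
    corner = np.asarray(blob.corner, float)
    extent = np.asarray(blob.extent, float)
    margin = 0.05
    lo = corner - 0.5 + margin
    hi = corner + extent - 0.5 - margin
    center = (lo + hi) / 2.0
    half = (hi - lo) / 2.0 * float(np.clip(spread, 1e-6, 1.0))
    return rng.uniform(center - half, center + half)


def _bundle_path(
    start_mm: np.ndarray,
    end_mm: np.ndarray,
    bundle: Bundle,
    step_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if bundle.waypoint_offset_mm is None:
        control = (start_mm + end_mm) / 2.0
    else:
        control = (start_mm + end_mm) / 2.0 + np.asarray(bundle.waypoint_offset_mm, float)
    offset = (
        rng.normal(0.0, bundle.jitter_sd_mm, size=3) if bundle.jitter_sd_mm > 0 else None
    )
    # control-polygon length bounds the Bezier speed; the sine taper of the
    # jitter offset adds at most pi*|offset| to it, so sizing the sample
    # count from their sum keeps the final point spacing below step_mm
    length = np.linalg.norm(control - start_mm) + np.linalg.norm(end_mm - control)
    if offset is not None:
        length += float(np.pi * np.linalg.norm(offset))
    n_points = max(bundle.points_per_streamline, int(np.ceil(length / step_mm)) + 1, 2)
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    path = (1 - t) ** 2 * start_mm + 2 * (1 - t) * t * control + t**2 * end_mm

    if offset is not None:
        taper = np.sin(np.pi * t)  # zero at both endpoints: they stay in their blobs
        path = path + taper * offset
    return path


def make_phantom(spec: PhantomSpec) -> tuple[VolumeGrid, list[np.ndarray], PhantomTruth]:
    """Build (label volume, tractogram, ground truth) from a phantom spec."""
    spec.validate()
    affine = _affine(spec)
    data = np.zeros(spec.grid_shape, dtype=np.int32)
    for blob in spec.blobs:
        sl = tuple(slice(c, c + e) for c, e in zip(blob.corner, blob.extent))
        data[sl] = blob.node_id
    labels = VolumeGrid(data=data, affine=affine)

    rng = np.random.default_rng(spec.seed)
    step_mm = 0.5 * min(spec.voxel_size)
    by_id = {b.node_id: b for b in spec.blobs}

    streamlines: list[np.ndarray] = []
    edge_counts: dict[Edge, int] = {}
    bundle_voxels: list[set[tuple[int, int, int]]] = []
    for bundle in spec.bundles:
        edge = Edge.make(bundle.node_a, bundle.node_b)
        edge_counts[edge] = edge_counts.get(edge, 0) + bundle.n_streamlines
        traversed: set[tuple[int, int, int]] = set()
        for _ in range(bundle.n_streamlines):
            start = labels.voxel_to_world(
                _sample_in_blob(by_id[bundle.node_a], rng, bundle.endpoint_spread))[0]
            end = labels.voxel_to_world(
                _sample_in_blob(by_id[bundle.node_b], rng, bundle.endpoint_spread))[0]
            path = _bundle_path(start, end, bundle, step_mm, rng)
            streamlines.append(path)
            traversed |= voxels_traversed(path, labels)
        bundle_voxels.append(traversed)

    crossing: set[tuple[int, int, int]] = set()
    for a in range(len(bundle_voxels)):
        for b in range(a + 1, len(bundle_voxels)):
            crossing |= bundle_voxels[a] & bundle_voxels[b]

    truth = PhantomTruth(edge_counts=edge_counts, crossing_voxels=crossing, seed=spec.seed)
    return labels, streamlines, truth


def canonical_crossing_phantom() -> tuple[VolumeGrid, list[np.ndarray], PhantomTruth]:
    """The built-in two-bundle crossing phantom used throughout the tests.

    20x20x20 grid, 1 mm isotropic, four 4-voxel-cube blobs (nodes 1-4) in
    the corners of the mid-axial band.  Bundle (1, 2): 30 streamlines along
    one diagonal; bundle (3, 4): 10 streamlines along the other, so the two
    cross centrally and any crossing voxel sees streamlines of both edges
    at roughly a 3:1 ratio.
    """
    return make_phantom(canonical_crossing_spec())


def canonical_crossing_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(20, 20, 20),
        voxel_size=(1.0, 1.0, 1.0),
        blobs=(
            Blob(1, (1, 1, 8), (4, 4, 4)),
            Blob(2, (15, 15, 8), (4, 4, 4)),
            Blob(3, (15, 1, 8), (4, 4, 4)),
            Blob(4, (1, 15, 8), (4, 4, 4)),
        ),
        bundles=(
            Bundle(1, 2, n_streamlines=30, jitter_sd_mm=0.4, endpoint_spread=0.25),
            Bundle(3, 4, n_streamlines=10, jitter_sd_mm=0.4, endpoint_spread=0.25),
        ),
        seed=DEFAULT_SEED,
    )


def default_lookup_names(node_ids: Sequence[int]) -> dict[int, str]:
    return {int(i): f"node_{int(i):02d}" for i in node_ids}
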