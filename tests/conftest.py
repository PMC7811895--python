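import numpy as np
import pytest

import regionconnect as rc


@pytest.fixture(scope="session")
def canonical_phantom():
    """Label volume, tractogram and ground truth of the built-in crossing phantom."""
    return rc.canonical_crossing_phantom()


@pytest.fixture(scope="session")
def canonical_field(canonical_phantom):
    labels, streamlines, _ = canonical_phantom
    return rc.build_edge_count_field(streamlines, labels)


@pytest.fixture(scope="session")
def lookup4():
    return rc.NodeLookup({i: f"node_{i:02d}" for i in range(1, 5)})


def dense_voxels_traversed(streamline, grid, step_fraction=0.01):
    """Brute-force traversal oracle: dense resampling plus adaptive refinement.

    Independent of the analytic segment-grid intersection used by the
    package: walks every segment at ``step_fraction`` x the smallest voxel
    size, bins each sample (half-open bins, boundary points to the larger
    index), and bisects between consecutive samples that land in different
    voxels.  Because voxels are convex, a straight subsegment whose two
    ends share a voxel lies entirely inside it, so the refinement recovers
    every traversed voxel down to ~1e-9 voxel units of chord length.
    """
    pts = np.asarray(streamline, float).reshape(-1, 3)
    vox_pts = grid.world_to_voxel(pts)
    shape = np.asarray(grid.shape[:3])
    out = set()

    def bin_of(q):
        return tuple(int(x) for x in np.floor(q + 0.5))

    def add(b):
        if all(0 <= b[k] < shape[k] for k in range(3)):
            out.add(b)

    def refine(a, b):
        stack = [(a, b)]
        while stack:
            lo, hi = stack.pop()
            blo, bhi = bin_of(lo), bin_of(hi)
            add(blo)
            add(bhi)
            if blo == bhi or np.max(np.abs(hi - lo)) < 1e-9:
                continue
            mid = (lo + hi) / 2.0
            stack.append((lo, mid))
            stack.append((mid, hi))

    step_vox = max(step_fraction, 1e-6)
    add(bin_of(vox_pts[0]))
    for a, b in zip(vox_pts[:-1], vox_pts[1:]):
        n = max(int(np.ceil(np.max(np.abs(b - a)) / step_vox)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        samples = a + t * (b - a)
        for lo, hi in zip(samples[:-1], samples[1:]):
            if bin_of(lo) != bin_of(hi):
                refine(lo, hi)
            else:
                add(bin_of(lo))
        add(bin_of(samples[-1]))
    return out


def random_affine(rng):
    """Random rigid rotation + anisotropic voxel sizes + translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    scales = rng.uniform(0.5, 2.5, size=3)
    affine = np.eye(4)
    affine[:3, :3] = q @ np.diag(scales)
    affine[:3, 3] = rng.uniform(-5, 5, size=3)
    return affine


def random_streamline(rng, grid, n_points=None):
    """Random polyline whose vertices lie inside the grid's world bounds."""
    n_points = n_points or rng.integers(2, 8)
    shape = np.asarray(grid.shape[:3])
    vox = rng.uniform(-0.49, shape - 0.51, size=(n_points, 3))
    return grid.voxel_to_world(vox)
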