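"""Spatial-correspondence metrics between streamline voxel sets and TDIs.

Volumetric overlap (OL) is the fraction of reference voxels the candidate
covers; volumetric overreach (OR) is the fraction of *candidate* voxels
lying outside the reference.  The candidate-relative overreach keeps
(1 - OR) a precision, so the F1 score

    F1 = 2 (1 - OR) OL / ((1 - OR) + OL)

is the harmonic mean of precision and recall, stays in [0, 1], and — for
binary voxel sets — coincides with the Dice coefficient.  A
reference-relative overreach could exceed 1 and push the formula negative,
which is why that convention is rejected here.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy import stats

from .io_formats import VolumeGrid, require_same_grid


@dataclasses.dataclass
class CorrespondenceScore:
    overlap: float
    overreach: float
    f1: float
    pearson_r: Optional[float]  # None when undefined (zero variance / tiny support)


def overlap_overreach(candidate: set, reference: set) -> tuple[float, float]:
    """(OL, OR) between two voxel sets; the reference must be non-empty."""
    candidate, reference = set(candidate), set(reference)
    if not reference:
        raise ValueError("reference voxel set is empty")
    ol = len(candidate & reference) / len(reference)
    orr = len(candidate - reference) / len(candidate) if candidate else 0.0
    return ol, orr


def f1_score(overlap: float, overreach: float) -> float:
    """F1 from overlap and (candidate-relative) overreach; 0 when degenerate."""
    if not 0 <= overlap <= 1 or not 0 <= overreach <= 1:
        raise ValueError("overlap and overreach must lie in [0, 1]")
    precision = 1.0 - overreach
    denom = precision + overlap
    if denom == 0.0:
        return 0.0
    return 2.0 * precision * overlap / denom


def tdi_pearson(a: VolumeGrid, b: VolumeGrid, support: str = "union") -> Optional[float]:
    """Pearson r between two track-density images over a voxel support.

    ``support`` is ``union`` (default: voxels nonzero in either map),
    ``intersection``, or ``all``.  Restricting to nonzero voxels avoids the
    vast zero background inflating the correlation.  Returns None when the
    correlation is undefined (fewer than 2 support voxels, or zero variance
    in either map).
    """
    require_same_grid(a, b, "track-density images")
    x = np.asarray(a.data, dtype=float).ravel()
    y = np.asarray(b.data, dtype=float).ravel()
    if support == "union":
        keep = (x != 0) | (y != 0)
    elif support == "intersection":
        keep = (x != 0) & (y != 0)
    elif support == "all":
        keep = np.ones_like(x, dtype=bool)
    else:
        raise ValueError(f"unknown support {support!r}")
    x, y = x[keep], y[keep]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return None
    return float(stats.pearsonr(x, y)[0])


def edge_correspondence(candidate_tdi: VolumeGrid, reference_tdi: VolumeGrid) -> CorrespondenceScore:
    """Score one candidate TDI against a reference TDI on the same grid.

    Voxel sets are the nonzero supports of each image.  Averaging scores
    across edges or subject pairs is a plain mean left to the caller.
    """
    require_same_grid(candidate_tdi, reference_tdi, "track-density images")
    cand = set(map(tuple, np.argwhere(np.asarray(candidate_tdi.data) != 0)))
    ref = set(map(tuple, np.argwhere(np.asarray(reference_tdi.data) != 0)))
    ol, orr = overlap_overreach(cand, ref)
    return CorrespondenceScore(
        overlap=ol,
        overreach=orr,
        f1=f1_score(ol, orr),
        pearson_r=tdi_pearson(candidate_tdi, reference_tdi),
    )
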