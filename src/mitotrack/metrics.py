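"""Segmentation-quality metrics: Jaccard coefficient and modified Hausdorff distance."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["jaccard", "modified_hausdorff", "ValidationReport", "validate_batch"]


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValueError("masks must be 2-D")
    return m


def jaccard(a, m) -> float:
    """Jaccard similarity coefficient |A ∩ M| / |A ∪ M| between pixel sets.

    1 means identical masks, 0 means disjoint.  Undefined (raises) when both
    masks are empty.
    """
    A, M = _as_mask(a), _as_mask(m)
    if A.shape != M.shape:
        raise ValueError("masks must have the same shape")
    union = np.logical_or(A, M).sum()
    if union == 0:
        raise ValueError("jaccard undefined: both masks empty")
    return float(np.logical_and(A, M).sum() / union)


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return mask & ~eroded


def modified_hausdorff(a, m, boundary_only: bool = False) -> float:
    """Modified Hausdorff distance between two masks, in pixels.

    The maximum of the two mean directed nearest-point Euclidean distances
    between the foreground pixel sets.  0 iff the sets coincide.  With
    ``boundary_only=True`` the distance is computed between boundary pixels
    only, the usual convention for contour comparison.

    Directed mean distances are evaluated with a Euclidean distance
    transform, which is exact on the pixel grid.
    """
    A, M = _as_mask(a), _as_mask(m)
    if A.shape != M.shape:
        raise ValueError("masks must have the same shape")
    if boundary_only:
        A, M = _boundary(A), _boundary(M)
    if A.sum() == 0 or M.sum() == 0:
        raise ValueError("modified_hausdorff undefined for empty masks")
    # distance_transform_edt(~M) holds, at every pixel, the distance to the
    # nearest pixel of M — i.e. d(., M) sampled on the whole grid.
    d_to_M = ndimage.distance_transform_edt(~M)
    d_to_A = ndimage.distance_transform_edt(~A)
    return float(max(d_to_M[A].mean(), d_to_A[M].mean()))


@dataclass
class ValidationReport:
    """Per-pair JSC/MHD values plus their means over a batch."""

    jsc: list[float] = field(default_factory=list)
    mhd: list[float] = field(default_factory=list)

    @property
    def mean_jsc(self) -> float:
        return float(np.mean(self.jsc))

    @property
    def mean_mhd(self) -> float:
        return float(np.mean(self.mhd))


def validate_batch(automated, manual, boundary_only: bool = False) -> ValidationReport:
    """Compare paired mask lists and collect JSC/MHD per pair."""
    if len(automated) != len(manual):
        raise ValueError("batch lengths differ")
    report = ValidationReport()
    for a, m in zip(automated, manual):
        report.jsc.append(jaccard(a, m))
        report.mhd.append(modified_hausdorff(a, m, boundary_only=boundary_only))
    return report
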