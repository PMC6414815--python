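"""Circular Hough transform detection of mitotic (rounded) cells.

Mitotic cells in phase contrast round up into bright-rimmed disks, so a
circle detector is a natural per-frame trigger for mitosis analysis.  Edge
pixels vote along their gradient direction into a 3-D (row, col, radius)
accumulator; peaks are circle candidates ranked by a radius-normalised
significance, and a greedy rule removes duplicate detections of the same
cell within a frame and across consecutive frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import gradient_magnitude

__all__ = [
    "CircleCandidate",
    "DetectionParams",
    "edge_map",
    "cht_accumulate",
    "find_circles",
    "select_mitotic_candidates",
]


@dataclass(frozen=True)
class CircleCandidate:
    """One circle hypothesis: centre (row, col), radius and accumulator peak value."""

    center_row: float
    center_col: float
    radius: float
    significance: float
    frame_index: int = 0


@dataclass
class DetectionParams:
    """Tunable knobs of the circle detector (a per-cell-line preset).

    ``edge_threshold`` and ``peak_threshold`` are fractions of the maximum
    gradient magnitude and of the accumulator maximum, respectively.
    ``dedup_spatial`` / ``dedup_temporal`` are the centre distances (px)
    below which two candidates in the same frame / in consecutive frames
    are considered the same cell.
    """

    radius_min: float = 6.0
    radius_max: float = 14.0
    edge_threshold: float = 0.3
    peak_threshold: float = 0.5
    max_candidates_per_frame: int = 5
    dedup_spatial: float | None = None
    dedup_temporal: float | None = None
    smooth_sigma: float = 1.5
    min_significance: float = 0.1

    def __post_init__(self):
        if not (0 < self.radius_min <= self.radius_max):
            raise ValueError("need 0 < radius_min <= radius_max")
        for name in ("edge_threshold", "peak_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.max_candidates_per_frame < 1:
            raise ValueError("max_candidates_per_frame must be >= 1")
        if self.dedup_spatial is None:
            self.dedup_spatial = self.radius_max
        if self.dedup_temporal is None:
            self.dedup_temporal = self.radius_max


def edge_map(image, edge_threshold: float) -> np.ndarray:
    """Binary edge mask: gradient magnitude >= threshold * max magnitude."""
    if not (0 < edge_threshold < 1):
        raise ValueError("edge_threshold must be in (0, 1)")
    grad = gradient_magnitude(image, eps=0.0)
    gmax = grad.max()
    if gmax == 0:
        return np.zeros_like(grad, dtype=bool)
    return grad >= edge_threshold * gmax


def _radius_bins(radius_range: tuple[float, float], n_radii: int) -> np.ndarray:
    rmin, rmax = radius_range
    if not (0 < rmin <= rmax) or n_radii < 1:
        raise ValueError("invalid radius range")
    return np.linspace(rmin, rmax, n_radii)


def cht_accumulate(edge_mask, grad_row, grad_col,
                   radius_range: tuple[float, float], n_radii: int) -> np.ndarray:
    """Gradient-directed circular Hough voting.

    Each edge pixel casts one vote per radius bin at the two candidate
    centres lying a distance r along +/- its gradient direction (bright and
    dark disks are covered by voting both ways).  Votes in each radius
    slice are divided by the circumference ``2 pi r`` so that peak values
    are comparable across radii.  Returns a (rows, cols, n_radii) array.
    """
    mask = np.asarray(edge_mask).astype(bool)
    radii = _radius_bins(radius_range, n_radii)
    acc = np.zeros(mask.shape + (n_radii,), dtype=float)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return acc
    gr = np.asarray(grad_row, dtype=float)[rows, cols]
    gc = np.asarray(grad_col, dtype=float)[rows, cols]
    norm = np.hypot(gr, gc)
    ok = norm > 0
    rows, cols, gr, gc, norm = rows[ok], cols[ok], gr[ok], gc[ok], norm[ok]
    ur, uc = gr / norm, gc / norm
    nr, nc = mask.shape
    for k, r in enumerate(radii):
        for sign in (1.0, -1.0):
            cr = np.rint(rows + sign * r * ur).astype(int)
            cc = np.rint(cols + sign * r * uc).astype(int)
            keep = (cr >= 0) & (cr < nr) & (cc >= 0) & (cc < nc)
            np.add.at(acc[:, :, k], (cr[keep], cc[keep]), 1.0)
        acc[:, :, k] /= 2.0 * np.pi * r
    return acc


def find_circles(image, params: DetectionParams, frame_index: int = 0,
                 n_radii: int | None = None) -> list[CircleCandidate]:
    """Detect circle candidates in one frame, sorted by significance.

    The frame is Gaussian-smoothed (``smooth_sigma``) before gradients are
    taken — noisy gradient directions smear the votes of large circles
    tangentially, depressing their peaks relative to small ones.  The
    accumulator slices are themselves Gaussian-smoothed (sigma = 1) before
    peak detection; local maxima above ``peak_threshold`` times the
    accumulator maximum become candidates, with nearby weaker peaks
    suppressed.
    """
    image = np.asarray(image, dtype=float)
    if params.smooth_sigma > 0:
        image = ndimage.gaussian_filter(image, params.smooth_sigma, mode="reflect")
    if n_radii is None:
        n_radii = max(int(round(params.radius_max - params.radius_min)) + 1, 2)
    radii = _radius_bins((params.radius_min, params.radius_max), n_radii)
    grad_row, grad_col = np.gradient(image)
    edges = edge_map(image, params.edge_threshold)
    acc = cht_accumulate(edges, grad_row, grad_col,
                         (params.radius_min, params.radius_max), n_radii)
    for k in range(n_radii):
        acc[:, :, k] = ndimage.gaussian_filter(acc[:, :, k], sigma=1.0)
    amax = acc.max()
    if amax <= 0:
        return []
    # the peak threshold is relative to this frame's strongest response;
    # the absolute floor keeps incoherent noise peaks out of frames that
    # contain no circular object at all (a ~10% aligned arc at minimum)
    thresh = max(params.peak_threshold * amax, params.min_significance)
    local_max = acc == ndimage.maximum_filter(acc, size=(5, 5, 3), mode="constant")
    peaks = np.argwhere(local_max & (acc >= thresh))
    if peaks.size == 0:
        return []
    values = acc[peaks[:, 0], peaks[:, 1], peaks[:, 2]]
    order = np.argsort(-values, kind="stable")
    candidates: list[CircleCandidate] = []
    taken: list[tuple[float, float]] = []
    for idx in order:
        r, c, k = peaks[idx]
        # one detection per circle: drop peaks too close to an accepted one
        if any((r - tr) ** 2 + (c - tc) ** 2 < params.radius_min**2 for tr, tc in taken):
            continue
        candidates.append(CircleCandidate(float(r), float(c), float(radii[k]),
                                          float(values[idx]), frame_index))
        taken.append((float(r), float(c)))
        if len(candidates) >= params.max_candidates_per_frame:
            break
    return candidates


def select_mitotic_candidates(per_frame: list[list[CircleCandidate]],
                              params: DetectionParams) -> list[CircleCandidate]:
    """Greedy global de-duplication across frames.

    Candidates are visited in decreasing significance; one is rejected if
    its centre lies within ``dedup_spatial`` px of an already accepted
    candidate in the same frame, or within ``dedup_temporal`` px of one in
    an adjacent frame.
    """
    pool = [c for frame in per_frame for c in frame]
    pool.sort(key=lambda c: (-c.significance, c.frame_index, c.center_row, c.center_col))
    accepted: list[CircleCandidate] = []

    def clashes(cand: CircleCandidate, other: CircleCandidate) -> bool:
        d2 = (cand.center_row - other.center_row) ** 2 + (cand.center_col - other.center_col) ** 2
        if cand.frame_index == other.frame_index:
            return d2 < params.dedup_spatial**2
        if abs(cand.frame_index - other.frame_index) == 1:
            return d2 < params.dedup_temporal**2
        return False

    for cand in pool:
        if not any(clashes(cand, acc) for acc in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: (c.frame_index, -c.significance))
    return accepted
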