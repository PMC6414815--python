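"""Shared image operators for phase-contrast analysis.

All operators act on 2-D ``float64`` arrays ("images") whose intensities are
assumed to live on a [0, 1] scale after :func:`normalize_intensities`.  The
conventions here are used by every downstream stage: detection, level-set
segmentation, tracking and feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "FrameSequence",
    "normalize_intensities",
    "gaussian_smooth",
    "gradient_magnitude",
    "local_std_map",
    "normal_velocity",
    "edge_indicator",
    "circularity",
    "mask_perimeter",
]


@dataclass
class FrameSequence:
    """An ordered greyscale time-lapse: frames plus the acquisition interval.

    Frames are 2-D float arrays on a common grid; ``frame_interval_min`` is
    the time between consecutive frames in minutes, the unit in which all
    durations are reported.
    """

    frames: list = field(default_factory=list)
    frame_interval_min: float = 5.0

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        shape = np.asarray(self.frames[0]).shape
        if any(np.asarray(f).shape != shape for f in self.frames):
            raise ValueError("all frames must share one shape")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return np.asarray(self.frames[i], dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.frames[0]).shape


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    return arr


def normalize_intensities(image) -> np.ndarray:
    """Linearly rescale an image to [0, 1].

    Constant images map to all zeros (the range is degenerate, so there is
    no contrast to preserve).
    """
    arr = _as_image(image)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def gaussian_smooth(image, sigma: float) -> np.ndarray:
    """Convolve with a Gaussian kernel (reflective boundary)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndimage.gaussian_filter(_as_image(image), sigma=sigma, mode="reflect")


def _central_gradients(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central differences in the interior, one-sided at the border."""
    grow, gcol = np.gradient(arr)
    return grow, gcol


def gradient_magnitude(image, eps: float = 0.0) -> np.ndarray:
    """Regularised gradient magnitude ``sqrt(dx^2 + dy^2 + eps^2)``.

    With ``eps=0`` this is the plain gradient magnitude; a positive ``eps``
    bounds the result away from zero so it can serve as a denominator.
    """
    arr = _as_image(image)
    grow, gcol = _central_gradients(arr)
    return np.sqrt(grow * grow + gcol * gcol + eps * eps)


def local_std_map(image) -> np.ndarray:
    """Population standard deviation over a 3x3 window around each pixel.

    Reflective padding at the border; the estimator divides by 9 (population
    variance), so a constant window gives exactly 0.
    """
    arr = _as_image(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    mean = ndimage.uniform_filter(arr, size=3, mode="reflect")
    mean_sq = ndimage.uniform_filter(arr * arr, size=3, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def normal_velocity(frame_a, frame_b, eps: float) -> np.ndarray:
    """Normal-velocity image |v| between two consecutive frames.

    |v| is the absolute temporal intensity difference (one frame unit)
    divided by the eps-regularised spatial gradient magnitude of
    ``frame_a``.  It is large inside moving cells — where intensities change
    over time while the spatial gradient stays weak — and small in static
    background, which makes it a far better region feature than raw
    intensity under the shade-off effect.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    a = _as_image(frame_a)
    b = _as_image(frame_b)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    return np.abs(b - a) / gradient_magnitude(a, eps)


def edge_indicator(
    image,
    sigma: float = 1.0,
    kappa: float = 0.3,
    mode: str = "local_std",
) -> np.ndarray:
    """Edge-detector function g in (0, 1]: ~1 in homogeneous regions, ~0 at edges.

    mode="gradient"
        The classical reciprocal form ``g = 1 / (1 + |grad(G_sigma * psi)|^2)``
        used by geodesic active contours.
    mode="local_std"
        Phase-contrast variant: smooth the image, take the 3x3 local standard
        deviation, rescale it to [0, 1] and apply ``g = 1 / (1 + (s/kappa)^2)``.
        Halo rims are locally very inhomogeneous, so this indicator marks cell
        boundaries even when plain intensity gradients are weak.
    """
    if sigma <= 0 or kappa <= 0:
        raise ValueError("sigma and kappa must be positive")
    arr = _as_image(image)
    if mode == "gradient":
        g = gradient_magnitude(gaussian_smooth(arr, sigma), eps=0.0)
        return 1.0 / (1.0 + g * g)
    if mode == "local_std":
        s = local_std_map(gaussian_smooth(arr, sigma))
        smax = s.max()
        if smax > 0:
            s = s / smax
        return 1.0 / (1.0 + (s / kappa) ** 2)
    raise ValueError(f"unknown edge indicator mode: {mode!r}")


def _smooth_closed_polygon(vertices: np.ndarray, window: int = 3,
                           passes: int = 2) -> np.ndarray:
    """Circular moving average of a closed polygon's vertices."""
    v = vertices[:-1] if np.allclose(vertices[0], vertices[-1]) else vertices
    if len(v) <= window:
        return vertices
    kernel = np.ones(window) / window
    half = window // 2
    for _ in range(passes):
        wrapped = np.vstack([v[-half:], v, v[:half]])
        v = np.column_stack([
            np.convolve(wrapped[:, 0], kernel, mode="valid"),
            np.convolve(wrapped[:, 1], kernel, mode="valid"),
        ])
    return np.vstack([v, v[:1]])


def mask_perimeter(mask) -> float:
    """Perimeter of a binary mask from its sub-pixel boundary polygon.

    The boundary is traced by marching squares at level 0.5 on the
    zero-padded mask and the resulting polygon is lightly smoothed (window
    3, two passes) before its length is measured.  Raw pixel-edge or
    staircase-polygon lengths overestimate the perimeter of curved shapes
    by 5-10%, biasing disk circularity well below 1; the smoothed polygon
    recovers disks to within ~1% at the price of slightly cutting sharp
    corners (a 20 px square measures ~0.85 instead of pi/4).
    """
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        contour = _smooth_closed_polygon(contour)
        seg = np.diff(contour, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def circularity(mask) -> float:
    """Isoperimetric circularity ``4 pi A / P^2`` of a binary mask.

    1 for an ideal disk, lower for elongated or ragged shapes.  The value is
    clipped to [0, 1.05] to absorb discretisation overshoot on small disks.
    """
    m = np.asarray(mask, dtype=bool)
    area = float(m.sum())
    if area == 0:
        raise ValueError("mask is empty")
    per = mask_perimeter(m)
    if per == 0:
        return 1.05
    return float(np.clip(4.0 * np.pi * area / (per * per), 0.0, 1.05))
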