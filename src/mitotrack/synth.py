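"""Synthetic phase-contrast time-lapse generator with ground truth.

The generator emulates the two image characteristics that make real
phase-contrast data hard: the *shade-off* effect (cell interiors render at
near-background intensity, so plain thresholding fails) and the *halo*
effect (a bright rim along cell membranes that intensifies as cells round
up before mitosis).  Cells follow scripted schedules — flat, rounding into
a mitotic disk, dividing into daughters, or collapsing into bright
apoptotic debris — and every frame comes with exact per-cell ground-truth
masks and event times, so the detection, tracking and classification
stages can be exercised end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .core import FrameSequence

__all__ = [
    "CellSpec",
    "SceneSpec",
    "GroundTruthEvent",
    "GroundTruth",
    "render_frame",
    "generate_sequence",
    "random_battery_scene",
    "FATES",
]

FATES = ("regular_division", "abnormal_division", "no_division", "apoptosis")


@dataclass
class CellSpec:
    """Script for one cell: where it is and what it does, frame by frame.

    ``trajectory`` is an (n_frames, 2) array of (row, col) centres.  Before
    ``rounding_frame`` the cell is a flat elongated blob; from then on a
    mitotic disk of ``base_radius``; from ``division_frame`` it splits into
    ``n_daughters`` separating disks, or from ``apoptosis_frame`` it
    collapses into a small bright fragment.  Leave all event frames None
    for a bystander that stays flat.
    """

    trajectory: np.ndarray
    base_radius: float = 10.0
    rounding_frame: int | None = None
    division_frame: int | None = None
    apoptosis_frame: int | None = None
    n_daughters: int = 2
    elongation: float = 3.0
    flat_scale: float = 0.85
    orientation: float = 0.0
    division_axis: float = 0.0

    def __post_init__(self):
        self.trajectory = np.asarray(self.trajectory, dtype=float)
        if self.division_frame is not None and self.apoptosis_frame is not None:
            raise ValueError("a cell divides or dies, not both")
        if self.rounding_frame is not None:
            for end in (self.division_frame, self.apoptosis_frame):
                if end is not None and end <= self.rounding_frame:
                    raise ValueError("rounding must precede division/apoptosis")
        if self.n_daughters < 1:
            raise ValueError("n_daughters must be >= 1")

    def state_at(self, t: int) -> str:
        if self.rounding_frame is None or t < self.rounding_frame:
            return "flat"
        if self.division_frame is not None and t >= self.division_frame:
            return "dividing"
        if self.apoptosis_frame is not None and t >= self.apoptosis_frame:
            return "apoptotic"
        return "mitotic"


@dataclass
class SceneSpec:
    """A full scene: geometry, photometry and the cast of cells.

    ``halo_gain`` is the peak brightness of the membrane rim above
    background; ``shadeoff_contrast`` the (small) interior-vs-background
    offset; ``noise_sigma`` the additive Gaussian noise level — all on the
    [0, 1] intensity scale.
    """

    shape: tuple[int, int] = (112, 112)
    n_frames: int = 26
    frame_interval_min: float = 5.0
    cells: list[CellSpec] = field(default_factory=list)
    background_level: float = 0.5
    halo_gain: float = 0.25
    shadeoff_contrast: float = 0.03
    noise_sigma: float = 0.005
    halo_width: float = 1.3
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for cell in self.cells:
            if cell.trajectory.shape != (self.n_frames, 2):
                raise ValueError("trajectory must provide one centre per frame")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(shape, center, a, b, theta) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    x = np.cos(theta) * dr + np.sin(theta) * dc
    y = -np.sin(theta) * dr + np.cos(theta) * dc
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


_TEX_SIZE = 256


@lru_cache(maxsize=64)
def _cell_texture_cached(seed: int):
    return _cell_texture_impl(seed)


def _cell_texture_impl(seed: int) -> np.ndarray:
    """Static smooth random texture carried along with a cell.

    Cell interiors in phase contrast are inhomogeneous (organelles,
    granularity) while the background is smooth; the texture translates
    rigidly with the cell so it also feeds the temporal-derivative signal
    of a moving cell.  Zero-mean, unit-ish amplitude; scaled at draw time.
    """
    rng = np.random.default_rng(seed)
    t = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (_TEX_SIZE, _TEX_SIZE)), 2.0)
    return t / max(np.abs(t).max(), 1e-12)


def _sample_texture(tex: np.ndarray, shape, center) -> np.ndarray:
    """Texture window for a frame, anchored to the (rounded) cell centre."""
    half = _TEX_SIZE // 2
    off_r = half - int(round(center[0]))
    off_c = half - int(round(center[1]))
    r_idx = np.clip(np.arange(shape[0]) + off_r, 0, _TEX_SIZE - 1)
    c_idx = np.clip(np.arange(shape[1]) + off_c, 0, _TEX_SIZE - 1)
    return tex[np.ix_(r_idx, c_idx)]


def _halo_bump(mask: np.ndarray, gain: float, width: float) -> np.ndarray:
    """Gaussian-profiled bright rim along the inside of the mask boundary.

    The crest sits ~2 px inside the outline, so the glow decays outwards
    across the boundary: the cell's visible extent (interior plus bright
    rim) coincides with its ground-truth mask.
    """
    if not mask.any():
        return np.zeros(mask.shape)
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    # signed distance to the outline: negative inside
    dist = np.where(mask, -(d_in - 0.5), d_out - 0.5)
    return gain * np.exp(-((dist + 2.0) ** 2) / (2.0 * width * width))


def _cell_support(cell: CellSpec, scene: SceneSpec, t: int):
    """Mask, interior level offset and halo gain factor for one cell at frame t."""
    state = cell.state_at(t)
    center = cell.trajectory[t]
    shape = scene.shape
    if state == "flat":
        b = cell.flat_scale * cell.base_radius
        a = cell.elongation * b
        mask = _ellipse_mask(shape, center, a, b, cell.orientation)
        return mask, scene.shadeoff_contrast, 1.0, 0.06
    if state == "mitotic":
        mask = _disk_mask(shape, center, cell.base_radius)
        return mask, 2.0 * scene.shadeoff_contrast, 1.6, 0.05
    if state == "dividing":
        k = t - cell.division_frame
        n = cell.n_daughters
        r_d = cell.base_radius / np.sqrt(n)
        # daughters separate for a few frames, then settle; the radial
        # offset is chosen so the gap between neighbouring daughters is the
        # same for any daughter count
        gap = 2.0 + 2.2 * min(k, 4)
        sep = (2.0 * r_d + gap) / (2.0 * np.sin(np.pi / max(n, 2)))
        angles = cell.division_axis + 2.0 * np.pi * np.arange(n) / max(n, 2)
        mask = np.zeros(shape, dtype=bool)
        for ang in angles[:n] if n > 1 else [cell.division_axis]:
            dcen = center + sep * np.array([np.sin(ang), np.cos(ang)])
            mask |= _disk_mask(shape, dcen, r_d)
        # daughters re-flatten: their rims fade out within ~5 frames
        fade = max(0.0, 1.0 - 0.2 * k)
        return mask, scene.shadeoff_contrast, 1.3 * fade, 0.05
    if state == "apoptotic":
        k = t - cell.apoptosis_frame
        radius = 0.3 * cell.base_radius * 0.8**k
        if radius < 1.2:
            return np.zeros(shape, dtype=bool), 0.0, 0.0, 0.0
        mask = _disk_mask(shape, center, radius)
        return mask, 0.35, 0.8, 0.0
    raise AssertionError(state)


def render_frame(scene: SceneSpec, t: int, rng: np.random.Generator | None = None):
    """Render one frame; returns (image, {cell_index: ground-truth mask}).

    The ground-truth mask of a cell is exactly the support used to draw its
    interior (daughter disks are disjoint by construction).  Noise is only
    added when ``rng`` is given; :func:`generate_sequence` threads a seeded
    generator through all frames.
    """
    if not (0 <= t < scene.n_frames):
        raise ValueError("frame index out of range")
    image = np.full(scene.shape, scene.background_level, dtype=float)
    masks: dict[int, np.ndarray] = {}
    for idx, cell in enumerate(scene.cells):
        mask, interior, halo_factor, tex_amp = _cell_support(cell, scene, t)
        masks[idx] = mask
        if mask.any():
            image = np.where(mask, scene.background_level + interior, image)
            if tex_amp > 0:
                tex = _cell_texture_cached(scene.seed * 1009 + idx)
                image = np.where(
                    mask, image + tex_amp * _sample_texture(tex, scene.shape, cell.trajectory[t]),
                    image)
            image += _halo_bump(mask, halo_factor * scene.halo_gain, scene.halo_width)
    if rng is not None and scene.noise_sigma > 0:
        image += rng.normal(0.0, scene.noise_sigma, size=scene.shape)
    return np.clip(image, 0.0, 1.5), masks


@dataclass
class GroundTruthEvent:
    """True timing and outcome of one scripted mitosis."""

    cell_id: int
    start_frame: int
    end_frame: int
    fate: str
    duration_min: float
    detection_center: np.ndarray
    base_radius: float


@dataclass
class GroundTruth:
    """Per-frame masks and the event table of a generated scene."""

    masks: list[dict[int, np.ndarray]]
    events: list[GroundTruthEvent]
    frame_interval_min: float

    def mask(self, cell_id: int, t: int) -> np.ndarray:
        return self.masks[t][cell_id]


def generate_sequence(scene: SceneSpec):
    """Render all frames of a scene; same seed gives byte-identical output."""
    rng = np.random.default_rng(scene.seed)
    frames, per_frame_masks = [], []
    for t in range(scene.n_frames):
        image, masks = render_frame(scene, t, rng=rng)
        frames.append(image)
        per_frame_masks.append(masks)
    events = []
    for idx, cell in enumerate(scene.cells):
        if cell.rounding_frame is None:
            continue
        if cell.division_frame is not None:
            end = cell.division_frame
            fate = "regular_division" if cell.n_daughters == 2 else "abnormal_division"
        elif cell.apoptosis_frame is not None:
            end = cell.apoptosis_frame
            fate = "apoptosis"
        else:
            end = scene.n_frames - 1
            fate = "no_division"
        events.append(GroundTruthEvent(
            cell_id=idx,
            start_frame=cell.rounding_frame,
            end_frame=end,
            fate=fate,
            duration_min=(end - cell.rounding_frame) * scene.frame_interval_min,
            detection_center=cell.trajectory[cell.rounding_frame].copy(),
            base_radius=cell.base_radius,
        ))
    seq = FrameSequence(frames=frames, frame_interval_min=scene.frame_interval_min)
    return seq, GroundTruth(per_frame_masks, events, scene.frame_interval_min)


# ---------------------------------------------------------------------------
# scripted scenes for the synthetic test battery
# ---------------------------------------------------------------------------

def _drift_trajectory(rng, n_frames, speed, lo, hi):
    """Constant drift that stays strictly inside the [lo, hi] box.

    The start point is sampled from the sub-box that keeps the whole path
    in bounds, so the cell never runs into a wall and stops (a frozen cell
    has no temporal signal, which would be an artefact, not biology).
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    angle = rng.uniform(0, 2 * np.pi)
    v = speed * np.array([np.sin(angle), np.cos(angle)])
    offset = v * (n_frames - 1)
    start_lo = lo - np.minimum(offset, 0)
    start_hi = hi - np.maximum(offset, 0)
    if np.any(start_hi < start_lo):  # drift too long for the box: shrink it
        scale = np.min((hi - lo) / (np.abs(offset) + 1e-9)) * 0.9
        v = v * min(scale, 1.0)
        offset = v * (n_frames - 1)
        start_lo = lo - np.minimum(offset, 0)
        start_hi = hi - np.maximum(offset, 0)
    start = rng.uniform(start_lo, start_hi)
    return start[None, :] + v[None, :] * np.arange(n_frames)[:, None]


def random_battery_scene(seed: int, fate: str | None = None,
                         with_bystander: bool = True) -> SceneSpec:
    """One randomised single-mitosis scene for the synthetic battery.

    The scripted cell rounds up at a random frame and then divides
    (bipolar or tripolar), undergoes apoptosis, or never divides,
    according to ``fate`` (default: cycles through all four classes with
    the seed).  A flat bystander cell that never rounds is placed in the
    opposite image half as a detection distractor.
    """
    rng = np.random.default_rng(seed)
    if fate is None:
        fate = FATES[seed % len(FATES)]
    if fate not in FATES:
        raise ValueError(f"unknown fate {fate!r}")
    n_frames = 26
    shape = (128, 128)
    rounding = int(rng.integers(6, 11))
    span = int(rng.integers(5, 10))
    base_radius = float(rng.uniform(9.0, 11.0))

    # scripted cell drifts in the left half; the bystander lives on the right
    traj = _drift_trajectory(rng, n_frames, speed=float(rng.uniform(0.6, 1.0)),
                             lo=(28.0, 28.0), hi=(shape[0] - 28.0, 64.0))

    division = apoptosis = None
    n_daughters = 2
    if fate == "regular_division":
        division = rounding + span
    elif fate == "abnormal_division":
        division = rounding + span
        n_daughters = 3
    elif fate == "apoptosis":
        apoptosis = rounding + span

    cells = [CellSpec(
        trajectory=traj,
        base_radius=base_radius,
        rounding_frame=rounding,
        division_frame=division,
        apoptosis_frame=apoptosis,
        n_daughters=n_daughters,
        orientation=float(rng.uniform(-0.3, 0.3)),  # flat phase roughly row-aligned
        division_axis=float(rng.uniform(0, np.pi)),
    )]
    if with_bystander:
        bys_traj = _drift_trajectory(rng, n_frames, speed=0.3,
                                     lo=(40.0, shape[1] - 28.0),
                                     hi=(shape[0] - 40.0, shape[1] - 24.0))
        cells.append(CellSpec(
            trajectory=bys_traj,
            base_radius=9.0,
            orientation=float(rng.uniform(-0.4, 0.4)),
        ))
    return SceneSpec(shape=shape, n_frames=n_frames, cells=cells, seed=seed)
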