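"""Mitosis analysis workflow: detect, track backwards and forwards, call fates.

For every circle detection (a rounded, mitotic cell) the workflow segments
that frame with the detection circle as initial contour, then propagates
the contour backwards in time — each frame initialised from the slightly
dilated mask of the frame after it — until the cell's morphology breaks
(area grows and circularity drops below threshold), which marks the start
of mitosis.  Forwards propagation from the detection frame continues until
the fate is decided: a persistent split into two components is a regular
division, into three or more an abnormal one, a collapse into a small
bright remnant is apoptosis, and a cell that never splits is scored as no
division.  Mitosis duration is (end - start) frames times the frame
interval in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .core import FrameSequence, circularity, gaussian_smooth
from .hough import CircleCandidate, DetectionParams, find_circles, select_mitotic_candidates
from .levelset import (
    DivergenceError,
    SegmentationParams,
    evolve_tracking,
    signed_distance_from_mask,
)

__all__ = [
    "TrackingParams",
    "CellTrack",
    "MitoticEvent",
    "extend_contour",
    "track_backwards",
    "track_forwards",
    "analyse_sequence",
    "summarise_events",
]

log = logging.getLogger(__name__)

FATE_LABELS = ("regular_division", "abnormal_division", "no_division", "apoptosis")


@dataclass
class TrackingParams:
    """Stopping rules and contour-propagation knobs for tracking.

    Backwards tracking stops when the segmented area exceeds
    ``area_increase_factor`` times the detection-frame area *and*
    circularity falls below ``circularity_threshold`` (both must hold — a
    mitotic cell is small and round, a flat cell is large and elongated).
    """

    circularity_threshold: float = 0.85
    area_increase_factor: float = 1.3
    dilation_radius: int = 3
    max_track_frames: int = 60
    split_persistence: int = 2
    min_component_area: float = 30.0
    presmooth_sigma: float = 1.0
    apoptosis_intensity_quantile: float = 0.9

    def validate(self) -> "TrackingParams":
        if not (0 < self.circularity_threshold < 1):
            raise ValueError("circularity_threshold must be in (0, 1)")
        if self.area_increase_factor <= 1:
            raise ValueError("area_increase_factor must exceed 1")
        if self.dilation_radius < 0 or self.max_track_frames < 1:
            raise ValueError("invalid dilation_radius or max_track_frames")
        if self.split_persistence < 1 or self.min_component_area < 0:
            raise ValueError("invalid split_persistence or min_component_area")
        return self


@dataclass
class CellTrack:
    """Per-frame masks of one tracked cell, in one tracking direction."""

    masks: dict[int, np.ndarray] = field(default_factory=dict)
    direction: str = "forwards"


@dataclass
class MitoticEvent:
    """One tracked mitosis with its timing, fate and per-frame masks."""

    cell_id: int
    detection_frame: int
    start_frame: int
    end_frame: int
    fate: str
    duration_min: float
    masks: dict[int, np.ndarray] = field(default_factory=dict)
    detection: CircleCandidate | None = None


def extend_contour(mask, radius: int) -> np.ndarray:
    """Morphological dilation by a disk of the given radius (0 = identity)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    m = np.asarray(mask).astype(bool)
    if radius == 0:
        return m.copy()
    rr, cc = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    selem = rr * rr + cc * cc <= radius * radius
    return ndimage.binary_dilation(m, structure=selem)


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _neighbor_index(t: int, direction: int, n: int) -> int:
    """Frame used for the temporal derivative: the one ahead in tracking order."""
    j = t + direction
    if 0 <= j < n:
        return j
    return t - direction  # clamp at the sequence ends


def _segment_frame(seq: FrameSequence, t: int, phi0, seg: SegmentationParams,
                   trk: TrackingParams, direction: int) -> np.ndarray:
    sigma = trk.presmooth_sigma
    frame = seq[t]
    neighbor = seq[_neighbor_index(t, direction, len(seq))]
    if sigma > 0:
        frame = gaussian_smooth(frame, sigma)
        neighbor = gaussian_smooth(neighbor, sigma)
    phi = evolve_tracking(frame, neighbor, phi0, seg)
    return phi <= 0


def _event_params(seg: SegmentationParams, detect_area: float,
                  preserve_topology: bool) -> SegmentationParams:
    """Per-event parameter copy: area floor anchored to the detection size."""
    t_area = seg.t_area if seg.t_area > 0 else 0.15 * detect_area
    return replace(seg, t_area=t_area, preserve_topology=preserve_topology)


def _segment_detection(seq, detection, seg, trk, direction):
    shape = seq.shape
    circle = _disk_mask(shape, (detection.center_row, detection.center_col),
                        detection.radius)
    if not circle.any() or circle.all():
        raise ValueError("detection circle degenerate for this frame")
    params = _event_params(seg, float(circle.sum()), preserve_topology=direction < 0)
    phi0 = signed_distance_from_mask(circle)
    mask = _segment_frame(seq, detection.frame_index, phi0, params, trk, direction)
    if not mask.any():
        raise ValueError("segmentation of the detection frame vanished")
    return mask, params


def track_backwards(seq: FrameSequence, detection: CircleCandidate,
                    seg: SegmentationParams, trk: TrackingParams):
    """Propagate the contour backwards to the start of mitosis.

    Returns ``(CellTrack, start_frame)``.  The morphology-break frame
    itself is not part of the track: the start of mitosis is the first
    frame in which the cell is already rounded.
    """
    trk.validate()
    t0 = detection.frame_index
    if not (0 <= t0 < len(seq)):
        raise ValueError("detection frame outside the sequence")
    mask, params = _segment_detection(seq, detection, seg, trk, direction=-1)
    # reference size for the area rule: the smallest (roundest) mask seen
    # so far, which is robust to overshoot at the detection frame itself
    area_ref = float(mask.sum())
    track = CellTrack(masks={t0: mask}, direction="backwards")
    start = t0
    prev = mask
    for t in range(t0 - 1, -1, -1):
        if t0 - t > trk.max_track_frames:
            break
        phi0 = signed_distance_from_mask(extend_contour(prev, trk.dilation_radius))
        cur = _segment_frame(seq, t, phi0, params, trk, direction=-1)
        if not cur.any():
            break
        area = float(cur.sum())
        circ = circularity(cur)
        if circ < trk.circularity_threshold and area > trk.area_increase_factor * area_ref:
            break  # morphology changed: the cell was still flat here
        area_ref = min(area_ref, area)
        track.masks[t] = cur
        start = t
        prev = cur
    return track, start


def _components(mask: np.ndarray, min_area: float) -> int:
    """Count daughter-sized components, ignoring hairline bridges.

    A binary opening by a radius-2 disk first removes bridges up to ~4 px
    wide: the level set pinches slowly through the low-velocity gap between
    separating daughters, and a lingering thin bridge must not hide an
    actual split.  Daughter-sized components easily survive the opening.
    """
    rr, cc = np.ogrid[-2:3, -2:3]
    opened = ndimage.binary_opening(mask, structure=rr * rr + cc * cc <= 4)
    labels, n = ndimage.label(opened, structure=np.ones((3, 3)))
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return int((np.asarray(sizes) >= min_area).sum())


def _daughter_count(mask: np.ndarray, min_area: float) -> int:
    """Number of daughter lobes in a tracked mask.

    Separate components count directly.  A single component may still be a
    dumbbell or rosette whose neck the level set has not pinched through
    yet (the vacated gap between separating daughters carries temporal
    signal for a few frames); in that case the lobes are counted as
    well-separated strong peaks of the mask's Euclidean distance
    transform — one inscribed disk of radius >= 3 px per daughter.
    """
    ncc = _components(mask, min_area)
    if ncc != 1:
        return ncc
    edt = ndimage.distance_transform_edt(mask)
    edt = ndimage.gaussian_filter(edt, 1.0)
    peaks = peak_local_max(edt, min_distance=7, threshold_abs=3.0,
                           exclude_border=False)
    return max(1, len(peaks))


def _count_daughter_circles(seq: FrameSequence, t: int, mask: np.ndarray,
                            detection: CircleCandidate, trk: TrackingParams) -> int:
    """Count daughter-sized circles inside a tracked mask at frame ``t``.

    The level set can keep a near-convex hull around symmetrically
    separating daughters for several frames (the vacated gaps still carry
    temporal signal), so component or lobe counts under-estimate the
    daughter number.  Daughter cells keep their bright rims, so a circular
    Hough transform restricted to daughter radii (0.4-0.9 of the parent
    detection) inside the mask counts them directly.
    """
    r = max(detection.radius, 6.0)
    params = DetectionParams(radius_min=max(3.0, 0.4 * r),
                             radius_max=max(4.0, 0.9 * r),
                             peak_threshold=0.4, max_candidates_per_frame=6)
    region = extend_contour(mask, 2)
    count = 0
    for c in find_circles(seq[t], params, frame_index=t):
        rr, cc = int(round(c.center_row)), int(round(c.center_col))
        if 0 <= rr < region.shape[0] and 0 <= cc < region.shape[1] and region[rr, cc]:
            count += 1
    return count


def _best_daughter_count(seq: FrameSequence, track: CellTrack,
                         morph_break: int | None, current: int,
                         detection: CircleCandidate, trk: TrackingParams) -> int:
    """Daughter-circle count maximised over the frames just after the break.

    Daughter rims are brightest right after division and fade as the
    daughters re-flatten, while the component split of the tracked mask
    may only settle a few frames later — so the circles are counted where
    they are visible, not where the split is confirmed.
    """
    start = current if morph_break is None else morph_break + 1
    best = 0
    for t in range(start, min(start + 3, current + 1)):
        mask = track.masks.get(t)
        if mask is None or not mask.any():
            continue
        best = max(best, _count_daughter_circles(seq, t, mask, detection, trk))
    if best == 0 and track.masks.get(current) is not None and track.masks[current].any():
        best = _count_daughter_circles(seq, current, track.masks[current], detection, trk)
    return best


def track_forwards(seq: FrameSequence, detection: CircleCandidate,
                   seg: SegmentationParams, trk: TrackingParams):
    """Propagate the contour forwards until the cell fate is decided.

    Returns ``(CellTrack, end_frame, fate)``.  Topology preservation is
    disabled so that the contour may split into daughter components.
    """
    trk.validate()
    t0 = detection.frame_index
    if not (0 <= t0 < len(seq)):
        raise ValueError("detection frame outside the sequence")
    mask, params = _segment_detection(seq, detection, seg, trk, direction=+1)
    track = CellTrack(masks={t0: mask}, direction="forwards")
    area0 = float(mask.sum())
    prev = mask
    split_frame: int | None = None
    morph_break: int | None = None
    shrink_frame: int | None = None
    persist = 0
    attempted = False
    end = t0
    last = min(t0 + trk.max_track_frames, len(seq) - 1)
    for t in range(t0 + 1, last + 1):
        phi0 = signed_distance_from_mask(extend_contour(prev, trk.dilation_radius))
        cur = _segment_frame(seq, t, phi0, params, trk, direction=+1)
        area = float(cur.sum())
        # the contour may need a couple of frames to collapse fully onto
        # apoptotic debris: date the event at the first sharp shrink
        if area < 0.5 * area0:
            if shrink_frame is None:
                shrink_frame = t
        else:
            shrink_frame = None
        if area < trk.min_component_area:
            bright = False
            if area > 0:
                frame = seq[t]
                thresh = np.quantile(frame, trk.apoptosis_intensity_quantile)
                bright = float(frame[cur].mean()) > thresh
            if bright or area == 0:
                track.masks[t] = cur
                # a collapse right at the morphology break is apoptosis; a
                # lost contour several frames into a division is not
                if morph_break is None or t <= morph_break + 1:
                    return track, shrink_frame if shrink_frame is not None else t, "apoptosis"
                break
        # the end of the round mitotic phase shows first as a morphology
        # break (the single mask deforms into a dumbbell / rosette while
        # the separating daughters still smear the velocity image); the
        # component count that confirms the division settles a few frames
        # later, so the break frame, not the split frame, dates the event
        if morph_break is None and cur.any() and circularity(cur) < trk.circularity_threshold:
            morph_break = t
        ncomp = _daughter_count(cur, trk.min_component_area)
        if ncomp >= 2:
            if split_frame is None:
                split_frame = t
            persist += 1
            track.masks[t] = cur
            if persist >= trk.split_persistence:
                n_d = max(ncomp, _best_daughter_count(seq, track, morph_break, t,
                                                      detection, trk))
                fate = "regular_division" if n_d == 2 else "abnormal_division"
                end = split_frame if morph_break is None else min(morph_break, split_frame)
                return track, end, fate
        else:
            if split_frame is not None:
                attempted = True  # transient pinch that re-merged
            split_frame = None
            persist = 0
            track.masks[t] = cur
        prev = cur if cur.any() else prev
        end = t
    if split_frame is not None and persist >= 1:
        ncomp = _daughter_count(track.masks[end], trk.min_component_area)
        n_d = max(ncomp, _best_daughter_count(seq, track, morph_break, end, detection, trk))
        fate = "regular_division" if n_d == 2 else "abnormal_division"
        return track, (split_frame if morph_break is None else min(morph_break, split_frame)), fate
    if attempted or (morph_break is not None and end - morph_break >= 2):
        # the mask deformed and stayed (or became) a single blob: a
        # division attempt that did not resolve into separated daughters;
        # the circle detector decides how many daughters are inside it
        n_d = _best_daughter_count(seq, track, morph_break, end, detection, trk)
        fate = "regular_division" if n_d == 2 else "abnormal_division"
        return track, morph_break if morph_break is not None else end, fate
    return track, end, "no_division"


# ---------------------------------------------------------------------------
# whole-sequence analysis
# ---------------------------------------------------------------------------

def _detect_all(seq: FrameSequence, det: DetectionParams) -> list[list[CircleCandidate]]:
    return [find_circles(seq[t], det, frame_index=t) for t in range(len(seq))]


def _cluster_candidates(cands: list[CircleCandidate],
                        spatial: float) -> list[CircleCandidate]:
    """One candidate per cell: greedily absorb detections of the same cell.

    Two detections belong to one cell when their centres lie within
    ``spatial`` px and their frames within 4 (a slowly drifting mitotic
    cell is re-detected in several nearby frames; a short window avoids
    absorbing a pre-division parent into its own daughters' detections).
    """
    out: list[CircleCandidate] = []
    for c in sorted(cands, key=lambda c: (-c.significance, c.frame_index,
                                          c.center_row, c.center_col)):
        absorbed = False
        for kept in out:
            d2 = (c.center_row - kept.center_row) ** 2 + (c.center_col - kept.center_col) ** 2
            if d2 < spatial**2 and abs(c.frame_index - kept.frame_index) <= 4:
                absorbed = True
                break
        if not absorbed:
            out.append(c)
    out.sort(key=lambda c: (c.frame_index, -c.significance))
    return out


def _tracks_overlap(a: MitoticEvent, b: MitoticEvent) -> bool:
    """True when two events segment the same pixels in some shared frame."""
    shared = set(a.masks) & set(b.masks)
    for t in shared:
        ma, mb = a.masks[t], b.masks[t]
        inter = float(np.logical_and(ma, mb).sum())
        denom = min(ma.sum(), mb.sum())
        if denom > 0 and inter / denom > 0.3:
            return True
    return False


def _merge_duplicate_events(events: list[MitoticEvent],
                            spatial: float) -> list[MitoticEvent]:
    """Drop events that re-track the same cell from a later detection.

    Two events are duplicates when their frame ranges overlap and their
    masks cover the same pixels in a shared frame (a daughter cell or
    debris re-detected after division backtracks over its parent); the
    event whose detection was more significant wins.
    """
    # among overlapping tracks the earliest detection represents the cell:
    # later detections re-track the same (still round) cell or its
    # daughters/debris after the event concluded
    order = sorted(events, key=lambda e: (e.detection_frame,
                                          -(e.detection.significance if e.detection else 0)))
    kept: list[MitoticEvent] = []
    for ev in order:
        dup = any(_tracks_overlap(ev, other) for other in kept)
        if not dup and ev.detection is not None:
            # a detection shortly after another event's conclusion, near its
            # final position, is a daughter cell or debris of that event
            for other in kept:
                if other.fate == "no_division" or not other.masks:
                    continue
                last = max(other.masks)
                ref = other.masks[last]
                if not ref.any():
                    continue
                if other.end_frame - 1 <= ev.detection_frame <= other.end_frame + 10:
                    zr, zc = ndimage.center_of_mass(ref)
                    d2 = (ev.detection.center_row - zr) ** 2 + (ev.detection.center_col - zc) ** 2
                    if d2 < (3.0 * spatial) ** 2:
                        dup = True
                        break
        if not dup:
            kept.append(ev)
    kept.sort(key=lambda e: (e.detection_frame, e.cell_id))
    for i, ev in enumerate(kept):
        ev.cell_id = i
    return kept


def summarise_events(events: list[MitoticEvent],
                     frame_interval_min: float) -> dict:
    """Event count, average mitosis duration (min) and fate distribution."""
    fates = {label: 0 for label in FATE_LABELS}
    for ev in events:
        fates[ev.fate] += 1
    amd = float(np.mean([ev.duration_min for ev in events])) if events else None
    return {
        "n_events": len(events),
        "amd_min": amd,
        "fate_counts": fates,
        "frame_interval_min": frame_interval_min,
    }


def analyse_sequence(seq: FrameSequence, det: DetectionParams,
                     seg: SegmentationParams, trk: TrackingParams):
    """Full pipeline on one sequence; returns ``(events, summary)``.

    Detection failures on individual candidates are logged and skipped so
    one degenerate track never aborts a batch.  Candidate significances are
    additionally gated at ``peak_threshold`` times the strongest detection
    in the whole sequence, which suppresses weak circle-like responses of
    flat cells in frames that contain no mitotic cell.
    """
    per_frame = _detect_all(seq, det)
    all_cands = [c for frame in per_frame for c in frame]
    if all_cands:
        smax = max(c.significance for c in all_cands)
        per_frame = [[c for c in frame if c.significance >= det.peak_threshold * smax]
                     for frame in per_frame]
    selected = select_mitotic_candidates(per_frame, det)
    # a cell that stays round for many frames is re-detected every other
    # frame (the pairwise rule only spans consecutive frames); track each
    # cell once, from its most significant detection
    selected = _cluster_candidates(selected, det.dedup_spatial)
    # track in significance order so an established event can veto later
    # detections of its own daughters or debris
    selected = sorted(selected, key=lambda c: (-c.significance, c.frame_index,
                                               c.center_row, c.center_col))
    events: list[MitoticEvent] = []
    zones: list[tuple[int, int, float, float, float]] = []
    for i, cand in enumerate(selected):
        suppressed = False
        for (t_lo, t_hi, zr, zc, zrad) in zones:
            if (t_lo <= cand.frame_index <= t_hi
                    and (cand.center_row - zr) ** 2 + (cand.center_col - zc) ** 2 < zrad**2):
                suppressed = True
                break
        if suppressed:
            continue
        try:
            back, start = track_backwards(seq, cand, seg, trk)
            fwd, end, fate = track_forwards(seq, cand, seg, trk)
        except (DivergenceError, ValueError) as exc:
            log.warning("skipping candidate at frame %d (%.1f, %.1f): %s",
                        cand.frame_index, cand.center_row, cand.center_col, exc)
            continue
        masks = {**back.masks, **fwd.masks}
        masks = {t: m for t, m in masks.items() if start <= t <= end}
        events.append(MitoticEvent(
            cell_id=i,
            detection_frame=cand.frame_index,
            start_frame=start,
            end_frame=end,
            fate=fate,
            duration_min=(end - start) * seq.frame_interval_min,
            masks=masks,
            detection=cand,
        ))
        if fate in ("regular_division", "abnormal_division", "apoptosis"):
            # daughter cells / apoptotic debris of a concluded event are
            # circle-like and re-trigger the detector for a while
            last = max(masks)
            ref = masks[last] if masks[last].any() else None
            if ref is not None:
                zr, zc = ndimage.center_of_mass(ref)
                zones.append((end - 1, end + 10, float(zr), float(zc),
                              3.0 * max(cand.radius, det.radius_max)))
    events = _merge_duplicate_events(events, det.dedup_spatial)
    events.sort(key=lambda e: (e.detection_frame, e.cell_id))
    for i, ev in enumerate(events):
        ev.cell_id = i
    return events, summarise_events(events, seq.frame_interval_min)
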