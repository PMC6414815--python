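"""Synthetic validation harness: run the pipeline against scripted truth.

Drives :func:`mitotrack.tracking.analyse_sequence` over batteries of
generated scenes and scores the recovered events against the generator's
ground truth — timing error in frames, fate agreement, and per-frame mask
overlap.  Both the test suite and the reproduction script use this module,
so the numbers they report come from one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PresetConfig, builtin_preset
from .metrics import jaccard
from .synth import generate_sequence, random_battery_scene
from .tracking import analyse_sequence

__all__ = ["BatteryResult", "score_scene", "run_battery"]


@dataclass
class BatteryResult:
    """Aggregated scores of a multi-scene tracking battery."""

    n_truth: int = 0
    n_matched: int = 0
    start_within_1: int = 0
    end_within_1: int = 0
    fate_correct: int = 0
    extra_events: int = 0
    mask_jscs: list[float] = field(default_factory=list)
    durations_min: list[tuple[float, float]] = field(default_factory=list)  # (found, true)

    @property
    def start_accuracy(self) -> float:
        return self.start_within_1 / max(self.n_truth, 1)

    @property
    def end_accuracy(self) -> float:
        return self.end_within_1 / max(self.n_truth, 1)

    @property
    def fate_accuracy(self) -> float:
        return self.fate_correct / max(self.n_truth, 1)

    @property
    def mean_mask_jsc(self) -> float:
        return float(np.mean(self.mask_jscs)) if self.mask_jscs else 0.0


def score_scene(seq, truth, events, result: BatteryResult) -> None:
    """Score one scene's recovered events against its ground truth."""
    used = set()
    for gt in truth.events:
        result.n_truth += 1
        best, best_err = None, None
        for i, ev in enumerate(events):
            if i in used:
                continue
            err = abs(ev.start_frame - gt.start_frame) + abs(ev.end_frame - gt.end_frame)
            if best_err is None or err < best_err:
                best, best_err = i, err
        if best is None:
            continue
        used.add(best)
        ev = events[best]
        result.n_matched += 1
        result.start_within_1 += abs(ev.start_frame - gt.start_frame) <= 1
        result.end_within_1 += abs(ev.end_frame - gt.end_frame) <= 1
        result.fate_correct += ev.fate == gt.fate
        result.durations_min.append((ev.duration_min, gt.duration_min))
        for t, mask in ev.masks.items():
            gt_mask = truth.mask(gt.cell_id, t)
            if mask.any() and gt_mask.any():
                result.mask_jscs.append(jaccard(mask, gt_mask))
    result.extra_events += max(0, len(events) - len(truth.events))


def run_battery(n_scenes: int = 20, base_seed: int = 0,
                config: PresetConfig | None = None) -> BatteryResult:
    """Analyse ``n_scenes`` scripted single-mitosis scenes and score them.

    Scene ``i`` uses seed ``base_seed + i`` and cycles through the four
    fate classes, so every battery covers bipolar and tripolar division,
    apoptosis and absence of division.
    """
    cfg = config or builtin_preset()
    result = BatteryResult()
    for i in range(n_scenes):
        scene = random_battery_scene(base_seed + i)
        seq, truth = generate_sequence(scene)
        events, _ = analyse_sequence(seq, cfg.detection, cfg.segmentation, cfg.tracking)
        score_scene(seq, truth, events, result)
    return result
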