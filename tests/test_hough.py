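"""Circle detection: edge maps, accumulator voting, peaks, de-duplication."""

import numpy as np
import pytest

from mitotrack.hough import (
    CircleCandidate,
    DetectionParams,
    cht_accumulate,
    edge_map,
    find_circles,
    select_mitotic_candidates,
)


def disk_image(shape, circles, fg=0.8, bg=0.2, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, bg)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for (r0, c0, rad) in circles:
        img = np.where((rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2, fg, img)
    return img + rng.normal(0, noise, shape)


class TestEdgeMap:
    def test_constant_image_empty(self):
        assert not edge_map(np.full((16, 16), 0.5), 0.3).any()

    def test_disk_edge_forms_ring(self):
        img = disk_image((64, 64), [(32, 32, 15)], noise=0.0)
        edges = edge_map(img, 0.3)
        rr, cc = np.nonzero(edges)
        dist = np.hypot(rr - 32, cc - 32)
        assert edges.any()
        assert np.all(np.abs(dist - 15) <= 1.5)

    def test_threshold_monotone(self, rng):
        img = rng.random((32, 32))
        low = edge_map(img, 0.2)
        high = edge_map(img, 0.6)
        assert not (high & ~low).any()

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            edge_map(np.zeros((4, 4)), 1.5)


class TestAccumulator:
    def test_single_edge_pixel_votes_on_two_rays(self):
        mask = np.zeros((41, 41), bool)
        mask[20, 20] = True
        grad_r = np.zeros((41, 41))
        grad_c = np.zeros((41, 41))
        grad_c[20, 20] = 1.0  # gradient along columns
        acc = cht_accumulate(mask, grad_r, grad_c, (5, 10), 6)
        votes = np.argwhere(acc.sum(axis=2) > 0)
        assert all(r == 20 for r, c in votes)
        assert set(abs(c - 20) for r, c in votes) <= set(range(5, 11))

    def test_ring_peak_at_centre_and_radius(self):
        img = disk_image((64, 64), [(30, 34, 12)], noise=0.0)
        grad_r, grad_c = np.gradient(img)
        edges = edge_map(img, 0.3)
        acc = cht_accumulate(edges, grad_r, grad_c, (8, 16), 9)
        r, c, k = np.unravel_index(np.argmax(acc), acc.shape)
        radii = np.linspace(8, 16, 9)
        assert abs(r - 30) <= 1 and abs(c - 34) <= 1
        assert abs(radii[k] - 12) <= 1

    def test_no_edges_zero_accumulator(self):
        acc = cht_accumulate(np.zeros((16, 16), bool), np.zeros((16, 16)),
                             np.zeros((16, 16)), (4, 8), 5)
        assert not acc.any()

    def test_vote_mass_bound(self, rng):
        mask = rng.random((32, 32)) < 0.1
        grad_r = rng.standard_normal((32, 32))
        grad_c = rng.standard_normal((32, 32))
        n_radii = 5
        acc = cht_accumulate(mask, grad_r, grad_c, (4, 8), n_radii)
        radii = np.linspace(4, 8, n_radii)
        raw_mass = sum((acc[:, :, k] * 2 * np.pi * radii[k]).sum() for k in range(n_radii))
        assert acc.min() >= 0
        assert raw_mass <= mask.sum() * 2 * n_radii + 1e-9


class TestFindCircles:
    PARAMS = DetectionParams(radius_min=6, radius_max=22,
                             peak_threshold=0.5, max_candidates_per_frame=8)

    def test_single_disk_recovered(self):
        img = disk_image((128, 128), [(40, 60, 12)], seed=1)
        cands = find_circles(img, self.PARAMS)
        assert len(cands) == 1
        c = cands[0]
        assert np.hypot(c.center_row - 40, c.center_col - 60) <= 2
        assert abs(c.radius - 12) <= 2

    def test_overlapping_pair_resolved(self):
        img = disk_image((128, 128), [(60, 50, 12), (60, 68, 12)], seed=3)
        cands = find_circles(img, self.PARAMS)
        assert len(cands) == 2
        cols = sorted(c.center_col for c in cands)
        assert abs(cols[0] - 50) <= 2 and abs(cols[1] - 68) <= 2

    def test_pure_noise_high_threshold_empty(self, rng):
        img = 0.5 + rng.normal(0, 0.02, (96, 96))
        params = DetectionParams(radius_min=6, radius_max=22, peak_threshold=0.9)
        assert find_circles(img, params) == []

    def test_recall_battery(self):
        # multiple disks of assorted radii, all recovered within 2 px
        for seed in range(5):
            rng = np.random.default_rng(seed)
            k = int(rng.integers(1, 6))
            circles = []
            while len(circles) < k:
                rad = rng.uniform(8, 20)
                r0 = rng.uniform(rad + 4, 124 - rad)
                c0 = rng.uniform(rad + 4, 124 - rad)
                if all(np.hypot(r0 - x, c0 - y) > rad + q + 4 for x, y, q in circles):
                    circles.append((r0, c0, rad))
            img = disk_image((128, 128), circles, seed=seed + 100)
            cands = find_circles(img, self.PARAMS)
            for (r0, c0, rad) in circles:
                best = min(cands, key=lambda c: np.hypot(c.center_row - r0, c.center_col - c0))
                assert np.hypot(best.center_row - r0, best.center_col - c0) <= 2
                assert abs(best.radius - rad) <= 2


class TestSelection:
    def make(self, frame, row, col, sig):
        return CircleCandidate(row, col, 10.0, sig, frame)

    PARAMS = DetectionParams(radius_min=6, radius_max=14,
                             dedup_spatial=10, dedup_temporal=10)

    def test_same_frame_close_pair_keeps_stronger(self):
        cands = [[self.make(0, 20, 20, 0.9), self.make(0, 22, 22, 0.5)]]
        kept = select_mitotic_candidates(cands, self.PARAMS)
        assert len(kept) == 1 and kept[0].significance == 0.9

    def test_consecutive_frames_deduplicated(self):
        cands = [[self.make(0, 20, 20, 0.9)], [self.make(1, 20, 20, 0.8)]]
        kept = select_mitotic_candidates(cands, self.PARAMS)
        assert len(kept) == 1

    def test_two_frame_gap_both_kept(self):
        cands = [[self.make(0, 20, 20, 0.9)], [], [self.make(2, 20, 20, 0.8)]]
        kept = select_mitotic_candidates(cands, self.PARAMS)
        assert len(kept) == 2

    def test_result_is_antichain(self, rng):
        frames = [[self.make(t, float(rng.uniform(0, 60)), float(rng.uniform(0, 60)),
                             float(rng.random())) for _ in range(6)] for t in range(4)]
        kept = select_mitotic_candidates(frames, self.PARAMS)
        for a in kept:
            for b in kept:
                if a is b:
                    continue
                d = np.hypot(a.center_row - b.center_row, a.center_col - b.center_col)
                if a.frame_index == b.frame_index:
                    assert d >= self.PARAMS.dedup_spatial
                elif abs(a.frame_index - b.frame_index) == 1:
                    assert d >= self.PARAMS.dedup_temporal


class TestParams:
    def test_invalid_radius_order(self):
        with pytest.raises(ValueError):
            DetectionParams(radius_min=10, radius_max=5)

    def test_dedup_defaults_to_radius_max(self):
        p = DetectionParams(radius_min=5, radius_max=17)
        assert p.dedup_spatial == 17 and p.dedup_temporal == 17
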