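"""Level-set primitives, energies, segmenters and digital topology."""

import numpy as np
import pytest

from mitotrack.levelset import (
    SegmentationParams,
    chan_vese,
    dirac_regularized,
    evolve_tracking,
    geodesic_active_contours,
    heaviside_sharp,
    is_simple_point,
    region_means,
    signed_distance_from_mask,
    tracking_energy,
)
from mitotrack.metrics import jaccard

from conftest import render_disk


class TestSignedDistance:
    def test_disk_centre_depth(self):
        mask = render_disk(10)
        phi = signed_distance_from_mask(mask)
        centre = (mask.shape[0] // 2, mask.shape[1] // 2)
        assert phi[centre] == pytest.approx(-10, abs=0.6)

    def test_sign_convention(self):
        mask = render_disk(6)
        phi = signed_distance_from_mask(mask)
        assert np.all(phi[mask] < 0)
        assert np.all(phi[~mask] > 0)

    def test_zero_level_on_boundary(self):
        mask = render_disk(8)
        phi = signed_distance_from_mask(mask)
        # every pixel adjacent to the contour is within one pixel of it
        near = np.abs(phi) <= 1.0
        assert near.any()
        assert np.all(np.abs(phi[near]) <= 1.0)

    def test_eikonal_in_band(self):
        phi = signed_distance_from_mask(render_disk(12))
        gr, gc = np.gradient(phi)
        gm = np.hypot(gr, gc)
        band = np.abs(phi) <= 6
        # away from the ridge the distance field has unit gradient
        assert np.median(np.abs(gm[band] - 1.0)) <= 0.2

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            signed_distance_from_mask(np.zeros((5, 5), bool))
        with pytest.raises(ValueError):
            signed_distance_from_mask(np.ones((5, 5), bool))


class TestHeavisideDirac:
    @pytest.mark.parametrize("phi,expected", [(0.0, 0.0), (-2.5, 0.0), (1e-9, 1.0)])
    def test_sharp_heaviside(self, phi, expected):
        assert heaviside_sharp(phi) == expected

    def test_dirac_at_zero(self):
        assert dirac_regularized(0.0, 1.0) == pytest.approx(1 / np.pi)

    def test_dirac_at_eps(self):
        for eps in (0.5, 1.0, 2.0):
            assert dirac_regularized(eps, eps) == pytest.approx(1 / (2 * np.pi * eps))

    def test_dirac_even(self):
        x = np.linspace(-5, 5, 41)
        assert np.allclose(dirac_regularized(x, 1.5), dirac_regularized(-x, 1.5))

    def test_dirac_bad_eps(self):
        with pytest.raises(ValueError):
            dirac_regularized(0.0, 0.0)


class TestRegionMeans:
    def test_piecewise_constant(self):
        mask = render_disk(5)
        phi = signed_distance_from_mask(mask)
        feature = np.where(mask, 10.0, 50.0)
        assert region_means(feature, phi) == (10.0, 50.0)

    def test_constant_feature(self):
        phi = signed_distance_from_mask(render_disk(5))
        assert region_means(np.full(phi.shape, 7.0), phi) == (7.0, 7.0)

    def test_matches_pixel_loop_oracle(self, rng):
        for _ in range(100):
            feature = rng.random((16, 16))
            phi = rng.standard_normal((16, 16))
            if not ((phi <= 0).any() and (phi > 0).any()):
                continue
            c1, c2 = region_means(feature, phi)
            ins, outs = [], []
            for i in range(16):
                for j in range(16):
                    (ins if phi[i, j] <= 0 else outs).append(feature[i, j])
            assert c1 == pytest.approx(np.mean(ins), abs=1e-12)
            assert c2 == pytest.approx(np.mean(outs), abs=1e-12)

    def test_degenerate_partition(self):
        with pytest.raises(ValueError):
            region_means(np.zeros((4, 4)), np.ones((4, 4)))


class TestTrackingEnergy:
    def test_zero_weights_zero_energy(self, rng):
        params = SegmentationParams(lambda1=0, lambda2=0, mu=0, nu=0, omega=0)
        phi = signed_distance_from_mask(render_disk(5))
        feature = rng.random(phi.shape)
        assert tracking_energy(feature, feature, phi, 0.3, 0.7, params) == 0.0

    def test_perfect_two_region_fit(self):
        mask = render_disk(6)
        phi = signed_distance_from_mask(mask)
        feature = np.where(mask, 0.9, 0.1)
        params = SegmentationParams(lambda1=1, lambda2=1, mu=0, nu=0, omega=0)
        assert tracking_energy(feature, feature, phi, 0.9, 0.1, params) == 0.0

    def test_length_quadrature_matches_circumference(self):
        # the delta-quadrature of |grad H| on a radius-20 disk approximates
        # the circle circumference 2*pi*20
        mask = render_disk(20, shape=(101, 101))
        phi = signed_distance_from_mask(mask)
        params = SegmentationParams(lambda1=0, lambda2=0, mu=1.0, nu=0, omega=0,
                                    eps_heaviside=1.0)
        e = tracking_energy(np.zeros_like(phi), np.zeros_like(phi), phi, 0, 0, params)
        assert e == pytest.approx(2 * np.pi * 20, rel=0.05)

    def test_area_penalty_sign_modes(self):
        mask = render_disk(5)
        phi = signed_distance_from_mask(mask)
        area = float(mask.sum())
        zeros = np.zeros_like(phi)
        below = SegmentationParams(lambda1=0, lambda2=0, mu=0, nu=0,
                                   omega=1.0, t_area=area + 100,
                                   area_penalty_sign="penalise_below")
        printed = SegmentationParams(lambda1=0, lambda2=0, mu=0, nu=0,
                                     omega=1.0, t_area=area - 100,
                                     area_penalty_sign="as_printed")
        assert tracking_energy(zeros, zeros, phi, 0, 0, below) == pytest.approx(0.5 * 100**2)
        assert tracking_energy(zeros, zeros, phi, 0, 0, printed) == pytest.approx(-0.5 * 100**2)


def _moving_disk_pair(shape=(72, 72), radius=12, shift=2, rng=None):
    """Two frames of a textured disk translating on a clean background."""
    rng = rng or np.random.default_rng(7)
    tex = np.zeros(shape)
    tex[:] = 0.08 * np.sin(np.arange(shape[0]))[:, None] * np.cos(np.arange(shape[1]))[None, :]
    def frame(center):
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
        img = np.full(shape, 0.5)
        img[mask] += 0.05 + tex[mask]
        d = np.sqrt((rr - center[0]) ** 2.0 + (cc - center[1]) ** 2.0)
        # bright rim just inside the outline, decaying across the boundary
        img += 0.3 * np.exp(-((d - radius + 2.0) ** 2) / (2 * 0.8**2))
        return img + rng.normal(0, 0.003, shape)
    c = (shape[0] // 2, shape[1] // 2)
    truth = (np.add.outer((np.arange(shape[0]) - c[0]) ** 2,
                          (np.arange(shape[1]) - c[1]) ** 2) <= radius**2)
    return frame(c), frame((c[0], c[1] + shift)), truth


class TestEvolveTracking:
    def test_moving_disk_recovered(self):
        f0, f1, truth = _moving_disk_pair()
        from scipy import ndimage
        init = ndimage.binary_dilation(truth, iterations=3)
        params = SegmentationParams(mu=0.05, eps_grad=0.05, omega=2e-3,
                                    t_area=0.15 * truth.sum())
        phi = evolve_tracking(f0, f1, signed_distance_from_mask(init), params)
        assert jaccard(phi <= 0, truth) >= 0.9

    def test_constant_velocity_curvature_shrink(self):
        # with a featureless frame pair the data term vanishes and the
        # length term drives mean-curvature shrinkage
        frame = np.full((64, 64), 0.5)
        init = render_disk(15, shape=(64, 64))
        areas = []
        for iters in (10, 40, 80, 120):
            params = SegmentationParams(mu=0.5, nu=0, omega=0, max_iters=iters)
            phi = evolve_tracking(frame, frame.copy(), signed_distance_from_mask(init), params)
            areas.append((phi <= 0).sum())
        assert all(b <= a for a, b in zip(areas, areas[1:]))
        assert areas[-1] < init.sum()

    def test_topology_preserved_single_component(self):
        from scipy import ndimage
        f0, f1, truth = _moving_disk_pair()
        init = ndimage.binary_dilation(truth, iterations=3)
        params = SegmentationParams(mu=0.05, eps_grad=0.05, preserve_topology=True)
        phi = evolve_tracking(f0, f1, signed_distance_from_mask(init), params)
        _, n = ndimage.label(phi <= 0, structure=np.ones((3, 3)))
        assert n == 1

    def test_intensity_shift_invariance(self):
        from scipy import ndimage
        f0, f1, truth = _moving_disk_pair()
        init = ndimage.binary_dilation(truth, iterations=3)
        params = SegmentationParams(mu=0.05, eps_grad=0.05)
        phi_a = evolve_tracking(f0, f1, signed_distance_from_mask(init), params)
        phi_b = evolve_tracking(f0 + 0.1, f1 + 0.1, signed_distance_from_mask(init), params)
        assert jaccard(phi_a <= 0, phi_b <= 0) >= 0.99

    def test_energy_non_increasing_between_reinits(self):
        from scipy import ndimage
        f0, f1, truth = _moving_disk_pair()
        init = ndimage.binary_dilation(truth, iterations=3)
        params = SegmentationParams(mu=0.05, eps_grad=0.05)
        log = []
        evolve_tracking(f0, f1, signed_distance_from_mask(init), params, energy_log=log)
        assert len(log) > 5
        e0 = log[0][1]
        for (_, e_prev, _), (_, e_next, reinit) in zip(log, log[1:]):
            if not reinit:
                assert e_next <= e_prev + 1e-6 * abs(e0)


class TestChanVese:
    def test_noisy_two_valued_disk(self, rng):
        truth = render_disk(18, shape=(96, 96))
        img = np.where(truth, 0.2, 0.8) + rng.normal(0, 0.05, (96, 96))
        init = render_disk(30, shape=(96, 96))
        params = SegmentationParams(mu=0.1, nu=0.0, max_iters=200)
        phi = chan_vese(img, signed_distance_from_mask(init), params)
        assert jaccard(phi <= 0, truth) >= 0.95

    def test_stationary_at_perfect_partition(self):
        truth = render_disk(10, shape=(48, 48))
        img = np.where(truth, 0.2, 0.8)
        params = SegmentationParams(mu=0.0, nu=0.0, max_iters=60)
        phi = chan_vese(img, signed_distance_from_mask(truth), params)
        assert np.array_equal(phi <= 0, truth)

    def test_swapped_lambdas_complementary(self, rng):
        truth = render_disk(14, shape=(64, 64))
        img = np.where(truth, 0.15, 0.85) + rng.normal(0, 0.02, (64, 64))
        init = render_disk(22, shape=(64, 64))
        params = SegmentationParams(mu=0.05, nu=0.0)
        phi = chan_vese(img, signed_distance_from_mask(init), params)
        # the model labels the dark disk as the inside region; swapping the
        # image contrast swaps the roles
        phi_sw = chan_vese(1.0 - img, signed_distance_from_mask(init), params)
        assert jaccard(phi <= 0, truth) >= 0.9
        assert jaccard(phi_sw <= 0, truth) >= 0.9


class TestGeodesicActiveContours:
    def test_constant_g_shrinks_monotonically(self):
        const = np.full((80, 80), 0.5)
        init = render_disk(12, shape=(80, 80))
        areas = []
        for iters in (20, 60, 120, 200):
            params = SegmentationParams(max_iters=iters)
            phi = geodesic_active_contours(const, signed_distance_from_mask(init), params)
            areas.append((phi <= 0).sum())
        assert all(b <= a for a, b in zip(areas, areas[1:]))
        assert areas[-1] < 0.5 * init.sum()

    def test_collapse_without_edges(self):
        const = np.full((80, 80), 0.5)
        init = render_disk(12, shape=(80, 80))
        params = SegmentationParams(max_iters=400)
        phi = geodesic_active_contours(const, signed_distance_from_mask(init), params)
        assert (phi <= 0).sum() < 0.05 * init.sum()

    def test_stops_on_strong_edge_ring(self):
        # an 8-bit-scale ring: the edge indicator vanishes on its slopes
        rr, cc = np.ogrid[:96, :96]
        d = np.sqrt((rr - 48.0) ** 2 + (cc - 48.0) ** 2)
        img = 100.0 + 80.0 * np.exp(-((d - 15.0) ** 2) / (2 * 1.5**2))
        init = render_disk(24, shape=(96, 96))
        params = SegmentationParams(max_iters=400)
        phi = geodesic_active_contours(img, signed_distance_from_mask(init), params)
        r_est = np.sqrt((phi <= 0).sum() / np.pi)
        # the front halts where the ring's outer slope begins (g ~ 0),
        # within 2 px of the outer edge of the bright band
        outer_edge = 15.0 + 2 * 1.5
        assert abs(r_est - outer_edge) <= 2.0


def brute_force_simple(patch):
    """Flip-test oracle with hand-rolled component labelling."""
    def components(cells, diag):
        cells = set(cells)
        seen, count = set(), 0
        for cell in cells:
            if cell in seen:
                continue
            count += 1
            stack = [cell]
            seen.add(cell)
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr, dc) == (0, 0):
                            continue
                        if not diag and dr != 0 and dc != 0:
                            continue
                        nb = (r + dr, c + dc)
                        if nb in cells and nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
        return count

    def counts(p):
        fg = [(i, j) for i in range(3) for j in range(3) if p[i][j]]
        bg = [(i, j) for i in range(3) for j in range(3) if not p[i][j]]
        return components(fg, diag=True), components(bg, diag=False)

    flipped = [row[:] for row in patch]
    flipped[1][1] = not flipped[1][1]
    return counts(patch) == counts(flipped)


class TestSimplePoints:
    def test_straight_edge_pixel_is_simple(self):
        mask = np.zeros((6, 6), bool)
        mask[2:, :] = True
        assert is_simple_point(mask, (2, 3))

    def test_isolated_pixel_not_simple(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert not is_simple_point(mask, (2, 2))

    def test_bridge_pixel_not_simple(self):
        mask = np.zeros((3, 5), bool)
        mask[:, :2] = True
        mask[:, 3:] = True
        mask[1, 2] = True
        assert not is_simple_point(mask, (1, 2))

    def test_all_512_configurations_match_oracle(self):
        for code in range(512):
            bits = [(code >> k) & 1 for k in range(9)]
            patch = [[bool(bits[3 * i + j]) for j in range(3)] for i in range(3)]
            mask = np.zeros((5, 5), bool)
            mask[1:4, 1:4] = np.array(patch)
            assert is_simple_point(mask, (2, 2)) == brute_force_simple(patch), code
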