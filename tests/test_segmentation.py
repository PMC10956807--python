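"""Edge map, gradient vector flow and snake segmentation."""

import numpy as np
import pytest

from dermafusion.enhance import enhance
from dermafusion.segmentation import (
    GVFParams,
    SnakeParams,
    VectorField,
    circle_contour,
    contour_to_mask,
    dice,
    edge_map,
    evolve_snake,
    gvf_direct_solve,
    gvf_field,
    segment_roi,
)


def make_disk(radius=30, size=128, lo=60.0, hi=200.0):
    img = np.full((size, size), hi)
    rr, cc = np.mgrid[0:size, 0:size]
    c = size // 2
    img[(rr - c) ** 2 + (cc - c) ** 2 <= radius**2] = lo
    return img


class TestEdgeMap:
    def test_constant_image_gives_zero_map(self):
        f = edge_map(np.full((32, 32), 50.0), sigma=2.0)
        assert np.all(f == 0)

    def test_nonnegative_everywhere(self, rng):
        f = edge_map(rng.random((32, 32)) * 255, sigma=1.5)
        assert f.min() >= 0

    def test_step_edge_peaks_at_the_step(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        f = edge_map(img, sigma=2.0)
        peak_cols = np.argmax(f, axis=1)
        assert np.all((peak_cols >= 15) & (peak_cols <= 16))
        # decays with distance from the step
        mid = f[16]
        assert mid[15] > mid[13] > mid[11] > mid[9]

    def test_rotation_equivariance_on_disk(self):
        img = make_disk()
        f = edge_map(img, sigma=2.0)
        f_rot = edge_map(np.rot90(img), sigma=2.0)
        np.testing.assert_allclose(np.rot90(f), f_rot, atol=1e-8)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            edge_map(np.zeros((8, 8)), sigma=0.0)


class TestGVF:
    def test_zero_edge_map_gives_zero_field(self):
        field = gvf_field(np.zeros((16, 16)), GVFParams(max_iter=50))
        assert np.all(field.u == 0) and np.all(field.v == 0)

    @pytest.mark.parametrize("shape", [(8, 8), (12, 10)])
    def test_iterative_solution_matches_direct_sparse_solve(self, shape):
        """On small grids the fixed point must agree with an exact
        linear solve of the same discretized stationarity system."""
        f = np.zeros(shape)
        f[shape[0] // 2, shape[1] // 2] = 1.0
        params = GVFParams(mu=0.2, max_iter=30000, tol=1e-12)
        it = gvf_field(f, params)
        direct = gvf_direct_solve(f, mu=0.2)
        assert np.abs(it.u - direct.u).max() <= 1e-4
        assert np.abs(it.v - direct.v).max() <= 1e-4

    def test_field_points_toward_isolated_edge(self):
        f = np.zeros((32, 32))
        f[16, 16] = 1.0
        field = gvf_field(f, GVFParams(max_iter=2000, tol=1e-10))
        rr, cc = np.mgrid[0:32, 0:32]
        d2 = (rr - 16.0) ** 2 + (cc - 16.0) ** 2
        near = (d2 > 0.5) & (d2 <= 25.0)
        to_edge = np.stack([16.0 - rr, 16.0 - cc], axis=-1)
        # v is the row-direction force, u the column-direction force
        dot = field.v * to_edge[..., 0] + field.u * to_edge[..., 1]
        assert np.all(dot[near] > 0)

    def test_residual_reported_when_not_converged(self):
        f = np.zeros((16, 16))
        f[8, 8] = 1.0
        field = gvf_field(f, GVFParams(max_iter=3, tol=0.0))
        assert field.n_iter == 3 and field.residual > 0

    def test_nonfinite_edge_map_rejected(self):
        f = np.zeros((8, 8))
        f[2, 2] = np.nan
        with pytest.raises(ValueError):
            gvf_field(f)

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            GVFParams(mu=0.5, dt=1.0)


class TestSnake:
    def test_pure_tension_shrinks_perimeter(self):
        field = VectorField(np.zeros((64, 64)), np.zeros((64, 64)))
        params = SnakeParams(alpha=0.5, beta=0.0, kappa=0.0, iterations=1)
        pts = circle_contour((32, 32), 20, n_points=60)

        def perimeter(c):
            closed = np.vstack([c, c[:1]])
            return np.sqrt((np.diff(closed, axis=0) ** 2).sum(1)).sum()

        perims = [perimeter(pts)]
        for _ in range(5):
            pts = evolve_snake(field, pts, params)
            perims.append(perimeter(pts))
        assert all(b < a for a, b in zip(perims, perims[1:]))

    def test_snake_locks_onto_disk_boundary(self):
        img = make_disk(radius=30)
        field = gvf_field(edge_map(img, sigma=2.0))
        final = evolve_snake(field, circle_contour((64, 64), 55))
        r = np.sqrt(((final - 64.0) ** 2).sum(axis=1))
        assert np.abs(r - 30.0).mean() <= 2.0

    def test_deterministic(self):
        img = make_disk(radius=25)
        field = gvf_field(edge_map(img, sigma=2.0))
        a = evolve_snake(field, circle_contour((64, 64), 50))
        b = evolve_snake(field, circle_contour((64, 64), 50))
        np.testing.assert_array_equal(a, b)

    def test_too_few_points_rejected(self):
        field = VectorField(np.zeros((16, 16)), np.zeros((16, 16)))
        with pytest.raises(ValueError):
            evolve_snake(field, np.array([[1.0, 1.0], [2.0, 2.0]]))


class TestSegmentROI:
    def test_dice_on_clean_lesion(self, clean_lesion):
        image, truth, _ = clean_lesion
        mask, _, _ = segment_roi(image, sigma=2.0)
        assert dice(mask, truth) >= 0.90

    def test_dice_on_noisy_lesion_after_enhancement(self, noisy_lesion):
        image, truth, _ = noisy_lesion
        mask, _, _ = segment_roi(enhance(image), sigma=2.0)
        assert dice(mask, truth) >= 0.80

    def test_roi_zero_outside_mask_and_bbox_tight(self, clean_lesion):
        image, _, _ = clean_lesion
        mask, roi, (r0, c0, r1, c1) = segment_roi(image, sigma=2.0)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        assert (r0, r1) == (rows[0], rows[-1] + 1)
        assert (c0, c1) == (cols[0], cols[-1] + 1)
        crop_mask = mask[r0:r1, c0:c1].astype(bool)
        assert np.all(roi[~crop_mask] == 0)

    def test_mask_is_binary(self, clean_lesion):
        image, _, _ = clean_lesion
        mask, _, _ = segment_roi(image, sigma=2.0)
        assert set(np.unique(mask)) <= {0, 1}


class TestDice:
    def test_identical_masks_give_one(self, rng):
        m = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        assert dice(m, m) == 1.0

    def test_symmetric(self, rng):
        a = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        b = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        assert dice(a, b) == dice(b, a)

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0, 0] = 1
        b[7, 7] = 1
        assert dice(a, b) == 0.0

    def test_contour_rasterization_matches_known_polygon(self):
        sq = np.array([[2.0, 2.0], [2.0, 6.0], [6.0, 6.0], [6.0, 2.0]])
        mask = contour_to_mask(sq, (10, 10))
        assert mask.sum() > 0
        assert mask[4, 4] == 1 and mask[0, 0] == 0
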