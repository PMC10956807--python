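"""Synthetic lesion-image and feature-blob generators."""

import numpy as np
import pytest

from dermafusion.matrix import read_matrix, write_matrix
from dermafusion.synthetic import (
    LesionSpec,
    default_class_specs,
    generate_class_dataset,
    generate_feature_matrix,
    generate_lesion_image,
    write_dataset,
)


class TestLesionImage:
    def test_exact_ellipse_area_when_regular(self, clean_lesion):
        _, mask, spec = clean_lesion
        a, b = spec.axes
        expected = np.pi * a * b
        assert abs(mask.sum() - expected) / expected < 0.01

    def test_determinism_byte_identical(self):
        spec = LesionSpec(center=(60, 60), axes=(30, 25), noise_sigma=7.0)
        img1, m1 = generate_lesion_image(spec, (128, 128), seed=5)
        img2, m2 = generate_lesion_image(spec, (128, 128), seed=5)
        assert np.array_equal(img1, img2) and np.array_equal(m1, m2)

    def test_different_seed_changes_noise(self):
        spec = LesionSpec(center=(60, 60), axes=(30, 25), noise_sigma=7.0)
        img1, _ = generate_lesion_image(spec, (128, 128), seed=5)
        img2, _ = generate_lesion_image(spec, (128, 128), seed=6)
        assert not np.array_equal(img1, img2)

    def test_mean_color_inside_mask_matches_spec(self, clean_lesion):
        image, mask, spec = clean_lesion
        inside = image[mask.astype(bool)].mean(axis=0)
        assert np.all(np.abs(inside - np.array(spec.lesion_color)) <= 2.0)

    def test_skin_color_outside_mask(self, clean_lesion):
        image, mask, spec = clean_lesion
        outside = image[~mask.astype(bool)].mean(axis=0)
        assert np.all(np.abs(outside - np.array(spec.skin_color)) <= 10.0)

    def test_lesion_out_of_frame_rejected(self):
        spec = LesionSpec(center=(10, 10), axes=(30, 25))
        with pytest.raises(ValueError, match="does not fit"):
            generate_lesion_image(spec, (64, 64), seed=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"axes": (0, 10)},
            {"lesion_color": (300, 0, 0)},
            {"border_irregularity": 1.5},
            {"noise_sigma": -1.0},
            {"hair_count": -1},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LesionSpec(**kwargs)

    def test_irregular_border_stays_within_amplitude(self):
        spec = LesionSpec(
            center=(64, 64), axes=(30, 30), border_irregularity=0.2
        )
        _, mask = generate_lesion_image(spec, (160, 160), seed=3)
        rr, cc = np.nonzero(mask)
        r = np.sqrt((rr - 64.0) ** 2 + (cc - 64.0) ** 2)
        assert r.max() <= 30 * 1.2 + 1.5  # half-pixel rasterization slack
        # and it is genuinely non-elliptical: boundary radius varies
        spec0 = LesionSpec(center=(64, 64), axes=(30, 30))
        _, mask0 = generate_lesion_image(spec0, (160, 160), seed=3)
        assert mask.sum() != mask0.sum() or not np.array_equal(mask, mask0)

    def test_hair_strokes_darken_image(self):
        base = LesionSpec(center=(64, 64), axes=(30, 25))
        hairy = LesionSpec(center=(64, 64), axes=(30, 25), hair_count=5)
        img0, _ = generate_lesion_image(base, (128, 128), seed=9)
        img1, _ = generate_lesion_image(hairy, (128, 128), seed=9)
        assert img1.mean() < img0.mean()


class TestClassDataset:
    def test_empty_when_n_per_class_zero(self):
        specs, names = default_class_specs((128, 128))
        data = generate_class_dataset(specs, 0, (128, 128), seed=0, class_names=names)
        assert len(data) == 0

    def test_uniform_label_histogram(self):
        specs, names = default_class_specs((96, 96))
        data = generate_class_dataset(specs, 5, (96, 96), seed=0, class_names=names)
        assert len(data) == 40
        counts = np.bincount(data.labels, minlength=8)
        assert np.all(counts == 5)

    def test_distinct_lesion_colors_stay_separated(self):
        spec_a = LesionSpec(center=(48, 48), axes=(20, 16), lesion_color=(60, 40, 30))
        spec_b = LesionSpec(center=(48, 48), axes=(20, 16), lesion_color=(180, 120, 110))
        data = generate_class_dataset([spec_a, spec_b], 10, (96, 96), seed=2)
        means = []
        for k in (0, 1):
            vals = [
                data.images[i][data.masks[i].astype(bool)].mean(axis=0)
                for i in range(len(data))
                if data.labels[i] == k
            ]
            means.append(np.mean(vals, axis=0))
        assert np.all(np.abs(means[0] - means[1]) >= 40)

    def test_negative_count_rejected(self):
        specs, _ = default_class_specs((96, 96))
        with pytest.raises(ValueError):
            generate_class_dataset(specs, -1, (96, 96), seed=0)

    def test_deterministic_in_seed(self):
        specs, _ = default_class_specs((96, 96), n_classes=2)
        d1 = generate_class_dataset(specs, 3, (96, 96), seed=7)
        d2 = generate_class_dataset(specs, 3, (96, 96), seed=7)
        assert all(np.array_equal(a, b) for a, b in zip(d1.images, d2.images))


class TestFeatureBlobs:
    def test_shape(self):
        fm, y = generate_feature_matrix(10, 7, 3.0, 4, seed=0)
        assert fm.shape == (40, 7) and y.shape == (40,)

    def test_separable_blobs_linearly_classifiable(self):
        from sklearn.linear_model import LogisticRegression

        fm, y = generate_feature_matrix(60, 10, 5.0, 3, seed=1)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        tr, te = idx[:120], idx[120:]
        clf = LogisticRegression(max_iter=1000).fit(fm.values[tr], y[tr])
        assert clf.score(fm.values[te], y[te]) >= 0.99

    def test_zero_separation_means_coincide(self):
        n = 400
        fm, y = generate_feature_matrix(n, 5, 0.0, 2, seed=2)
        mu0 = fm.values[y == 0].mean(axis=0)
        mu1 = fm.values[y == 1].mean(axis=0)
        assert np.all(np.abs(mu0 - mu1) <= 4.0 / np.sqrt(n))

    @pytest.mark.parametrize("p,K", [(0, 2), (3, 0)])
    def test_invalid_dims_rejected(self, p, K):
        with pytest.raises(ValueError):
            generate_feature_matrix(5, p, 1.0, K)


class TestDatasetIO:
    def test_roundtrip_layout_and_manifest(self, tmp_path):
        specs, names = default_class_specs((96, 96), n_classes=2)
        data = generate_class_dataset(specs, 2, (96, 96), seed=0, class_names=names)
        manifest = write_dataset(data, tmp_path / "ds")
        assert manifest.exists()
        pngs = sorted((tmp_path / "ds").rglob("*.png"))
        # 4 images + 4 masks
        assert len(pngs) == 8
        text = manifest.read_text().splitlines()
        assert text[0] == "id,class,split"
        assert len(text) == 5

    def test_matrix_tsv_roundtrip(self, tmp_path):
        fm, _ = generate_feature_matrix(3, 4, 1.0, 2, seed=0)
        path = tmp_path / "m.tsv"
        write_matrix(fm, path)
        back = read_matrix(path)
        assert back.row_ids == fm.row_ids
        np.testing.assert_allclose(back.values, fm.values, rtol=0, atol=0)
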