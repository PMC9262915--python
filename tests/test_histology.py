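import numpy as np
import pandas as pd
import pytest

from hippoquant import histology, synth

PARAMS = histology.QuantParams(intensity_threshold=20.0)


def single_cell_image(radius_um=5.0, pixel_um=0.5, size=128, value=100.0):
    mask = np.zeros((size, size), dtype=np.int32)
    yy, xx = np.ogrid[:size, :size]
    c = size // 2
    mask[(yy - c) ** 2 + (xx - c) ** 2 <= (radius_um / pixel_um) ** 2] = 1
    ch = np.full((size, size), value)
    return histology.AnnotatedImage(channels={"stain": ch}, pixel_size_um=pixel_um,
                                    roi_masks=mask)


class TestRoiIntensity:
    def test_uniform_channel(self):
        img = single_cell_image(value=100.0)
        out = histology.roi_mean_intensity(img, "stain", PARAMS)
        assert out["mean_intensity"].tolist() == [100.0]

    def test_subthreshold_zeroed(self):
        img = single_cell_image(value=5.0)  # below threshold 20
        out = histology.roi_mean_intensity(img, "stain", PARAMS)
        assert out["mean_intensity"].tolist() == [0.0]

    def test_round_trip_with_generator(self, stain_image):
        img, truth = stain_image
        out = histology.roi_mean_intensity(img, "arom", PARAMS)
        merged = out.merge(truth, left_on="roi", right_on="cell")
        rel = np.abs(merged["mean_intensity"] - merged["stain_intensity"]) \
            / merged["stain_intensity"]
        assert rel.max() <= 0.02

    def test_suprathreshold_only_mode(self):
        img = single_cell_image(value=100.0)
        img.channels["stain"][::2, :] = 0.0  # half the pixels below threshold
        full = histology.roi_mean_intensity(img, "stain", PARAMS)
        supra = histology.roi_mean_intensity(img, "stain", PARAMS,
                                             suprathreshold_only=True)
        assert supra["mean_intensity"][0] == 100.0
        assert full["mean_intensity"][0] < 100.0


class TestPerimetricRing:
    def test_annulus_area_close_to_analytic(self):
        img = single_cell_image(radius_um=5.0, pixel_um=0.5)
        ring, clipped = histology.perimetric_ring(img.roi_masks, 1, 3.8, 0.5)
        measured = ring.sum() * 0.5 ** 2
        analytic = np.pi * ((5.0 + 3.8) ** 2 - 5.0 ** 2)
        tol = 2 * np.pi * (5.0 + 3.8) * 0.5  # one pixel-perimeter worth
        assert abs(measured - analytic) <= tol
        assert not clipped
        assert not np.any(ring & (img.roi_masks == 1))  # disjoint from the cell

    def test_zero_width_ring_empty(self):
        img = single_cell_image()
        ring, _ = histology.perimetric_ring(img.roi_masks, 1, 0.0, 0.5)
        assert not ring.any()

    def test_distant_cells_have_disjoint_rings(self, stain_image):
        img, _ = stain_image
        r1, _ = histology.perimetric_ring(img.roi_masks, 1, 3.8, img.pixel_size_um)
        r2, _ = histology.perimetric_ring(img.roi_masks, 2, 3.8, img.pixel_size_um)
        assert not np.any(r1 & r2)

    def test_missing_label_raises(self):
        img = single_cell_image()
        with pytest.raises(ValueError):
            histology.perimetric_ring(img.roi_masks, 99, 3.8, 0.5)

    def test_ring_intensity_recovers_programmed_rings(self, stain_image):
        img, truth = stain_image
        out = histology.ring_mean_intensity(img, "WFA", PARAMS)
        merged = out.merge(truth, left_on="roi", right_on="cell")
        ringed = merged[merged["has_ring"]]["ring_mean_intensity"]
        bare = merged[~merged["has_ring"]]["ring_mean_intensity"]
        if len(ringed) and len(bare):
            assert ringed.min() > bare.max()


class TestDotDensity:
    def test_no_suprathreshold_pixels(self):
        img = single_cell_image(value=5.0)
        out = histology.dot_density(img, "stain", img.roi_masks == 1, PARAMS)
        assert out["n_dots"] == 0 and out["density_per_um2"] == 0.0

    def test_programmed_density_exact(self, stain_image):
        img, truth = stain_image
        for _, row in truth.head(10).iterrows():
            out = histology.dot_density(img, "dots", img.roi_masks == row["cell"],
                                        PARAMS)
            assert out["n_dots"] == row["n_dots"]
            assert out["density_per_um2"] == pytest.approx(
                row["n_dots"] / row["area_um2"])

    def test_threshold_monotonicity(self, stain_image):
        img, _ = stain_image
        roi = img.roi_masks > 0
        densities = [histology.dot_density(
            img, "dots", roi, histology.QuantParams(intensity_threshold=thr)
        )["density_per_um2"] for thr in (20.0, 100.0, 150.0, 250.0)]
        assert all(a >= b for a, b in zip(densities, densities[1:]))

    def test_empty_roi_raises(self, stain_image):
        img, _ = stain_image
        with pytest.raises(ValueError):
            histology.dot_density(img, "dots", np.zeros_like(img.roi_masks, bool),
                                  PARAMS)


class TestChanceColocalization:
    def test_double_flip_is_identity(self, stain_image):
        img, _ = stain_image
        flipped = histology.AnnotatedImage(
            channels={"dots": np.fliplr(img.channels["dots"])},
            pixel_size_um=img.pixel_size_um, roi_masks=img.roi_masks)
        roi = img.roi_masks == 1
        once = histology.chance_colocalization(img, "dots", roi, PARAMS)
        twice = histology.chance_colocalization(flipped, "dots", roi, PARAMS)
        assert twice["chance"]["n_dots"] == once["observed"]["n_dots"]

    def test_rot180_mode_available(self, stain_image):
        img, _ = stain_image
        roi = img.roi_masks == 1
        out = histology.chance_colocalization(img, "dots", roi, PARAMS, mode="rot180")
        assert "chance" in out

    def test_in_cell_dots_are_enriched(self, stain_image):
        img, _ = stain_image
        obs, cha = [], []
        for lab in img.labels:
            c = histology.chance_colocalization(img, "dots", img.roi_masks == lab,
                                                PARAMS)
            obs.append(c["observed"]["density_per_um2"])
            cha.append(c["chance"]["density_per_um2"])
        assert np.mean(obs) > np.mean(cha)


class TestCumulativeCurves:
    def test_single_animal_equals_own_curve(self):
        out = histology.cumulative_curves({"m1": [1.0, 2.0, 3.0]}, n_bins=4)
        assert np.array_equal(out["mean"], out["per_animal"]["m1"])

    def test_identical_values_step_function(self):
        out = histology.cumulative_curves({"m1": [5.0] * 10}, n_bins=6)
        curve = out["mean"]
        assert curve[0] == 0.0 or curve[0] == 1.0  # edges bracket the value
        assert curve[-1] == 1.0
        assert set(np.unique(curve)) <= {0.0, 1.0}

    def test_mean_between_two_shifted_animals(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 400)
        b = a + 1.5
        out = histology.cumulative_curves({"a": a, "b": b}, n_bins=18)
        ca, cb, m = out["per_animal"]["a"], out["per_animal"]["b"], out["mean"]
        interior = slice(3, -3)
        strict = (ca[interior] > cb[interior])
        assert np.all(m[interior][strict] < ca[interior][strict])
        assert np.all(m[interior][strict] > cb[interior][strict])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histology.cumulative_curves({})
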