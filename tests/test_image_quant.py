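"""Thresholding, shape metrics, size bins and cluster density."""

import numpy as np
import pytest
from skimage.draw import disk as skdisk

import gelmech as gm
from gelmech import synthetic


def _disk_mask(shape, center, r):
    m = np.zeros(shape, dtype=bool)
    rr, cc = skdisk(center, r, shape=shape)
    m[rr, cc] = True
    return m


class TestBinarize:
    def test_bimodal_recovers_truth_mask(self):
        spec = gm.ImageSpec(
            shape_px=(256, 256), noise_sd=6, seed=1,
            objects=(gm.ImageObject("ellipse", (128, 128), (120, 80)),),
        )
        img, _ = gm.generate_cell_image(spec)
        mask, thr = gm.binarize(img)
        truth = synthetic._ellipse_mask((256, 256), (128, 128), (40, 60), 0.0)
        agreement = np.mean(mask == truth)
        assert agreement >= 0.99
        assert 25 < thr < 230

    def test_polarity_flag_flips_mask(self):
        rng = np.random.default_rng(0)
        img = np.where(_disk_mask((64, 64), (32, 32), 20), 40, 220).astype(np.uint8)
        img = np.clip(img + rng.normal(0, 3, img.shape), 0, 255).astype(np.uint8)
        dark, _ = gm.binarize(img, dark_foreground=True)
        bright, _ = gm.binarize(255 - img, dark_foreground=False)
        assert np.mean(dark == bright) > 0.995

    def test_half_and_half_fraction(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[:, 32:] = 255
        mask, _ = gm.binarize(img)
        assert mask.mean() == pytest.approx(0.5)

    def test_constant_image_fails(self):
        with pytest.raises(ValueError):
            gm.binarize(np.full((32, 32), 100, dtype=np.uint8))


class TestMeasureShapes:
    def test_disk_circularity_and_roundness(self):
        mask = _disk_mask((500, 500), (250, 250), 200)
        df = gm.measure_shapes(mask, pixel_size=1.0)
        row = df.iloc[0]
        assert 0.98 <= row["circularity"] <= 1.0
        assert row["roundness"] == pytest.approx(1.0, abs=0.01)
        assert row["area_um2"] == pytest.approx(np.pi * 200**2, rel=0.01)

    def test_ellipse_roundness(self):
        spec = gm.ImageSpec(shape_px=(256, 256), pixel_size_um=0.5, noise_sd=0,
                            objects=(gm.ImageObject("ellipse", (64, 64), (40, 20), 0.6),))
        img, _ = gm.generate_cell_image(spec)
        mask, _ = gm.binarize(img)
        df = gm.measure_shapes(mask, pixel_size=0.5)
        assert df.iloc[0]["roundness"] == pytest.approx(0.5, abs=0.01)

    def test_square_circularity(self):
        mask = np.zeros((400, 400), dtype=bool)
        mask[50:350, 50:350] = True
        df = gm.measure_shapes(mask, pixel_size=1.0)
        assert df.iloc[0]["circularity"] == pytest.approx(np.pi / 4, abs=0.01)

    def test_scale_covariance(self):
        mask = _disk_mask((200, 200), (100, 100), 60)
        d1 = gm.measure_shapes(mask, pixel_size=1.0).iloc[0]
        d2 = gm.measure_shapes(mask, pixel_size=2.0).iloc[0]
        assert d2["area_um2"] == pytest.approx(4 * d1["area_um2"], rel=1e-9)
        assert d2["perimeter_um"] == pytest.approx(2 * d1["perimeter_um"], rel=1e-9)
        assert d2["major_um"] == pytest.approx(2 * d1["major_um"], rel=1e-9)
        assert d2["circularity"] == pytest.approx(d1["circularity"], rel=1e-9)
        assert d2["roundness"] == pytest.approx(d1["roundness"], rel=1e-9)

    def test_rotation_invariance_within_discretisation(self):
        vals = []
        for angle in (0.0, 0.4, 0.9, 1.3):
            spec = gm.ImageSpec(shape_px=(300, 300), noise_sd=0,
                                objects=(gm.ImageObject("ellipse", (150, 150), (160, 90), angle),))
            img, _ = gm.generate_cell_image(spec)
            mask, _ = gm.binarize(img)
            row = gm.measure_shapes(mask).iloc[0]
            vals.append((row["area_um2"], row["perimeter_um"], row["roundness"]))
        vals = np.array(vals)
        spread = np.ptp(vals, axis=0) / vals.mean(axis=0)
        assert np.all(spread <= 0.02)

    def test_circularity_never_exceeds_one(self):
        rng = np.random.default_rng(4)
        blob = rng.random((128, 128)) > 0.7
        df = gm.measure_shapes(blob, min_area_px=5)
        assert (df["circularity"] <= 1.0).all()

    def test_min_area_filter_and_empty_mask(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10, 10] = True  # below min area
        assert gm.measure_shapes(mask).empty
        assert gm.measure_shapes(np.zeros((32, 32), bool)).empty

    def test_recovery_against_generator_truth(self):
        """Area within 2% and roundness within 0.02 of the analytic truth."""
        objs = (
            gm.ImageObject("ellipse", (80, 80), (100, 60), 0.3),
            gm.ImageObject("ellipse", (250, 120), (60, 50), 1.1),
            gm.ImageObject("ellipse", (150, 300), (120, 40), 2.0),
        )
        spec = gm.ImageSpec(shape_px=(400, 400), noise_sd=5, seed=8, objects=objs)
        img, truth = gm.generate_cell_image(spec)
        mask, _ = gm.binarize(img)
        df = gm.measure_shapes(mask).sort_values("area_um2").reset_index(drop=True)
        tr = truth.sort_values("area_um2").reset_index(drop=True)
        assert len(df) == 3
        for i in range(3):
            assert df.loc[i, "area_um2"] == pytest.approx(tr.loc[i, "area_um2"], rel=0.02)
            assert df.loc[i, "roundness"] == pytest.approx(tr.loc[i, "roundness"], abs=0.02)


class TestSizeBins:
    def test_default_preset_example(self):
        df = gm.bin_cluster_sizes([5, 25, 120, 300], preset="default")
        occupied = df[df["percent"] > 0]
        assert set(occupied["bin"]) == {"<10 um", "10-30 um", "100-150 um", ">250 um"}
        assert (occupied["percent"] == 25.0).all()
        assert df["percent"].sum() == pytest.approx(100.0)

    def test_all_in_one_bin(self):
        df = gm.bin_cluster_sizes([110, 120, 130])
        assert df.set_index("bin").loc["100-150 um", "percent"] == 100.0

    def test_paper_preset_gap_goes_to_unbinned(self):
        df = gm.bin_cluster_sizes([75.0], preset="paper")
        assert df.set_index("bin").loc["unbinned", "percent"] == 100.0
        # the same size is covered by the default preset
        df2 = gm.bin_cluster_sizes([75.0], preset="default")
        assert df2.set_index("bin").loc["50-100 um", "percent"] == 100.0

    def test_left_closed_edges(self):
        df = gm.bin_cluster_sizes([10.0], preset="default").set_index("bin")
        assert df.loc["10-30 um", "percent"] == 100.0

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            gm.bin_cluster_sizes([])


class TestClusterDensity:
    def test_fully_foreground_roi(self):
        mask = np.ones((64, 64), dtype=bool)
        dens, _ = gm.cluster_density(mask)
        assert dens == 100.0

    def test_checkerboard(self):
        img = np.indices((64, 64)).sum(axis=0) % 2
        dens, _ = gm.cluster_density(img.astype(bool))
        assert dens == pytest.approx(50.0)

    def test_generator_truth_recovered_within_2_points(self):
        spec = gm.ImageSpec(
            shape_px=(512, 512), seed=2, noise_sd=4,
            objects=(gm.ImageObject("cluster", (256, 256), (300, 200), 0.3, fill_density=0.70),),
        )
        img, truth = gm.generate_cell_image(spec)
        roi = synthetic._ellipse_mask((512, 512), (256, 256), (100, 150), 0.3)
        dens, thr = gm.cluster_density(img, roi=roi)
        assert dens == pytest.approx(100 * truth.iloc[0]["fill_density"], abs=2.0)
        assert thr is not None

    def test_polygon_roi(self):
        img = np.full((64, 64), 255, dtype=np.uint8)
        img[16:32, 16:32] = 0
        poly = np.array([[16, 16], [16, 47], [47, 47], [47, 16]])
        dens, _ = gm.cluster_density(img, roi=poly)
        assert dens == pytest.approx(25.0, abs=2.0)

    def test_empty_roi_fails(self):
        with pytest.raises(ValueError):
            gm.cluster_density(np.ones((8, 8), bool), roi=np.zeros((8, 8), bool))


def test_identify_clusters_threshold_on_area():
    # three isolated single cells and one multicellular-sized component
    mask = _disk_mask((300, 300), (40, 40), 8)
    mask |= _disk_mask((300, 300), (40, 260), 8)
    mask |= _disk_mask((300, 300), (260, 40), 8)
    mask |= _disk_mask((300, 300), (200, 200), 50)
    clusters = gm.identify_clusters(mask, pixel_size=1.0)
    assert len(clusters) == 1
    assert clusters.iloc[0]["size_um"] == pytest.approx(100, rel=0.05)
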