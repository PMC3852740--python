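"""Machine-vision pipeline: segmentation, dilation, background, features."""

import numpy as np
import pytest

import probeloc as pl
from probeloc.features import (
    QC_NO_SIGNAL,
    QC_PASS,
    QC_SATURATED,
    SegmentationResult,
)
from probeloc.render import MAX_INTENSITY


def _disk_point_count(radius: int) -> int:
    # brute-force count of integer lattice points with x^2 + y^2 <= r^2
    return sum(
        1
        for x in range(-radius, radius + 1)
        for y in range(-radius, radius + 1)
        if x * x + y * y <= radius * radius
    )


class TestSegmentNuclei:
    def test_recovers_rendered_nuclei(self, noiseless_renders):
        ims = noiseless_renders["organelle"][0]
        mask = pl.segment_nuclei(ims.channels["Hoechst"])
        overlap = np.sum(mask & ims.nuclear_mask) / np.sum(ims.nuclear_mask)
        assert overlap >= 0.90

    def test_blank_channel_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning):
            mask = pl.segment_nuclei(np.zeros((64, 64)))
        assert not mask.any()

    def test_counts_well_separated_nuclei(self):
        from scipy import ndimage

        img = np.zeros((256, 256))
        yy, xx = np.mgrid[0:256, 0:256]
        for cy, cx in ((60, 60), (180, 190)):
            img[((yy - cy) / 12.0) ** 2 + ((xx - cx) / 9.0) ** 2 <= 1] = 2000.0
        mask = pl.segment_nuclei(img + 50.0)
        _, n = ndimage.label(mask)
        assert n == 2


class TestDilateMask:
    def test_empty_stays_empty(self):
        assert not pl.dilate_mask(np.zeros((32, 32), dtype=bool)).any()

    def test_single_pixel_becomes_euclidean_disk(self):
        mask = np.zeros((41, 41), dtype=bool)
        mask[20, 20] = True
        assert pl.dilate_mask(mask, radius=10).sum() == _disk_point_count(10) == 317

    def test_monotone_in_input(self):
        rng = np.random.default_rng(3)
        a = rng.random((64, 64)) > 0.995
        b = a | (rng.random((64, 64)) > 0.995)
        da, db = pl.dilate_mask(a), pl.dilate_mask(b)
        assert np.all(db[da])
        assert np.all(da[a])  # dilation contains its input


class TestCombineChannels:
    def test_zero_channels_pass_through(self):
        x = np.arange(16).reshape(4, 4)
        z = np.zeros_like(x)
        assert np.array_equal(pl.combine_probe_channels(x, z, z), x)

    def test_no_clipping_at_channel_ceiling(self):
        full = np.full((8, 8), MAX_INTENSITY)
        assert np.all(pl.combine_probe_channels(full, full, full) == 3 * MAX_INTENSITY)

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(0)
        a, b, c = (rng.integers(0, 4096, (16, 16)) for _ in range(3))
        got = pl.combine_probe_channels(a, b, c)
        for i in range(16):
            for j in range(16):
                assert got[i, j] == a[i, j] + b[i, j] + c[i, j]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pl.combine_probe_channels(np.zeros((4, 4)), np.zeros((5, 4)), np.zeros((4, 4)))


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        img = np.full((16, 16), 37.0)
        bg = np.zeros((16, 16), dtype=bool)
        bg[:4] = True
        assert np.all(pl.subtract_background(img, bg) == 0.0)

    def test_median_arithmetic_and_truncation(self):
        img = np.array([[1.0, 2.0], [3.0, 100.0]])
        bg = np.ones((2, 2), dtype=bool)
        # median of {1,2,3,100} = 2.5; negatives truncate at zero
        out = pl.subtract_background(img, bg)
        assert np.allclose(out, [[0.0, 0.0], [0.5, 97.5]])
        assert out.min() >= 0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            pl.subtract_background(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestQC:
    def test_no_probe_signal_excluded(self):
        ims = pl.render_image_set("organelle", intensity_scale=0.0, seed=6)
        assert pl.extract_features(ims).qc_status == QC_NO_SIGNAL

    def test_saturated_cells_excluded(self, noiseless_renders):
        ims = noiseless_renders["membrane"][0]
        saturated = {
            name: arr.copy() for name, arr in ims.channels.items()
        }
        for name in ("FITC", "TRITC", "Cy5"):
            saturated[name][ims.cell_mask] = MAX_INTENSITY
        nuclear = pl.segment_nuclei(saturated["Hoechst"])
        seg = SegmentationResult(nuclear, pl.dilate_mask(nuclear))
        total = pl.combine_probe_channels(
            saturated["FITC"], saturated["TRITC"], saturated["Cy5"]
        )
        assert pl.qc_image(total, seg, probe_channels=saturated) == QC_SATURATED

    def test_ordinary_render_passes(self):
        ims = pl.render_image_set("membrane", seed=8)
        assert pl.extract_features(ims).qc_status == QC_PASS


class TestComputeFeatures:
    @staticmethod
    def _masks(shape=(32, 32)):
        nuclear = np.zeros(shape, dtype=bool)
        nuclear[10:18, 10:18] = True
        cell = np.zeros(shape, dtype=bool)
        cell[6:24, 6:24] = True
        return nuclear, cell, ~cell

    def test_constant_cell_gives_unit_ratio_and_zero_cv(self):
        nuclear, cell, bg = self._masks()
        corrected = np.where(cell, 100.0, 0.0)
        raw = corrected + 10.0
        feats = pl.compute_features(corrected, nuclear, cell, raw, bg)
        assert feats["cv_cell"] == pytest.approx(0.0)
        assert feats["cyto_nuc_ratio"] == pytest.approx(1.0)

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(1)
        nuclear, cell, bg = self._masks()
        corrected = rng.random((32, 32)) * cell
        raw = corrected + 5.0
        f1 = pl.compute_features(corrected, nuclear, cell, raw, bg)
        f2 = pl.compute_features(corrected * 7.5, nuclear, cell, raw, bg)
        assert f1["cv_cell"] == pytest.approx(f2["cv_cell"], rel=1e-12)

    def test_zero_nuclear_mean_flagged_infinite(self):
        nuclear, cell, bg = self._masks()
        corrected = np.where(cell & ~nuclear, 50.0, 0.0)
        raw = corrected + 5.0
        feats = pl.compute_features(corrected, nuclear, cell, raw, bg)
        assert np.isinf(feats["cyto_nuc_ratio"])
        assert "zero_nuclear_mean" in feats["flags"]

    def test_matches_naive_reference_implementation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            nuclear, cell, bg = self._masks()
            raw = rng.integers(0, 4096, (32, 32)).astype(float)
            med = float(np.median(sorted(raw[bg].ravel())))
            corrected = np.maximum(raw - med, 0.0)
            feats = pl.compute_features(corrected, nuclear, cell, raw, bg)
            cellvals = [corrected[i, j] for i in range(32) for j in range(32) if cell[i, j]]
            cyto = [corrected[i, j] for i in range(32) for j in range(32)
                    if cell[i, j] and not nuclear[i, j]]
            nuc = [corrected[i, j] for i in range(32) for j in range(32) if nuclear[i, j]]
            mean = sum(cellvals) / len(cellvals)
            sd = (sum((v - mean) ** 2 for v in cellvals) / len(cellvals)) ** 0.5
            assert feats["cv_cell"] == pytest.approx(sd / mean, rel=1e-12)
            assert feats["cyto_nuc_ratio"] == pytest.approx(
                (sum(cyto) / len(cyto)) / (sum(nuc) / len(nuc)), rel=1e-12
            )
            rawcell = [raw[i, j] for i in range(32) for j in range(32) if cell[i, j]]
            assert feats["cell_background_ratio"] == pytest.approx(
                (sum(rawcell) / len(rawcell)) / med, rel=1e-12
            )


class TestClassSeparation:
    def test_features_separate_true_classes_on_noiseless_renders(self, noiseless_renders):
        feats = {
            cls: [pl.extract_features(ims) for ims in renders]
            for cls, renders in noiseless_renders.items()
        }
        for recs in feats.values():
            assert all(r.qc_status == QC_PASS for r in recs)
        for org, mem, nuc in zip(
            feats["organelle"], feats["membrane"], feats["nuclear"]
        ):
            assert org.cv_cell > mem.cv_cell
            assert org.cv_cell > nuc.cv_cell
            assert org.cyto_nuc_ratio > 1.0
            assert mem.cyto_nuc_ratio > 1.0
            assert nuc.cyto_nuc_ratio < 1.0
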