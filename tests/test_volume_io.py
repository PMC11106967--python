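"""Volume I/O, histogram peak finding, rescaling and cropping."""

import numpy as np
import pytest

from rootct.volume_io import (
    CTVolume,
    LabelVolume,
    HistogramPeaks,
    PeakDetectionError,
    read_volume,
    write_volume,
    read_label,
    find_histogram_peaks,
    rescale_to_gray8,
    to_unit,
    crop_center,
)


class TestTypes:
    def test_gray8_range_enforced(self):
        with pytest.raises(ValueError):
            CTVolume(np.full((2, 2, 2), 300.0), "gray8")

    def test_unit_range_enforced(self):
        with pytest.raises(ValueError):
            CTVolume(np.full((2, 2, 2), 1.5), "unit")

    def test_volume_must_be_3d(self):
        with pytest.raises(ValueError):
            CTVolume(np.zeros((4, 4), dtype=np.uint8), "gray8")

    def test_label_coerces_0_255_bytes(self):
        lab = LabelVolume(np.array([[[0, 255]]], dtype=np.uint8))
        assert lab.data.dtype == np.bool_
        assert lab.data.tolist() == [[[False, True]]]

    def test_label_rejects_arbitrary_values(self):
        with pytest.raises(ValueError):
            LabelVolume(np.array([[[3]]], dtype=np.uint8))

    def test_peaks_must_be_ordered(self):
        with pytest.raises(ValueError):
            HistogramPeaks(air_peak=10.0, soil_peak=5.0)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["tiff_stack", "slice_dir", "nifti"])
    def test_gray8_round_trip(self, tmp_path, gray8_volume, fmt):
        target = tmp_path / ("vol" if fmt == "slice_dir" else "vol.tif")
        if fmt == "nifti":
            target = tmp_path / "vol.nii"
        write_volume(gray8_volume, target, fmt)
        back = read_volume(target)
        assert back.dtype_tag == "gray8"
        np.testing.assert_array_equal(back.data, gray8_volume.data)

    @pytest.mark.parametrize("fmt", ["tiff_stack", "slice_dir", "nifti"])
    def test_raw16_round_trip(self, tmp_path, raw16_bimodal, fmt):
        target = tmp_path / ("vol" if fmt == "slice_dir" else "vol.tif")
        if fmt == "nifti":
            target = tmp_path / "vol.nii"
        write_volume(raw16_bimodal, target, fmt)
        back = read_volume(target)
        assert back.dtype_tag == "raw16"
        np.testing.assert_array_equal(back.data, raw16_bimodal.data)

    def test_label_round_trip_as_bytes(self, tmp_path, rng):
        lab = LabelVolume(rng.random((5, 6, 7)) > 0.5)
        write_volume(lab, tmp_path / "lab.tif", "tiff_stack")
        back = read_label(tmp_path / "lab.tif")
        np.testing.assert_array_equal(back.data, lab.data)

    def test_unit_round_trip_nifti(self, tmp_path, rng):
        vol = CTVolume(rng.random((4, 5, 6)).astype(np.float32), "unit")
        write_volume(vol, tmp_path / "v.nii", "nifti")
        back = read_volume(tmp_path / "v.nii")
        np.testing.assert_allclose(back.data, vol.data, rtol=0, atol=1e-7)

    def test_stack_axis_is_first(self, tmp_path):
        vol = CTVolume(
            np.arange(3 * 4 * 4, dtype=np.uint8).reshape(3, 4, 4), "gray8"
        )
        write_volume(vol, tmp_path / "s", "slice_dir")
        files = sorted((tmp_path / "s").iterdir())
        assert len(files) == 3
        back = read_volume(tmp_path / "s")
        assert back.shape == (3, 4, 4)
        np.testing.assert_array_equal(back.data, vol.data)

    def test_missing_path(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.tif")

    def test_inconsistent_slice_shapes(self, tmp_path):
        import tifffile

        d = tmp_path / "bad"
        d.mkdir()
        tifffile.imwrite(d / "a.tif", np.zeros((4, 4), dtype=np.uint8))
        tifffile.imwrite(d / "b.tif", np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="inconsistent"):
            read_volume(d)


class TestHistogramPeaks:
    def test_gaussian_mixture_recovered(self, raw16_bimodal):
        peaks = find_histogram_peaks(raw16_bimodal)
        # bandwidth: bin width (19000/256 ~ 75) plus smoothing of 2 bins
        bw = (20000 - 1000) / 256 * 3
        assert abs(peaks.air_peak - 1000) < bw
        assert abs(peaks.soil_peak - 20000) < bw

    def test_recovery_over_many_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 4096
            data = np.concatenate(
                [rng.normal(1000, 20, n), rng.normal(20000, 200, n)]
            )
            vol = CTVolume(
                np.clip(np.round(data), 0, 65535)
                .astype(np.uint16)
                .reshape(16, 16, 32),
                "raw16",
            )
            peaks = find_histogram_peaks(vol)
            bw = (data.max() - data.min()) / 256 * 3
            assert abs(peaks.air_peak - 1000) < bw, seed
            assert abs(peaks.soil_peak - 20000) < bw, seed

    def test_two_value_volume_exact(self):
        data = np.array([100, 200] * 32, dtype=np.uint16).reshape(4, 4, 4)
        peaks = find_histogram_peaks(CTVolume(data, "raw16"))
        assert peaks.air_peak == 100
        assert peaks.soil_peak == 200

    def test_constant_volume_fails(self):
        vol = CTVolume(np.full((4, 4, 4), 7, dtype=np.uint16), "raw16")
        with pytest.raises(PeakDetectionError):
            find_histogram_peaks(vol)

    def test_unimodal_fails(self, rng):
        data = np.clip(rng.normal(5000, 30, 4096), 0, 65535)
        vol = CTVolume(
            np.round(data).astype(np.uint16).reshape(16, 16, 16), "raw16"
        )
        with pytest.raises(PeakDetectionError):
            find_histogram_peaks(vol)


class TestRescale:
    PEAKS = HistogramPeaks(air_peak=1000.0, soil_peak=21000.0)

    def _vol(self, values):
        data = np.asarray(values, dtype=np.uint16).reshape(1, 1, -1)
        return CTVolume(data, "raw16")

    def test_anchor_points(self):
        out = rescale_to_gray8(self._vol([1000, 21000]), self.PEAKS)
        assert out.data.ravel().tolist() == [0, 128]

    def test_clipping_both_ends(self):
        # air+2*(soil-air) maps to 256 before clipping at 255
        out = rescale_to_gray8(self._vol([0, 500, 41000, 65535]), self.PEAKS)
        assert out.data.ravel().tolist() == [0, 0, 255, 255]

    def test_monotone_non_decreasing(self, rng):
        values = np.sort(rng.integers(0, 65536, 300)).astype(np.uint16)
        out = rescale_to_gray8(self._vol(values), self.PEAKS)
        assert (np.diff(out.data.ravel().astype(int)) >= 0).all()

    def test_round_half_away_from_zero(self):
        # 1 raw unit = 128/20000 gray; value at exactly half a gray level
        peaks = HistogramPeaks(air_peak=0.0, soil_peak=256.0)
        # 128*(1/256) = 0.5 -> rounds to 1 (away from zero)
        out = rescale_to_gray8(self._vol([1]), peaks)
        assert out.data.ravel().tolist() == [1]

    def test_degenerate_peaks_rejected(self):
        with pytest.raises(ValueError):
            HistogramPeaks(air_peak=5.0, soil_peak=5.0)

    def test_wrong_dtype_rejected(self, gray8_volume):
        with pytest.raises(ValueError):
            rescale_to_gray8(gray8_volume, self.PEAKS)


class TestToUnit:
    def test_values(self):
        vol = CTVolume(np.array([[[0, 128, 255]]], dtype=np.uint8), "gray8")
        out = to_unit(vol)
        assert out.dtype_tag == "unit"
        np.testing.assert_allclose(
            out.data.ravel(), [0.0, 128 / 255, 1.0], atol=1e-7
        )

    def test_rejects_non_gray8(self, raw16_bimodal):
        with pytest.raises(ValueError):
            to_unit(raw16_bimodal)


class TestCropCenter:
    def test_paper_geometry(self):
        # 9 cm radius at 0.3 mm voxels from a 1024-wide plane -> side 599
        vol = CTVolume(
            np.zeros((2, 1024, 1024), dtype=np.uint8), "gray8", voxel_size_mm=0.3
        )
        out = crop_center(vol, 90.0)
        assert out.shape == (2, 599, 599)

    def test_side_is_odd(self, gray8_volume):
        out = crop_center(gray8_volume, 4 * gray8_volume.voxel_size_mm)
        assert out.shape[1] % 2 == 1 and out.shape[2] % 2 == 1

    def test_idempotent(self, gray8_volume):
        r = 4 * gray8_volume.voxel_size_mm
        once = crop_center(gray8_volume, r)
        twice = crop_center(once, r)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_single_voxel_column(self, gray8_volume):
        out = crop_center(gray8_volume, gray8_volume.voxel_size_mm)
        assert out.shape == (gray8_volume.shape[0], 1, 1)

    def test_radius_too_large(self, gray8_volume):
        with pytest.raises(ValueError):
            crop_center(gray8_volume, 100.0)

    def test_circular_mask_zeroes_corners(self):
        vol = CTVolume(
            np.full((1, 21, 21), 9, dtype=np.uint8), "gray8", voxel_size_mm=1.0
        )
        out = crop_center(vol, 10.0, circular_mask=True)
        side = out.shape[1]
        assert out.data[0, 0, 0] == 0  # corner farther than radius
        assert out.data[0, side // 2, side // 2] == 9  # centre untouched

    def test_full_plane_no_mask_is_identity(self):
        vol = CTVolume(
            np.arange(5 * 5 * 5, dtype=np.uint16).reshape(5, 5, 5),
            "raw16",
            voxel_size_mm=1.0,
        )
        out = crop_center(vol, 3.0)  # side = 5 = full plane
        np.testing.assert_array_equal(out.data, vol.data)
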