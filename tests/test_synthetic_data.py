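"""Phantom generation, noise model and scan-time series."""

import numpy as np
import pytest

from rootct.filtering import rsavis3d_filter
from rootct.metrics import psnr
from rootct.synthetic_data import (
    PhantomSpec,
    NoiseSpec,
    generate_phantom,
    apply_noise,
    make_scan_series,
    tiny_spec,
    demo_spec,
)
from rootct.volume_io import find_histogram_peaks, rescale_to_gray8
from scipy import ndimage


class TestSpecs:
    def test_presets(self):
        assert tiny_spec().shape == (96, 96, 96)
        assert demo_spec().shape == (192, 192, 192)

    def test_air_must_be_darkest(self):
        with pytest.raises(ValueError):
            PhantomSpec(air_level=30000.0)

    def test_zero_contrast_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(root_level=20000.0, soil_level=20000.0)

    def test_oversized_roots_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shape=(8, 8, 8), root_radius_vox=(5.0, 6.0))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(gaussian_sigma=-1.0)


class TestGeneratePhantom:
    def test_deterministic_given_seed(self):
        a_vol, a_lab = generate_phantom(tiny_spec(seed=5))
        b_vol, b_lab = generate_phantom(tiny_spec(seed=5))
        np.testing.assert_array_equal(a_vol.data, b_vol.data)
        np.testing.assert_array_equal(a_lab.data, b_lab.data)

    def test_different_seed_differs(self):
        a, _ = generate_phantom(tiny_spec(seed=1))
        b, _ = generate_phantom(tiny_spec(seed=2))
        assert (a.data != b.data).any()

    def test_no_roots_empty_label_and_bimodal_histogram(self):
        spec = tiny_spec(n_roots=0)
        vol, lab = generate_phantom(spec)
        assert not lab.data.any()
        peaks = find_histogram_peaks(vol)
        assert abs(peaks.air_peak - spec.air_level) < 600
        assert abs(peaks.soil_peak - spec.soil_level) < 600

    def test_peaks_recovered_with_roots(self):
        for seed in range(5):
            spec = tiny_spec(seed=seed)
            vol, _ = generate_phantom(spec)
            peaks = find_histogram_peaks(vol)
            assert abs(peaks.air_peak - spec.air_level) < 600
            assert abs(peaks.soil_peak - spec.soil_level) < 600

    def test_straight_root_is_vertical_cylinder(self):
        """Tortuosity 0 + full downward bias must rasterise a vertical
        tube: every interior label slice is the same disk."""
        spec = tiny_spec(
            n_roots=1, tortuosity=0.0, downward_bias=1.0,
            root_radius_vox=(2.0, 2.0), seed=3,
        )
        _, lab = generate_phantom(spec)
        H = spec.shape[0]
        air_gap = max(1, int(round(spec.air_gap_frac * H)))
        first = lab.data[air_gap + 3]
        assert first.any()
        for h in range(air_gap + 3, H - 4):
            np.testing.assert_array_equal(lab.data[h], first, err_msg=f"slice {h}")

    def test_tube_rasterisation_matches_ball_union_oracle(self):
        """_stamp_tube equals the brute-force union of balls around the
        centreline, for an off-lattice vertical centreline."""
        from rootct.synthetic_data import _stamp_tube

        shape = (20, 16, 16)
        radius = 2.0
        points = [np.array([h, 7.3, 8.7]) for h in range(4, 16)]
        label = np.zeros(shape, dtype=bool)
        _stamp_tube(label, points, radius)
        zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
        oracle = np.zeros(shape, dtype=bool)
        for p in points:
            oracle |= (
                (zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2
            ) <= radius**2
        np.testing.assert_array_equal(label, oracle)
        # per-slice area in the tube interior equals the analytic disk
        disk = ((yy[0] - 7.3) ** 2 + (xx[0] - 8.7) ** 2) <= radius**2
        for h in range(6, 14):
            assert label[h].sum() == disk.sum()

    def test_root_voxels_darker_than_soil(self):
        spec = tiny_spec(seed=0)
        vol, lab = generate_phantom(spec)
        root_mean = vol.data[lab.data].mean()
        # soil = inside pot, below air gap, not root
        H, W, D = spec.shape
        w = np.arange(W) - (W - 1) / 2
        inside = (w[:, None] ** 2 + w[None, :] ** 2) < (0.8 * W / 2) ** 2
        soil_mask = np.zeros(spec.shape, bool)
        soil_mask[int(0.2 * H) :] = inside
        soil_mask &= ~lab.data
        assert root_mean < vol.data[soil_mask].mean() - 5000

    def test_label_false_in_air(self):
        spec = tiny_spec(seed=0)
        _, lab = generate_phantom(spec)
        air_gap = max(1, int(round(spec.air_gap_frac * spec.shape[0])))
        assert not lab.data[:air_gap].any()

    def test_lateral_branches_add_voxels(self):
        base = tiny_spec(seed=4)
        branched = tiny_spec(seed=4, lateral_branch_prob=0.2)
        _, a = generate_phantom(base)
        _, b = generate_phantom(branched)
        assert b.data.sum() > a.data.sum()


class TestFilterEnrichment:
    def test_root_shell_response_exceeds_background(self):
        """The prefilter must enrich root boundaries relative to soil."""
        for seed in range(10):
            spec = tiny_spec(seed=seed, shape=(64, 64, 64), n_roots=2)
            vol, lab = generate_phantom(spec)
            g8 = rescale_to_gray8(vol, find_histogram_peaks(vol))
            filtered = rsavis3d_filter(g8)
            shell = ndimage.binary_dilation(lab.data, iterations=2) & ~lab.data
            H, W = spec.shape[:2]
            w = np.arange(W) - (W - 1) / 2
            inside = (w[:, None] ** 2 + w[None, :] ** 2) < (0.7 * W / 2) ** 2
            soil = np.zeros(spec.shape, bool)
            soil[int(0.25 * H) :] = inside
            soil &= ~ndimage.binary_dilation(lab.data, iterations=4)
            assert (
                filtered.data[shell].mean() > filtered.data[soil].mean()
            ), seed


class TestApplyNoise:
    def test_zero_noise_is_identity(self):
        vol, _ = generate_phantom(tiny_spec(seed=1, shape=(32, 32, 32)))
        out = apply_noise(vol, NoiseSpec(0.0, binning=False))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_noise_std_matches_sigma(self):
        from rootct.volume_io import CTVolume

        clean = CTVolume(
            np.full((64, 64, 64), 30000, dtype=np.uint16), "raw16"
        )
        sigma = 500.0
        out = apply_noise(clean, NoiseSpec(sigma, seed=3))
        sd = (out.data.astype(float) - 30000).std()
        assert abs(sd - sigma) / sigma < 0.05

    def test_psnr_decreases_with_sigma(self):
        vol, _ = generate_phantom(tiny_spec(seed=2, shape=(48, 48, 48)))
        values = []
        for s in (200.0, 800.0, 2400.0):
            noisy = apply_noise(vol, NoiseSpec(s, seed=1))
            values.append(psnr(noisy.data, vol.data, max_val=65535.0))
        assert values[0] > values[1] > values[2]

    def test_binning_blurs_in_plane(self):
        vol, _ = generate_phantom(tiny_spec(seed=2, shape=(32, 32, 32)))
        out = apply_noise(vol, NoiseSpec(0.0, binning=True))
        # blur reduces in-plane gradient energy
        g_in = np.abs(np.diff(vol.data.astype(float), axis=1)).mean()
        g_out = np.abs(np.diff(out.data.astype(float), axis=1)).mean()
        assert g_out < g_in


class TestScanSeries:
    def test_alignment_contract(self):
        series, label = make_scan_series(
            tiny_spec(seed=0, shape=(32, 32, 32)), [0.0, 500.0, 1500.0]
        )
        assert len(series) == 3
        for vol in series:
            assert vol.shape == label.shape

    def test_single_zero_sigma_is_clean(self):
        spec = tiny_spec(seed=1, shape=(32, 32, 32))
        series, _ = make_scan_series(spec, [0.0])
        clean, _ = generate_phantom(spec)
        np.testing.assert_array_equal(series[0].data, clean.data)

    def test_psnr_ordering_across_series(self):
        spec = tiny_spec(seed=3, shape=(48, 48, 48))
        sigmas = [0.0, 300.0, 900.0, 1800.0, 2700.0, 3600.0]
        series, _ = make_scan_series(spec, sigmas)
        clean, _ = generate_phantom(spec)
        values = [
            psnr(v.data, clean.data, 65535.0) for v in series[1:]
        ]
        assert values == sorted(values, reverse=True)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_scan_series(tiny_spec(), [1.0, 2.0], [True])
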