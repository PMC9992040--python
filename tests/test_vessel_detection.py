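"""Noise estimation, significance testing, clustering and the filter chain."""

import numpy as np
import pytest

from perfopulse.pc_io import CinePCSeries, ROIMask
from perfopulse.synthetic_cine import render_cine, AcquisitionSpec
from perfopulse.vessel_detection import (
    Cluster,
    DetectionConfig,
    circularity_filter,
    cluster_and_select,
    cluster_axis_lengths,
    detect_perforators,
    estimate_noise_map,
    magnitude_snr_mask,
    proximity_dedup,
    significant_velocity_mask,
)


def series_from_complex(cplx, spacing=(0.2, 0.2), venc=20.0):
    return CinePCSeries(
        magnitude=np.abs(cplx),
        phase=np.angle(cplx),
        pixel_spacing_mm=spacing,
        venc_cm_s=venc,
        grid_kind="reconstructed",
    )


def noise_series(rng, n_phases=12, shape=(128, 128), tissue=100.0, sigma=5.0):
    cplx = tissue + sigma * (
        rng.standard_normal((n_phases, *shape)) + 1j * rng.standard_normal((n_phases, *shape))
    )
    return series_from_complex(cplx)


def full_roi(series):
    return ROIMask(np.ones(series.shape[1:], dtype=bool))


class TestNoiseMap:
    def test_constant_signal_gives_zero(self):
        cplx = np.full((5, 8, 8), 3 + 4j)
        s = series_from_complex(cplx)
        noise = estimate_noise_map(s, full_roi(s))
        assert np.allclose(noise, 0.0)

    def test_recovers_planted_channel_sd(self, rng):
        s = noise_series(rng, sigma=5.0)
        noise = estimate_noise_map(s, full_roi(s))
        assert noise.size >= 10_000
        assert np.nanmean(noise) == pytest.approx(5.0, rel=0.03)

    def test_shift_invariance(self, rng):
        base = 5.0 * (rng.standard_normal((12, 16, 16)) + 1j * rng.standard_normal((12, 16, 16)))
        s1 = series_from_complex(100.0 + base)
        s2 = series_from_complex(100.0 + (37.0 - 21.0j) + base)
        roi = full_roi(s1)
        np.testing.assert_allclose(
            estimate_noise_map(s1, roi), estimate_noise_map(s2, roi), rtol=1e-9
        )

    def test_nan_outside_roi_and_errors(self, rng):
        s = noise_series(rng, shape=(8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True
        noise = estimate_noise_map(s, ROIMask(mask))
        assert np.isnan(noise[0, 0]) and np.isfinite(noise[2, 2])
        with pytest.raises(ValueError, match="empty"):
            estimate_noise_map(s, ROIMask(np.zeros((8, 8), dtype=bool)))
        two_phase = series_from_complex((100.0 + 0j) * np.ones((2, 8, 8)))
        with pytest.raises(ValueError, match="phases"):
            estimate_noise_map(two_phase, ROIMask(mask))


class TestMagnitudeSNRMask:
    def test_threshold_is_exclusive(self):
        # mean magnitude exactly 2*sigma is removed; well above is kept
        mag = np.ones((4, 1, 3))
        mag[:, 0, 0] = 2.0  # SNR exactly 2 -> removed
        mag[:, 0, 1] = 10.0  # SNR 10 -> kept
        mag[:, 0, 2] = 1.0  # SNR 1 -> removed
        s = CinePCSeries(mag, np.zeros_like(mag), (0.2, 0.2), 20.0, grid_kind="reconstructed")
        noise = np.ones((1, 3))
        keep = magnitude_snr_mask(s, noise, ROIMask(np.ones((1, 3), bool)))
        assert list(keep[0]) == [False, True, False]

    def test_outside_roi_removed_and_zero_sigma_kept(self):
        mag = 10.0 * np.ones((4, 2, 2))
        s = CinePCSeries(mag, np.zeros_like(mag), (0.2, 0.2), 20.0, grid_kind="reconstructed")
        noise = np.array([[1.0, 0.0], [1.0, 1.0]])
        roi = ROIMask(np.array([[True, True], [False, True]]))
        keep = magnitude_snr_mask(s, noise, roi)
        assert keep[0, 0] and keep[0, 1] and keep[1, 1]
        assert not keep[1, 0]  # outside ROI despite high SNR


class TestSignificantVelocity:
    def test_uncorrected_false_positive_rate_matches_alpha(self, rng):
        s = noise_series(rng, shape=(128, 128))
        roi = full_roi(s)
        noise = estimate_noise_map(s, roi)
        keep = magnitude_snr_mask(s, noise, roi)
        cfg = DetectionConfig(multiple_testing="none", alpha=0.05)
        sig = significant_velocity_mask(s, noise, keep, cfg)
        frac = sig.sum() / keep.sum()
        assert frac == pytest.approx(0.05, abs=0.01)

    def test_fdr_controls_global_null(self, rng):
        s = noise_series(rng, shape=(128, 128))
        roi = full_roi(s)
        noise = estimate_noise_map(s, roi)
        keep = magnitude_snr_mask(s, noise, roi)
        sig = significant_velocity_mask(s, noise, keep, DetectionConfig(multiple_testing="fdr"))
        assert sig.sum() == 0

    def test_strong_vessel_is_significant(self, rng):
        cplx = 100.0 + 5.0 * (
            rng.standard_normal((12, 32, 32)) + 1j * rng.standard_normal((12, 32, 32))
        )
        cplx[:, 16, 16] = 300.0 * np.exp(1j * np.pi * 8.0 / 20.0)  # 8 cm/s
        s = series_from_complex(cplx)
        roi = full_roi(s)
        noise = estimate_noise_map(s, roi)
        keep = magnitude_snr_mask(s, noise, roi)
        sig = significant_velocity_mask(s, noise, keep)
        assert sig[16, 16]


class TestClustering:
    def test_connectivity_definition(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True  # diagonal touch
        v = np.ones((4, 4))
        assert len(cluster_and_select(mask, v, DetectionConfig(connectivity=8))) == 1
        assert len(cluster_and_select(mask, v, DetectionConfig(connectivity=4))) == 2

    def test_representative_is_fastest_pixel(self):
        mask = np.zeros((1, 3), bool)
        mask[0, :] = True
        v = np.array([[4.0, 9.0, 7.0]])
        (cl,) = cluster_and_select(mask, v)
        assert cl.rep == (0, 1)
        assert cl.rep_velocity_cm_s == 9.0

    def test_tie_breaks_in_raster_order(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 2] = mask[1, 0] = mask[1, 1] = True
        v = np.full((3, 3), 5.0)
        (cl,) = cluster_and_select(mask, v)
        assert cl.rep == (0, 2)  # smallest row wins, then smallest col

    def test_empty_mask_gives_empty_result(self):
        assert cluster_and_select(np.zeros((4, 4), bool), np.zeros((4, 4))) == []


class TestCircularity:
    def test_single_pixel_has_unit_ratio(self):
        assert cluster_axis_lengths(np.array([[3, 3]])) == (0.5, 0.5)

    def test_line_cluster_removed(self):
        # 1x5 line: population variance 2 along the line -> ratio 2*sqrt(2)/0.5
        pixels = np.array([[0, c] for c in range(5)])
        major, minor = cluster_axis_lengths(pixels)
        assert major == pytest.approx(2 * np.sqrt(2.0))
        assert minor == 0.5
        cl = Cluster(pixels=pixels, rep=(0, 0), rep_velocity_cm_s=5.0)
        circularity_filter([cl])
        assert cl.removed_by == "circularity"

    def test_square_cluster_kept(self):
        pixels = np.array([[r, c] for r in range(3) for c in range(3)])
        cl = Cluster(pixels=pixels, rep=(1, 1), rep_velocity_cm_s=5.0)
        circularity_filter([cl])
        assert cl.removed_by is None
        assert cl.axis_ratio == pytest.approx(1.0)


def mk_cluster(row, col, v):
    return Cluster(pixels=np.array([[row, col]]), rep=(row, col), rep_velocity_cm_s=v)


class TestProximityDedup:
    SPACING = (0.1, 0.1)

    def test_close_pair_keeps_fastest(self):
        a, b = mk_cluster(0, 0, 8.0), mk_cluster(0, 10, 6.0)  # 1.0 mm apart
        proximity_dedup([a, b], self.SPACING)
        assert a.removed_by is None
        assert b.removed_by == "proximity"

    def test_distant_pair_both_kept(self):
        a, b = mk_cluster(0, 0, 8.0), mk_cluster(0, 13, 6.0)  # 1.3 mm
        proximity_dedup([a, b], self.SPACING)
        assert a.removed_by is None and b.removed_by is None

    def test_chain_resolved_greedily(self):
        # A-B-C, 1.0 mm steps, velocities 9 > 8 > 7: A and C survive
        a, b, c = mk_cluster(0, 0, 9.0), mk_cluster(0, 10, 8.0), mk_cluster(0, 20, 7.0)
        proximity_dedup([a, b, c], self.SPACING)
        assert [x.removed_by for x in (a, b, c)] == [None, "proximity", None]


class TestDetectPerforators:
    def test_empty_noise_scene_detects_nothing_with_fdr(self):
        acq = AcquisitionSpec(fov_mm=19.2, noise_sigma=10.0, seed=20)
        series, roi, _ = render_cine([], acq)
        vessels = detect_perforators(series, roi, DetectionConfig(multiple_testing="fdr"))
        assert vessels.n_detected == 0

    def test_deterministic_for_fixed_input(self, standard_scene_run):
        series, roi = standard_scene_run["series"], standard_scene_run["roi"]
        again = detect_perforators(series, roi)
        assert again.table.equals(standard_scene_run["vessels"].table)

    @pytest.mark.parametrize(
        "stricter",
        [
            dict(magnitude_snr_min=5.0),
            dict(alpha=0.001),
            dict(axis_ratio_max=1.5),
            dict(min_separation_mm=2.5),
        ],
    )
    def test_monotone_in_each_threshold(self, standard_scene_run, stricter):
        series, roi = standard_scene_run["series"], standard_scene_run["roi"]
        base = standard_scene_run["vessels"].n_detected
        n = detect_perforators(series, roi, DetectionConfig(**stricter)).n_detected
        assert n <= base

    def test_provenance_accounts_for_every_candidate(self, standard_scene_run):
        vessels = standard_scene_run["vessels"]
        prov = vessels.provenance
        assert (prov["removed_by"] == "").sum() == vessels.n_detected
        assert set(prov["removed_by"]) <= {"", "circularity", "proximity"}
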