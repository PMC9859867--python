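"""ROI enhancement, AV ratio, arrival detection, curve extraction, MIP."""
import numpy as np
import pytest

from collateraltime import (ExtractionParams, av_ratio, contrast_arrival,
                            mip_collateral_ratio, roi_enhancement,
                            time_invariant_mip)
from collateraltime.errors import (ArrivalNotFoundError, ConfigurationError,
                                   GeometryError)
from collateraltime.series import CTPSeries


def brute_force_sphere_median(volume, center, radius_mm, voxel_size_mm):
    """Independent oracle: scan every voxel, lower-middle median."""
    vals = []
    for idx in np.ndindex(volume.shape):
        d = np.sqrt(sum(((i - c) * s) ** 2
                        for i, c, s in zip(idx, center, voxel_size_mm)))
        if d <= radius_mm:
            vals.append(volume[idx])
    vals.sort()
    return vals[(len(vals) - 1) // 2]


class TestRoiEnhancement:
    def test_uniform_volume(self):
        vol = np.full((8, 8, 8), 73.5)
        assert roi_enhancement(vol, (4, 4, 4), 2.5, (1, 1, 1)) == 73.5

    def test_tiny_radius_returns_center_voxel(self):
        vol = np.arange(8 ** 3, dtype=float).reshape(8, 8, 8)
        assert roi_enhancement(vol, (3, 5, 2), 0.4, (1, 1, 1)) == vol[3, 5, 2]

    def test_planted_five_values_median(self):
        # an in-plane cross of exactly 5 voxels carries {10,20,30,40,50};
        # 2 mm slice spacing keeps the z-neighbours outside the 1 mm sphere
        vol = np.full((9, 9, 9), 1000.0)
        vol[4, 4, 4] = 30.0
        vol[3, 4, 4], vol[5, 4, 4] = 10.0, 50.0
        vol[4, 3, 4], vol[4, 5, 4] = 20.0, 40.0
        assert roi_enhancement(vol, (4, 4, 4), 1.0, (1, 1, 2)) == 30.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.normal(100, 30, size=(10, 12, 8))
        center = tuple(rng.uniform(2, 6) for _ in range(3))
        radius = float(rng.uniform(1.5, 4.0))
        spacing = (1.0, 1.5, 2.0)
        assert roi_enhancement(vol, center, radius, spacing) == \
            brute_force_sphere_median(vol, center, radius, spacing)

    def test_sphere_off_grid_raises(self):
        with pytest.raises(GeometryError):
            roi_enhancement(np.zeros((5, 5, 5)), (50, 50, 50), 1.0, (1, 1, 1))


class TestAvRatio:
    def test_examples(self):
        assert av_ratio(140.0, 90.0, 40.0) == pytest.approx(2.0)
        assert av_ratio(40.0, 140.0, 40.0) == 0.0
        assert np.isnan(av_ratio(100.0, 40.0, 40.0))

    def test_negative_arterial_excess_clamped(self):
        assert av_ratio(30.0, 90.0, 40.0) == 0.0


class TestContrastArrival:
    def test_interpolated_crossing(self):
        arterial = np.array([40.0, 40.0, 40.0, 60.0, 120.0])
        times = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        ext = ExtractionParams(arrival_delta_hu=10.0)
        assert contrast_arrival(arterial, times, ext) == pytest.approx(5.0)

    def test_flat_curve_not_found(self):
        with pytest.raises(ArrivalNotFoundError):
            contrast_arrival(np.full(10, 40.0), np.arange(10.0),
                             ExtractionParams())

    def test_arrival_monotone_in_delta(self):
        arterial = np.array([40.0, 40.0, 45.0, 60.0, 120.0, 300.0])
        times = np.arange(6) * 2.0
        arrivals = [contrast_arrival(arterial, times,
                                     ExtractionParams(arrival_delta_hu=d))
                    for d in (1.0, 4.0, 20.0, 80.0)]
        assert arrivals == sorted(arrivals)


class TestExtractTics:
    def test_symmetric_phantom_cr_is_100(self, symmetric_tics):
        valid = np.isfinite(symmetric_tics.cr_percent)
        assert valid.sum() >= 20
        np.testing.assert_allclose(symmetric_tics.cr_percent[valid], 100.0,
                                   atol=1e-9)

    def test_curve_lengths_match_frames(self, symmetric_model, symmetric_tics):
        n = symmetric_model.config.n_frames
        assert n == 30
        for arr in (symmetric_tics.vol_occluded_ml, symmetric_tics.cr_percent,
                    symmetric_tics.arterial_hu, symmetric_tics.venous_hu,
                    symmetric_tics.av_ratio):
            assert len(arr) == n

    def test_av_validity_tracks_venous_above_blood(self, symmetric_tics):
        expected = symmetric_tics.venous_hu > symmetric_tics.blood_hu
        np.testing.assert_array_equal(np.isfinite(symmetric_tics.av_ratio),
                                      expected)


class TestMip:
    def test_mip_dominates_every_frame(self, symmetric_series):
        mip = time_invariant_mip(symmetric_series)
        for i in range(symmetric_series.n_frames):
            assert np.all(mip >= symmetric_series.data[i])

    def test_duplicated_frame_mip_equals_frame(self):
        frame = np.random.default_rng(0).normal(50, 10, size=(4, 4, 4)).astype(np.float32)
        series = CTPSeries(np.stack([frame, frame]), [0.0, 2.0], (1, 1, 1))
        np.testing.assert_array_equal(time_invariant_mip(series), frame)

    def test_single_frame_rejected(self):
        series = CTPSeries(np.zeros((1, 4, 4, 4)), [0.0], (1, 1, 1))
        with pytest.raises(ConfigurationError):
            time_invariant_mip(series)

    def test_symmetric_phantom_mip_cr_is_100(self, symmetric_model,
                                             symmetric_series):
        assert mip_collateral_ratio(symmetric_series,
                                    symmetric_model.region_spec()) == \
            pytest.approx(100.0, abs=1e-9)

    def test_mip_cr_captures_late_filling(self, delayed_model, delayed_tics):
        series = delayed_model.simulate_series()
        cr_mip = mip_collateral_ratio(series, delayed_model.region_spec())
        arterial_peak_frame = int(np.argmax(delayed_tics.arterial_hu))
        cr_at_peak = delayed_tics.cr_percent[arterial_peak_frame]
        assert cr_mip >= cr_at_peak
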