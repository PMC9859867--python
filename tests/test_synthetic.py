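"""Phantom generator: bolus model, geometry symmetry, mCTA sampling, cohorts."""
import numpy as np
import pytest

from collateraltime import (PhantomConfig, PhantomModel, SegmentationParams,
                            cohort_configs, extract_tics, gamma_variate,
                            generate_cohort, generate_phantom, sample_mcta)
from collateraltime.errors import ConfigurationError

from conftest import make_model


class TestGammaVariate:
    @pytest.mark.parametrize("t0,alpha,beta,amp", [
        (8.0, 3.0, 2.0, 350.0), (4.0, 2.5, 1.5, 100.0), (0.0, 4.0, 3.0, 1.0)])
    def test_prearrival_peak_and_linearity(self, t0, alpha, beta, amp):
        assert gamma_variate(t0, t0, alpha, beta, amp) == 0.0
        assert gamma_variate(t0 - 5.0, t0, alpha, beta, amp) == 0.0
        peak = gamma_variate(t0 + alpha * beta, t0, alpha, beta, amp)
        assert peak == pytest.approx(amp, rel=1e-12)
        t = np.linspace(t0 - 2, t0 + 30, 50)
        np.testing.assert_allclose(gamma_variate(t, t0, alpha, beta, 2 * amp),
                                   2 * gamma_variate(t, t0, alpha, beta, amp),
                                   rtol=1e-12)

    def test_peak_is_global_maximum(self):
        t = np.linspace(0, 60, 6001)
        vals = gamma_variate(t, 8.0, 3.0, 2.0, 350.0)
        assert vals.max() <= 350.0 + 1e-9

    @pytest.mark.parametrize("alpha,beta", [(0.0, 2.0), (-1.0, 2.0), (3.0, 0.0)])
    def test_invalid_shape_raises(self, alpha, beta):
        with pytest.raises(ConfigurationError):
            gamma_variate(10.0, 8.0, alpha, beta, 350.0)


class TestPhantom:
    def test_symmetric_filling_identical_volumes(self, symmetric_model, symmetric_tics):
        valid = np.isfinite(symmetric_tics.cr_percent)
        assert valid.sum() >= 20
        np.testing.assert_array_equal(symmetric_tics.vol_occluded_ml,
                                      symmetric_tics.vol_contralateral_ml)

    def test_zero_fraction_no_occluded_enhancement(self):
        model = make_model(collateral_fraction=0.0, collateral_delay_s=3.0)
        tics = extract_tics(model.simulate_series(), model.region_spec())
        assert np.all(tics.vol_occluded_ml == 0.0)

    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig(seed=123)
        s1 = PhantomModel(cfg).simulate_series()
        s2 = PhantomModel(cfg).simulate_series()
        np.testing.assert_array_equal(s1.data, s2.data)
        s3 = PhantomModel(PhantomConfig(seed=124)).simulate_series()
        assert not np.array_equal(s1.data, s3.data)

    def test_occluded_volume_monotone_in_fraction(self):
        seg = SegmentationParams()
        vols = []
        for cf in (0.3, 0.6, 0.9):
            model = make_model(collateral_fraction=cf, collateral_delay_s=3.0)
            tics = extract_tics(model.simulate_series(), model.region_spec(), seg)
            vols.append(tics.vol_occluded_ml)
        assert np.all(vols[1] >= vols[0]) and np.all(vols[2] >= vols[1])

    def test_venous_peak_lags_arterial_by_transit_time(self, symmetric_model,
                                                       symmetric_tics):
        t = symmetric_tics.times_s
        lag = (t[np.argmax(symmetric_tics.venous_hu)]
               - t[np.argmax(symmetric_tics.arterial_hu)])
        cfg = symmetric_model.config
        assert abs(lag - cfg.venous_delay_s) <= cfg.frame_interval_s

    def test_too_few_frames_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(duration_s=20.0, frame_interval_s=2.0)

    def test_generate_phantom_contract(self):
        series, regions, truth = generate_phantom(PhantomConfig(seed=5))
        assert series.n_frames == 30
        assert truth.collateral_fraction == 1.0
        assert not (regions.mca_occluded_mask & regions.mca_contralateral_mask).any()


class TestSampleMcta:
    def test_sample_times_arithmetic(self, symmetric_model):
        _, times = sample_mcta(symmetric_model, 8.0, (8.0, 8.0))
        np.testing.assert_allclose(times, [8.0, 16.0, 24.0])

    def test_noise_free_sampling_matches_frame(self, symmetric_model,
                                               symmetric_series):
        volumes, _ = sample_mcta(symmetric_model, 20.0, (8.0, 8.0))
        np.testing.assert_allclose(volumes[0], symmetric_series.data[10],
                                   atol=1e-4)

    def test_zero_delays_identical_volumes(self, symmetric_model):
        volumes, _ = sample_mcta(symmetric_model, 20.0, (0.0, 0.0))
        np.testing.assert_array_equal(volumes[0], volumes[1])
        np.testing.assert_array_equal(volumes[1], volumes[2])

    def test_sampling_beyond_duration_rejected(self, symmetric_model):
        with pytest.raises(ConfigurationError):
            sample_mcta(symmetric_model, 50.0, (8.0, 8.0))

    def test_truth_update(self, symmetric_model):
        truth = symmetric_model.ground_truth()
        sample_mcta(symmetric_model, 18.0, (8.0, 7.0), truth=truth)
        assert truth.true_mcta_offset_s == 18.0
        assert truth.mcta_delays_s == (8.0, 7.0)


class TestCohort:
    def test_cohort_size_and_covariate_ranges(self):
        subjects = cohort_configs(58, seed=3)
        assert len(subjects) == 58
        for cfg, truth in subjects:
            assert 0.05 <= truth.collateral_fraction <= 1.0
            assert 0 <= truth.covariates["aspects"] <= 10
            assert 0 <= truth.covariates["nihss"] <= 42
            assert (truth.true_mcta_offset_s + sum(truth.mcta_delays_s)
                    <= cfg.duration_s)

    def test_zero_covariate_noise_is_monotone_in_fraction(self):
        subjects = cohort_configs(40, seed=1, aspects_noise_sd=0.0,
                                  nihss_noise_sd=0.0)
        order = sorted(subjects, key=lambda s: s[1].collateral_fraction)
        aspects = [t.covariates["aspects"] for _, t in order]
        nihss = [t.covariates["nihss"] for _, t in order]
        assert all(a2 >= a1 for a1, a2 in zip(aspects, aspects[1:]))
        assert all(n2 <= n1 for n1, n2 in zip(nihss, nihss[1:]))

    def test_seeds_change_cohort(self):
        cf1 = [t.collateral_fraction for _, t in cohort_configs(5, seed=1)]
        cf2 = [t.collateral_fraction for _, t in cohort_configs(5, seed=2)]
        assert cf1 != cf2
        assert cf1 == [t.collateral_fraction for _, t in cohort_configs(5, seed=1)]

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            cohort_configs(1, seed=0)

    def test_generate_cohort_materializes(self):
        small = PhantomConfig(grid_shape=(64, 64, 32))
        out = generate_cohort(2, small, seed=9)
        assert len(out) == 2
        series, regions, truth = out[0]
        assert series.n_frames == 30
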