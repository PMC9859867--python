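"""Equilibrium finding, AV-curve normalization and phase classification."""
import numpy as np
import pytest

from collateraltime import (Phase, classify_phase, find_equilibrium,
                            label_frames, normalize_av_curve)
from collateraltime.curves import TimeIntensityCurves, av_ratio_curve
from collateraltime.errors import (ConfigurationError, DegenerateCurveError,
                                   EquilibriumNotFoundError)
from collateraltime.phases import PHASE_ORDER, NormalizedAVCurve
from collateraltime.synthetic import analytic_roi_tics

from conftest import random_curve_config


def curves_from_rois(arterial, venous, times, blood=40.0, arrival=None):
    arterial = np.asarray(arterial, float)
    nanv = np.full_like(arterial, np.nan)
    return TimeIntensityCurves(
        times_s=np.asarray(times, float),
        vol_occluded_ml=nanv.copy(), vol_contralateral_ml=nanv.copy(),
        cr_percent=nanv.copy(), arterial_hu=arterial,
        venous_hu=np.asarray(venous, float),
        av_ratio=av_ratio_curve(arterial, venous, blood),
        arrival_s=arrival, blood_hu=blood)


class TestFindEquilibrium:
    def test_interpolated_crossing_matches_hand_computation(self):
        # ratios [1.5, 0.8]: crossing of 1 at t = 10 + 2 * (0.5 / 0.7)
        curves = curves_from_rois([100.0, 80.0], [80.0, 90.0], [10.0, 12.0])
        np.testing.assert_allclose(curves.av_ratio, [1.5, 0.8])
        assert find_equilibrium(curves) == pytest.approx(10 + 2 * 0.5 / 0.7)

    def test_ratio_always_above_one_not_found(self):
        curves = curves_from_rois([300.0, 200.0, 150.0],
                                  [90.0, 80.0, 70.0], [0.0, 2.0, 4.0])
        with pytest.raises(EquilibriumNotFoundError):
            find_equilibrium(curves)

    def test_exact_unity_sample_returns_its_time(self):
        curves = curves_from_rois([140.0, 90.0, 60.0],
                                  [60.0, 90.0, 80.0], [0.0, 2.0, 4.0])
        # ratios [5, 1, 0.5]: sample at t = 2 is exactly 1
        assert find_equilibrium(curves) == 2.0


class TestNormalize:
    def test_landmark_values(self):
        cfg = random_curve_config(np.random.default_rng(7))
        norm = normalize_av_curve(analytic_roi_tics(cfg))
        assert norm.value_at(norm.t_peak_s) == pytest.approx(1.0, abs=1e-12)
        assert norm.value_at(norm.t_equi_s) == pytest.approx(0.0, abs=1e-9)
        assert norm.t_peak_s < norm.t_equi_s < norm.t_min_s

    def test_normalization_arithmetic(self):
        # raw ratios [3, 1, 0.5, 0.4, 0.6]; peak 3 -> (0.5 - 1)/(3 - 1) = -0.25
        ratios = np.array([3.0, 1.0, 0.5, 0.4, 0.6])
        venous = np.full(5, 140.0)
        arterial = 40.0 + ratios * 100.0
        norm = normalize_av_curve(curves_from_rois(arterial, venous,
                                                   np.arange(5) * 2.0))
        assert norm.normalized[2] == pytest.approx(-0.25)

    def test_flat_curve_degenerate(self):
        curves = curves_from_rois([90.0] * 5, [90.0] * 5, np.arange(5) * 2.0)
        with pytest.raises(DegenerateCurveError):
            normalize_av_curve(curves)

    def test_invariant_to_shared_rescaling_of_excesses(self):
        cfg = random_curve_config(np.random.default_rng(3))
        tics = analytic_roi_tics(cfg)
        scaled = curves_from_rois(40 + 2.5 * (tics.arterial_hu - 40),
                                  40 + 2.5 * (tics.venous_hu - 40),
                                  tics.times_s, arrival=tics.arrival_s)
        a = normalize_av_curve(tics)
        b = normalize_av_curve(scaled)
        np.testing.assert_allclose(a.normalized, b.normalized, atol=1e-10)
        assert a.t_equi_s == pytest.approx(b.t_equi_s)


def synthetic_norm_curve():
    """Hand-built normalized curve with every phase represented."""
    times = np.arange(0.0, 40.0, 2.0)
    values = np.array([0.05, 0.1, 0.3, 0.6, 1.0, 0.8, 0.6, 0.4, 0.2, 0.05,
                       -0.1, -0.2, -0.3, -0.35, -0.3, -0.2, -0.15, -0.1,
                       -0.05, -0.02])
    t_equi = 18.0 + 2.0 * 0.05 / 0.15   # first zero crossing after the peak
    return NormalizedAVCurve(times_s=times, normalized=values, t_peak_s=8.0,
                             t_equi_s=t_equi, t_min_s=26.0,
                             arrival_s=1.0, valid_range=(0.0, 38.0))


class TestClassifyPhase:
    @pytest.mark.parametrize("t,expected", [
        (0.5, Phase.PRE),    # before contrast arrival
        (2.0, Phase.PRE),    # value below the 0.2 upslope threshold
        (6.0, Phase.EA),     # 0.6 on the upslope
        (10.0, Phase.PA),    # 0.8 on the downslope
        (12.5, Phase.PA),    # still above 0.5
        (13.0, Phase.EQ),    # exactly 0.5 -> later phase
        (16.0, Phase.EQ),
        (22.0, Phase.PV),    # -0.2 between equilibrium and minimum
        (26.0, Phase.PV),    # the minimum itself
        (30.0, Phase.LV),
    ])
    def test_examples(self, t, expected):
        assert classify_phase(synthetic_norm_curve(), t) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_phase(synthetic_norm_curve(), 39.9)

    def test_phase_order_along_synthetic_curves(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            norm = normalize_av_curve(analytic_roi_tics(random_curve_config(rng)))
            labels = label_frames(norm)
            ranks = [PHASE_ORDER.index(p) for p in labels]
            assert ranks == sorted(ranks)


def dense_grid_oracle(norm, grid):
    """Brute-force labeler applied directly to the phase definition."""
    v = np.interp(grid, norm.times_s, norm.normalized)
    peak = grid[int(np.argmax(v))]
    post = grid > peak
    t_min = grid[post][int(np.argmin(v[post]))] if post.any() else grid[-1]
    labels = []
    for t, val in zip(grid, v):
        if t < peak:
            if (norm.arrival_s is not None and t < norm.arrival_s) or val < 0.2:
                labels.append(Phase.PRE)
            else:
                labels.append(Phase.EA)
        elif t > t_min:
            labels.append(Phase.LV)
        elif val <= 0.0:
            labels.append(Phase.PV)
        elif val > 0.5:
            labels.append(Phase.PA)
        else:
            labels.append(Phase.EQ)
    return labels


def test_classification_agrees_with_dense_grid_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        norm = normalize_av_curve(analytic_roi_tics(random_curve_config(rng)))
        lo, hi = norm.valid_range
        grid = np.round(np.arange(lo, hi + 1e-9, 0.01), 6)
        ours = [classify_phase(norm, float(t)) for t in grid]
        assert ours == dense_grid_oracle(norm, grid)
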