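import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neuropet import (
    SRTMParams,
    TimeActivityCurve,
    auto_tstar,
    cumulative_integral,
    dvr_map,
    logan_fit,
    roi_means,
    simulate_subject,
    srtm_tac,
)
from neuropet.logan_kinetics import _logan_xy, _ols_line

positive_tacs = st.lists(st.floats(0.1, 100.0), min_size=22, max_size=22)


class TestCumulativeIntegral:
    def test_constant_tac_closed_form(self, schedule):
        tac = TimeActivityCurve(np.full(22, 2.5), schedule)
        out = cumulative_integral(tac)
        assert out[-1] == pytest.approx(2.5 * 3600.0)

    def test_unit_tac_totals_3600_activity_seconds(self, schedule):
        tac = TimeActivityCurve(np.ones(22), schedule)
        assert cumulative_integral(tac)[-1] == pytest.approx(3600.0)

    def test_matches_step_function_quadrature(self, schedule):
        rng = np.random.default_rng(1)
        vals = rng.random(22) * 10
        tac = TimeActivityCurve(vals, schedule)
        out = cumulative_integral(tac)
        # oracle: 1-s Riemann sum over the frame-averaged step function
        t = np.arange(0, 3600)
        step = vals[np.searchsorted(schedule.end, t, side="right")]
        oracle = np.cumsum(step)
        for i, end in enumerate(schedule.end):
            assert out[i] == pytest.approx(oracle[int(end) - 1], rel=1e-12)

    def test_non_decreasing_for_nonnegative(self, schedule):
        tac = TimeActivityCurve(np.linspace(0, 5, 22), schedule)
        assert np.all(np.diff(cumulative_integral(tac)) >= 0)


class TestLoganFit:
    @given(positive_tacs)
    def test_self_reference_identity(self, schedule, values):
        tac = TimeActivityCurve(np.asarray(values), schedule)
        fit = logan_fit(tac, tac, tstar=30.0)
        assert fit.dvr == pytest.approx(1.0, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)

    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, schedule, ref_tac, fine_ref, c):
        tac = srtm_tac(fine_ref, SRTMParams(BP=0.3), schedule)
        base = logan_fit(tac, ref_tac, tstar=30.0)
        scaled = logan_fit(
            TimeActivityCurve(tac.values * c, schedule),
            TimeActivityCurve(ref_tac.values * c, schedule),
            tstar=30.0,
        )
        assert scaled.dvr == pytest.approx(base.dvr, rel=1e-9)
        assert scaled.r2 == pytest.approx(base.r2, rel=1e-9)

    def test_slope_matches_normal_equations_oracle(self, schedule, ref_tac,
                                                   fine_ref):
        tac = srtm_tac(fine_ref, SRTMParams(BP=-0.144), schedule)
        sel = schedule.mid / 60.0 >= 30.0
        x, y = _logan_xy(tac.values, ref_tac, sel, None)
        # brute-force normal equations
        A = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        fit = logan_fit(tac, ref_tac, tstar=30.0)
        assert fit.dvr == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_srtm_dvr_0856_recovered(self, schedule, ref_tac, fine_ref):
        tac = srtm_tac(fine_ref, SRTMParams(R1=1.0, k2=0.4, BP=-0.144), schedule)
        fit = logan_fit(tac, ref_tac, tstar=30.0)
        assert fit.dvr == pytest.approx(0.856, rel=0.01)
        assert fit.n_points == 6

    def test_tstar_beyond_scan_rejected(self, schedule, ref_tac):
        with pytest.raises(ValueError, match="no frames at or beyond"):
            logan_fit(ref_tac, ref_tac, tstar=70.0)

    def test_mismatched_schedules_rejected(self, schedule, ref_tac):
        from neuropet import FrameSchedule

        other = FrameSchedule(np.array([0.0, 60, 120]), np.array([60.0, 60, 60]))
        short = TimeActivityCurve(np.ones(3), other)
        with pytest.raises(ValueError, match="share a frame schedule"):
            logan_fit(short, ref_tac)

    def test_k2prime_variant_close_to_classic_at_equilibrium(self, schedule,
                                                             ref_tac, fine_ref):
        tac = srtm_tac(fine_ref, SRTMParams(BP=0.5), schedule)
        classic = logan_fit(tac, ref_tac, tstar=30.0)
        corrected = logan_fit(tac, ref_tac, tstar=30.0, k2prime=0.4)
        assert corrected.dvr == pytest.approx(classic.dvr, rel=0.02)

    def test_auto_tstar_accepts_linear_curve(self, schedule, ref_tac, fine_ref):
        tac = srtm_tac(fine_ref, SRTMParams(BP=0.3), schedule)
        t = auto_tstar(tac, ref_tac)
        assert t in (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
        fit = logan_fit(tac, ref_tac, tstar=t)
        assert fit.dvr == pytest.approx(1.3, rel=0.02)


class TestOlsKernel:
    def test_broadcasts_over_leading_axis(self):
        rng = np.random.default_rng(2)
        x = rng.random((5, 8))
        y = 2.0 * x + 1.0 + 0.01 * rng.random((5, 8))
        slope, intercept, r2 = _ols_line(x, y)
        assert slope.shape == (5,)
        for i in range(5):
            s, b, r = _ols_line(x[i], y[i])
            assert slope[i] == pytest.approx(float(s))
            assert intercept[i] == pytest.approx(float(b))


class TestDvrMap:
    def test_noiseless_per_label_recovery(self, atlas32, schedule):
        dvrs = {1: 1.0, 2: 1.1, 3: 0.9, 4: 1.0, 5: 0.6}
        img = simulate_subject(atlas32, dvrs, schedule, noise_scale=0.0, seed=0)
        table = roi_means(dvr_map(img, atlas32, tstar=30.0), atlas32)
        for _, row in table.iterrows():
            assert row["mean_dvr"] == pytest.approx(dvrs[row["label"]], rel=0.01)

    def test_all_zero_image_gives_all_nan_map(self, atlas16, schedule):
        from neuropet import DynamicImage

        img = DynamicImage(
            data=np.zeros(atlas16.labels.shape + (22,)),
            affine=atlas16.affine, schedule=schedule,
        )
        m = dvr_map(img, atlas16, tstar=30.0)
        assert np.all(np.isnan(m.data))

    def test_reference_region_mean_is_one_under_noise(self, atlas16, schedule,
                                                      label_dvr_unit):
        """Monte-Carlo: reference-region mean DVR = 1.00 +/- 0.02."""
        for rep in range(10):
            img = simulate_subject(atlas16, label_dvr_unit, schedule,
                                   noise_scale=0.05, seed=200 + rep)
            m = dvr_map(img, atlas16, tstar=30.0)
            ref_mean = np.nanmean(m.data[atlas16.role_mask("reference_region")])
            assert ref_mean == pytest.approx(1.0, abs=0.02)

    def test_nan_confined_to_outside_analysis_mask(self, atlas16, schedule,
                                                   label_dvr_unit):
        img = simulate_subject(atlas16, label_dvr_unit, schedule,
                               noise_scale=0.0, seed=0)
        m = dvr_map(img, atlas16, tstar=30.0)
        mask = atlas16.analysis_mask()
        assert np.all(np.isfinite(m.data[mask]))
        assert np.all(np.isnan(m.data[~mask]))
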