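"""Gamma-variate fitting and maximum-slope perfusion estimation."""

import numpy as np
import pytest

import liverkin as lk
from liverkin.maxslope import (
    GammaFit,
    NoInteriorPeakError,
    fit_gamma_variate,
    gamma_variate,
    max_upslope,
    perfusion_from_slopes,
    perfusion_params,
    time_to_peak,
)
from liverkin.tac import DomainError, FrameSchedule, TimeActivityCurve


def _sampled_gamma(y_max=10.0, t_max=15.0, alpha=3.0, t0=5.0, groups="24x5"):
    sched = FrameSchedule.from_groups(groups)
    vals = gamma_variate(sched.mid_s, y_max, t_max, alpha, t0)
    return TimeActivityCurve(sched, vals, roi_kind="aorta")


class TestGammaVariate:
    def test_peak_identity_and_onset_limit(self):
        g = GammaFit(10.0, 15.0, 3.0, 5.0, (0.0, 60.0))
        assert g.curve(np.array([g.t0 + g.t_max]))[0] == pytest.approx(10.0, rel=1e-12)
        # power-law onset: Y -> 0 as t -> t0+
        eps = np.array([5.0 + 1e-6])
        assert g.curve(eps)[0] < 1e-10
        assert np.all(g.curve(np.array([0.0, 5.0])) == 0.0)

    def test_refit_recovers_noiseless_parameters(self):
        """Forward-simulate-then-refit oracle at 1% tolerance."""
        tac = _sampled_gamma()
        g = fit_gamma_variate(tac)
        assert g.y_max == pytest.approx(10.0, rel=0.01)
        assert g.t_max == pytest.approx(15.0, rel=0.01)
        assert g.alpha == pytest.approx(3.0, rel=0.01)
        assert g.t0 == pytest.approx(5.0, abs=0.15)

    def test_default_window_requires_interior_peak(self):
        sched = FrameSchedule.from_groups("10x5")
        rising = TimeActivityCurve(sched, np.linspace(0, 9, 10))
        with pytest.raises(NoInteriorPeakError):
            fit_gamma_variate(rising)
        # an explicit window waives the requirement
        g = fit_gamma_variate(rising, window=(0.0, 50.0), baseline=True)
        assert g.alpha > 0

    def test_window_with_too_few_frames_rejected(self):
        tac = _sampled_gamma()
        with pytest.raises(DomainError):
            fit_gamma_variate(tac, window=(0.0, 11.0))

    def test_baseline_pedestal_fit(self):
        sched = FrameSchedule.from_groups("24x5")
        vals = 2.0 + gamma_variate(sched.mid_s, 5.0, 20.0, 3.0, 10.0)
        tac = TimeActivityCurve(sched, vals)
        g = fit_gamma_variate(tac, window=(0.0, 120.0), baseline=True)
        assert g.baseline == pytest.approx(2.0, abs=0.05)
        assert g.y_max == pytest.approx(5.0, rel=0.02)


class TestMaxUpslope:
    def test_maximiser_position_alpha_four(self):
        g = GammaFit(10.0, 20.0, 4.0, 3.0, (0.0, 60.0))
        s = max_upslope(g)
        # 1 - 1/sqrt(4) = 0.5 -> maximiser at t0 + 10 s
        assert s.t_at_s == pytest.approx(13.0, abs=1e-6)
        assert not s.degenerate_onset

    def test_slope_matches_finite_difference_oracle(self):
        g = GammaFit(10.0, 15.0, 3.0, 5.0, (0.0, 60.0))
        s = max_upslope(g)
        ts = np.arange(g.t0, g.t0 + 3 * g.t_max, 0.01)
        fd = np.max(np.diff(g.curve(ts)) / 0.01)
        assert s.slope == pytest.approx(fd, rel=1e-3)

    def test_linear_scaling_in_y_max(self):
        g1 = GammaFit(10.0, 15.0, 3.0, 5.0, (0.0, 60.0))
        g2 = GammaFit(20.0, 15.0, 3.0, 5.0, (0.0, 60.0))
        assert max_upslope(g2).slope == pytest.approx(
            2.0 * max_upslope(g1).slope, rel=1e-12
        )

    def test_degenerate_onset_flagged_for_small_alpha(self):
        g = GammaFit(10.0, 15.0, 0.8, 5.0, (0.0, 60.0))
        s = max_upslope(g, window=(5.0, 40.0))
        assert s.degenerate_onset
        assert s.slope > 0

    def test_window_clipping_picks_boundary(self):
        g = GammaFit(10.0, 20.0, 4.0, 0.0, (0.0, 60.0))
        # unconstrained maximiser at 10 s; a window ending earlier clips it
        s = max_upslope(g, window=(0.0, 5.0))
        assert s.t_at_s == pytest.approx(5.0)
        assert s.slope == pytest.approx(g.slope(np.array([5.0]))[0], rel=1e-12)


class TestPerfusionArithmetic:
    def test_hand_computed_hap(self):
        p = perfusion_from_slopes(0.02, 10.0, 0.01, 10.0)
        assert p.hap == pytest.approx(12.0)  # 0.002 * 6000
        assert p.tlp == p.hap + p.hvp

    def test_symmetric_supply_gives_half(self):
        p = perfusion_from_slopes(0.03, 10.0, 0.06, 20.0)
        assert p.hpi == pytest.approx(0.5)

    def test_zero_arterial_slope(self):
        p = perfusion_from_slopes(0.0, 10.0, 0.01, 10.0)
        assert p.hap == 0.0 and p.hpi == 0.0 and p.tlp == p.hvp

    def test_zero_vessel_peak_rejected(self):
        with pytest.raises(DomainError):
            perfusion_from_slopes(0.02, 0.0, 0.01, 10.0)

    def test_zero_total_perfusion_reported_missing(self):
        p = perfusion_from_slopes(0.0, 10.0, 0.0, 10.0)
        assert np.isnan(p.hpi)


class TestTimeToPeak:
    def test_peak_difference(self):
        aorta = GammaFit(30.0, 20.0, 4.0, 0.0, (0.0, 60.0))
        roi = GammaFit(5.0, 30.0, 3.0, 10.0, (0.0, 60.0))
        assert time_to_peak(roi, aorta) == pytest.approx(20.0)
        assert time_to_peak(aorta, aorta) == 0.0

    def test_hcc_peaks_before_background_liver(self, ifp):
        """Arterially-fed lesions peak earlier than portally-fed liver:
        the TTP distributions separate at the group level."""
        sched = lk.make_schedule("short_term")
        rng = np.random.default_rng(2)
        med = {}
        for grp in ("hcc", "liver"):
            dist = lk.GroupDistribution.from_table(f"combined_{grp}")
            ttps = []
            for _, row in dist.sample(6, rng).iterrows():
                p = lk.KineticParams(**{k: float(row[k]) for k in
                                        ("k1", "k2", "k3", "k4", "hpi", "vb")})
                s = lk.simulate_subject(p, ifp, sched, noise_cv=0.02, rng=rng)
                perf = perfusion_params(s.tissue, s.aorta, s.portal_vein, s.spleen)
                ttps.append(perf.ttp_s)
            med[grp] = np.median(ttps)
        assert med["hcc"] < med["liver"]


class TestPerfusionPipeline:
    def test_tlp_identity_and_scale_invariant_hpi(self, hcc_subject_noiseless):
        s = hcc_subject_noiseless
        perf = perfusion_params(s.tissue, s.aorta, s.portal_vein, s.spleen)
        assert perf.tlp == perf.hap + perf.hvp
        c = 3.7
        scaled = {
            k: t.with_values(t.values * c) for k, t in s.tacs().items()
        }
        perf_c = perfusion_params(
            scaled["tissue"], scaled["aorta"], scaled["portal_vein"], scaled["spleen"]
        )
        assert perf_c.hpi == pytest.approx(perf.hpi, abs=1e-6)
        assert perf_c.hap == pytest.approx(perf.hap, rel=1e-5)

    def test_frame_slope_mode_runs(self, hcc_subject_noiseless):
        s = hcc_subject_noiseless
        perf = perfusion_params(
            s.tissue, s.aorta, s.portal_vein, s.spleen, slope_source="frames"
        )
        assert perf.tlp > 0

    def test_toy_flow_recovery(self):
        """Delay-free toy: tissue uptake F * int C_B recovers F within 5%
        (brute-force oracle: the analytic slope of the uptake curve is
        F * C_B, maximised at the input peak)."""
        F = 0.01
        sched = FrameSchedule.from_groups("40x2")
        t = sched.mid_s
        fine = np.arange(0.0, 80.001, 0.01)
        bolus = gamma_variate(fine, 20.0, 25.0, 3.0, 5.0)
        cum = np.cumsum(bolus) * 0.01
        tac_in = TimeActivityCurve(
            sched, gamma_variate(t, 20.0, 25.0, 3.0, 5.0), roi_kind="aorta"
        )
        tac_tis = TimeActivityCurve(sched, F * np.interp(t, fine, cum))
        g_in = fit_gamma_variate(tac_in)
        g_tis = fit_gamma_variate(tac_tis, window=(0.0, 60.0), baseline=True,
                                  min_alpha=1.0)
        slope = max_upslope(g_tis, window=(g_tis.t0, 60.0)).slope
        assert slope / g_in.y_max == pytest.approx(F, rel=0.05)
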