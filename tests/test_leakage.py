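"""Side-branch leakage models and the Huo-Kassab flow budget."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vffr1d as v
from vffr1d.errors import DomainError, LeakageError, SimulationFailure
from vffr1d.leakage import leak_conductance, leak_homogenous, leak_localized, leak_none
from vffr1d.solver import march_pressure
from tests.conftest import PA_SI, identity_segmentation

Q_IN = 4e-6  # m^3/s (240 mL/min)


class TestHuoKassab:
    def test_no_taper_no_leak(self):
        assert v.huo_kassab_flow_ratio(1.2e-3, 1.2e-3) == 1.0
        assert v.side_branch_budget(Q_IN, 1.2e-3, 1.2e-3) == 0.0

    def test_reconstruction_scale_taper(self):
        # mean inlet/outlet diameters 2.7 and 1.9 mm: leak roughly equals
        # outlet flow (ratio just above 2)
        ratio = v.huo_kassab_flow_ratio(1.35e-3, 0.95e-3)
        assert ratio == pytest.approx(2.2703, abs=5e-4)
        budget = v.side_branch_budget(Q_IN, 1.35e-3, 0.95e-3)
        q_out = Q_IN - budget
        assert budget == pytest.approx(q_out, rel=0.30)

    def test_analytic_inversion(self):
        assert v.huo_kassab_flow_ratio(2 ** (3 / 7), 1.0) == pytest.approx(2.0, rel=1e-14)

    @pytest.mark.parametrize("r_in,r_out", [(0.0, 1e-3), (1e-3, 0.0), (-1e-3, 1e-3)])
    def test_domain(self, r_in, r_out):
        with pytest.raises(DomainError):
            v.huo_kassab_flow_ratio(r_in, r_out)

    @settings(max_examples=50, derandomize=True)
    @given(r_in=st.floats(0.5e-3, 2.5e-3), r_out=st.floats(0.5e-3, 2.5e-3))
    def test_ratio_monotone_and_positive(self, r_in, r_out):
        ratio = v.huo_kassab_flow_ratio(r_in, r_out)
        assert ratio > 0
        if r_in > r_out:
            assert ratio > 1
        budget = v.side_branch_budget(Q_IN, r_in, r_out)
        assert 0.0 <= budget < Q_IN


class TestNoLeak:
    def test_zero_everywhere(self, tapered_profile, tapered_segmentation):
        leak = leak_none(tapered_profile, tapered_segmentation)
        assert not leak.q.any()
        assert leak.total_leak == 0.0

    def test_axial_flow_constant(self, tapered_profile, tapered_segmentation, fluid):
        _, qflow, reason = march_pressure(tapered_profile, tapered_segmentation,
                                          np.zeros(200), Q_IN, PA_SI, fluid)
        assert reason is None
        np.testing.assert_allclose(qflow, Q_IN, rtol=1e-14)


class TestHomogenous:
    def test_untapered_tube_zero_budget(self, uniform_profile, uniform_segmentation):
        leak = leak_homogenous(uniform_profile, uniform_segmentation, Q_IN)
        assert not leak.q.any()

    def test_uniform_density_without_stenosis(self, tapered_profile, tapered_segmentation):
        leak = leak_homogenous(tapered_profile, tapered_segmentation, Q_IN)
        expected = leak.total_leak / tapered_profile.length
        np.testing.assert_allclose(leak.q, expected, rtol=1e-9)

    def test_renormalisation_over_stenosed_middle_third(self):
        """Quadrature oracle: q doubles nowhere but rescales to the healthy arc."""
        prof = v.generate_vessel(v.VesselSpec(length_mm=30, r_in_mm=1.35, r_out_mm=0.95))
        n = prof.n_points
        mask = np.zeros(n, bool)
        mask[n // 3: 2 * n // 3] = True
        seg = v.HealthySegmentation(r_healthy=prof.r, area_ratio=np.ones(n),
                                    stenosed_mask=mask,
                                    stenosis_intervals=((n // 3, 2 * n // 3),))
        leak = leak_homogenous(prof, seg, Q_IN)
        assert not leak.q[mask].any()
        # direct quadrature of the indicator gives the renormalising arc length
        coverage = np.trapezoid((~mask).astype(float), prof.s)
        np.testing.assert_allclose(leak.q[~mask], leak.total_leak / coverage, rtol=1e-9)
        assert np.trapezoid(leak.q, prof.s) == pytest.approx(leak.total_leak, rel=1e-10)

    def test_fully_stenosed_vessel_rejected(self, tapered_profile):
        n = tapered_profile.n_points
        seg = v.HealthySegmentation(r_healthy=tapered_profile.r,
                                    area_ratio=np.ones(n),
                                    stenosed_mask=np.ones(n, bool),
                                    stenosis_intervals=((0, n),))
        with pytest.raises(LeakageError):
            leak_homogenous(tapered_profile, seg, Q_IN)


class TestLocalized:
    def test_untapered_tube(self, uniform_profile, uniform_segmentation):
        leak = leak_localized(uniform_profile, uniform_segmentation, Q_IN)
        assert not leak.q.any()

    def test_step_taper_concentrates_leak_at_the_step(self):
        prof = v.generate_vessel(v.VesselSpec(length_mm=30, r_in_mm=1.3, r_out_mm=1.0,
                                              taper_mode="stepped", n_steps=1))
        seg = identity_segmentation(prof)
        leak = leak_localized(prof, seg, Q_IN)
        # all weight lives on the few points around the radius step
        step = np.argmin(np.abs(prof.r - 1.15e-3))
        window = np.zeros(prof.n_points, bool)
        window[step - 3: step + 4] = True
        inside = np.trapezoid(np.where(window, leak.q, 0.0), prof.s)
        assert inside == pytest.approx(leak.total_leak, rel=1e-6)

    def test_radius_recovery_region_does_not_leak(self):
        # taper, then a recovery segment where the radius increases again
        s = np.linspace(0.0, 0.03, 200)
        r = np.where(s < 0.015, 1.4e-3 - (s / 0.015) * 0.3e-3,
                     1.1e-3 + ((s - 0.015) / 0.015) * 0.1e-3)
        prof = v.CentrelineProfile(s=s, r=r)
        leak = leak_localized(prof, identity_segmentation(prof), Q_IN)
        recovery = s > 0.0155
        assert not leak.q[recovery].any()

    def test_budget_integral(self, tapered_profile, tapered_segmentation):
        leak = leak_localized(tapered_profile, tapered_segmentation, Q_IN)
        assert np.trapezoid(leak.q, tapered_profile.s) == pytest.approx(
            leak.total_leak, rel=1e-10)

    def test_fallback_when_all_taper_is_stenosed(self):
        """Taper confined to a flagged interval falls back to a uniform spread."""
        s = np.linspace(0.0, 0.03, 200)
        r = np.interp(s, [0, 0.014, 0.016, 0.03], [1.3e-3, 1.3e-3, 1.0e-3, 1.0e-3])
        prof = v.CentrelineProfile(s=s, r=r)
        mask = (s >= 0.0135) & (s <= 0.0165)
        seg = v.HealthySegmentation(r_healthy=r, area_ratio=np.ones(200),
                                    stenosed_mask=mask,
                                    stenosis_intervals=((int(np.argmax(mask)),
                                                         int(len(s) - np.argmax(mask[::-1]))),))
        leak = leak_localized(prof, seg, Q_IN)
        assert "uniform fallback" in leak.notes
        assert np.trapezoid(leak.q, s) == pytest.approx(leak.total_leak, rel=1e-10)


class TestConductance:
    def test_unstenosed_matches_localized(self, tapered_profile, tapered_segmentation, fluid):
        res = v.simulate_at_flow(tapered_profile, tapered_segmentation,
                                 "conductance", Q_IN, PA_SI, fluid)
        base = leak_localized(tapered_profile, tapered_segmentation, Q_IN)
        assert res.converged
        # recovered leak field: d(Q)/ds
        q_rec = -np.gradient(res.qflow, tapered_profile.s)
        healthy = base.q > 0
        np.testing.assert_allclose(q_rec[healthy][2:-2], base.q[healthy][2:-2], rtol=0.02)

    def test_distal_leak_reduced_behind_stenosis(self, fluid):
        """Identical step tapers straddling a stenosis: distal step leaks
        less, by roughly the local pressure ratio."""
        spec = v.VesselSpec(length_mm=40, r_in_mm=1.4, r_out_mm=1.0,
                            taper_mode="stepped", n_steps=2,
                            stenoses=(v.Stenosis(0.5, 0.6, 1.0),))
        prof = v.generate_vessel(spec)
        seg = v.estimate_and_segment(prof)
        q_in = 2e-6
        res = v.simulate_at_flow(prof, seg, "conductance", q_in, PA_SI, fluid)
        assert res.converged
        # healthy-configuration reference pressure for the conductance field
        prof_h = v.CentrelineProfile(s=prof.s, r=seg.r_healthy)
        seg_h = v.HealthySegmentation.all_healthy(prof_h)
        base_h = leak_localized(prof_h, seg_h, q_in)
        p_h, _, _ = march_pressure(prof_h, seg_h, base_h.q, q_in, PA_SI, fluid)
        leak = leak_conductance(prof, seg, q_in, res.p, p_reference=p_h)
        loc = leak_localized(prof, seg, q_in)
        end = seg.stenosis_intervals[-1][1]
        assert np.all(leak.q[end:] <= loc.q[end:] + 1e-18)
        # normalised by the anatomical (localized) distribution, the leak
        # attenuation between the two steps tracks the pressure ratio
        n3 = prof.n_points // 3
        i_prox = int(np.argmax(loc.q[:n3]))
        i_dist = 2 * n3 + int(np.argmax(loc.q[2 * n3:]))
        atten = (leak.q[i_dist] / loc.q[i_dist]) / (leak.q[i_prox] / loc.q[i_prox])
        p_ratio = res.p[i_dist] / res.p[i_prox]
        assert atten == pytest.approx(p_ratio, rel=0.05)
        assert atten < 1.0

    def test_zero_flow_limit_reproduces_localized(self, tapered_profile,
                                                  tapered_segmentation, fluid):
        q_small = 1e-9  # vanishing viscous loss: P uniform, conductance = localized
        res = v.simulate_at_flow(tapered_profile, tapered_segmentation,
                                 "conductance", q_small, PA_SI, fluid)
        base = leak_localized(tapered_profile, tapered_segmentation, q_small)
        q_rec = -np.gradient(res.qflow, tapered_profile.s)
        healthy = base.q > 0
        np.testing.assert_allclose(q_rec[healthy][2:-2], base.q[healthy][2:-2], rtol=1e-3)

    def test_rejects_non_positive_pressure(self, tapered_profile, tapered_segmentation):
        p = np.full(200, PA_SI)
        p[50] = -1.0
        with pytest.raises(SimulationFailure):
            leak_conductance(tapered_profile, tapered_segmentation, Q_IN, p)


class TestPorosity:
    def test_untapered_tube_is_no_leak(self, uniform_profile, uniform_segmentation, fluid):
        res_p = v.simulate_at_flow(uniform_profile, uniform_segmentation,
                                   "porosity", Q_IN, PA_SI, fluid)
        res_n = v.simulate_at_flow(uniform_profile, uniform_segmentation,
                                   "none", Q_IN, PA_SI, fluid)
        assert res_p.converged
        np.testing.assert_allclose(res_p.p, res_n.p, rtol=1e-12)
        np.testing.assert_allclose(res_p.qflow, Q_IN, rtol=1e-12)

    def test_calibration_reproduces_huo_kassab(self, tapered_profile,
                                               tapered_segmentation, fluid):
        res = v.simulate_at_flow(tapered_profile, tapered_segmentation,
                                 "porosity", Q_IN, PA_SI, fluid)
        assert res.converged
        expected = v.huo_kassab_flow_ratio(tapered_profile.r_in, tapered_profile.r_out)
        assert Q_IN / res.q_out == pytest.approx(expected, rel=0.005)

    def test_requires_calibrated_mobility(self, tapered_profile, tapered_segmentation,
                                          fluid):
        with pytest.raises(DomainError):
            v.leak_porosity(tapered_profile, tapered_segmentation,
                            np.full(200, PA_SI), v.PorosityConfig(), fluid)

    def test_rejects_non_positive_pressure(self, tapered_profile, tapered_segmentation,
                                           fluid):
        p = np.zeros(200)
        with pytest.raises(SimulationFailure):
            v.leak_porosity(tapered_profile, tapered_segmentation, p,
                            v.PorosityConfig(darcy_kappa=1e-9), fluid)


@pytest.mark.parametrize("model", ["homogenous", "localized", "conductance", "porosity"])
def test_no_leak_at_stenosed_points_and_non_negative(model, stenosed_profile,
                                                     stenosed_segmentation, fluid):
    res = v.simulate_at_flow(stenosed_profile, stenosed_segmentation, model,
                             2e-6, PA_SI, fluid)
    assert res.converged
    mask = stenosed_segmentation.stenosed_mask
    # flow is constant through the stenosis: no leakage inside
    inner = np.flatnonzero(mask)
    assert np.max(np.abs(np.diff(res.qflow[inner]))) < 1e-18
    # leakage never reverses into the vessel
    assert np.all(np.diff(res.qflow) <= 1e-18)


@pytest.mark.parametrize("model", v.MODEL_IDS)
def test_no_taper_degeneracy(model, uniform_profile, uniform_segmentation, fluid):
    """With zero taper the side-branch budget vanishes: all five models
    reproduce the no-leak pressure field."""
    ref = v.simulate_at_flow(uniform_profile, uniform_segmentation, "none",
                             3e-6, PA_SI, fluid)
    res = v.simulate_at_flow(uniform_profile, uniform_segmentation, model,
                             3e-6, PA_SI, fluid)
    assert res.converged
    np.testing.assert_allclose(res.p, ref.p, rtol=1e-9)
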