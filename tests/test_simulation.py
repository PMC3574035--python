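"""Integrator, schedules, steady-state solver and parameter scans."""

import numpy as np
import pytest

from cholsim import (
    BoundarySet,
    Model,
    ModelOptions,
    ParameterSet,
    Schedule,
    ScheduleEntry,
    StateVector,
    integrate,
    make_ramp,
    parameter_scan,
    steady_state,
)
from cholsim.model import PARAMETER_NAMES


def zero_rate_params() -> ParameterSet:
    zeros = {n: 0.0 for n in PARAMETER_NAMES
             if n.startswith("k") or n in ("khrs", "kprs", "HRS", "PRS")}
    zeros.update({n: 0.0 for n in ("ICSmax", "BCRmax", "HCSmax", "PCSmax")})
    return ParameterSet.default().replace(**zeros)


class TestIntegrate:
    def test_zero_span_returns_initial_state(self, default_model):
        m = default_model
        traj = integrate(m.params, m.boundaries, m.state, 0.0)
        assert traj.times.tolist() == [0.0]
        np.testing.assert_array_equal(traj.ys[0], m.state.to_array())

    def test_zero_rates_constant_trajectory(self):
        p = zero_rate_params()
        s0 = StateVector.default()
        traj = integrate(p, BoundarySet(), s0, 50.0)
        expected = np.tile(s0.to_array(), (len(traj.times), 1))
        np.testing.assert_allclose(traj.ys, expected, rtol=0, atol=1e-12)

    def test_excretion_sinks_increase_over_100_days(self, default_model):
        """Faecal cholesterol and bile-salt losses accumulate monotonically."""
        m = default_model
        traj = integrate(m.params, m.boundaries, m.state, 100.0,
                         t_eval=np.linspace(0, 100, 51))
        assert np.all(np.diff(traj["EC"]) > 0)
        assert np.all(np.diff(traj["EBS"]) > 0)

    def test_all_sinks_nondecreasing(self, calibrated_model):
        m = calibrated_model
        traj = integrate(m.params, m.boundaries, m.state, 2000.0,
                         t_eval=np.linspace(0, 2000, 60))
        for sink in ("EC", "EBS", "PSS", "HLDLRD", "PLDLRD"):
            assert np.all(np.diff(traj[sink]) >= 0), sink

    def test_clamped_species_stay_fixed(self, default_model):
        m = default_model
        traj = integrate(m.params, m.boundaries, m.state, 200.0,
                         clamp=("NHDL", "HFC"))
        assert traj["NHDL"][-1] == m.state.NHDL
        assert traj["HFC"][-1] == m.state.HFC

    def test_schedule_breakpoints_recorded(self, default_model):
        m = default_model
        sched = make_ramp("DC", 10.0, 20.0, 304.0, 500.0)
        traj = integrate(m.params, m.boundaries, m.state, 30.0, schedule=sched)
        assert traj.events == (10.0, 20.0)


class TestSchedule:
    def test_ramp_endpoints_and_midpoint(self):
        sched = make_ramp("khrs", 0.0, 16_425.0, 100.0, 50.0)
        assert sched.value_at("khrs", -5.0) == 100.0
        assert sched.value_at("khrs", 0.0) == 100.0
        assert sched.value_at("khrs", 16_425.0 / 2) == pytest.approx(75.0)
        assert sched.value_at("khrs", 16_425.0) == 50.0
        assert sched.value_at("khrs", 99_999.0) == 50.0

    def test_constant_ramp(self):
        sched = make_ramp("k6", 0.0, 10.0, 2.0, 2.0)
        for t in (0.0, 3.3, 10.0, 50.0):
            assert sched.value_at("k6", t) == 2.0

    def test_step_shape(self):
        e = ScheduleEntry("DC", 5.0, 5.0, 304.0, 600.0, shape="step")
        assert e.value_at(4.999) == 304.0
        assert e.value_at(5.0) == 600.0

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="unknown schedule target"):
            make_ramp("not_a_parameter", 0.0, 1.0, 0.0, 1.0)

    def test_overlapping_entries_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            Schedule(entries=(
                ScheduleEntry("k6", 0.0, 10.0, 1.0, 2.0),
                ScheduleEntry("k6", 5.0, 15.0, 2.0, 3.0),
            ))

    def test_applied_ramp_reaches_endpoint(self, default_model):
        m = default_model
        sched = make_ramp("DC", 0.0, 50.0, 304.0, 604.0)
        traj = integrate(m.params, m.boundaries, m.state, 50.0, schedule=sched,
                         t_eval=np.linspace(0, 50, 11))
        # intake flux at the end reflects DC = 604
        d_end = traj.final_state
        assert sched.value_at("DC", 50.0) == 604.0
        assert d_end.IC > m.state.IC  # extra intake accumulated


class TestSteadyState:
    def test_clamped_cascade_matches_closed_form(self, default_model):
        """With the hepatic pool, receptors and HDL-C held fixed (and CETP
        transfer gains off), the lipoprotein cascade is linear and solvable in
        closed form; the root-finder must reproduce it."""
        m = default_model
        p, b, s = m.params, m.boundaries, m.state
        opts = ModelOptions(strict_paper_cetp=True)
        clamp = ("HFC", "HLDLR", "PLDLR", "HDLC")
        ss = steady_state(p, b, s, mode="rootfind", options=opts,
                          clamp=clamp, tol=1e-10)
        v_star = p.k12 * s.HFC / (p.k14 * s.HLDLR + p.k15 * b.LPL)
        i_star = p.k15 * b.LPL * v_star / (p.k16 * s.HLDLR + p.k17 * b.HSL)
        l_star = (p.k17 * b.HSL * i_star - p.k21) / (
            p.k18 * s.HLDLR + p.k19 + p.k20 * s.PLDLR)
        assert ss["VLDLC"] == pytest.approx(v_star, rel=1e-9)
        assert ss["IDLC"] == pytest.approx(i_star, rel=1e-9)
        assert ss["LDLC"] == pytest.approx(l_star, rel=1e-9)
        # clamped species were not moved
        for name in clamp:
            assert ss[name] == getattr(s, name)

    def test_zero_input_plasma_drains(self):
        """No intake, no VLDL export, no synthesis, no HDL scavenging:
        every plasma lipoprotein fraction decays towards zero."""
        p = ParameterSet.default().replace(
            k1=0.0, k12=0.0, k26=0.0,
            ICSmax=0.0, HCSmax=0.0, PCSmax=0.0)
        m = Model.default()
        # the hepatic pool is held fixed: without synthesis it would slowly
        # drain to the singular boundary, which is not what this test probes
        traj = integrate(p, m.boundaries, m.state, 5000.0,
                         clamp=("NHDL", "HFC", "PFC"),
                         rtol=1e-6, atol=1e-6)
        f = traj.final_state
        for sp in ("VLDLC", "IDLC", "LDLC", "HDLC"):
            assert getattr(f, sp) < 1e-3, sp

    def test_integrate_mode_agrees_with_rootfind(self, calibrated_model):
        m = calibrated_model
        ss_root = steady_state(m.params, m.boundaries, m.state,
                               mode="rootfind", tol=1e-8)
        ss_int = steady_state(m.params, m.boundaries, m.state,
                              mode="integrate", tol=1e-6)
        for sp in ("VLDLC", "IDLC", "LDLC", "HDLC", "HFC", "PFC", "HLDLR"):
            assert ss_int[sp] == pytest.approx(ss_root[sp], rel=1e-3), sp

    def test_longer_integration_stays_put(self, calibrated_model):
        """Once the residual tolerance is met, integrating 10x longer moves
        no included species by more than 0.1%."""
        m = calibrated_model
        ss = steady_state(m.params, m.boundaries, m.state, tol=1e-8)
        traj = integrate(m.params, m.boundaries, ss.state, 40_000.0,
                         clamp=("NHDL",))
        f = traj.final_state
        for sp in ("VLDLC", "IDLC", "LDLC", "HDLC", "HFC", "PFC",
                   "HLDLR", "PLDLR", "IC", "IBS", "HBS", "HCE", "PCE"):
            assert getattr(f, sp) == pytest.approx(ss[sp], rel=1e-3), sp

    def test_excluded_species_reported(self, calibrated_model):
        m = calibrated_model
        ss = steady_state(m.params, m.boundaries, m.state, tol=1e-7)
        assert set(("EC", "EBS", "PSS", "HLDLRD", "PLDLRD", "NHDL")) <= set(
            ss.excluded)


class TestParameterScan:
    def test_singleton_scan_equals_steady_state(self, calibrated_model):
        m = calibrated_model
        ss = steady_state(m.params, m.boundaries, m.state, tol=1e-7)
        scan = parameter_scan(m.params, m.boundaries, m.state, "k1", [m.params.k1])
        assert scan.results[0]["LDLC"] == pytest.approx(ss["LDLC"], rel=1e-6)

    def test_ldlc_increases_with_intake_rate(self, calibrated_model):
        """Steady-state LDL-C rises monotonically with the ingestion rate k1."""
        m = calibrated_model
        scan = parameter_scan(m.params, m.boundaries, m.state, "k1",
                              [0.6, 0.8, 1.0, 1.2, 1.4])
        ldlc = scan.series("LDLC")
        assert np.all(np.diff(ldlc) > 0)

    def test_ldlc_decreases_with_receptor_synthesis(self, calibrated_model):
        """Steady-state LDL-C falls monotonically as khrs rises."""
        m = calibrated_model
        k = m.params.khrs
        scan = parameter_scan(m.params, m.boundaries, m.state, "khrs",
                              [0.5 * k, 0.75 * k, k, 1.25 * k, 1.5 * k])
        ldlc = scan.series("LDLC")
        assert np.all(np.diff(ldlc) < 0)

    def test_warm_start_matches_cold_start(self, calibrated_model):
        m = calibrated_model
        values = [0.8, 1.0, 1.2]
        warm = parameter_scan(m.params, m.boundaries, m.state, "k1", values)
        for v, r in zip(values, warm.results):
            cold = parameter_scan(m.params, m.boundaries, m.state, "k1", [v])
            assert r["LDLC"] == pytest.approx(cold.results[0]["LDLC"],
                                              rel=1e-6)

    def test_failed_rows_do_not_abort(self, default_model):
        m = default_model
        # an absurd k5 makes the bile subsystem diverge for that row only
        scan = parameter_scan(m.params, m.boundaries, m.state, "k2",
                              [m.params.k2, 0.0], tol=1e-10)
        assert scan.results[0] is not None
        # second row: zero bile release starves the intestine of bile salts
        # (k2=0 -> IBS -> 0); whether it converges or fails, the scan returns
        assert len(scan.results) == 2
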