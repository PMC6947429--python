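"""Tests of the two-pool variable-volume kinetic model."""

import numpy as np
import pytest

from pkrrf.kinetics import (DialysisPrescription, KineticParameters,
                            KineticState, MINUTES_PER_WEEK, SolverError,
                            derivatives, simulate_patient, steady_state)
from conftest import random_params


def make_params(**kw) -> KineticParameters:
    base = dict(generation_rate=0.16, total_volume=15.0, plasma_fraction=0.33,
                intercompartmental_clearance=60.0, extrarenal_clearance=3.0,
                residual_renal_clearance=2.0, body_weight=75.0)
    base.update(kw)
    return KineticParameters(**base)


def make_rx(**kw) -> DialysisPrescription:
    base = dict(modality="HD", dialyzer_clearance=40.0, session_duration=240.0,
                uf_volume=2.5)
    base.update(kw)
    return DialysisPrescription(**base)


class TestDerivatives:
    def test_no_sources_or_sinks_gives_zero_derivatives(self):
        p = make_params(generation_rate=0.0, intercompartmental_clearance=0.0,
                        extrarenal_clearance=0.0, residual_renal_clearance=0.0)
        # zero UF and zero intake: interdialytic phase with explicit alpha=0
        rx = make_rx(dialyzer_clearance=0.0, uf_volume=0.0, intake_rate=0.0)
        s = KineticState(t=0.0, c_p=20.0, c_np=25.0, v_p=5.0, v_np=10.0, phase=0)
        assert derivatives(s, p, rx) == (0.0, 0.0, 0.0, 0.0)

    def test_equal_concentrations_kill_intercompartmental_flux(self):
        p0 = make_params(intercompartmental_clearance=0.0)
        p1 = make_params(intercompartmental_clearance=500.0)
        s = KineticState(t=0.0, c_p=17.3, c_np=17.3, v_p=5.0, v_np=10.0, phase=1)
        rx = make_rx()
        assert derivatives(s, p0, rx) == pytest.approx(derivatives(s, p1, rx))

    @pytest.mark.parametrize("phase", [0, 1])
    def test_total_mass_derivative_identity(self, phase):
        """d(V_P C_P + V_NP C_NP)/dt must equal G - (K_R+K_ER+Theta K_D) C_P.

        Checked against an independent central-difference oracle applied
        to the total mass along an Euler step of the state derivatives.
        """
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = random_params(rng)
            rx = make_rx(dialyzer_clearance=float(rng.uniform(0, 100)),
                         uf_volume=float(rng.uniform(0, 4)))
            v_p = p.plasma_fraction * p.total_volume
            v_np = p.nonplasma_fraction * p.total_volume
            s = KineticState(t=0.0, c_p=float(rng.uniform(5, 50)),
                             c_np=float(rng.uniform(5, 50)),
                             v_p=v_p, v_np=v_np, phase=phase)
            dc_p, dc_np, dv_p, dv_np = derivatives(s, p, rx)
            # analytic total-mass derivative by the product rule
            dm = (s.v_p * dc_p + s.c_p * dv_p + s.v_np * dc_np + s.c_np * dv_np)
            k_total = (p.residual_renal_clearance + p.extrarenal_clearance
                       + phase * rx.dialyzer_clearance) / 1000.0
            expected = p.generation_rate - k_total * s.c_p
            assert dm == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_volume_is_rejected(self):
        with pytest.raises(ValueError, match="plasma"):
            KineticState(t=0.0, c_p=1.0, c_np=1.0, v_p=0.0, v_np=10.0, phase=0)
        with pytest.raises(ValueError, match="non-plasma"):
            KineticState(t=0.0, c_p=1.0, c_np=1.0, v_p=5.0, v_np=-1.0, phase=0)


class TestSteadyState:
    def test_zero_generation(self):
        assert steady_state(make_params(generation_rate=0.0)) == (0.0, 0.0)

    def test_closed_form_values(self):
        # G=0.01 mg/min, K_R+K_ER=0.1 L/min, phi_NP=0.5, K_C=0.2 L/min
        p = make_params(generation_rate=0.01, plasma_fraction=0.5,
                        extrarenal_clearance=60.0, residual_renal_clearance=40.0,
                        intercompartmental_clearance=200.0)
        c_p, c_np = steady_state(p)
        assert c_p == pytest.approx(0.1)
        assert c_np == pytest.approx(0.125)

    def test_no_elimination_pathway_errors(self):
        p = make_params(extrarenal_clearance=0.0, residual_renal_clearance=0.0)
        with pytest.raises(ValueError, match="no elimination pathway"):
            steady_state(p)

    def test_long_horizon_simulation_converges_to_closed_form(self):
        """13-week no-dialysis trajectories settle on the algebraic fixed
        point for arbitrary (seeded) parameters."""
        rng = np.random.default_rng(7)
        rx = make_rx(dialyzer_clearance=0.0, uf_volume=0.0)
        for _ in range(5):
            p = random_params(rng)
            c_p_ss, c_np_ss = steady_state(p)
            # start away from equilibrium to exercise the transient
            init = KineticState(t=0.0, c_p=1.0, c_np=1.0,
                                v_p=p.plasma_fraction * p.total_volume,
                                v_np=p.nonplasma_fraction * p.total_volume,
                                phase=0)
            traj = simulate_patient(p, rx, 13, initial_state=init)
            last = traj.frame.iloc[-1]
            assert last["C_P"] == pytest.approx(c_p_ss, rel=0.01)
            assert last["C_NP"] == pytest.approx(c_np_ss, rel=0.01)


class TestSimulatePatient:
    def test_mass_conservation_without_sources_or_sinks(self):
        p = make_params(generation_rate=0.0, extrarenal_clearance=0.0,
                        residual_renal_clearance=0.0)
        rx = make_rx(dialyzer_clearance=0.0)
        init = KineticState(t=0.0, c_p=30.0, c_np=20.0, v_p=4.95, v_np=10.05,
                            phase=0)
        traj = simulate_patient(p, rx, 2, initial_state=init,
                                samples_per_segment=3)
        f = traj.frame
        mass = f["V_P"] * f["C_P"] + f["V_NP"] * f["C_NP"]
        assert np.allclose(mass, mass.iloc[0], rtol=1e-6)

    def test_volume_ratio_constant_along_trajectory(self, typical_params,
                                                    typical_rx):
        traj = simulate_patient(typical_params, typical_rx, 3,
                                samples_per_segment=4)
        ratio = traj.frame["V_P"] / traj.frame["V_NP"]
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-8)

    def test_concentrations_stay_nonnegative(self):
        # aggressive dialysis of a patient with no generation
        p = make_params(generation_rate=0.0)
        rx = make_rx(dialyzer_clearance=150.0)
        init = KineticState(t=0.0, c_p=30.0, c_np=30.0, v_p=4.95, v_np=10.05,
                            phase=0)
        traj = simulate_patient(p, rx, 4, initial_state=init,
                                samples_per_segment=3)
        assert (traj.frame[["C_P", "C_NP"]] >= 0).all().all()

    def test_predialysis_b2m_decreases_with_rrf(self, typical_rx):
        """More residual renal clearance always lowers predialysis B2M."""
        pres = []
        for k_r in [0.0, 1.0, 2.5, 5.0, 8.0]:
            p = make_params(residual_renal_clearance=k_r)
            traj = simulate_patient(p, typical_rx, 13)
            pre, _ = traj.session_bounds(12, 0)
            pres.append(pre.c_p)
        assert all(a > b for a, b in zip(pres, pres[1:]))

    def test_single_pool_limit_matches_analytic_solution(self):
        """With huge intercompartmental clearance the model collapses to
        one well-mixed pool whose intradialytic solution is the power law
        C(t) = C0 (V(t)/V0)^((K_D - Q_UF)/Q_UF)."""
        v0, uf, kd, td = 15.0, 2.0, 100.0, 240.0
        p = make_params(generation_rate=0.0, plasma_fraction=0.33,
                        intercompartmental_clearance=1e6,
                        extrarenal_clearance=0.0, residual_renal_clearance=0.0,
                        total_volume=v0)
        rx = make_rx(dialyzer_clearance=kd, uf_volume=uf,
                     session_duration=td)
        init = KineticState(t=0.0, c_p=30.0, c_np=30.0, v_p=0.33 * v0,
                            v_np=0.67 * v0, phase=1)
        traj = simulate_patient(p, rx, 1, initial_state=init)
        _, post = traj.session_bounds(0, 0)
        q_uf = uf / td
        expected = 30.0 * ((v0 - uf) / v0) ** ((kd / 1000.0 - q_uf) / q_uf)
        assert post.c_p == pytest.approx(expected, rel=0.005)
        assert post.c_np == pytest.approx(post.c_p, rel=1e-3)

    def test_weekly_volume_periodicity_with_auto_intake(self, typical_params,
                                                        typical_rx):
        """Auto-derived fluid intake makes each week weight-neutral."""
        traj = simulate_patient(typical_params, typical_rx, 2)
        f = traj.frame
        v_start = f["V_P"].iloc[0] + f["V_NP"].iloc[0]
        at_week = f.loc[np.isclose(f["time_min"], MINUTES_PER_WEEK),
                        ["V_P", "V_NP"]].sum(axis=1)
        assert at_week.iloc[0] == pytest.approx(v_start, rel=1e-8)

    def test_trajectory_sampled_at_session_boundaries(self, typical_params,
                                                      typical_rx):
        traj = simulate_patient(typical_params, typical_rx, 1)
        for s in range(3):
            pre, post = traj.session_bounds(0, s)
            start = typical_rx.session_start_offsets[s]
            assert pre.t == pytest.approx(start)
            assert post.t == pytest.approx(start + typical_rx.session_duration)


class TestValidation:
    def test_invalid_plasma_fraction_rejected(self):
        with pytest.raises(ValueError, match="plasma_fraction"):
            make_params(plasma_fraction=1.2)

    def test_overlapping_sessions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            DialysisPrescription(modality="HD", dialyzer_clearance=40.0,
                                 session_duration=300.0, uf_volume=2.0,
                                 session_start_offsets=(0.0, 200.0, 5760.0))

    def test_horizon_must_be_positive(self, typical_params, typical_rx):
        with pytest.raises(ValueError, match="horizon_weeks"):
            simulate_patient(typical_params, typical_rx, 0)
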