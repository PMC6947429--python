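"""Two-compartment, variable-volume kinetic model of beta-2-microglobulin.

The body is split into a plasma/perfusing pool (P) and a non-plasma pool
(NP) whose volumes stay in a fixed ratio.  B2M is generated in both pools
in proportion to their fractional volumes, exchanged between them by an
intercompartmental clearance, and removed by residual renal clearance,
extrarenal clearance and (during dialysis sessions) dialyzer clearance.
Volumes shrink under ultrafiltration intradialytically and recover through
fluid intake interdialytically.

Internal units are minutes, liters and mg; clearances are supplied in
mL/min and converted to L/min on construction of :class:`KineticParameters`
and :class:`DialysisPrescription`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

MINUTES_PER_WEEK = 10_080.0

__all__ = [
    "KineticParameters",
    "DialysisPrescription",
    "KineticState",
    "Trajectory",
    "derivatives",
    "simulate_patient",
    "steady_state",
    "SolverError",
]


class SolverError(RuntimeError):
    """ODE integration failed; carries the offending time window."""

    def __init__(self, message: str, t_start: float, t_end: float):
        super().__init__(f"{message} (segment {t_start:.1f}-{t_end:.1f} min)")
        self.t_start = t_start
        self.t_end = t_end


@dataclass(frozen=True)
class KineticParameters:
    """Per-patient kinetic constants.

    Parameters
    ----------
    generation_rate : float
        B2M generation rate G, mg/min (split across pools by fractional
        volume).
    total_volume : float
        Total distribution volume V at the start-of-week (dry) state, L.
    plasma_fraction : float
        Fraction of the distribution volume that is plasma/perfusing,
        in (0, 1).  The non-plasma fraction is its complement.
    intercompartmental_clearance : float
        Exchange clearance between the two pools, mL/min.
    extrarenal_clearance : float
        Non-renal, non-dialytic elimination clearance, mL/min.
    residual_renal_clearance : float
        Residual renal clearance (the RRF), mL/min.
    body_weight : float
        Body weight, kg (carried for downstream feature construction).
    """

    generation_rate: float
    total_volume: float
    plasma_fraction: float
    intercompartmental_clearance: float
    extrarenal_clearance: float
    residual_renal_clearance: float
    body_weight: float

    def __post_init__(self):
        if not 0.0 < self.plasma_fraction < 1.0:
            raise ValueError("plasma_fraction must lie strictly in (0, 1)")
        if self.generation_rate < 0:
            raise ValueError("generation_rate must be >= 0")
        if self.total_volume <= 0:
            raise ValueError("total_volume must be > 0")
        for name in ("intercompartmental_clearance", "extrarenal_clearance",
                     "residual_renal_clearance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # L/min forms, converted once here so the ODE never sees mL.
        object.__setattr__(self, "_kc_l", self.intercompartmental_clearance / 1000.0)
        object.__setattr__(self, "_ker_l", self.extrarenal_clearance / 1000.0)
        object.__setattr__(self, "_kr_l", self.residual_renal_clearance / 1000.0)

    @property
    def nonplasma_fraction(self) -> float:
        return 1.0 - self.plasma_fraction


@dataclass(frozen=True)
class DialysisPrescription:
    """Dialysis schedule and session parameters for one patient.

    ``dialyzer_clearance`` is the total B2M clearance of the dialyzer
    (diffusive + adsorptive + convective components combined), mL/min.
    ``session_start_offsets`` are minutes from the start of the week;
    the default is a Monday/Wednesday/Friday pattern.  ``intake_rate``
    (L/min) may be ``None``, in which case interdialytic fluid intake is
    auto-derived per gap so that the fluid gained between two consecutive
    sessions equals the next session's ultrafiltration volume
    (weight-neutral weeks).
    """

    modality: str
    dialyzer_clearance: float
    session_duration: float
    uf_volume: float
    sessions_per_week: int = 3
    session_start_offsets: tuple[float, ...] | None = None
    intake_rate: float | None = None
    substitution_flow: float | None = None  # L/h, HDF, informational

    def __post_init__(self):
        if self.modality not in ("HD", "HDF"):
            raise ValueError("modality must be 'HD' or 'HDF'")
        if self.dialyzer_clearance < 0:
            raise ValueError("dialyzer_clearance must be >= 0")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be > 0")
        if self.uf_volume < 0:
            raise ValueError("uf_volume must be >= 0")
        if self.session_start_offsets is None:
            step = MINUTES_PER_WEEK / 3.5  # 48 h between weekday sessions
            offsets = tuple(i * step for i in range(self.sessions_per_week))
            object.__setattr__(self, "session_start_offsets", offsets)
        offsets = tuple(float(o) for o in self.session_start_offsets)
        if len(offsets) != self.sessions_per_week:
            raise ValueError("session_start_offsets length must equal sessions_per_week")
        for a, b in zip(offsets, offsets[1:]):
            if b < a + self.session_duration:
                raise ValueError("session windows overlap within the week")
        if offsets[-1] + self.session_duration > MINUTES_PER_WEEK:
            raise ValueError("last session extends past the week boundary")
        object.__setattr__(self, "session_start_offsets", offsets)
        object.__setattr__(self, "_kd_l", self.dialyzer_clearance / 1000.0)

    @property
    def uf_rate(self) -> float:
        """Ultrafiltration rate Q_UF during a session, L/min."""
        return self.uf_volume / self.session_duration

    def interdialytic_intake_rates(self) -> list[float]:
        """Fluid-intake rate (L/min) for each gap following a session.

        Auto-derived rates make each week weight-neutral: the volume
        gained over a gap equals the ultrafiltration volume of the next
        session.  An explicit ``intake_rate`` overrides all gaps.
        """
        starts = list(self.session_start_offsets)
        gaps = []
        for i, s in enumerate(starts):
            end = s + self.session_duration
            nxt = starts[i + 1] if i + 1 < len(starts) else starts[0] + MINUTES_PER_WEEK
            gaps.append(nxt - end)
        if self.intake_rate is not None:
            return [self.intake_rate] * len(gaps)
        return [self.uf_volume / g if g > 0 else 0.0 for g in gaps]


@dataclass(frozen=True)
class KineticState:
    """Instantaneous state of the two-pool system."""

    t: float
    c_p: float
    c_np: float
    v_p: float
    v_np: float
    phase: int  # 1 intradialytic, 0 interdialytic

    def __post_init__(self):
        if self.v_p <= 0:
            raise ValueError("plasma compartment volume must be > 0")
        if self.v_np <= 0:
            raise ValueError("non-plasma compartment volume must be > 0")


def derivatives(state: KineticState, params: KineticParameters,
                rx: DialysisPrescription, intake_rate: float | None = None,
                ) -> tuple[float, float, float, float]:
    """Time derivatives of (C_P, C_NP, V_P, V_NP).

    Mass balances (clearances in L/min):

        d(V_P C_P)/dt  = phi_P G - (K_R + K_ER + Theta K_D) C_P - K_C (C_P - C_NP)
        d(V_NP C_NP)/dt = phi_NP G + K_C (C_P - C_NP)
        dV_P/dt  = phi_P  (-Theta Q_UF + (1 - Theta) alpha)
        dV_NP/dt = phi_NP (-Theta Q_UF + (1 - Theta) alpha)

    Concentration derivatives follow by the product rule.  ``intake_rate``
    overrides the prescription's interdialytic intake alpha (L/min) for
    the current gap; the default uses a weekly-average value.
    """
    theta = state.phase
    q = -rx.uf_rate if theta else _default_alpha(rx, intake_rate)
    dv_p = params.plasma_fraction * q
    dv_np = params.nonplasma_fraction * q
    flux = params._kc_l * (state.c_p - state.c_np)
    elim = (params._kr_l + params._ker_l + theta * rx._kd_l) * state.c_p
    dm_p = params.plasma_fraction * params.generation_rate - elim - flux
    dm_np = params.nonplasma_fraction * params.generation_rate + flux
    dc_p = (dm_p - state.c_p * dv_p) / state.v_p
    dc_np = (dm_np - state.c_np * dv_np) / state.v_np
    return (dc_p, dc_np, dv_p, dv_np)


def _default_alpha(rx: DialysisPrescription, override: float | None) -> float:
    if override is not None:
        return override
    if rx.intake_rate is not None:
        return rx.intake_rate
    inter = MINUTES_PER_WEEK - rx.sessions_per_week * rx.session_duration
    total_uf = rx.sessions_per_week * rx.uf_volume
    return total_uf / inter if inter > 0 else 0.0


def steady_state(params: KineticParameters) -> tuple[float, float]:
    """Closed-form fixed point with no dialysis and no fluid shifts.

    With Theta = 0 and alpha = 0 the system settles at

        C_P  = G / (K_R + K_ER)
        C_NP = C_P + phi_NP G / K_C

    Returns (C_P, C_NP) in mg/L.
    """
    k_elim = params._kr_l + params._ker_l
    if k_elim <= 0:
        raise ValueError("no elimination pathway; steady state undefined")
    if params.generation_rate == 0:
        return (0.0, 0.0)
    if params._kc_l <= 0:
        raise ValueError("intercompartmental clearance must be > 0 for a "
                         "two-pool steady state")
    c_p = params.generation_rate / k_elim
    c_np = c_p + params.nonplasma_fraction * params.generation_rate / params._kc_l
    return (c_p, c_np)


@dataclass
class Trajectory:
    """Sampled kinetic trajectory with session bookkeeping.

    ``frame`` has columns time_min, C_P, C_NP, V_P, V_NP, phase.
    ``session_index`` maps (week, session-within-week) to the row indices
    of the session start and end instants.
    """

    frame: pd.DataFrame
    session_index: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)

    def session_bounds(self, week: int, session: int) -> tuple[KineticState, KineticState]:
        """States at the start (predialysis) and end (postdialysis) of a session."""
        i0, i1 = self.session_index[(week, session)]
        return self._row_state(i0), self._row_state(i1)

    def _row_state(self, i: int) -> KineticState:
        r = self.frame.iloc[i]
        return KineticState(t=r["time_min"], c_p=r["C_P"], c_np=r["C_NP"],
                            v_p=r["V_P"], v_np=r["V_NP"], phase=int(r["phase"]))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _segment_rhs(y, t, phi_p, phi_np, g, k_out, kc, q):
    c_p, c_np, v_p, v_np = y
    dv_p = phi_p * q
    dv_np = phi_np * q
    flux = kc * (c_p - c_np)
    dc_p = (phi_p * g - k_out * c_p - flux - c_p * dv_p) / v_p
    dc_np = (phi_np * g + flux - c_np * dv_np) / v_np
    return (dc_p, dc_np, dv_p, dv_np)


def _build_week_segments(rx: DialysisPrescription) -> list[tuple[float, float, int, float]]:
    """(start, end, theta, q) segments covering one week, in order.

    q is the volume-change rate of the *total* volume (L/min): -Q_UF
    intradialytically, +alpha interdialytically.
    """
    alphas = rx.interdialytic_intake_rates()
    starts = list(rx.session_start_offsets)
    segs = []
    if starts[0] > 0:
        # gap before the first session belongs to the previous week's last
        # session; use its intake rate
        segs.append((0.0, starts[0], 0, alphas[-1]))
    for i, s in enumerate(starts):
        end = s + rx.session_duration
        segs.append((s, end, 1, -rx.uf_rate))
        nxt = starts[i + 1] if i + 1 < len(starts) else MINUTES_PER_WEEK
        if nxt > end:
            segs.append((end, nxt, 0, alphas[i]))
    return segs


def simulate_patient(params: KineticParameters, rx: DialysisPrescription,
                     horizon_weeks: int = 13, *,
                     initial_state: KineticState | None = None,
                     rtol: float = 1e-8, atol: float = 1e-10,
                     samples_per_segment: int = 0) -> Trajectory:
    """Integrate the two-pool system over a multi-week schedule.

    Time is segmented at every session boundary and each segment is
    integrated separately with LSODA (stiffness-switching), so the
    intradialytic indicator never produces a discontinuous right-hand
    side inside a solver step.  The state is continuous across switches.

    The default initial condition is the no-dialysis steady state (volumes
    at the dry-weight split); pass ``initial_state`` to override, e.g. for
    degenerate parameter sets with no elimination pathway.

    ``samples_per_segment`` adds that many interior sample points per
    segment to the returned trajectory (session boundaries are always
    included).
    """
    if horizon_weeks < 1:
        raise ValueError("horizon_weeks must be >= 1")
    if initial_state is None:
        c_p0, c_np0 = steady_state(params)
        y = np.array([c_p0, c_np0,
                      params.plasma_fraction * params.total_volume,
                      params.nonplasma_fraction * params.total_volume])
    else:
        y = np.array([initial_state.c_p, initial_state.c_np,
                      initial_state.v_p, initial_state.v_np])

    week_segs = _build_week_segments(rx)
    phi_p, phi_np = params.plasma_fraction, params.nonplasma_fraction
    g, kc = params.generation_rate, params._kc_l
    k_base = params._kr_l + params._ker_l

    times, states, phases = [0.0], [y.copy()], [week_segs[0][2]]
    session_index: dict[tuple[int, int], tuple[int, int]] = {}

    for week in range(horizon_weeks):
        t_week = week * MINUTES_PER_WEEK
        session = 0
        for (s, e, theta, q) in week_segs:
            t0, t1 = t_week + s, t_week + e
            k_out = k_base + (rx._kd_l if theta else 0.0)
            n_interior = samples_per_segment if samples_per_segment > 0 else 0
            t_eval = np.linspace(t0, t1, 2 + n_interior)
            if y[2] <= 0 or y[3] <= 0:
                comp = "plasma" if y[2] <= 0 else "non-plasma"
                raise SolverError(f"non-positive {comp} compartment volume", t0, t1)
            sol, info = odeint(_segment_rhs, y, t_eval,
                               args=(phi_p, phi_np, g, k_out, kc, q),
                               rtol=rtol, atol=atol, mxstep=10_000,
                               full_output=True)
            if info["message"] != "Integration successful.":
                raise SolverError(f"LSODA failure: {info['message']}", t0, t1)
            if theta:
                i_start = len(times) - 1  # boundary state already recorded
            for i in range(1, len(t_eval)):
                times.append(t_eval[i])
                states.append(sol[i])
                phases.append(theta)
            y = sol[-1].copy()
            if theta:
                session_index[(week, session)] = (i_start, len(times) - 1)
                session += 1

    arr = np.asarray(states)
    frame = pd.DataFrame({
        "time_min": times,
        "C_P": arr[:, 0], "C_NP": arr[:, 1],
        "V_P": arr[:, 2], "V_NP": arr[:, 3],
        "phase": phases,
    })
    return Trajectory(frame=frame, session_index=session_index)
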