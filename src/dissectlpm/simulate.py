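"""Pulsatile simulation of the dissection circuit to periodic steady state.

State variables (clinical units):

* ``p_tl``  -- TL pressure at the proximal node (mmHg)
* ``q_tlo`` -- TL downstream flow (ml/s)
* ``p_fl``  -- FL pressure at the proximal node (mmHg)
* ``q_fl``  -- FL axial flow toward the distal tear (ml/s)

with dynamics

    dP_TL/dt  = (Q_TLi - Q_TLo) / C_TL
    dQ_TLo/dt = (P_TL - P_PH - R_TL Q_TLo) / L_TL
    dP_FL/dt  = (Q_PT - Q_FL) / C_FL
    dQ_FL/dt  = (P_FL - P_DT - R_FL Q_FL) / L_FL

closed algebraically (Ohm's law at the tears and periphery, Kirchhoff's
junction rule) by

    Q_PT  = (P_TL - P_FL) / R_PT        (0 if the proximal tear is absent)
    Q_TLi = Q_i - Q_PT
    Q_PH  = Q_TLo + Q_FL
    P_PH  = R_PH Q_PH + P_o
    P_DT  = R_DT Q_FL + P_PH            (= P_FL if the distal tear is absent)

An absent distal tear removes the FL axial branch: ``q_fl`` is identically
zero and its equation is dropped.

Integration
-----------
The circuit is linear and time-invariant, ``dx/dt = A x + b(t)``, forced by
a band-limited periodic inflow.  The default integrator is therefore exact:
the periodic particular solution is assembled per inflow harmonic from
``(i w_k I - A)^{-1}``, and the decaying transient is propagated with the
matrix exponential ``expm(A h)`` on the fixed output grid.  This is
uniformly accurate for any wall stiffness — the near-rigid regime turns
the lumina into weakly damped megahertz-range oscillators that defeat
conventional variable-step stiff solvers — at a cost independent of the
stiffness.  A variable-step method (``method="LSODA"`` etc.) is kept as an
option and as a cross-check.  Either way the solver is iterated cycle by
cycle from the supplied initial state until two consecutive cycles agree,
which defines periodic steady state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .core import DissectionModelSpec, InvalidModelError
from .waveforms import PeriodicWaveform

__all__ = [
    "SolverSettings",
    "StateVector",
    "AlgebraicSignals",
    "SimulationResult",
    "SimulationError",
    "state_derivative",
    "algebraic_close",
    "simulate",
    "dc_steady_state",
    "DCOperatingPoint",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "time_s",
    "p_tl_mmHg",
    "p_fl_mmHg",
    "p_dt_mmHg",
    "p_ph_mmHg",
    "q_i_ml_s",
    "q_tli_ml_s",
    "q_tlo_ml_s",
    "q_pt_ml_s",
    "q_fl_ml_s",
    "q_ph_ml_s",
]


class SimulationError(RuntimeError):
    """Raised when the integrator fails outright."""


@dataclass
class SolverSettings:
    """Integrator and steady-state settings.

    ``output_step`` must divide the inflow period to within one part in
    1e9.  Steady state is declared when the largest absolute change of any
    state series between consecutive cycles drops below
    ``steady_state_tol * (peak-to-peak P_TL)``, floored at ``10 * atol``.
    ``method`` is ``"exact"`` (matrix-exponential propagator, default) or
    any stiff-capable ``scipy.integrate.solve_ivp`` method name, for which
    ``rtol``/``atol`` are the step-error tolerances.
    """

    output_step: float = 0.01
    rtol: float = 1e-8
    atol: float = 1e-10
    max_cycles: int = 100
    steady_state_tol: float = 1e-6
    method: str = "exact"
    warn_on_nonconvergence: bool = True

    def __post_init__(self) -> None:
        if not (self.output_step > 0.0):
            raise ValueError("output_step must be positive")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")

    def samples_per_cycle(self, period: float) -> int:
        n = round(period / self.output_step)
        if n < 1 or abs(n * self.output_step - period) > 1e-9 * period:
            raise ValueError(
                f"output_step {self.output_step} does not divide the period {period}"
            )
        return n


@dataclass(frozen=True)
class StateVector:
    p_tl: float
    q_tlo: float
    p_fl: float
    q_fl: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_tl, self.q_tlo, self.p_fl, self.q_fl])

    @classmethod
    def from_array(cls, y) -> "StateVector":
        return cls(*(float(v) for v in y))


@dataclass
class AlgebraicSignals:
    """Algebraically closed signals; scalar or array valued."""

    q_i: np.ndarray
    q_pt: np.ndarray
    q_tli: np.ndarray
    q_ph: np.ndarray
    p_ph: np.ndarray
    p_dt: np.ndarray


class _CircuitOperator:
    """Constant-coefficient form dx/dt = A x + b0 + g * Q_i(t), specialised
    to the tear topology.  ``active`` lists the live state indices: the
    ``q_fl`` equation is dropped for a dead-end (single-proximal-tear) FL."""

    def __init__(self, model: DissectionModelSpec):
        c_tl = model.tl_elements.compliance
        c_fl = model.fl_elements.compliance
        if c_tl <= 0.0 or c_fl <= 0.0:
            raise InvalidModelError("compliances must be strictly positive for simulation")
        r_tl, l_tl = model.tl_elements.resistance, model.tl_elements.inertance
        r_fl, l_fl = model.fl_elements.resistance, model.fl_elements.inertance
        r_ph = model.peripheral.resistance
        p_o = model.peripheral.outlet_pressure
        self.model = model

        A = np.zeros((4, 4))
        b0 = np.zeros(4)
        g = np.zeros(4)
        # dP_TL/dt
        g[0] = 1.0 / c_tl
        A[0, 1] = -1.0 / c_tl
        if model.has_proximal_tear:
            r_pt = model.proximal_tear.resistance
            A[0, 0] -= 1.0 / (r_pt * c_tl)
            A[0, 2] += 1.0 / (r_pt * c_tl)
            # dP_FL/dt gains the tear inflow
            A[2, 0] += 1.0 / (r_pt * c_fl)
            A[2, 2] -= 1.0 / (r_pt * c_fl)
        # dQ_TLo/dt
        A[1, 0] = 1.0 / l_tl
        A[1, 1] = -(r_ph + r_tl) / l_tl
        b0[1] = -p_o / l_tl
        if model.has_distal_tear:
            r_dt = model.distal_tear.resistance
            A[1, 3] = -r_ph / l_tl
            # dP_FL/dt loses the axial outflow
            A[2, 3] += -1.0 / c_fl
            # dQ_FL/dt
            A[3, 1] = -r_ph / l_fl
            A[3, 2] = 1.0 / l_fl
            A[3, 3] = -(r_dt + r_fl + r_ph) / l_fl
            b0[3] = -p_o / l_fl
            self.active = [0, 1, 2, 3]
        else:
            self.active = [0, 1, 2]
        self.A = A
        self.b0 = b0
        self.g = g

    def rhs(self, t, y, inflow):
        return self.A @ y + self.b0 + self.g * inflow(t)

    def jac(self, t, y, *args):
        return self.A

    def close(self, y: np.ndarray, q_i) -> AlgebraicSignals:
        """Algebraic closures for state(s) ``y`` (shape (4,) or (4, n))."""
        m = self.model
        p_tl, q_tlo, p_fl, q_fl = y[0], y[1], y[2], y[3]
        if m.has_proximal_tear:
            q_pt = (p_tl - p_fl) / m.proximal_tear.resistance
        else:
            q_pt = np.zeros_like(np.asarray(p_tl, dtype=float))
        q_tli = q_i - q_pt
        q_ph = q_tlo + q_fl
        p_ph = m.peripheral.resistance * q_ph + m.peripheral.outlet_pressure
        if m.has_distal_tear:
            p_dt = m.distal_tear.resistance * q_fl + p_ph
        else:
            p_dt = p_fl  # dead-end branch carries no flow, no pressure drop
        return AlgebraicSignals(q_i=q_i, q_pt=q_pt, q_tli=q_tli, q_ph=q_ph, p_ph=p_ph, p_dt=p_dt)


def state_derivative(
    state: StateVector, t: float, model: DissectionModelSpec, inflow: PeriodicWaveform
) -> StateVector:
    """Time derivative of the state at time ``t``."""
    op = _CircuitOperator(model)
    dy = op.rhs(t, state.as_array(), inflow)
    if not model.has_distal_tear:
        dy[3] = 0.0
    return StateVector.from_array(dy)


def algebraic_close(
    state: StateVector, t: float, model: DissectionModelSpec, inflow: PeriodicWaveform
) -> AlgebraicSignals:
    """Close the algebraic signals for a single state at time ``t``."""
    op = _CircuitOperator(model)
    return op.close(state.as_array(), float(np.asarray(inflow(t), dtype=float)))


@dataclass
class SimulationResult:
    """One converged cycle on the uniform output grid ``[0, T)``."""

    time: np.ndarray
    p_tl: np.ndarray
    p_fl: np.ndarray
    p_dt: np.ndarray
    p_ph: np.ndarray
    q_i: np.ndarray
    q_tli: np.ndarray
    q_tlo: np.ndarray
    q_pt: np.ndarray
    q_fl: np.ndarray
    q_ph: np.ndarray
    period: float
    cycles_run: int
    converged: bool
    scenario_id: str = ""
    final_state: Optional[np.ndarray] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        series = [
            self.time,
            self.p_tl,
            self.p_fl,
            self.p_dt,
            self.p_ph,
            self.q_i,
            self.q_tli,
            self.q_tlo,
            self.q_pt,
            self.q_fl,
            self.q_ph,
        ]
        return pd.DataFrame(dict(zip(RESULT_COLUMNS, series)))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def read_csv(cls, path) -> "SimulationResult":
        df = pd.read_csv(path)
        missing = [c for c in RESULT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        t = df["time_s"].to_numpy(float)
        period = t[-1] + (t[1] - t[0]) if t.size > 1 else 0.0
        return cls(
            time=t,
            p_tl=df["p_tl_mmHg"].to_numpy(float),
            p_fl=df["p_fl_mmHg"].to_numpy(float),
            p_dt=df["p_dt_mmHg"].to_numpy(float),
            p_ph=df["p_ph_mmHg"].to_numpy(float),
            q_i=df["q_i_ml_s"].to_numpy(float),
            q_tli=df["q_tli_ml_s"].to_numpy(float),
            q_tlo=df["q_tlo_ml_s"].to_numpy(float),
            q_pt=df["q_pt_ml_s"].to_numpy(float),
            q_fl=df["q_fl_ml_s"].to_numpy(float),
            q_ph=df["q_ph_ml_s"].to_numpy(float),
            period=period,
            cycles_run=0,
            converged=True,
        )


class _ExactPropagator:
    """Exact cycle integrator for the LTI circuit.

    The inflow is represented by the trigonometric interpolant of its
    samples; the particular periodic response follows per harmonic from
    ``x_k = (i w_k I - A)^{-1} g c_k`` and the transient decays through
    ``expm(A h)`` steps on the output grid.
    """

    def __init__(self, op: _CircuitOperator, inflow: PeriodicWaveform, grid: np.ndarray):
        idx = op.active
        A = op.A[np.ix_(idx, idx)]
        b0 = op.b0[idx]
        g = op.g[idx]
        self.idx = idx
        self.n = grid.size - 1
        T = inflow.period
        ns = inflow.n_samples
        c = np.fft.rfft(inflow.samples) / ns
        k = np.arange(c.size)
        w = 2.0 * math.pi * k / T
        # weights of the real trig interpolant (DC and Nyquist count once)
        weights = np.full(c.size, 2.0)
        weights[0] = 1.0
        if ns % 2 == 0:
            weights[-1] = 1.0
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                x_dc = np.linalg.solve(-A, b0 + g * c[0].real)
                m = len(idx)
                systems = (
                    1j * w[1:, None, None] * np.eye(m)[None, :, :] - A[None, :, :]
                )
                rhs = (g[None, :] * c[1:, None])[:, :, None]
                xk = np.linalg.solve(systems, rhs)[:, :, 0]
                self.M = expm(A * (grid[1] - grid[0]))
        except np.linalg.LinAlgError as exc:
            raise SimulationError(f"circuit operator is singular: {exc}") from exc
        if not (np.all(np.isfinite(x_dc)) and np.all(np.isfinite(xk)) and np.all(np.isfinite(self.M))):
            raise SimulationError("exact propagator produced non-finite terms (ill-scaled circuit)")
        phase = np.exp(1j * np.outer(grid, w[1:]))  # (n+1, K)
        wk = weights[1:]
        self.xp = x_dc[None, :] + np.real((phase * wk[None, :]) @ xk)
        self.q_grid = c[0].real + np.real(phase @ (wk * c[1:]))

    def run_cycle(self, y4: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Propagate one cycle from full state ``y4``; returns the state
        series on the grid (4 x n+1) and the full end state."""
        d = y4[self.idx] - self.xp[0]
        n = self.n
        m = len(self.idx)
        D = np.empty((n + 1, m))
        with np.errstate(over="ignore", invalid="ignore"):
            for j in range(n + 1):
                D[j] = d
                if j < n:
                    d = self.M @ d
        X = self.xp + D
        out = np.zeros((4, n + 1))
        for row, i in enumerate(self.idx):
            out[i] = X[:, row]
        y_end = np.zeros(4)
        y_end[self.idx] = X[n]
        return out, y_end


def simulate(
    model: DissectionModelSpec,
    inflow: PeriodicWaveform,
    settings: Optional[SolverSettings] = None,
    initial_state: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Integrate the circuit cycle by cycle until periodic steady state.

    Starts from zero state (or ``initial_state``) and compares consecutive
    cycles on the output grid.  A run that exhausts ``max_cycles`` is
    returned with ``converged=False`` (never silently).
    """
    settings = settings or SolverSettings()
    if inflow.kind != "flow":
        raise ValueError("inflow waveform must be of kind 'flow'")
    T = inflow.period
    n = settings.samples_per_cycle(T)
    grid = np.linspace(0.0, T, n + 1)
    op = _CircuitOperator(model)

    y = np.zeros(4) if initial_state is None else np.asarray(initial_state, dtype=float).copy()
    if y.shape != (4,):
        raise ValueError("initial_state must have shape (4,)")
    if not model.has_distal_tear:
        y[3] = 0.0  # dead-end FL: axial branch removed

    exact = settings.method == "exact"
    prop = _ExactPropagator(op, inflow, grid) if exact else None

    prev = None
    cur = None
    converged = False
    cycles = 0
    for cycle in range(settings.max_cycles):
        if exact:
            series, y = prop.run_cycle(y)
        else:
            sol = solve_ivp(
                op.rhs,
                (0.0, T),
                y,
                method=settings.method,
                t_eval=grid,
                args=(inflow,),
                jac=op.jac,
                rtol=settings.rtol,
                atol=settings.atol,
            )
            if not sol.success:
                raise SimulationError(
                    f"integrator failed in cycle {cycle + 1} for {model.scenario_id}: "
                    f"{sol.message}"
                )
            series, y = sol.y, sol.y[:, -1].copy()
        cur = series[:, :n]
        cycles = cycle + 1
        if prev is not None:
            diff = float(np.max(np.abs(cur - prev)))
            scale = float(np.ptp(cur[0]))
            tol = max(settings.steady_state_tol * scale, 10.0 * settings.atol)
            if diff <= tol:
                converged = True
                break
        prev = cur

    if not converged and settings.warn_on_nonconvergence:
        logger.warning(
            "simulation of %s did not reach periodic steady state in %d cycles",
            model.scenario_id,
            settings.max_cycles,
        )

    t_out = grid[:n]
    if exact:
        q_i = prop.q_grid[:n]
    else:
        q_i = np.asarray(inflow(t_out), dtype=float)
    sig = op.close(cur, q_i)
    return SimulationResult(
        time=t_out,
        p_tl=cur[0],
        p_fl=cur[2],
        p_dt=np.broadcast_to(sig.p_dt, t_out.shape).copy(),
        p_ph=sig.p_ph,
        q_i=q_i,
        q_tli=sig.q_tli,
        q_tlo=cur[1],
        q_pt=np.broadcast_to(sig.q_pt, t_out.shape).copy(),
        q_fl=cur[3],
        q_ph=sig.q_ph,
        period=T,
        cycles_run=cycles,
        converged=converged,
        scenario_id=model.scenario_id,
        final_state=y,
    )


@dataclass
class DCOperatingPoint:
    """Algebraic solution of the pure-resistor network under constant
    inflow (capacitors open, inductors shorted)."""

    p_tl: float
    p_fl: float
    p_dt: float
    p_ph: float
    q_i: float
    q_tli: float
    q_tlo: float
    q_pt: float
    q_fl: float
    q_ph: float

    def as_state(self) -> np.ndarray:
        return np.array([self.p_tl, self.q_tlo, self.p_fl, self.q_fl])


def dc_steady_state(model: DissectionModelSpec, constant_inflow: float) -> DCOperatingPoint:
    """Independent resistor-network oracle for constant inflow.

    With both tears the inlet flow splits between the TL path (R_TL) and
    the tear path (R_PT + R_FL + R_DT) in inverse proportion to their
    resistances; with a single tear the FL is a dead end and carries no
    mean flow.
    """
    q = float(constant_inflow)
    r_tl = model.tl_elements.resistance
    r_fl = model.fl_elements.resistance
    r_ph = model.peripheral.resistance
    p_o = model.peripheral.outlet_pressure
    p_ph = r_ph * q + p_o
    if model.has_proximal_tear and model.has_distal_tear:
        r_path = model.proximal_tear.resistance + r_fl + model.distal_tear.resistance
        q_tlo = q * r_path / (r_tl + r_path)
        q_fl = q * r_tl / (r_tl + r_path)
        q_pt = q_fl
        p_tl = p_ph + r_tl * q_tlo
        p_fl = p_tl - model.proximal_tear.resistance * q_pt
        p_dt = model.distal_tear.resistance * q_fl + p_ph
    elif model.has_proximal_tear:  # dead-end FL, fed proximally
        q_tlo, q_fl, q_pt = q, 0.0, 0.0
        p_tl = p_ph + r_tl * q
        p_fl = p_tl
        p_dt = p_fl
    else:  # distal tear only: dead-end FL hanging off the junction
        q_tlo, q_fl, q_pt = q, 0.0, 0.0
        p_tl = p_ph + r_tl * q
        p_fl = p_ph
        p_dt = p_ph
    return DCOperatingPoint(
        p_tl=p_tl,
        p_fl=p_fl,
        p_dt=p_dt,
        p_ph=p_ph,
        q_i=q,
        q_tli=q - q_pt,
        q_tlo=q_tlo,
        q_pt=q_pt,
        q_fl=q_fl,
        q_ph=q_tlo + q_fl,
    )
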