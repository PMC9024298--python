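"""Fixed-step RK4 integration of the deterministic delayed SIR system.

The system (population fractions, delay omega in the vaccination return
term, f the Crowley–Martin denominator)::

    dS/dt = -beta S I / f - b S + p b I + b (1 - I) - m S
            + m S(t - omega) e^{-b omega}
    dI/dt =  beta S I / f - gamma I - p b I
    dR/dt =  gamma I - b R + m S - m S(t - omega) e^{-b omega}

The right-hand sides sum to ``b (1 - S - I - R)``, so the unit simplex is
invariant.  The delayed susceptible fraction is obtained by linear
interpolation into the stored past (and from the history function for
times before the start).
"""

from __future__ import annotations

import math

import numpy as np

from .config import SimulationConfig
from .history import HistoryFunction
from .model import EpidemicState, ModelParameters, crowley_martin_denominator
from .trajectory import Trajectory

__all__ = ["deterministic_drift", "integrate_dde"]


def _drift(s: float, i: float, r: float, s_delayed: float, p: ModelParameters):
    f = 1.0 + p.alpha1 * s + p.alpha2 * i + p.alpha1 * p.alpha2 * s * i
    inc = p.beta * s * i / f
    ret = p.m * s_delayed * math.exp(-p.b * p.omega)
    ds = -inc - p.b * s + p.p * p.b * i + p.b * (1.0 - i) - p.m * s + ret
    di = inc - p.gamma * i - p.p * p.b * i
    dr = p.gamma * i - p.b * r + p.m * s - ret
    return ds, di, dr


def deterministic_drift(
    state: EpidemicState, s_delayed: float, params: ModelParameters
) -> tuple[float, float, float]:
    """Right-hand side (dS, dI, dR) of the delayed system at one state.

    ``s_delayed`` is the susceptible fraction at time ``t - omega``.
    """
    if s_delayed < 0:
        raise ValueError(f"delayed S must be >= 0, got {s_delayed}")
    return _drift(state.S, state.I, state.R, s_delayed, params)


def integrate_dde(
    params: ModelParameters,
    history: HistoryFunction,
    config: SimulationConfig,
) -> Trajectory:
    """Integrate the deterministic delayed system with classical RK4.

    The delayed term at each Runge–Kutta stage is evaluated by dense
    output into the stored past: the history function for times before 0,
    cubic Hermite interpolation (node values plus node derivatives) on the
    committed grid — which preserves the fourth-order accuracy a linear
    lookup would degrade — and a linear blend toward the stage estimate
    for the sub-step gap a delay shorter than ``dt`` can reach into.
    Fourth-order accurate away from the delay-activation kink at
    ``t = omega``.
    """
    dt = config.dt
    n = config.n_steps
    omega = params.omega

    t = np.linspace(0.0, n * dt, n + 1)
    S = np.empty(n + 1)
    I = np.empty(n + 1)
    R = np.empty(n + 1)
    dS = np.empty(n + 1)  # node derivatives for Hermite dense output
    S[0], I[0], R[0] = history.s0, history.i0, history.r0

    def s_at(tq: float, k: int, t_stage: float, s_stage: float,
             dknown: int) -> float:
        """S at query time tq, given k committed points and a stage estimate.

        ``dknown`` is the last node whose derivative is already stored;
        intervals beyond it fall back to linear interpolation.
        """
        if tq <= 0.0:
            return history.s_history(tq)
        tk = k * dt
        if tq <= tk + 1e-12 * max(1.0, tk):
            pos = tq / dt
            j = min(int(pos), k - 1) if k >= 1 else 0
            u = pos - j
            if u < 1e-12:
                return S[j]
            if u > 1.0 - 1e-12:
                return S[j + 1]
            if j + 1 > dknown:
                return S[j] * (1.0 - u) + S[j + 1] * u
            h00 = (1.0 + 2.0 * u) * (1.0 - u) ** 2
            h10 = u * (1.0 - u) ** 2
            h01 = u * u * (3.0 - 2.0 * u)
            h11 = u * u * (u - 1.0)
            return (
                h00 * S[j]
                + h10 * dt * dS[j]
                + h01 * S[j + 1]
                + h11 * dt * dS[j + 1]
            )
        # delay shorter than the step: blend toward the stage estimate
        if t_stage == tk:
            return s_stage
        w = (tq - tk) / (t_stage - tk)
        return S[k] * (1.0 - w) + s_stage * w

    for k in range(n):
        tk = k * dt
        s, i, r = S[k], I[k], R[k]

        sd1 = s_at(tk - omega, k, tk, s, dknown=k - 1)
        k1 = _drift(s, i, r, sd1, params)
        dS[k] = k1[0]

        th = tk + 0.5 * dt
        s2, i2, r2 = s + 0.5 * dt * k1[0], i + 0.5 * dt * k1[1], r + 0.5 * dt * k1[2]
        sd2 = s_at(th - omega, k, th, s2, dknown=k)
        k2 = _drift(s2, i2, r2, sd2, params)

        s3, i3, r3 = s + 0.5 * dt * k2[0], i + 0.5 * dt * k2[1], r + 0.5 * dt * k2[2]
        sd3 = s_at(th - omega, k, th, s3, dknown=k)
        k3 = _drift(s3, i3, r3, sd3, params)

        tf = tk + dt
        s4, i4, r4 = s + dt * k3[0], i + dt * k3[1], r + dt * k3[2]
        sd4 = s_at(tf - omega, k, tf, s4, dknown=k)
        k4 = _drift(s4, i4, r4, sd4, params)

        S[k + 1] = s + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        I[k + 1] = i + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        R[k + 1] = r + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

    return Trajectory(t=t, S=S, I=I, R=R)
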