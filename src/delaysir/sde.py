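"""Euler–Maruyama and Milstein stepping for the delayed epidemic SDE.

Noise enters through the transmission coefficient
(``beta dt -> beta dt + sigma dB``), so a single Brownian motion drives the
S and I equations with the diffusion coefficient
``g = sigma S I / f(S, I)`` entering with opposite signs::

    dS = [ -beta S I/f - b S + p b I + b(1 - I) - m S
           + m S(t-omega) e^{-b omega} ] dt  -  g dB
    dI = [  beta S I/f - gamma I - p b I ] dt  +  g dB

R is reconstructed as ``1 - S - I``.  The Milstein scheme adds the
``0.5 sigma^2 (S I / f) (xi^2 - 1) dt`` correction (minus on S, plus on I),
implemented exactly in that form.  The same standard-normal draw ``xi``
enters both equations, so the noise cancels from ``S + I`` at every step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import SimulationConfig
from .history import HistoryFunction
from .model import ModelParameters
from .trajectory import Trajectory

__all__ = [
    "em_step",
    "milstein_step",
    "simulate_path",
    "simulate_ensemble",
    "immunity_level",
    "EnsembleSummary",
]


def _reduced_drift(s: float, i: float, s_delay: float, p: ModelParameters):
    f = 1.0 + p.alpha1 * s + p.alpha2 * i + p.alpha1 * p.alpha2 * s * i
    inc = p.beta * s * i / f
    ds = (
        -inc
        - p.b * s
        + p.p * p.b * i
        + p.b * (1.0 - i)
        - p.m * s
        + p.m * s_delay * math.exp(-p.b * p.omega)
    )
    di = inc - p.gamma * i - p.p * p.b * i
    return ds, di, s * i / f


def em_step(
    state: tuple[float, float],
    s_delay: float,
    xi: float,
    params: ModelParameters,
    dt: float,
) -> tuple[float, float]:
    """One Euler–Maruyama step of the reduced (S, I) system.

    The same draw ``xi`` enters S with ``-g sqrt(dt)`` and I with
    ``+g sqrt(dt)`` (one shared Brownian motion), so ``S + I`` carries no
    noise term.
    """
    s, i = state
    ds, di, si_over_f = _reduced_drift(s, i, s_delay, params)
    g = params.sigma * si_over_f
    noise = g * math.sqrt(dt) * xi
    return s + ds * dt - noise, i + di * dt + noise


def milstein_step(
    state: tuple[float, float],
    s_delay: float,
    xi: float,
    params: ModelParameters,
    dt: float,
) -> tuple[float, float]:
    """One Milstein step: the EM update plus the ``(xi^2 - 1) dt`` correction.

    The correction ``0.5 sigma^2 (S I / f)(xi^2 - 1) dt`` is subtracted
    from S and added to I.  At ``xi = +-1`` it vanishes and the step
    coincides with :func:`em_step`; its expectation over ``xi ~ N(0,1)``
    is zero.
    """
    s, i = state
    ds, di, si_over_f = _reduced_drift(s, i, s_delay, params)
    g = params.sigma * si_over_f
    noise = g * math.sqrt(dt) * xi
    corr = 0.5 * params.sigma**2 * si_over_f * (xi * xi - 1.0) * dt
    return s + ds * dt - noise - corr, i + di * dt + noise + corr


_STEPPERS = {"euler_maruyama": em_step, "milstein": milstein_step}


def simulate_path(
    params: ModelParameters,
    history: HistoryFunction,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[Trajectory, int]:
    """Simulate one sample path of the delayed SDE on the uniform grid.

    The delayed value at step ``k`` is the stored ``S[k - omega/dt]`` (the
    delay must land on the grid) or the history function for negative
    times.  With ``sigma = 0`` the path is exactly the forward-Euler
    solution of the deterministic system.

    Returns the trajectory (with ``R = 1 - S - I``) and the number of
    clamped (negative-undershoot) updates.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    step = _STEPPERS[config.scheme]
    dt = config.dt
    n = config.n_steps
    lag = config.delay_lag(params.omega)

    S = np.empty(n + 1)
    I = np.empty(n + 1)
    S[0], I[0] = history.s0, history.i0
    xis = rng.standard_normal(n)
    clamped = 0

    for k in range(n):
        j = k - lag
        s_delay = S[j] if j >= 0 else history.s_history(j * dt)
        s1, i1 = step((S[k], I[k]), s_delay, xis[k], params, dt)
        if s1 < 0.0 or i1 < 0.0:
            if config.positivity_policy == "error":
                raise RuntimeError(
                    f"negative update at step {k + 1} (t={(k + 1) * dt:g}): "
                    f"S={s1:.6g}, I={i1:.6g}"
                )
            if s1 < 0.0:
                s1 = 0.0
                clamped += 1
            if i1 < 0.0:
                i1 = 0.0
                clamped += 1
        S[k + 1], I[k + 1] = s1, i1

    t = np.linspace(0.0, n * dt, n + 1)
    return Trajectory(t=t, S=S, I=I, R=1.0 - S - I), clamped


@dataclass
class EnsembleSummary:
    """Pointwise mean trajectory plus per-path diagnostics.

    ``paths_I`` holds every realization of I (n_realizations x grid) so
    per-path decay diagnostics can be computed downstream; terminal states
    and tail time-averages of I are precomputed per path.
    """

    t: np.ndarray
    mean_S: np.ndarray
    mean_I: np.ndarray
    paths_I: np.ndarray
    terminal_S: np.ndarray
    terminal_I: np.ndarray
    tail_mean_I: np.ndarray
    clamp_events: int
    config: SimulationConfig

    @property
    def mean_R(self) -> np.ndarray:
        return 1.0 - self.mean_S - self.mean_I

    def sidecar_dict(self) -> dict:
        return {
            "n_realizations": self.config.n_realizations,
            "seed": self.config.seed,
            "scheme": self.config.scheme,
            "dt": self.config.dt,
            "t_end": self.config.t_end,
            "clamp_events": self.clamp_events,
        }

    def write(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Mean-trajectory CSV plus a JSON sidecar with the run settings."""
        Trajectory(t=self.t, S=self.mean_S, I=self.mean_I, R=self.mean_R).to_csv(csv_path)
        if sidecar_path is not None:
            Path(sidecar_path).write_text(
                json.dumps(self.sidecar_dict(), indent=2) + "\n"
            )


def path_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, platform-stable substream for path ``index``.

    Built from a counter-based seed sequence keyed on (seed, index), so
    ensembles are reproducible and paths are statistically independent.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_ensemble(
    params: ModelParameters,
    history: HistoryFunction,
    config: SimulationConfig,
    tail_fraction: float = 0.5,
) -> EnsembleSummary:
    """Simulate ``config.n_realizations`` independent paths and average them.

    Path ``i`` uses the substream ``path_rng(config.seed, i)``.  The tail
    time-average of I per path is taken over the last ``tail_fraction`` of
    the horizon.
    """
    n_paths = config.n_realizations
    n = config.n_steps
    paths_S_terminal = np.empty(n_paths)
    paths_I = np.empty((n_paths, n + 1))
    clamp_total = 0
    t = None
    mean_S = np.zeros(n + 1)

    for i in range(n_paths):
        traj, clamped = simulate_path(params, history, config, path_rng(config.seed, i))
        clamp_total += clamped
        paths_I[i] = traj.I
        paths_S_terminal[i] = traj.S[-1]
        mean_S += traj.S
        t = traj.t

    mean_S /= n_paths
    tail_start = int(math.floor((1.0 - tail_fraction) * n))
    tail_mean_I = paths_I[:, tail_start:].mean(axis=1)

    return EnsembleSummary(
        t=t,
        mean_S=mean_S,
        mean_I=paths_I.mean(axis=0),
        paths_I=paths_I,
        terminal_S=paths_S_terminal,
        terminal_I=paths_I[:, -1],
        tail_mean_I=tail_mean_I,
        clamp_events=clamp_total,
        config=config,
    )


def immunity_level(
    traj: Trajectory, history: HistoryFunction, params: ModelParameters
) -> np.ndarray:
    """Cumulative immunity level V(t) driven by the vaccination balance.

    ``dV/dt = m S(t) - m S(t - omega) e^{-b omega}``: inflow of newly
    protected susceptibles minus the (mortality-discounted) outflow of
    those whose immunity wanes.  Advanced by trapezoidal quadrature with
    the convention ``V(0) = 0``; exact for constant S, where
    ``V(t) = m s (1 - e^{-b omega}) t``.
    """
    dt = traj.dt
    if dt <= 0:
        raise ValueError("trajectory must have at least two grid points")
    lag_f = params.omega / dt
    lag = int(round(lag_f))
    if abs(lag_f - lag) > 1e-8:
        raise ValueError(f"omega/dt = {lag_f} must be integral for the delayed lookup")

    n = traj.t.size
    s_del = np.empty(n)
    for k in range(n):
        j = k - lag
        s_del[k] = traj.S[j] if j >= 0 else history.s_history(j * dt)

    rate = params.m * traj.S - params.m * s_del * math.exp(-params.b * params.omega)
    v = np.zeros(n)
    v[1:] = np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)
    return v
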