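"""Empirical extinction / persistence diagnostics on simulated ensembles.

The theory makes two asymptotic claims: under the extinction conditions
``limsup ln I(t)/t <= lambda_I < 0`` almost surely, and under persistence
``liminf <I>(t) >= I* > 0`` where ``<X>(t) = (1/t) int_0^t X(s) ds``.  On a
finite horizon these become measurable checks: a least-squares slope of
``ln I`` over a tail window per path, and the tail value of the running
time average of the ensemble-mean I.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .model import ModelParameters, ThresholdReport, classify_regime
from .sde import EnsembleSummary

__all__ = ["time_average", "log_decay_rate", "verify_regime", "RegimeCheckReport"]

#: floor for logarithms of a (possibly clamped-to-zero) infected series
LOG_FLOOR = 1e-300


def time_average(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Running time average ``<X>(t) = (1/t) int_0^t X(s) ds``.

    Trapezoidal quadrature on the uniform grid, exact for affine signals.
    The value at ``t = 0`` is defined by continuity as ``X(0)``.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    if t.size == 1:
        return x.copy()
    integral = cumulative_trapezoid(x, t, initial=0.0)
    avg = np.empty_like(x)
    avg[0] = x[0]
    avg[1:] = integral[1:] / (t[1:] - t[0])
    return avg


def log_decay_rate(
    t: np.ndarray,
    i_series: np.ndarray,
    tail_window: tuple[float, float] | None = None,
    floor: float = LOG_FLOOR,
) -> float:
    """Least-squares slope of ``ln I`` against ``t`` over a tail window.

    Estimates the exponential decay (or growth) rate of the infected
    fraction; for ``I(t) = I0 e^{-c t}`` it returns ``-c`` exactly.
    Values below ``floor`` are floored before taking logs so that paths
    clamped to zero still yield a (very negative) finite slope.
    """
    t = np.asarray(t, dtype=float)
    i_series = np.asarray(i_series, dtype=float)
    if tail_window is None:
        lo, hi = t[0] + 0.5 * (t[-1] - t[0]), t[-1]
    else:
        lo, hi = tail_window
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if mask.sum() < 2:
        raise ValueError(f"tail window [{lo}, {hi}] contains fewer than two grid points")
    logs = np.log(np.maximum(i_series[mask], floor))
    slope, _ = np.polyfit(t[mask], logs, 1)
    return float(slope)


@dataclass
class RegimeCheckReport:
    """Outcome of the empirical extinction / persistence checks.

    Each check is ``"pass"`` / ``"fail"`` when the corresponding
    theoretical bound exists and ``"not_applicable"`` otherwise.
    """

    measured_log_slope: float
    lambda_I: Optional[float]
    tail_mean_I: float
    i_star: Optional[float]
    extinction_check: str
    persistence_check: str
    tail_window: tuple[float, float]
    path_pass_fraction: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "measured_log_slope": self.measured_log_slope,
            "lambda_I": self.lambda_I,
            "tail_mean_I": self.tail_mean_I,
            "i_star": self.i_star,
            "extinction_check": self.extinction_check,
            "persistence_check": self.persistence_check,
            "tail_window": list(self.tail_window),
            "path_pass_fraction": self.path_pass_fraction,
        }


def verify_regime(
    ensemble: EnsembleSummary,
    params: ModelParameters,
    tol_slope: float = 0.05,
    tol_rel: float = 0.1,
    majority: float = 0.9,
    tail_fraction: float = 0.5,
    thresholds: ThresholdReport | None = None,
) -> RegimeCheckReport:
    """Check the asymptotic extinction / persistence bounds on an ensemble.

    Extinction: per-path tail log-slopes of I must satisfy
    ``slope <= lambda_I + tol_slope`` for at least a ``majority`` fraction
    of paths (the bound holds almost surely, but finite paths fluctuate).
    Persistence: the tail average of the running mean ``<I>`` of the
    ensemble mean must be ``>= (1 - tol_rel) * I*``.  Either check is
    not applicable when its theoretical bound is absent.
    """
    if thresholds is None:
        thresholds = classify_regime(params)
    t = ensemble.t
    horizon = t[-1] - t[0]
    lo = t[0] + (1.0 - tail_fraction) * horizon
    window = (lo, float(t[-1]))
    if horizon < 2.0 * (lo - t[0]) - 1e-9:
        raise ValueError("horizon must be at least twice the tail-window start")

    slopes = np.array(
        [log_decay_rate(t, path, tail_window=window) for path in ensemble.paths_I]
    )
    mean_slope = float(np.median(slopes))

    running = time_average(t, ensemble.mean_I)
    tail_mask = t >= lo - 1e-12
    tail_mean = float(running[tail_mask].mean())

    lam = thresholds.lambda_I
    if lam is None:
        extinction = "not_applicable"
        frac = None
    else:
        frac = float(np.mean(slopes <= lam + tol_slope))
        extinction = "pass" if frac >= majority else "fail"

    istar = thresholds.i_star
    if istar is None:
        persistence = "not_applicable"
    else:
        persistence = "pass" if tail_mean >= (1.0 - tol_rel) * istar else "fail"

    return RegimeCheckReport(
        measured_log_slope=mean_slope,
        lambda_I=lam,
        tail_mean_I=tail_mean,
        i_star=istar,
        extinction_check=extinction,
        persistence_check=persistence,
        tail_window=window,
        path_pass_fraction=frac,
    )
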