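"""Initial data for the delayed system: state at t=0 plus S on [-omega, 0).

The delay term needs the susceptible fraction over the interval before the
start of the integration.  The default history is the constant function
``S(theta) = S(0)``; a tabulated history (piecewise-linear between sample
points) may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["HistoryFunction"]


@dataclass(frozen=True)
class HistoryFunction:
    """Initial state (S(0), I(0), R(0)) and pre-history of S on [-omega, 0).

    Parameters
    ----------
    s0, i0
        Initial susceptible and infected fractions.
    r0
        Initial recovered fraction.  Defaults to ``1 - s0 - i0`` so that the
        state starts on the unit simplex.
    theta, s_values
        Optional tabulated history: sample times in [-omega, 0] (ascending)
        and the matching S values.  Linear interpolation in between; the
        first value extends to earlier times.  When omitted, the history is
        the constant ``s0``.
    """

    s0: float
    i0: float
    r0: Optional[float] = None
    theta: Optional[Sequence[float]] = None
    s_values: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.s0 < 0 or self.i0 < 0:
            raise ValueError(f"initial fractions must be >= 0: S(0)={self.s0}, I(0)={self.i0}")
        if self.r0 is None:
            # The reduced stochastic system tracks only (S, I); some study
            # scenarios start with S + I > 1, making the bookkeeping
            # R = 1 - S - I transiently negative.  Only an explicit
            # negative R(0) is rejected.
            object.__setattr__(self, "r0", 1.0 - self.s0 - self.i0)
        elif self.r0 < 0:
            raise ValueError(f"R(0) must be >= 0, got {self.r0}")
        if (self.theta is None) != (self.s_values is None):
            raise ValueError("theta and s_values must be supplied together")
        if self.theta is not None:
            th = np.asarray(self.theta, dtype=float)
            sv = np.asarray(self.s_values, dtype=float)
            if th.shape != sv.shape or th.ndim != 1 or th.size == 0:
                raise ValueError("theta and s_values must be matching 1-d arrays")
            if np.any(np.diff(th) <= 0):
                raise ValueError("theta must be strictly increasing")
            if np.any(sv < 0):
                raise ValueError("history S values must be >= 0")
            object.__setattr__(self, "theta", th)
            object.__setattr__(self, "s_values", sv)

    def s_history(self, theta: float) -> float:
        """S at a time ``theta <= 0`` before the start of integration."""
        if theta > 0:
            raise ValueError(f"history queried at positive time {theta}")
        if self.theta is None:
            return self.s0
        return float(np.interp(theta, self.theta, self.s_values))
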