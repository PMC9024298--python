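"""Simulation configuration shared by the deterministic and stochastic steppers."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SimulationConfig"]

_SCHEMES = ("euler_maruyama", "milstein")
_POLICIES = ("truncate", "error")


@dataclass(frozen=True)
class SimulationConfig:
    """Stepping and ensemble settings.

    ``dt`` defaults to 0.1 and ``n_realizations`` to 50 — the grid and
    ensemble size used throughout the built-in scenarios.  For the
    stochastic schemes the delay must land on the grid (``omega/dt``
    integral); that is checked against the model parameters at run time.

    ``positivity_policy`` governs what happens when a discrete update
    undershoots zero: ``truncate`` clamps the component at 0 (and counts
    the event), ``error`` aborts with the offending step index.
    """

    dt: float = 0.1
    t_end: float = 100.0
    n_realizations: int = 50
    seed: int = 0
    scheme: str = "milstein"
    positivity_policy: str = "truncate"

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not self.t_end > 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.n_realizations < 1:
            raise ValueError(f"n_realizations must be >= 1, got {self.n_realizations}")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")
        if self.positivity_policy not in _POLICIES:
            raise ValueError(
                f"positivity_policy must be one of {_POLICIES}, got {self.positivity_policy!r}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def delay_lag(self, omega: float) -> int:
        """Delay expressed in grid steps; rejects off-grid delays."""
        lag = omega / self.dt
        lag_int = int(round(lag))
        if abs(lag - lag_int) > 1e-8:
            raise ValueError(
                f"omega/dt = {lag} is not integral: the delay must land on the grid "
                f"(omega={omega}, dt={self.dt})"
            )
        return lag_int
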