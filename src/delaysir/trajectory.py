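"""Trajectory container: aligned (S, I, R[, V]) series on a uniform grid."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time series of the epidemic state on a uniform grid.

    ``V`` is the optional cumulative immunity level driven by
    ``dV/dt = m S(t) - m S(t-omega) e^{-b omega}``.
    """

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    V: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("S", "I", "R"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} does not match the time grid length")
            setattr(self, name, arr)
        if self.V is not None:
            self.V = np.asarray(self.V, dtype=float)
            if self.V.shape != self.t.shape:
                raise ValueError("V does not match the time grid length")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * max(1.0, abs(steps[0]))):
                raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size >= 2 else 0.0

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "S": self.S, "I": self.I, "R": self.R}
        if self.V is not None:
            data["V"] = self.V
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        # 17 significant digits round-trips IEEE doubles bit-identically
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            t=df["t"].to_numpy(),
            S=df["S"].to_numpy(),
            I=df["I"].to_numpy(),
            R=df["R"].to_numpy(),
            V=df["V"].to_numpy() if "V" in df.columns else None,
        )
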