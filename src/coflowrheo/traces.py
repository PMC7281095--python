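"""Time-series containers shared by the simulation, imaging, and
estimation layers.

The central quantity is the co-flow interface fraction ``alpha``: the
fraction of the channel width occupied by the test fluid (blood).  Its
linearizing transform ``beta = 1/(1 - alpha)`` is what the circuit model
evolves and what the exponential time-constant fits consume.  Traces are
stored on a uniform sampling grid (0.5 s by default in the experiments
this package models) and round-trip through plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D array, got shape {arr.shape}")
    return arr


@dataclass
class InterfaceTrace:
    """Interface fraction over time.

    ``beta`` is always derived from ``alpha`` so the identity
    ``beta = 1/(1 - alpha)`` holds to machine precision.  When the
    channel width ``W_um`` is known, the blood-filled width
    ``W_B = alpha * W`` is available as well.
    """

    t: np.ndarray
    alpha: np.ndarray
    W_um: float | None = None
    Q_T_mLh: np.ndarray | None = None
    Q_R_mLh: np.ndarray | None = None

    def __post_init__(self):
        self.t = _as_1d(self.t)
        self.alpha = _as_1d(self.alpha)
        if self.t.shape != self.alpha.shape:
            raise ValueError("t and alpha must have the same length")
        if np.any(self.alpha < 0) or np.any(self.alpha >= 1):
            raise ValueError("alpha must lie in [0, 1)")
        for name in ("Q_T_mLh", "Q_R_mLh"):
            q = getattr(self, name)
            if q is not None:
                q = _as_1d(q)
                if q.shape != self.t.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, q)

    @property
    def beta(self) -> np.ndarray:
        return 1.0 / (1.0 - self.alpha)

    @property
    def W_B_um(self) -> np.ndarray | None:
        if self.W_um is None:
            return None
        return self.alpha * self.W_um

    @classmethod
    def from_beta(cls, t, beta, **kwargs) -> "InterfaceTrace":
        beta = _as_1d(beta)
        if np.any(beta < 1):
            raise ValueError("beta must be >= 1 (alpha would be negative)")
        return cls(t=t, alpha=1.0 - 1.0 / beta, **kwargs)

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        if len(self) < 2:
            raise ValueError("need at least two samples to infer dt")
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.t}
        if self.Q_T_mLh is not None:
            cols["Q_T_mLh"] = self.Q_T_mLh
        if self.Q_R_mLh is not None:
            cols["Q_R_mLh"] = self.Q_R_mLh
        cols["alpha"] = self.alpha
        cols["beta"] = self.beta
        if self.W_um is not None:
            cols["W_B_um"] = self.W_B_um
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "InterfaceTrace":
        df = pd.read_csv(path)
        kwargs = {}
        for col, name in (("Q_T_mLh", "Q_T_mLh"), ("Q_R_mLh", "Q_R_mLh")):
            if col in df.columns:
                kwargs[name] = df[col].to_numpy()
        if "alpha" in df.columns:
            alpha = df["alpha"].to_numpy()
        elif "beta" in df.columns:
            alpha = 1.0 - 1.0 / df["beta"].to_numpy()
        else:
            raise ValueError("CSV must contain an 'alpha' or 'beta' column")
        return cls(t=df["time_s"].to_numpy(), alpha=alpha, **kwargs)


@dataclass
class IntensityTrace:
    """ROI-averaged image intensity over time, in raw gray levels."""

    t: np.ndarray
    I: np.ndarray

    def __post_init__(self):
        self.t = _as_1d(self.t)
        self.I = _as_1d(self.I)
        if self.t.shape != self.I.shape:
            raise ValueError("t and I must have the same length")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "I_mean": self.I})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "IntensityTrace":
        df = pd.read_csv(path)
        return cls(t=df["time_s"].to_numpy(), I=df["I_mean"].to_numpy())


@dataclass
class VelocityTrace:
    """ROI-averaged blood velocity over time (mm/s), as produced by
    micro-PIV in the experiment this package emulates."""

    t: np.ndarray
    U_mm_s: np.ndarray

    def __post_init__(self):
        self.t = _as_1d(self.t)
        self.U_mm_s = _as_1d(self.U_mm_s)
        if self.t.shape != self.U_mm_s.shape:
            raise ValueError("t and U must have the same length")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "U_mm_s": self.U_mm_s})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "VelocityTrace":
        df = pd.read_csv(path)
        return cls(t=df["time_s"].to_numpy(), U_mm_s=df["U_mm_s"].to_numpy())
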