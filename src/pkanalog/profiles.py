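"""Unit mapping from simulation measurements to plasma concentration profiles.

The analog is relationally grounded, so simulation time steps and plasma
amounts must be mapped to hours and concentration units before comparison
with clinical data:

    t_r = (t_s - offset) * x_scale        (referent time, h)
    C   = A_plasma * d / y_scale          (plasma concentration)

where ``t_s`` is the time-step stamp of a measurement, ``offset`` accounts
for end-of-cycle measurement timing (default 1), ``A_plasma`` is the total
drug amount in the plasma grid, and ``d`` is the referent dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import AnalogParameters

__all__ = [
    "PlasmaProfile",
    "map_time",
    "map_concentration",
    "build_profile",
    "read_profile_csv",
    "write_profile_csv",
]


def map_time(t_s: float | np.ndarray, x_scale: float, offset: int = 1):
    """Map simulation time step(s) to referent time in hours."""
    if x_scale <= 0:
        raise ValueError("x_scale must be positive")
    return (np.asarray(t_s, dtype=float) - offset) * x_scale


def map_concentration(a_plasma: float | np.ndarray, d: float, y_scale: float):
    """Map total plasma amount(s) to concentration units via the referent
    dose ``d`` and the subject's ``y_scale``."""
    if y_scale <= 0:
        raise ValueError("y_scale must be positive")
    if d <= 0:
        raise ValueError("d must be positive")
    return np.asarray(a_plasma, dtype=float) * d / y_scale


@dataclass(frozen=True)
class PlasmaProfile:
    """An ordered concentration-time profile in mapped (real-world) units."""

    times: np.ndarray  # hours, strictly increasing, first >= 0
    conc: np.ndarray  # concentration units, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and conc must be matching 1-D arrays")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be strictly increasing and start at >= 0")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "conc": self.conc})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PlasmaProfile":
        return cls(
            times=frame["time_h"].to_numpy(dtype=float),
            conc=frame["conc"].to_numpy(dtype=float),
        )


def build_profile(
    trajectory: pd.DataFrame,
    params: AnalogParameters,
    d: float = 1.0,
    offset: int = 1,
) -> PlasmaProfile:
    """Map a simulation trajectory's per-cycle plasma totals to a profile.

    Samples whose mapped time is negative (measurements taken before the
    offset point) are discarded, so the first reportable sample sits at
    t_r = 0.
    """
    t_r = map_time(trajectory["cycle"].to_numpy(), params.x_scale, offset)
    conc = map_concentration(trajectory["plasma"].to_numpy(), d, params.y_scale)
    keep = t_r >= 0
    return PlasmaProfile(times=t_r[keep], conc=conc[keep])


def read_profile_csv(path: str | Path) -> PlasmaProfile:
    """Read a two-column ``time_h,conc`` CSV (header required)."""
    frame = pd.read_csv(path)
    missing = {"time_h", "conc"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return PlasmaProfile.from_frame(frame)


def write_profile_csv(profile: PlasmaProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)
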