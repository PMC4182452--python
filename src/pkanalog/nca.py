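"""Noncompartmental analysis of a plasma concentration profile.

Computes the model-free summary a PK analyst would read off the curve:
peak concentration (c_max), peak time (t_max, earliest occurrence on ties),
lag time (t_lag, the time of the last zero sample before the first
measurable concentration) and the linear-trapezoidal area under the curve
over all sampled time points (auc_all).  No terminal-phase parameters
(half-life, extrapolated AUC, clearance) are estimated: the profiles here
cover an observation window too short for reliable terminal fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .profiles import PlasmaProfile

__all__ = ["NCAResult", "nca", "count_peaks"]


def count_peaks(values) -> int:
    """Count local maxima of a sampled series, boundaries included.

    Plateaus are compressed first; an index is a peak when the series rises
    into it (or it sits at the left boundary) and falls out of it (or it
    sits at the right boundary).  A monotone rise therefore has exactly one
    peak — at its last sample — and a double-peaked profile has two.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return 0
    w = v[np.r_[True, np.diff(v) != 0]]
    if w.size == 1:
        return int(w[0] > 0)
    rising = np.r_[True, np.diff(w) > 0]
    falling = np.r_[np.diff(w) < 0, True]
    return int(np.sum(rising & falling))


@dataclass(frozen=True)
class NCAResult:
    """t_lag and t_max are NaN when the profile never leaves zero."""

    t_lag: float
    t_max: float
    c_max: float
    auc_all: float

    def as_dict(self) -> dict[str, float]:
        return {
            "t_lag_h": self.t_lag,
            "t_max_h": self.t_max,
            "c_max": self.c_max,
            "auc_all": self.auc_all,
        }


def nca(profile: PlasmaProfile) -> NCAResult:
    """Noncompartmental summary of one profile (at least two samples)."""
    if len(profile) < 2:
        raise ValueError("NCA requires at least two samples")
    t = profile.times
    c = profile.conc
    auc = float(np.trapezoid(c, t))

    nonzero = np.flatnonzero(c > 0)
    if nonzero.size == 0:
        return NCAResult(t_lag=math.nan, t_max=math.nan, c_max=0.0, auc_all=auc)

    first_nonzero = int(nonzero[0])
    t_lag = 0.0 if first_nonzero == 0 else float(t[first_nonzero - 1])

    i_max = int(np.argmax(c))  # argmax returns the earliest of equal maxima
    return NCAResult(
        t_lag=t_lag,
        t_max=float(t[i_max]),
        c_max=float(c[i_max]),
        auc_all=auc,
    )
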