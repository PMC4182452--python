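"""Banded similarity criteria for validating a simulated plasma profile.

A simulated profile is compared against a referent at the referent's own
sampling times (the simulated curve is linearly interpolated; referent
points outside the simulated time span are flagged, never silently
dropped).  The validation rule: every referent-nonzero point must fall
within an outer relative band of the referent value (default +/-30%), and
at least ``min_inner_count`` of them (default 4) within an inner band
(default +/-10%).  A profile meeting both conditions passes; the analog
parameterization that produced it is considered valid until falsified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import PlasmaProfile

__all__ = ["SimilarityCriteria", "SimilarityReport", "align_profiles", "similarity_check"]


@dataclass(frozen=True)
class SimilarityCriteria:
    outer_band: float = 0.30
    inner_band: float = 0.10
    min_inner_count: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.inner_band < self.outer_band:
            raise ValueError("need 0 < inner_band < outer_band")
        if self.min_inner_count < 1:
            raise ValueError("min_inner_count must be >= 1")


@dataclass(frozen=True)
class SimilarityReport:
    """Per-point band classification plus the overall verdict.

    ``points`` columns: time, ref, sim, rel_dev, band (``inner``/``outer``/
    ``outside``/``uncovered``), checked.  ``passed`` is true iff every
    checked point lies within the outer band, no checked point is
    uncovered, and at least ``min_inner_count`` lie within the inner band.
    """

    points: pd.DataFrame
    passed: bool
    n_inner: int
    n_checked: int
    criteria: SimilarityCriteria


def align_profiles(simulated: PlasmaProfile, referent: PlasmaProfile) -> pd.DataFrame:
    """Pair simulated values with referent samples at referent times.

    Returns columns ``time, ref, sim, covered``; ``covered`` is False where
    the referent time lies outside the simulated span (no extrapolation —
    ``sim`` is NaN there).
    """
    if len(simulated) == 0 or len(referent) == 0:
        raise ValueError("cannot align empty profiles")
    t_ref = referent.times
    covered = (t_ref >= simulated.times[0]) & (t_ref <= simulated.times[-1])
    sim = np.where(
        covered, np.interp(t_ref, simulated.times, simulated.conc), np.nan
    )
    return pd.DataFrame(
        {"time": t_ref, "ref": referent.conc, "sim": sim, "covered": covered}
    )


def similarity_check(
    paired: pd.DataFrame, criteria: SimilarityCriteria | None = None
) -> SimilarityReport:
    """Classify each referent-nonzero point against the bands and decide.

    Band membership is closed: a point is within band ``b`` iff
    ``|sim - ref| <= b * ref``.  Points with zero referent value are not
    checked (the relative band is undefined there); an uncovered
    referent-nonzero point counts as a failure.
    """
    criteria = criteria or SimilarityCriteria()
    ref = paired["ref"].to_numpy(dtype=float)
    sim = paired["sim"].to_numpy(dtype=float)
    covered = paired["covered"].to_numpy(dtype=bool)

    checked = ref > 0
    if not checked.any():
        raise ValueError("all referent values are zero; similarity is undefined")

    with np.errstate(invalid="ignore", divide="ignore"):
        rel_dev = np.abs(sim - ref) / np.where(checked, ref, np.nan)

    band = np.full(ref.shape, "unchecked", dtype=object)
    ok = checked & covered
    band[ok & (rel_dev <= criteria.inner_band)] = "inner"
    band[ok & (rel_dev > criteria.inner_band) & (rel_dev <= criteria.outer_band)] = "outer"
    band[ok & (rel_dev > criteria.outer_band)] = "outside"
    band[checked & ~covered] = "uncovered"

    n_checked = int(checked.sum())
    n_inner = int((band == "inner").sum())
    all_within_outer = bool(np.isin(band[checked], ("inner", "outer")).all())
    passed = all_within_outer and n_inner >= criteria.min_inner_count

    points = paired.assign(rel_dev=rel_dev, band=band, checked=checked)
    return SimilarityReport(
        points=points,
        passed=passed,
        n_inner=n_inner,
        n_checked=n_checked,
        criteria=criteria,
    )
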