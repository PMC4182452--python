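"""Subject parameterizations and synthetic referent profiles.

Twelve parameter files — six study subjects under fasting and fed
conditions — ship with the package; fields a subject file does not set fall
back to the stock defaults.  A small generator builds referent-like single-
and multi-peak plasma profiles for exercising the similarity validator,
since real observed concentration data are external to this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .params import AnalogParameters

__all__ = [
    "SubjectConfig",
    "ReferentSpec",
    "CONDITIONS",
    "SUBJECT_IDS",
    "load_subject_config",
    "synth_referent",
]

CONDITIONS = ("fasting", "fed")
SUBJECT_IDS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SubjectConfig:
    subject_id: int
    condition: str
    params: AnalogParameters


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("pkanalog").joinpath("fixtures", name)))


def load_subject_config(subject_id: int, condition: str) -> SubjectConfig:
    """Load the shipped parameterization for one subject and condition."""
    if subject_id not in SUBJECT_IDS:
        raise KeyError(f"unknown subject {subject_id!r}; expected 1-6")
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}; expected fasting or fed")
    path = _fixture_path(f"subject{subject_id}_{condition}.yaml")
    return SubjectConfig(
        subject_id=subject_id,
        condition=condition,
        params=AnalogParameters.from_file(path),
    )


@dataclass(frozen=True)
class ReferentSpec:
    """Recipe for a synthetic referent profile: a sum of Gaussian-shaped
    peaks sampled at fixed times with multiplicative lognormal-free noise of
    a given coefficient of variation.  Purely synthetic — a stand-in for
    digitized observed profiles used only to exercise the validator."""

    sample_times: tuple[float, ...]
    peaks: tuple[tuple[float, float, float], ...]  # (center h, width h, height)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sample_times must be non-empty and strictly increasing")
        for _, width, height in self.peaks:
            if width <= 0 or height < 0:
                raise ValueError("peak widths must be positive, heights non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def synth_referent(spec: ReferentSpec) -> pd.DataFrame:
    """Sample the sum-of-peaks curve; returns columns ``time_h, conc``.

    Noise is multiplicative: each sample is scaled by a normal factor with
    mean 1 and standard deviation ``noise_cv``, truncated at zero so
    concentrations stay non-negative.  Deterministic for a fixed seed.
    """
    t = np.asarray(spec.sample_times, dtype=float)
    conc = np.zeros_like(t)
    for center, width, height in spec.peaks:
        conc += height * np.exp(-0.5 * ((t - center) / width) ** 2)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        factors = np.maximum(rng.normal(1.0, spec.noise_cv, size=t.shape), 0.0)
        conc = conc * factors
    return pd.DataFrame({"time_h": t, "conc": conc})
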