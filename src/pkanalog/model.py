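"""High-level model object over the grid engine.

``DispositionAnalog`` bundles a parameterization with the operations a user
runs against it: simulate a trajectory, map it to a plasma profile,
summarize it by NCA, and calibrate it against a referent profile via the
iterative refinement loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .engine import run_simulation
from .experiment import ProposalRule, RefinementResult, iterate_refinement
from .nca import NCAResult, nca
from .params import AnalogParameters
from .profiles import PlasmaProfile, build_profile
from .similarity import SimilarityCriteria
from .subjects import load_subject_config

__all__ = ["DispositionAnalog", "SimulationRun"]


@dataclass(frozen=True)
class SimulationRun:
    """One executed simulation: the trajectory plus the parameters that
    produced it."""

    params: AnalogParameters
    trajectory: pd.DataFrame
    seed: int

    def to_profile(self, dose_d: float = 1.0, offset: int = 1) -> PlasmaProfile:
        return build_profile(self.trajectory, self.params, d=dose_d, offset=offset)

    def nca(self, dose_d: float = 1.0) -> NCAResult:
        return nca(self.to_profile(dose_d=dose_d))


class DispositionAnalog:
    """A parameterized whole-body disposition analog."""

    def __init__(self, params: AnalogParameters | None = None):
        self.params = params or AnalogParameters()

    @classmethod
    def from_subject(cls, subject_id: int, condition: str) -> "DispositionAnalog":
        return cls(load_subject_config(subject_id, condition).params)

    @classmethod
    def from_file(cls, path: str | Path) -> "DispositionAnalog":
        return cls(AnalogParameters.from_file(path))

    def simulate(self, n_cycles: int = 20, seed: int = 0) -> SimulationRun:
        return SimulationRun(
            params=self.params,
            trajectory=run_simulation(self.params, n_cycles=n_cycles, seed=seed),
            seed=seed,
        )

    def fit(
        self,
        referent: PlasmaProfile,
        proposal_rule: ProposalRule,
        max_iter: int = 100,
        n_cycles: int = 20,
        seed: int = 0,
        dose_d: float = 1.0,
        criteria: SimilarityCriteria | None = None,
    ) -> RefinementResult:
        """Calibrate against a referent profile; see
        :func:`pkanalog.experiment.iterate_refinement`."""
        return iterate_refinement(
            referent,
            self.params,
            proposal_rule,
            max_iter=max_iter,
            n_cycles=n_cycles,
            seed=seed,
            dose_d=dose_d,
            criteria=criteria,
        )
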