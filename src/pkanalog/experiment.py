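"""Batch experimentation: subject panels, parameter sweeps and iterative
refinement against a referent profile.

This module plays the role of an experiment manager: it instantiates a fresh
analog per run, executes it for a fixed number of cycles, maps the
measurements to real-world units, summarizes them by noncompartmental
analysis, and logs enough metadata (seed, parameter hash, cycle count,
package version) that any reported number can be re-derived.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .engine import run_simulation
from .nca import NCAResult, nca
from .params import AnalogParameters
from .profiles import PlasmaProfile, build_profile
from .similarity import SimilarityCriteria, SimilarityReport, align_profiles, similarity_check
from .subjects import CONDITIONS, SUBJECT_IDS, load_subject_config

__all__ = [
    "PanelSummary",
    "SweepResult",
    "RefinementResult",
    "run_subject_panel",
    "parameter_sweep",
    "iterate_refinement",
    "random_search_rule",
    "run_manifest",
    "NCA_METRICS",
]

NCA_METRICS = ("t_lag_h", "t_max_h", "c_max", "auc_all")


def params_hash(params: AnalogParameters) -> str:
    payload = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_manifest(params: AnalogParameters, n_cycles: int, seeds: Sequence[int]) -> dict:
    """Provenance record attached to every batch result."""
    return {
        "version": __version__,
        "params_hash": params_hash(params),
        "n_cycles": int(n_cycles),
        "seeds": [int(s) for s in seeds],
    }


def _seed_averaged_nca(
    params: AnalogParameters, n_cycles: int, seeds: Sequence[int], dose_d: float
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-seed NCA rows plus their across-seed mean for one parameterization."""
    rows = []
    for seed in seeds:
        trajectory = run_simulation(params, n_cycles=n_cycles, seed=int(seed))
        result = nca(build_profile(trajectory, params, d=dose_d))
        rows.append({"seed": int(seed), **result.as_dict()})
    per_seed = pd.DataFrame(rows)
    return per_seed, {m: float(per_seed[m].mean()) for m in NCA_METRICS}


@dataclass(frozen=True)
class PanelSummary:
    """Across-subject NCA summary for one condition (mean +/- SD, ddof=1)."""

    condition: str
    per_subject: pd.DataFrame  # one row per subject: seed-averaged NCA
    per_seed: pd.DataFrame  # one row per (subject, seed)
    mean: pd.Series
    sd: pd.Series
    seed_dispersion: pd.Series  # SD across seeds of the panel means
    manifest: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd, "seed_sd": self.seed_dispersion})


def run_subject_panel(
    condition: str,
    n_cycles: int = 20,
    seeds: Sequence[int] = (0,),
    dose_d: float = 1.0,
) -> PanelSummary:
    """Run all six subjects under one condition and summarize their NCA.

    Each subject runs once per seed; NCA metrics are averaged across seeds
    per subject before taking the across-subject mean and SD (n-1
    denominator).  ``seed_dispersion`` reports how much the panel means move
    across seeds.
    """
    if condition not in CONDITIONS:
        raise KeyError(f"unknown condition {condition!r}")
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    subject_rows, seed_rows, manifests = [], [], []
    for subject_id in SUBJECT_IDS:
        config = load_subject_config(subject_id, condition)
        per_seed, means = _seed_averaged_nca(config.params, n_cycles, seeds, dose_d)
        subject_rows.append({"subject": subject_id, **means})
        seed_rows.append(per_seed.assign(subject=subject_id))
        manifests.append({"subject": subject_id, **run_manifest(config.params, n_cycles, seeds)})
    per_subject = pd.DataFrame(subject_rows).set_index("subject")
    per_seed = pd.concat(seed_rows, ignore_index=True)
    # panel mean per seed, then its dispersion across seeds
    by_seed = per_seed.groupby("seed")[list(NCA_METRICS)].mean()
    seed_sd = by_seed.std(ddof=1) if len(seeds) > 1 else by_seed.iloc[0] * np.nan
    return PanelSummary(
        condition=condition,
        per_subject=per_subject,
        per_seed=per_seed,
        mean=per_subject[list(NCA_METRICS)].mean(),
        sd=per_subject[list(NCA_METRICS)].std(ddof=1),
        seed_dispersion=seed_sd,
        manifest=manifests,
    )


@dataclass(frozen=True)
class SweepRecord:
    value: float
    trajectories: list[pd.DataFrame]
    nca_results: list[NCAResult]
    mean_nca: dict[str, float]


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    records: list[SweepRecord]
    manifest: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"value": r.value, **r.mean_nca} for r in self.records]
        ).set_index("value")


def parameter_sweep(
    base: AnalogParameters,
    name: str,
    values: Sequence[float],
    n_cycles: int = 20,
    seeds: Sequence[int] = (0,),
    dose_d: float = 1.0,
) -> SweepResult:
    """Re-run the analog from a shared base, varying one parameter.

    Every value runs with the same seed list, so differences between records
    reflect the parameter, not the noise realization.
    """
    if not hasattr(base, name):
        raise KeyError(f"unknown parameter {name!r}")
    records, manifests = [], []
    for value in values:
        params = base.replace(**{name: value})  # validates the range
        trajectories, results = [], []
        for seed in seeds:
            trajectory = run_simulation(params, n_cycles=n_cycles, seed=int(seed))
            trajectories.append(trajectory)
            results.append(nca(build_profile(trajectory, params, d=dose_d)))
        mean_nca = {
            m: float(np.mean([r.as_dict()[m] for r in results])) for m in NCA_METRICS
        }
        records.append(SweepRecord(value, trajectories, results, mean_nca))
        manifests.append({"value": value, **run_manifest(params, n_cycles, seeds)})
    return SweepResult(parameter=name, records=records, manifest=manifests)


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of the simulate-validate-revise loop.

    ``status`` is ``"validated"`` when an iteration met the similarity
    criteria, else ``"falsified"`` once the iteration budget is spent —
    a reported outcome, not an error.
    """

    status: str
    params: AnalogParameters
    n_iterations: int
    history: pd.DataFrame  # per-iteration similarity metrics
    final_report: SimilarityReport

    @property
    def validated(self) -> bool:
        return self.status == "validated"

    def summary(self) -> str:
        lines = [
            f"Refinement {self.status} after {self.n_iterations} iteration(s)",
            f"  final: {self.final_report.n_inner}/{self.final_report.n_checked} "
            f"points in the inner band "
            f"(need >= {self.final_report.criteria.min_inner_count}); "
            f"outer band +/-{self.final_report.criteria.outer_band:.0%}, "
            f"inner +/-{self.final_report.criteria.inner_band:.0%}",
        ]
        return "\n".join(lines)


ProposalRule = Callable[[AnalogParameters, SimilarityReport | None, int], AnalogParameters]


def iterate_refinement(
    referent: PlasmaProfile,
    start: AnalogParameters,
    proposal_rule: ProposalRule,
    max_iter: int = 100,
    n_cycles: int = 20,
    seed: int = 0,
    dose_d: float = 1.0,
    criteria: SimilarityCriteria | None = None,
) -> RefinementResult:
    """Iteratively revise parameters until the similarity criteria pass.

    Each iteration i (1-based) first asks ``proposal_rule(params, report, i)``
    for the parameterization to try (the rule receives the previous
    iteration's report, or None on the first call), then simulates with seed
    ``seed + i - 1`` and validates against ``referent``.  Stops at the first
    pass or after ``max_iter`` iterations.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    criteria = criteria or SimilarityCriteria()
    params = start
    report: SimilarityReport | None = None
    rows = []
    for i in range(1, max_iter + 1):
        params = proposal_rule(params, report, i)
        trajectory = run_simulation(params, n_cycles=n_cycles, seed=seed + i - 1)
        simulated = build_profile(trajectory, params, d=dose_d)
        report = similarity_check(align_profiles(simulated, referent), criteria)
        max_dev = float(
            report.points.loc[report.points["checked"], "rel_dev"].max()
        )
        rows.append(
            {
                "iteration": i,
                "passed": report.passed,
                "n_inner": report.n_inner,
                "n_checked": report.n_checked,
                "max_rel_dev": max_dev,
                "params_hash": params_hash(params),
            }
        )
        if report.passed:
            return RefinementResult("validated", params, i, pd.DataFrame(rows), report)
    assert report is not None
    return RefinementResult("falsified", params, max_iter, pd.DataFrame(rows), report)


def random_search_rule(
    names: Sequence[str],
    seed: int = 0,
    delay_high: int = 14,
) -> ProposalRule:
    """A simple scripted proposal rule: redraw the named parameters uniformly
    at random each iteration (fractions/probabilities/ratios/rates in [0, 1],
    delays as integers in [0, delay_high]).  The first iteration keeps the
    starting parameters untouched, so a known-good start validates
    immediately."""
    rng = np.random.default_rng(seed)

    def rule(
        params: AnalogParameters, report: SimilarityReport | None, iteration: int
    ) -> AnalogParameters:
        if iteration == 1:
            return params
        changes = {}
        for name in names:
            if name.endswith("_delay"):
                changes[name] = int(rng.integers(0, delay_high + 1))
            else:
                changes[name] = float(rng.uniform(0.0, 1.0))
        return params.replace(**changes)

    return rule
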