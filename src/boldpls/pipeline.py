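"""End-to-end orchestration: participant flow, stage composition, reporting.

`run_analysis` ties the stages together in the study's fixed order:
clinical gating (depression/mania severity), subset filtering (patients-
only or single-site control reruns), confound residualization of the
imaging matrix, PLS correlation fit, within-group permutation and
bootstrap inference, and the post-hoc battery. The whole run is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as bio
from .cohort import CohortSpec, behavior_matrix, default_truth, generate_cohort, generate_variability_maps
from .confounds import ConfoundRegressor, encode_confounds
from .pls import PLSCorrelation, compute_loadings
from .posthoc import posthoc_battery
from .resampling import bootstrap_test, permutation_test

MADRS_GATE = 15.0  # excluded iff strictly above
YMRS_GATE = 7.0


@dataclass
class Config:
    """All pipeline constants; defaults are the study's fixed values."""

    f_lo: float = 0.01
    f_hi: float = 0.10
    fd_threshold_mm: float = 0.5
    n_before: int = 1
    n_after: int = 2
    min_seconds: float = 240.0
    gm_threshold: float = 0.5
    madrs_gate: float = MADRS_GATE
    ymrs_gate: float = YMRS_GATE
    n_perm: int = 1000
    n_boot: int = 1000
    z_threshold: float = 3.0
    fdr_q: float = 0.05
    seed: int = 0
    groups: tuple | None = None  # subset filter, e.g. ("BD","ADHD","BPD")
    scanners: tuple | None = None  # subset filter on scanner levels
    procrustes: bool = True
    literal_fd: bool = False
    deconfound_behavior: bool = False
    loadings_source: str = "deconfounded"  # or "original"
    apply_clinical_gates: bool = True

    def validate(self) -> None:
        for name in ("fd_threshold_mm", "min_seconds", "gm_threshold", "z_threshold", "fdr_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError("need 0 <= f_lo < f_hi")
        if self.loadings_source not in ("deconfounded", "original"):
            raise ValueError("loadings_source must be 'deconfounded' or 'original'")

    def echo(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FlowSummary:
    recruited: dict
    exclusions: list  # [(reason, {group: n}), ...]
    final: dict

    @property
    def final_n(self) -> int:
        return sum(self.final.values())

    def as_dict(self) -> dict:
        return {
            "recruited": dict(self.recruited),
            "exclusions": [{"reason": r, "counts": dict(c)} for r, c in self.exclusions],
            "final": dict(self.final),
            "final_n": self.final_n,
        }


def apply_participant_flow(recruited: dict, exclusion_tallies: list) -> FlowSummary:
    """Sequentially subtract per-group exclusion tallies from recruitment
    counts; inconsistent tallies (negative remainders) are rejected."""
    remaining = {g: int(n) for g, n in recruited.items()}
    if any(n < 0 for n in remaining.values()):
        raise ValueError("negative recruitment count")
    for reason, counts in exclusion_tallies:
        for g, n in counts.items():
            if n < 0:
                raise ValueError(f"negative exclusion tally for {g} ({reason})")
            if g not in remaining:
                raise ValueError(f"exclusion for unknown group {g!r} ({reason})")
            remaining[g] -= int(n)
            if remaining[g] < 0:
                raise ValueError(
                    f"inconsistent tallies: group {g} drops below zero at step {reason!r}"
                )
    return FlowSummary(
        recruited=dict(recruited),
        exclusions=[(r, dict(c)) for r, c in exclusion_tallies],
        final=remaining,
    )


@dataclass
class RunReport:
    flow: FlowSummary
    component_table: pd.DataFrame
    n_flagged_brain: list
    n_flagged_behavior: list
    posthoc: pd.DataFrame
    config: dict
    seed: int
    brain_saliences: np.ndarray | None = None
    brain_z: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "flow": self.flow.as_dict(),
            "components": self.component_table.to_dict(orient="records"),
            "n_flagged_brain": list(self.n_flagged_brain),
            "n_flagged_behavior": list(self.n_flagged_behavior),
            "posthoc": self.posthoc.to_dict(orient="records"),
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        bio.write_json(self.as_dict(), path)


def _gate_exclusions(cohort: pd.DataFrame, config: Config):
    """Clinical severity gates: exclusion iff MADRS > gate or YMRS > gate
    (strict inequalities)."""
    madrs_bad = cohort["madrs"] > config.madrs_gate
    ymrs_bad = ~madrs_bad & (cohort["ymrs"] > config.ymrs_gate)
    keep = ~(madrs_bad | ymrs_bad)
    tallies = []
    for reason, mask in (("madrs_above_gate", madrs_bad), ("ymrs_above_gate", ymrs_bad)):
        counts = cohort.loc[mask, "group"].value_counts().to_dict()
        tallies.append((reason, {g: int(n) for g, n in counts.items()}))
    return keep.to_numpy(), tallies


def run_analysis(
    cohort: pd.DataFrame,
    X: np.ndarray,
    config: Config | None = None,
    mask: np.ndarray | None = None,
) -> RunReport:
    """Run the full analysis on a cohort table and a stacked participant-
    by-voxel variability matrix (already z-scored per participant, or any
    matrix of per-voxel measures).

    Stages: subset filter -> clinical gates -> voxel mask -> confound
    residualization of X -> PLS fit -> within-group permutation ->
    within-group bootstrap -> post-hoc battery on component 1 scores.
    """
    config = config if config is not None else Config()
    config.validate()
    X = np.asarray(X, float)
    if X.shape[0] != len(cohort):
        raise ValueError("imaging rows do not match cohort rows")
    cohort = cohort.reset_index(drop=True)

    recruited = {g: int(n) for g, n in cohort["group"].value_counts().items()}
    keep = np.ones(len(cohort), bool)
    tallies = []
    if config.groups is not None:
        drop = ~cohort["group"].isin(config.groups).to_numpy()
        tallies.append(
            ("outside_group_subset",
             {g: int(n) for g, n in cohort.loc[drop, "group"].value_counts().items()})
        )
        keep &= ~drop
    if config.scanners is not None:
        drop = ~cohort["scanner"].isin(config.scanners).to_numpy() & keep
        tallies.append(
            ("outside_scanner_subset",
             {g: int(n) for g, n in cohort.loc[drop, "group"].value_counts().items()})
        )
        keep &= ~drop
    cohort = cohort.loc[keep].reset_index(drop=True)
    X = X[keep]

    if config.apply_clinical_gates:
        gkeep, gate_tallies = _gate_exclusions(cohort, config)
        tallies.extend(gate_tallies)
        cohort = cohort.loc[gkeep].reset_index(drop=True)
        X = X[gkeep]
    flow = apply_participant_flow(recruited, tallies)

    if mask is not None:
        X = X[:, np.asarray(mask, bool)]

    design = encode_confounds(cohort)
    X_orig = X
    X = ConfoundRegressor(design).fit_transform(X)
    Y_orig = behavior_matrix(cohort)
    Y = ConfoundRegressor(design).fit_transform(Y_orig) if config.deconfound_behavior else Y_orig

    model = PLSCorrelation().fit(X, Y)
    groups = cohort["group"].to_numpy()
    perm = permutation_test(
        X, Y, groups, model,
        n_perm=config.n_perm, procrustes=config.procrustes, seed=config.seed,
    )
    X_src = X_orig if config.loadings_source == "original" else X
    boot = bootstrap_test(
        X, Y, groups, model,
        n_boot=config.n_boot, threshold=config.z_threshold,
        procrustes=config.procrustes, seed=config.seed + 1,
        X_loading_source=X_src, Y_loading_source=Y_orig,
    )
    post = posthoc_battery(
        model.x_scores_[:, 0], model.y_scores_[:, 0], cohort, q=config.fdr_q
    )
    return RunReport(
        flow=flow,
        component_table=bio.component_table(model, perm.perm_p),
        n_flagged_brain=[int(boot.brain_flagged[:, k].sum()) for k in range(model.n_components_)],
        n_flagged_behavior=[int(boot.behavior_flagged[:, k].sum()) for k in range(model.n_components_)],
        posthoc=post,
        config=config.echo(),
        seed=config.seed,
        brain_saliences=model.x_saliences_,
        brain_z=boot.brain_z,
    )


def simulate_study(
    config: Config | None = None,
    n_voxels: int = 2000,
    effect_size: float = 0.5,
    noise_sd: float = 1.0,
    spec: CohortSpec | None = None,
    truth=None,
):
    """Generate a full synthetic study: cohort + planted truth + maps.

    Returns ``(cohort, X, truth)``; all randomness descends from
    ``config.seed``.
    """
    config = config if config is not None else Config()
    spec = spec if spec is not None else CohortSpec(seed=config.seed)
    cohort = generate_cohort(spec)
    if truth is None:
        truth = default_truth(n_voxels, effect_size=effect_size, seed=config.seed + 10_000)
    X, _ = generate_variability_maps(
        cohort, truth, n_voxels, noise_sd=noise_sd, seed=config.seed + 20_000
    )
    return cohort, X, truth
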