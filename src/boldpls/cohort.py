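"""Synthetic transdiagnostic cohorts with planted brain-behavior structure.

Generates (i) a cohort table whose per-group behavioral moments are matched
exactly to a user-supplied specification (defaults emulate a four-group
clinical sample of 166 participants: healthy controls, bipolar disorder,
ADHD, and borderline personality disorder, with affective lability (ALS),
depression (MADRS) and mania (YMRS) scores), (ii) participant-by-voxel
variability matrices carrying a planted rank-one brain-behavior component of
controlled effect size, and (iii) raw band-limited BOLD-like runs with
motion traces for end-to-end pipeline tests.

All randomness is driven by explicit integer seeds; there is no global
random state anywhere in this module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("HC", "BD", "ADHD", "BPD")
MEASURES = ("als", "madrs", "ymrs")

#: Per-group (mean, SD) of the three behavior scales in the emulated sample.
DEFAULT_BEHAVIOR_MOMENTS = {
    "HC": {"als": (0.42, 0.40), "madrs": (1.23, 2.17), "ymrs": (0.66, 1.39)},
    "BD": {"als": (1.04, 0.64), "madrs": (4.84, 4.51), "ymrs": (1.68, 1.87)},
    "ADHD": {"als": (1.12, 0.48), "madrs": (3.55, 3.44), "ymrs": (0.00, 0.00)},
    "BPD": {"als": (1.80, 0.46), "madrs": (7.68, 3.45), "ymrs": (1.47, 1.39)},
}

DEFAULT_GROUP_SIZES = {"HC": 64, "BD": 63, "ADHD": 20, "BPD": 19}

#: age mean/SD, fraction female, scanner occupancy (4 scanners), mean-FD mean/SD
DEFAULT_CONFOUND_MODEL = {
    "HC": {
        "age": (35.06, 12.01),
        "sex_f": 37 / 64,
        "scanner": (16 / 64, 48 / 64, 0.0, 0.0),
        "mean_fd": (0.17, 0.07),
    },
    "BD": {
        "age": (37.22, 11.61),
        "sex_f": 30 / 63,
        "scanner": (16 / 63, 21 / 63, 10 / 63, 16 / 63),
        "mean_fd": (0.17, 0.09),
    },
    "ADHD": {
        "age": (24.00, 3.45),
        "sex_f": 7 / 20,
        "scanner": (1.0, 0.0, 0.0, 0.0),
        "mean_fd": (0.14, 0.05),
    },
    "BPD": {
        "age": (27.05, 4.67),
        "sex_f": 1.0,
        "scanner": (1.0, 0.0, 0.0, 0.0),
        "mean_fd": (0.13, 0.04),
    },
}


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``behavior_moments[group][measure] = (mean, sd)``; the realized sample
    moments match these exactly (see :func:`generate_cohort`).
    ``confound_model[group]`` holds ``age`` (mean, sd), ``sex_f`` (fraction
    female in [0, 1]), ``scanner`` (occupancy over scanner levels, sums to
    1), and ``mean_fd`` (mean, sd).
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    behavior_moments: dict = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_BEHAVIOR_MOMENTS.items()}
    )
    confound_model: dict = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_CONFOUND_MODEL.items()}
    )
    seed: int = 0
    clip_at_zero: bool = False  # optional, off by default: clipping biases means

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size {n}")
            for meas, (mu, sd) in self.behavior_moments[g].items():
                if sd < 0:
                    raise ValueError(f"negative SD {sd} for {g}/{meas}")
            cm = self.confound_model[g]
            if not 0.0 <= cm["sex_f"] <= 1.0:
                raise ValueError(f"sex fraction out of [0,1] for {g}")
            if abs(sum(cm["scanner"]) - 1.0) > 1e-9:
                raise ValueError(f"scanner occupancy for {g} does not sum to 1")
            if cm["age"][1] < 0 or cm["mean_fd"][1] < 0:
                raise ValueError(f"negative SD in confound model for {g}")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted latent component.

    ``brain_salience_true`` (length V) and ``behavior_salience_true``
    (length B) are unit-norm; ``effect_size`` is the fraction of total X
    variance carried by the planted component. ``group_offsets`` maps a
    group label to a pair ``(x_offset, y_offset)``; only the X side is
    added by :func:`generate_variability_maps` (behavioral group
    differences already come from the per-group moments).
    """

    brain_salience_true: np.ndarray
    behavior_salience_true: np.ndarray
    effect_size: float = 0.5
    confound_effects: np.ndarray | None = None  # K x V
    group_offsets: dict | None = None

    def __post_init__(self) -> None:
        self.brain_salience_true = np.asarray(self.brain_salience_true, float)
        self.behavior_salience_true = np.asarray(self.behavior_salience_true, float)
        for name in ("brain_salience_true", "behavior_salience_true"):
            v = getattr(self, name)
            nrm = np.linalg.norm(v)
            if nrm == 0:
                raise ValueError(f"{name} is all zero")
            if abs(nrm - 1.0) > 1e-8:
                setattr(self, name, v / nrm)
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must lie in [0, 1)")

    @property
    def support(self) -> np.ndarray:
        """Indices of voxels with non-zero planted weight."""
        return np.flatnonzero(self.brain_salience_true)


def default_truth(
    n_voxels: int,
    effect_size: float = 0.5,
    support_fraction: float = 0.10,
    behavior_salience: np.ndarray | None = None,
    group_offsets: dict | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Planted truth with sparse brain support and an affective-lability /
    depression dominated behavior pattern (mania near zero), echoing the
    loading profile typical of emotion-dysregulation components."""
    rng = np.random.default_rng(seed)
    n_sup = max(1, int(round(support_fraction * n_voxels)))
    b = np.zeros(n_voxels)
    signs = rng.choice([-1.0, 1.0], size=n_sup)
    b[:n_sup] = signs * (1.0 + 0.25 * rng.standard_normal(n_sup))
    b /= np.linalg.norm(b)
    if behavior_salience is None:
        behavior_salience = np.array([0.70, 0.70, 0.08])
    return SyntheticTruth(
        brain_salience_true=b,
        behavior_salience_true=behavior_salience,
        effect_size=effect_size,
        group_offsets=group_offsets,
    )


def _moment_match(raw: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affinely rescale ``raw`` so the sample mean/SD (ddof=0) are exact."""
    n = raw.size
    if sd == 0.0 or n == 1:
        return np.full(n, mean)
    s = raw.std()
    if s == 0.0:  # astronomically unlikely for continuous draws; be safe
        raise RuntimeError("degenerate draw: zero sample variance")
    return (raw - raw.mean()) / s * sd + mean


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate a cohort table with exactly matched group moments.

    Per group and measure the realized sample mean and SD (population
    convention, ddof=0) equal the specified moments to numerical precision:
    standard-normal deviates are drawn per group and affinely rescaled.
    Sex and scanner are assigned as exact counts (largest-remainder
    rounding of the specified proportions) shuffled within group.

    Returns a DataFrame with columns
    ``participant_id group age sex scanner mean_fd als madrs ymrs``.
    """
    spec = spec if spec is not None else CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g, n in spec.group_sizes.items():
        cm = spec.confound_model[g]
        age = _moment_match(rng.standard_normal(n), *cm["age"])
        fd = _moment_match(rng.standard_normal(n), *cm["mean_fd"])
        beh = {}
        for meas in MEASURES:
            mu, sd = spec.behavior_moments[g][meas]
            vals = _moment_match(rng.standard_normal(n), mu, sd)
            if spec.clip_at_zero:
                vals = np.clip(vals, 0.0, None)
            beh[meas] = vals
        n_f = int(round(cm["sex_f"] * n))
        sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
        rng.shuffle(sex)
        scanner = _exact_counts(np.asarray(cm["scanner"], float), n)
        rng.shuffle(scanner)
        for i in range(n):
            rows.append(
                {
                    "participant_id": f"{g}{i:03d}",
                    "group": g,
                    "age": age[i],
                    "sex": sex[i],
                    "scanner": int(scanner[i]),
                    "mean_fd": fd[i],
                    "als": beh["als"][i],
                    "madrs": beh["madrs"][i],
                    "ymrs": beh["ymrs"][i],
                }
            )
    return pd.DataFrame(rows)


def _exact_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n items over levels 1..L."""
    quota = proportions * n
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    return np.repeat(np.arange(1, len(proportions) + 1), counts)


def behavior_matrix(cohort: pd.DataFrame) -> np.ndarray:
    """N x 3 behavior matrix in fixed column order (ALS, MADRS, YMRS)."""
    return cohort[list(MEASURES)].to_numpy(float)


def generate_variability_maps(
    cohort: pd.DataFrame,
    truth: SyntheticTruth,
    n_voxels: int,
    noise_sd: float = 1.0,
    seed: int = 0,
    confounds: np.ndarray | None = None,
):
    """Participant-by-voxel matrix with a planted rank-one component.

    X = latent_score * brain_salience' * scale + confounds @ confound_effects
        + group X-offsets + iid N(0, noise_sd) noise,

    where ``latent_score`` is the pooled-standardized projection of the
    cohort's behavior matrix onto ``behavior_salience_true`` (unit variance,
    so its correlation with Y @ u_true is exactly 1). ``scale`` is set so
    the planted component carries ``truth.effect_size`` of the total X
    variance: scale^2 = es/(1-es) * V * noise_sd^2 (scale=1 when
    noise_sd=0).

    Returns ``(X, latent_score)``.
    """
    V = int(n_voxels)
    if truth.brain_salience_true.size != V:
        raise ValueError(
            f"truth has {truth.brain_salience_true.size} voxel weights, expected {V}"
        )
    if V < truth.support.size:
        raise ValueError("n_voxels smaller than the planted support")
    rng = np.random.default_rng(seed)
    Y = behavior_matrix(cohort)
    Yz = (Y - Y.mean(0)) / np.where(Y.std(0) > 0, Y.std(0), 1.0)
    latent = Yz @ truth.behavior_salience_true
    lsd = latent.std()
    if lsd > 0:
        latent = (latent - latent.mean()) / lsd
    es = truth.effect_size
    if es == 0.0:
        scale = 0.0
    elif noise_sd == 0.0:
        scale = 1.0
    else:
        scale = np.sqrt(es / (1.0 - es) * V * noise_sd**2)
    X = scale * np.outer(latent, truth.brain_salience_true)
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal((len(cohort), V))
    if confounds is not None and truth.confound_effects is not None:
        X = X + np.asarray(confounds, float) @ truth.confound_effects
    if truth.group_offsets:
        for g, (x_off, _y_off) in truth.group_offsets.items():
            idx = (cohort["group"] == g).to_numpy()
            X[idx] += np.asarray(x_off, float)
    return X, latent


def generate_bold_run(
    n_frames: int,
    n_voxels: int,
    tr: float,
    target_sd: np.ndarray,
    spike_frames: set | None = None,
    seed: int = 0,
    participant_id: str = "sim",
    f_lo: float = 0.01,
    f_hi: float = 0.10,
):
    """Band-limited Gaussian run plus a motion trace with planted FD spikes.

    Time-courses are white Gaussian noise band-passed to [f_lo, f_hi] Hz
    and rescaled per voxel so the in-band SD equals ``target_sd`` exactly.
    Baseline motion is a tiny random walk whose framewise displacement
    stays well below 0.5 mm; each spike frame adds a persistent 0.8 mm
    translation step, so FD exceeds 0.5 mm at exactly those frames.
    """
    from .variability import BoldRun, bandpass_filter

    if n_frames < 10:
        raise ValueError(f"n_frames must be >= 10, got {n_frames}")
    if tr <= 0:
        raise ValueError("TR must be positive")
    spike_frames = set() if spike_frames is None else set(int(s) for s in spike_frames)
    for s in spike_frames:
        if not 0 <= s < n_frames:
            raise ValueError(f"spike frame {s} outside [0, {n_frames})")
        if s == 0:
            # fd[0] is 0 by convention, so no excursion can exist there
            raise ValueError("spike frame 0 cannot produce an FD excursion")
    target_sd = np.broadcast_to(np.asarray(target_sd, float), (n_voxels,))
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_frames, n_voxels))
    data = bandpass_filter(data, tr, f_lo, f_hi)
    sd = data.std(0)
    sd[sd == 0] = 1.0
    data = data / sd * target_sd

    motion = np.cumsum(
        np.concatenate(
            [
                rng.normal(0.0, 0.01, (n_frames, 3)),  # translations, mm
                rng.normal(0.0, 1e-4, (n_frames, 3)),  # rotations, rad
            ],
            axis=1,
        ),
        axis=0,
    )
    motion[0] = 0.0
    for s in spike_frames:
        motion[s:, 0] += 0.8
    return BoldRun(data=data, tr=tr, motion=motion, participant_id=participant_id)
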