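"""From motion-annotated BOLD time-courses to z-scored variability maps.

The per-participant measure of neural variability is the standard deviation
of each preprocessed voxel time-course, computed after nuisance regression,
ideal band-pass filtering (0.01-0.10 Hz), and motion scrubbing, then
z-scored across all in-mask voxels within the participant. With an ideal
frequency-domain filter this SD is identical (Parseval) to the amplitude of
low-frequency fluctuations (ALFF) in the same band, and it is strongly
rank-correlated with mean-square successive differences (MSSD); both
alternatives are provided.

Framewise displacement follows the standard backward-difference convention:
the sum of absolute changes of the three translations (mm) plus the three
rotations converted to arc length on a 50 mm sphere. A literal variant that
sums the parameters themselves without differencing is available behind
``literal=True`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_ROTATION_RADIUS_MM = 50.0
DEFAULT_MIN_SECONDS = 240.0
DEFAULT_BAND = (0.01, 0.10)


@dataclass
class BoldRun:
    """One participant's T x V time-course with motion parameters.

    ``motion`` columns are three translations in mm followed by three
    rotations in radians (SPM realignment convention).
    """

    data: np.ndarray
    tr: float
    motion: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.motion = np.asarray(self.motion, float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be T x V with T >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in data")
        if self.motion.shape != (self.data.shape[0], 6):
            raise ValueError("motion must be T x 6 matching data rows")
        if not np.all(np.isfinite(self.motion)):
            raise ValueError("non-finite values in motion")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class ScrubResult:
    fd: np.ndarray
    keep: np.ndarray
    retained_seconds: float


@dataclass
class AnalysisMask:
    """Boolean voxel-inclusion mask with a human-readable provenance tag."""

    include: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include, bool)
        if not self.include.any():
            raise ValueError("analysis mask is empty")


@dataclass
class VariabilityMap:
    """Per-participant voxel vector of BOLD-signal SD (z-units if zscored)."""

    values: np.ndarray
    zscored: bool = False
    mask_id: str = ""
    participant_id: str = ""


@dataclass
class ExclusionVerdict:
    """Participant dropped by the minimum-retained-duration gate."""

    participant_id: str
    retained_seconds: float
    reason: str = "insufficient retained scan time"


def framewise_displacement(
    motion: np.ndarray,
    rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM,
    literal: bool = False,
) -> np.ndarray:
    """Scalar head-motion series from six realignment parameters.

    Default: backward differences, fd[t] = sum |d trans_t| (mm)
    + radius * sum |d rot_t| (rad -> mm arc length); fd[0] = 0.
    ``literal=True`` sums the absolute parameters without differencing
    (no-derivative reading, for sensitivity analyses only).
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion parameters")
    scaled = motion.copy()
    scaled[:, 3:] *= rotation_radius_mm
    if literal:
        return np.abs(scaled).sum(axis=1)
    fd = np.zeros(motion.shape[0])
    fd[1:] = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return fd


def scrub_mask(
    fd: np.ndarray,
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    n_before: int = 1,
    n_after: int = 2,
) -> np.ndarray:
    """Frames to keep after censoring FD excursions with a padding window.

    A frame t is removed iff some frame s with fd[s] > threshold (strictly
    greater) satisfies s - n_before <= t <= s + n_after, windows clipped at
    the run boundaries.
    """
    fd = np.asarray(fd, float)
    if not np.all(np.isfinite(fd)):
        raise ValueError("non-finite FD values")
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    T = fd.size
    keep = np.ones(T, bool)
    for s in np.flatnonzero(fd > threshold_mm):
        keep[max(0, s - n_before) : min(T, s + n_after + 1)] = False
    return keep


def min_duration_ok(keep: np.ndarray, tr: float, min_seconds: float = DEFAULT_MIN_SECONDS) -> bool:
    """True iff the retained scan time reaches ``min_seconds`` (>= compare)."""
    if tr <= 0:
        raise ValueError("TR must be positive")
    return bool(np.count_nonzero(keep) * tr >= min_seconds)


def nuisance_regress(data: np.ndarray, regressors: np.ndarray | None) -> np.ndarray:
    """Per-voxel least-squares removal of nuisance signals (plus intercept).

    The design is [intercept | regressors]; residuals are orthogonal to its
    column span. Rank-deficient designs are rejected with the offending
    columns named (0-based indices into ``regressors``).
    """
    data = np.asarray(data, float)
    T = data.shape[0]
    if regressors is None or (hasattr(regressors, "size") and np.size(regressors) == 0):
        design = np.ones((T, 1))
    else:
        regressors = np.asarray(regressors, float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != T:
            raise ValueError("regressor rows must match data rows")
        if regressors.shape[1] >= T:
            raise ValueError("need more frames than regressors")
        design = np.column_stack([np.ones(T), regressors])
        bad = _dependent_columns(design)
        if bad:
            raise ValueError(
                "rank-deficient nuisance design; dependent regressor column(s): "
                + ", ".join(str(b - 1) for b in bad)
            )
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def _dependent_columns(design: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Columns linearly dependent on their predecessors (greedy QR sweep)."""
    bad = []
    basis = np.empty((design.shape[0], 0))
    for j in range(design.shape[1]):
        col = design[:, j]
        if basis.shape[1]:
            col = col - basis @ (basis.T @ col)
        nrm = np.linalg.norm(col)
        if nrm <= tol * max(1.0, np.linalg.norm(design[:, j])):
            bad.append(j)
        else:
            basis = np.column_stack([basis, col / nrm])
    return bad


def _band_mask(T: int, tr: float, f_lo: float, f_hi: float) -> np.ndarray:
    nyquist = 1.0 / (2.0 * tr)
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"f_hi {f_hi} Hz exceeds Nyquist {nyquist:.6g} Hz at TR {tr}")
    freqs = np.fft.rfftfreq(T, d=tr)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    mask[0] = False  # DC always removed
    return mask


def bandpass_filter(
    data: np.ndarray, tr: float, f_lo: float = DEFAULT_BAND[0], f_hi: float = DEFAULT_BAND[1]
) -> np.ndarray:
    """Ideal frequency-domain band-pass: out-of-band Fourier bins zeroed."""
    data = np.asarray(data, float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    T = data.shape[0]
    mask = _band_mask(T, tr, f_lo, f_hi)
    spec = np.fft.rfft(data, axis=0)
    spec[~mask] = 0.0
    out = np.fft.irfft(spec, n=T, axis=0)
    return out[:, 0] if squeeze else out


def variability_sd(data: np.ndarray, keep: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel population SD over kept frames (the variability measure)."""
    data = np.asarray(data, float)
    if keep is None:
        keep = np.ones(data.shape[0], bool)
    keep = np.asarray(keep, bool)
    if np.count_nonzero(keep) < 2:
        raise ValueError("fewer than 2 kept frames")
    return data[keep].std(axis=0)


def alff(
    data: np.ndarray, tr: float, f_lo: float = DEFAULT_BAND[0], f_hi: float = DEFAULT_BAND[1]
) -> np.ndarray:
    """Amplitude of low-frequency fluctuations, normalized to equal the SD
    of the ideally band-passed series (Parseval identity)."""
    data = np.asarray(data, float)
    squeeze = data.ndim == 1
    if squeeze:
        data = data[:, None]
    T = data.shape[0]
    mask = _band_mask(T, tr, f_lo, f_hi)
    spec = np.fft.rfft(data, axis=0)
    # rfft Parseval weights: interior bins count twice, DC/Nyquist once
    w = np.full(mask.size, 2.0)
    w[0] = 1.0
    if T % 2 == 0:
        w[-1] = 1.0
    power = (w[mask, None] * np.abs(spec[mask]) ** 2).sum(axis=0)
    out = np.sqrt(power) / T
    return out[0] if squeeze else out


def mssd(data: np.ndarray, keep: np.ndarray | None = None) -> np.ndarray:
    """Mean squared successive difference over consecutive kept-frame pairs."""
    data = np.asarray(data, float)
    if keep is None:
        keep = np.ones(data.shape[0], bool)
    keep = np.asarray(keep, bool)
    pair = keep[:-1] & keep[1:]
    if not pair.any():
        raise ValueError("no consecutive kept frame pair")
    d = np.diff(data, axis=0)
    return (d[pair] ** 2).mean(axis=0)


def zscore_map(
    values: np.ndarray, mask: AnalysisMask, participant_id: str = ""
) -> VariabilityMap:
    """Z-score a voxel map across in-mask voxels (population SD); voxels
    outside the mask become NaN."""
    values = np.asarray(values, float)
    if values.size != mask.include.size:
        raise ValueError("map length does not match mask")
    inm = values[mask.include]
    sd = inm.std()
    if sd <= 0:
        raise ValueError("zero in-mask variance; cannot z-score")
    out = np.full(values.size, np.nan)
    out[mask.include] = (inm - inm.mean()) / sd
    return VariabilityMap(values=out, zscored=True, mask_id=mask.source, participant_id=participant_id)


def build_analysis_mask(
    gm_prob: np.ndarray,
    exclusion: np.ndarray | None = None,
    gm_threshold: float = 0.5,
) -> AnalysisMask:
    """Gray-matter-probability threshold (>=) minus an exclusion mask."""
    gm_prob = np.asarray(gm_prob, float)
    if gm_prob.min() < 0 or gm_prob.max() > 1:
        raise ValueError("gray-matter probabilities must lie in [0, 1]")
    include = gm_prob >= gm_threshold
    desc = f"gm>={gm_threshold}"
    if exclusion is not None:
        include = include & ~np.asarray(exclusion, bool)
        desc += ",exclusion applied"
    if not include.any():
        raise ValueError("empty analysis mask after thresholding/exclusion")
    return AnalysisMask(include=include, source=desc)


@dataclass
class VariabilityConfig:
    f_lo: float = DEFAULT_BAND[0]
    f_hi: float = DEFAULT_BAND[1]
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM
    n_before: int = 1
    n_after: int = 2
    min_seconds: float = DEFAULT_MIN_SECONDS
    rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM
    literal_fd: bool = False


def extract_variability(
    run: BoldRun,
    nuisance: np.ndarray | None,
    mask: AnalysisMask,
    config: VariabilityConfig | None = None,
):
    """Full per-participant pipeline, in the fixed order: nuisance
    regression -> band-pass -> FD -> scrubbing -> duration gate ->
    per-voxel SD over kept frames -> within-participant z-scoring.

    Returns a ``(VariabilityMap, ScrubResult)`` pair, or an
    ``ExclusionVerdict`` if retained time falls below the gate. Kept frames
    enter only the SD computation; they are not re-filtered.
    """
    cfg = config if config is not None else VariabilityConfig()
    resid = nuisance_regress(run.data, nuisance)
    filtered = bandpass_filter(resid, run.tr, cfg.f_lo, cfg.f_hi)
    fd = framewise_displacement(run.motion, cfg.rotation_radius_mm, literal=cfg.literal_fd)
    keep = scrub_mask(fd, cfg.fd_threshold_mm, cfg.n_before, cfg.n_after)
    retained = float(np.count_nonzero(keep) * run.tr)
    if not min_duration_ok(keep, run.tr, cfg.min_seconds):
        return ExclusionVerdict(run.participant_id, retained)
    sd = variability_sd(filtered, keep)
    vmap = zscore_map(sd, mask, participant_id=run.participant_id)
    return vmap, ScrubResult(fd=fd, keep=keep, retained_seconds=retained)
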