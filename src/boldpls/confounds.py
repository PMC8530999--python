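"""Residualization of imaging data on demographic/motion confounds.

Age, sex, scanner, and mean framewise displacement are linearly regressed
out of the stacked participant-by-voxel matrix before the PLS step. The
behavior matrix is deliberately left untouched by default; a flag enables
symmetric deconfounding for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

REQUIRED_COLUMNS = ("age", "sex", "scanner", "mean_fd")


@dataclass
class ConfoundDesign:
    """Numeric confound design (no intercept column; one is always added
    implicitly by the residualizer)."""

    matrix: np.ndarray
    column_names: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def encode_confounds(cohort: pd.DataFrame) -> ConfoundDesign:
    """Build the N x K design: age and mean FD numeric, sex as a single
    female indicator, scanner as L-1 treatment indicators against the
    lexicographically first level. Single-level categoricals are dropped
    with a warning; missing values are rejected with the offending rows."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks required columns: {missing_cols}")
    na_rows = cohort.index[cohort[list(REQUIRED_COLUMNS)].isna().any(axis=1)].tolist()
    if na_rows:
        raise ValueError(f"missing confound values in rows: {na_rows}")

    cols, names, notes = [], [], []
    cols.append(cohort["age"].to_numpy(float))
    names.append("age")
    sex_levels = sorted(cohort["sex"].astype(str).unique())
    if len(sex_levels) >= 2:
        cols.append((cohort["sex"].astype(str) == "F").to_numpy(float))
        names.append("sex_F")
    else:
        notes.append(f"sex has a single level ({sex_levels[0]}); column dropped")
        warnings.warn(notes[-1])
    scanner_levels = sorted(cohort["scanner"].astype(str).unique())
    if len(scanner_levels) >= 2:
        for lev in scanner_levels[1:]:  # first level is the reference
            cols.append((cohort["scanner"].astype(str) == lev).to_numpy(float))
            names.append(f"scanner_{lev}")
    else:
        notes.append(f"scanner has a single level ({scanner_levels[0]}); column dropped")
        warnings.warn(notes[-1])
    cols.append(cohort["mean_fd"].to_numpy(float))
    names.append("mean_fd")
    return ConfoundDesign(matrix=np.column_stack(cols), column_names=names, notes=notes)


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Per-voxel linear confound removal.

    Fits ordinary least squares of every voxel column on
    [intercept | design] and returns residuals; residual columns have mean
    zero and are orthogonal to every design column. Idempotent: applying
    the fitted transform to its own output changes nothing.

    Parameters
    ----------
    design : ConfoundDesign or array-like of shape (n_samples, n_confounds)
    """

    def __init__(self, design=None):
        self.design = design

    def _design_matrix(self, n: int) -> np.ndarray:
        d = self.design
        if isinstance(d, ConfoundDesign):
            d = d.matrix
        if d is None:
            return np.ones((n, 1))
        d = np.asarray(d, float)
        if d.ndim == 1:
            d = d[:, None]
        if d.shape[0] != n:
            raise ValueError("design rows do not match data rows")
        return np.column_stack([np.ones(n), d])

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (participants x voxels)")
        D = self._design_matrix(X.shape[0])
        if X.shape[0] <= D.shape[1]:
            raise ValueError("need more participants than design columns")
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("rank-deficient confound design (with intercept)")
        # thin-QR projector basis; reused by transform
        self.q_, _ = np.linalg.qr(D)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "q_"):
            raise RuntimeError("ConfoundRegressor is not fitted")
        X = np.asarray(X, float)
        if X.shape[0] != self.q_.shape[0]:
            raise ValueError("row count differs from the fitted design")
        return X - self.q_ @ (self.q_.T @ X)


def residualize(X: np.ndarray, design: ConfoundDesign | np.ndarray | None) -> np.ndarray:
    """Functional wrapper around :class:`ConfoundRegressor`."""
    return ConfoundRegressor(design).fit_transform(X)
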