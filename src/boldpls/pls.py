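"""Partial least squares correlation (PLS-C) between brain and behavior.

The model decomposes the behavior-by-voxel cross-correlation matrix
R = Y_z' X_z / (N - 1) by singular value decomposition, R = U S V'. Each
latent component (LC) k pairs a unit-norm behavior salience U[:, k] with a
unit-norm brain salience V[:, k]; S[k]^2 / sum S^2 is the fraction of
brain-behavior covariance the component explains. Projecting each
participant's (standardized) data onto the saliences yields brain scores
Lx = X_z V[:, k] and behavior scores Ly = Y_z U[:, k]. Loadings are Pearson
correlations of the original columns with those scores.

Both X and Y columns are z-scored (population SD) before the cross-product,
pooled over the whole sample. The sign of each component is fixed by making
the largest-magnitude entry of the behavior salience positive; brain
salience and both score vectors flip jointly, so the fit is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator


def standardize_columns(M: np.ndarray):
    """Z-score columns to mean 0 and population SD 1.

    Returns ``(Z, means, sds)``. Constant columns are rejected by name
    (index), since they carry no correlation information.
    """
    M = np.asarray(M, float)
    means = M.mean(axis=0)
    sds = M.std(axis=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at index: {bad.tolist()}")
    return (M - means) / sds, means, sds


def _apply_sign_convention(U: np.ndarray, V: np.ndarray):
    """Flip each component so the behavior salience's largest-magnitude
    entry is positive; returns the per-component flip signs."""
    flips = np.ones(U.shape[1])
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            flips[k] = -1.0
    return U * flips, V * flips, flips


@dataclass
class LatentComponent:
    """One fitted latent component plus (optional) inference results."""

    index: int
    singular_value: float
    brain_salience: np.ndarray
    behavior_salience: np.ndarray
    brain_scores: np.ndarray
    behavior_scores: np.ndarray
    explained_covariance: float
    perm_p: float | None = None
    brain_loadings: np.ndarray | None = None
    behavior_loadings: np.ndarray | None = None
    brain_loading_z: np.ndarray | None = None
    behavior_loading_z: np.ndarray | None = None

    @property
    def score_correlation(self) -> float:
        """Pearson r between brain and behavior scores."""
        return float(np.corrcoef(self.brain_scores, self.behavior_scores)[0, 1])


class PLSCorrelation(BaseEstimator):
    """SVD-based PLS correlation estimator.

    Parameters
    ----------
    n_components : int or None
        Components to retain; ``None`` keeps all min(B, rank).

    Attributes (after ``fit(X, Y)``)
    --------------------------------
    x_saliences_ : (V, C) orthonormal brain saliences (SVD right vectors)
    y_saliences_ : (B, C) orthonormal behavior saliences (left vectors)
    singular_values_ : (C,) non-increasing
    explained_covariance_ : (C,) S^2 / sum S^2 over all components
    x_scores_, y_scores_ : (N, C) brain and behavior scores
    x_mean_, x_sd_, y_mean_, y_sd_ : standardization constants
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, Y):
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2-D with equal row counts")
        N, B = Y.shape[0], Y.shape[1]
        if N < B + 2:
            raise ValueError(f"need at least B+2={B + 2} rows, got {N}")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("non-finite entries in X or Y")
        Xz, self.x_mean_, self.x_sd_ = standardize_columns(X)
        Yz, self.y_mean_, self.y_sd_ = standardize_columns(Y)
        R = Yz.T @ Xz / (N - 1)
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        V = Vt.T
        tol = S[0] * max(R.shape) * np.finfo(float).eps if S.size else 0.0
        rank = max(1, int(np.sum(S > tol)))
        C = rank if self.n_components is None else min(self.n_components, rank)
        total = float(np.sum(S**2))
        U, V, flips = _apply_sign_convention(U[:, :C], V[:, :C])
        self.y_saliences_ = U
        self.x_saliences_ = V
        self.singular_values_ = S[:C]
        self.explained_covariance_ = S[:C] ** 2 / total
        self.x_scores_ = Xz @ V
        self.y_scores_ = Yz @ U
        self.n_components_ = C
        self.n_samples_ = N
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "x_saliences_"):
            raise RuntimeError("PLSCorrelation is not fitted")

    def transform(self, X, Y=None):
        """Project new (or the training) data onto the fitted saliences
        using the training standardization. Returns brain scores, or a
        (brain, behavior) pair when Y is given."""
        self._check_fitted()
        Lx = ((np.asarray(X, float) - self.x_mean_) / self.x_sd_) @ self.x_saliences_
        if Y is None:
            return Lx
        Ly = ((np.asarray(Y, float) - self.y_mean_) / self.y_sd_) @ self.y_saliences_
        return Lx, Ly

    def components(self) -> list[LatentComponent]:
        self._check_fitted()
        out = []
        for k in range(self.n_components_):
            out.append(
                LatentComponent(
                    index=k,
                    singular_value=float(self.singular_values_[k]),
                    brain_salience=self.x_saliences_[:, k],
                    behavior_salience=self.y_saliences_[:, k],
                    brain_scores=self.x_scores_[:, k],
                    behavior_scores=self.y_scores_[:, k],
                    explained_covariance=float(self.explained_covariance_[k]),
                )
            )
        return out


def _column_correlations(M: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Pearson r of every column of M with a score vector; zero-variance
    columns yield NaN (flagged, not raised)."""
    M = np.asarray(M, float)
    s = score - score.mean()
    s_sd = np.sqrt((s**2).mean())
    Mc = M - M.mean(axis=0)
    m_sd = np.sqrt((Mc**2).mean(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc * s[:, None]).mean(axis=0) / (m_sd * s_sd)
    r[m_sd == 0] = np.nan
    return r


def compute_loadings(model: PLSCorrelation, X_orig: np.ndarray, Y_orig: np.ndarray):
    """Loadings: Pearson correlations between original columns and scores.

    ``X_orig``/``Y_orig`` must share the fitted row order. By default the
    caller passes the matrices that actually entered the fit (i.e. the
    deconfounded X); passing the pre-deconfounding matrix is equally valid
    and is a pipeline-level option.

    Returns ``(brain_loadings, behavior_loadings)`` of shapes (V, C), (B, C).
    """
    model._check_fitted()
    X_orig = np.asarray(X_orig, float)
    Y_orig = np.asarray(Y_orig, float)
    if X_orig.shape[0] != model.n_samples_:
        raise ValueError("row count differs from the fitted sample")
    C = model.n_components_
    bl = np.column_stack(
        [_column_correlations(X_orig, model.x_scores_[:, k]) for k in range(C)]
    )
    yl = np.column_stack(
        [_column_correlations(Y_orig, model.y_scores_[:, k]) for k in range(C)]
    )
    return bl, yl


def report_component(
    model: PLSCorrelation,
    k: int,
    loadings: tuple | None = None,
    behavior_names: tuple = ("als", "madrs", "ymrs"),
    top_n: int = 10,
) -> dict:
    """Human-readable summary of component k: score correlation, explained
    covariance fraction, and the strongest-loading variables."""
    model._check_fitted()
    if not 0 <= k < model.n_components_:
        raise ValueError(f"component index {k} out of range")
    comp = model.components()[k]
    summary = {
        "component": k,
        "singular_value": comp.singular_value,
        "explained_covariance": comp.explained_covariance,
        "score_correlation": comp.score_correlation,
    }
    if loadings is not None:
        bl, yl = loadings
        order = np.argsort(-np.abs(np.nan_to_num(bl[:, k])))[:top_n]
        summary["top_voxels"] = [
            {"voxel": int(v), "loading": float(bl[v, k])} for v in order
        ]
        summary["behavior_loadings"] = {
            name: float(yl[i, k]) for i, name in enumerate(behavior_names[: yl.shape[0]])
        }
    return summary
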