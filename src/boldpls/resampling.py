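"""Group-restricted resampling inference for PLS correlation.

Significance: the observed singular values are compared against a null
distribution built by permuting the behavior rows *within each diagnostic
group* (so latent components cannot be driven by group differences) and
refitting. Reliability: loadings are given bootstrap z-scores from samples
drawn with replacement *within each group* (group sizes preserved exactly
in every replicate).

Resampled singular structures are aligned to the original one by an
orthogonal procrustes rotation of the behavior-side basis (rotation
propagated to the singular values and the brain side); a sign-flip-only
mode exists for comparison. Permutation p-values use the add-one
convention, p = (1 + #{null >= observed}) / (1 + n_perm), so the smallest
attainable p is exactly 1/(n_perm + 1).

One parent seed deterministically spawns one child seed per replicate, so
results are independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pls import PLSCorrelation, _column_correlations, standardize_columns

DEFAULT_N_PERM = 1000
DEFAULT_N_BOOT = 1000
DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class PermutationResult:
    n_perm: int
    null_singular_values: np.ndarray  # n_perm x C
    perm_p: np.ndarray  # C
    procrustes_used: bool
    seed: int


@dataclass
class BootstrapResult:
    n_boot: int
    brain_loading_sd: np.ndarray  # V x C
    behavior_loading_sd: np.ndarray  # B x C
    brain_z: np.ndarray
    behavior_z: np.ndarray
    threshold: float
    brain_flagged: np.ndarray  # boolean V x C, |z| >= threshold
    behavior_flagged: np.ndarray
    seed: int


def _group_indices(groups) -> dict:
    groups = np.asarray(groups)
    return {g: np.flatnonzero(groups == g) for g in np.unique(groups)}


def permute_within_groups(Y: np.ndarray, groups, rng: np.random.Generator) -> np.ndarray:
    """Shuffle the rows of Y only among rows sharing a group label."""
    Y = np.asarray(Y, float)
    out = Y.copy()
    for idx in _group_indices(groups).values():
        out[idx] = Y[idx[rng.permutation(idx.size)]]
    return out


def bootstrap_indices(groups, rng: np.random.Generator) -> np.ndarray:
    """Row indices of one within-group bootstrap sample: each group
    contributes its own size of rows drawn with replacement."""
    parts = [idx[rng.integers(0, idx.size, idx.size)] for idx in _group_indices(groups).values()]
    return np.concatenate(parts)


def procrustes_rotation(U_ref: np.ndarray, U_res: np.ndarray) -> np.ndarray:
    """Orthogonal Q minimizing ||U_ref - U_res @ Q||_F."""
    U_ref = np.asarray(U_ref, float)
    U_res = np.asarray(U_res, float)
    if U_ref.shape != U_res.shape:
        raise ValueError("dimension mismatch between reference and resampled bases")
    P, _, Qt = np.linalg.svd(U_res.T @ U_ref)
    return P @ Qt


def sign_flip_rotation(U_ref: np.ndarray, U_res: np.ndarray) -> np.ndarray:
    """Diagonal +/-1 'rotation' matching each resampled component's sign
    to the reference (no mixing across components)."""
    if U_ref.shape != U_res.shape:
        raise ValueError("dimension mismatch between reference and resampled bases")
    d = np.sign(np.sum(U_ref * U_res, axis=0))
    d[d == 0] = 1.0
    return np.diag(d)


def procrustes_align(U_ref, U_res, S_res, V_res=None, mode: str = "rotation"):
    """Align a resampled singular structure (U', S', V') to a reference.

    The rotation is estimated on the behavior-side basis and propagated:
    aligned saliences are U'Q and V'Q, and the aligned singular values are
    the column norms of U' diag(S') Q (= norms of diag(S') Q columns, since
    U' is orthonormal). With identical inputs Q = I and everything is
    returned unchanged.

    Returns ``(U_rot, S_rot, V_rot, Q)`` (``V_rot`` is None if V' is None).
    """
    rot = procrustes_rotation if mode == "rotation" else sign_flip_rotation
    Q = rot(np.asarray(U_ref, float), np.asarray(U_res, float))
    U_rot = U_res @ Q
    S_rot = np.linalg.norm(np.diag(np.asarray(S_res, float)) @ Q, axis=0)
    V_rot = None if V_res is None else np.asarray(V_res, float) @ Q
    return U_rot, S_rot, V_rot, Q


def _child_seeds(seed: int, n: int) -> list:
    return np.random.SeedSequence(seed).spawn(n)


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    groups,
    model: PLSCorrelation,
    n_perm: int = DEFAULT_N_PERM,
    procrustes: bool = True,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null of the singular values under within-group shuffles
    of the behavior rows (X untouched)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    model._check_fitted()
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    N = X.shape[0]
    C = model.n_components_
    Xz, _, _ = standardize_columns(X)
    U_ref = model.y_saliences_
    S_obs = model.singular_values_
    null = np.empty((n_perm, C))
    for i, ss in enumerate(_child_seeds(seed, n_perm)):
        rng = np.random.default_rng(ss)
        Yp = permute_within_groups(Y, groups, rng)
        Yz, _, _ = standardize_columns(Yp)
        Rp = Yz.T @ Xz / (N - 1)
        Up, Sp, _ = np.linalg.svd(Rp, full_matrices=False)
        if procrustes:
            _, S_rot, _, _ = procrustes_align(U_ref, Up[:, :C], Sp[:C], mode="rotation")
            null[i] = S_rot
        else:
            null[i] = Sp[:C]
    perm_p = (1 + (null >= S_obs).sum(axis=0)) / (1 + n_perm)
    return PermutationResult(
        n_perm=n_perm,
        null_singular_values=null,
        perm_p=perm_p,
        procrustes_used=procrustes,
        seed=seed,
    )


def bootstrap_test(
    X: np.ndarray,
    Y: np.ndarray,
    groups,
    model: PLSCorrelation,
    n_boot: int = DEFAULT_N_BOOT,
    threshold: float = DEFAULT_Z_THRESHOLD,
    procrustes: bool = True,
    seed: int = 0,
    X_loading_source: np.ndarray | None = None,
    Y_loading_source: np.ndarray | None = None,
) -> BootstrapResult:
    """Bootstrap z-scores of the loadings under within-group resampling.

    Each replicate resamples rows jointly from X and Y within each group,
    refits, aligns the resampled saliences to the originals, recomputes
    loadings on the replicate, and the z-score is the original loading
    divided by the bootstrap SD of the replicate loadings. Entries with
    |z| >= threshold are flagged as reliable contributors.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    model._check_fitted()
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    for g, idx in _group_indices(groups).items():
        if idx.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members; cannot bootstrap")
    Xsrc = X if X_loading_source is None else np.asarray(X_loading_source, float)
    Ysrc = Y if Y_loading_source is None else np.asarray(Y_loading_source, float)
    N = X.shape[0]
    C = model.n_components_
    mode = "rotation" if procrustes else "signflip"
    U_ref = model.y_saliences_

    # original loadings (z numerators)
    bl0 = np.column_stack([_column_correlations(Xsrc, model.x_scores_[:, k]) for k in range(C)])
    yl0 = np.column_stack([_column_correlations(Ysrc, model.y_scores_[:, k]) for k in range(C)])

    bl_acc = np.empty((n_boot,) + bl0.shape)
    yl_acc = np.empty((n_boot,) + yl0.shape)
    for i, ss in enumerate(_child_seeds(seed, n_boot)):
        rng = np.random.default_rng(ss)
        rows = bootstrap_indices(groups, rng)
        Xz, _, _ = standardize_columns(X[rows])
        Yz, _, _ = standardize_columns(Y[rows])
        Rb = Yz.T @ Xz / (N - 1)
        Ub, Sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
        _, _, Vb_rot, Q = procrustes_align(
            U_ref, Ub[:, :C], Sb[:C], Vbt.T[:, :C], mode=mode
        )
        Ub_rot = Ub[:, :C] @ Q
        Lx = Xz @ Vb_rot
        Ly = Yz @ Ub_rot
        bl_acc[i] = np.column_stack(
            [_column_correlations(Xsrc[rows], Lx[:, k]) for k in range(C)]
        )
        yl_acc[i] = np.column_stack(
            [_column_correlations(Ysrc[rows], Ly[:, k]) for k in range(C)]
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        bl_sd = np.nanstd(bl_acc, axis=0, ddof=1)
        yl_sd = np.nanstd(yl_acc, axis=0, ddof=1)
        brain_z = np.where(bl_sd > 0, bl0 / bl_sd, np.inf * np.sign(bl0))
        behavior_z = np.where(yl_sd > 0, yl0 / yl_sd, np.inf * np.sign(yl0))
    return BootstrapResult(
        n_boot=n_boot,
        brain_loading_sd=bl_sd,
        behavior_loading_sd=yl_sd,
        brain_z=brain_z,
        behavior_z=behavior_z,
        threshold=threshold,
        brain_flagged=np.abs(brain_z) >= threshold,
        behavior_flagged=np.abs(behavior_z) >= threshold,
        seed=seed,
    )
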