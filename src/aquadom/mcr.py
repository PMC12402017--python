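"""Multivariate curve resolution (MCR-ALS) with a trilinearity constraint.

The K preprocessed sample EEMs, each ``n_ex x n_em``, are stacked
vertically into the column-wise augmented matrix ``D_aug`` (shape
``K*n_ex x n_em``) and factored as

    D_k = S_ex C_k S_em^T + E_k,      k = 1..K

with common excitation profiles ``S_ex`` (n_ex x nc), common emission
profiles ``S_em`` (nc x n_em) and sample-specific diagonal contribution
matrices ``C_k``. Alternating least squares enforces non-negativity on
both factor matrices through exact active-set NNLS subproblems; the
trilinearity constraint additionally forces, for every component, its
block of the augmented excitation factor to be rank one across samples,
which removes the rotational ambiguity of the plain bilinear model and
yields an essentially unique, PARAFAC-like solution.

Fit quality is the explained data variance

    R2 = 100 * (1 - sum (d - dhat)^2 / sum d^2)

with sums over all unmasked cells of the stack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .io_formats import EEM, EEMStack, ValidationError  # noqa: F401  (EEMStack re-exported here)
from .synthetic import SyntheticTruth, component_profiles

__all__ = [
    "EEMStack",
    "MCRResult",
    "estimate_rank",
    "purest_variables",
    "fit_mcr_trilinear",
    "explained_variance",
    "lack_of_fit",
    "match_components",
]


@dataclass
class MCRResult:
    """Resolved profiles and contributions of an MCR-ALS fit.

    ``S_ex`` columns and ``S_em`` rows are max-normalized to 1; all
    magnitude information sits in the contribution matrix ``C`` (K x nc).
    Components are sorted by descending total contribution.
    """

    S_ex: np.ndarray
    S_em: np.ndarray
    C: np.ndarray
    r2: float
    lof: float
    n_iter: int
    converged: bool
    history: list
    ex_grid: np.ndarray
    em_grid: np.ndarray
    sample_ids: list
    trilinear: bool = True

    @property
    def nc(self) -> int:
        return self.S_ex.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Model estimate of the augmented matrix (K*n_ex x n_em)."""
        blocks = [
            self.S_ex @ np.diag(self.C[k]) @ self.S_em
            for k in range(self.C.shape[0])
        ]
        return np.vstack(blocks)

    def ex_max(self, component: int, min_wavelength: float = -np.inf) -> float:
        """Excitation wavelength of a component's band maximum.

        ``min_wavelength`` restricts the search, e.g. to the main band
        at >= 260 nm when a UV shoulder is present.
        """
        sel = self.ex_grid >= min_wavelength
        prof = self.S_ex[sel, component]
        return float(self.ex_grid[sel][np.argmax(prof)])

    def em_max(self, component: int) -> float:
        """Emission wavelength of a component's band maximum."""
        return float(self.em_grid[np.argmax(self.S_em[component])])

    def to_dict(self) -> dict:
        return {
            "nc": self.nc,
            "r2": self.r2,
            "lof": self.lof,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "trilinear": self.trilinear,
            "history": list(self.history),
            "sample_ids": list(self.sample_ids),
            "ex_grid": self.ex_grid.tolist(),
            "em_grid": self.em_grid.tolist(),
            "S_ex": self.S_ex.tolist(),
            "S_em": self.S_em.tolist(),
            "C": self.C.tolist(),
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


# ---------------------------------------------------------------------
# fit diagnostics
# ---------------------------------------------------------------------

def explained_variance(
    D: np.ndarray, Dhat: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Explained data variance R2 (percent); masked cells are excluded.

    May be negative for models worse than the zero model; never clipped.
    """
    D = np.asarray(D, float)
    Dhat = np.asarray(Dhat, float)
    if D.shape != Dhat.shape:
        raise ValidationError("D and Dhat must have the same shape")
    if mask is not None:
        keep = ~np.asarray(mask, bool)
        D, Dhat = D[keep], Dhat[keep]
    tss = float(np.sum(D**2))
    if tss == 0:
        raise ValidationError("total sum of squares is zero")
    rss = float(np.sum((D - Dhat) ** 2))
    return 100.0 * (1.0 - rss / tss)


def lack_of_fit(
    D: np.ndarray, Dhat: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Lack of fit percent: 100 * sqrt(rss / tss) over unmasked cells."""
    D = np.asarray(D, float)
    Dhat = np.asarray(Dhat, float)
    if mask is not None:
        keep = ~np.asarray(mask, bool)
        D, Dhat = D[keep], Dhat[keep]
    tss = float(np.sum(D**2))
    if tss == 0:
        raise ValidationError("total sum of squares is zero")
    return 100.0 * float(np.sqrt(np.sum((D - Dhat) ** 2) / tss))


# ---------------------------------------------------------------------
# rank estimation and SIMPLISMA initialization
# ---------------------------------------------------------------------

def _filled_augmented(stack: EEMStack) -> np.ndarray:
    """Augmented matrix with masked cells filled along the emission axis."""
    D = stack.augmented()
    mask = stack.augmented_mask()
    if mask is None:
        return D
    em = stack.em_grid
    D = D.copy()
    for i in range(D.shape[0]):
        bad = mask[i]
        if bad.any():
            if bad.all():
                raise ValidationError("fully masked emission row; cannot fill")
            good = ~bad
            D[i, bad] = np.interp(em[bad], em[good], D[i, good])
            first, last = np.flatnonzero(good)[[0, -1]]
            D[i, :first] = 0.0
            D[i, last + 1:] = 0.0
    return D


def estimate_rank(stack: EEMStack, threshold: float = 0.999):
    """Estimate the number of significant components by SVD.

    A component is significant when its individual share of the squared
    singular-value spectrum is at least ``1 - threshold`` (0.1% by
    default); for an exact-rank stack this coincides with the smallest
    rank reaching ``threshold`` cumulative variance, and unlike the
    cumulative rule it does not count the long tail of noise singular
    values. The full spectrum is returned for scree inspection.
    """
    D = _filled_augmented(stack)
    if not np.any(D):
        raise ValidationError("stack is identically zero")
    s = np.linalg.svd(D, compute_uv=False)
    share = s**2 / np.sum(s**2)
    rank = int(np.sum(share >= (1.0 - threshold)))
    return max(rank, 1), s


def purest_variables(D: np.ndarray, n: int, noise_allowance: float = 5.0) -> list:
    """SIMPLISMA-style selection of the ``n`` purest columns of ``D``.

    Purity of column j is std_j / (mean_j + offset) with offset equal to
    ``noise_allowance`` percent of the largest column mean; each pick
    maximizes purity weighted by independence from the already selected
    columns (the determinant of their correlation-around-origin
    submatrix). Fully deterministic; ties break to the lowest index.
    """
    D = np.asarray(D, float)
    if D.ndim != 2:
        raise ValidationError("D must be a matrix")
    if not (1 <= n <= D.shape[1]):
        raise ValidationError(f"cannot select {n} columns from {D.shape[1]}")
    if np.any(D < 0):
        raise ValidationError("D must be nonnegative")
    m = D.mean(axis=0)
    s = D.std(axis=0)
    offset = noise_allowance * m.max() / 100.0
    purity = s / (m + offset)
    norms = np.linalg.norm(D, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    L = D / safe
    selected: list = []
    for _ in range(n):
        best_j, best_score = -1, -np.inf
        for j in range(D.shape[1]):
            if j in selected:
                continue
            idx = selected + [j]
            G = L[:, idx].T @ L[:, idx]
            weight = float(np.linalg.det(G))
            score = purity[j] * max(weight, 0.0)
            if score > best_score + 1e-15:
                best_score, best_j = score, j
        selected.append(best_j)
    return selected


# ---------------------------------------------------------------------
# ALS machinery
# ---------------------------------------------------------------------

def _nnls_rows(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """argmin_{X>=0} ||A X - D||_F, column by column (exact active set)."""
    X = np.empty((A.shape[1], D.shape[1]))
    for j in range(D.shape[1]):
        X[:, j], _ = nnls(A, D[:, j])
    return X


def _nnls_cols(S: np.ndarray, D: np.ndarray) -> np.ndarray:
    """argmin_{A>=0} ||A S - D||_F, row by row (exact active set)."""
    St = np.ascontiguousarray(S.T)
    A = np.empty((D.shape[0], S.shape[0]))
    for i in range(D.shape[0]):
        A[i], _ = nnls(St, D[i])
    return A


def _refold(a_col: np.ndarray, n_ex: int, K: int) -> np.ndarray:
    """Refold one augmented excitation column into an n_ex x K matrix."""
    return a_col.reshape(K, n_ex).T


def _rank1_project(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best nonnegative rank-1 approximation factors of M (leading triplet).

    Signs are fixed so both factors point into the nonnegative orthant;
    residual negative entries are clipped at zero.
    """
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    u = U[:, 0]
    v = s[0] * Vt[0]
    if u.sum() < 0:
        u, v = -u, -v
    return np.clip(u, 0.0, None), np.clip(v, 0.0, None)


def _apply_trilinearity(A: np.ndarray, n_ex: int, K: int) -> np.ndarray:
    """Replace each component's refolded block by its rank-1 approximation."""
    out = np.empty_like(A)
    for c in range(A.shape[1]):
        u, v = _rank1_project(_refold(A[:, c], n_ex, K))
        out[:, c] = np.outer(v, u).ravel()  # sample-major back to augmented layout
    return out


def fit_mcr_trilinear(
    stack: EEMStack,
    nc: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    apply_trilinearity: bool = True,
    init: str = "auto",
    seed: Optional[int] = 0,
    n_random_restarts: int = 2,
) -> MCRResult:
    """Fit the trilinearity-constrained MCR-ALS model to an EEM stack.

    Parameters
    ----------
    stack : EEMStack
        K preprocessed EEMs on a common grid. Masked cells are handled by
        expectation-style imputation: they start emission-interpolated and
        are replaced by the current model estimate at every iteration,
        which excludes them from the effective residual.
    nc : int
        Number of components to resolve.
    max_iter, tol : int, float
        ALS stops when the relative change in lack of fit over one
        iteration drops below ``tol``, or at ``max_iter`` (then
        ``converged`` is False).
    apply_trilinearity : bool
        Enforce the per-component rank-1 constraint across samples.
    init : {"auto", "simplisma", "simplisma_cols", "random"}
        ``simplisma`` seeds the emission profiles with the purest rows of
        the augmented matrix; ``simplisma_cols`` seeds the excitation
        factor with the purest columns; ``random`` draws a nonnegative
        factor (uses ``seed``). ``auto`` runs both SIMPLISMA starts plus
        ``n_random_restarts`` seeded random starts and keeps the fit with
        the lowest lack of fit — ALS with overlapping components has
        genuine local minima, so a small multi-start is the default.
    """
    if init == "auto":
        rng = np.random.default_rng(seed)
        candidates = [("simplisma", None), ("simplisma_cols", None)] + [
            ("random", int(rng.integers(0, 2**31 - 1)))
            for _ in range(n_random_restarts)
        ]
        best: Optional[MCRResult] = None
        for name, sd in candidates:
            fit = fit_mcr_trilinear(
                stack, nc, max_iter=max_iter, tol=tol,
                apply_trilinearity=apply_trilinearity, init=name, seed=sd,
            )
            if best is None or fit.lof < best.lof:
                best = fit
        return best
    K = len(stack)
    if apply_trilinearity and K < 2:
        raise ValidationError("trilinear fitting needs at least 2 samples")
    n_ex, n_em = stack[0].shape
    if nc < 1 or nc > min(K * n_ex, n_em):
        raise ValidationError(f"nc={nc} out of range for a {K * n_ex}x{n_em} stack")

    D_obs = stack.augmented()
    mask = stack.augmented_mask()
    D = _filled_augmented(stack)

    if init == "simplisma":
        # purest rows of the augmented matrix = the most distinct measured
        # emission spectra; they seed S_em, from which the first excitation
        # factor is solved. Markedly more robust than seeding from the
        # purest emission columns when excitation profiles are collinear.
        rows = purest_variables(D.T, nc)
        S_em0 = D[rows, :].copy()
        S_em0 /= np.maximum(S_em0.max(axis=1, keepdims=True), 1e-30)
        A = _nnls_cols(S_em0, D)
        if apply_trilinearity:
            A = _apply_trilinearity(A, n_ex, K)
    elif init == "simplisma_cols":
        cols = purest_variables(D, nc)
        A = D[:, cols].copy()
    elif init == "random":
        rng = np.random.default_rng(seed)
        A = rng.uniform(0.1, 1.0, size=(K * n_ex, nc)) * D.max()
    else:
        raise ValidationError(f"unknown init {init!r}")

    history: list = []
    prev_lof = np.inf
    converged = False
    n_iter = 0
    S_em = np.zeros((nc, n_em))
    for n_iter in range(1, max_iter + 1):
        # (iii) emission profiles given the excitation factor
        S_em = _nnls_rows(A, D)
        # rescale: S_em rows to max 1, compensated in A (model unchanged)
        scale = S_em.max(axis=1)
        scale[scale == 0] = 1.0
        S_em /= scale[:, None]
        A *= scale[None, :]
        # (i) augmented excitation factor given S_em
        A = _nnls_cols(S_em, D)
        # (ii) trilinearity: per-component rank-1 across the sample mode
        if apply_trilinearity:
            A = _apply_trilinearity(A, n_ex, K)
        Dhat = A @ S_em
        cur_lof = lack_of_fit(D_obs, Dhat, mask)
        history.append(explained_variance(D_obs, Dhat, mask))
        if mask is not None:
            D = D_obs.copy()
            D[mask] = Dhat[mask]  # EM imputation of excised cells
        if prev_lof < np.inf and abs(prev_lof - cur_lof) <= tol * max(prev_lof, 1e-30):
            converged = True
            break
        prev_lof = cur_lof

    # fit quality of the converged bilinear model (identical to the
    # unpacked trilinear reconstruction when the constraint is active)
    Dhat = A @ S_em
    final_r2 = explained_variance(D_obs, Dhat, mask)
    final_lof = lack_of_fit(D_obs, Dhat, mask)

    # unpack common S_ex and per-sample contributions from the final factor
    S_ex = np.empty((n_ex, nc))
    C = np.empty((K, nc))
    for c in range(nc):
        M = _refold(A[:, c], n_ex, K)
        u, v = _rank1_project(M)
        if not apply_trilinearity:
            # common profile = leading direction; contributions by projection
            unorm = np.linalg.norm(u)
            if unorm > 0:
                v = (u / unorm**2) @ M
                v = np.clip(v, 0.0, None)
        S_ex[:, c] = u
        C[:, c] = v

    # normalization convention: profiles peak at 1, magnitude lives in C
    ex_scale = S_ex.max(axis=0)
    ex_scale[ex_scale == 0] = 1.0
    em_scale = S_em.max(axis=1)
    em_scale[em_scale == 0] = 1.0
    S_ex = S_ex / ex_scale[None, :]
    S_em = S_em / em_scale[:, None]
    C = C * (ex_scale * em_scale)[None, :]

    # sort components by descending total contribution
    order = np.argsort(-C.sum(axis=0), kind="stable")
    S_ex, S_em, C = S_ex[:, order], S_em[order, :], C[:, order]

    result = MCRResult(
        S_ex=S_ex, S_em=S_em, C=C,
        r2=final_r2,
        lof=final_lof,
        n_iter=n_iter, converged=converged, history=history,
        ex_grid=stack.ex_grid.copy(), em_grid=stack.em_grid.copy(),
        sample_ids=list(stack.sample_ids), trilinear=apply_trilinearity,
    )
    if not converged:
        import warnings

        warnings.warn(
            f"MCR-ALS did not converge in {max_iter} iterations "
            f"(lof {result.lof:.4g}%)", stacklevel=2,
        )
    return result


def match_components(result: MCRResult, truth: SyntheticTruth):
    """Optimally match resolved components to generator ground truth.

    Returns ``(permutation, similarities)`` where ``permutation[i]`` is
    the truth component assigned to resolved component ``i`` and the
    similarity is the cosine between concatenated (excitation, emission)
    profiles, each mode unit-normalized first.
    """
    nc = result.nc
    if nc != len(truth.components):
        raise ValidationError(
            f"component count mismatch: result {nc}, truth {len(truth.components)}"
        )
    T_ex, T_em = component_profiles(truth.components, result.ex_grid, result.em_grid)

    def unit(x):
        n = np.linalg.norm(x)
        return x / n if n > 0 else x

    R = np.stack([
        np.concatenate([unit(result.S_ex[:, c]), unit(result.S_em[c])])
        for c in range(nc)
    ])
    T = np.stack([
        np.concatenate([unit(T_ex[:, c]), unit(T_em[c])]) for c in range(nc)
    ])
    # each concatenated vector has norm sqrt(2): two unit halves
    cos = np.clip((R @ T.T) / 2.0, -1.0, 1.0)
    row, col = linear_sum_assignment(-cos)
    perm = np.empty(nc, dtype=int)
    sims = np.empty(nc)
    for r_, c_ in zip(row, col):
        perm[r_] = c_
        sims[r_] = cos[r_, c_]
    return perm, sims
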