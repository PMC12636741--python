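"""Maximum-likelihood exploratory factor analysis with oblique promax rotation.

Implements the classic Lawley/Joreskog ML estimator on a correlation matrix:
the k-factor model decomposes the item correlation matrix R as

    R = L L' + Psi,

with loadings L (p x k) and diagonal uniquenesses Psi. The discrepancy
function is minimised over the uniquenesses only; conditional on Psi the
loadings have a closed form via the eigendecomposition of
Psi^{-1/2} R Psi^{-1/2}. Varimax and promax rotations follow the standard
Kaiser/Hendrickson-White algorithms, matching the behaviour of R's
``factanal``/``promax`` which this module is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "MLFactorFit",
    "ml_efa_corr",
    "varimax",
    "promax",
    "efa_dof",
    "tucker_congruence",
    "congruence_matrix",
    "match_factors",
    "EFAConvergenceError",
]


class EFAConvergenceError(RuntimeError):
    """Raised when the uniqueness optimisation fails to converge."""

    def __init__(self, message: str, n_iter: int):
        super().__init__(f"{message} (iterations: {n_iter})")
        self.n_iter = n_iter


@dataclass
class MLFactorFit:
    """Unrotated ML solution on a correlation matrix."""

    loadings: np.ndarray  # p x k, canonical (L' Psi^-1 L diagonal, descending)
    uniquenesses: np.ndarray  # length p
    objective: float  # value of the ML discrepancy function
    dof: int
    n_iter: int
    heywood: bool  # any uniqueness clipped at the lower bound


def efa_dof(p: int, k: int) -> int:
    """Degrees of freedom of the k-factor model for p items: ((p-k)^2-(p+k))/2."""
    return ((p - k) ** 2 - (p + k)) // 2


def _objective_and_grad(psi: np.ndarray, R: np.ndarray, k: int):
    # F(psi) = sum_{j>k} (lam_j - log lam_j) - (p - k) for eigenvalues of
    # Psi^-1/2 R Psi^-1/2; gradient (at the conditional loadings) is
    # (h_i^2 + psi_i - 1) / psi_i^2 with h_i^2 the communality.
    p = R.shape[0]
    sc = 1.0 / np.sqrt(psi)
    Rs = R * sc[:, None] * sc[None, :]
    lam, vec = linalg.eigh(Rs)
    lam = lam[::-1]
    vec = vec[:, ::-1]
    tail = np.maximum(lam[k:], 1e-12)
    f = float(np.sum(tail - np.log(tail)) - (p - k))
    load = vec[:, :k] * np.sqrt(np.maximum(lam[:k] - 1.0, 0.0))
    comm = np.sum(load**2, axis=1) * psi  # back on the original scale
    grad = (comm + psi - 1.0) / psi**2
    return f, grad


def _conditional_loadings(psi: np.ndarray, R: np.ndarray, k: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    Rs = R * sc[:, None] * sc[None, :]
    lam, vec = linalg.eigh(Rs)
    lam = lam[::-1]
    vec = vec[:, ::-1]
    load = vec[:, :k] * np.sqrt(np.maximum(lam[:k] - 1.0, 0.0))
    # sign convention: column sum nonnegative (deterministic output)
    signs = np.where(load.sum(axis=0) < 0, -1.0, 1.0)
    return (load / sc[:, None]) * signs[None, :]


def ml_efa_corr(
    R: np.ndarray,
    k: int,
    *,
    lower: float = 0.005,
    start: np.ndarray | None = None,
    maxiter: int = 1000,
) -> MLFactorFit:
    """Fit a k-factor ML model to correlation matrix ``R``.

    Uniquenesses are bounded below at ``lower``; a solution pinned at the
    bound (Heywood case) is flagged rather than rejected. ``start`` allows
    warm-starting (used heavily by jackknife resampling).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p):
        raise ValueError("R must be square")
    if k < 1:
        raise ValueError("k must be >= 1")
    if efa_dof(p, k) <= 0:
        raise ValueError(f"k={k} leaves no degrees of freedom for p={p} items")

    if start is None:
        # 1 - squared multiple correlation, the usual communality prior
        inv_diag = np.diag(linalg.inv(R))
        start = np.clip(1.0 / inv_diag, lower, 1.0)
    x0 = np.clip(start, lower, 1.0)

    res = optimize.minimize(
        _objective_and_grad,
        x0,
        args=(R, k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lower, 1.0)] * p,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise EFAConvergenceError("ML factor optimisation failed", res.nit)
    psi = np.clip(res.x, lower, 1.0)
    loadings = _conditional_loadings(psi, R, k)
    heywood = bool(np.any(psi <= lower + 1e-12))
    return MLFactorFit(
        loadings=loadings,
        uniquenesses=psi,
        objective=float(res.fun),
        dof=efa_dof(p, k),
        n_iter=int(res.nit),
        heywood=heywood,
    )


def bartlett_chisq(objective: float, p: int, k: int, n_obs: int) -> float:
    """Bartlett-corrected chi-square statistic of the ML fit."""
    return max(objective, 0.0) * (n_obs - 1 - (2 * p + 5) / 6.0 - (2 * k) / 3.0)


def varimax(L: np.ndarray, *, normalize: bool = True, eps: float = 1e-8, maxiter: int = 1000):
    """Varimax rotation; returns (rotated loadings, rotation matrix).

    With ``normalize`` the rows are Kaiser-normalised before rotation, as in
    R's ``varimax`` default.
    """
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    if normalize:
        sc = np.sqrt(np.sum(L**2, axis=1))
        sc[sc == 0] = 1.0
        X = L / sc[:, None]
    else:
        sc = None
        X = L.copy()
    T = np.eye(k)
    d = 0.0
    for _ in range(maxiter):
        Z = X @ T
        B = X.T @ (Z**3 - Z * (np.sum(Z**2, axis=0) / p)[None, :])
        U, s, Vt = linalg.svd(B)
        T = U @ Vt
        d_new = float(np.sum(s))
        if d_new < d * (1 + eps):
            break
        d = d_new
    Z = X @ T
    if normalize:
        Z = Z * sc[:, None]
    return Z, T


def promax(L: np.ndarray, *, power: int = 4, normalize: bool = True):
    """Promax oblique rotation (Hendrickson & White).

    Returns ``(pattern, phi, rotmat)``: the pattern loadings, the factor
    correlation matrix and the total rotation applied to the input loadings.
    For a single factor the rotation is the identity.
    """
    L = np.asarray(L, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k), np.eye(k)
    A, T_vm = varimax(L, normalize=normalize)
    Q = A * np.abs(A) ** (power - 1)  # element-wise target, sign preserved
    U = linalg.lstsq(A, Q)[0]
    d = np.diag(linalg.inv(U.T @ U))
    U = U * np.sqrt(d)[None, :]
    pattern = A @ U
    Ui = linalg.inv(U)
    phi = Ui @ Ui.T
    # symmetrise and force unit diagonal against round-off
    phi = (phi + phi.T) / 2.0
    dphi = np.sqrt(np.diag(phi))
    phi = phi / np.outer(dphi, dphi)
    rotmat = T_vm @ U
    return pattern, phi, rotmat


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence (cosine similarity) between two loading columns."""
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b) / (na * nb)


def congruence_matrix(ref: np.ndarray, est: np.ndarray) -> np.ndarray:
    """Matrix of Tucker congruences between columns of ``ref`` and ``est``."""
    rn = ref / np.maximum(np.linalg.norm(ref, axis=0), 1e-12)
    en = est / np.maximum(np.linalg.norm(est, axis=0), 1e-12)
    return rn.T @ en


def match_factors(ref: np.ndarray, est: np.ndarray):
    """Match estimated factor columns to reference columns.

    Greedy assignment by maximal absolute Tucker congruence with sign
    alignment; factor order and column signs are arbitrary in EFA, so any
    cross-fit comparison must align first.

    Returns ``(perm, signs, ambiguous)`` where ``est[:, perm] * signs``
    aligns with ``ref``. ``ambiguous`` flags replicates where two estimated
    columns competed for the same reference column within 1e-6.
    """
    C = congruence_matrix(ref, est)
    k = C.shape[0]
    perm = np.full(k, -1, dtype=int)
    signs = np.ones(k)
    ambiguous = False
    A = np.abs(C.copy())
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(A), A.shape)
        best = A[i, j]
        A_row = np.delete(A[i], j)
        if A_row.size and best - A_row.max() < 1e-6 and best > 0:
            ambiguous = True
        perm[i] = j
        signs[i] = 1.0 if C[i, j] >= 0 else -1.0
        A[i, :] = -np.inf
        A[:, j] = -np.inf
    return perm, signs, ambiguous
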