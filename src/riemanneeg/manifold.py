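"""Affine-invariant Riemannian geometry on symmetric positive definite matrices.

Spatial covariance matrices of EEG trials live on the SPD manifold, and the
natural metric there is the affine-invariant one:

    delta(A, B) = || logm(A^{-1/2} B A^{-1/2}) ||_F
                = sqrt( sum_i ln^2 lambda_i(A^{-1} B) )

This module provides the primitives the decoders are built from: the
distance, geodesics, the Karcher (Frechet) mean, tangent-space mapping with
its inverse, recentering (parallel transport toward identity), and the
incremental one-trial mean update used by online adaptation.

All matrix functions go through symmetric eigendecomposition with a small
relative eigenvalue floor, which keeps them robust to nearly-singular
covariance estimates without changing well-conditioned results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datatypes import ConvergenceWarning

#: Relative eigenvalue floor applied inside matrix log/sqrt.
EIG_FLOOR = 1e-12


def _eig_fun(M: np.ndarray, fun, floor: float | None = EIG_FLOOR) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of (a stack of) symmetric matrices."""
    w, V = np.linalg.eigh(M)
    if floor is not None:
        w = np.maximum(w, floor * np.abs(w[..., -1:]))
    return np.einsum("...ik,...k,...jk->...ij", V, fun(w), V)


def sqrtm(M: np.ndarray) -> np.ndarray:
    """Symmetric matrix square root of an SPD matrix (or stack)."""
    return _eig_fun(M, np.sqrt)


def invsqrtm(M: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root of an SPD matrix (or stack)."""
    return _eig_fun(M, lambda w: 1.0 / np.sqrt(w))


def logm(M: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix (or stack)."""
    return _eig_fun(M, np.log)


def expm(M: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (or stack)."""
    return _eig_fun(M, np.exp, floor=None)


def _check_pair(A: np.ndarray, B: np.ndarray) -> None:
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"SPD dimension mismatch: {A.shape} vs {B.shape}")


def riemannian_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant distance delta(A, B) between two SPD matrices.

    Symmetric, zero iff A == B, and invariant under congruence
    A -> W A W^T, B -> W B W^T for any invertible W (in particular under
    channel re-mixing and rescaling).
    """
    _check_pair(A, B)
    # eigvalsh(B, A) yields the (real, positive) eigenvalues of A^{-1} B
    w = scipy.linalg.eigvalsh(B, A)
    w = np.maximum(w, np.finfo(float).tiny)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def distances_to(refs: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Distances from one SPD matrix C to a stack of SPD matrices refs."""
    return np.array([riemannian_distance(R, C) for R in refs])


def geodesic(A: np.ndarray, B: np.ndarray, t: float) -> np.ndarray:
    """Point at parameter t on the geodesic from A (t=0) to B (t=1).

    gamma(t) = A^{1/2} (A^{-1/2} B A^{-1/2})^t A^{1/2}, satisfying
    delta(A, gamma(t)) = t * delta(A, B).
    """
    _check_pair(A, B)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"geodesic parameter t must be in [0, 1], got {t}")
    if t == 0.0:
        return np.array(A, dtype=float, copy=True)
    if t == 1.0:
        return np.array(B, dtype=float, copy=True)
    As = sqrtm(A)
    Ais = invsqrtm(A)
    mid = _eig_fun(Ais @ B @ Ais, lambda w: w**t)
    out = As @ mid @ As
    return 0.5 * (out + out.T)


@dataclass
class MeanSettings:
    """Controls for the Karcher-mean fixed-point iteration.

    tol is on the Frobenius norm of the tangent-space gradient (the mean of
    log-maps at the current estimate); step 1.0 with halving on gradient
    increase is a conventional safeguarded choice.
    """

    tol: float = 1e-8
    max_iter: int = 50
    step: float = 1.0
    init: str = "arithmetic_mean"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("arithmetic_mean", "first_element"):
            raise ValueError(f"unknown init {self.init!r}")


def karcher_mean(
    covs: np.ndarray | list,
    settings: MeanSettings | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Karcher (Frechet) mean of SPD matrices under the affine-invariant metric.

    The mean minimizes sum_i w_i delta^2(M, C_i); the fixed-point iteration
    maps all matrices to the tangent space at the current estimate, averages,
    and maps back, until the gradient norm drops below ``settings.tol``.

    A :class:`ConvergenceWarning` is emitted (and the last iterate returned)
    if ``max_iter`` is exhausted first.
    """
    C = np.asarray(covs, dtype=float)
    if C.ndim == 2:
        C = C[None]
    if C.shape[0] == 0:
        raise ValueError("karcher_mean requires a nonempty list of matrices")
    if C.shape[0] == 1:
        return np.array(C[0], copy=True)
    settings = settings or MeanSettings()
    if weights is None:
        w = np.full(C.shape[0], 1.0 / C.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()

    M = np.einsum("k,kij->ij", w, C) if settings.init == "arithmetic_mean" else np.array(C[0], copy=True)
    step = settings.step
    prev_norm = np.inf
    for _ in range(settings.max_iter):
        Ms = sqrtm(M)
        Mis = invsqrtm(M)
        logs = logm(Mis @ C @ Mis)
        S = np.einsum("k,kij->ij", w, logs)
        grad_norm = float(np.linalg.norm(S, "fro"))
        if grad_norm < settings.tol:
            return M
        if grad_norm > prev_norm:
            step = max(step / 2.0, 1e-4)
        prev_norm = grad_norm
        M = Ms @ expm(step * S) @ Ms
        M = 0.5 * (M + M.T)
    warnings.warn(
        f"Karcher mean did not reach tol={settings.tol:g} in "
        f"{settings.max_iter} iterations (gradient norm {grad_norm:.3g})",
        ConvergenceWarning,
        stacklevel=2,
    )
    return M


def _vech_weighted(S: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix with sqrt(2) weights off the diagonal.

    The weighting makes the Euclidean norm of the vector equal the Frobenius
    norm of S, hence (for S a log-map) the Riemannian distance.
    """
    n = S.shape[-1]
    iu = np.triu_indices(n)
    w = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    return S[..., iu[0], iu[1]] * w


def _unvech_weighted(v: np.ndarray, n: int) -> np.ndarray:
    iu = np.triu_indices(n)
    w = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    S = np.zeros(v.shape[:-1] + (n, n))
    S[..., iu[0], iu[1]] = v / w
    S = S + np.swapaxes(S, -1, -2)
    S[..., np.arange(n), np.arange(n)] *= 0.5
    return S


def tangent_dim(n: int) -> int:
    """Dimension n(n+1)/2 of the tangent space at an n x n SPD point."""
    return n * (n + 1) // 2


def tangent_map(C: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Log-map C (or a stack) to the tangent space at ref, as a weighted vector.

    v = vech( logm(ref^{-1/2} C ref^{-1/2}) ) with sqrt(2)-weighted
    off-diagonals, so ||v||_2 == riemannian_distance(ref, C).
    """
    C = np.asarray(C, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if C.shape[-1] != ref.shape[-1]:
        raise ValueError("tangent_map dimension mismatch")
    Ris = invsqrtm(ref)
    return _vech_weighted(logm(Ris @ C @ Ris))


def inverse_tangent_map(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Exp-map a weighted tangent vector (or stack) back to the SPD manifold at ref."""
    ref = np.asarray(ref, dtype=float)
    n = ref.shape[-1]
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != tangent_dim(n):
        raise ValueError(
            f"tangent vector length {v.shape[-1]} does not match dimension "
            f"{n} (expected {tangent_dim(n)})"
        )
    Rs = sqrtm(ref)
    return Rs @ expm(_unvech_weighted(v, n)) @ Rs


def recenter(C: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Recenter C (or a stack) at reference R: R^{-1/2} C R^{-1/2}.

    This congruence is an isometry; recentering a set at its own Karcher
    mean moves that mean to the identity, which is the rebias operation the
    adaptive decoders use to absorb distribution shift.
    """
    C = np.asarray(C, dtype=float)
    R = np.asarray(R, dtype=float)
    if C.shape[-1] != R.shape[-1]:
        raise ValueError("recenter dimension mismatch")
    Ris = invsqrtm(R)
    out = Ris @ C @ Ris
    return 0.5 * (out + np.swapaxes(out, -1, -2))


def incremental_mean(M: np.ndarray, C: np.ndarray, n: int) -> np.ndarray:
    """One-step running Karcher mean update.

    With n matrices already absorbed into M, the new mean after observing C
    is the geodesic point geodesic(M, C, 1/(n+1)) -- the manifold analogue
    of the running arithmetic mean.
    """
    if n < 1:
        raise ValueError("incremental_mean requires n >= 1 absorbed matrices")
    return geodesic(M, C, 1.0 / (n + 1.0))
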