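"""Generalized SVD under row and column metrics.

The decomposition R = P Δ Qᵀ with PᵀBP = QᵀWQ = I is the engine of every
analysis variant: B carries the category masses, W the variable weights.
It is computed by a plain SVD of B^{1/2} R W^{1/2} followed by a
back-transform, which avoids forming cross-product matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GsvdResult", "gsvd", "generalized_distance"]


@dataclass
class GsvdResult:
    """Generalized singular triplets of a matrix under metrics (B, W).

    Attributes
    ----------
    P : (I, L) left generalized singular vectors, PᵀBP = I.
    Q : (J, L) right generalized singular vectors, QᵀWQ = I.
    delta : (L,) singular values, strictly positive, nonincreasing.
    rank : L, the number of singular values above the rank tolerance.
    """

    P: np.ndarray
    Q: np.ndarray
    delta: np.ndarray

    @property
    def rank(self) -> int:
        return self.delta.size

    @property
    def eigenvalues(self) -> np.ndarray:
        """Λ = Δ²: per-dimension variance of the factor scores."""
        return self.delta**2

    def reconstruct(self) -> np.ndarray:
        return (self.P * self.delta) @ self.Q.T


def _metric_sqrt(metric: np.ndarray, side: int, name: str):
    """Return (half, inv_half) as (apply_fn_left, apply_fn_right)-friendly arrays.

    Diagonal metrics are passed as 1-D vectors; a general symmetric
    positive-definite metric is accepted as a 2-D matrix and handled through
    its symmetric square root.
    """
    metric = np.asarray(metric, dtype=float)
    if not np.all(np.isfinite(metric)):
        raise ValueError(f"{name} metric contains non-finite entries")
    if metric.ndim == 1:
        if metric.shape[0] != side:
            raise ValueError(f"{name} metric length {metric.shape[0]} != {side}")
        if np.any(metric <= 0):
            raise ValueError(f"{name} metric must be strictly positive")
        h = np.sqrt(metric)
        return h, 1.0 / h
    if metric.shape != (side, side):
        raise ValueError(f"{name} metric shape {metric.shape} != ({side}, {side})")
    sym = 0.5 * (metric + metric.T)
    evals, evecs = np.linalg.eigh(sym)
    if np.any(evals <= 0):
        raise ValueError(f"{name} metric is not positive definite")
    h = (evecs * np.sqrt(evals)) @ evecs.T
    ih = (evecs / np.sqrt(evals)) @ evecs.T
    return h, ih


def _apply(metric_half, mat, side: str) -> np.ndarray:
    if metric_half.ndim == 1:
        return metric_half[:, None] * mat if side == "left" else mat * metric_half
    return metric_half @ mat if side == "left" else mat @ metric_half


def gsvd(R: np.ndarray, B: np.ndarray, W: np.ndarray, tol: float | None = None) -> GsvdResult:
    """Generalized SVD of ``R`` under row metric ``B`` and column metric ``W``.

    Parameters
    ----------
    R : (I, J) real matrix.
    B : row metric — length-I positive vector (diagonal) or I x I SPD matrix.
    W : column metric — length-J positive vector or J x J SPD matrix.
    tol : rank tolerance; defaults to max(I, J) * eps * delta_max.

    Returns
    -------
    GsvdResult with P Δ Qᵀ = R (to numerical precision on the retained
    rank), PᵀBP = QᵀWQ = I, and a deterministic sign convention: each right
    vector is flipped so its entry of largest magnitude is positive (ties
    broken by lowest index).
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2:
        raise ValueError("R must be 2-D")
    if not np.all(np.isfinite(R)):
        raise ValueError("R contains non-finite entries")
    i, j = R.shape
    bh, bih = _metric_sqrt(B, i, "row")
    wh, wih = _metric_sqrt(W, j, "column")

    Rt = _apply(bh, _apply(wh, R, "right"), "left")
    U, s, Vt = np.linalg.svd(Rt, full_matrices=False)

    if tol is None:
        tol = max(i, j) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    L = int(keep.sum())
    U, s, Vt = U[:, :L], s[:L], Vt[:L]

    P = _apply(bih, U, "left")
    Q = _apply(wih, Vt.T, "left")

    # sign convention on Q, mirrored on P so the product is unchanged
    for ell in range(L):
        lead = np.argmax(np.abs(Q[:, ell]))
        if Q[lead, ell] < 0:
            Q[:, ell] = -Q[:, ell]
            P[:, ell] = -P[:, ell]
    return GsvdResult(P=P, Q=Q, delta=s)


def generalized_distance(x: np.ndarray, y: np.ndarray, W: np.ndarray) -> float:
    """Squared generalized Euclidean distance (x−y)ᵀ W (x−y).

    ``W`` may be a positive vector (diagonal metric) or an SPD matrix.
    Nonnegative; zero iff x == y for positive-definite W.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d = x - y
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        if W.shape != x.shape:
            raise ValueError("metric dimension mismatch")
        return float(np.sum(W * d * d))
    if W.shape != (x.size, x.size):
        raise ValueError("metric dimension mismatch")
    return float(d @ W @ d)
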