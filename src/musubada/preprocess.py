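"""Row/column/subtable transforms applied before the discriminant analysis.

Every transform that estimates parameters (column means, standard
deviations, per-subtable scales, STATIS weights) stores them, and new rows
— held-out observations in cross-validation — are transformed with the
stored training-set parameters only.  This is what keeps leave-one-out and
leave-one-block-out estimates honest: the left-out rows never contribute to
the preprocessing statistics.

Transforms
----------
center        subtract training column means
zscore        center and scale columns to unit (population) SD
row_sum       divide each row by its sum
row_ss        divide each row by its Euclidean norm (sum of squares -> 1)
hellinger     square root of each row's relative-frequency profile
mfa           divide each subtable by its first singular value
statis        scale each subtable by the square root of its STATIS weight
              (first eigenvector of the between-subtable RV matrix)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PreprocessParams",
    "Preprocessor",
    "center_columns",
    "zscore_columns",
    "normalize_rows",
    "hellinger_transform",
    "mfa_normalize_subtables",
    "statis_weights",
    "rv_coefficient",
]


# ---------------------------------------------------------------- primitives
def center_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract column means (uniform row averaging); returns (X', means)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    return X - means, means


def zscore_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale each column to SD 1 (population denominator N).

    Raises on a zero-variance column, naming the offending column.
    """
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # ddof=0: matches the mass-weighted inertia algebra
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) {bad.tolist()}: cannot z-score")
    return (X - means) / sds, means, sds


def normalize_rows(X: np.ndarray, mode: str = "sum_of_squares") -> np.ndarray:
    """Rescale each row so its sum (``mode='sum'``) or sum of squared
    elements (``mode='sum_of_squares'``) equals one."""
    X = np.asarray(X, dtype=float)
    if mode == "sum":
        norms = X.sum(axis=1)
    elif mode == "sum_of_squares":
        norms = np.sqrt((X**2).sum(axis=1))
    else:
        raise ValueError(f"unknown row normalization mode {mode!r}")
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-norm row(s) {bad.tolist()}: cannot normalize")
    return X / norms[:, None]


def hellinger_transform(X: np.ndarray) -> np.ndarray:
    """Square root of each row's relative-frequency profile.

    Rows become points on the unit sphere (squared entries sum to 1); the
    Euclidean geometry on these rows is the Hellinger distance between the
    original count profiles.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("hellinger transform requires nonnegative entries")
    sums = X.sum(axis=1)
    bad = np.flatnonzero(sums == 0)
    if bad.size:
        raise ValueError(f"zero-sum row(s) {bad.tolist()}: cannot form profiles")
    return np.sqrt(X / sums[:, None])


def mfa_normalize_subtables(
    X: np.ndarray, col_subtables: np.ndarray, subtable_order: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each subtable by its first singular value (multiple factor
    analysis normalization), so no single subtable dominates the first
    dimension by virtue of a large leading eigenvalue.

    Returns (X', scales) with scales ordered like ``subtable_order``.
    """
    X = np.asarray(X, dtype=float).copy()
    scales = np.empty(len(subtable_order))
    for k, label in enumerate(subtable_order):
        cols = np.flatnonzero(col_subtables == label)
        sv1 = np.linalg.svd(X[:, cols], compute_uv=False)[0]
        if sv1 == 0:
            raise ValueError(f"subtable {label!r} is all zero: cannot MFA-normalize")
        X[:, cols] /= sv1
        scales[k] = sv1
    return X, scales


def rv_coefficient(S1: np.ndarray, S2: np.ndarray) -> float:
    """RV coefficient between two positive-semidefinite cross-product
    matrices: trace(S1 S2) / sqrt(trace(S1²) trace(S2²))."""
    num = np.sum(S1 * S2)
    den = np.sqrt(np.sum(S1 * S1) * np.sum(S2 * S2))
    if den == 0:
        raise ValueError("degenerate (zero) cross-product matrix in RV coefficient")
    return float(num / den)


def statis_weights(
    X: np.ndarray, col_subtables: np.ndarray, subtable_order: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subtable STATIS weights and the between-subtable RV matrix.

    Each subtable k is summarized by the rows x rows cross-product of its
    column-centered block, S_k = X_k X_kᵀ.  The K x K matrix of RV
    coefficients between these summaries measures how much structure the
    subtables share; its first eigenvector (rescaled to sum 1) gives each
    subtable a weight proportional to its agreement with the consensus.
    """
    labels = list(subtable_order)
    if len(labels) < 2:
        raise ValueError("STATIS weighting needs at least 2 subtables")
    cross = []
    for label in labels:
        cols = np.flatnonzero(col_subtables == label)
        Xk = X[:, cols]
        Xk = Xk - Xk.mean(axis=0)
        S = Xk @ Xk.T
        if not np.any(S):
            raise ValueError(f"subtable {label!r} has zero cross-product")
        cross.append(S)
    K = len(labels)
    rv = np.eye(K)
    for a in range(K):
        for b in range(a + 1, K):
            rv[a, b] = rv[b, a] = rv_coefficient(cross[a], cross[b])
    evals, evecs = np.linalg.eigh(rv)
    lead = evecs[:, -1]
    if lead.sum() < 0:  # Perron vector of a nonneg-dominant matrix: fix the sign
        lead = -lead
    lead = np.clip(lead, 0.0, None)
    weights = lead / lead.sum()
    return weights, rv


# ------------------------------------------------------------------ pipeline
@dataclass
class PreprocessParams:
    """Parameters captured while fitting a preprocessing pipeline."""

    applied_steps: list[str] = field(default_factory=list)
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    mfa_scale: np.ndarray | None = None
    statis_weight: np.ndarray | None = None

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "applied_steps": list(self.applied_steps),
            "column_means": arr(self.column_means),
            "column_sds": arr(self.column_sds),
            "mfa_scale": arr(self.mfa_scale),
            "statis_weight": arr(self.statis_weight),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessParams":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            applied_steps=list(d["applied_steps"]),
            column_means=arr(d.get("column_means")),
            column_sds=arr(d.get("column_sds")),
            mfa_scale=arr(d.get("mfa_scale")),
            statis_weight=arr(d.get("statis_weight")),
        )


_INTERACTING = {"zscore", "row_sum", "row_ss", "hellinger"}


class Preprocessor:
    """Ordered preprocessing pipeline with train/apply separation.

    ``fit_transform`` estimates parameters on the training rows and returns
    the transformed matrix; ``transform`` replays the recorded steps on new
    rows using only the stored parameters.
    """

    def __init__(self, steps, col_subtables=None, subtable_order=None):
        self.steps = list(steps)
        self.col_subtables = None if col_subtables is None else np.asarray(col_subtables)
        self.subtable_order = None if subtable_order is None else np.asarray(subtable_order)
        self.params = PreprocessParams()
        if len(_INTERACTING & set(self.steps)) > 1:
            warnings.warn(
                "combining z-scoring with row normalization: transforms interact; "
                "they are applied in the order listed",
                stacklevel=2,
            )

    def _need_subtables(self, step):
        if self.col_subtables is None or self.subtable_order is None:
            raise ValueError(f"step {step!r} requires a column subtable design")

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        self.params = PreprocessParams()
        for step in self.steps:
            if step == "center":
                X, self.params.column_means = center_columns(X)
            elif step == "zscore":
                X, self.params.column_means, self.params.column_sds = zscore_columns(X)
            elif step == "row_sum":
                X = normalize_rows(X, "sum")
            elif step == "row_ss":
                X = normalize_rows(X, "sum_of_squares")
            elif step == "hellinger":
                X = hellinger_transform(X)
            elif step == "mfa":
                self._need_subtables(step)
                X, self.params.mfa_scale = mfa_normalize_subtables(
                    X, self.col_subtables, self.subtable_order
                )
            elif step == "statis":
                self._need_subtables(step)
                w, _ = statis_weights(X, self.col_subtables, self.subtable_order)
                self.params.statis_weight = w
                X = self._scale_subtables(X, np.sqrt(w))
            else:
                raise ValueError(f"unknown preprocessing step {step!r}")
            self.params.applied_steps.append(step)
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the fitted pipeline to new rows (training parameters only)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        for step in self.params.applied_steps:
            if step == "center":
                X = X - self.params.column_means
            elif step == "zscore":
                X = (X - self.params.column_means) / self.params.column_sds
            elif step == "row_sum":
                X = normalize_rows(X, "sum")
            elif step == "row_ss":
                X = normalize_rows(X, "sum_of_squares")
            elif step == "hellinger":
                X = hellinger_transform(X)
            elif step == "mfa":
                X = self._scale_subtables(X, 1.0 / self.params.mfa_scale)
            elif step == "statis":
                X = self._scale_subtables(X, np.sqrt(self.params.statis_weight))
        return X

    def _scale_subtables(self, X: np.ndarray, factors: np.ndarray) -> np.ndarray:
        X = X.copy()
        for k, label in enumerate(self.subtable_order):
            cols = np.flatnonzero(self.col_subtables == label)
            X[:, cols] *= factors[k]
        return X
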