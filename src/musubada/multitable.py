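"""Multi-table ("multi-subject") step: partial projections and inertias.

Each subtable — the block of columns contributed by one subject or ROI —
projects the category barycenters into the common factor space through its
own slice of the metric and the right singular vectors, scaled by K so that
the plain average of the K partial projections recovers the consensus
factor scores.  The per-subtable, per-dimension partial inertias decompose
each eigenvalue additively, which is how the subtables driving the
discrimination are identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bada import BadaModel

__all__ = [
    "PartialDecomposition",
    "partial_scores",
    "project_supplementary_partial",
    "partial_inertia",
]


def _require_diagonal_w(model: BadaModel) -> np.ndarray:
    if model.w.ndim != 1:
        raise ValueError(
            "partial projections require a diagonal column metric; the "
            "classical-DA within-covariance metric couples columns across "
            "subtables and does not decompose by block"
        )
    return model.w


def _subtable_cols(model: BadaModel, label) -> np.ndarray:
    cols = np.flatnonzero(model.col_subtables == label)
    if cols.size == 0:
        raise KeyError(f"subtable {label!r} absent from model")
    return cols


@dataclass
class PartialDecomposition:
    """Per-subtable factor scores and per-dimension partial inertias."""

    F_partial: np.ndarray         # K x I x L category partial scores
    partial_inertia: np.ndarray   # K x L
    contributions: np.ndarray     # K x L, columns sum to 1
    subtables: np.ndarray
    categories: np.ndarray

    def inertia_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.partial_inertia,
            index=pd.Index(self.subtables, name="subtable"),
            columns=[f"dim{l + 1}" for l in range(self.partial_inertia.shape[1])],
        )


def partial_scores(model: BadaModel, observation_level: bool = False) -> PartialDecomposition:
    """Partial projections F_k = K · R_k W_k Q_k for every subtable.

    ``R_k`` is the barycenter matrix restricted to subtable k's columns
    (centered with the matching slice of the grand barycenter), so the
    output is I x L per subtable and the barycentric identity
    (1/K) Σ_k F_k = F holds exactly.  With ``observation_level=True`` the
    training rows are projected instead of the barycenters (N x L per
    subtable).
    """
    w = _require_diagonal_w(model)
    K = len(model.subtables)
    base = model.Xt if observation_level else model.R
    n_out = base.shape[0]
    L = model.gsvd.rank
    F_partial = np.empty((K, n_out, L))
    for k, label in enumerate(model.subtables):
        cols = _subtable_cols(model, label)
        Xk = base[:, cols] - model.center[cols]
        F_partial[k] = K * (Xk * w[cols]) @ model.gsvd.Q[cols]
    pi = partial_inertia(model)
    lam = model.gsvd.eigenvalues
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(lam > 0, pi / lam, 0.0)
    return PartialDecomposition(
        F_partial=F_partial, partial_inertia=pi, contributions=contrib,
        subtables=model.subtables, categories=model.categories,
    )


def project_supplementary_partial(model: BadaModel, x_sup: np.ndarray, subtable) -> np.ndarray:
    """Project supplementary rows that only span one subtable's columns:
    f = K · x W_k Q_k.  ``x_sup`` must already be preprocessed like the
    corresponding training columns (use the model's stored parameters)."""
    w = _require_diagonal_w(model)
    cols = _subtable_cols(model, subtable)
    x = np.atleast_2d(np.asarray(x_sup, dtype=float))
    if x.shape[1] != cols.size:
        raise ValueError(
            f"subtable {subtable!r} has {cols.size} columns, got {x.shape[1]}"
        )
    K = len(model.subtables)
    xc = x - model.center[cols]
    return K * (xc * w[cols]) @ model.gsvd.Q[cols]


def partial_inertia(model: BadaModel) -> np.ndarray:
    """K x L matrix of partial inertias: the W-weighted sum of squared
    variable factor scores within each subtable, per dimension.  Summing
    over the subtables recovers each dimension's eigenvalue."""
    w = _require_diagonal_w(model)
    G = model.G
    out = np.empty((len(model.subtables), G.shape[1]))
    for k, label in enumerate(model.subtables):
        cols = _subtable_cols(model, label)
        out[k] = (w[cols, None] * G[cols] ** 2).sum(axis=0)
    return out
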