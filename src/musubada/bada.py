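"""Barycentric discriminant analysis (BADA).

Each category is represented by the barycenter (mass-weighted mean row) of
its observations; the I x J barycenter matrix is centered at the grand
barycenter and decomposed with a generalized SVD under the category-mass
metric B and the variable-weight metric W.  Observations are projected into
the resulting factor space as supplementary elements and assigned to the
nearest category.

The choice of masses and weights selects the analysis variant:

plain       user masses and weights (defaults: uniform) on any real table.
dica        discriminant correspondence analysis for count tables: rows are
            profiles (relative frequencies), row masses are relative row
            totals, column weights the inverse column frequencies — the
            chi-square geometry of correspondence analysis.
hellinger   square-root profiles with uniform masses and weights: Euclidean
            geometry on the sphere, the Hellinger distance between count
            profiles.
classical   W is the (pseudo-)inverse of the pooled within-category
            covariance: classical linear discriminant geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datamodel import AnalysisConfig, DiscriminantTable
from .gsvd import GsvdResult, gsvd
from .preprocess import Preprocessor, hellinger_transform, normalize_rows

__all__ = [
    "BadaModel",
    "ClassificationReport",
    "compute_barycenters",
    "fit",
    "project_rows",
    "score_distances",
    "classify",
    "loadings",
]

logger = logging.getLogger(__name__)


def compute_barycenters(
    X: np.ndarray, masses: np.ndarray, row_categories: np.ndarray, categories: np.ndarray
) -> np.ndarray:
    """Category barycenters: mass-weighted mean rows, masses rescaled to
    sum 1 within each category."""
    X = np.asarray(X, dtype=float)
    R = np.empty((len(categories), X.shape[1]))
    for i, c in enumerate(categories):
        idx = row_categories == c
        m = masses[idx]
        tot = m.sum()
        if tot <= 0:
            raise ValueError(f"category {c!r} has zero total mass")
        R[i] = (m / tot) @ X[idx]
    return R


def _within_covariance(X: np.ndarray, masses: np.ndarray, row_categories, categories) -> np.ndarray:
    """Pooled within-category covariance under the row masses."""
    m = masses / masses.sum()
    S = np.zeros((X.shape[1], X.shape[1]))
    for c in categories:
        idx = row_categories == c
        mi = m[idx]
        mu = (mi / mi.sum()) @ X[idx]
        D = X[idx] - mu
        S += (D * mi[:, None]).T @ D
    return S


@dataclass
class BadaModel:
    """Fitted barycentric discriminant model."""

    R: np.ndarray                 # I x J barycenters (transformed space, uncentered)
    center: np.ndarray            # grand barycenter (b-weighted mean row of R)
    gsvd: GsvdResult
    F: np.ndarray                 # I x L category factor scores
    G: np.ndarray                 # J x L variable factor scores (Q * delta)
    b: np.ndarray                 # category masses used in the GSVD
    w: np.ndarray                 # column metric (vector, or matrix for classical)
    masses: np.ndarray            # row masses actually used
    categories: np.ndarray
    col_subtables: np.ndarray
    variant: str
    preprocessor: Preprocessor | None
    config: AnalysisConfig
    H: np.ndarray | None = None   # training-row factor scores
    Xt: np.ndarray | None = None  # transformed training data (cached)
    row_categories: np.ndarray | None = None
    row_blocks: np.ndarray | None = None
    condition_number: float | None = field(default=None)

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.gsvd.eigenvalues

    @property
    def subtables(self) -> np.ndarray:
        return pd.unique(pd.Series(self.col_subtables)).astype(self.col_subtables.dtype)

    # --------------------------------------------------------------- helpers
    def transform_rows(self, X: np.ndarray) -> np.ndarray:
        """Apply the variant's row transform / fitted preprocessing to raw rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.variant == "dica":
            return normalize_rows(X, "sum")
        if self.variant == "hellinger":
            return hellinger_transform(X)
        if self.preprocessor is not None:
            return self.preprocessor.transform(X)
        return X

    def _apply_w(self, M: np.ndarray) -> np.ndarray:
        w = self.w
        return M * w if w.ndim == 1 else M @ w


def _variant_metrics(table: DiscriminantTable, config: AnalysisConfig):
    """Transformed data, row masses, category masses b and column metric w
    for the requested variant."""
    X = table.data
    if config.variant == "dica":
        if np.any(X < 0):
            raise ValueError("DICA requires nonnegative count data")
        grand = X.sum()
        col_freq = X.sum(axis=0) / grand
        if np.any(col_freq == 0):
            bad = np.flatnonzero(col_freq == 0)
            raise ValueError(f"zero column frequency under DICA: column(s) {bad.tolist()}")
        Xt = normalize_rows(X, "sum")
        masses = X.sum(axis=1) / grand          # CA convention: relative row totals
        w = 1.0 / col_freq
        pre = None
    elif config.variant == "hellinger":
        Xt = hellinger_transform(X)
        masses = np.full(table.n_rows, 1.0 / table.n_rows)
        w = np.full(table.n_cols, 1.0 / table.n_cols)
        pre = None
    else:
        pre = Preprocessor(
            config.preprocess,
            col_subtables=table.col_subtables,
            subtable_order=table.subtables,
        )
        Xt = pre.fit_transform(X)
        masses = table.row_masses
        w = table.col_weights
    cats = table.categories
    b = np.array([masses[table.row_categories == c].sum() for c in cats])
    b = b / b.sum()
    return Xt, masses, b, w, pre


def fit(table: DiscriminantTable, config: AnalysisConfig | None = None) -> BadaModel:
    """Fit the barycentric discriminant model.

    Runs the variant's preprocessing, computes category barycenters, centers
    them at the grand barycenter, and decomposes with the generalized SVD
    under (B, W).  Factor scores F = PΔ; variable scores G = QΔ; training
    rows are projected as supplementary elements.
    """
    if config is None:
        config = AnalysisConfig()
    Xt, masses, b, w, pre = _variant_metrics(table, config)
    cats = table.categories
    R = compute_barycenters(Xt, masses, table.row_categories, cats)

    cond = None
    if config.variant == "classical":
        S = _within_covariance(Xt, masses, table.row_categories, cats)
        if config.ridge > 0:
            S = S + config.ridge * np.eye(S.shape[0])
        sv = np.linalg.svd(S, compute_uv=False)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        if cond > 1e12:
            logger.warning(
                "within-category covariance is near-singular (condition %.3g); "
                "using pseudo-inverse — consider a ridge", cond,
            )
        w = np.linalg.pinv(S, hermitian=True)

    center = b @ R
    res = gsvd(R - center, b, w)
    if config.n_components != "all":
        L = min(int(config.n_components), res.rank)
        res = GsvdResult(P=res.P[:, :L], Q=res.Q[:, :L], delta=res.delta[:L])
    F = res.P * res.delta
    G = res.Q * res.delta

    model = BadaModel(
        R=R, center=center, gsvd=res, F=F, G=G, b=b, w=np.asarray(w, dtype=float),
        masses=np.asarray(masses, dtype=float), categories=cats,
        col_subtables=table.col_subtables, variant=config.variant,
        preprocessor=pre, config=config, condition_number=cond,
    )
    model.Xt = Xt
    model.H = project_rows(model, Xt, preprocessed=True)
    model.row_categories = table.row_categories
    model.row_blocks = table.row_blocks
    return model


def project_rows(model: BadaModel, X: np.ndarray, preprocessed: bool = False) -> np.ndarray:
    """Project rows as supplementary elements: H = (X − center) W Q.

    These projections are barycentric: the mass-weighted category means of
    the projected training rows reproduce the category factor scores F.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not preprocessed:
        X = model.transform_rows(X)
    if X.shape[1] != model.R.shape[1]:
        raise ValueError(
            f"expected {model.R.shape[1]} columns, got {X.shape[1]}"
        )
    return model._apply_w(X - model.center) @ model.gsvd.Q


def score_distances(H: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances in factor space, observations x categories."""
    H = np.atleast_2d(H)
    F = np.atleast_2d(F)
    if H.shape[1] != F.shape[1]:
        raise ValueError("factor-space dimension mismatch between H and F")
    return cdist(H, F, metric="sqeuclidean")


@dataclass
class ClassificationReport:
    """Nearest-barycenter assignments and the confusion matrix.

    The confusion matrix follows the convention: columns are the actual
    categories, rows the predicted categories.
    """

    distances: np.ndarray
    assigned: np.ndarray
    categories: np.ndarray
    mode: str = "fixed"
    confusion: pd.DataFrame | None = None
    accuracy: float | None = None
    per_category_accuracy: pd.Series | None = None
    n_ties: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.distances, columns=[f"d2_{c}" for c in self.categories])
        df["assigned"] = self.assigned
        return df


def classify(
    model: BadaModel,
    data: DiscriminantTable | np.ndarray,
    preprocessed: bool = False,
    mode: str = "fixed",
) -> ClassificationReport:
    """Assign each observation to the nearest category barycenter.

    Ties in the argmin are broken toward the lowest category index and
    counted in ``n_ties`` (with a logged warning).  When ``data`` is a
    :class:`DiscriminantTable`, the actual labels are used to build the
    confusion matrix and accuracies.
    """
    actual = None
    if isinstance(data, DiscriminantTable):
        actual = data.row_categories
        X = data.data
    else:
        X = data
    H = project_rows(model, X, preprocessed=preprocessed)
    D = score_distances(H, model.F)
    idx = np.argmin(D, axis=1)
    ties = int(np.sum((D == D.min(axis=1, keepdims=True)).sum(axis=1) > 1))
    if ties:
        logger.warning("%d observation(s) equidistant from >=2 categories; "
                       "assigned to the lowest category index", ties)
    assigned = model.categories[idx]

    report = ClassificationReport(
        distances=D, assigned=assigned, categories=model.categories,
        mode=mode, n_ties=ties,
    )
    if actual is not None:
        report.confusion = confusion_matrix(assigned, actual, model.categories)
        correct = assigned == actual
        report.accuracy = float(correct.mean())
        report.per_category_accuracy = pd.Series(
            {c: float(correct[actual == c].mean()) for c in model.categories}
        )
    return report


def confusion_matrix(predicted, actual, categories) -> pd.DataFrame:
    """I x I counts: rows = predicted category, columns = actual category."""
    M = pd.DataFrame(0, index=categories, columns=categories, dtype=int)
    for p, a in zip(predicted, actual):
        M.loc[p, a] += 1
    M.index.name = "predicted"
    M.columns.name = "actual"
    return M


def loadings(model: BadaModel, kind: str = "G") -> np.ndarray:
    """Variable-level descriptions of the discriminant dimensions.

    kind='Q'            right generalized singular vectors.
    kind='G'            variable factor scores Q Δ.
    kind='correlation'  b-mass-weighted correlation between each barycenter
                        column and each factor-score column.
    """
    if kind == "Q":
        return model.gsvd.Q
    if kind == "G":
        return model.G
    if kind == "correlation":
        b = model.b / model.b.sum()
        Rc = model.R - b @ model.R
        Fc = model.F - b @ model.F
        sd_r = np.sqrt(b @ (Rc**2))
        sd_f = np.sqrt(b @ (Fc**2))
        if np.any(sd_r == 0):
            bad = np.flatnonzero(sd_r == 0)
            raise ValueError(f"zero-variance column(s) {bad.tolist()} under correlation loadings")
        cov = (Rc * b[:, None]).T @ Fc
        return cov / np.outer(sd_r, sd_f)
    raise ValueError(f"unknown loadings kind {kind!r}")
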