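"""Inference for the barycentric discriminant model.

Fixed-effect quality is measured on the training observations; random-effect
quality is estimated by cross-validation (leave-one-out, or leave-one-block-
out when observations are temporally correlated within blocks).  Category
separation is quantified by the inertia decomposition and its R², tested by
permutation; the stability of category positions by stratified bootstrap of
the barycenters, displayed as confidence ellipses, with Bonferroni / Šidák
corrections for the multiple pairwise comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .bada import (
    BadaModel,
    ClassificationReport,
    classify,
    compute_barycenters,
    confusion_matrix,
    fit,
    project_rows,
    score_distances,
    _within_covariance,
)
from .datamodel import AnalysisConfig, DiscriminantTable
from .gsvd import gsvd

__all__ = [
    "InertiaDecomposition",
    "inertia_decomposition",
    "PermutationResult",
    "permutation_test",
    "CrossValResult",
    "crossvalidate",
    "project_leftout_into_full",
    "bootstrap_barycenters",
    "Ellipse",
    "EllipseSet",
    "fit_ellipse",
    "confidence_ellipses",
    "ellipses_overlap",
    "separation_flags",
    "corrected_level",
]

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------ inertia
@dataclass
class InertiaDecomposition:
    """Additive decomposition of factor-space inertia: total = within + between."""

    total: float
    within: float
    between: float
    r_squared: float
    permutation_p: float | None = None
    n_permutations: int = 0


def _decompose(H: np.ndarray, masses: np.ndarray, labels: np.ndarray, categories: np.ndarray) -> InertiaDecomposition:
    m = masses / masses.sum()
    grand = m @ H
    total = float(m @ ((H - grand) ** 2).sum(axis=1))
    within = 0.0
    between = 0.0
    for c in categories:
        idx = labels == c
        mi = m[idx]
        bi = mi.sum()
        fi = (mi / bi) @ H[idx]
        within += float(mi @ ((H[idx] - fi) ** 2).sum(axis=1))
        between += bi * float(((fi - grand) ** 2).sum())
    r2 = between / total if total > 0 else 0.0
    return InertiaDecomposition(total=total, within=within, between=between, r_squared=r2)


def inertia_decomposition(model: BadaModel) -> InertiaDecomposition:
    """Total, within-category and between-category inertia of the training
    projections, and R² = between / total.

    The grand barycenter is the mass-weighted mean of the projected rows
    (equivalently the b-weighted mean of the category factor scores), which
    makes the ANOVA-style additivity exact.
    """
    return _decompose(model.H, model.masses, model.row_categories, model.categories)


# -------------------------------------------------------------- permutation
@dataclass
class PermutationResult:
    observed_r2: float
    p_value: float
    null_r2: np.ndarray
    n_permutations: int
    exchangeable_unit: str


def _rsq_for_labels(model: BadaModel, labels: np.ndarray) -> float:
    """Refit barycenters + GSVD on the cached transformed data with new
    labels and return R².  Valid because every row transform in the package
    is label-free; the classical-DA column metric is recomputed per
    relabeling since it does depend on the labels."""
    Xt, masses = model.Xt, model.masses
    cats = model.categories
    b = np.array([masses[labels == c].sum() for c in cats])
    b = b / b.sum()
    R = compute_barycenters(Xt, masses, labels, cats)
    if model.variant == "classical":
        S = _within_covariance(Xt, masses, labels, cats)
        if model.config.ridge > 0:
            S = S + model.config.ridge * np.eye(S.shape[0])
        w = np.linalg.pinv(S, hermitian=True)
    else:
        w = model.w
    center = b @ R
    Rc = R - center
    if not np.any(Rc):
        return 0.0
    res = gsvd(Rc, b, w)
    Xc = Xt - center
    H = (Xc * w if w.ndim == 1 else Xc @ w) @ res.Q
    return _decompose(H, masses, labels, cats).r_squared


def _exchangeable_units(table: DiscriminantTable):
    """(unit ids per row, label per unit) for permutation: blocks when the
    design declares them, otherwise individual observations."""
    if table.row_blocks is not None:
        units = table.blocks
        unit_labels = []
        for u in units:
            cats = np.unique(table.row_categories[table.row_blocks == u])
            if cats.size != 1:
                raise ValueError(
                    f"block {u!r} spans {cats.size} categories; blocks must be "
                    "nested within categories to serve as exchangeable units"
                )
            unit_labels.append(cats[0])
        return "block", units, np.array(unit_labels), table.row_blocks
    n = table.n_rows
    ids = np.arange(n)
    return "observation", ids, table.row_categories.copy(), ids


def permutation_test(
    table: DiscriminantTable,
    config: AnalysisConfig | None = None,
    model: BadaModel | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test of R²: category labels are shuffled across the
    exchangeable units (whole blocks when present, since within-block rows
    are not independent), the model is refitted, and the p-value is the
    add-one estimator (1 + #{R*² ≥ R²}) / (1 + n_permutations)."""
    if config is None:
        config = AnalysisConfig()
    if model is None:
        model = fit(table, config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_perm = config.n_permutations
    if n_perm < 99:
        logger.warning("n_permutations=%d is low; p-value resolution is coarse", n_perm)

    unit_kind, units, unit_labels, row_units = _exchangeable_units(table)
    if len(units) < table.n_categories:
        raise ValueError(
            f"{len(units)} exchangeable {unit_kind}s for {table.n_categories} "
            "categories: cannot permute"
        )
    observed = inertia_decomposition(model).r_squared
    # map each row to its unit position once
    unit_pos = {u: i for i, u in enumerate(units)}
    row_to_unit = np.array([unit_pos[u] for u in row_units])

    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(len(units))
        labels = unit_labels[perm][row_to_unit]
        null[p] = _rsq_for_labels(model, labels)
    p_value = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_perm)
    return PermutationResult(
        observed_r2=observed, p_value=float(p_value), null_r2=null,
        n_permutations=n_perm, exchangeable_unit=unit_kind,
    )


# ---------------------------------------------------------- cross-validation
@dataclass
class CrossValResult:
    report: ClassificationReport
    hhat: np.ndarray              # N x L projections into the full solution
    htilde: np.ndarray            # per-row scores in their fold's space (object arr)
    fold_of_row: np.ndarray


def _folds(table: DiscriminantTable, cv_mode: str):
    if cv_mode == "leave-one-block-out":
        if table.row_blocks is None:
            raise ValueError("leave-one-block-out requires block labels")
        for blk in table.blocks:
            yield np.flatnonzero(table.row_blocks == blk)
    else:
        for n in range(table.n_rows):
            yield np.array([n])


def crossvalidate(
    table: DiscriminantTable,
    config: AnalysisConfig | None = None,
    full_model: BadaModel | None = None,
) -> CrossValResult:
    """Random-effect evaluation by leave-one-out / leave-one-block-out.

    Per fold the preprocessing parameters, barycenters and GSVD are
    re-estimated on the retained rows only; held-out rows are transformed
    with the fold's training parameters, projected (h̃ = x W₋ Q₋) and
    assigned to the nearest fold barycenter.  Each held-out row is also
    re-projected into the full solution through its fold reconstruction
    (ĥ = x W₋ Q₋ Q₋ᵀ W Q) for prediction-interval clouds.
    """
    if config is None:
        config = AnalysisConfig()
    if full_model is None:
        full_model = fit(table, config)
    n = table.n_rows
    L_full = full_model.gsvd.rank
    hhat = np.full((n, L_full), np.nan)
    assigned = np.empty(n, dtype=table.row_categories.dtype)
    dist_rows = [None] * n
    fold_of_row = np.empty(n, dtype=int)
    all_cats = set(table.categories.tolist())

    for f, test_idx in enumerate(_folds(table, config.cv_mode)):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        missing = all_cats - set(table.row_categories[train_idx].tolist())
        if missing:
            raise ValueError(
                f"fold {f} empties category {sorted(missing)[0]!r}: "
                "cannot cross-validate"
            )
        sub = table.subset_rows(train_idx)
        m = fit(sub, config)
        X_test = table.data[test_idx]
        ht = project_rows(m, X_test, preprocessed=False)
        D = score_distances(ht, m.F)
        pick = np.argmin(D, axis=1)
        assigned[test_idx] = m.categories[pick]
        for r, row_i in enumerate(test_idx):
            dist_rows[row_i] = (m.categories, D[r])
            fold_of_row[row_i] = f
        hhat[test_idx] = project_leftout_into_full(full_model, m, X_test)

    correct = assigned == table.row_categories
    import pandas as pd

    report = ClassificationReport(
        distances=np.zeros((0, 0)),
        assigned=assigned,
        categories=table.categories,
        mode="random",
        confusion=confusion_matrix(assigned, table.row_categories, table.categories),
        accuracy=float(correct.mean()),
        per_category_accuracy=pd.Series(
            {c: float(correct[table.row_categories == c].mean()) for c in table.categories}
        ),
    )
    return CrossValResult(report=report, hhat=hhat, htilde=np.array(dist_rows, dtype=object),
                          fold_of_row=fold_of_row)


def project_leftout_into_full(
    model_full: BadaModel, model_minus: BadaModel, X: np.ndarray, preprocessed: bool = False
) -> np.ndarray:
    """Project held-out rows into the full solution via their fold
    reconstruction: the row is projected in the fold space, reconstructed
    from those factor scores (x̃ = h̃ Q₋ᵀ), and the reconstruction is
    projected as a supplementary element of the full model."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not preprocessed:
        X = model_minus.transform_rows(X)
    ht = model_minus._apply_w(X - model_minus.center) @ model_minus.gsvd.Q
    x_rec = ht @ model_minus.gsvd.Q.T + model_minus.center
    return project_rows(model_full, x_rec, preprocessed=True)


# ------------------------------------------------------------------ bootstrap
def bootstrap_barycenters(
    model: BadaModel,
    n_bootstrap: int | None = None,
    fix_blocks: bool | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap the category barycenters in the fixed factor space.

    Observations are resampled with replacement within each category — and
    within each category x block stratum when the block structure is
    declared fixed — and each replicate's mass-weighted barycenters are
    projected with the original solution (linearity of the projection lets
    this run on the cached factor scores H).  Returns an
    (n_bootstrap, I, L) array.
    """
    cfg = model.config
    if n_bootstrap is None:
        n_bootstrap = cfg.n_bootstrap
    if fix_blocks is None:
        fix_blocks = cfg.fix_blocks
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    H, m, labels = model.H, model.masses, model.row_categories
    blocks = model.row_blocks if (fix_blocks and model.row_blocks is not None) else None

    strata_per_cat: list[list[np.ndarray]] = []
    for c in model.categories:
        cat_idx = np.flatnonzero(labels == c)
        if blocks is None:
            strata = [cat_idx]
        else:
            strata = [cat_idx[blocks[cat_idx] == blk]
                      for blk in np.unique(blocks[cat_idx])]
        for s in strata:
            if s.size == 1:
                logger.warning("stratum of size 1 in category %r: resampled trivially", c)
        strata_per_cat.append(strata)

    out = np.empty((n_bootstrap, len(model.categories), H.shape[1]))
    for bidx in range(n_bootstrap):
        for i, strata in enumerate(strata_per_cat):
            take = np.concatenate([s[rng.integers(0, s.size, s.size)] for s in strata])
            mw = m[take]
            out[bidx, i] = (mw / mw.sum()) @ H[take]
    return out


# -------------------------------------------------------------------- ellipses
@dataclass
class Ellipse:
    """2-D elliptical region {p : (p−c)ᵀ S⁻¹ (p−c) ≤ r²} fitted to points."""

    center: np.ndarray
    shape: np.ndarray             # 2x2 PSD (sample covariance of the points)
    radius2: float
    level: float
    kind: str                     # tolerance | prediction | confidence
    dims: tuple[int, int] = (0, 1)
    degenerate: bool = False
    _inv: np.ndarray = field(default=None, repr=False)

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(points) - self.center
        return np.einsum("ni,ij,nj->n", P, self._inv, P)

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Inside or on the boundary (within numerical tolerance)."""
        return self.mahalanobis2(points) <= self.radius2 * (1 + tol) + tol


def fit_ellipse(points: np.ndarray, level: float, kind: str = "tolerance",
                dims: tuple[int, int] = (0, 1)) -> Ellipse:
    """Ellipse covering the stated fraction of the points.

    Center = mean of the points, shape = their sample covariance, and the
    radius is the empirical Mahalanobis quantile: the smallest radius such
    that ceil(level * n) points lie inside or on the boundary.  Collinear
    point clouds yield a flagged degenerate ellipse (pseudo-inverse metric,
    zero minor axis).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = points.shape
    if d != 2:
        raise ValueError("fit_ellipse expects n x 2 points")
    if not (0 < level <= 1):
        raise ValueError(f"coverage level must be in (0, 1], got {level}")
    center = points.mean(axis=0)
    if n < 2:
        S = np.zeros((2, 2))
    else:
        S = np.cov(points, rowvar=False)
    degenerate = n < 3 or np.linalg.matrix_rank(S, tol=1e-12 * max(1.0, np.trace(S))) < 2
    if degenerate:
        logger.warning("degenerate (collinear) point cloud: ellipse has a zero minor axis")
        inv = np.linalg.pinv(S, hermitian=True)
    else:
        inv = np.linalg.inv(S)
    e = Ellipse(center=center, shape=S, radius2=0.0, level=level, kind=kind,
                dims=dims, degenerate=degenerate, _inv=inv)
    d2 = np.sort(e.mahalanobis2(points))
    k = min(n, max(1, math.ceil(level * n)))
    e.radius2 = float(d2[k - 1])
    return e


@dataclass
class EllipseSet:
    """Per-category ellipses for one dimension pair, plus the corrected level."""

    ellipses: dict
    kind: str
    level: float
    corrected: float
    dims: tuple[int, int]


def corrected_level(alpha: float, I: int, method: str = "none") -> float:
    """Coverage level for pairwise category comparisons among I categories.

    'bonferroni' -> 1 − 2α/(I(I−1)); 'sidak' -> (1−α)^(1/m) with
    m = I(I−1)/2 pairs; 'none' -> 1 − α.  Both corrections reduce to 1 − α
    when I = 2 (a single comparison).
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if I < 2:
        raise ValueError("need at least 2 categories")
    if method == "none":
        return 1.0 - alpha
    if method == "bonferroni":
        return 1.0 - 2.0 * alpha / (I * (I - 1))
    if method == "sidak":
        m = I * (I - 1) / 2.0
        return (1.0 - alpha) ** (1.0 / m)
    raise ValueError(f"unknown correction {method!r}")


def confidence_ellipses(
    boot_F: np.ndarray,
    categories: np.ndarray,
    alpha: float = 0.05,
    correction: str = "none",
    dims: tuple[int, int] = (0, 1),
) -> EllipseSet:
    """Confidence ellipses from bootstrapped barycenters, one per category,
    on the requested dimension pair, at the (possibly corrected) level."""
    I = len(categories)
    level = corrected_level(alpha, I, correction)
    ells = {}
    for i, c in enumerate(categories):
        pts = boot_F[:, i, :][:, list(dims)]
        ells[c] = fit_ellipse(pts, level, kind="confidence", dims=dims)
    return EllipseSet(ellipses=ells, kind="confidence", level=1 - alpha,
                      corrected=level, dims=dims)


def ellipses_overlap(e1: Ellipse, e2: Ellipse, n_samples: int = 513) -> bool:
    """Approximate overlap test: sample along the segment joining the two
    centers and report overlap if any sampled point lies inside both
    regions (each center is inside its own ellipse, so disjoint centers
    separated by a gap are detected reliably for convex regions)."""
    if bool(e1.contains(e2.center[None])[0]) or bool(e2.contains(e1.center[None])[0]):
        return True
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    seg = e1.center + t * (e2.center - e1.center)
    both = e1.contains(seg) & e2.contains(seg)
    return bool(both.any())


def separation_flags(sets: list[EllipseSet], categories: np.ndarray) -> dict:
    """Pairwise separation verdicts across one or more dimension-pair maps.

    Non-overlap in ANY map implies the categories are separated in the whole
    space; overlap in every examined map is reported as inconclusive (the
    overlap may be a projection artifact).
    """
    out = {}
    cats = list(categories)
    for a in range(len(cats)):
        for b in range(a + 1, len(cats)):
            pair = (cats[a], cats[b])
            sep = any(
                not ellipses_overlap(s.ellipses[cats[a]], s.ellipses[cats[b]])
                for s in sets
            )
            out[pair] = "separated" if sep else "inconclusive in examined projections"
    return out
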