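"""Core data containers for barycentric discriminant analysis.

A :class:`DiscriminantTable` holds the N x J observations-by-variables
matrix together with the two designs that drive the analysis: a category
label per row (the classes to discriminate, e.g. stimulus categories) and a
subtable label per column (the blocks of variables contributed by each
subject or region of interest, allowed to differ in size).  Rows carry
masses, columns carry weights; these define the metrics of the generalized
PCA downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DiscriminantTable", "AnalysisConfig"]

VARIANTS = ("plain", "dica", "hellinger", "classical")
PREPROCESS_STEPS = ("center", "zscore", "row_sum", "row_ss", "hellinger", "mfa", "statis")
CORRECTIONS = ("none", "bonferroni", "sidak")
CV_MODES = ("leave-one-out", "leave-one-block-out")


def _unique_stable(labels: np.ndarray) -> np.ndarray:
    """Unique labels in order of first appearance (never silently sorted)."""
    return pd.unique(pd.Series(labels)).astype(labels.dtype)


@dataclass
class DiscriminantTable:
    """Observations x variables table with row/column designs and metrics.

    Parameters
    ----------
    data
        N x J real matrix (observations in rows, variables in columns).
    row_categories
        Length-N category label per row; I distinct values, each with at
        least one row.
    col_subtables
        Length-J subtable label per column; K distinct values.  Columns of
        one subtable need not be contiguous.
    row_blocks
        Optional length-N block label per row (e.g. scanning run); the
        exchangeable/resampling unit for block-aware inference.
    row_masses
        Nonnegative mass per row, default 1/N.
    col_weights
        Strictly positive weight per column, default 1/J.
    category_masses
        Mass per category (ordered like :attr:`categories`); defaults to
        the row masses aggregated per category and rescaled to sum 1.
    subtable_weights
        Positive weight per subtable (ordered like :attr:`subtables`),
        default 1/K.  Stored and exposed; enters computation only if the
        user folds it into ``col_weights``.
    row_ids, col_ids
        Optional identifiers used by the text I/O layer for alignment.
    """

    data: np.ndarray
    row_categories: np.ndarray
    col_subtables: np.ndarray
    row_blocks: np.ndarray | None = None
    row_masses: np.ndarray | None = None
    col_weights: np.ndarray | None = None
    category_masses: np.ndarray | None = None
    subtable_weights: np.ndarray | None = None
    row_ids: np.ndarray | None = None
    col_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite entries")
        n, j = self.data.shape
        self.row_categories = np.asarray(self.row_categories)
        self.col_subtables = np.asarray(self.col_subtables)
        if self.row_categories.shape != (n,):
            raise ValueError(
                f"row design has {self.row_categories.size} records for {n} rows"
            )
        if self.col_subtables.shape != (j,):
            raise ValueError(
                f"column design has {self.col_subtables.size} records for {j} columns"
            )
        if self.row_blocks is not None:
            self.row_blocks = np.asarray(self.row_blocks)
            if self.row_blocks.shape != (n,):
                raise ValueError("row_blocks length does not match row count")

        if self.row_masses is None:
            self.row_masses = np.full(n, 1.0 / n)
        else:
            self.row_masses = np.asarray(self.row_masses, dtype=float)
            if self.row_masses.shape != (n,):
                raise ValueError("row_masses length does not match row count")
            if np.any(self.row_masses < 0):
                raise ValueError("row masses must be nonnegative")
            if self.row_masses.sum() <= 0:
                raise ValueError("row masses must have positive total")
        if self.col_weights is None:
            self.col_weights = np.full(j, 1.0 / j)
        else:
            self.col_weights = np.asarray(self.col_weights, dtype=float)
            if self.col_weights.shape != (j,):
                raise ValueError("col_weights length does not match column count")
            if np.any(self.col_weights <= 0):
                raise ValueError("column weights must be strictly positive")

        cats = self.categories
        if len(cats) < 2:
            raise ValueError("need at least 2 categories")
        if n < len(cats):
            raise ValueError("fewer rows than categories")
        cat_mass = np.array(
            [self.row_masses[self.row_categories == c].sum() for c in cats]
        )
        if np.any(cat_mass <= 0):
            empty = cats[np.argmin(cat_mass)]
            raise ValueError(f"category {empty!r} has zero total mass")
        if self.category_masses is None:
            self.category_masses = cat_mass / cat_mass.sum()
        else:
            self.category_masses = np.asarray(self.category_masses, dtype=float)
            if self.category_masses.shape != (len(cats),):
                raise ValueError("category_masses length does not match category count")
            if np.any(self.category_masses < 0):
                raise ValueError("category masses must be nonnegative")
        if self.subtable_weights is None:
            k = len(self.subtables)
            self.subtable_weights = np.full(k, 1.0 / k)
        else:
            self.subtable_weights = np.asarray(self.subtable_weights, dtype=float)
            if self.subtable_weights.shape != (len(self.subtables),):
                raise ValueError("subtable_weights length does not match subtable count")
            if np.any(self.subtable_weights <= 0):
                raise ValueError("subtable weights must be strictly positive")

    # ------------------------------------------------------------------ views
    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def categories(self) -> np.ndarray:
        """Distinct category labels, order of first appearance."""
        return _unique_stable(self.row_categories)

    @property
    def subtables(self) -> np.ndarray:
        """Distinct subtable labels, order of first appearance."""
        return _unique_stable(self.col_subtables)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def n_subtables(self) -> int:
        return len(self.subtables)

    @property
    def blocks(self) -> np.ndarray | None:
        if self.row_blocks is None:
            return None
        return _unique_stable(self.row_blocks)

    def subtable_columns(self, label) -> np.ndarray:
        """Column indices belonging to one subtable."""
        idx = np.flatnonzero(self.col_subtables == label)
        if idx.size == 0:
            raise KeyError(f"unknown subtable {label!r}")
        return idx

    def category_rows(self, label) -> np.ndarray:
        idx = np.flatnonzero(self.row_categories == label)
        if idx.size == 0:
            raise KeyError(f"unknown category {label!r}")
        return idx

    def subset_rows(self, idx: np.ndarray) -> "DiscriminantTable":
        """Row subset with masses renormalized to sum 1 (for CV folds)."""
        idx = np.asarray(idx)
        m = self.row_masses[idx]
        return DiscriminantTable(
            data=self.data[idx],
            row_categories=self.row_categories[idx],
            col_subtables=self.col_subtables,
            row_blocks=None if self.row_blocks is None else self.row_blocks[idx],
            row_masses=m / m.sum(),
            col_weights=self.col_weights,
            row_ids=None if self.row_ids is None else self.row_ids[idx],
            col_ids=self.col_ids,
        )


@dataclass
class AnalysisConfig:
    """Analysis settings: variant, preprocessing recipe, resampling, CV."""

    variant: str = "plain"
    preprocess: Sequence[str] = field(default_factory=list)
    n_components: int | str = "all"
    n_bootstrap: int = 1000
    n_permutations: int = 999
    seed: int = 0
    alpha: float = 0.05
    correction: str = "none"
    cv_mode: str = "leave-one-out"
    fix_blocks: bool = True
    ridge: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        for step in self.preprocess:
            if step not in PREPROCESS_STEPS:
                raise ValueError(
                    f"unknown preprocessing step {step!r}; choose from {PREPROCESS_STEPS}"
                )
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.correction not in CORRECTIONS:
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.cv_mode not in CV_MODES:
            raise ValueError(f"unknown cv_mode {self.cv_mode!r}")
        if self.n_components != "all":
            if not isinstance(self.n_components, int) or self.n_components < 1:
                raise ValueError("n_components must be 'all' or a positive integer")
        if self.variant in ("dica", "hellinger") and self.preprocess:
            raise ValueError(
                f"variant {self.variant!r} defines its own row transform; "
                "preprocess steps are not combinable with it"
            )

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "preprocess": list(self.preprocess),
            "n_components": self.n_components,
            "n_bootstrap": self.n_bootstrap,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "alpha": self.alpha,
            "correction": self.correction,
            "cv_mode": self.cv_mode,
            "fix_blocks": self.fix_blocks,
            "ridge": self.ridge,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)
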