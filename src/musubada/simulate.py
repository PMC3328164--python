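"""Synthetic data emulating the multi-subject block-design regime.

Rows are scans organized as I stimulus categories x blocks x repeated scans;
columns are variables (voxels) partitioned into K subtables of unequal
sizes, one per subject.  Category separation is a mean shift confined to a
chosen subset of subtables (the "carriers"), and within-block noise is
AR(1)-correlated in time — the minimal mechanism that reproduces the
temporal dependence which makes leave-one-block-out cross-validation differ
from leave-one-out.

The default spec mirrors the structure of a 7-category, 8-blocks-per-
category, 16-scans-per-block, 10-subject design, with subtable widths scaled
to desk size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import DiscriminantTable

__all__ = ["SimSpec", "generate", "generate_counts"]


@dataclass
class SimSpec:
    """Generator settings and their invariants.

    effect_size is the standard deviation of the category mean shift per
    carrier column, in units of noise_sd (noise_sd defaults to 1).  Because
    the shift is spread over every carrier column, category separability
    grows with the carrier width; the default of 0.12 is calibrated so that
    the default 7-category, 10-subtable design lands in a strong-but-
    imperfect regime (near-perfect training-set classification, held-out
    accuracy around one half) rather than a trivially separable one.
    intra_block_rho is the lag-1 autocorrelation of the within-block noise.
    """

    n_categories: int = 7
    n_blocks: int = 8                 # blocks per category
    scans_per_block: int = 16
    subtable_sizes: tuple = (28, 35, 41, 30, 47, 33, 39, 44, 31, 36)
    effect_size: float = 0.12
    effect_carriers: tuple | None = None   # subtable indices carrying signal; None = all
    intra_block_rho: float = 0.5
    noise_sd: float = 1.0
    counts_per_row: int = 200              # row total for the count generator
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")
        for name in ("n_blocks", "scans_per_block", "counts_per_row"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.subtable_sizes) < 1 or any(j < 1 for j in self.subtable_sizes):
            raise ValueError("every subtable needs >= 1 column")
        if not (0.0 <= self.intra_block_rho < 1.0):
            raise ValueError("intra_block_rho must be in [0, 1)")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be nonnegative")
        if self.effect_carriers is not None:
            k = len(self.subtable_sizes)
            if any(not (0 <= c < k) for c in self.effect_carriers):
                raise ValueError("effect_carriers must index subtables")

    @property
    def n_subtables(self) -> int:
        return len(self.subtable_sizes)

    @property
    def n_cols(self) -> int:
        return int(sum(self.subtable_sizes))

    @property
    def n_rows(self) -> int:
        return self.n_categories * self.n_blocks * self.scans_per_block


def _designs(spec: SimSpec):
    cats = np.array([f"cat{i + 1}" for i in range(spec.n_categories)])
    row_categories = np.repeat(cats, spec.n_blocks * spec.scans_per_block)
    blocks = np.concatenate([
        np.repeat([f"{c}_blk{b + 1}" for b in range(spec.n_blocks)], spec.scans_per_block)
        for c in cats
    ])
    col_subtables = np.concatenate([
        np.full(jk, f"sub{k + 1}") for k, jk in enumerate(spec.subtable_sizes)
    ])
    return cats, row_categories, blocks, col_subtables


def _carrier_mask(spec: SimSpec, col_subtables: np.ndarray) -> np.ndarray:
    if spec.effect_carriers is None:
        return np.ones(spec.n_cols, dtype=bool)
    mask = np.zeros(spec.n_cols, dtype=bool)
    for k in spec.effect_carriers:
        mask |= col_subtables == f"sub{k + 1}"
    return mask


def _ar1_noise(rng: np.random.Generator, n_steps: int, n_cols: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series per column: lag-1 autocorrelation rho,
    marginal standard deviation sd."""
    z = rng.standard_normal((n_steps, n_cols))
    out = np.empty_like(z)
    out[0] = z[0]
    scale = np.sqrt(1.0 - rho**2)
    for t in range(1, n_steps):
        out[t] = rho * out[t - 1] + scale * z[t]
    return sd * out


def generate(spec: SimSpec, rng: np.random.Generator | None = None):
    """Draw one dataset; returns (table, ground_truth).

    ground_truth holds the true category mean matrix (I x J, nonzero only on
    carrier columns), the category labels, and the carrier column mask, so
    recovery tests never re-derive them.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cats, row_categories, blocks, col_subtables = _designs(spec)
    mask = _carrier_mask(spec, col_subtables)

    means = np.zeros((spec.n_categories, spec.n_cols))
    if spec.effect_size > 0 and mask.any():
        means[:, mask] = spec.effect_size * rng.standard_normal(
            (spec.n_categories, int(mask.sum()))
        )

    X = np.empty((spec.n_rows, spec.n_cols))
    row = 0
    for i in range(spec.n_categories):
        for _ in range(spec.n_blocks):
            noise = _ar1_noise(rng, spec.scans_per_block, spec.n_cols,
                               spec.intra_block_rho, spec.noise_sd)
            X[row:row + spec.scans_per_block] = means[i] + noise
            row += spec.scans_per_block

    table = DiscriminantTable(
        data=X, row_categories=row_categories, col_subtables=col_subtables,
        row_blocks=blocks,
        row_ids=np.array([f"scan{r + 1}" for r in range(spec.n_rows)]),
        col_ids=np.array([f"v{j + 1}" for j in range(spec.n_cols)]),
    )
    truth = {"category_means": means, "categories": cats, "carrier_mask": mask}
    return table, truth


def generate_counts(spec: SimSpec, rng: np.random.Generator | None = None):
    """Multinomial count rows with category-specific probability profiles
    (for the DICA / Hellinger variants); returns (table, ground_truth).

    Profiles are softmax perturbations of a shared baseline, with the
    perturbation scale set by effect_size and confined to carrier columns;
    effect_size = 0 gives identical profiles across categories.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cats, row_categories, blocks, col_subtables = _designs(spec)
    mask = _carrier_mask(spec, col_subtables)

    base = rng.standard_normal(spec.n_cols)
    logits = np.tile(base, (spec.n_categories, 1))
    if spec.effect_size > 0 and mask.any():
        logits[:, mask] += spec.effect_size * rng.standard_normal(
            (spec.n_categories, int(mask.sum()))
        )
    profiles = np.exp(logits - logits.max(axis=1, keepdims=True))
    profiles /= profiles.sum(axis=1, keepdims=True)

    X = np.empty((spec.n_rows, spec.n_cols))
    for r in range(spec.n_rows):
        i = r // (spec.n_blocks * spec.scans_per_block)
        X[r] = rng.multinomial(spec.counts_per_row, profiles[i])

    table = DiscriminantTable(
        data=X, row_categories=row_categories, col_subtables=col_subtables,
        row_blocks=blocks,
        row_ids=np.array([f"row{r + 1}" for r in range(spec.n_rows)]),
        col_ids=np.array([f"v{j + 1}" for j in range(spec.n_cols)]),
    )
    truth = {"profiles": profiles, "categories": cats, "carrier_mask": mask}
    return table, truth
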