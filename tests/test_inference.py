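"""Inertia decomposition, permutation test, cross-validation, bootstrap,
ellipses and multiplicity corrections."""

import numpy as np
import pytest

from musubada import (
    AnalysisConfig,
    DiscriminantTable,
    SimSpec,
    bootstrap_barycenters,
    classify,
    confidence_ellipses,
    corrected_level,
    crossvalidate,
    ellipses_overlap,
    fit,
    fit_ellipse,
    generate,
    inertia_decomposition,
    permutation_test,
    project_leftout_into_full,
    project_rows,
    separation_flags,
)


# ------------------------------------------------------------------ inertia
def _one_dim_table():
    # scores -3,-1 | 1,3 around barycenters -2, 2 in a single variable with
    # unit column weight: within = 1, between = 4, total = 5
    return DiscriminantTable(
        data=np.array([[-3.0], [-1.0], [1.0], [3.0]]),
        row_categories=np.array(["A", "A", "B", "B"]),
        col_subtables=np.array(["s1"]),
        col_weights=np.array([1.0]),
    )


def test_inertia_hand_case():
    model = fit(_one_dim_table(), AnalysisConfig())
    dec = inertia_decomposition(model)
    assert abs(dec.within - 1.0) < 1e-10
    assert abs(dec.between - 4.0) < 1e-10
    assert abs(dec.total - 5.0) < 1e-10
    assert abs(dec.r_squared - 0.8) < 1e-12


def test_inertia_degenerate_cases(small_table, centered_config):
    # observations equal to their barycenter -> within = 0, R2 = 1
    R_rows = np.repeat(np.arange(6.0).reshape(3, 2), 4, axis=0)
    t = DiscriminantTable(data=R_rows, row_categories=np.repeat(["A", "B", "C"], 4),
                          col_subtables=np.array(["s1", "s1"]))
    dec = inertia_decomposition(fit(t, AnalysisConfig()))
    assert dec.within < 1e-20 and abs(dec.r_squared - 1.0) < 1e-12
    # all barycenters equal -> between = 0, R2 = 0
    rng = np.random.default_rng(1)
    noise = rng.standard_normal((4, 2))
    t2 = DiscriminantTable(data=np.vstack([noise, noise]),
                           row_categories=np.repeat(["A", "B"], 4),
                           col_subtables=np.array(["s1", "s1"]))
    dec2 = inertia_decomposition(fit(t2, AnalysisConfig()))
    assert abs(dec2.r_squared) < 1e-12


def test_inertia_additivity_all_variants(small_table, count_table):
    for table, cfg in [
        (small_table, AnalysisConfig(preprocess=["center"])),
        (small_table, AnalysisConfig(preprocess=["center", "mfa", "row_ss"])),
        (count_table, AnalysisConfig(variant="dica")),
        (count_table, AnalysisConfig(variant="hellinger")),
    ]:
        dec = inertia_decomposition(fit(table, cfg))
        assert abs(dec.total - dec.within - dec.between) <= 1e-8 * max(dec.total, 1e-30)


# -------------------------------------------------------------- permutation
def test_permutation_saturated_statistic():
    spec = SimSpec(n_categories=3, n_blocks=4, scans_per_block=4,
                   subtable_sizes=(6, 4), effect_size=5.0,
                   intra_block_rho=0.0, seed=2)
    table, _ = generate(spec)
    cfg = AnalysisConfig(preprocess=["center"], n_permutations=99, seed=4)
    res = permutation_test(table, cfg)
    assert res.p_value == 1.0 / (99 + 1)
    assert res.exchangeable_unit == "block"


def test_permutation_degenerate_identical_rows():
    t = DiscriminantTable(data=np.ones((8, 3)),
                          row_categories=np.repeat(["A", "B"], 4),
                          col_subtables=np.array(["s1"] * 3))
    res = permutation_test(t, AnalysisConfig(n_permutations=99))
    assert res.observed_r2 == 0.0 and res.p_value == 1.0


def test_permutation_requires_enough_units():
    t = DiscriminantTable(data=np.arange(8.0).reshape(4, 2),
                          row_categories=np.array(["A", "A", "B", "B"]),
                          col_subtables=np.array(["s1", "s1"]),
                          row_blocks=np.array(["b1", "b1", "b2", "b2"]))
    # 2 blocks for 2 categories is allowed; mixed-category block is not
    t_bad = DiscriminantTable(data=t.data, row_categories=t.row_categories,
                              col_subtables=t.col_subtables,
                              row_blocks=np.array(["b1", "b2", "b2", "b1"]))
    with pytest.raises(ValueError, match="spans"):
        permutation_test(t_bad, AnalysisConfig(n_permutations=99))


# ---------------------------------------------------------- cross-validation
def test_loo_on_duplicated_rows_matches_fixed():
    """With every row duplicated, leaving one copy out barely perturbs the
    solution: random-effect accuracy equals fixed-effect accuracy."""
    rng = np.random.default_rng(3)
    base = rng.standard_normal((8, 4)) + np.repeat([[2.0], [-2.0]], 4, axis=0)
    X = np.repeat(base, 2, axis=0)
    t = DiscriminantTable(data=X, row_categories=np.repeat(["A", "B"], 8),
                          col_subtables=np.array(["s1"] * 4))
    cfg = AnalysisConfig(preprocess=["center"], cv_mode="leave-one-out")
    model = fit(t, cfg)
    fixed = classify(model, t).accuracy
    cv = crossvalidate(t, cfg, full_model=model)
    assert cv.report.accuracy == fixed


def test_cv_error_when_fold_empties_category():
    t = DiscriminantTable(data=np.arange(12.0).reshape(6, 2),
                          row_categories=np.array(["A"] * 4 + ["B"] * 2),
                          col_subtables=np.array(["s1", "s1"]),
                          row_blocks=np.array(["b1", "b1", "b2", "b2", "b3", "b3"]))
    with pytest.raises(ValueError, match="empties category 'B'"):
        crossvalidate(t, AnalysisConfig(cv_mode="leave-one-block-out"))


def test_hhat_equals_h_when_spans_coincide():
    """When the fold factor space spans the whole variable space (3 centered
    barycenters in 2 variables), the reconstruction loses nothing and the
    reconstruction-based projection returns the direct projection."""
    rng = np.random.default_rng(8)
    X = rng.standard_normal((12, 2)) + np.repeat([[3.0, 0.0], [0.0, 3.0], [-3.0, -3.0]],
                                                 4, axis=0)
    t = DiscriminantTable(data=X, row_categories=np.repeat(["A", "B", "C"], 4),
                          col_subtables=np.array(["s1", "s1"]))
    cfg = AnalysisConfig(cv_mode="leave-one-out")
    model = fit(t, cfg)
    assert model.gsvd.rank == 2  # full variable space
    cv = crossvalidate(t, cfg, full_model=model)
    np.testing.assert_allclose(cv.hhat, model.H, atol=1e-9)


def test_reconstruction_projection_fixed_point(small_table, centered_config):
    model = fit(small_table, centered_config)
    h = project_leftout_into_full(model, model, small_table.data[:3])
    np.testing.assert_allclose(h, model.H[:3], atol=1e-9)


def test_cv_preprocessing_is_leak_free(small_table):
    """Corrupting the held-out block leaves the fold's model untouched."""
    cfg = AnalysisConfig(preprocess=["center", "mfa"], cv_mode="leave-one-block-out")
    blocks = small_table.blocks
    test_idx = np.flatnonzero(small_table.row_blocks == blocks[0])
    train_idx = np.setdiff1d(np.arange(small_table.n_rows), test_idx)
    m1 = fit(small_table.subset_rows(train_idx), cfg)
    corrupted = small_table.data.copy()
    corrupted[test_idx] *= 1e6
    t2 = DiscriminantTable(data=corrupted, row_categories=small_table.row_categories,
                           col_subtables=small_table.col_subtables,
                           row_blocks=small_table.row_blocks)
    m2 = fit(t2.subset_rows(train_idx), cfg)
    np.testing.assert_array_equal(m1.gsvd.Q, m2.gsvd.Q)
    np.testing.assert_array_equal(m1.preprocessor.params.column_means,
                                  m2.preprocessor.params.column_means)


# ------------------------------------------------------------------ bootstrap
def test_bootstrap_zero_variance_replicates_F():
    R_rows = np.repeat(np.arange(6.0).reshape(3, 2), 5, axis=0)
    t = DiscriminantTable(data=R_rows, row_categories=np.repeat(["A", "B", "C"], 5),
                          col_subtables=np.array(["s1", "s1"]))
    model = fit(t, AnalysisConfig(n_bootstrap=50, seed=0))
    boot = bootstrap_barycenters(model)
    for b in range(boot.shape[0]):
        np.testing.assert_allclose(boot[b], model.F, atol=1e-12)


def test_bootstrap_mean_near_F(small_table, centered_config):
    model = fit(small_table, centered_config)
    boot = bootstrap_barycenters(model, n_bootstrap=400,
                                 rng=np.random.default_rng(12))
    mean = boot.mean(axis=0)
    se = boot.std(axis=0) / np.sqrt(boot.shape[0])
    assert np.all(np.abs(mean - model.F) <= 3 * se + 1e-12)


def test_bootstrap_deterministic_given_seed(small_table, centered_config):
    model = fit(small_table, centered_config)
    b1 = bootstrap_barycenters(model, n_bootstrap=20, rng=np.random.default_rng(5))
    b2 = bootstrap_barycenters(model, n_bootstrap=20, rng=np.random.default_rng(5))
    np.testing.assert_array_equal(b1, b2)


# -------------------------------------------------------------------- ellipses
def test_ellipse_on_circle():
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    pts = np.c_[np.cos(theta), np.sin(theta)]
    e = fit_ellipse(pts, level=1.0)
    np.testing.assert_allclose(e.center, [0, 0], atol=1e-12)
    # all points on the boundary
    np.testing.assert_allclose(e.mahalanobis2(pts), e.radius2, rtol=1e-9)


def test_ellipse_quantile_exact_count():
    rng = np.random.default_rng(31)
    pts = rng.standard_normal((100, 2))
    e = fit_ellipse(pts, level=0.95)
    assert int(e.contains(pts).sum()) == 95


def test_ellipse_collinear_degenerate_flag():
    pts = np.c_[np.arange(10.0), 2.0 * np.arange(10.0)]
    e = fit_ellipse(pts, level=0.9)
    assert e.degenerate


def test_prediction_ellipse_keeps_cloud_mean():
    rng = np.random.default_rng(7)
    pts = rng.standard_normal((50, 2)) + [3.0, -1.0]
    e = fit_ellipse(pts, level=0.95, kind="prediction")
    np.testing.assert_allclose(e.center, pts.mean(axis=0))
    assert e.kind == "prediction"


def test_overlap_and_separation_flags():
    rng = np.random.default_rng(9)
    a = fit_ellipse(rng.standard_normal((60, 2)) * 0.3, level=0.95)
    b = fit_ellipse(rng.standard_normal((60, 2)) * 0.3 + [10.0, 0.0], level=0.95)
    c = fit_ellipse(rng.standard_normal((60, 2)) * 0.3 + [0.2, 0.0], level=0.95)
    assert not ellipses_overlap(a, b)
    assert ellipses_overlap(a, c)

    import musubada.inference as inf
    es = inf.EllipseSet(ellipses={"A": a, "B": b, "C": c}, kind="confidence",
                        level=0.95, corrected=0.95, dims=(0, 1))
    flags = separation_flags([es], np.array(["A", "B", "C"]))
    assert flags[("A", "B")] == "separated"
    assert "inconclusive" in flags[("A", "C")]


def test_confidence_ellipses_apply_correction(small_table, centered_config):
    model = fit(small_table, centered_config)
    boot = bootstrap_barycenters(model, n_bootstrap=100,
                                 rng=np.random.default_rng(2))
    es = confidence_ellipses(boot, model.categories, alpha=0.05,
                             correction="bonferroni")
    I = len(model.categories)
    assert abs(es.corrected - (1 - 2 * 0.05 / (I * (I - 1)))) < 1e-12


# --------------------------------------------------------------- corrections
def test_corrected_level_reduces_to_single_comparison():
    assert abs(corrected_level(0.05, 2, "bonferroni") - 0.95) < 1e-12
    assert abs(corrected_level(0.05, 2, "sidak") - 0.95) < 1e-12
    assert abs(corrected_level(0.05, 2, "none") - 0.95) < 1e-12


def test_corrected_level_seven_categories():
    assert abs(corrected_level(0.05, 7, "bonferroni") - (1 - 0.1 / 42)) < 1e-12
    m = 7 * 6 / 2
    assert abs(corrected_level(0.05, 7, "sidak") - 0.95 ** (1 / m)) < 1e-12


def test_corrected_level_validation():
    with pytest.raises(ValueError):
        corrected_level(1.5, 3)
    with pytest.raises(ValueError):
        corrected_level(0.05, 1)
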