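"""Barycenters, factor scores, projections, classification, loadings."""

import numpy as np
import pytest

from musubada import (
    AnalysisConfig,
    DiscriminantTable,
    SimSpec,
    classify,
    compute_barycenters,
    crossvalidate,
    fit,
    generate,
    loadings,
    project_rows,
    score_distances,
)


def test_barycenters_equal_masses():
    X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    R = compute_barycenters(X, np.full(3, 1 / 3), np.array(["A", "A", "B"]),
                            np.array(["A", "B"]))
    np.testing.assert_allclose(R, [[2.0, 3.0], [5.0, 6.0]])


def test_barycenters_weighted():
    X = np.array([[4.0, 0.0], [0.0, 4.0], [8.0, 8.0]])
    R = compute_barycenters(X, np.array([0.5, 0.25, 0.25]),
                            np.array(["A", "A", "A"]), np.array(["A"]))
    np.testing.assert_allclose(R, [[4.0, 3.0]])


def test_barycenters_identical_rows():
    v = np.array([2.0, -1.0, 0.5])
    X = np.tile(v, (6, 1))
    R = compute_barycenters(X, np.full(6, 1 / 6),
                            np.repeat(["A", "B"], 3), np.array(["A", "B"]))
    np.testing.assert_allclose(R, np.tile(v, (2, 1)))


def test_rank_bounds(small_table, centered_config):
    model = fit(small_table, centered_config)
    I, J = small_table.n_categories, small_table.n_cols
    assert model.gsvd.rank <= min(I - 1, J)  # centered barycenters


def test_two_separated_categories_give_one_dimension():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.standard_normal((10, 2)) + [5, 0],
                   rng.standard_normal((10, 2)) - [5, 0]])
    t = DiscriminantTable(data=X, row_categories=np.repeat(["A", "B"], 10),
                          col_subtables=np.array(["s1", "s1"]))
    model = fit(t, AnalysisConfig(preprocess=["center"]))
    assert model.gsvd.rank == 1


def test_fit_deterministic(small_table, centered_config):
    m1 = fit(small_table, centered_config)
    m2 = fit(small_table, centered_config)
    np.testing.assert_array_equal(m1.F, m2.F)
    np.testing.assert_array_equal(m1.gsvd.Q, m2.gsvd.Q)


def test_projection_of_barycenters_recovers_F(small_table, centered_config):
    model = fit(small_table, centered_config)
    H = project_rows(model, model.R, preprocessed=True)
    np.testing.assert_allclose(H, model.F, atol=1e-10)


@pytest.mark.parametrize("variant,steps", [
    ("plain", []),
    ("plain", ["center"]),
    ("plain", ["center", "mfa", "row_ss"]),
    ("plain", ["zscore"]),
])
def test_barycentric_property_plain_variants(small_table, variant, steps):
    """Mass-weighted category means of the projected observations equal the
    category factor scores, whatever the preprocessing."""
    model = fit(small_table, AnalysisConfig(variant=variant, preprocess=steps))
    Hbar = compute_barycenters(model.H, model.masses,
                               small_table.row_categories, small_table.categories)
    np.testing.assert_allclose(Hbar, model.F, atol=1e-10)


def test_barycentric_property_count_variants(count_table):
    for variant in ("dica", "hellinger"):
        model = fit(count_table, AnalysisConfig(variant=variant))
        Hbar = compute_barycenters(model.H, model.masses,
                                   count_table.row_categories, count_table.categories)
        np.testing.assert_allclose(Hbar, model.F, atol=1e-10)


def test_variance_identity(small_table, centered_config):
    """Per-dimension B-weighted variance of F equals the eigenvalue."""
    model = fit(small_table, centered_config)
    np.testing.assert_allclose(model.F.T @ (model.b[:, None] * model.F),
                               np.diag(model.eigenvalues), atol=1e-10)


def test_supplementary_row_equal_to_barycenter(small_table, centered_config):
    model = fit(small_table, centered_config)
    h = project_rows(model, model.R[1][None], preprocessed=True)
    np.testing.assert_allclose(h[0], model.F[1], atol=1e-10)


def test_score_distances_hand_case():
    F = np.array([[0.0, 0.0], [2.0, 0.0]])
    h = np.array([[0.9, 5.0]])
    D = score_distances(h, F)
    np.testing.assert_allclose(D, [[25.81, 26.21]])
    assert np.argmin(D) == 0


def test_classifying_barycenters_is_perfect(small_table, centered_config):
    model = fit(small_table, centered_config)
    rep = classify(model, model.R, preprocessed=True)
    np.testing.assert_array_equal(rep.assigned, model.categories)


def test_fixed_effect_confusion_convention(small_table, centered_config):
    model = fit(small_table, centered_config)
    rep = classify(model, small_table)
    # columns = actual categories: column sums are the category sizes
    col_sums = rep.confusion.sum(axis=0).to_numpy()
    sizes = [np.sum(small_table.row_categories == c) for c in small_table.categories]
    np.testing.assert_array_equal(col_sums, sizes)
    assert rep.accuracy == np.trace(rep.confusion.to_numpy()) / small_table.n_rows


def test_equidistant_tie_goes_to_lowest_index():
    X = np.array([[-1.0], [1.0], [0.0]])
    t = DiscriminantTable(data=np.vstack([X[:2], X[:2]]),
                          row_categories=np.array(["A", "B", "A", "B"]),
                          col_subtables=np.array(["s1"]))
    model = fit(t, AnalysisConfig())
    rep = classify(model, np.array([[0.0]]))
    assert rep.assigned[0] == "A" and rep.n_ties == 1


def test_zero_effect_accuracy_near_chance():
    spec = SimSpec(n_categories=4, n_blocks=3, scans_per_block=8,
                   subtable_sizes=(6, 6), effect_size=0.0,
                   intra_block_rho=0.0, seed=21)
    table, _ = generate(spec)
    model = fit(table, AnalysisConfig(preprocess=["center"]))
    rep = classify(model, table)
    # fixed-effect accuracy overfits above 1/I but stays far from 1
    n, p = table.n_rows, 1 / 4
    assert rep.accuracy < 0.75


def test_fixed_accuracy_beats_random_accuracy_majority():
    """Training-set accuracy >= held-out accuracy in most replicates."""
    wins = 0
    n_reps = 20
    for s in range(n_reps):
        spec = SimSpec(n_categories=3, n_blocks=3, scans_per_block=4,
                       subtable_sizes=(5, 4), effect_size=0.6,
                       intra_block_rho=0.3, seed=300 + s)
        table, _ = generate(spec)
        cfg = AnalysisConfig(preprocess=["center"], cv_mode="leave-one-block-out")
        model = fit(table, cfg)
        fixed = classify(model, table).accuracy
        random_ = crossvalidate(table, cfg, full_model=model).report.accuracy
        wins += fixed >= random_
    assert wins > n_reps / 2


def test_dica_no_effect_on_flat_table():
    t = DiscriminantTable(data=np.array([[10.0, 10.0], [10.0, 10.0]]),
                          row_categories=np.array(["A", "B"]),
                          col_subtables=np.array(["s1", "s1"]))
    model = fit(t, AnalysisConfig(variant="dica"))
    assert model.gsvd.rank == 0  # identical profiles: nothing beyond the centroid


def test_classical_variant_whitens_within_covariance():
    rng = np.random.default_rng(6)
    X = np.vstack([rng.multivariate_normal([0, 0], [[4.0, 1.5], [1.5, 1.0]], 40),
                   rng.multivariate_normal([4, 2], [[4.0, 1.5], [1.5, 1.0]], 40)])
    t = DiscriminantTable(data=X, row_categories=np.repeat(["A", "B"], 40),
                          col_subtables=np.array(["s1", "s1"]))
    model = fit(t, AnalysisConfig(variant="classical"))
    assert model.w.ndim == 2 and model.condition_number is not None
    rep = classify(model, t)
    assert rep.accuracy > 0.8


def test_loadings_kinds(small_table, centered_config):
    model = fit(small_table, centered_config)
    Q = loadings(model, "Q")
    G = loadings(model, "G")
    np.testing.assert_allclose(G, Q * model.gsvd.delta, atol=1e-12)
    C = loadings(model, "correlation")
    assert np.all(np.abs(C) <= 1.0 + 1e-10)


def test_loading_magnitude_tracks_separation():
    """The variable with the larger barycenter separation carries the
    larger dimension-1 loading in a 2-variable, 2-category toy."""
    X = np.array([[5.0, 0.1], [5.2, -0.1], [-5.0, 0.1], [-5.2, -0.1]])
    t = DiscriminantTable(data=X, row_categories=np.array(["A", "A", "B", "B"]),
                          col_subtables=np.array(["s1", "s1"]))
    model = fit(t, AnalysisConfig(preprocess=["center"]))
    G = loadings(model, "G")
    assert abs(G[0, 0]) > abs(G[1, 0])


def test_truncated_components(small_table):
    model = fit(small_table, AnalysisConfig(preprocess=["center"], n_components=1))
    assert model.F.shape[1] == 1 and model.gsvd.rank == 1
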