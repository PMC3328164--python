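import numpy as np
import pytest

from musubada import AnalysisConfig, DiscriminantTable, SimSpec, generate


@pytest.fixture
def tiny_table():
    """3 observations, 2 variables, 2 categories, 1 subtable."""
    return DiscriminantTable(
        data=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        row_categories=np.array(["A", "A", "B"]),
        col_subtables=np.array(["s1", "s1"]),
    )


@pytest.fixture
def small_table():
    """Seeded 3-category block-design table with 2 unequal subtables."""
    spec = SimSpec(
        n_categories=3, n_blocks=4, scans_per_block=4,
        subtable_sizes=(7, 5), effect_size=1.2, intra_block_rho=0.3, seed=11,
    )
    table, _ = generate(spec)
    return table


@pytest.fixture
def three_subtable_table():
    spec = SimSpec(
        n_categories=3, n_blocks=3, scans_per_block=4,
        subtable_sizes=(6, 4, 5), effect_size=1.0, intra_block_rho=0.2, seed=23,
    )
    table, _ = generate(spec)
    return table


@pytest.fixture
def count_table():
    """Nonnegative integer table for the DICA / Hellinger variants."""
    rng = np.random.default_rng(5)
    X = rng.poisson(8.0, size=(20, 6)).astype(float) + 1.0
    return DiscriminantTable(
        data=X,
        row_categories=np.repeat(["A", "B", "C", "D"], 5),
        col_subtables=np.array(["s1"] * 4 + ["s2"] * 2),
    )


@pytest.fixture
def centered_config():
    return AnalysisConfig(preprocess=["center"])
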