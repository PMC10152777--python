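import warnings

import numpy as np
import pytest

from scea import SyntheticSpec, generate_counts, preprocess

warnings.filterwarnings("ignore", message="encoder layer dims")
warnings.filterwarnings("ignore", message="input has .* genes")


@pytest.fixture(scope="session")
def small_counts():
    """80 cells x 250 genes, 3 well-separated clusters, with truth labels."""
    spec = SyntheticSpec(n_cells=80, n_genes=250, n_clusters=3,
                         log_fold_change=3.0, dropout_rate=0.3, seed=11)
    return generate_counts(spec)


@pytest.fixture(scope="session")
def small_normalized(small_counts):
    """QC-filtered and log-normalized version of the small dataset."""
    X, labels = small_counts
    Xp, report = preprocess(X)
    pos = {c: i for i, c in enumerate(X.cell_ids)}
    kept = np.array([pos[c] for c in Xp.cell_ids])
    return Xp, labels[kept], report


@pytest.fixture(scope="session")
def two_block_similarity():
    """40x40 symmetric nonnegative two-community matrix with cross noise."""
    rng = np.random.default_rng(5)
    n, half = 40, 20
    S = rng.uniform(0.0, 0.1, size=(n, n))
    S[:half, :half] += rng.uniform(0.5, 0.9, size=(half, half))
    S[half:, half:] += rng.uniform(0.5, 0.9, size=(half, half))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    return S
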