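import numpy as np
import pandas as pd
import pytest

from chronospace import simulate_posterior_set, simulate_tree
from chronospace.trees import ChronospaceMatrix


@pytest.fixture
def three_taxon_file(tmp_path):
    p = tmp_path / "one.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    return p


@pytest.fixture(scope="session")
def small_tree():
    return simulate_tree(12, root_age=300.0, seed=11)


@pytest.fixture(scope="session")
def small_set(small_tree):
    return simulate_posterior_set(small_tree, {"clock": "a"}, n_samples=40, seed=7)


def make_matrix(X, labels, factor="g", run=None):
    """Wrap a raw array + labels into a ChronospaceMatrix with dummy keys."""
    X = np.asarray(X, dtype=float)
    keys = tuple(
        frozenset({f"t{j}", f"u{j}"} | ({"z"} if j == X.shape[1] - 1 else set()))
        for j in range(X.shape[1])
    )
    meta = pd.DataFrame({factor: list(labels)})
    if run is not None:
        meta["run_id"] = list(run)
    return ChronospaceMatrix(X, keys, meta)


def random_matrix(rng, n=None, p=None, g=None):
    """A random age matrix with balanced-ish random level labels."""
    n = n or int(rng.integers(6, 51))
    p = p or int(rng.integers(2, 11))
    g = g or int(rng.integers(2, 5))
    X = rng.normal(100.0, 15.0, size=(n, p))
    while True:
        labels = [f"L{rng.integers(g)}" for _ in range(n)]
        counts = pd.Series(labels).value_counts()
        if len(counts) >= 2 and counts.min() >= 2:
            return X, labels
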