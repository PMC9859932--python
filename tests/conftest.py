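import numpy as np
import pandas as pd
import pytest

from eigencascade import Cascade, CascadeSet, ExpressionMatrix, cascades_from_dependency


def edge_f1(estimated: CascadeSet, truth: CascadeSet) -> float:
    """F1 of unoriented edge recovery; 1.0 when both edge sets are empty."""
    est = {frozenset(c.members) for c in estimated.edges()}
    tru = {frozenset(c.members) for c in truth.edges()}
    if not est and not tru:
        return 1.0
    tp = len(est & tru)
    if tp == 0:
        return 0.0
    precision = tp / len(est)
    recall = tp / len(tru)
    return 2 * precision * recall / (precision + recall)


def random_possessed_set(rng: np.random.Generator, max_genes: int = 8) -> CascadeSet:
    """A complete possessed-cascade set from a random dependency oracle."""
    n = int(rng.integers(1, max_genes + 1))
    genes = [f"g{i}" for i in range(n)]
    dep_table = {
        (x, y): bool(rng.random() < 0.4) for x in genes for y in genes if x != y
    }
    return cascades_from_dependency(lambda x, y: dep_table[(x, y)], genes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix(rng):
    """A 200-cell, 5-gene matrix with two correlated genes (a drives b)."""
    a = rng.normal(size=200)
    values = pd.DataFrame(
        {
            "a": a,
            "b": a + 0.5 * rng.normal(size=200),
            "c": rng.normal(size=200),
            "d": rng.normal(size=200),
            "e": rng.normal(size=200),
        },
        index=[f"cell{i}" for i in range(200)],
    )
    return ExpressionMatrix(values)
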