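"""Ground-truth GRNs and synthetic expression data.

The generator realizes the causal picture behind the method: each cell
class has a directed acyclic graph over the gene universe, every gene also
receives an independent exogenous noise term (the environment element), and
expression is drawn from the corresponding linear-Gaussian structural
model.  A logistic/binary mode mirrors the chi-square test path, and a
block-loading factor generator supports the FA/clustering stages.

Because the DAG, the weights and the seed are stored, every stage of the
pipeline — CI tests, skeleton recovery, eigen-cascades, d*, labeling and
estimation — can be scored against a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cascades import Cascade, CascadeSet
from .io import ExpressionMatrix

__all__ = [
    "GroundTruth",
    "random_dag",
    "sample_cells",
    "sample_cells_binary",
    "make_dataset",
    "perturb_grn",
    "make_factor_blocks",
]


@dataclass(frozen=True)
class GroundTruth:
    """A weighted DAG with noise level: one cell class's generating model."""

    genes: tuple                 # sorted gene symbols
    order: tuple                 # topological order
    edges: dict                  # (parent, child) -> weight
    noise_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(sorted(self.genes)))
        object.__setattr__(self, "order", tuple(self.order))
        object.__setattr__(self, "edges", dict(self.edges))
        if set(self.order) != set(self.genes):
            raise ValueError("topological order must cover exactly the genes")
        pos = {g: i for i, g in enumerate(self.order)}
        for (u, v) in self.edges:
            if pos[u] >= pos[v]:
                raise ValueError(f"edge {u}->{v} violates the topological order")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def cascade_set(self) -> CascadeSet:
        """Oriented possessed cascades: child depends on parent per edge."""
        cascades = [Cascade.singleton(g) for g in self.genes]
        cascades += [Cascade.pair(child, parent) for parent, child in self.edges]
        return CascadeSet(frozenset(self.genes), cascades, oriented=True)

    def skeleton(self) -> CascadeSet:
        """True unoriented skeleton (singletons plus undirected edges)."""
        return self.cascade_set().to_undirected()

    def weight_matrix(self) -> pd.DataFrame:
        w = pd.DataFrame(0.0, index=self.genes, columns=self.genes)
        for (u, v), wt in self.edges.items():
            w.loc[u, v] = wt
        return w

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "order": list(self.order),
            "edges": [[u, v, w] for (u, v), w in sorted(self.edges.items())],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            tuple(d["genes"]),
            tuple(d["order"]),
            {(u, v): w for u, v, w in d["edges"]},
            d.get("noise_sd", 1.0),
            d.get("seed"),
        )


def _gene_names(n: int) -> list:
    width = max(2, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def random_dag(
    n_genes: int,
    edge_prob: float,
    weight_range=(0.5, 1.5),
    seed: int = 0,
    noise_sd: float = 1.0,
    genes=None,
) -> GroundTruth:
    """Erdős–Rényi DAG over a random topological order.

    Each forward pair (in a uniformly random order) receives an edge with
    probability *edge_prob*; weights are uniform in ±[lo, hi] with random
    sign, so effects are bounded away from zero.
    """
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    genes = sorted(genes) if genes is not None else _gene_names(n_genes)
    if len(genes) != n_genes:
        raise ValueError("genes must match n_genes")
    rng = np.random.default_rng(seed)
    order = [genes[i] for i in rng.permutation(n_genes)]
    lo, hi = weight_range
    edges = {}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_prob:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                edges[(order[i], order[j])] = float(sign * rng.uniform(lo, hi))
    return GroundTruth(tuple(genes), tuple(order), edges, noise_sd, seed)


def sample_cells(
    gt: GroundTruth, n_cells: int, seed: int = 0, class_id: str = "c0"
) -> ExpressionMatrix:
    """Draw cells from the linear-Gaussian structural model of *gt*.

    In topological order, each gene is the weighted sum of its parents plus
    an independent Gaussian exogenous term with SD ``gt.noise_sd``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for g in gt.order:
        x = rng.normal(0.0, gt.noise_sd, size=n_cells)
        for (u, v), w in gt.edges.items():
            if v == g:
                x = x + w * cols[u]
        cols[g] = x
    values = pd.DataFrame(
        {g: cols[g] for g in gt.genes},
        index=[f"{class_id}_{i}" for i in range(n_cells)],
    )
    labels = pd.Series(class_id, index=values.index)
    return ExpressionMatrix(values, class_labels=labels)


def sample_cells_binary(
    gt: GroundTruth,
    n_cells: int,
    flip_prob: float = 0.1,
    seed: int = 0,
    class_id: str = "c0",
) -> ExpressionMatrix:
    """Binary analogue for the chi-square test path.

    Root genes are fair coins; every other gene copies the parity (XOR) of
    its parents and flips with probability *flip_prob*.
    """
    if not 0.0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    cols = {}
    for g in gt.order:
        parents = [u for (u, v) in gt.edges if v == g]
        if not parents:
            x = rng.integers(0, 2, size=n_cells)
        else:
            x = np.zeros(n_cells, dtype=int)
            for u in parents:
                x ^= cols[u]
            flips = rng.random(n_cells) < flip_prob
            x = np.where(flips, 1 - x, x)
        cols[g] = x
    values = pd.DataFrame(
        {g: cols[g].astype(float) for g in gt.genes},
        index=[f"{class_id}_{i}" for i in range(n_cells)],
    )
    labels = pd.Series(class_id, index=values.index)
    return ExpressionMatrix(values, class_labels=labels)


def make_dataset(class_specs, seed: int = 0, binary: bool = False) -> tuple:
    """Concatenate per-class samples into one shuffled labeled dataset.

    *class_specs* is a list of ``(class_id, GroundTruth, n_cells)``.  All
    classes must share one gene universe.  Returns ``(matrix, truth)``
    where *truth* maps class id to its GroundTruth.
    """
    ids = [cid for cid, _, _ in class_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate class ids")
    universes = {gt.genes for _, gt, _ in class_specs}
    if len(universes) != 1:
        raise ValueError("all classes must share one gene universe")
    seeds = np.random.SeedSequence(seed).spawn(len(class_specs) + 1)
    sampler = sample_cells_binary if binary else sample_cells
    parts = [
        sampler(gt, n, seed=int(s.generate_state(1)[0] % (2**31)), class_id=cid)
        for (cid, gt, n), s in zip(class_specs, seeds[:-1])
    ]
    values = pd.concat([p.values for p in parts])
    labels = pd.concat([p.class_labels for p in parts])
    rng = np.random.default_rng(seeds[-1].generate_state(1)[0] % (2**31))
    perm = rng.permutation(len(values))
    values, labels = values.iloc[perm], labels.iloc[perm]
    truth = {cid: gt for cid, gt, _ in class_specs}
    return ExpressionMatrix(values, class_labels=labels), truth


def perturb_grn(gt: GroundTruth, n_edits: int, seed: int = 0) -> GroundTruth:
    """Apply *n_edits* single-edge additions/deletions, never reusing a pair.

    Each edit flips the presence of one forward pair (w.r.t. the original
    topological order, so acyclicity is preserved by construction).  A pair
    is edited at most once, so no edit cancels another and the skeleton's
    Hamming distance from the original is exactly *n_edits* (counted on
    unoriented edges).
    """
    if n_edits < 0:
        raise ValueError("n_edits must be non-negative")
    rng = np.random.default_rng(seed)
    forward = [
        (u, v)
        for i, u in enumerate(gt.order)
        for v in gt.order[i + 1:]
    ]
    if n_edits > len(forward):
        raise ValueError(
            f"cannot make {n_edits} independent edits on {len(forward)} pairs"
        )
    edges = dict(gt.edges)
    available = sorted(forward)
    chosen = rng.choice(len(available), size=n_edits, replace=False)
    for idx in chosen:
        u, v = available[idx]
        if (u, v) in edges:
            del edges[(u, v)]
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            edges[(u, v)] = float(sign * rng.uniform(0.5, 1.5))
    return replace(gt, edges=edges, seed=None)


def make_factor_blocks(
    n_blocks: int = 2,
    block_size: int = 10,
    loading: float = 0.8,
    n_cells: int = 500,
    n_noise: int = 0,
    seed: int = 0,
) -> tuple:
    """Block-loading factor-structure data for FA and clustering tests.

    Each block of genes loads *loading* on its own latent factor and 0 on
    the rest; unique variance tops variables up to unit total variance.
    Pure-noise genes (if any) are appended with symbols ``noise##``.
    Returns ``(matrix, block_assignment)`` where the assignment maps each
    block gene to its factor index.
    """
    if not 0.0 < loading < 1.0:
        raise ValueError("loading must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_cells, n_blocks))
    unique_sd = np.sqrt(1.0 - loading**2)
    cols, assignment = {}, {}
    for b in range(n_blocks):
        for j in range(block_size):
            name = f"b{b}_{j:02d}"
            cols[name] = loading * factors[:, b] + rng.normal(
                0.0, unique_sd, size=n_cells
            )
            assignment[name] = b
    for j in range(n_noise):
        cols[f"noise{j:02d}"] = rng.normal(size=n_cells)
    values = pd.DataFrame(cols, index=[f"cell{i}" for i in range(n_cells)])
    return ExpressionMatrix(values), assignment
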