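"""End-to-end validation studies on synthetic data.

Each function here sets up a known ground truth with the synthetic
generator, runs one stage of the pipeline against it, and returns a
summary number (a violation count, a calibration rate, a recovery score).
They are the package's self-checks: the test suite asserts on their
outputs and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .cascades import (
    Cascade,
    CascadeSet,
    RestrictionSpec,
    cascades_from_dependency,
    restrict_induced,
    restrict_quotient,
    to_undirected,
)
from .classes import CellClass, compare, d_star, hamming
from .features import (
    iterative_factor_analysis,
    parallel_analysis,
    select_by_communality,
)
from .grn import chi2_ci_test, eigen_cascades, fisher_z_test, pc_skeleton
from .io import ExpressionMatrix
from .synthetic import make_factor_blocks, perturb_grn, random_dag, sample_cells
from .tropical import EPSILON, trop_add, trop_mul, tropical_add, tropical_mul, z_map

__all__ = [
    "semiring_axiom_violations",
    "quotient_induced_mismatches",
    "metric_axiom_violations",
    "ci_test_rejection_rate",
    "pc_recovery_f1",
    "annotation_recovery",
    "dstar_monotonicity",
    "fa_block_recovery",
    "parallel_analysis_rates",
    "edge_f1",
]


def edge_f1(estimated: CascadeSet, truth: CascadeSet) -> float:
    """F1 score of unoriented edge recovery (1.0 for two empty edge sets)."""
    est = {frozenset(c.members) for c in estimated.edges()}
    tru = {frozenset(c.members) for c in truth.edges()}
    if not est and not tru:
        return 1.0
    tp = len(est & tru)
    if tp == 0:
        return 0.0
    precision, recall = tp / len(est), tp / len(tru)
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Algebra
# ---------------------------------------------------------------------------

def semiring_axiom_violations() -> int:
    """Exhaustive check of the per-cascade semirings and the z homomorphism.

    Over every cascade shape (singleton and pair), every combination of
    carrier elements is checked for commutativity, associativity,
    distributivity, the identities, ε-absorption, and agreement of z with
    the target tropical operations.  Returns the number of violated
    identities (0 when the algebra is correct).
    """
    violations = 0
    for ctx in (Cascade.singleton("a"), Cascade.pair("a", "b")):
        carrier = sorted(ctx.members) + [EPSILON]
        add = lambda x, y: tropical_add(x, y, ctx)
        mul = lambda x, y: tropical_mul(x, y, ctx)
        z = lambda x: z_map(x, ctx)
        g = ctx.dependent
        for x, y in product(carrier, repeat=2):
            violations += add(x, y) != add(y, x)
            violations += mul(x, y) != mul(y, x)
            violations += z(add(x, y)) != trop_add(z(x), z(y))
            violations += z(mul(x, y)) != trop_mul(z(x), z(y))
        for x in carrier:
            violations += add(x, EPSILON) != x
            violations += mul(x, g) != x
        for x, y, w in product(carrier, repeat=3):
            violations += add(add(x, y), w) != add(x, add(y, w))
            violations += mul(mul(x, y), w) != mul(x, mul(y, w))
            violations += mul(x, add(y, w)) != add(mul(x, y), mul(x, w))
    return violations


def quotient_induced_mismatches(
    n_instances: int = 1000, max_genes: int = 8, seed: int = 0
) -> int:
    """Count disagreements between quotient and induced-subgraph restriction
    on random (universe, dependency oracle, kept-subset) instances."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, max_genes + 1))
        genes = [f"g{i}" for i in range(n)]
        table = {(x, y): bool(rng.random() < 0.4)
                 for x in genes for y in genes if x != y}
        cset = cascades_from_dependency(lambda x, y: table[(x, y)], genes)
        kept = frozenset(g for g in genes if rng.random() < 0.6)
        spec = RestrictionSpec(cset.universe, kept)
        if (restrict_quotient(cset, spec).cascades
                != restrict_induced(cset, spec).cascades):
            mismatches += 1
    return mismatches


def metric_axiom_violations(n_triples: int = 500, seed: int = 0) -> int:
    """Check the Hamming pseudo-metric axioms and the d* identity/bound/
    subset properties on random unoriented cascade-set triples."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(6)]

    def random_set() -> CascadeSet:
        cascades = [Cascade.unoriented([g]) for g in genes]
        for i in range(6):
            for j in range(i + 1, 6):
                if rng.random() < 0.3:
                    cascades.append(Cascade.unoriented([genes[i], genes[j]]))
        return CascadeSet(frozenset(genes), cascades, oriented=False)

    violations = 0
    for _ in range(n_triples):
        a, b, c = random_set(), random_set(), random_set()
        violations += hamming(a, b) < 0
        violations += hamming(a, b) != hamming(b, a)
        violations += hamming(a, a) != 0
        violations += hamming(a, c) > hamming(a, b) + hamming(b, c)
        v = d_star(a, b)
        violations += not 0.0 <= v <= 1.0
        violations += (v == 0.0) != (a.cascades <= b.cascades)
        violations += d_star(a, a) != 0.0
    return violations


# ---------------------------------------------------------------------------
# CI tests and skeleton recovery
# ---------------------------------------------------------------------------

def ci_test_rejection_rate(
    test_kind: str = "fisher_z",
    n: int = 10000,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error rate of the marginal CI test under exact independence."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        if test_kind == "fisher_z":
            values = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x", "y"])
            m = ExpressionMatrix(values)
            p = fisher_z_test("x", "y", [], m).p_value
        else:
            values = pd.DataFrame(
                rng.integers(0, 2, size=(n, 2)).astype(float), columns=["x", "y"]
            )
            m = ExpressionMatrix(values)
            p = chi2_ci_test("x", "y", [], m, bins="asis").p_value
        rejections += p < alpha
    return rejections / n_reps


def pc_recovery_f1(
    n_seeds: int = 20,
    n_genes: int = 6,
    edge_prob: float = 0.4,
    n_cells: int = 5000,
    alpha: float = 0.01,
    max_cond: int = 3,
    seed: int = 0,
) -> float:
    """Mean edge-F1 of the PC-stable skeleton on random linear-Gaussian DAGs."""
    f1s = []
    for i in range(n_seeds):
        gt = random_dag(n_genes, edge_prob, seed=seed + i)
        m = sample_cells(gt, n_cells, seed=seed + 10_000 + i)
        skeleton = pc_skeleton(m, m.genes, alpha=alpha, max_cond=max_cond)
        f1s.append(edge_f1(skeleton, gt.skeleton()))
    return float(np.mean(f1s))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _distinct_dags(n_classes: int, n_genes: int, edge_prob: float, seed: int):
    """Draw ground-truth DAGs with pairwise distinct skeletons."""
    dags, offset = [], 0
    while len(dags) < n_classes:
        gt = random_dag(n_genes, edge_prob, seed=seed + offset)
        offset += 1
        if all(hamming(gt.skeleton(), d.skeleton()) > 0 for d in dags):
            dags.append(gt)
        if offset > 100 * n_classes:
            raise RuntimeError("could not draw distinct ground-truth DAGs")
    return dags


def annotation_recovery(
    n_replicates: int = 20,
    n_classes: int = 3,
    n_genes: int = 6,
    n_cells: int = 1000,
    edge_prob: float = 0.4,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Labeling and estimation accuracy on matched synthetic datasets.

    Per replicate: draw distinct ground-truth GRNs, sample an independent
    reference and query class from each, learn eigen-cascades, and run both
    annotation modes.  A replicate counts as correct for a mode when every
    centered class's assignment (the innermost ring; ties all reported)
    contains its true counterpart.  Returns per-mode counts of fully
    correct replicates.
    """
    correct = {"labeling": 0, "estimation": 0}
    for rep in range(n_replicates):
        base = seed + 1000 * rep
        dags = _distinct_dags(n_classes, n_genes, edge_prob, base)
        refs, queries = [], []
        for i, gt in enumerate(dags):
            mr = sample_cells(gt, n_cells, seed=base + 100 + i)
            mq = sample_cells(gt, n_cells, seed=base + 200 + i)
            refs.append(CellClass(
                f"c{i}", "ref", frozenset(),
                eigen_cascades(mr, mr.genes, alpha=alpha)))
            queries.append(CellClass(
                f"c{i}", "query", frozenset(),
                eigen_cascades(mq, mq.genes, alpha=alpha)))
        lab = compare("labeling", refs, queries)
        est = compare("estimation", queries, refs)
        if all(("query", r.center[1]) in r.assignment for r in lab):
            correct["labeling"] += 1
        if all(("ref", r.center[1]) in r.assignment for r in est):
            correct["estimation"] += 1
    correct["n_replicates"] = n_replicates
    return correct


def dstar_monotonicity(
    n_replicates: int = 20,
    edit_counts=(0, 1, 2, 3),
    n_genes: int = 6,
    n_cells: int = 1000,
    edge_prob: float = 0.4,
    seed: int = 0,
) -> dict:
    """d* against a fixed reference as the query's GRN drifts away.

    For each replicate a reference class is learned from a base GRN; query
    classes are learned from GRNs perturbed by k edge edits.  Returns the
    median d* per k and the Spearman correlation of the medians with k —
    positive when structural divergence is reflected in the score.
    """
    per_k = {k: [] for k in edit_counts}
    for rep in range(n_replicates):
        base = seed + 500 * rep
        gt = random_dag(n_genes, edge_prob, seed=base)
        ref_m = sample_cells(gt, n_cells, seed=base + 1)
        ref = eigen_cascades(ref_m, ref_m.genes)
        for k in edit_counts:
            edited = perturb_grn(gt, k, seed=base + 10 + k)
            qm = sample_cells(edited, n_cells, seed=base + 50 + k)
            query = eigen_cascades(qm, qm.genes)
            per_k[k].append(d_star(query, ref))
    medians = {k: float(np.median(v)) for k, v in per_k.items()}
    rho = stats.spearmanr(list(medians.keys()), list(medians.values())).statistic
    return {"medians": medians, "spearman_rho": float(rho)}


# ---------------------------------------------------------------------------
# Factor analysis
# ---------------------------------------------------------------------------

def fa_block_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Two-block loading design: does the EFA loop find 2 factors and the
    communality filter recover exactly the block genes?"""
    recovered = 0
    for i in range(n_seeds):
        m, assignment = make_factor_blocks(
            n_blocks=2, block_size=10, loading=0.8, n_cells=500, seed=seed + i
        )
        try:
            model = iterative_factor_analysis(m, m.genes, seed=seed + i)
        except ValueError:
            continue
        report = select_by_communality(model, 0.5)
        if model.n_factors == 2 and set(report.selected) == set(assignment):
            recovered += 1
    return {"recovered": recovered, "n_seeds": n_seeds}


def parallel_analysis_rates(n_runs: int = 40, seed: int = 0) -> dict:
    """Dimension-recovery rates of parallel analysis.

    Pure 500 × 50 noise should retain 0 components; the two-block loading
    design should retain exactly 2.  Returns the fraction of runs hitting
    each target.
    """
    rng = np.random.default_rng(seed)
    noise_zero = 0
    for i in range(n_runs):
        noise = ExpressionMatrix(pd.DataFrame(rng.normal(size=(500, 50))))
        noise_zero += parallel_analysis(noise, n_perm=100, seed=seed + i) == 0
    two_factor = 0
    for i in range(n_runs):
        m, _ = make_factor_blocks(2, 10, 0.8, 500, seed=seed + 100 + i)
        two_factor += parallel_analysis(m, n_perm=100, seed=seed + 100 + i) == 2
    return {
        "noise_zero_rate": noise_zero / n_runs,
        "two_factor_rate": two_factor / n_runs,
        "n_runs": n_runs,
    }
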