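"""GRN structure learning: conditional-independence tests and the PC-stable skeleton.

A cell class's eigen-cascades are estimated from its pooled expression
matrix: start from the complete undirected graph over the chosen vertex
genes and delete the edge x–y as soon as some conditioning set (drawn from
current neighbors, size 0..max_cond) fails to reject independence.
Orientations are deliberately never computed — the annotation metric works
on undirected structure, so the skeleton is the whole output.

Continuous data use the Fisher z-test on partial correlations; discretized
data use a stratified chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cascades import Cascade, CascadeSet
from .io import ExpressionMatrix

__all__ = [
    "CITestResult",
    "fisher_z_test",
    "chi2_ci_test",
    "pc_skeleton",
    "eigen_cascades",
]

#: classical minimum expected count per contingency cell
CHI2_EXPECTED_FLOOR = 5.0


@dataclass(frozen=True)
class CITestResult:
    pair: tuple
    conditioning_set: frozenset
    p_value: float
    statistic: float
    test_kind: str
    skipped_strata: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.pair[0] in self.conditioning_set or self.pair[1] in self.conditioning_set:
            raise ValueError("conditioning set must exclude the tested pair")


class _FisherZEngine:
    """Partial-correlation z-tests from one precomputed correlation matrix."""

    def __init__(self, m: ExpressionMatrix, genes):
        self.genes = sorted(genes)
        sub = m.values[self.genes].to_numpy(dtype=float)
        self.n = sub.shape[0]
        sd = sub.std(axis=0, ddof=1)
        zero_var = [g for g, s in zip(self.genes, sd) if s == 0]
        if zero_var:
            raise ValueError(f"zero-variance genes: {zero_var}")
        self.corr = np.corrcoef(sub, rowvar=False)
        self.index = {g: i for i, g in enumerate(self.genes)}

    def test(self, x, y, cond) -> CITestResult:
        cond = sorted(cond)
        k = len(cond)
        if self.n <= k + 3:
            raise ValueError(
                f"need more than |cond| + 3 = {k + 3} samples, have {self.n}"
            )
        idx = [self.index[x], self.index[y]] + [self.index[c] for c in cond]
        if not cond:  # marginal correlation needs no inversion
            r = self.corr[idx[0], idx[1]]
            r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
            z = np.arctanh(r) * np.sqrt(self.n - 3)
            p = 2.0 * stats.norm.sf(abs(z))
            return CITestResult((x, y), frozenset(), float(p), float(z), "fisher_z")
        sub = self.corr[np.ix_(idx, idx)]
        try:
            prec = np.linalg.inv(sub)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"collinear conditioning set for ({x}, {y}) given {cond}"
            ) from err
        if not np.isfinite(prec).all() or np.linalg.cond(sub) > 1e12:
            raise ValueError(
                f"collinear conditioning set for ({x}, {y}) given {cond}"
            )
        r = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        z = np.arctanh(r) * np.sqrt(self.n - k - 3)
        p = 2.0 * stats.norm.sf(abs(z))
        return CITestResult((x, y), frozenset(cond), float(p), float(z), "fisher_z")


def _median_split(col: np.ndarray) -> np.ndarray:
    return (col > np.median(col)).astype(int)


class _Chi2Engine:
    """Stratified chi-square CI tests on discretized data."""

    def __init__(self, m: ExpressionMatrix, genes, bins="median"):
        self.genes = sorted(genes)
        raw = m.values[self.genes]
        if bins == "median":
            disc = raw.apply(lambda c: _median_split(c.to_numpy()), axis=0)
        elif callable(bins):
            disc = raw.apply(lambda c: bins(c.to_numpy()), axis=0)
        elif bins == "asis":
            disc = raw.astype(int)
        else:
            raise ValueError(f"unknown binning rule {bins!r}")
        for g in self.genes:
            if disc[g].nunique() < 2:
                raise ValueError(f"gene {g} has fewer than 2 levels after binning")
        self.disc = disc
        self.n = disc.shape[0]

    def test(self, x, y, cond) -> CITestResult:
        cond = sorted(cond)
        stat, dof, skipped = 0.0, 0, 0
        if cond:
            grouped = self.disc.groupby(cond, sort=True)
            strata = (g for _, g in grouped)
        else:
            strata = [self.disc]
        any_used = False
        for stratum in strata:
            table = pd.crosstab(stratum[x], stratum[y]).to_numpy(dtype=float)
            if table.shape[0] < 2 or table.shape[1] < 2:
                skipped += 1
                continue
            expected = stats.contingency.expected_freq(table)
            if (expected < CHI2_EXPECTED_FLOOR).any():
                skipped += 1
                continue
            res = stats.chi2_contingency(table, correction=False)
            stat += float(res.statistic)
            dof += int(res.dof)
            any_used = True
        if not any_used:
            raise ValueError(
                f"insufficient counts: all strata skipped for ({x}, {y}) given {cond}"
            )
        p = float(stats.chi2.sf(stat, dof))
        return CITestResult((x, y), frozenset(cond), p, stat, "chi_square", skipped)


def _make_engine(m: ExpressionMatrix, genes, test_kind: str, bins="median"):
    if test_kind == "fisher_z":
        return _FisherZEngine(m, genes)
    if test_kind == "chi_square":
        return _Chi2Engine(m, genes, bins)
    raise ValueError(f"unknown test kind {test_kind!r}")


def fisher_z_test(x, y, cond, m: ExpressionMatrix) -> CITestResult:
    """Fisher z-test of partial correlation of *x*, *y* given *cond*.

    The partial correlation comes from inverting the sub-correlation matrix;
    the statistic is atanh(r)·sqrt(n − |cond| − 3) against a standard normal.
    """
    return _FisherZEngine(m, {x, y} | set(cond)).test(x, y, cond)


def chi2_ci_test(x, y, cond, m: ExpressionMatrix, bins="median") -> CITestResult:
    """Stratified chi-square independence test on discretized expression.

    Statistics and degrees of freedom are pooled over the conditioning
    strata; strata with expected counts below the classical floor of 5 are
    skipped and counted in ``skipped_strata``.
    """
    return _Chi2Engine(m, {x, y} | set(cond), bins).test(x, y, cond)


def pc_skeleton(
    m: ExpressionMatrix,
    genes,
    alpha: float = 0.01,
    max_cond: int = 3,
    test_kind: str = "fisher_z",
    bins="median",
) -> CascadeSet:
    """PC-stable skeleton of the GRN over *genes*, as an unoriented cascade set.

    Starts from the complete graph; at each level ℓ = 0..max_cond the
    adjacency sets are frozen, and an edge x–y is removed when some
    conditioning set of size ℓ drawn from the frozen neighborhoods of x or y
    yields p > alpha.  Gene order and conditioning-set enumeration are
    deterministic (lexicographic), and the frozen neighborhoods make the
    result independent of edge-processing order.
    """
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in m.values.columns]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if max_cond < 0:
        raise ValueError("max_cond must be non-negative")
    engine = _make_engine(m, genes, test_kind, bins)

    adj = {g: set(h for h in genes if h != g) for g in genes}
    for level in range(max_cond + 1):
        frozen = {g: sorted(nb) for g, nb in adj.items()}
        if all(len(nb) - 1 < level for nb in frozen.values()):
            break
        for x, y in combinations(genes, 2):
            if y not in adj[x]:
                continue
            candidates = []
            seen = set()
            for side in (x, y):
                other = y if side == x else x
                pool = [g for g in frozen[side] if g != other]
                for cond in combinations(pool, level):
                    if cond not in seen:
                        seen.add(cond)
                        candidates.append(cond)
            for cond in candidates:
                try:
                    res = engine.test(x, y, list(cond))
                except ValueError as err:
                    raise ValueError(
                        f"CI test failed for edge {x}-{y} given {list(cond)}: {err}"
                    ) from err
                if res.p_value > alpha:
                    adj[x].discard(y)
                    adj[y].discard(x)
                    break

    cascades = [Cascade.unoriented([g]) for g in genes]
    for x, y in combinations(genes, 2):
        if y in adj[x]:
            cascades.append(Cascade.unoriented([x, y]))
    return CascadeSet(frozenset(genes), cascades, oriented=False)


def eigen_cascades(
    m: ExpressionMatrix,
    genes,
    alpha: float = 0.01,
    max_cond: int = 3,
    test_kind: str = "fisher_z",
    bins="median",
    min_cells: int = 30,
    class_id=None,
) -> CascadeSet:
    """Eigen-cascades of one cell class from its pooled expression matrix.

    The skeleton learned from the pooled matrix approximates the
    intersection of the member cells' possessed cascades: an edge survives
    only if dependence is supported across the class as a whole.
    """
    if m.n_cells < min_cells:
        label = f" for class {class_id!r}" if class_id is not None else ""
        raise ValueError(
            f"class{label} has {m.n_cells} cells, below the floor of {min_cells}"
        )
    genes = sorted(set(genes))
    if len(genes) == 1:
        return CascadeSet(frozenset(genes),
                          [Cascade.unoriented(genes)], oriented=False)
    return pc_skeleton(m, genes, alpha, max_cond, test_kind, bins)
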