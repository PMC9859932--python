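"""Vertex-gene selection: marker panel, KMO/MSA, parallel analysis, the
iterative factor-analysis loop, and the GBDT importance route."""

import numpy as np
import pandas as pd
import pytest

from eigencascade import (
    ExpressionMatrix,
    gbdt_importance_selection,
    groupwise_sd_rank,
    iterative_factor_analysis,
    kmo_from_corr,
    kmo_msa,
    load_marker_panel,
    make_factor_blocks,
    ovr_metrics,
    parallel_analysis,
    random_undersample,
    select_by_communality,
)


class TestMarkerPanel:
    def test_panel_size_and_uniqueness(self):
        panel = load_marker_panel()
        assert len(panel) == 90
        assert len(set(panel.entries)) == 90

    def test_fifteen_identities(self):
        panel = load_marker_panel()
        assert len(panel.categories) == 15
        assert "astrocytes" in panel.categories
        assert panel.genes_for("OPCs") == ["PDGFRA"]

    def test_known_members(self):
        genes = set(load_marker_panel().genes)
        assert {"GFAP", "SATB2", "GAD2", "PDGFRA", "HBB"} <= genes


def textbook_kmo(corr):
    """Independent step-by-step oracle: anti-image partial correlations via
    explicit per-pair regression residual algebra on the inverse."""
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    inv = np.linalg.inv(corr)
    num_per = np.zeros(p)
    den_per = np.zeros(p)
    for j in range(p):
        for i in range(p):
            if i == j:
                continue
            pc = -inv[i, j] / np.sqrt(inv[i, i] * inv[j, j])
            num_per[j] += corr[i, j] ** 2
            den_per[j] += corr[i, j] ** 2 + pc**2
    return num_per.sum() / den_per.sum(), num_per / den_per


class TestKMO:
    def test_matches_oracle_on_equicorrelated_matrix(self):
        corr = np.full((3, 3), 0.7)
        np.fill_diagonal(corr, 1.0)
        overall, msa = kmo_from_corr(corr)
        oracle_overall, oracle_msa = textbook_kmo(corr)
        assert overall == pytest.approx(oracle_overall, abs=1e-10)
        np.testing.assert_allclose(msa, oracle_msa, atol=1e-10)
        assert np.ptp(msa) < 1e-12  # symmetric design: equal MSA per variable

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(20):
            x = rng.normal(size=(200, 5))
            x[:, 1] += 0.5 * x[:, 0]
            x[:, 3] += 0.3 * x[:, 2]
            corr = np.corrcoef(x, rowvar=False)
            overall, msa = kmo_from_corr(corr)
            oracle_overall, oracle_msa = textbook_kmo(corr)
            assert overall == pytest.approx(oracle_overall, abs=1e-8)
            np.testing.assert_allclose(msa, oracle_msa, atol=1e-8)

    def test_zero_correlation_degenerates_with_warning(self):
        corr = np.eye(4)
        with pytest.warns(UserWarning, match="undefined"):
            overall, msa = kmo_from_corr(corr)
        assert np.isnan(overall)
        assert np.isnan(msa).all()

    def test_duplicated_variable_is_singular(self, rng):
        a = rng.normal(size=300)
        m = ExpressionMatrix(pd.DataFrame({
            "x": a, "x2": a, "y": rng.normal(size=300),
        }))
        with pytest.raises(ValueError, match="singular"):
            kmo_msa(m, ["x", "x2", "y"])

    def test_ridge_fallback_handles_singularity(self, rng):
        a = rng.normal(size=300)
        m = ExpressionMatrix(pd.DataFrame({
            "x": a, "x2": a, "y": rng.normal(size=300),
        }))
        overall, msa = kmo_msa(m, ["x", "x2", "y"], ridge=True)
        assert 0.0 <= overall <= 1.0


class TestParallelAnalysis:
    def test_pure_noise_retains_nothing(self, rng):
        hits = sum(
            parallel_analysis(
                ExpressionMatrix(pd.DataFrame(rng.normal(size=(500, 50)))),
                n_perm=50, seed=s) == 0
            for s in range(20)
        )
        assert hits >= 19

    def test_two_blocks_retain_two(self, rng):
        hits = 0
        for s in range(20):
            m, _ = make_factor_blocks(2, 10, 0.8, 500, seed=s)
            hits += parallel_analysis(m, n_perm=50, seed=s) == 2
        assert hits >= 19

    def test_rank_one_signal_retains_one(self, rng):
        m, _ = make_factor_blocks(1, 12, 0.9, 500, seed=4)
        assert parallel_analysis(m, n_perm=50, seed=4) == 1

    def test_retained_nonincreasing_in_percentile(self):
        m, _ = make_factor_blocks(2, 8, 0.7, 300, seed=6)
        counts = [parallel_analysis(m, n_perm=50, percentile=p, seed=6)
                  for p in (50, 75, 95, 99)]
        assert counts == sorted(counts, reverse=True)

    def test_input_validation(self):
        m, _ = make_factor_blocks(1, 5, 0.8, 100, seed=0)
        with pytest.raises(ValueError):
            parallel_analysis(m, n_perm=0)


class TestIterativeFactorAnalysis:
    def test_two_clean_blocks(self):
        m, assignment = make_factor_blocks(2, 10, 0.8, 600, seed=1)
        model = iterative_factor_analysis(m, m.genes, seed=1)
        assert model.n_factors == 2
        # each block loads on its own factor above the floor
        for block in (0, 1):
            block_genes = [g for g, b in assignment.items() if b == block]
            loadings = model.loadings.loc[block_genes].abs()
            top_factor = loadings.max(axis=0).idxmax()
            assert (loadings[top_factor] >= 0.5).all() or (
                loadings.drop(columns=top_factor).max(axis=0) < loadings[top_factor]
            ).all()

    def test_communality_uniqueness_partition(self):
        m, _ = make_factor_blocks(2, 10, 0.8, 600, seed=2)
        model = iterative_factor_analysis(m, m.genes, seed=2)
        np.testing.assert_allclose(
            model.communalities + model.uniquenesses, 1.0, atol=1e-6
        )

    def test_noise_genes_end_low(self):
        m, assignment = make_factor_blocks(2, 10, 0.8, 600, n_noise=5, seed=3)
        model = iterative_factor_analysis(m, m.genes, seed=3)
        report = select_by_communality(model, 0.5)
        noise = {g for g in m.genes if g.startswith("noise")}
        assert not (set(report.selected) & noise)

    def test_all_noise_errors(self, rng):
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(400, 12)),
            columns=[f"n{i}" for i in range(12)]))
        with pytest.raises(ValueError):
            iterative_factor_analysis(m, m.genes, seed=5)


@pytest.fixture(scope="module")
def model():
    m, _ = make_factor_blocks(2, 10, 0.8, 600, seed=7)
    return iterative_factor_analysis(m, m.genes, seed=7)


class TestCommunalitySelection:
    def test_block_genes_selected(self, model):
        report = select_by_communality(model, 0.5)
        assert set(report.selected) == set(model.variables)

    def test_floor_one_empty(self, model):
        assert select_by_communality(model, 1.0).selected == ()

    def test_floor_zero_all(self, model):
        assert set(select_by_communality(model, 0.0).selected) == set(model.variables)


class TestGroupwiseSDRank:
    def test_designed_marker_ranks_first(self, rng):
        n = 300
        labels = pd.Series(np.repeat(["a", "b", "c"], n // 3))
        values = pd.DataFrame(rng.normal(size=(n, 11)),
                              columns=[f"g{i}" for i in range(10)] + ["marker"])
        values["marker"] = labels.map({"a": 5.0, "b": 0.0, "c": 0.0}).to_numpy()
        values["marker"] += rng.normal(scale=0.1, size=n)
        values.index = labels.index = [f"cell{i}" for i in range(n)]
        m = ExpressionMatrix(values)
        report = groupwise_sd_rank(m, labels, top_n=3)
        assert report.selected[0] == "marker"

    def test_constant_group_means_rank_last(self, rng):
        labels = pd.Series(["a"] * 50 + ["b"] * 50)
        values = pd.DataFrame({
            "flat": np.tile([1.0], 100),
            "varies": np.r_[np.zeros(50), np.ones(50)],
        })
        values.index = labels.index = [f"c{i}" for i in range(100)]
        report = groupwise_sd_rank(ExpressionMatrix(values), labels, top_n=10)
        assert report.scores["flat"] == 0.0
        assert report.selected[-1] == "flat"

    def test_top_n_overflow_returns_all(self, small_matrix):
        labels = pd.Series(["a"] * 100 + ["b"] * 100, index=small_matrix.cell_ids)
        report = groupwise_sd_rank(small_matrix, labels, top_n=100)
        assert len(report.selected) == 5

    def test_single_group_rejected(self, small_matrix):
        labels = pd.Series("a", index=small_matrix.cell_ids)
        with pytest.raises(ValueError):
            groupwise_sd_rank(small_matrix, labels)


class TestRandomUndersample:
    @pytest.fixture
    def imbalanced(self, rng):
        sizes = {"a": 100, "b": 50, "c": 20}
        labels = pd.Series(
            [cls for cls, n in sizes.items() for _ in range(n)],
            index=[f"cell{i}" for i in range(170)],
        )
        values = pd.DataFrame(rng.normal(size=(170, 3)), index=labels.index,
                              columns=["g1", "g2", "g3"])
        return ExpressionMatrix(values, class_labels=labels)

    def test_downsampled_to_minimum(self, imbalanced):
        out = random_undersample(imbalanced, imbalanced.class_labels, seed=0)
        assert out.class_labels.value_counts().to_dict() == {"a": 20, "b": 20, "c": 20}

    def test_deterministic_per_seed(self, imbalanced):
        a = random_undersample(imbalanced, imbalanced.class_labels, seed=3)
        b = random_undersample(imbalanced, imbalanced.class_labels, seed=3)
        assert a.cell_ids == b.cell_ids

    def test_balanced_input_keeps_everything(self, imbalanced):
        balanced = random_undersample(imbalanced, imbalanced.class_labels, seed=0)
        again = random_undersample(balanced, balanced.class_labels, seed=9)
        assert sorted(again.cell_ids) == sorted(balanced.cell_ids)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(42)
    n = 600
    labels = pd.Series(np.repeat(["a", "b", "c"], n // 3))
    values = pd.DataFrame(rng.normal(size=(n, 51)),
                          columns=[f"g{i}" for i in range(50)] + ["sep"])
    values["sep"] = labels.map({"a": 0.0, "b": 5.0, "c": 10.0}).to_numpy()
    values["sep"] += rng.normal(size=n)
    values.index = labels.index = [f"cell{i}" for i in range(n)]
    groups = pd.Series([f"grp{i % 10}" for i in range(n)], index=values.index)
    return ExpressionMatrix(values, class_labels=labels, group_labels=groups)


class TestGBDTSelection:
    def test_separating_gene_selected(self, separable):
        report = gbdt_importance_selection(
            separable, separable.class_labels, separable.group_labels, seed=0)
        assert "sep" in report.selected
        assert report.scores.index[0] == "sep"  # top median importance

    def test_column_permutation_invariance(self, separable):
        report = gbdt_importance_selection(
            separable, separable.class_labels, separable.group_labels, seed=0)
        shuffled = separable.subset_genes(list(reversed(separable.genes)))
        report2 = gbdt_importance_selection(
            shuffled, separable.class_labels, separable.group_labels, seed=0)
        assert set(report.selected) == set(report2.selected)

    def test_too_many_folds_rejected(self, separable):
        groups = pd.Series(
            [f"grp{i % 5}" for i in range(separable.n_cells)],
            index=separable.cell_ids)
        with pytest.raises(ValueError, match="exceeds"):
            gbdt_importance_selection(
                separable, separable.class_labels, groups, n_folds=10)

    @pytest.mark.parametrize("trial", range(3))
    def test_noise_only_selection_is_near_empty(self, trial):
        """With no signal among many candidate genes, early stopping keeps
        per-fold importances sparse and the all-fold-stable set near-empty."""
        rng = np.random.default_rng(trial)
        n, p = 300, 1000
        labels = pd.Series(np.repeat(["a", "b", "c"], n // 3))
        values = pd.DataFrame(rng.normal(size=(n, p)),
                              columns=[f"g{i}" for i in range(p)])
        values.index = labels.index = [f"cell{i}" for i in range(n)]
        groups = pd.Series([f"grp{i % 10}" for i in range(n)], index=values.index)
        m = ExpressionMatrix(values, class_labels=labels)
        report = gbdt_importance_selection(m, labels, groups, seed=trial)
        assert len(report.selected) <= 3


class TestOvRMetrics:
    def test_perfect_scores(self):
        labels = pd.Series(["a", "a", "b", "b", "c", "c"])
        scores = pd.DataFrame({c: (labels == c).astype(float) for c in "abc"})
        out = ovr_metrics(labels, scores)
        assert out["macro_auc"] == 1.0
        assert out["micro_ap"] == 1.0
        assert all(v == 1.0 for v in out["auc"].values())

    def test_reversed_scores(self):
        labels = pd.Series(["a", "a", "b", "b"])
        scores = pd.DataFrame({c: 1.0 - (labels == c).astype(float) for c in "ab"})
        out = ovr_metrics(labels, scores)
        assert all(v == 0.0 for v in out["auc"].values())

    def test_random_scores_near_half(self, rng):
        n = 10000
        labels = pd.Series(rng.choice(["a", "b", "c"], size=n))
        scores = pd.DataFrame(rng.random((n, 3)), columns=["a", "b", "c"])
        out = ovr_metrics(labels, scores)
        assert abs(out["macro_auc"] - 0.5) < 0.02

    def test_single_class_rejected(self):
        labels = pd.Series(["a", "a"])
        with pytest.raises(ValueError):
            ovr_metrics(labels, pd.DataFrame({"a": [0.1, 0.2]}))
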