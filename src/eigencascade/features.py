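"""Vertex-gene selection for GRNs.

Two complementary routes pick the genes that become GRN vertices:

* an exploratory-factor-analysis workflow on a curated marker panel —
  KMO/MSA adequacy filtering, parallel analysis for the number of factors,
  principal-axis extraction with quartimin (oblique) rotation, recursive
  elimination of weakly loaded factors, and a communality threshold;
* a gradient-boosted decision tree (L1/L2-regularized LightGBM) trained to
  predict class labels after random undersampling, keeping only genes whose
  feature importance is nonzero in *every* grouped stratified CV fold.

The packaged marker panel lists 90 literature-curated CNS marker genes over
15 cellular identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import linalg

from .io import ExpressionMatrix

__all__ = [
    "MarkerPanel",
    "FactorModel",
    "SelectionReport",
    "load_marker_panel",
    "kmo_msa",
    "kmo_from_corr",
    "parallel_analysis",
    "iterative_factor_analysis",
    "select_by_communality",
    "groupwise_sd_rank",
    "random_undersample",
    "gbdt_importance_selection",
    "ovr_metrics",
]


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerPanel:
    """Curated (gene, cellular identity) pairs shipped with the package."""

    entries: tuple  # of (symbol, category)

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate (gene, category) pairs in panel")

    @property
    def genes(self) -> list:
        return [g for g, _ in self.entries]

    @property
    def categories(self) -> list:
        return sorted({c for _, c in self.entries})

    def genes_for(self, category: str) -> list:
        return [g for g, c in self.entries if c == category]

    def __len__(self) -> int:
        return len(self.entries)


def load_marker_panel() -> MarkerPanel:
    """Load the packaged 90-gene CNS marker panel."""
    with resources.files("eigencascade.data").joinpath("markers.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return MarkerPanel(tuple(zip(df["symbol"], df["category"])))


# ---------------------------------------------------------------------------
# Sampling adequacy (KMO / MSA)
# ---------------------------------------------------------------------------

def kmo_from_corr(corr: np.ndarray, ridge: bool = False):
    """KMO and per-variable MSA from a correlation matrix.

    Both statistics compare squared marginal correlations with squared
    anti-image partial correlations; values near 1 mean the variables share
    enough common variance for factor analysis to be sensible.
    """
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    if p < 3:
        raise ValueError("KMO needs at least 3 variables")
    try:
        if ridge:
            prec = linalg.inv(corr + 1e-8 * np.eye(p))
        else:
            if np.linalg.cond(corr) > 1e12:
                raise np.linalg.LinAlgError("ill-conditioned correlation matrix")
            prec = linalg.inv(corr)
    except (np.linalg.LinAlgError, linalg.LinAlgError) as err:
        raise ValueError(
            "singular correlation matrix; pass ridge=True to regularize"
        ) from err
    d = np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
    partial = -prec / d
    np.fill_diagonal(partial, 0.0)
    r2 = corr**2
    np.fill_diagonal(r2, 0.0)
    pc2 = partial**2

    denom_per = r2.sum(axis=0) + pc2.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        msa = np.where(denom_per > 0, r2.sum(axis=0) / denom_per, np.nan)
    denom_all = r2.sum() + pc2.sum()
    overall = r2.sum() / denom_all if denom_all > 0 else np.nan
    if np.isnan(overall):
        warnings.warn("all pairwise correlations are zero; KMO undefined")
    return float(overall), msa


def kmo_msa(m: ExpressionMatrix, variables, ridge: bool = False):
    """KMO (overall) and MSA (per variable) on the matrix's correlation."""
    variables = sorted(variables)
    corr = np.corrcoef(m.values[variables].to_numpy(dtype=float), rowvar=False)
    overall, msa = kmo_from_corr(corr, ridge=ridge)
    return overall, pd.Series(msa, index=variables)


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------

def parallel_analysis(
    m: ExpressionMatrix | pd.DataFrame,
    n_perm: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis: retained dimensionality of the data.

    Correlation-matrix eigenvalues of the observed data are compared rank by
    rank against the chosen percentile of eigenvalues from matrices whose
    columns were independently permuted (which destroys correlation while
    preserving the margins).  Retention stops at the first rank whose
    observed eigenvalue fails to exceed its null threshold.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    values = m.values if isinstance(m, ExpressionMatrix) else m
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    real = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, p))
    shuffled = x.copy()
    for i in range(n_perm):
        for j in range(p):
            rng.shuffle(shuffled[:, j])
        null[i] = np.sort(np.linalg.eigvalsh(np.corrcoef(shuffled, rowvar=False)))[::-1]
    thresholds = np.percentile(null, percentile, axis=0)
    retained = 0
    for r, t in zip(real, thresholds):
        if r > t:
            retained += 1
        else:
            break
    return retained


# ---------------------------------------------------------------------------
# Factor analysis
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """A fitted, rotated common-factor model on standardized variables."""

    variables: list
    n_factors: int
    loadings: pd.DataFrame          # rotated pattern matrix, variables × factors
    communalities: pd.Series        # rotation-invariant, from unrotated loadings
    uniquenesses: pd.Series
    rotation: str
    phi: np.ndarray                 # factor correlation matrix (oblique)
    means: pd.Series                # standardization parameters of the fit data
    sds: pd.Series

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError("a factor model needs at least one factor")
        resid = (self.communalities + self.uniquenesses - 1.0).abs()
        if (resid > 1e-6).any():
            raise ValueError("communality + uniqueness must equal 1 per variable")


def _fit_rotated(x: np.ndarray, variables, k: int):
    """Fit a k-factor model by iterated principal axis, quartimin-rotated."""
    from statsmodels.multivariate.factor import Factor
    from statsmodels.multivariate.factor_rotation import rotate_factors

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = Factor(x, n_factor=k, method="pa").fit()
    unrotated = np.asarray(res.loadings)[:, :k]
    communality = (unrotated**2).sum(axis=1)
    if k > 1:
        rotated, t = rotate_factors(unrotated, "quartimin")
        phi = t.T @ t
    else:
        rotated, phi = unrotated, np.eye(1)
    loadings = pd.DataFrame(
        rotated, index=variables, columns=[f"F{i + 1}" for i in range(k)]
    )
    return loadings, pd.Series(communality, index=variables), phi


def iterative_factor_analysis(
    m: ExpressionMatrix,
    variables,
    msa_floor: float = 0.6,
    loading_floor: float = 0.5,
    n_perm: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
    msa_refilter: bool = True,
) -> FactorModel:
    """The full EFA loop: MSA filter → parallel analysis → rotate → prune.

    Variables with MSA below *msa_floor* are dropped (re-applied each
    iteration unless *msa_refilter* is False); the starting number of
    factors comes from parallel analysis; after quartimin rotation the
    weakest factor (smallest max |loading|) is eliminated and the model
    refitted until every factor carries at least one |loading| ≥
    *loading_floor*.
    """
    variables = sorted(variables)
    missing = [v for v in variables if v not in m.values.columns]
    if missing:
        raise KeyError(f"variables not in matrix: {missing}")

    filtered_once = False
    while True:
        if len(variables) < 3:
            raise ValueError("fewer than 3 variables survive the MSA filter")
        _, msa = kmo_msa(m, variables)
        keep = [v for v in variables if not np.isnan(msa[v]) and msa[v] >= msa_floor]
        if keep == variables or (filtered_once and not msa_refilter):
            break
        if not keep:
            raise ValueError("no variables survive the MSA filter")
        variables = keep
        filtered_once = True
        if not msa_refilter:
            break

    sub = m.values[variables]
    k = parallel_analysis(sub, n_perm=n_perm, percentile=percentile, seed=seed)
    k = min(k, len(variables) - 1)
    if k < 1:
        raise ValueError("no interpretable factors: parallel analysis retains none")

    x = sub.to_numpy(dtype=float)
    while True:
        loadings, communality, phi = _fit_rotated(x, variables, k)
        peak = loadings.abs().max(axis=0)
        weakest = peak.idxmin()
        if peak[weakest] >= loading_floor:
            break
        if k == 1:
            raise ValueError(
                "no interpretable factors: every factor's loadings fall below "
                f"{loading_floor}"
            )
        k -= 1  # refit without the weakest factor

    return FactorModel(
        variables=variables,
        n_factors=k,
        loadings=loadings,
        communalities=communality,
        uniquenesses=1.0 - communality,
        rotation="quartimin" if k > 1 else "none",
        phi=phi,
        means=sub.mean(),
        sds=sub.std(ddof=1),
    )


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of one gene-selection method."""

    method: str
    selected: tuple
    scores: pd.Series
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.selected) - set(self.scores.index)
        if unknown:
            raise ValueError(f"selected genes without scores: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": list(self.selected),
            "scores": {str(k): float(v) for k, v in self.scores.items()},
            "parameters": {k: v for k, v in self.parameters.items()},
        }


def select_by_communality(model: FactorModel, floor: float = 0.5) -> SelectionReport:
    """Genes whose communality strictly exceeds *floor*."""
    scores = model.communalities
    selected = tuple(sorted(scores.index[scores > floor]))
    return SelectionReport("communality", selected, scores, {"floor": floor})


# ---------------------------------------------------------------------------
# GBDT route
# ---------------------------------------------------------------------------

def groupwise_sd_rank(m: ExpressionMatrix, labels, top_n: int = 1000) -> SelectionReport:
    """Rank genes by the SD of their class-wise mean expression."""
    labels = pd.Series(labels).reindex(m.values.index)
    if labels.nunique() < 2:
        raise ValueError("groupwise SD ranking needs at least 2 label groups")
    group_means = m.values.groupby(labels, observed=True).mean()
    sd = group_means.std(ddof=1, axis=0)
    ranked = sd.sort_values(ascending=False, kind="stable")
    selected = tuple(ranked.index[: min(top_n, len(ranked))])
    return SelectionReport("sd_rank", selected, ranked, {"top_n": top_n})


def random_undersample(m: ExpressionMatrix, labels, seed: int = 0) -> ExpressionMatrix:
    """Downsample every class to the minimum class size, without replacement."""
    labels = pd.Series(labels).reindex(m.values.index)
    counts = labels.value_counts()
    if (counts == 0).any() or labels.isna().any():
        raise ValueError("every cell needs a class label")
    floor = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = []
    for cls in sorted(counts.index.astype(str)):
        members = sorted(labels.index[labels.astype(str) == cls])
        chosen = rng.choice(len(members), size=floor, replace=False)
        keep.extend(members[i] for i in sorted(chosen))
    sub = m.subset_cells(keep)
    if sub.class_labels is None:
        sub.class_labels = labels.loc[keep]
    return sub


def gbdt_importance_selection(
    m: ExpressionMatrix,
    labels,
    groups,
    n_folds: int = 5,
    reg_l1: float = 0.1,
    reg_l2: float = 0.1,
    seed: int = 0,
    **lgbm_params,
) -> SelectionReport:
    """Stable GBDT feature importances under grouped stratified CV.

    An L1/L2-regularized LightGBM classifier is trained on each of
    *n_folds* grouped stratified folds; a gene is selected only if its
    importance is nonzero in every fold.  Scores are the per-gene median
    importances across folds.

    Within each fold the training split is further divided 75/25 into fit
    and validation parts; boosting stops early once validation loss stalls
    and importances are read at the best iteration, so uninformative genes
    cannot accumulate splits from overfitted late rounds.
    """
    import lightgbm as lgb
    from sklearn.model_selection import StratifiedGroupKFold, train_test_split

    labels = pd.Series(labels).reindex(m.values.index).astype(str)
    groups = pd.Series(groups).reindex(m.values.index).astype(str)
    if labels.isna().any() or groups.isna().any():
        raise ValueError("labels and groups must cover every cell")
    n_groups = groups.nunique()
    if n_folds > n_groups:
        raise ValueError(
            f"n_folds={n_folds} exceeds the number of groups ({n_groups})"
        )
    classes = sorted(labels.unique())
    x = m.values.to_numpy(dtype=float)
    y = labels.to_numpy()

    params = dict(
        objective="multiclass" if len(classes) > 2 else "binary",
        num_class=len(classes) if len(classes) > 2 else None,
        reg_alpha=reg_l1,
        reg_lambda=reg_l2,
        n_estimators=200,
        random_state=seed,
        verbose=-1,
    )
    params = {k: v for k, v in params.items() if v is not None}
    params.update(lgbm_params)

    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    for fold_id, (train_idx, _) in enumerate(splitter.split(x, y, groups)):
        present = set(y[train_idx])
        absent = sorted(set(classes) - present)
        if absent:
            raise ValueError(
                f"classes {absent} absent from the training split of fold {fold_id}"
            )
        fit_idx, val_idx = train_test_split(
            train_idx, test_size=0.25, random_state=seed,
            stratify=y[train_idx],
        )
        model = lgb.LGBMClassifier(**params)
        model.fit(
            x[fit_idx], y[fit_idx],
            eval_set=[(x[val_idx], y[val_idx])],
            callbacks=[lgb.early_stopping(10, verbose=False)],
        )
        importances = model.booster_.feature_importance(
            importance_type="split", iteration=model.best_iteration_
        )
        per_fold.append(pd.Series(importances, index=m.values.columns))
    fi = pd.DataFrame(per_fold)
    stable = fi.columns[(fi > 0).all(axis=0)]
    median_fi = fi.median(axis=0).sort_values(ascending=False, kind="stable")
    return SelectionReport(
        "gbdt",
        tuple(sorted(stable)),
        median_fi,
        {"n_folds": n_folds, "reg_l1": reg_l1, "reg_l2": reg_l2, "seed": seed},
    )


def ovr_metrics(true_labels, predicted_scores: pd.DataFrame) -> dict:
    """One-versus-rest ROC-AUC and average precision, per class and averaged.

    Returns per-class AUC/AP, their macro-averaged AUC, and the micro-
    averaged AP (computed over the pooled binary indicator matrix).
    """
    from sklearn.metrics import average_precision_score, roc_auc_score
    from sklearn.preprocessing import label_binarize

    true_labels = pd.Series(true_labels).astype(str)
    classes = sorted(true_labels.unique())
    if len(classes) < 2:
        raise ValueError("OvR metrics need at least 2 classes")
    missing = [c for c in classes if c not in predicted_scores.columns]
    if missing:
        raise KeyError(f"no score column for classes: {missing}")
    y_bin = label_binarize(true_labels, classes=classes)
    if y_bin.shape[1] == 1:  # binary case: one indicator column per class
        y_bin = np.hstack([1 - y_bin, y_bin])
    scores = predicted_scores[classes].to_numpy(dtype=float)
    auc = {c: float(roc_auc_score(y_bin[:, i], scores[:, i]))
           for i, c in enumerate(classes)}
    ap = {c: float(average_precision_score(y_bin[:, i], scores[:, i]))
          for i, c in enumerate(classes)}
    return {
        "auc": auc,
        "ap": ap,
        "macro_auc": float(np.mean(list(auc.values()))),
        "micro_ap": float(average_precision_score(y_bin, scores, average="micro")),
    }
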