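"""Cell-class formation: factor scores, k-means with silhouette-based k,
and partition-agreement utilities."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import Partition
from .features import FactorModel
from .io import ExpressionMatrix

__all__ = [
    "ClusteringReport",
    "factor_scores",
    "kmeans_select",
    "categorical_entropy",
    "partition_agreement",
]


def factor_scores(model: FactorModel, m: ExpressionMatrix) -> pd.DataFrame:
    """Regression-method (Thurstone) factor scores on standardized variables.

    Scores are ``Z R⁻¹ S`` where Z standardizes the model variables with the
    matrix's own moments, R is their observed correlation matrix, and
    S = Λ Φ is the structure matrix of the (possibly oblique) rotation.
    """
    if model.n_factors < 1 or not model.variables:
        raise ValueError("empty factor model")
    missing = [v for v in model.variables if v not in m.values.columns]
    if missing:
        raise KeyError(f"model variables not in matrix: {missing}")
    sub = m.values[model.variables].to_numpy(dtype=float)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [v for v, s in zip(model.variables, sd) if s == 0]
        raise ValueError(f"zero-variance variables: {bad}")
    z = (sub - mu) / sd
    r = np.corrcoef(z, rowvar=False)
    if r.ndim == 0:  # single variable
        r = np.array([[1.0]])
    structure = model.loadings.to_numpy() @ model.phi
    weights = np.linalg.solve(r, structure)
    return pd.DataFrame(z @ weights, index=m.values.index,
                        columns=model.loadings.columns)


@dataclass
class ClusteringReport:
    """Diagnostics over a k range plus the chosen partition."""

    k_range: list
    mean_silhouette: dict
    sd_silhouette: dict
    inertia: dict
    inertia_diff: dict
    size_entropy: dict
    chosen_k: int
    labels: Partition

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "mean_silhouette": {str(k): v for k, v in self.mean_silhouette.items()},
            "sd_silhouette": {str(k): v for k, v in self.sd_silhouette.items()},
            "inertia": {str(k): v for k, v in self.inertia.items()},
            "inertia_diff": {str(k): v for k, v in self.inertia_diff.items()},
            "size_entropy": {str(k): v for k, v in self.size_entropy.items()},
            "chosen_k": self.chosen_k,
            "labels": dict(self.labels.assignment),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def categorical_entropy(labels) -> float:
    """Entropy (nats) of the cluster-size distribution."""
    labels = pd.Series(list(labels))
    if labels.empty:
        raise ValueError("entropy of an empty labeling is undefined")
    p = labels.value_counts(normalize=True).to_numpy()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() + 0.0)


def kmeans_select(
    scores: pd.DataFrame,
    k_range=range(2, 16),
    seed: int = 0,
    n_init: int = 10,
    dataset_id: str = "dataset",
) -> ClusteringReport:
    """k-means over *k_range*, choosing k by the mean silhouette coefficient.

    The SD of the silhouette, the entropy of the cluster-size distribution,
    and inertia (with successive differences) are reported as imbalance and
    elbow diagnostics but never used for selection; silhouette ties break
    toward the smaller k.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_samples

    x = np.asarray(scores, dtype=float)
    n = x.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if np.unique(x, axis=0).shape[0] < 2:
        raise ValueError("silhouette undefined: all points identical")

    mean_sil, sd_sil, inertia, entropy, labelings = {}, {}, {}, {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(x)
        sil = silhouette_samples(x, lab)
        mean_sil[k] = float(sil.mean())
        sd_sil[k] = float(sil.std(ddof=0))
        inertia[k] = float(km.inertia_)
        entropy[k] = categorical_entropy(lab)
        labelings[k] = lab
    inertia_diff = {
        k2: inertia[k1] - inertia[k2]
        for k1, k2 in zip(k_range[:-1], k_range[1:])
    }
    chosen_k = min(k_range, key=lambda k: (-mean_sil[k], k))
    assignment = {
        str(cid): str(int(lab))
        for cid, lab in zip(scores.index, labelings[chosen_k])
    }
    return ClusteringReport(
        k_range=k_range,
        mean_silhouette=mean_sil,
        sd_silhouette=sd_sil,
        inertia=inertia,
        inertia_diff=inertia_diff,
        size_entropy=entropy,
        chosen_k=chosen_k,
        labels=Partition(dataset_id, assignment),
    )


def partition_agreement(a: Partition, b: Partition) -> tuple:
    """Adjusted Rand index and adjusted mutual information of two partitions."""
    from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

    cells_a, cells_b = set(a.assignment), set(b.assignment)
    if cells_a != cells_b:
        raise ValueError("partitions cover different cell sets")
    order = sorted(cells_a)
    la = [a.assignment[c] for c in order]
    lb = [b.assignment[c] for c in order]
    return (
        float(adjusted_rand_score(la, lb)),
        float(adjusted_mutual_info_score(la, lb)),
    )
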