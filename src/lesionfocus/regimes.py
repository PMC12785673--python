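"""Explanation-regime analysis: standardize → PCA(3) → k-means in PC1–PC2.

XAI records (one per slice × class × mode) are standardized, projected
onto three principal components, and clustered with k-means (k = 3) in
the PC1–PC2 plane.  Clusters are then given data-driven regime names by a
deterministic rule on their feature means:

* the cluster with the highest mean APIL20 → ``peri_lesion`` (attribution
  hugging the lesion rim, relatively low leakage);
* of the remainder, the higher mean ARIL20 → ``retina_dominant``
  (diffuse intra-retinal focus near, but not on, the lesion);
* the rest → ``narrow_coverage`` (small off-lesion focus missing most of
  the lesion).  With only two non-empty clusters this regime is absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "DEFAULT_FEATURES",
    "RegimeModel",
    "standardize_features",
    "pca3",
    "kmeans_pc12",
    "label_regimes",
    "cluster_summary",
    "regime_prevalence",
    "fit_regimes",
]

#: Feature columns entering the factor analysis.
DEFAULT_FEATURES = (
    "APIL20", "Dice20", "Leak20", "ARIL20", "FP", "LP", "PAM", "FC", "COM_dist",
)

REGIME_NAMES = ("retina_dominant", "peri_lesion", "narrow_coverage")


def standardize_features(
    table: pd.DataFrame, features: Sequence[str] = DEFAULT_FEATURES
) -> tuple[pd.DataFrame, dict]:
    """Zero-mean unit-variance scaling (population SD) per feature.

    Rows with undefined entries (e.g. FC when APIL20 = 0) are excluded;
    constant features are guarded to zeros.  Returns the scaled table
    (original index preserved) and the fitted parameters.
    """
    sub = table.loc[:, list(features)].astype(float)
    keep = sub.notna().all(axis=1)
    sub = sub.loc[keep]
    if len(sub) < 2:
        raise ValueError("need at least 2 complete rows to standardize")
    scaler = StandardScaler()
    scaled = scaler.fit_transform(sub.values)
    scaled = np.where(scaler.scale_[None, :] > 1e-12, scaled, 0.0)
    params = {
        "features": tuple(features),
        "mean": scaler.mean_.copy(),
        "scale": scaler.scale_.copy(),
        "n_dropped": int((~keep).sum()),
    }
    return pd.DataFrame(scaled, index=sub.index, columns=features), params


def pca3(scaled: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Three-component PCA with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive.  Returns ``(loadings, scores, explained_variance_ratio)``
    where loadings has shape (k, n_features), k = min(3, rank).
    """
    if len(scaled) < 3:
        raise ValueError("need at least 3 rows for a 3-component PCA")
    k = min(3, min(scaled.shape))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(scaled.values)
    loadings = pca.components_.copy()
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    cols = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    return loadings, pd.DataFrame(scores, index=scaled.index, columns=cols), (
        pca.explained_variance_ratio_.copy()
    )


def kmeans_pc12(
    scores: pd.DataFrame, k: int = 3, seed: int = 42
) -> tuple[pd.Series, np.ndarray]:
    """Lloyd k-means (k-means++ init, 10 restarts) on the PC1–PC2 plane."""
    if len(scores) < k:
        raise ValueError(f"need at least {k} rows for k={k}")
    pts = scores[["PC1", "PC2"]].values
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assignments = km.fit_predict(pts)
    return pd.Series(assignments, index=scores.index, name="cluster"), (
        km.cluster_centers_.copy()
    )


def label_regimes(cluster_means: pd.DataFrame) -> dict[int, str]:
    """Map cluster ids to regime names from their APIL20/ARIL20 means.

    Requires columns APIL20, ARIL20 and (for tie-breaks) COM_dist, indexed
    by cluster id; accepts 2 or 3 non-empty clusters.
    """
    ids = list(cluster_means.index)
    if not 2 <= len(ids) <= 3:
        raise ValueError("expected 2 or 3 non-empty clusters")
    means = cluster_means.copy()
    pl = means["APIL20"].idxmax()
    rest = means.drop(index=pl)
    # higher ARIL20 wins retina_dominant; ties resolve to lower COM-dist
    order = rest.sort_values(
        by=["ARIL20", "COM_dist"], ascending=[False, True]
    ).index
    mapping = {int(pl): "peri_lesion", int(order[0]): "retina_dominant"}
    if len(order) > 1:
        mapping[int(order[1])] = "narrow_coverage"
    return mapping


def cluster_summary(
    table: pd.DataFrame,
    assignments: pd.Series,
    features: Sequence[str] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Per-cluster n and feature means (FC averaged over defined rows)."""
    df = table.loc[assignments.index].copy()
    df["cluster"] = assignments
    rows = []
    for cid, g in df.groupby("cluster"):
        row: dict[str, object] = {"cluster": int(cid), "n": len(g)}
        for f in features:
            row[f] = float(g[f].mean(skipna=True))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster").sort_index()


def regime_prevalence(
    assignments: pd.Series, labels: dict[int, str]
) -> dict[str, float]:
    """Percentage share of records per regime, one decimal place."""
    n = len(assignments)
    counts = assignments.map(labels).value_counts()
    out = {name: 0.0 for name in REGIME_NAMES if name in labels.values()}
    for name, c in counts.items():
        out[name] = round(100.0 * c / n, 1)
    return out


@dataclass
class RegimeModel:
    """Fitted regime analysis: scaler parameters, PCA loadings and
    explained-variance shares, k-means centroids in PC1–PC2, the
    cluster→regime map, and the per-row outputs."""

    features: tuple[str, ...]
    scaler_params: dict
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    centroids: np.ndarray
    labels: dict[int, str]
    scores: pd.DataFrame
    assignments: pd.Series
    summary: pd.DataFrame
    prevalence: dict[str, float]

    def regime_of(self) -> pd.Series:
        return self.assignments.map(self.labels)


def fit_regimes(
    table: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
    k: int = 3,
    seed: int = 42,
) -> RegimeModel:
    """Run the full standardize → PCA(3) → k-means → label pipeline."""
    scaled, params = standardize_features(table, features)
    loadings, scores, evr = pca3(scaled)
    assignments, centroids = kmeans_pc12(scores, k=k, seed=seed)
    summary = cluster_summary(table, assignments, features)
    labels = label_regimes(summary)
    prevalence = regime_prevalence(assignments, labels)
    return RegimeModel(
        features=tuple(features),
        scaler_params=params,
        loadings=loadings,
        explained_variance_ratio=evr,
        centroids=centroids,
        labels=labels,
        scores=scores,
        assignments=assignments,
        summary=summary,
        prevalence=prevalence,
    )
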