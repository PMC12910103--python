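"""K-means seascape classification with silhouette-width selection of k.

The cluster unit defaults to the calendar day: matched dual-frequency layer
descriptors are aggregated per day (plus mean position), z-scored per column,
and partitioned by K-means; the number of clusters is the k in a configured
range maximising the mean silhouette width (ties broken toward the smallest
k, for parsimony).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io import ValidationError
from .layers import SSLayer

logger = logging.getLogger("sslseascape")

DESCRIPTOR_COLUMNS = [
    "min_depth_18", "max_depth_18", "width_18", "mean_sv_18",
    "min_depth_38", "max_depth_38", "width_38", "mean_sv_38",
    "lon", "lat",
]


def build_descriptor_matrix(
    layers18: list[SSLayer],
    layers38: list[SSLayer],
    pairs: list[tuple[int, int, float]],
    unit: str = "per_day",
) -> pd.DataFrame:
    """Descriptor matrix of cluster units from matched dual-frequency layers.

    One row per matched pair (``per_layer``) or per calendar day
    (``per_day``).  Daily aggregates are cell-count-weighted means over the
    day's matched pairs, so a day's profile is set by its major layers rather
    than by near-threshold scraps.  Columns are min/max depth, width and mean
    Sv at each frequency plus mean lon/lat.  Rows with any missing descriptor
    are dropped with a log message.
    """
    if not pairs:
        raise ValidationError("no matched layer pairs")
    rows = []
    for i, j, _ in pairs:
        a, b = layers18[i], layers38[j]
        rows.append(
            {
                "date": a.date,
                "min_depth_18": a.min_depth, "max_depth_18": a.max_depth,
                "width_18": a.width, "mean_sv_18": a.mean_sv,
                "min_depth_38": b.min_depth, "max_depth_38": b.max_depth,
                "width_38": b.width, "mean_sv_38": b.mean_sv,
                "lon": (a.lon + b.lon) / 2.0, "lat": (a.lat + b.lat) / 2.0,
                "weight": float(a.n_cells + b.n_cells),
            }
        )
    df = pd.DataFrame(rows)
    if unit == "per_day":
        def _wmean(g: pd.DataFrame) -> pd.Series:
            w = g["weight"] / g["weight"].sum()
            return pd.Series({c: float((g[c] * w).sum()) for c in DESCRIPTOR_COLUMNS})

        df = df.groupby("date").apply(_wmean, include_groups=False).reset_index()
    elif unit == "per_layer":
        df = df.drop(columns="weight")
    else:
        raise ValidationError("unit must be per_day or per_layer")
    n0 = len(df)
    df = df.dropna(subset=DESCRIPTOR_COLUMNS).reset_index(drop=True)
    if len(df) < n0:
        logger.info("build_descriptor_matrix: dropped %d row(s) with missing descriptors", n0 - len(df))
    if len(df) < 2:
        raise ValidationError("need at least 2 cluster units")
    return df


def standardize(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Column-wise z-score; constant columns raise (degenerate for clustering)."""
    arr = np.asarray(X, dtype=float)
    sd = arr.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValidationError("standardize: constant descriptor column")
    return (arr - arr.mean(axis=0)) / sd


def kmeans_cluster(
    X: np.ndarray, k: int, seed: int = 0, n_init: int = 20
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` K-means (k-means++ seeding, Lloyd iterations).

    Returns 0-based labels, centroids and inertia; deterministic for a fixed
    seed.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if X.shape[0] <= k:
        raise ValidationError("need more rows than clusters")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd", tol=1e-6, max_iter=300)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_, float(km.inertia_)


def select_k_silhouette(
    X: np.ndarray, k_range: tuple[int, int] = (2, 8), seed: int = 0, n_init: int = 20
) -> tuple[int, dict[int, float]]:
    """Choose k maximising mean silhouette width over ``k_range``.

    The usable range is clipped to k <= n_rows - 1 (silhouette is undefined
    beyond); ties break toward the smallest k.
    """
    X = np.asarray(X, dtype=float)
    if np.allclose(X, X[0]):
        raise ValidationError("degenerate matrix: all rows equal")
    kmin, kmax = k_range
    kmax_eff = min(kmax, X.shape[0] - 1)
    if kmax_eff < kmin:
        raise ValidationError(f"too few rows ({X.shape[0]}) for k_range {k_range}")
    if kmax_eff < kmax:
        logger.info("select_k_silhouette: k range clipped to (%d, %d) by sample size", kmin, kmax_eff)
    silhouette_by_k: dict[int, float] = {}
    for k in range(kmin, kmax_eff + 1):
        labels, _, _ = kmeans_cluster(X, k, seed=seed, n_init=n_init)
        if len(np.unique(labels)) < 2:
            silhouette_by_k[k] = -1.0
            continue
        silhouette_by_k[k] = float(silhouette_score(X, labels, metric="euclidean"))
    k_star = max(sorted(silhouette_by_k), key=lambda k: (silhouette_by_k[k], -k))
    return k_star, silhouette_by_k


def summarize_clusters(labels: np.ndarray, raw: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster five-number summaries of each raw descriptor.

    Returns one row per (cluster, descriptor) with min, Q1, median, Q3, max
    and the count of Tukey outliers (beyond 1.5 IQR from the quartiles).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("no cluster labels")
    rows = []
    for lab in np.unique(labels):
        sub = raw.loc[labels == lab]
        if sub.empty:
            raise ValidationError(f"empty cluster {lab}")
        for col in raw.columns:
            v = sub[col].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            outliers = int(np.sum((v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)))
            rows.append(
                {
                    "cluster": int(lab), "descriptor": col,
                    "min": float(v.min()), "q1": float(q1), "median": float(med),
                    "q3": float(q3), "max": float(v.max()), "n_outliers": outliers,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SeascapeClassification:
    """Full clustering result: matrix, silhouette curve, labels and summaries."""

    descriptor_frame: pd.DataFrame  # raw descriptors per unit
    X: np.ndarray  # standardized matrix
    k_selected: int
    labels: np.ndarray  # 1-based cluster labels
    centroids: np.ndarray  # standardized space
    silhouette_by_k: dict[int, float]
    summaries: pd.DataFrame = field(default=None)


def classify_seascapes(
    frame: pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_init: int = 20,
    columns: list[str] | None = None,
) -> SeascapeClassification:
    """End-to-end: standardize, select k by silhouette, cluster, summarize."""
    cols = columns or [c for c in DESCRIPTOR_COLUMNS if c in frame.columns]
    X = standardize(frame[cols])
    k_star, sil = select_k_silhouette(X, k_range, seed=seed, n_init=n_init)
    labels0, centroids, _ = kmeans_cluster(X, k_star, seed=seed, n_init=n_init)
    labels = labels0 + 1
    summaries = summarize_clusters(labels, frame[cols])
    return SeascapeClassification(
        descriptor_frame=frame,
        X=X,
        k_selected=k_star,
        labels=labels,
        centroids=centroids,
        silhouette_by_k=sil,
        summaries=summaries,
    )
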