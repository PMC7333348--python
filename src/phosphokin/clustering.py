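"""Max-scaled kinetics, t-SNE embedding, and density-peak clustering.

Regulated-site kinetics are summarized as condition means of linear
intensities scaled by the maximum over the time course, embedded in 2D
with t-SNE, and clustered by local density maxima (Rodriguez-Laio
decision-graph style): cluster centers are points that combine high
local density rho with a large distance delta to any denser point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .core import KineticsMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "scale_kinetics",
    "embed_2d",
    "density_peak_cluster",
    "cluster_summaries",
    "ClusterMap",
]


def scale_kinetics(
    matrix: KineticsMatrix, site_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-site condition means of linear intensities, scaled by their max.

    ``matrix`` must be imputed (and normally replicate-normalized) so
    that condition means are computable; values are exponentiated back
    to the linear scale before averaging and scaling, so every scaled
    kinetic lies in (0, 1] with its maximum exactly 1.
    """
    if site_ids is not None:
        matrix = matrix.subset(site_ids)
    arr, reps, conds, _ = matrix.to_array()
    linear = np.power(2.0, arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(linear, axis=1)  # (site, cond)
    if not np.isfinite(means).all():
        raise ValueError("condition means not computable for every condition")
    if (means <= 0).any():
        raise ValueError("nonpositive mean intensity; scale expects linear values")
    scaled = means / means.max(axis=1, keepdims=True)
    return pd.DataFrame(scaled, index=matrix.data.index, columns=conds)


def embed_2d(scaled: pd.DataFrame, seed: int, perplexity: float = 30.0) -> pd.DataFrame:
    """Deterministic (seeded) t-SNE embedding of scaled kinetics."""
    n = len(scaled)
    if n < 3 * perplexity + 1:
        raise ValueError(
            f"{n} sites is too few for perplexity {perplexity}; "
            "use a smaller perplexity"
        )
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        learning_rate="auto",
    )
    xy = ts.fit_transform(scaled.to_numpy(dtype=float))
    return pd.DataFrame(xy, index=scaled.index, columns=["x", "y"])


@dataclass
class ClusterMap:
    """Density-peak clustering diagnostics and labels.

    ``table`` has columns x, y, rho (Gaussian-kernel local density),
    delta (distance to the nearest denser point; the global density
    maximum gets the maximum pairwise distance), nearest_higher (row
    position of that point, -1 for the global maximum), cluster
    (0-based), is_center.
    """

    table: pd.DataFrame
    dc: float

    @property
    def labels(self) -> pd.Series:
        return self.table["cluster"]

    @property
    def n_clusters(self) -> int:
        return int(self.table["cluster"].nunique())


def density_peak_cluster(
    coords: pd.DataFrame,
    dc_quantile: float = 0.02,
    center_sd: float = 1.5,
) -> ClusterMap:
    """Cluster 2D points by local density maxima.

    rho_i = sum_{j != i} exp(-(d_ij / d_c)^2) with d_c the
    ``dc_quantile`` quantile of all pairwise distances. Centers are
    points whose gamma = rho * delta exceeds mean + ``center_sd`` sd of
    gamma (at least one center — the gamma maximum — is always chosen);
    remaining points are assigned, in order of decreasing density, to
    the cluster of their nearest denser neighbor.
    """
    if len(coords) < 2:
        raise ValueError("need at least 2 points to cluster")
    X = coords[["x", "y"]].to_numpy(dtype=float)
    n = len(X)
    cond = pdist(X)
    D = squareform(cond)
    dc = float(np.quantile(cond, dc_quantile))
    if dc <= 0:
        logger.warning("degenerate distances (dc = 0); treating as one cluster")
        dc = 1e-12
    rho = np.exp(-((D / dc) ** 2)).sum(axis=1) - 1.0
    # strict density ordering with index tie-break
    order = np.lexsort((np.arange(n), -rho))  # descending rho
    delta = np.empty(n)
    nearest = np.full(n, -1, dtype=int)
    dmax = float(cond.max())
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = dmax
            continue
        higher = order[:pos]
        j = higher[np.argmin(D[i, higher])]
        delta[i] = D[i, j]
        nearest[i] = j
    gamma = rho * delta
    thr = gamma.mean() + center_sd * gamma.std()
    centers = np.where(gamma > thr)[0]
    if centers.size == 0:
        centers = np.array([int(np.argmax(gamma))])
    centers = centers[np.argsort(-gamma[centers])]  # ties: larger gamma first
    labels = np.full(n, -1, dtype=int)
    for ci, c in enumerate(centers):
        labels[c] = ci
    for i in order:
        if labels[i] == -1:
            labels[i] = labels[nearest[i]]
    table = pd.DataFrame(
        {
            "x": X[:, 0],
            "y": X[:, 1],
            "rho": rho,
            "delta": delta,
            "nearest_higher": nearest,
            "cluster": labels,
            "is_center": np.isin(np.arange(n), centers),
        },
        index=coords.index,
    )
    return ClusterMap(table=table, dc=dc)


def cluster_summaries(cmap: ClusterMap, scaled: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster size and mean scaled kinetic, ordered C1, C2, ...

    Up-regulated clusters (kinetic peak after t = 0) come first, by time
    of maximum and then by persistence (value at the last time point
    relative to the peak, transients first); dephosphorylation clusters
    (peak at t = 0) follow.
    """
    conds = list(scaled.columns)
    rows = []
    for label, idx in cmap.table.groupby("cluster").groups.items():
        mean = scaled.loc[idx].mean(axis=0)
        peak_ix = int(np.argmax(mean.to_numpy()))
        rows.append(
            {
                "cluster": label,
                "size": len(idx),
                "peak_time": conds[peak_ix],
                "persistence": float(mean.iloc[-1] / mean.max()),
                "is_down": peak_ix == 0,
                **{f"mean[{c}]": float(mean[c]) for c in conds},
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["is_down", "peak_time", "persistence"]
    ).reset_index(drop=True)
    df.insert(0, "name", [f"C{i + 1}" for i in range(len(df))])
    return df
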