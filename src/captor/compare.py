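"""Cross-cell-type comparison of promoter interactomes.

Significant interactions from several cell types are assembled into a
peak matrix (union of interactions significant in at least one type,
asinh-transformed scores), clustered with a BIC-selected Gaussian mixture
(a reproducible stand-in for legacy Bayesian mixture clustering of the
same model family), summarized by per-cluster cell-type specificity
scores, and ordinated at the sample level by PCA and average-linkage
hierarchical clustering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

__all__ = [
    "build_peak_matrix",
    "cluster_interactions",
    "specificity_scores",
    "compare_samples",
]

EPS = 1e-8


def build_peak_matrix(
    calls: dict[str, pd.DataFrame], score_threshold: float = 5.0
) -> pd.DataFrame:
    """Union peak matrix of asinh(score) over interactions significant somewhere.

    Rows are keyed ``bait:otherEnd``; columns are cell types; a score
    missing in a cell type is 0 before the asinh transform.
    """
    cols = {}
    sig_rows = set()
    for ct, df in calls.items():
        key = df["bait_id"].astype(str) + ":" + df["otherend_id"].astype(str)
        s = pd.Series(df["score"].to_numpy(), index=key)
        s = s.groupby(level=0).max()
        cols[ct] = s
        sig_rows.update(s.index[s >= score_threshold])
    if not sig_rows:
        raise ValueError("no interaction significant in any cell type")
    pm = pd.DataFrame(index=sorted(sig_rows))
    for ct, s in cols.items():
        pm[ct] = s.reindex(pm.index).fillna(0.0)
    return np.arcsinh(pm)


def cluster_interactions(
    pm: pd.DataFrame,
    n_clusters: int | None = None,
    k_max: int = 12,
    seed: int = 0,
) -> pd.Series:
    """Cluster peak-matrix rows with a Gaussian mixture.

    When ``n_clusters`` is None the number of components is chosen by BIC
    over 1..k_max.  Deterministic given ``seed``.
    """
    X = pm.to_numpy()
    if len(X) == 0:
        raise ValueError("empty peak matrix")
    if n_clusters is not None and len(X) < n_clusters:
        raise ValueError("fewer rows than requested clusters")
    if np.allclose(X, X[0], atol=1e-12):
        warnings.warn("all rows identical: returning a single cluster")
        return pd.Series(np.zeros(len(X), dtype=int), index=pm.index)
    if n_clusters is None:
        best, best_bic = 1, np.inf
        for k in range(1, min(k_max, len(X)) + 1):
            gm = GaussianMixture(
                n_components=k, covariance_type="diag", random_state=seed,
                reg_covar=1e-4,
            ).fit(X)
            bic = gm.bic(X)
            if bic < best_bic - 1e-9:
                best, best_bic = k, bic
        n_clusters = best
    gm = GaussianMixture(
        n_components=n_clusters, covariance_type="diag", random_state=seed,
        reg_covar=1e-4,
    ).fit(X)
    return pd.Series(gm.predict(X), index=pm.index)


def specificity_scores(pm: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Per-cluster, per-cell-type specificity of interaction scores.

    specificity(c, t) = (mean of cluster c in type t - cluster mean over
    types) / (sd over types + eps).  Rows are centered across types.
    """
    means = pm.groupby(clusters.reindex(pm.index)).mean()
    centered = means.sub(means.mean(axis=1), axis=0)
    return centered.div(means.std(axis=1, ddof=0) + EPS, axis=0)


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    l = _newick(node.get_left(), labels)
    r = _newick(node.get_right(), labels)
    dl = max(node.dist - node.get_left().dist, 0.0)
    dr = max(node.dist - node.get_right().dist, 0.0)
    return f"({l}:{dl:.6g},{r}:{dr:.6g})"


def compare_samples(pm: pd.DataFrame) -> dict:
    """Sample-level ordination of the peak matrix columns.

    Returns PCA coordinates and variance shares of the cell types
    (centered rows-as-features), the average-linkage Euclidean linkage
    matrix and its newick serialization.
    """
    if pm.shape[1] < 2:
        raise ValueError("need at least two cell types")
    X = pm.to_numpy().T  # samples x features
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    result = {
        "pca_coords": pd.DataFrame(
            coords, index=pm.columns,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
    d = pdist(X, metric="euclidean")
    Z = average(d)
    result["linkage"] = Z
    tree = to_tree(Z)
    result["newick"] = _newick(tree, list(pm.columns)) + ";"
    return result
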