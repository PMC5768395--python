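"""Two-way unsupervised hierarchical clustering of the site-level matrix.

Methylation proportions are log10-transformed (with a pseudocount guarding
zeros), pairwise distances are computed between samples and — on the
transpose — between sites, and both are clustered agglomeratively with
average linkage (UPGMA).  Cutting the sample dendrogram at its top merge
yields two clusters; the one holding the majority of normal samples is
labelled ``N-like``, the other ``T-like``.

Distances are Bray-Curtis by default (the community-ecology dissimilarity,
applied here to the log-scale profiles) with Euclidean as the alternative.
Missing entries are handled by pairwise-complete computation: each pair of
profiles is compared over the features both observe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator

from .errors import DataError
from .io import MethylationMatrix, SampleMeta

DISTANCES = ("braycurtis", "euclidean")


def _pairwise_complete(X: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance vector over rows, ignoring unshared missing entries."""
    n = X.shape[0]
    out = np.empty(n * (n - 1) // 2)
    idx = 0
    observed = ~np.isnan(X)
    for i in range(n - 1):
        xi = X[i]
        rest = X[i + 1:]
        shared = observed[i] & observed[i + 1:]
        diff = np.abs(xi - rest)
        if metric == "euclidean":
            d = np.sqrt(np.nansum(np.where(shared, diff ** 2, 0.0), axis=1))
        else:  # braycurtis
            num = np.nansum(np.where(shared, diff, 0.0), axis=1)
            den = np.nansum(np.where(shared, np.abs(xi + rest), 0.0), axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(den > 0, num / den, 0.0)
        if not shared.any(axis=1).all():
            raise DataError("a pair of profiles shares no observed feature")
        out[idx: idx + len(d)] = d
        idx += len(d)
    return out


@dataclass
class ClusterResult:
    sample_linkage: np.ndarray
    site_linkage: np.ndarray
    labels: pd.Series            # sample -> {"N-like", "T-like"}
    sample_order: list[str]
    site_order: list[str]
    distance: str
    pseudocount: float


class TwoWayCluster(BaseEstimator):
    """Average-linkage two-way clustering of log10 methylation.

    Parameters
    ----------
    distance : "braycurtis" (default) or "euclidean"
    linkage : linkage method, default ``average`` (UPGMA)
    pseudocount : added before log10; default 0.005, half the 1% detection
        floor of the melting assay, so fully unmethylated entries stay finite.

    Attributes (after fit)
    ----------------------
    sample_linkage_, site_linkage_ : scipy linkage matrices
    labels_ : ndarray of two-cluster memberships (1/2) per sample
    """

    def __init__(self, distance: str = "braycurtis", linkage: str = "average",
                 pseudocount: float = 0.005):
        self.distance = distance
        self.linkage = linkage
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        df = X.data if isinstance(X, MethylationMatrix) else pd.DataFrame(X)
        if df.shape[0] < 3:
            raise DataError("need at least 3 samples to cluster")
        if (df < 0).any().any():
            raise DataError("negative methylation values")
        if self.distance not in DISTANCES:
            raise ValueError(f"distance must be one of {DISTANCES}")
        if df.isna().all(axis=1).any() or df.isna().all(axis=0).any():
            raise DataError("all-missing sample or site profile")
        L = np.log10(df.to_numpy(dtype=float) + self.pseudocount)
        self.sample_linkage_ = hierarchy.linkage(
            _pairwise_complete(L, self.distance), method=self.linkage)
        self.site_linkage_ = hierarchy.linkage(
            _pairwise_complete(L.T, self.distance), method=self.linkage)
        self.labels_ = hierarchy.fcluster(self.sample_linkage_, 2,
                                          criterion="maxclust")
        self.feature_names_in_ = np.asarray(df.columns)
        self.sample_ids_ = list(df.index)
        return self


def cluster_two_way(
    matrix, meta: SampleMeta, distance: str = "braycurtis",
    linkage: str = "average", pseudocount: float = 0.005,
) -> ClusterResult:
    """Cluster samples and sites; name the two sample clusters N-like/T-like.

    The cluster containing the majority of the normal samples becomes
    ``N-like`` (ties resolve to the cluster with the higher fraction of
    normals, then to cluster 1).
    """
    est = TwoWayCluster(distance=distance, linkage=linkage,
                        pseudocount=pseudocount).fit(matrix)
    cls = meta.classes_for(est.sample_ids_)
    n_normal = {c: int(((est.labels_ == c) & (cls == "normal").to_numpy()).sum())
                for c in (1, 2)}
    size = {c: int((est.labels_ == c).sum()) for c in (1, 2)}
    frac = {c: n_normal[c] / size[c] if size[c] else 0.0 for c in (1, 2)}
    n_like = 1 if (n_normal[1], frac[1], -1) >= (n_normal[2], frac[2], -2) else 2
    labels = pd.Series(
        np.where(est.labels_ == n_like, "N-like", "T-like"),
        index=pd.Index(est.sample_ids_, name="sample_id"), name="cluster",
    )
    sample_order = [est.sample_ids_[i]
                    for i in hierarchy.leaves_list(est.sample_linkage_)]
    site_order = [str(est.feature_names_in_[i])
                  for i in hierarchy.leaves_list(est.site_linkage_)]
    return ClusterResult(
        sample_linkage=est.sample_linkage_, site_linkage=est.site_linkage_,
        labels=labels, sample_order=sample_order, site_order=site_order,
        distance=distance, pseudocount=pseudocount,
    )


def cluster_purity(result: ClusterResult, meta: SampleMeta) -> tuple[pd.DataFrame, int]:
    """Per-cluster composition by class and stage, plus the misassignment count.

    A sample is misassigned when its class is the minority class of its
    cluster under the N-like/T-like naming (tumors in N-like, normals in
    T-like).
    """
    cls = meta.classes_for(result.labels.index)
    stage = meta.stages_for(result.labels.index)
    comp = (
        pd.DataFrame({"cluster": result.labels, "class": cls, "stage": stage})
        .groupby(["cluster", "class", "stage"], observed=True)
        .size().rename("count").reset_index()
    )
    mis = int(((result.labels == "N-like") & (cls == "tumor")).sum()
              + ((result.labels == "T-like") & (cls == "normal")).sum())
    return comp, mis


def plot_heatmap(matrix, result: ClusterResult, path) -> None:
    """Plain clustered heatmap + dendrogram ordering, for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.data if isinstance(matrix, MethylationMatrix) else pd.DataFrame(matrix)
    L = np.log10(df + result.pseudocount)
    ordered = L.loc[result.sample_order, result.site_order]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(ordered.to_numpy().T, aspect="auto", cmap="RdYlGn_r")
    ax.set_xlabel("samples (dendrogram order)")
    ax.set_ylabel("sites (dendrogram order)")
    fig.colorbar(im, ax=ax, label="log10 methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
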