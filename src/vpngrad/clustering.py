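"""Connectivity-based clustering of VPN cells and partner-correlation analysis.

Individual cells of one VPN type are clustered by the similarity of their
synaptic output profiles: partners receiving fewer than 50 synapses from
the whole population are excluded (roughly one synapse per cell, the EM
reconstruction noise floor), within-type connections are removed, columns
are standardized to unit variance, and k-means is run on up to ten
principal components with k chosen from the within-cluster
sum-of-squares scree.  Between-partner similarity is quantified by the
pairwise Spearman correlation of per-cell synapse-count vectors over the
top 25 partners (300 unique pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted


def preprocess_matrix(
    matrix: pd.DataFrame,
    min_total: int = 50,
    self_type_ids=(),
) -> pd.DataFrame:
    """Filter and standardize a connectivity matrix for clustering.

    Drops partners with column total below ``min_total``, partners belonging
    to the VPN's own type, and constant columns (which cannot be scaled),
    then centers and scales the rest to unit variance across cells.
    """
    if matrix.empty:
        raise ValueError("empty connectivity matrix")
    keep = [c for c in matrix.columns if c not in set(self_type_ids)]
    sub = matrix[keep]
    sub = sub.loc[:, sub.sum(axis=0) >= min_total]
    sd = sub.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping constant partner columns: {list(sub.columns[constant])}", stacklevel=2
        )
        sub = sub.loc[:, ~constant]
        sd = sd[~constant]
    if sub.shape[1] == 0:
        raise ValueError("no partners survive threshold")
    return (sub - sub.mean(axis=0)) / sd


def select_k(wss_curve, rel_tol: float = 1e-3) -> int:
    """Pick k at the elbow of a within-cluster sum-of-squares curve.

    The elbow is the k maximizing the discrete second difference
    ``WSS(k-1) - 2 WSS(k) + WSS(k+1)``; a curve indistinguishable from
    linear (no structure) returns 1.
    """
    w = np.asarray(wss_curve, float)
    if len(w) < 3:
        raise ValueError("curve too short (need >= 3 points)")
    if np.any(np.diff(w) > 1e-9 * max(1.0, abs(w[0]))):
        raise ValueError("WSS curve must be non-increasing")
    sec = w[:-2] - 2 * w[1:-1] + w[2:]  # second difference at k = 2..K-1
    span = w.max() - w.min()
    if span == 0 or sec.max() <= rel_tol * span:
        return 1
    return int(np.argmax(sec)) + 2


@dataclass
class ClusterResult:
    labels: pd.Series
    k: int
    pca_scores: pd.DataFrame
    eigenvalues: np.ndarray
    wss_curve: np.ndarray
    degenerate: bool = False


class VPNClusterer(BaseEstimator, ClusterMixin):
    """Cluster VPN cells by output connectivity (PCA + k-means).

    Parameters
    ----------
    min_total : int
        Minimum population-total synapse count for a partner to be kept.
    self_type_ids : tuple
        Partner columns belonging to the VPN's own cell type (removed).
    max_pcs : int
        Upper bound on retained principal components; the actual number is
        the eigenvalue-scree elbow, capped here.
    k : int or None
        Number of clusters; ``None`` selects k from the WSS scree elbow.
    n_restarts : int
        k-means restarts (k-means++ initialization, best inertia kept).
    random_state : int
        Seed for k-means.

    Attributes
    ----------
    labels_ : ndarray
        Cluster label (1..k) per cell.
    k_ : int
        Number of clusters used.
    eigenvalues_ : ndarray
        PCA eigenvalue spectrum of the scaled matrix.
    wss_curve_ : ndarray
        Within-cluster sum of squares for k = 1..k_max.
    """

    def __init__(
        self,
        min_total: int = 50,
        self_type_ids=(),
        max_pcs: int = 10,
        k: int | None = None,
        k_max: int = 8,
        n_restarts: int = 25,
        random_state: int = 0,
    ):
        self.min_total = min_total
        self.self_type_ids = self_type_ids
        self.max_pcs = max_pcs
        self.k = k
        self.k_max = k_max
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if len(X) and bool((X.nunique(axis=0) <= 1).all()):
            # every cell has the same output profile: nothing to cluster
            warnings.warn("all cells have identical profiles; k forced to 1", stacklevel=2)
            self.degenerate_ = True
            self.k_ = 1
            self.cell_ids_ = X.index.to_numpy()
            self.partner_ids_ = X.columns.to_numpy()
            self.labels_ = np.ones(len(X), dtype=int)
            self.eigenvalues_ = np.zeros(1)
            self.wss_curve_ = np.zeros(1)
            self.scores_ = np.zeros((len(X), 1))
            return self
        scaled = preprocess_matrix(X, self.min_total, self.self_type_ids)
        self.cell_ids_ = scaled.index.to_numpy()
        self.partner_ids_ = scaled.columns.to_numpy()
        values = scaled.to_numpy(float)
        n_cells = values.shape[0]

        self.degenerate_ = bool(np.allclose(values, values[0]))
        if self.degenerate_:
            warnings.warn("all cells have identical scaled profiles; k forced to 1", stacklevel=2)
            self.k_ = 1
            self.labels_ = np.ones(n_cells, dtype=int)
            self.eigenvalues_ = np.zeros(1)
            self.wss_curve_ = np.zeros(1)
            self.scores_ = np.zeros((n_cells, 1))
            return self

        pca = PCA(random_state=self.random_state)
        scores = pca.fit_transform(values)
        self.eigenvalues_ = pca.explained_variance_
        if len(self.eigenvalues_) >= 3:
            pc_elbow = select_k(self.eigenvalues_)
            n_pcs = max(1, min(self.max_pcs, pc_elbow if pc_elbow > 1 else self.max_pcs))
        else:
            n_pcs = len(self.eigenvalues_)
        n_pcs = min(n_pcs, scores.shape[1])
        self.n_pcs_ = n_pcs
        self.scores_ = scores[:, :n_pcs]

        k_max = min(self.k_max, n_cells)
        wss = []
        fits = {}
        for kk in range(1, k_max + 1):
            with warnings.catch_warnings():
                # duplicate PCA scores can leave fewer distinct centres than k
                warnings.filterwarnings("ignore", category=ConvergenceWarning)
                km = KMeans(
                    n_clusters=kk,
                    n_init=self.n_restarts,
                    init="k-means++",
                    random_state=self.random_state,
                ).fit(self.scores_)
            wss.append(km.inertia_)
            fits[kk] = km
        self.wss_curve_ = np.minimum.accumulate(np.asarray(wss))

        if self.k is not None:
            if self.k > n_cells:
                raise ValueError(f"k={self.k} exceeds number of cells {n_cells}")
            self.k_ = self.k
        else:
            self.k_ = select_k(self.wss_curve_) if len(self.wss_curve_) >= 3 else 1
        self.labels_ = fits[self.k_].labels_ + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def result_(self) -> ClusterResult:
        check_is_fitted(self, "labels_")
        return ClusterResult(
            labels=pd.Series(self.labels_, index=self.cell_ids_, name="cluster"),
            k=self.k_,
            pca_scores=pd.DataFrame(self.scores_, index=self.cell_ids_),
            eigenvalues=self.eigenvalues_,
            wss_curve=self.wss_curve_,
            degenerate=self.degenerate_,
        )


def cluster_vpns(
    scaled_or_raw: pd.DataFrame,
    max_pcs: int = 10,
    k: int | None = None,
    seed: int = 0,
    **kwargs,
) -> ClusterResult:
    """Functional wrapper over :class:`VPNClusterer`."""
    est = VPNClusterer(max_pcs=max_pcs, k=k, random_state=seed, min_total=kwargs.pop("min_total", 0), **kwargs)
    est.fit(scaled_or_raw)
    return est.result_()


def partner_correlation_matrix(
    matrix: pd.DataFrame,
    top_n: int = 25,
    self_type_ids=(),
) -> tuple[pd.DataFrame, list]:
    """Pairwise Spearman correlation over the top-n partners' count vectors.

    Partners are ranked by population-total synapse count (own-type columns
    excluded).  For n = 25 partners this gives the 300 unique unordered
    pairs.  Constant count vectors have undefined rank correlation and are
    reported as NaN, never as 0.  The returned ordering comes from
    average-linkage hierarchical clustering of 1 - rho.
    """
    keep = [c for c in matrix.columns if c not in set(self_type_ids)]
    sub = matrix[keep]
    if sub.shape[1] < top_n:
        raise ValueError(f"need at least {top_n} partners, have {sub.shape[1]}")
    top = sub.sum(axis=0).sort_values(ascending=False).index[:top_n]
    sub = sub[top]
    # Spearman = Pearson on mid-ranks; constant columns stay NaN (undefined)
    corr = sub.rank(axis=0).corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)

    finite = ~corr.isna().any(axis=1)
    ordered = list(corr.index[~finite])
    sub_corr = corr.loc[finite, finite]
    if sub_corr.shape[0] >= 2:
        dist = squareform(np.clip(1.0 - sub_corr.to_numpy(), 0, 2), checks=False)
        order_idx = leaves_list(linkage(dist, method="average"))
        ordered = [sub_corr.index[i] for i in order_idx] + ordered
    else:
        ordered = list(corr.index)
    return corr, ordered


def synapse_cv(matrix: pd.DataFrame, min_total: int = 50) -> tuple[pd.Series, float]:
    """Coefficient of variation of synapse number per partner, and its mean.

    CV uses the population standard deviation over cells; partners making
    fewer than ``min_total`` synapses in total are excluded, and zero-mean
    columns (undefined CV) are dropped with a warning.
    """
    sub = matrix.loc[:, matrix.sum(axis=0) >= min_total]
    if sub.shape[1] == 0:
        raise ValueError("no partners survive threshold")
    mean = sub.mean(axis=0)
    zero = mean == 0
    if zero.any():
        warnings.warn(f"zero-mean partners excluded from CV: {list(sub.columns[zero])}", stacklevel=2)
        sub, mean = sub.loc[:, ~zero], mean[~zero]
    cv = sub.std(axis=0, ddof=0) / mean
    return cv, float(cv.mean())
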