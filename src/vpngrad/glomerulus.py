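"""Spatial organization of synapse sites inside an optic glomerulus.

For anticorrelated partner pairs, a max-margin linear classifier gives the
optimal plane separating the two partners' postsynaptic-site clouds; the
median of those planes is the unbiased separator for the whole VPN type.
Projections of each partner's sites onto the separator normal are compared
by the median-to-median distance and the two-sample Kolmogorov-Smirnov
statistic.  Further metrics: the correlation between per-cell axo-dendritic
overlap and synapse count, a quantitative axon-topography index, and
centroids normalized to the glomerulus axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp, rankdata, spearmanr
from sklearn.svm import SVC

from .io import GlomerulusSites


@dataclass
class SeparatingPlane:
    point: np.ndarray
    normal: np.ndarray  # unit

    @property
    def offset(self) -> float:
        return float(self.point @ self.normal)


@dataclass
class SeparationResult:
    pair: tuple
    plane: SeparatingPlane
    projections_a: np.ndarray
    projections_b: np.ndarray
    median_distance: float  # signed along the plane normal
    d_ks: float
    p_value: float


def _svm_plane(
    sites_a: np.ndarray, sites_b: np.ndarray, C: float = 1.0, max_fit_sites: int = 1000
) -> SeparatingPlane:
    # plane estimation scales poorly with cloud size; fit on a deterministic
    # subsample per class, project every site afterwards
    rng = np.random.default_rng(0)
    if len(sites_a) > max_fit_sites:
        sites_a = sites_a[rng.choice(len(sites_a), max_fit_sites, replace=False)]
    if len(sites_b) > max_fit_sites:
        sites_b = sites_b[rng.choice(len(sites_b), max_fit_sites, replace=False)]
    X = np.vstack([sites_a, sites_b])
    y = np.concatenate([np.zeros(len(sites_a)), np.ones(len(sites_b))])
    clf = SVC(kernel="linear", C=C).fit(X, y)
    w = clf.coef_[0]
    nrm = np.linalg.norm(w)
    normal = w / nrm
    # point on the decision plane w.x + b = 0
    point = -clf.intercept_[0] / nrm * normal
    return SeparatingPlane(point=point, normal=normal)


def _median_plane(planes: list[SeparatingPlane]) -> SeparatingPlane:
    normals = np.array([p.normal for p in planes])
    offsets = np.array([p.offset for p in planes])
    # flip into the hemisphere of the first normal (planes are axial objects)
    flip = np.sign(normals @ normals[0])
    flip[flip == 0] = 1.0
    normals = normals * flip[:, None]
    offsets = offsets * flip
    n = np.median(normals, axis=0)
    n /= np.linalg.norm(n)
    d = float(np.median(offsets))
    return SeparatingPlane(point=d * n, normal=n)


def _ks(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    method = "exact" if max(len(a), len(b)) <= 25 else "asymp"
    res = ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


def site_separation(
    sites: GlomerulusSites,
    pairs,
    min_sites: int = 5,
    C: float = 1.0,
) -> tuple[dict, SeparatingPlane | None]:
    """Separating-plane statistics for each anticorrelated partner pair.

    Per pair: a soft-margin linear-kernel SVM plane between the two
    partners' postsynaptic-site clouds.  The median plane across pairs is
    the unbiased separator; every partner's sites are projected onto its
    normal, and per pair the signed median-to-median distance and
    two-sample KS statistic of the projections are reported.  Pairs with a
    class below ``min_sites`` sites are skipped with a warning.

    Returns ``(results_by_pair, median_plane)``.
    """
    rng = np.random.default_rng(0)
    usable, planes = [], []
    for a, b in pairs:
        pa, pb = sites.postsynaptic_sites(a), sites.postsynaptic_sites(b)
        if len(pa) < min_sites or len(pb) < min_sites:
            warnings.warn(f"pair ({a}, {b}) skipped: class below {min_sites} sites", stacklevel=2)
            continue
        # cross-fit: the plane is estimated on one half of each cloud and the
        # projection statistics are computed on the held-out half, so the KS
        # test stays calibrated (fitting and testing on the same sites makes
        # the separator overfit noise and the null anticonservative)
        ia, ib = rng.permutation(len(pa)), rng.permutation(len(pb))
        ha, hb = len(pa) // 2, len(pb) // 2
        usable.append((a, b, pa[ia[ha:]], pb[ib[hb:]]))
        planes.append(_svm_plane(pa[ia[:ha]], pb[ib[:hb]], C=C))
    if not usable:
        return {}, None
    median = _median_plane(planes)

    results = {}
    for (a, b, pa, pb), plane in zip(usable, planes):
        proj_a = pa @ median.normal
        proj_b = pb @ median.normal
        d, p = _ks(proj_a, proj_b)
        results[(a, b)] = SeparationResult(
            pair=(a, b),
            plane=plane,
            projections_a=proj_a,
            projections_b=proj_b,
            median_distance=float(np.median(proj_a) - np.median(proj_b)),
            d_ks=d,
            p_value=p,
        )
    return results, median


def _permutation_p(x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p-value for the Spearman correlation of x, y."""
    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    obs = float(np.mean(rx * ry))
    perms = np.array([np.mean(rx * rng.permutation(ry)) for _ in range(n_perm)])
    return float((np.sum(np.abs(perms) >= abs(obs) - 1e-12) + 1) / (n_perm + 1))


def axodendritic_overlap_correlation(
    sites: GlomerulusSites,
    partner,
    counts: pd.Series,
    radius: float = 2.0,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between per-cell axo-dendritic overlap and synapse count.

    Overlap for a VPN cell is the number of its presynaptic sites lying
    within ``radius`` of any dendritic point of the partner.  Significance
    is a two-sided permutation test of the Spearman correlation.  Returns
    ``(nan, nan)`` when the overlap vector is constant (undefined
    correlation).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    dend = np.asarray(sites.partner_dendrites[partner], float)
    tree = cKDTree(dend)
    cells = [c for c in counts.index if len(sites.presynaptic_sites(c)) > 0]
    if len(cells) < 10:
        raise ValueError("need at least 10 cells with presynaptic sites")
    overlap = np.array(
        [np.sum(np.asarray(tree.query(sites.presynaptic_sites(c))[0]) <= radius) for c in cells],
        float,
    )
    y = counts.loc[cells].to_numpy(float)
    if np.ptp(overlap) == 0 or np.ptp(y) == 0:
        warnings.warn("constant overlap or counts; correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho = float(spearmanr(overlap, y).statistic)
    p = _permutation_p(overlap, y, n_perm, np.random.default_rng(seed))
    return rho, p


def topography_index(
    dendrite_coordinate: pd.Series,
    axon_centroids: pd.DataFrame,
    axis: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Quantitative axon-topography index.

    Spearman correlation between each cell's lobula gradient coordinate and
    the scalar coordinate of its glomerulus axon-terminal centroid along the
    glomerulus principal axis (first principal direction of all terminals
    unless ``axis`` is given), with a permutation p-value.
    """
    cells = [c for c in dendrite_coordinate.index if c in axon_centroids.index]
    if len(cells) < 10:
        raise ValueError("need at least 10 cells")
    term = axon_centroids.loc[cells].to_numpy(float)
    if axis is None:
        centred = term - term.mean(axis=0)
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        if s[0] == 0:
            raise ValueError("degenerate glomerulus axis (zero variance)")
        axis = vt[0]
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    coord = term @ axis
    if np.ptp(coord) == 0:
        raise ValueError("degenerate glomerulus axis (zero variance)")
    x = dendrite_coordinate.loc[cells].to_numpy(float)
    rho = float(spearmanr(x, coord).statistic)
    p = _permutation_p(x, coord, n_perm, np.random.default_rng(seed))
    return rho, p


def normalized_axis_centroid(points, interval: tuple[float, float]) -> float:
    """Mean scalar coordinate min-max normalized to ``interval`` (0-1 range),
    e.g. a dendritic-arbor centroid along the sagittal glomerulus diameter."""
    lo, hi = interval
    if not hi > lo:
        raise ValueError("interval length must be positive")
    x = np.asarray(points, float)
    if x.size == 0:
        raise ValueError("empty point set")
    if (x < lo).any() or (x > hi).any():
        warnings.warn("points outside interval clipped", stacklevel=2)
        x = np.clip(x, lo, hi)
    return float((x.mean() - lo) / (hi - lo))
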