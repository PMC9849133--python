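"""Mapping differential connectivity back onto the lobula.

Dendritic endpoint clouds are reduced to per-cell centroids and projected
onto a cut-plane separating the lobula; each partner's synapse-weighted
input centroid (component-wise weighted median of cell centroids) marks the
lobula region feeding it most strongly.  The most anticorrelated partner
pairs define a median separation line, and signed distances between partner
centroids along the perpendicular projection line quantify the spatial
segregation of connectivity gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.stats import linregress, spearmanr

from .io import ArborPointCloud


@dataclass
class CutPlane:
    """An anchored plane with orthonormal in-plane axes.

    The lobula side is the half-space the normal points into.
    """

    anchor: np.ndarray
    normal: np.ndarray
    axes: np.ndarray  # (2, 3) orthonormal in-plane directions

    def __post_init__(self):
        self.anchor = np.asarray(self.anchor, float)
        self.normal = np.asarray(self.normal, float)
        self.normal = self.normal / np.linalg.norm(self.normal)
        self.axes = np.asarray(self.axes, float)
        gram = np.vstack([self.axes, self.normal]) @ np.vstack([self.axes, self.normal]).T
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ValueError("normal and in-plane axes must be mutually orthonormal")

    @classmethod
    def from_normal(cls, anchor, normal, data: np.ndarray | None = None) -> "CutPlane":
        """Build in-plane axes; orientation follows the dominant in-plane
        variance direction of ``data`` when given."""
        normal = np.asarray(normal, float)
        normal = normal / np.linalg.norm(normal)
        if data is not None and len(data) >= 2:
            centred = np.asarray(data, float) - np.mean(data, axis=0)
            inplane = centred - np.outer(centred @ normal, normal)
            _, _, vt = np.linalg.svd(inplane, full_matrices=False)
            u = vt[0] - (vt[0] @ normal) * normal
            u /= np.linalg.norm(u)
        else:
            trial = np.array([1.0, 0.0, 0.0])
            if abs(trial @ normal) > 0.9:
                trial = np.array([0.0, 1.0, 0.0])
            u = trial - (trial @ normal) * normal
            u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        return cls(np.asarray(anchor, float), normal, np.vstack([u, v]))

    def to_plane(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection into in-plane (u, v) coordinates."""
        return (np.asarray(points, float) - self.anchor) @ self.axes.T

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.anchor) @ self.normal


@dataclass
class ProjectedMap:
    """2D lobula projection: per-cell dendritic centroids and the hull."""

    centroids: pd.DataFrame  # index = cell id, columns u, v
    hull: np.ndarray  # (m, 2) hull vertices over all endpoint projections
    plane: CutPlane
    weights: pd.DataFrame | None = None  # cells x partners synapse counts

    @property
    def hull_area(self) -> float:
        x, y = self.hull[:, 0], self.hull[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class SeparationGeometry:
    threshold: float
    selected_pairs: list
    separation_point: np.ndarray  # 2D anchor of the median separation line
    separation_direction: np.ndarray  # unit 2D direction of the separation line
    projection_direction: np.ndarray  # unit 2D direction, perpendicular
    partner_centroids: dict = field(default_factory=dict)
    map_connectivity_correlation: float = float("nan")


def project_dendrites(arbors, plane: CutPlane, weights: pd.DataFrame | None = None) -> ProjectedMap:
    """Per-cell dendritic centroids projected onto the cut-plane.

    Endpoints on the non-lobula side of the plane are discarded; cells left
    with no endpoints are excluded with a warning.  The hull is the convex
    hull of all retained endpoint projections across cells.
    """
    if isinstance(arbors, dict):
        arbors = list(arbors.values())
    rows, ids, all_proj, skipped = [], [], [], []
    for arbor in arbors:
        pts = arbor.dendrite_endpoints
        kept = pts[plane.signed_distance(pts) >= 0] if len(pts) else pts
        if len(kept) == 0:
            skipped.append(arbor.neuron_id)
            continue
        centroid3d = kept.mean(axis=0)
        rows.append(plane.to_plane(centroid3d[None, :])[0])
        ids.append(arbor.neuron_id)
        all_proj.append(plane.to_plane(kept))
    if skipped:
        warnings.warn(f"cells with no endpoints on the lobula side excluded: {skipped}", stacklevel=2)
    if not rows:
        raise ValueError("no cells with endpoints on the lobula side")
    proj = np.vstack(all_proj)
    try:
        hull = proj[ConvexHull(proj).vertices] if len(proj) >= 3 else proj
    except Exception:  # degenerate (collinear) endpoint sets have no 2D hull
        hull = proj
    centroids = pd.DataFrame(rows, index=ids, columns=["u", "v"])
    if weights is not None:
        weights = weights.reindex(centroids.index)
    return ProjectedMap(centroids=centroids, hull=hull, plane=plane, weights=weights)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest v with cumulative weight >= half."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def weighted_input_centroid(pmap: ProjectedMap, weights) -> np.ndarray:
    """Synapse-weighted input centroid of one partner: the component-wise
    weighted median of cell centroids along the plane axes."""
    w = np.asarray(pd.Series(weights).reindex(pmap.centroids.index), float)
    if np.all(np.nan_to_num(w) <= 0):
        raise ValueError("all weights zero")
    mask = np.nan_to_num(w) > 0
    uv = pmap.centroids.to_numpy(float)[mask]
    w = w[mask]
    return np.array([weighted_median(uv[:, 0], w), weighted_median(uv[:, 1], w)])


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho via explicit mid-ranks (defined from 2 observations up,
    unlike scipy's version; NaN only if either vector is constant)."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def _axial_median_angle(angles_deg: np.ndarray) -> float:
    """Median of undirected line orientations (axial data, period 180 deg):
    the observed orientation minimizing the summed axial distance."""
    a = np.asarray(angles_deg, float) % 180.0
    def axial_dist(x, y):
        d = np.abs(x - y) % 180.0
        return np.minimum(d, 180.0 - d)
    costs = [axial_dist(a, cand).sum() for cand in a]
    return float(a[int(np.argmin(costs))])


def anticorrelated_separation(
    corr: pd.DataFrame,
    pmap: ProjectedMap,
    weights: pd.DataFrame,
) -> SeparationGeometry:
    """Optimal unbiased separator of the most anticorrelated partner pairs.

    The anticorrelation threshold is chosen, over the grid of observed
    negative pair correlations, to maximize the absolute Spearman
    correlation between pairwise weighted-centroid distances and
    connectivity correlations of the selected pairs.  Each selected pair
    contributes the perpendicular bisector of the segment joining its two
    weighted centroids; the median separation line combines those bisectors
    (axial circular median of orientations through the component-wise
    median of midpoints), and the projection line is its perpendicular.
    """
    partners = [p for p in corr.index if p in weights.columns]
    cents = {p: weighted_input_centroid(pmap, weights[p]) for p in partners}

    pairs, rhos = [], []
    for i, a in enumerate(partners):
        for b in partners[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r < 0:
                pairs.append((a, b))
                rhos.append(float(r))
    if not pairs:
        raise ValueError("no anticorrelated pairs")
    rhos = np.asarray(rhos)

    best = None
    for thr in np.sort(np.unique(rhos)):
        sel = rhos <= thr
        if sel.sum() < 2:
            continue
        d = np.array([np.linalg.norm(cents[a] - cents[b]) for (a, b), s in zip(pairs, sel) if s])
        r = rhos[sel]
        score = abs(_rank_corr(d, r))
        if np.isfinite(score) and (best is None or score > best[0]):
            best = (score, thr)
    if best is None:  # single candidate pair: select the most negative
        best = (float("nan"), float(rhos.min()))
    score, thr = best
    selected = [p for p, r in zip(pairs, rhos) if r <= thr]

    angles, midpoints = [], []
    for a, b in selected:
        seg = cents[b] - cents[a]
        bisector = np.degrees(np.arctan2(seg[1], seg[0])) + 90.0
        angles.append(bisector)
        midpoints.append((cents[a] + cents[b]) / 2)
    med_angle = _axial_median_angle(np.asarray(angles))
    sep_dir = np.array([np.cos(np.deg2rad(med_angle)), np.sin(np.deg2rad(med_angle))])
    proj_dir = np.array([-sep_dir[1], sep_dir[0]])
    mid = np.median(np.vstack(midpoints), axis=0)
    return SeparationGeometry(
        threshold=thr,
        selected_pairs=selected,
        separation_point=mid,
        separation_direction=sep_dir,
        projection_direction=proj_dir,
        partner_centroids=cents,
        map_connectivity_correlation=score,
    )


def centroid_distance_matrix(geometry: SeparationGeometry, centroids: dict | None = None) -> pd.DataFrame:
    """Signed pairwise distances between partner centroids projected on the
    projection line; antisymmetric by construction.  Partners without a
    centroid get missing entries."""
    cents = geometry.partner_centroids if centroids is None else centroids
    names = list(cents)
    s = {p: (np.nan if c is None else float(np.dot(c, geometry.projection_direction))) for p, c in cents.items()}
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            mat.loc[a, b] = s[a] - s[b]
    return mat


@dataclass
class GradientFit:
    slope: float
    intercept: float
    spearman_rho: float
    spearman_p: float


def gradient_fit(coordinate, counts) -> GradientFit:
    """OLS fit and Spearman correlation of synapse counts against a scalar
    dendritic-centroid coordinate."""
    x = np.asarray(coordinate, float)
    y = np.asarray(counts, float)
    if len(x) < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance coordinate")
    fit = linregress(x, y)
    sp = spearmanr(x, y)
    return GradientFit(float(fit.slope), float(fit.intercept), float(sp.statistic), float(sp.pvalue))


def pair_spearman(counts_a, counts_b) -> float:
    """Spearman correlation between two partners' per-cell count vectors."""
    return float(spearmanr(np.asarray(counts_a, float), np.asarray(counts_b, float)).statistic)
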