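"""Anatomical receptive-field model.

Dendritic arbors of all cells are mapped onto a common second-order surface
through the lobula; each cell's projected dendritic polygon defines a 2D
circular Gaussian receptive field in eye coordinates — unit height, centre
at the polygon centroid, width the radius of the equal-area circle.  A
downstream neuron's RF is the synapse-weighted sum of its inputs'
Gaussians, and its predicted looming response sums each cell's synapse
count times the fraction of that cell's RF covered by the stimulus at
maximum size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .io import ArborPointCloud
from .stimulus import LoomingStimulus, overlap_fraction


@dataclass
class QuadraticSurface:
    """Least-squares surface z = a + bx + cy + dx^2 + exy + fy^2 in a frame
    whose z-axis is the point cloud's minor principal axis."""

    coefficients: np.ndarray  # (a, b, c, d, e, f)
    origin: np.ndarray
    rotation: np.ndarray  # (3, 3); rows are frame axes, z last
    residual: float

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.rotation.T

    def project(self, points: np.ndarray) -> np.ndarray:
        """Surface-intrinsic (u, v) coordinates of points (shallow-surface
        geodesic approximation: the in-frame (x, y))."""
        return self.to_frame(points)[:, :2]

    def height(self, uv: np.ndarray) -> np.ndarray:
        x, y = np.asarray(uv, float).T
        a, b, c, d, e, f = self.coefficients
        return a + b * x + c * y + d * x * x + e * x * y + f * y * y


def fit_surface(points: np.ndarray) -> QuadraticSurface:
    """Fit a second-order surface to all dendritic endpoints jointly."""
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < 6:
        raise ValueError("need at least 6 points for a quadratic surface")
    origin = pts.mean(axis=0)
    centred = pts - origin
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    rot = vt  # rows: major, middle, minor axes; z = minor
    local = centred @ rot.T
    x, y, z = local.T
    design = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("degenerate endpoint configuration (rank-deficient fit)")
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = float(np.sqrt(np.mean((design @ coef - z) ** 2)))
    return QuadraticSurface(coefficients=coef, origin=origin, rotation=rot, residual=resid)


@dataclass
class EyeFrame:
    """Affine (similarity) map from surface-intrinsic coordinates to eye
    coordinates, anchored by two reference surface points with known eye
    positions: the eye centre and a dorsal point on the central meridian."""

    anchor_surface: np.ndarray  # (2, 2) surface (u, v)
    anchor_eye: np.ndarray  # (2, 2) (azimuth, elevation) deg

    def __post_init__(self):
        self.anchor_surface = np.asarray(self.anchor_surface, float).reshape(2, 2)
        self.anchor_eye = np.asarray(self.anchor_eye, float).reshape(2, 2)
        if np.allclose(self.anchor_surface[0], self.anchor_surface[1]):
            raise ValueError("anchor surface points must be distinct")
        s = self.anchor_surface[:, 0] + 1j * self.anchor_surface[:, 1]
        e = self.anchor_eye[:, 0] + 1j * self.anchor_eye[:, 1]
        self._alpha = (e[1] - e[0]) / (s[1] - s[0])
        self._beta = e[0] - self._alpha * s[0]

    @property
    def scale(self) -> float:
        """Degrees of visual angle per surface unit."""
        return float(abs(self._alpha))

    def to_eye(self, uv: np.ndarray) -> np.ndarray:
        uv = np.asarray(uv, float).reshape(-1, 2)
        z = self._alpha * (uv[:, 0] + 1j * uv[:, 1]) + self._beta
        return np.column_stack([z.real, z.imag])


@dataclass
class GaussianRF:
    """One cell's receptive field: a unit-height 2D circular Gaussian."""

    centre: tuple  # (azimuth, elevation) deg
    sigma_deg: float
    height: float = 1.0

    def __post_init__(self):
        if self.sigma_deg <= 0:
            raise ValueError("sigma must be positive")

    def value(self, azimuth, elevation) -> np.ndarray:
        az0, el0 = self.centre
        cos_el = np.cos(np.deg2rad(el0))
        d2 = ((np.asarray(azimuth, float) - az0) * cos_el) ** 2 + (np.asarray(elevation, float) - el0) ** 2
        return self.height * np.exp(-d2 / (2 * self.sigma_deg**2))


def _polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if area == 0:
        return vertices.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6 * area)
    cy = ((y + yn) * cross).sum() / (6 * area)
    return np.array([cx, cy])


def arbor_to_rf(
    arbor: ArborPointCloud,
    surface: QuadraticSurface,
    frame: EyeFrame,
    width_mode: str = "sigma",
) -> GaussianRF:
    """One cell's anatomical RF from its dendritic polygon.

    The dendritic endpoints are projected onto the surface; the convex hull
    of the projections is the cell's field-of-view polygon.  The Gaussian is
    centred at the polygon centroid (mapped to eye coordinates) with unit
    height; its width is the radius of the equal-area circle.  With
    ``width_mode="sigma"`` (default) that radius is the Gaussian sigma; with
    ``"cutoff"`` it is read as a 2-sigma cutoff radius instead.
    """
    pts = arbor.dendrite_endpoints
    if len(pts) < 3:
        raise ValueError(f"arbor {arbor.neuron_id!r}: need >= 3 dendrite endpoints")
    uv = surface.project(pts)
    hull = ConvexHull(uv)
    area = hull.volume  # 2D hull: volume is the polygon area
    centre_uv = _polygon_centroid(uv[hull.vertices])
    centre_eye = frame.to_eye(centre_uv)[0]
    r_eq = np.sqrt(area / np.pi) * frame.scale
    if width_mode == "sigma":
        sigma = r_eq
    elif width_mode == "cutoff":
        sigma = r_eq / 2.0
    else:
        raise ValueError(f"unknown width_mode {width_mode!r}")
    return GaussianRF(centre=tuple(centre_eye), sigma_deg=float(sigma))


@dataclass
class DnRF:
    """A descending neuron's RF: synapse-weighted sum of cell Gaussians."""

    components: list = field(default_factory=list)  # (GaussianRF, weight)

    def response_surface(self, azimuth_grid, elevation_grid) -> np.ndarray:
        az, el = np.meshgrid(np.asarray(azimuth_grid, float), np.asarray(elevation_grid, float))
        out = np.zeros_like(az)
        for rf_i, w in self.components:
            out += w * rf_i.value(az, el)
        return out


def build_dn_rf(rfs: dict, weights) -> DnRF:
    """Assemble a DN receptive field from per-cell RFs and synapse counts."""
    comps = [(rfs[c], float(weights[c])) for c in rfs if c in weights and weights[c] > 0]
    return DnRF(components=comps)


def dn_response(dnrf: DnRF, stim: LoomingStimulus, coverage_mode: str = "area") -> float:
    """Predicted looming response: sum over cells of synapse count times the
    covered fraction of that cell's RF; non-overlapping cells contribute 0."""
    total = 0.0
    for rf_i, w in dnrf.components:
        if w < 0:
            raise ValueError("negative synapse weight")
        frac = overlap_fraction(rf_i, stim, coverage_mode=coverage_mode)
        total += w * frac
    return float(total)


def hemifield_profile(
    dnrf: DnRF,
    azimuth_grid,
    template: LoomingStimulus,
    coverage_mode: str = "area",
) -> np.ndarray:
    """Predicted tuning curve across azimuth, normalized to its maximum.

    The stimulus template is recentred at each azimuth of the grid (keeping
    its elevation), mirroring looming presentations across the visual
    hemifield.
    """
    azimuths = np.asarray(azimuth_grid, float)
    if azimuths.size == 0:
        raise ValueError("empty azimuth grid")
    resp = np.array([dn_response(dnrf, template.recentred(az), coverage_mode) for az in azimuths])
    peak = resp.max()
    if peak <= 0:
        raise ValueError("no response anywhere on the grid; cannot normalize")
    return resp / peak
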