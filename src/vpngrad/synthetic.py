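"""Synthetic connectomes, takeoff angles and membrane-potential traces.

The generator stands in for EM connectome volumes: it plants linear
synapse-count gradients of individual VPN cells onto downstream partners as
a function of each cell's dendritic position on a 2D lobula sheet, with
optional Poisson count noise, and builds a glomerulus whose axon terminals
either preserve the dendritic order (topographic) or ignore it.  Every
planted quantity is returned as ground truth so each analysis stage can be
checked against what was actually put in.

Geometry conventions
--------------------
The lobula is the rectangle ``[0, extent]^2`` in the z=0 plane; dendritic
arbors are isotropic Gaussian endpoint clouds around each cell's (x, y)
centroid.  The glomerulus is a separate elongated box displaced along +x;
its long axis is x.  For a partner with gradient direction ``d`` (degrees in
the lobula plane) and unit vector ``u``, the gradient coordinate of a cell at
position ``p`` is the min-shifted scalar projection

    g(p) = p . u - min_{q in lobula} q . u

so that ``g`` runs from 0 regardless of direction and the expected synapse
count ``baseline + slope * g(p)`` is non-negative whenever baseline and
slope are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AXON_TERMINAL,
    DENDRITE_ENDPOINT,
    ArborPointCloud,
    GlomerulusSites,
    write_skeleton_swc,
    write_synapse_table,
)
from .kinematics import EphysTrace


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration cannot yield valid counts."""


@dataclass(frozen=True)
class PartnerSpec:
    """Planted connectivity profile of one postsynaptic partner.

    ``direction_deg=None`` means a position-independent ("uniform") partner:
    every cell makes ``baseline`` expected synapses onto it.
    """

    name: str
    direction_deg: float | None
    slope: float = 0.0
    baseline: float = 20.0

    def __post_init__(self):
        if self.baseline < 0:
            raise ConfigurationError(f"partner {self.name}: negative baseline")
        if self.slope < 0:
            raise ConfigurationError(
                f"partner {self.name}: negative slope would give negative expected "
                "counts; encode the sign in direction_deg instead"
            )
        if self.direction_deg is None and self.slope != 0:
            raise ConfigurationError(f"partner {self.name}: uniform partner with non-zero slope")


def _default_partners() -> tuple:
    # an anterior-posterior antiparallel pair, a dorso-ventral antiparallel
    # pair, and one position-independent partner; counts span roughly 20-70,
    # the dynamic range of LC4-DN synapse numbers in EM data
    return (
        PartnerSpec("DN_A", 0.0, 5.0, 20.0),
        PartnerSpec("DN_P", 180.0, 5.0, 20.0),
        PartnerSpec("DN_D", 90.0, 5.0, 20.0),
        PartnerSpec("DN_V", 270.0, 5.0, 20.0),
        PartnerSpec("DN_U", None, 0.0, 30.0),
    )


def antiparallel_pair_specs(
    direction_deg: float = 0.0, slope: float = 5.0, baseline: float = 20.0
) -> tuple:
    """Two partners with exactly opposing gradients along one axis."""
    return (
        PartnerSpec("DN_A", direction_deg % 360.0, slope, baseline),
        PartnerSpec("DN_P", (direction_deg + 180.0) % 360.0, slope, baseline),
    )


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic connectome."""

    n_vpn: int = 60
    lobula_extent: float = 10.0
    partner_specs: tuple = field(default_factory=_default_partners)
    count_noise: str = "poisson"  # {"none", "poisson"}
    topographic_axons: bool = True
    glomerulus_extent: float = 10.0
    glomerulus_width: float = 3.0
    site_dispersion: float = 1.0
    n_endpoints: int = 30
    endpoint_sigma: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.n_vpn < 2:
            raise ConfigurationError("n_vpn must be >= 2")
        if self.count_noise not in ("none", "poisson"):
            raise ConfigurationError(f"unknown count_noise {self.count_noise!r}")
        if self.lobula_extent <= 0 or self.glomerulus_extent <= 0:
            raise ConfigurationError("extents must be positive")
        names = [s.name for s in self.partner_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate partner names")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    positions: pd.DataFrame  # per-cell lobula (x, y)
    partner_directions: dict  # name -> direction deg or None
    partner_slopes: dict
    partner_baselines: dict
    cluster_labels: pd.Series  # coarse anterior/posterior planted labels
    anticorrelated_pairs: list  # (name_a, name_b) with opposing directions
    topographic: bool
    expected_counts: pd.DataFrame
    axon_centroids: pd.DataFrame  # per-cell glomerulus terminal centroid (x, y, z)
    gradient_coordinate: pd.Series  # per-cell coordinate along the primary axis
    glomerulus_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    glomerulus_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))


def _unit(direction_deg: float) -> np.ndarray:
    rad = np.deg2rad(direction_deg)
    return np.array([np.cos(rad), np.sin(rad)])


def gradient_coordinate(positions: np.ndarray, direction_deg: float, extent: float) -> np.ndarray:
    """Min-shifted scalar projection of lobula positions on a gradient axis."""
    u = _unit(direction_deg)
    corners = np.array([[0, 0], [extent, 0], [0, extent], [extent, extent]], float)
    return positions @ u - (corners @ u).min()


def _jittered_grid(n: int, extent: float, rng: np.random.Generator) -> np.ndarray:
    n_side = int(np.ceil(np.sqrt(n)))
    axis = np.linspace(0.0, extent, n_side)
    xx, yy = np.meshgrid(axis, axis)
    grid = np.column_stack([xx.ravel(), yy.ravel()])[:n]
    spacing = extent / max(n_side - 1, 1)
    jitter = rng.normal(0.0, 0.15 * spacing, size=grid.shape)
    return np.clip(grid + jitter, 0.0, extent)


def generate_connectome(config: SyntheticConfig):
    """Generate arbors, a connectivity matrix, glomerulus sites and truth.

    Returns
    -------
    arbors : dict[str, ArborPointCloud]
    matrix : pandas.DataFrame
        Cells x partners integer synapse counts.
    sites : GlomerulusSites
    truth : GroundTruth
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pos, rng_counts, rng_glom, rng_sites = (np.random.default_rng(s) for s in ss.spawn(4))

    cells = [f"vpn_{i:03d}" for i in range(config.n_vpn)]
    partners = [s.name for s in config.partner_specs]
    pos = _jittered_grid(config.n_vpn, config.lobula_extent, rng_pos)

    expected = np.empty((config.n_vpn, len(partners)))
    for j, spec in enumerate(config.partner_specs):
        if spec.direction_deg is None:
            expected[:, j] = spec.baseline
        else:
            g = gradient_coordinate(pos, spec.direction_deg, config.lobula_extent)
            expected[:, j] = spec.baseline + spec.slope * g
    if (expected < 0).any():
        raise ConfigurationError("negative expected synapse count under the given specs")

    if config.count_noise == "none":
        counts = np.rint(expected).astype(int)
    else:
        counts = rng_counts.poisson(expected)
    matrix = pd.DataFrame(counts, index=cells, columns=partners)

    # glomerulus: box displaced along +x, long axis = x
    g_origin = np.array([2.5 * config.lobula_extent, 0.0, 0.0])
    g_axis = np.array([1.0, 0.0, 0.0])
    gradient_specs = [s for s in config.partner_specs if s.direction_deg is not None]
    primary_dir = gradient_specs[0].direction_deg if gradient_specs else 0.0
    g_primary = gradient_coordinate(pos, primary_dir, config.lobula_extent)
    span = np.ptp(g_primary) or 1.0
    t = (g_primary - g_primary.min()) / span  # normalized 0..1 along primary axis
    if config.topographic_axons:
        gx = np.clip(t + rng_glom.normal(0.0, 0.05, size=config.n_vpn), 0, 1)
        gx *= config.glomerulus_extent
    else:
        gx = rng_glom.uniform(0.0, config.glomerulus_extent, size=config.n_vpn)
    gyz = rng_glom.normal(config.glomerulus_width / 2, config.glomerulus_width / 6, size=(config.n_vpn, 2))
    axon_centroids = g_origin + np.column_stack([gx, gyz[:, 0], gyz[:, 1]])

    arbors = {}
    for i, cid in enumerate(cells):
        dend = np.column_stack([np.broadcast_to(pos[i], (config.n_endpoints, 2)).copy(), np.zeros(config.n_endpoints)])
        dend += rng_pos.normal(0.0, config.endpoint_sigma, size=dend.shape)
        term = axon_centroids[i] + rng_glom.normal(0.0, config.site_dispersion / 2, size=(5, 3))
        points = np.vstack([dend, term])
        labels = np.array([DENDRITE_ENDPOINT] * config.n_endpoints + [AXON_TERMINAL] * 5, object)
        arbors[cid] = ArborPointCloud(cid, points, labels)

    # synapse sites: topographic sites trace the presynaptic cell's terminal,
    # which localizes each partner's postsynaptic cloud where its high-weight
    # cells terminate; non-topographic sites are uniform in the glomerulus box
    rows = []
    for i, cid in enumerate(cells):
        for j, pname in enumerate(partners):
            c = int(counts[i, j])
            if c == 0:
                continue
            if config.topographic_axons:
                xyz = axon_centroids[i] + rng_sites.normal(0.0, config.site_dispersion, size=(c, 3))
            else:
                lo, hi = g_origin, g_origin + np.array(
                    [config.glomerulus_extent, config.glomerulus_width, config.glomerulus_width]
                )
                xyz = rng_sites.uniform(lo, hi, size=(c, 3))
            for p in xyz:
                rows.append((cid, pname, p[0], p[1], p[2]))
    site_df = pd.DataFrame(rows, columns=["pre_id", "post_id", "x", "y", "z"])

    # each partner's dendrites occupy the glomerulus pole matching its
    # gradient: the axis image of the lobula region its preferred cells
    # terminate in (position-independent partners sit at the axis centre)
    partner_dendrites = {}
    for j, spec in enumerate(config.partner_specs):
        if spec.direction_deg is None or spec.slope == 0:
            c = 0.0
        else:
            c = np.cos(np.deg2rad(spec.direction_deg - primary_dir))
        centre = g_origin + np.array(
            [
                (1 + c) / 2 * config.glomerulus_extent,
                config.glomerulus_width / 2,
                config.glomerulus_width / 2,
            ]
        )
        spread = np.array(
            [config.glomerulus_extent / 8, config.glomerulus_width / 4, config.glomerulus_width / 4]
        )
        partner_dendrites[spec.name] = centre + rng_sites.normal(0.0, 1.0, size=(150, 3)) * spread
    sites = GlomerulusSites(sites=site_df, partner_dendrites=partner_dendrites)

    # coarse planted labels: which half of the primary gradient axis
    labels = pd.Series(np.where(t >= np.median(t), 1, 0), index=cells, name="cluster")
    anti = []
    for a in range(len(gradient_specs)):
        for b in range(a + 1, len(gradient_specs)):
            da, db = gradient_specs[a].direction_deg, gradient_specs[b].direction_deg
            if np.isclose((da - db) % 360.0, 180.0):
                anti.append((gradient_specs[a].name, gradient_specs[b].name))

    truth = GroundTruth(
        positions=pd.DataFrame(pos, index=cells, columns=["x", "y"]),
        partner_directions={s.name: s.direction_deg for s in config.partner_specs},
        partner_slopes={s.name: s.slope for s in config.partner_specs},
        partner_baselines={s.name: s.baseline for s in config.partner_specs},
        cluster_labels=labels,
        anticorrelated_pairs=anti,
        topographic=config.topographic_axons,
        expected_counts=pd.DataFrame(expected, index=cells, columns=partners),
        axon_centroids=pd.DataFrame(axon_centroids, index=cells, columns=["x", "y", "z"]),
        gradient_coordinate=pd.Series(g_primary, index=cells, name="gradient_coordinate"),
        glomerulus_origin=g_origin,
        glomerulus_axis=g_axis,
    )
    return arbors, matrix, sites, truth


def generate_profile_connectome(
    n_cells_per_cluster: int = 30,
    n_clusters: int = 2,
    n_partners: int = 10,
    separation: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Connectivity matrix with discrete planted output profiles.

    Each cluster of cells shares one expected output profile; profiles of
    different clusters differ by ``separation`` synapses on a disjoint subset
    of partners.  Used to test connectivity-based clustering recovery.

    Returns ``(matrix, labels)``.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(10.0, 30.0, size=(n_clusters, n_partners))
    for c in range(n_clusters):
        base[c, np.arange(n_partners) % n_clusters == c] += separation
    labels = np.repeat(np.arange(n_clusters), n_cells_per_cluster)
    expected = base[labels]
    counts = expected + rng.normal(0.0, noise_sd, size=expected.shape)
    counts = np.clip(np.rint(counts), 0, None).astype(int)
    cells = [f"vpn_{i:03d}" for i in range(len(labels))]
    cols = [f"partner_{j:02d}" for j in range(n_partners)]
    return pd.DataFrame(counts, index=cells, columns=cols), pd.Series(labels, index=cells, name="cluster")


def generate_takeoff_angles(n: int, mean_direction: float, concentration: float, seed: int) -> np.ndarray:
    """Draw takeoff directions (degrees) from a von Mises distribution.

    ``concentration == 0`` gives the circular-uniform distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    draws = rng.vonmises(np.deg2rad(mean_direction), concentration, size=n)
    return np.rad2deg(draws) % 360.0


def generate_ephys_trace(
    duration_ms: float,
    rate_khz: float,
    baseline_mv: float = -60.0,
    depol_amplitude_mv: float = 0.0,
    depol_window_ms: tuple = (0.0, 0.0),
    spike_times_ms: tuple = (),
    spike_amplitude_mv: float = 20.0,
    spike_rise_ms: float = 0.5,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
    stimulus_onset_ms: float | None = None,
) -> EphysTrace:
    """Membrane-potential trace: baseline + ramped boxcar depolarization +
    stereotyped triangular spikes + Gaussian noise."""
    if rate_khz <= 0:
        raise ValueError("rate must be positive")
    for st in spike_times_ms:
        if not (0 <= st <= duration_ms):
            raise ValueError(f"spike time {st} outside trace duration")
    n = int(round(duration_ms * rate_khz))
    t = np.arange(n) / rate_khz
    v = np.full(n, baseline_mv, float)

    d0, d1 = depol_window_ms
    if depol_amplitude_mv != 0.0 and d1 > d0:
        ramp = (d1 - d0) / 4
        rise = np.clip((t - d0) / ramp, 0, 1)
        fall = np.clip((d1 - t) / ramp, 0, 1)
        v += depol_amplitude_mv * np.minimum(rise, fall) * ((t >= d0) & (t <= d1))

    for st in spike_times_ms:
        up = np.clip((t - st + spike_rise_ms) / spike_rise_ms, 0, 1)
        down = np.clip(1 - (t - st) / (2 * spike_rise_ms), 0, 1)
        wave = np.where(t < st, up, down)
        wave[(t < st - spike_rise_ms) | (t > st + 2 * spike_rise_ms)] = 0
        v += spike_amplitude_mv * wave

    if noise_sd_mv > 0:
        v += np.random.default_rng(seed).normal(0.0, noise_sd_mv, size=n)

    onset = duration_ms / 2 if stimulus_onset_ms is None else stimulus_onset_ms
    return EphysTrace(samples_mv=v, rate_khz=rate_khz, stimulus_onset_ms=onset)


def write_fixture_dir(config: SyntheticConfig, out_dir) -> None:
    """Write SWC skeletons, the synapse table and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arbors, matrix, sites, truth = generate_connectome(config)
    skel = out / "skeletons"
    skel.mkdir(exist_ok=True)
    for cid, arbor in arbors.items():
        write_skeleton_swc(arbor, skel / f"{cid}.swc")
    write_synapse_table(sites, out / "synapses.csv")
    matrix.to_csv(out / "matrix.csv")
    truth_json = {
        "partner_directions": truth.partner_directions,
        "partner_slopes": truth.partner_slopes,
        "partner_baselines": truth.partner_baselines,
        "anticorrelated_pairs": truth.anticorrelated_pairs,
        "topographic": truth.topographic,
        "cluster_labels": truth.cluster_labels.to_dict(),
        "positions": truth.positions.to_dict(orient="index"),
        "seed": config.seed,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
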