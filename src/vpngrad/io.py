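"""File formats and core containers.

Connectivity matrices are plain :class:`pandas.DataFrame` objects with VPN
cell ids on the rows, postsynaptic partner ids on the columns, and
non-negative integer synapse counts as entries.  Coordinates are treated as
dimensionless throughout; a ``units`` string may be carried in configs and
reports but never enters any computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: point-label vocabulary for :class:`ArborPointCloud`
DENDRITE_ENDPOINT = "dendrite_endpoint"
AXON_TERMINAL = "axon_terminal"
PRESYNAPTIC_SITE = "presynaptic_site"
POSTSYNAPTIC_SITE = "postsynaptic_site"

_SWC_LABELS = {2: AXON_TERMINAL, 3: DENDRITE_ENDPOINT}
_SWC_CODES = {AXON_TERMINAL: 2, DENDRITE_ENDPOINT: 3}


@dataclass
class ArborPointCloud:
    """Labelled 3D points belonging to one neuron.

    Parameters
    ----------
    neuron_id
        Identifier of the neuron.
    points
        ``(n, 3)`` float array of coordinates.
    labels
        Length-``n`` array of point labels (``dendrite_endpoint``,
        ``axon_terminal``, ``presynaptic_site``, ``postsynaptic_site`` or an
        opaque ``type_<code>`` carried over from SWC).
    """

    neuron_id: str
    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"non-finite coordinates in arbor {self.neuron_id!r}")

    def with_label(self, label: str) -> np.ndarray:
        """Return the ``(m, 3)`` coordinates carrying ``label``."""
        return self.points[self.labels == label]

    @property
    def dendrite_endpoints(self) -> np.ndarray:
        return self.with_label(DENDRITE_ENDPOINT)

    @property
    def axon_terminals(self) -> np.ndarray:
        return self.with_label(AXON_TERMINAL)


@dataclass
class GlomerulusSites:
    """Synapse-site point clouds inside an optic glomerulus.

    ``sites`` holds one row per synapse (``pre_id, post_id, x, y, z``);
    postsynaptic clouds per partner and presynaptic clouds per VPN cell are
    views of the same table.  ``partner_dendrites`` optionally carries the
    dendritic point cloud of each postsynaptic partner inside the glomerulus
    (used by the axo-dendritic overlap analysis).
    """

    sites: pd.DataFrame
    partner_dendrites: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"pre_id", "post_id", "x", "y", "z"} - set(self.sites.columns)
        if missing:
            raise ValueError(f"sites table missing columns {sorted(missing)}")

    def postsynaptic_sites(self, partner) -> np.ndarray:
        sub = self.sites[self.sites["post_id"] == partner]
        return sub[["x", "y", "z"]].to_numpy(float)

    def presynaptic_sites(self, cell) -> np.ndarray:
        sub = self.sites[self.sites["pre_id"] == cell]
        return sub[["x", "y", "z"]].to_numpy(float)

    @property
    def partners(self) -> list:
        return sorted(self.sites["post_id"].unique().tolist())

    @property
    def cells(self) -> list:
        return sorted(self.sites["pre_id"].unique().tolist())


def read_skeleton_swc(path) -> ArborPointCloud:
    """Read a neuron skeleton in SWC format and return its endpoints.

    The SWC dialect is seven whitespace-separated columns
    ``id type x y z radius parent`` with ``#`` comment lines.  Endpoints are
    nodes without children; type code 3 maps to dendrite endpoints, 2 to axon
    terminals, and any other code is preserved as ``type_<code>`` but excluded
    from downstream endpoint analyses.
    """
    path = Path(path)
    nodes: dict[int, tuple] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                nid = int(cols[0])
                ntype = int(cols[1])
                xyz = tuple(float(c) for c in cols[2:5])
                parent = int(cols[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable SWC row") from exc
            nodes[nid] = (lineno, ntype, xyz, parent)
            order.append(nid)
    if not nodes:
        raise ValueError(f"{path}: empty SWC file")

    has_child = set()
    for nid, (lineno, _, _, parent) in nodes.items():
        if parent == -1:
            continue
        if parent not in nodes:
            raise ValueError(f"{path}:{lineno}: parent id {parent} not in file")
        has_child.add(parent)

    pts, labels = [], []
    for nid in order:
        if nid in has_child:
            continue
        _, ntype, xyz, _ = nodes[nid]
        pts.append(xyz)
        labels.append(_SWC_LABELS.get(ntype, f"type_{ntype}"))
    return ArborPointCloud(neuron_id=path.stem, points=np.array(pts, float), labels=np.array(labels, object))


def write_skeleton_swc(arbor: ArborPointCloud, path) -> None:
    """Write an arbor as a star-shaped SWC tree (soma root, endpoints as leaves)."""
    path = Path(path)
    centroid = arbor.points.mean(axis=0) if len(arbor.points) else np.zeros(3)
    with open(path, "w") as fh:
        fh.write(f"# neuron {arbor.neuron_id}\n")
        fh.write(f"1 1 {centroid[0]:.17g} {centroid[1]:.17g} {centroid[2]:.17g} 1 -1\n")
        for i, (p, lab) in enumerate(zip(arbor.points, arbor.labels), start=2):
            code = _SWC_CODES.get(lab, 0)
            fh.write(f"{i} {code} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g} 1 1\n")


def read_synapse_table(path) -> tuple[pd.DataFrame, GlomerulusSites]:
    """Read a synapse table CSV into a connectivity matrix and site clouds.

    The table has header ``pre_id, post_id, x, y, z`` and one row per synapse;
    matrix entry ``(i, j)`` counts the rows with ``pre_id == i`` and
    ``post_id == j``.  Duplicate coordinates are allowed (multi-synapse
    contacts are real).  The sum of all matrix entries equals the number of
    rows.
    """
    df = pd.read_csv(path)
    missing = {"pre_id", "post_id", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric coordinate in column {col!r} at row {row}")
        df[col] = coerced
    if df.empty:
        logger.warning("%s: synapse table has no rows; returning empty matrix", path)
        warnings.warn(f"{path}: empty synapse table", stacklevel=2)
        return pd.DataFrame(dtype=int), GlomerulusSites(sites=df)
    matrix = pd.crosstab(df["pre_id"], df["post_id"])
    matrix.index.name = None
    matrix.columns.name = None
    return matrix, GlomerulusSites(sites=df)


def write_synapse_table(sites: GlomerulusSites, path) -> None:
    sites.sites.to_csv(path, index=False, columns=["pre_id", "post_id", "x", "y", "z"])
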