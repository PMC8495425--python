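"""STORM post-processing: localization filtering, DBSCAN molecule calling,
and two-channel molecule ratios per ROI.

A "molecule" is a DBSCAN cluster of 3D localization points — by default 3
or more points within a 100 nm radius — represented by its center of mass.
The two-channel ratio (e.g., membrane estrogen receptor vs AMPA-receptor
subunit) is the ratio of molecule counts inside a shared ROI polygon.

Cluster labeling is deliberately order-invariant: clusters are connected
components of core points, and border points attach to their *nearest*
core point (ties then break by lowest cluster id under centroid
lexicographic ordering), rather than inheriting whichever cluster a scan
visits first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Point, Polygon
from sklearn.neighbors import NearestNeighbors

from .core import RoiPolygon, StormCloud, ValidationError

__all__ = [
    "MoleculeSet",
    "filter_localizations",
    "local_density_filter",
    "dbscan_molecules",
    "count_molecules_in_roi",
    "receptor_ratio",
]


@dataclass
class MoleculeSet:
    """Called molecules: per-cluster centers of mass (nm) and member counts."""

    centers: np.ndarray  # (M, 3) nm
    member_counts: np.ndarray  # per cluster
    channel: str
    labels: np.ndarray  # per input point: cluster index or −1 (noise)

    @property
    def n_molecules(self) -> int:
        return len(self.centers)


def filter_localizations(
    cloud: StormCloud,
    min_photons: float = 0.0,
    z_min: float = -300.0,
    z_max: float = 300.0,
):
    """Photon-count and axial-position filter.

    Keeps points with photons ≥ min_photons and z in the closed interval
    [z_min, z_max] (default ±300 nm, the astigmatic calibration range).
    Returns (filtered_cloud, log) where log counts removals per criterion.
    """
    z = cloud.xyz[:, 2]
    pass_photons = cloud.photons >= min_photons
    pass_z = (z >= z_min) & (z <= z_max)
    keep = pass_photons & pass_z
    log = {
        "n_in": len(cloud),
        "n_fail_photons": int(np.sum(~pass_photons)),
        "n_fail_z": int(np.sum(~pass_z)),
        "n_out": int(np.sum(keep)),
    }
    return cloud.select(keep), log


def local_density_filter(
    cloud: StormCloud, min_neighbors: int = 2, radius: float = 150.0
):
    """Optional sparse-point pre-filter (off by default in the pipeline):
    discard points with fewer than ``min_neighbors`` other points within
    ``radius`` nm."""
    if len(cloud) == 0:
        return cloud, {"n_in": 0, "n_out": 0}
    nn = NearestNeighbors(radius=radius).fit(cloud.xyz)
    counts = np.array([len(idx) - 1 for idx in nn.radius_neighbors(cloud.xyz)[1]])
    keep = counts >= min_neighbors
    return cloud.select(keep), {"n_in": len(cloud), "n_out": int(keep.sum())}


def dbscan_molecules(
    cloud: StormCloud,
    eps: float = 100.0,
    min_points: int = 3,
    xy_only: bool = False,
):
    """DBSCAN molecule calling in nm coordinates.

    A core point has ≥ ``min_points`` points (counting itself) within
    ``eps``; clusters are connected components of core points plus border
    points (non-core within ``eps`` of a core point); everything else is
    noise. Border points attach to the nearest core point. Per-cluster
    center of mass is the unweighted mean of member coordinates. Cluster
    ids are assigned by lexicographic order of the centroids, making the
    output independent of point order.

    Returns (MoleculeSet, noise_indices).
    """
    channels = np.unique(cloud.channel)
    if len(channels) > 1:
        raise ValidationError("dbscan_molecules expects a single channel per call")
    channel = str(channels[0]) if len(channels) else ""
    n = len(cloud)
    coords = cloud.xyz[:, :2] if xy_only else cloud.xyz
    if n == 0:
        return (
            MoleculeSet(np.empty((0, 3)), np.empty(0, int), channel, np.empty(0, int)),
            np.empty(0, int),
        )

    nn = NearestNeighbors(radius=eps).fit(coords)
    neighbor_idx = nn.radius_neighbors(coords, return_distance=False)
    counts = np.array([len(idx) for idx in neighbor_idx])  # includes self
    core = counts >= min_points

    labels = np.full(n, -1, dtype=int)
    core_ids = np.nonzero(core)[0]
    if len(core_ids):
        # connected components over core-core adjacency
        pos_of = {int(i): k for k, i in enumerate(core_ids)}
        rows, cols = [], []
        for i in core_ids:
            for j in neighbor_idx[i]:
                if core[j]:
                    rows.append(pos_of[int(i)])
                    cols.append(pos_of[int(j)])
        adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(core_ids), len(core_ids))
        )
        n_comp, comp = connected_components(adj, directed=False)
        labels[core_ids] = comp

        # border points: nearest core point within eps
        border_ids = np.nonzero(~core)[0]
        if len(border_ids):
            core_nn = NearestNeighbors(n_neighbors=1).fit(coords[core_ids])
            dist, nearest = core_nn.kneighbors(coords[border_ids])
            ok = dist[:, 0] <= eps
            labels[border_ids[ok]] = comp[nearest[ok, 0]]

        # relabel by centroid lexicographic order (order invariance)
        centers = np.array(
            [cloud.xyz[labels == k].mean(axis=0) for k in range(n_comp)]
        )
        order = np.lexsort((centers[:, 2], centers[:, 1], centers[:, 0]))
        remap = np.empty(n_comp, dtype=int)
        remap[order] = np.arange(n_comp)
        labels[labels >= 0] = remap[labels[labels >= 0]]
        centers = centers[order]
        member_counts = np.bincount(labels[labels >= 0], minlength=n_comp)
    else:
        centers = np.empty((0, 3))
        member_counts = np.empty(0, dtype=int)

    noise = np.nonzero(labels == -1)[0]
    return MoleculeSet(centers, member_counts, channel, labels), noise


def count_molecules_in_roi(molecules: MoleculeSet, roi: RoiPolygon) -> int:
    """Count molecule centers inside or on the boundary of the ROI polygon
    (x, y only; z ignored)."""
    poly = Polygon(roi.vertices)
    if not poly.is_valid or poly.area == 0:
        raise ValidationError(f"degenerate ROI polygon {roi.label!r}")
    return int(
        sum(poly.covers(Point(x, y)) for x, y in molecules.centers[:, :2])
    )


def receptor_ratio(
    molecules_a: MoleculeSet, molecules_b: MoleculeSet, roi: RoiPolygon
) -> float:
    """Molecule-count ratio a/b within one ROI (e.g., GPER1 / GluR2-AMPAR)."""
    n_a = count_molecules_in_roi(molecules_a, roi)
    n_b = count_molecules_in_roi(molecules_b, roi)
    if n_b == 0:
        raise ValidationError(
            f"ROI {roi.label!r}: denominator channel has no molecules; ratio undefined"
        )
    return n_a / n_b
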