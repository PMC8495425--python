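"""Shared domain types, coordinate conventions, and file I/O.

Units convention
----------------
Trajectories and masks live in micrometers and seconds; STORM localization
clouds live in nanometers (the natural scale of the clustering radius).
Conversions happen only at module boundaries.

Coordinate convention (global, single): 0-based pixel indices, position
(0.0, 0.0) at the *center* of the top-left pixel, x rightward (columns),
y downward (rows). Subpixel Gaussian fits, masks, simulated movies and
trajectories all share it.

Text precision: micrometer columns are written with 6 decimals, nanometer
columns with 2 — round-trips are lossless at that precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TrackdiffError",
    "FormatError",
    "ValidationError",
    "AcquisitionParams",
    "Trajectory",
    "DisplacementSeries",
    "RoiPolygon",
    "SynapseMask",
    "StormCloud",
    "read_trajectories",
    "write_trajectories",
    "read_mask",
    "write_mask",
    "read_storm_csv",
    "write_storm_csv",
    "read_rois",
    "write_rois",
    "load_config",
]

UM_DECIMALS = 6
NM_DECIMALS = 2


class TrackdiffError(Exception):
    """Base class for all package errors."""


class FormatError(TrackdiffError):
    """A file does not match the declared on-disk format."""


class ValidationError(TrackdiffError):
    """Input violates a documented invariant."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera timing and geometry for one recording.

    Parameters
    ----------
    frame_interval : float
        Seconds between consecutive frame starts (the displacement
        time base Δt).
    exposure : float
        Integration time per frame in seconds; must not exceed
        ``frame_interval``. Continuous illumination over the exposure
        produces motion blur with coefficient R = 1/6.
    pixel_size : float
        Micrometers per pixel.
    blur_coefficient : float
        Dimensionless motion-blur coefficient R in [0, 1/4]. Defaults to
        1/6 (continuous illumination).
    """

    frame_interval: float
    exposure: float
    pixel_size: float
    blur_coefficient: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if not self.exposure > 0:
            raise ValidationError("exposure must be > 0")
        if self.frame_interval < self.exposure:
            raise ValidationError(
                "frame_interval must be >= exposure "
                f"({self.frame_interval} < {self.exposure})"
            )
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")
        if not 0.0 <= self.blur_coefficient <= 0.25:
            raise ValidationError("blur_coefficient R must lie in [0, 1/4]")


@dataclass
class Trajectory:
    """Ordered per-frame 2D positions of one tracked molecule.

    Positions are in micrometers, frames are strictly increasing integer
    indices. ``intensities`` is optional (per-frame summed counts) and is
    only needed for photobleaching analysis.
    """

    track_id: str
    frames: np.ndarray
    positions: np.ndarray
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must be an (N, 2) array")
        if len(self.frames) != len(self.positions):
            raise ValidationError("frames and positions must align")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValidationError(
                f"track {self.track_id!r}: frame indices must be strictly increasing"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError(f"track {self.track_id!r}: non-finite positions")
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
            if len(self.intensities) != len(self.frames):
                raise ValidationError("intensities must align with frames")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def x(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.positions[:, 1]

    def is_gapless(self) -> bool:
        """True when frame indices are consecutive (no dropped frames)."""
        return bool(np.all(np.diff(self.frames) == 1)) if self.n_points > 1 else True


@dataclass
class DisplacementSeries:
    """Per-step displacements Δx_k = x_{k+1} − x_k (micrometers) of one track."""

    dx: np.ndarray
    dy: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise ValidationError("dx and dy must be equal-length 1D arrays")
        if not self.dt > 0:
            raise ValidationError("dt must be > 0")

    def __len__(self) -> int:
        return len(self.dx)

    @property
    def n_steps(self) -> int:
        return len(self.dx)


@dataclass
class RoiPolygon:
    """A simple (non-self-intersecting) polygon region of interest.

    Vertices are (x, y) pairs; the unit (µm for trajectory work, nm for
    STORM work) is carried by the ``unit`` tag.
    """

    vertices: np.ndarray
    label: str = ""
    unit: str = "um"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("vertices must be an (M, 2) array")
        if len(self.vertices) < 3:
            raise ValidationError("a polygon needs at least 3 vertices")
        from shapely.geometry import Polygon

        poly = Polygon(self.vertices)
        if not poly.is_simple or poly.area == 0:
            raise ValidationError(f"ROI {self.label!r} is degenerate or self-intersecting")


@dataclass
class SynapseMask:
    """Binary occupancy map defining the synaptic area.

    ``occupancy[row, col]`` is True where the pixel is synaptic. Physical
    position of pixel (row, col) center is (col*pixel_size, row*pixel_size)
    plus ``origin`` — the same convention trajectories use.
    """

    occupancy: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise ValidationError("occupancy must be a 2D array")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")

    @property
    def area_um2(self) -> float:
        """Total synaptic area in µm²."""
        return float(self.occupancy.sum()) * self.pixel_size**2

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Whether positions (µm) fall in a synaptic pixel.

        A position belongs to the pixel whose center is nearest (containing
        pixel under the pixel-center origin convention). Positions outside
        the map bounds are reported as outside.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float)) - self.origin[0]
        y = np.atleast_1d(np.asarray(y, dtype=float)) - self.origin[1]
        col = np.floor(x / self.pixel_size + 0.5).astype(int)
        row = np.floor(y / self.pixel_size + 0.5).astype(int)
        nrow, ncol = self.occupancy.shape
        in_bounds = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
        out = np.zeros(x.shape, dtype=bool)
        out[in_bounds] = self.occupancy[row[in_bounds], col[in_bounds]]
        return out

    def dilated(self, iterations: int = 1) -> "SynapseMask":
        """Morphologically dilated copy (used for sensitivity checks)."""
        from scipy.ndimage import binary_dilation

        return SynapseMask(
            binary_dilation(self.occupancy, iterations=iterations),
            self.pixel_size,
            self.origin,
        )


@dataclass
class StormCloud:
    """3D STORM localization cloud in nanometers.

    ``xyz`` is (N, 3); ``photons`` per-point collected photon counts;
    ``channel`` per-point channel label.
    """

    xyz: np.ndarray
    photons: np.ndarray
    channel: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.photons = np.asarray(self.photons, dtype=float).reshape(-1)
        self.channel = np.asarray(self.channel).reshape(-1)
        n = len(self.xyz)
        if len(self.photons) != n or len(self.channel) != n:
            raise ValidationError("xyz, photons and channel must align")
        if n and not np.all(np.isfinite(self.xyz)):
            raise ValidationError("non-finite STORM coordinates")
        if n and np.any(self.photons < 0):
            raise ValidationError("negative photon counts")

    def __len__(self) -> int:
        return len(self.xyz)

    def select(self, keep: np.ndarray) -> "StormCloud":
        return StormCloud(self.xyz[keep], self.photons[keep], self.channel[keep])

    def channels(self) -> dict:
        """Partition into per-channel clouds."""
        return {
            str(c): self.select(self.channel == c) for c in np.unique(self.channel)
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TRAJ_REQUIRED = ("track_id", "frame", "x_um", "y_um")


def read_trajectories(path, params: AcquisitionParams | None = None) -> list[Trajectory]:
    """Read a trajectory table (CSV: track_id, frame, x_um, y_um[, intensity])."""
    df = pd.read_csv(path)
    for col in _TRAJ_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"trajectory file {path} is missing column {col!r}")
    if df.duplicated(subset=["track_id", "frame"]).any():
        dup = df[df.duplicated(subset=["track_id", "frame"])].iloc[0]
        raise ValidationError(
            f"duplicate (track_id, frame) = ({dup['track_id']}, {dup['frame']})"
        )
    has_intensity = "intensity" in df.columns
    out: list[Trajectory] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(dtype=np.int64),
                positions=grp[["x_um", "y_um"]].to_numpy(dtype=float),
                intensities=grp["intensity"].to_numpy(dtype=float)
                if has_intensity
                else None,
            )
        )
    return out


def write_trajectories(trajs: Iterable[Trajectory], path) -> None:
    """Write trajectories as CSV (µm to 6 decimals; lossless round-trip)."""
    trajs = sorted(trajs, key=lambda t: t.track_id)  # deterministic output order
    rows = []
    any_intensity = any(t.intensities is not None for t in trajs)
    for t in trajs:
        for i in range(t.n_points):
            row = {
                "track_id": t.track_id,
                "frame": int(t.frames[i]),
                "x_um": f"{t.positions[i, 0]:.{UM_DECIMALS}f}",
                "y_um": f"{t.positions[i, 1]:.{UM_DECIMALS}f}",
            }
            if any_intensity:
                val = t.intensities[i] if t.intensities is not None else np.nan
                row["intensity"] = f"{val:.3f}"
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mask(path, pixel_size: float) -> SynapseMask:
    """Read a single-page 8-bit TIFF mask; nonzero pixels are synaptic."""
    with tifffile.TiffFile(str(path)) as tif:
        if len(tif.pages) > 1:
            raise FormatError(
                f"{path} has {len(tif.pages)} pages; use synapse.project_mask_stack "
                "to reduce a time-lapse stack to a single mask first"
            )
        img = tif.pages[0].asarray()
    return SynapseMask(img != 0, pixel_size)


def write_mask(mask: SynapseMask, path) -> None:
    tifffile.imwrite(str(path), mask.occupancy.astype(np.uint8) * 255)


_STORM_REQUIRED = ("x_nm", "y_nm", "z_nm", "photons", "channel")


def read_storm_csv(path) -> StormCloud:
    """Read a STORM localization table (x_nm, y_nm, z_nm, photons, channel)."""
    df = pd.read_csv(path)
    for col in _STORM_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"STORM file {path} is missing column {col!r}")
    if len(df) and (df["photons"] < 0).any():
        raise ValidationError("negative photon counts in STORM table")
    return StormCloud(
        xyz=df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float),
        photons=df["photons"].to_numpy(dtype=float),
        channel=df["channel"].to_numpy(),
    )


def write_storm_csv(cloud: StormCloud, path) -> None:
    """Write a STORM cloud (nm to 2 decimals; lossless round-trip)."""
    df = pd.DataFrame(
        {
            "x_nm": [f"{v:.{NM_DECIMALS}f}" for v in cloud.xyz[:, 0]],
            "y_nm": [f"{v:.{NM_DECIMALS}f}" for v in cloud.xyz[:, 1]],
            "z_nm": [f"{v:.{NM_DECIMALS}f}" for v in cloud.xyz[:, 2]],
            "photons": [f"{v:.1f}" for v in cloud.photons],
            "channel": cloud.channel,
        }
    )
    df.to_csv(path, index=False)


def read_rois(path) -> list[RoiPolygon]:
    """Read ROI polygons from JSON: [{"label", "vertices_um"|"vertices_nm"}, ...]."""
    with open(path) as fh:
        raw = json.load(fh)
    rois = []
    for item in raw:
        if "vertices_um" in item:
            verts, unit = item["vertices_um"], "um"
        elif "vertices_nm" in item:
            verts, unit = item["vertices_nm"], "nm"
        else:
            raise FormatError("ROI entry needs vertices_um or vertices_nm")
        rois.append(RoiPolygon(np.asarray(verts, float), item.get("label", ""), unit))
    return rois


def write_rois(rois: Sequence[RoiPolygon], path) -> None:
    payload = [
        {"label": r.label, f"vertices_{r.unit}": r.vertices.tolist()} for r in rois
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_config(path) -> dict:
    """Load a TOML run configuration."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
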