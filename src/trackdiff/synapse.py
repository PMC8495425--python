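"""Synaptic vs extrasynaptic trajectory classification and dwell time.

A trajectory is *synaptic* if at least one of its frames falls inside the
labeled synaptic area (binary mask), *extrasynaptic* otherwise. Dwell time
is the total time a synaptic receptor spends inside the area
(frames_inside × frame interval); per-visit durations are also reported so
either convention can be summarized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SynapseMask, Trajectory, ValidationError

__all__ = [
    "SynapticResult",
    "DwellTimeSummary",
    "project_mask_stack",
    "classify_trajectory",
    "dwell_time_summary",
    "synaptic_content",
]


@dataclass
class SynapticResult:
    track_id: str
    label: str  # 'synaptic' | 'extrasynaptic'
    frames_inside: int
    dwell_time: float  # seconds; frames_inside × frame_interval
    visits: int  # maximal consecutive inside-runs
    visit_lengths: list = field(default_factory=list)  # frames per visit
    out_of_bounds: int = 0  # positions outside the mask map (warned, counted)


@dataclass
class DwellTimeSummary:
    mean: float  # seconds
    sem: float  # seconds; 0 with single_track=True when n == 1
    n: int
    single_track: bool = False


def project_mask_stack(
    stack: np.ndarray, mode: str = "max", threshold: float = 0.5, pixel_size: float = 1.0
) -> SynapseMask:
    """Z-project a time-lapse stack and binarize into a synapse mask.

    ``mode`` is 'max' (default — a synapse visible in any frame counts) or
    'average'; the projection is thresholded at ``threshold`` × its maximum.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValidationError("stack must be a non-empty (frames, H, W) array")
    if mode == "average":
        proj = stack.mean(axis=0)
    elif mode == "max":
        proj = stack.max(axis=0)
    else:
        raise ValidationError(f"unknown projection mode {mode!r}")
    peak = proj.max()
    occ = proj >= threshold * peak if peak > 0 else np.zeros_like(proj, dtype=bool)
    return SynapseMask(occ, pixel_size)


def classify_trajectory(traj: Trajectory, mask: SynapseMask) -> SynapticResult:
    """Classify one trajectory against the synaptic mask.

    A frame is "inside" iff the position's containing pixel is synaptic;
    the trajectory is synaptic iff inside on at least one frame. Positions
    outside the mask bounds count as outside (warned).
    """
    inside = mask.contains(traj.x, traj.y)

    # out-of-bounds positions (pixel index outside the map)
    col = np.floor((traj.x - mask.origin[0]) / mask.pixel_size + 0.5).astype(int)
    row = np.floor((traj.y - mask.origin[1]) / mask.pixel_size + 0.5).astype(int)
    nrow, ncol = mask.occupancy.shape
    oob = int(np.sum((row < 0) | (row >= nrow) | (col < 0) | (col >= ncol)))
    if oob:
        warnings.warn(
            f"track {traj.track_id!r}: {oob} positions outside the mask bounds "
            "(treated as extrasynaptic)",
            stacklevel=2,
        )

    frames_inside = int(inside.sum())
    # maximal consecutive inside-runs
    visits, visit_lengths = 0, []
    run = 0
    for flag in inside:
        if flag:
            run += 1
        elif run:
            visits += 1
            visit_lengths.append(run)
            run = 0
    if run:
        visits += 1
        visit_lengths.append(run)

    return SynapticResult(
        track_id=traj.track_id,
        label="synaptic" if frames_inside >= 1 else "extrasynaptic",
        frames_inside=frames_inside,
        dwell_time=float("nan"),  # filled by dwell_time_summary / caller
        visits=visits,
        visit_lengths=visit_lengths,
        out_of_bounds=oob,
    )


def dwell_time_summary(results, frame_interval: float) -> DwellTimeSummary | None:
    """Mean ± SEM synaptic dwell time over synaptic tracks only.

    Per-track dwell time is frames_inside × frame_interval (total time
    inside). With a single synaptic track the SEM is reported as 0 and
    flagged. Returns None (with a warning) when no track is synaptic.
    """
    dwell = []
    for r in results:
        r.dwell_time = r.frames_inside * frame_interval
        if r.label == "synaptic":
            dwell.append(r.dwell_time)
    if not dwell:
        warnings.warn("no synaptic tracks; dwell time undefined", stacklevel=2)
        return None
    dwell = np.asarray(dwell)
    n = len(dwell)
    sem = float(np.std(dwell, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return DwellTimeSummary(mean=float(dwell.mean()), sem=sem, n=n, single_track=n == 1)


def synaptic_content(results) -> float:
    """Fraction of trajectories classified synaptic (per recording)."""
    results = list(results)
    if not results:
        raise ValidationError("synaptic content needs at least 1 track")
    n_syn = sum(1 for r in results if r.label == "synaptic")
    return n_syn / len(results)
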