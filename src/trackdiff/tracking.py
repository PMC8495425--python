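"""From movie frames to quality-filtered trajectories.

Spot detection (bandpass + local maxima), subpixel 2D Gaussian
localization, intensity-trace extraction and one-step photobleaching
detection, minimum-step linking (globally optimal per frame pair), and the
minimum-length / artifact track filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .core import AcquisitionParams, Trajectory, ValidationError

__all__ = [
    "SpotCandidate",
    "Localization",
    "IntensityTrace",
    "detect_spots",
    "fit_gaussian_2d",
    "localize_movie",
    "extract_intensity_trace",
    "detect_bleach_steps",
    "fit_lognormal_intensity",
    "link_spots",
    "filter_tracks",
]


@dataclass(frozen=True)
class SpotCandidate:
    """Pixel-level detection: (row, col) of a candidate local maximum."""

    row: int
    col: int
    response: float = 0.0


@dataclass
class Localization:
    """Subpixel localization of one spot in one frame (physical units)."""

    frame: int
    x: float  # µm
    y: float  # µm
    intensity: float  # integrated counts 2πA s²
    psf_sigma: float  # µm
    background: float  # counts
    fit_ok: bool = True


@dataclass
class IntensityTrace:
    """Per-frame summed counts for one spot/track."""

    values: np.ndarray
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if len(self.values) != len(self.frames):
            raise ValidationError("values and frames must align")

    def __len__(self) -> int:
        return len(self.values)


def detect_spots(frame: np.ndarray, min_snr: float = 5.0, window: int = 7):
    """Candidate spots: local maxima of a bandpass-filtered image exceeding
    background + min_snr × noise sd; candidates within window/2 of an edge
    are discarded, and maxima closer than ``window`` merge into one.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValidationError("detect_spots expects a single 2D frame")
    # difference-of-Gaussians bandpass: keeps spot-scale structure only
    bp = ndimage.gaussian_filter(img, 1.0) - ndimage.gaussian_filter(img, window / 2.0)
    noise_sd = 1.4826 * np.median(np.abs(bp - np.median(bp)))
    thresh = np.median(bp) + min_snr * noise_sd
    local_max = ndimage.maximum_filter(bp, size=window) == bp
    cand = local_max & (bp > thresh) & (bp > 0)
    half = window // 2
    cand[:half, :] = cand[-half:, :] = False
    cand[:, :half] = cand[:, -half:] = False
    rows, cols = np.nonzero(cand)
    raw = sorted(
        (SpotCandidate(int(r), int(c), float(bp[r, c])) for r, c in zip(rows, cols)),
        key=lambda s: (-s.response, s.row, s.col),
    )
    # greedy suppression: equal-response plateaus and maxima closer than
    # `window` collapse into the strongest candidate
    accepted: list[SpotCandidate] = []
    for s in raw:
        if all(
            max(abs(s.row - a.row), abs(s.col - a.col)) >= window for a in accepted
        ):
            accepted.append(s)
    return accepted


def _gauss2d(params, rr, cc):
    A, r0, c0, s, b = params
    return A * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s**2)) + b


def fit_gaussian_2d(
    patch: np.ndarray,
    offset: tuple[int, int] = (0, 0),
    pixel_size: float = 1.0,
    frame: int = 0,
    init: SpotCandidate | None = None,
) -> Localization:
    """Least-squares symmetric 2D Gaussian fit A·exp(−r²/2s²) + b on a patch.

    ``offset`` is the (row, col) of the patch's top-left pixel in the full
    frame; the returned center is subpixel and converted to µm with
    ``pixel_size``. ``fit_ok`` is False when the optimizer fails, the fitted
    width leaves (0.5, 5) px, or the amplitude is non-positive.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 5:
        raise ValidationError("patch must be 2D with side >= 5 px")
    if not np.all(np.isfinite(patch)):
        raise ValidationError("non-finite values in patch")
    rr, cc = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]]
    b0 = float(patch.min())
    A0 = float(patch.max() - b0)
    if init is not None:
        r_init, c_init = float(init.row - offset[0]), float(init.col - offset[1])
    else:
        r_init, c_init = np.unravel_index(np.argmax(patch), patch.shape)
    x0 = np.array([A0, float(r_init), float(c_init), 1.5, b0])

    def resid(p):
        return (_gauss2d(p, rr, cc) - patch).ravel()

    fit_ok = True
    try:
        res = optimize.least_squares(
            resid,
            x0,
            bounds=(
                [0.0, -2.0, -2.0, 0.1, -np.inf],
                [np.inf, patch.shape[0] + 1.0, patch.shape[1] + 1.0, 10.0, np.inf],
            ),
        )
        A, r0, c0, s, b = res.x
        fit_ok = bool(res.success)
    except Exception:
        A, r0, c0, s, b = x0
        fit_ok = False
    ptp = float(patch.max() - patch.min())
    if not (0.5 < s < 5.0) or A <= max(1e-9, 0.05 * ptp):
        fit_ok = False
    return Localization(
        frame=frame,
        x=(c0 + offset[1]) * pixel_size,
        y=(r0 + offset[0]) * pixel_size,
        intensity=float(2 * np.pi * A * s**2),
        psf_sigma=float(s * pixel_size),
        background=float(b),
        fit_ok=fit_ok,
    )


def localize_movie(
    movie: np.ndarray,
    acq: AcquisitionParams,
    min_snr: float = 5.0,
    window: int = 7,
    patch_half: int = 4,
) -> list[Localization]:
    """Detect and Gaussian-fit every spot in every frame of a stack."""
    out: list[Localization] = []
    for f, frame_img in enumerate(np.asarray(movie, dtype=float)):
        for cand in detect_spots(frame_img, min_snr=min_snr, window=window):
            r0 = max(cand.row - patch_half, 0)
            c0 = max(cand.col - patch_half, 0)
            patch = frame_img[
                r0 : cand.row + patch_half + 1, c0 : cand.col + patch_half + 1
            ]
            if min(patch.shape) < 5:
                continue
            loc = fit_gaussian_2d(
                patch, offset=(r0, c0), pixel_size=acq.pixel_size, frame=f, init=cand
            )
            if loc.fit_ok:
                out.append(loc)
    return out


def extract_intensity_trace(
    movie: np.ndarray,
    traj: Trajectory,
    radius: int,
    pixel_size: float,
) -> IntensityTrace:
    """Background-subtracted summed counts in a disk around the tracked
    position, per frame. Background is the median of an annulus two pixels
    outside the disk, scaled to the disk area."""
    movie = np.asarray(movie, dtype=float)
    n_frames, nrow, ncol = movie.shape
    if traj.frames.max() >= n_frames:
        raise ValidationError("trajectory frame index beyond movie length")
    values = np.zeros(traj.n_points)
    yy, xx = np.mgrid[0:nrow, 0:ncol]
    for i, (f, (x, y)) in enumerate(zip(traj.frames, traj.positions)):
        col, row = x / pixel_size, y / pixel_size
        d2 = (yy - row) ** 2 + (xx - col) ** 2
        disk = d2 <= radius**2
        annulus = (d2 > (radius + 1) ** 2) & (d2 <= (radius + 3) ** 2)
        bg = float(np.median(movie[f][annulus])) if annulus.any() else 0.0
        values[i] = movie[f][disk].sum() - bg * disk.sum()
    return IntensityTrace(values=values, frames=traj.frames.copy())


def _best_split(seg: np.ndarray):
    """Best single change point of a segment by residual sum of squares."""
    n = len(seg)
    if n < 2:
        return None, 0.0
    csum = np.cumsum(seg)
    csq = np.cumsum(seg**2)
    total_rss = csq[-1] - csum[-1] ** 2 / n
    ks = np.arange(1, n)
    left = csq[ks - 1] - csum[ks - 1] ** 2 / ks
    rs = csum[-1] - csum[ks - 1]
    right = (csq[-1] - csq[ks - 1]) - rs**2 / (n - ks)
    rss = left + right
    k = int(ks[np.argmin(rss)])
    return k, float(total_rss - rss.min())


def detect_bleach_steps(trace: IntensityTrace, penalty: float = 30.0):
    """Count downward intensity steps by binary change-point segmentation.

    A split is accepted iff it reduces the residual sum of squares by more
    than ``penalty`` × the noise variance (robustly estimated from first
    differences). A spot is classified single-fluorophore iff exactly one
    downward step is found.

    Returns (n_down_steps, step_frames).
    """
    vals = np.asarray(trace.values, dtype=float)
    if len(vals) < 10:
        raise ValidationError("trace too short for step detection (need >= 10)")
    d = np.diff(vals)
    noise_sd = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    noise_var = max(noise_sd**2, 1e-12)

    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        k, gain = _best_split(vals[lo:hi])
        if k is None or gain <= penalty * noise_var:
            return
        breakpoints.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, len(vals))
    breakpoints.sort()
    edges = [0, *breakpoints, len(vals)]
    levels = [vals[edges[i] : edges[i + 1]].mean() for i in range(len(edges) - 1)]
    down = [
        int(trace.frames[breakpoints[i]])
        for i in range(len(breakpoints))
        if levels[i + 1] < levels[i]
    ]
    return len(down), down


def fit_lognormal_intensity(intensities) -> tuple[float, float, float]:
    """ML lognormal fit of spot intensities.

    Returns (mu, sigma, ks_distance): mu/sigma are the mean and sd of the
    log intensities (the lognormal MLE), and ks_distance is the one-sample
    Kolmogorov-Smirnov distance between the log values and the fitted
    normal — a goodness-of-fit measure (larger = worse fit).
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < 20:
        raise ValidationError("need at least 20 intensities")
    if np.any(x <= 0):
        raise ValidationError("intensities must be positive for a lognormal fit")
    logx = np.log(x)
    mu = float(np.mean(logx))
    sigma = float(np.std(logx))  # MLE (ddof=0)
    if sigma == 0:
        return mu, sigma, 0.0
    ks = stats.kstest(logx, "norm", args=(mu, sigma)).statistic
    return mu, sigma, float(ks)


def link_spots(
    localizations,
    max_step: float,
    max_gap: int = 0,
) -> list[Trajectory]:
    """Minimum-step-size linking: per frame pair, the globally optimal
    assignment minimizing total link distance, with links beyond
    ``max_step`` (µm) forbidden.

    ``localizations`` is an iterable of :class:`Localization` (any order).
    Unlinked detections start new tracks; a track not re-found within
    ``max_gap`` frames terminates. Every localization ends up in exactly
    one track.
    """
    locs = sorted(localizations, key=lambda l: l.frame)
    if not locs:
        return []
    by_frame: dict[int, list[Localization]] = {}
    for l in locs:
        by_frame.setdefault(int(l.frame), []).append(l)

    BIG = 1e9
    active: list[dict] = []  # {'locs': [...], 'last_frame': int}
    finished: list[list[Localization]] = []

    for f in sorted(by_frame):
        dets = by_frame[f]
        # retire tracks that have been dark too long
        still = []
        for tr in active:
            if f - tr["last_frame"] > max_gap + 1:
                finished.append(tr["locs"])
            else:
                still.append(tr)
        active = still

        if active and dets:
            cost = np.full((len(active), len(dets)), BIG)
            for i, tr in enumerate(active):
                last = tr["locs"][-1]
                for j, d in enumerate(dets):
                    dist = float(np.hypot(d.x - last.x, d.y - last.y))
                    if dist <= max_step:
                        cost[i, j] = dist
            ri, ci = optimize.linear_sum_assignment(cost)
            taken = set()
            for i, j in zip(ri, ci):
                if cost[i, j] < BIG:
                    active[i]["locs"].append(dets[j])
                    active[i]["last_frame"] = f
                    taken.add(j)
            for j, d in enumerate(dets):
                if j not in taken:
                    active.append({"locs": [d], "last_frame": f})
        else:
            for d in dets:
                active.append({"locs": [d], "last_frame": f})

    finished.extend(tr["locs"] for tr in active)

    trajs = []
    for i, chain in enumerate(finished):
        trajs.append(
            Trajectory(
                track_id=f"t{i:05d}",
                frames=np.array([l.frame for l in chain]),
                positions=np.array([[l.x, l.y] for l in chain]),
                intensities=np.array([l.intensity for l in chain]),
            )
        )
    return trajs


def filter_tracks(
    trajs,
    min_frames: int = 15,
    artifact_step_um: float = 1.0,
):
    """Length and artifact screen: keep tracks with at least ``min_frames``
    localizations and no single-frame step larger than ``artifact_step_um``
    (an automated surrogate for manual artifact inspection — the rule and
    every exclusion are logged).

    Returns (retained, exclusion_log) where the log is a DataFrame with
    columns track_id, n_frames, reason ∈ {short, artifact_step}.
    """
    retained, log_rows = [], []
    for t in trajs:
        if t.n_points < min_frames:
            log_rows.append(
                {"track_id": t.track_id, "n_frames": t.n_points, "reason": "short"}
            )
            continue
        steps = np.linalg.norm(np.diff(t.positions, axis=0), axis=1)
        if len(steps) and steps.max() > artifact_step_um:
            log_rows.append(
                {
                    "track_id": t.track_id,
                    "n_frames": t.n_points,
                    "reason": "artifact_step",
                }
            )
            continue
        retained.append(t)
    log = pd.DataFrame(log_rows, columns=["track_id", "n_frames", "reason"])
    return retained, log
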