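"""End-to-end simulation studies.

These drive the whole chain — mechanistic trajectory simulation, per-track
ML fitting, the group σ̂ QC screen, and the group-level KS comparison — to
measure detection power and type-I error of the pipeline under known ground
truth. The default conditions mirror a typical live-cell recording: 400
trajectories per condition, 30-frame tracks (29 displacement steps), 33 ms
frames, 30 nm localization noise, and a treated/vehicle diffusion ratio of
0.45 (a 55% slowdown).
"""

from __future__ import annotations

import numpy as np

from .core import AcquisitionParams
from .mle import displacements, fit_mle, sigma_qc_filter
from .simulate import MotionModel, simulate_trajectory
from .stats import ks_compare

__all__ = ["fit_condition", "ks_experiment", "ks_rejection_rate"]


def fit_condition(
    D_true: float,
    n_tracks: int,
    n_frames: int,
    sigma_loc: float,
    acq: AcquisitionParams,
    seed,
    n_substeps: int = 20,
) -> list:
    """Simulate one condition and fit every track; returns DiffusionEstimates."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    model = MotionModel("brownian", D_true)
    ests = []
    for i, child in enumerate(ss.spawn(n_tracks)):
        _, traj = simulate_trajectory(
            model, acq, n_frames, sigma_loc, seed=child,
            n_substeps=n_substeps, track_id=f"c{i}",
        )
        ests.append(
            fit_mle(displacements(traj, acq.frame_interval), acq, track_id=traj.track_id)
        )
    return ests


def ks_experiment(
    D_vehicle: float,
    d_ratio: float,
    acq: AcquisitionParams,
    seed,
    n_tracks: int = 400,
    n_frames: int = 30,
    sigma_loc: float = 0.03,
) -> tuple[float, float]:
    """One two-condition experiment: returns the (KS D, p) of QC-passed D̂."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_veh, s_tr = ss.spawn(2)
    groups = []
    for D_true, s in ((D_vehicle, s_veh), (D_vehicle * d_ratio, s_tr)):
        ests = fit_condition(D_true, n_tracks, n_frames, sigma_loc, acq, s)
        retained, _, _ = sigma_qc_filter(ests)
        groups.append(np.array([e.D_hat for e in retained]))
    return ks_compare(groups[0], groups[1])


def ks_rejection_rate(
    d_ratio: float,
    alpha: float,
    acq: AcquisitionParams,
    seed,
    n_replicates: int = 100,
    n_tracks: int = 400,
    n_frames: int = 30,
    sigma_loc: float = 0.03,
    D_vehicle: float = 0.058,
) -> float:
    """Fraction of replicate experiments whose KS p falls below alpha.

    With ``d_ratio`` < 1 this measures detection power; with
    ``d_ratio`` = 1 it measures the type-I error rate.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_replicates):
        _, p = ks_experiment(
            D_vehicle, d_ratio, acq, child,
            n_tracks=n_tracks, n_frames=n_frames, sigma_loc=sigma_loc,
        )
        if p < alpha:
            rejections += 1
    return rejections / n_replicates
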