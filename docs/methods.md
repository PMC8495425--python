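# Methods

## The observation model

A molecule diffusing freely with coefficient D (µm²/s) is imaged at frame
interval Δt with exposure T_E ≤ Δt. Two camera effects distort the observed
displacement statistics:

- **Static localization noise.** Each fitted position carries independent
  Gaussian error with sd σ (µm). This *adds* 2σ² to the apparent per-step
  displacement variance and induces a *negative* lag-1 displacement
  covariance −σ² (consecutive displacements share one noisy endpoint).
- **Motion blur.** Under continuous illumination the camera reports the
  average position over the exposure, not a point sample. This *removes*
  4RDΔt from the apparent variance and induces a *positive* lag-1
  covariance +2RDΔt, where R is the blur coefficient
  R = (1/T)∫₀ᵀ S(t)(1 − S(t)) dt for the cumulative illumination
  fraction S(t); R = 1/6 for a uniform shutter, 0 for an instantaneous one.

Together, the N per-step displacements of one axis are zero-mean Gaussian
with a symmetric tridiagonal Toeplitz covariance: diagonal
a = 2DΔt − 2(2DRΔt − σ²), off-diagonal b = 2DRΔt − σ². The matrix is
positive definite for every D > 0, σ² ≥ 0, R ≤ 1/4 (a + 2b = 2DΔt and
a − 2b = 2DΔt(1 − 4R) + 4σ² are both positive), so the likelihood is
well-defined on the whole parameter domain.

When the sampling interval exceeds the exposure (dark gaps), the same
structure holds with an effective R scaled by T_E/Δt; the simulator supports
this regime and both timing parameters are always exposed separately.

## Likelihood evaluation and optimization

The per-trajectory log-likelihood (x and y pooled as independent axes) is
maximized over (log D, σ²) with L-BFGS-B, bounds D ∈ [10⁻⁶, 10] µm²/s,
σ² ∈ [0, 0.25] µm², from five starts: a covariance-based (CVE) start plus a
log-spaced D grid. Likelihood ties below 10⁻⁶ resolve toward smaller D, and
the optimizer stops early once two independent starts agree on the optimum.
The reported log-likelihood omits the −N·log 2π constant, which shifts all
values uniformly and cannot move the maximizer.

Three evaluation routes exist and are cross-checked in the tests:

- `loglik_exact`: banded Cholesky factorization of the tridiagonal Σ, O(N).
- the fitter's internal route: the eigendecomposition of a symmetric
  tridiagonal Toeplitz matrix is the type-I discrete sine basis, so the
  squared DST-I coefficients of (Δx, Δy) are sufficient statistics and each
  likelihood evaluation is a closed-form O(N) expression in
  λ_k = a + 2b·cos(πk/(N+1)). Identical to the banded route to ~1e-16
  relative; this is what makes the multi-hundred-thousand-fit simulation
  studies cheap.
- `loglik_circulant`: the circulant surrogate (λ_k = a + 2b·cos(2πk/N),
  quadratic forms via FFT), the classical trick for making repeated
  evaluation affordable at large N. Within 1% of exact for N ≥ 256 across
  the D × σ grid of interest; crude below N ≈ 8 (a warning is issued).

The closed-form CVE — D = ⟨Δ²⟩/2Δt + ⟨Δ_kΔ_{k+1}⟩/Δt,
σ² = R⟨Δ²⟩ + (2R−1)⟨Δ_kΔ_{k+1}⟩ — inverts the model moments exactly and is
kept as an independent oracle. It is deliberately *not* clipped: a negative
D or σ² is a diagnostic that the track is noise-dominated.

## The σ quality screen

Estimated noise far from the group's behaviour signals a failed
optimization or a mislinked track. Following the screen's standard form,
the group mean μ of σ̂ is computed once over converged fits and a fit is
retained iff σ̂ ∈ [0.1μ, 1.9μ] (±90% of the mean; the percentile-band
alternative reading is noted but not implemented). The mean is *not*
recomputed after exclusion.

One behaviour worth knowing: for short tracks in the fast/low-noise regime
(e.g., D = 0.1 µm²/s, σ = 20 nm, 29 steps) the blur correlation dominates
the noise signature and roughly a fifth of genuine trajectories carry no
resolvable σ at all — their CVE σ² is negative and the ML σ̂ sits at the
zero boundary. The band excludes exactly those, so per-condition retention
there is ~75% while the overall six-condition experiment retains ~93%.
This is the estimator's true sampling distribution (the MLE boundary mass
matches the independent CVE's negative mass), not an optimization failure.

## Synthetic data

The simulator is mechanistic, not statistical: motion blur is produced by
averaging `n_substeps` true Brownian sub-positions per exposure (default
50), localization noise is added per frame, and confinement reflects the
path at the walls of a square corral (implemented by folding the free
path, which is exactly equivalent to per-step reflection). The estimator is
therefore tested against simulated physics rather than against samples from
its own covariance model. With many substeps the empirical displacement
covariance converges to the tridiagonal model with R = 1/6 (the discrete
average has R_n = (n² − 1)/6n², i.e. 0.16660 at n = 50 — far below
sampling error at the scales tested); with one substep it matches R = 0.

Default study conditions mirror the targeted experiment: 33 ms frame
interval equal to exposure, 160 nm pixels, D in 0.02–0.25 µm²/s, σ in
20–50 nm, 15–30-frame tracks, 400 trajectories per recording. The square
corral (side 0.4 µm default, MSD plateau L²/3) is a modeling choice — the
confinement geometry of real synaptic domains is unknown; an optional
geometric photobleaching lifetime produces realistic track-length
distributions for the ≥15-frame filter to act on.

What the simulator does **not** emulate: EMCCD gain-register noise, dye
blinking/re-activation photophysics beyond one-step bleaching, anisotropic
or astigmatic PSFs, drift, and heterogeneous per-molecule mobility within a
condition. Passing tests therefore demonstrate correctness of the analysis
under the stated model, not robustness to every camera artifact of real
recordings.

## Tracking

Spot detection is a difference-of-Gaussians bandpass with robust (MAD)
noise scaling; subpixel localization is a least-squares symmetric 2D
Gaussian fit (fits with width outside 0.5–5 px or vanishing amplitude are
flagged). Linking solves, per frame pair, the global minimum-total-distance
assignment (Hungarian algorithm) with links beyond a gate forbidden — a
deterministic reading of "minimum step size" linking that an exhaustive
small-case oracle can verify; the gate default is 5·√(4·D_max·Δt). Gap
closing is off by default ("subsequent images") but configurable. The
manual artifact screen of interactive workflows is replaced by a logged
rule: any single-frame step above 1 µm (configurable) excludes the track.
Every exclusion is written to a log with a reason code.

One-step photobleaching, the single-fluorophore criterion, is detected by
binary change-point splitting on the intensity trace: a split is accepted
when it reduces the residual sum of squares by more than `penalty` (default
30) × the robust noise variance from first differences. Spot-intensity
histograms are validated against a lognormal by the ML fit of log-values
plus a KS distance.

## MSD and motion classification

MSD(mΔT) is evaluated exactly with overlapping pairs; `max_lag` defaults to
half the track length (longer lags are noise-dominated). The
Brownian-vs-confined call fits a line 4Dt + c and a saturating curve
A(1 − exp(−4Dt/A)) + c; the shared intercept c absorbs the 4σ² − 8RDΔt
blur/noise offset so neither model is penalized for it. Two guards make the
call usable on single-track time-averaged MSDs, which wander enough that an
unconstrained saturating model mimics free motion: the saturating fit must
beat the line by a 5% residual margin *and* actually saturate within the
observed window (4·D·t_max/A ≥ 2 plateau times). Both residual sums, the
fitted plateau and the saturation depth are reported so users can
re-threshold. At the validation conditions (300-frame tracks, 30 lags) the
per-class accuracy is ≥ 90%.

## Synapse analysis

The synapse mask comes from a Z-projection of the synapse-label channel —
max projection by default (a synapse visible in any frame counts; the
average-projection alternative is supported) — thresholded at a configurable
fraction of the projected maximum (default 0.5; real masks are typically
thresholded manually, so the value is always logged). A trajectory is
synaptic iff at least one frame's containing pixel is synaptic. Dwell time
is total inside-time per synaptic track (frames_inside × Δt); per-visit run
lengths are also emitted since "time spent inside" admits a per-visit
reading. Point-in-mask is containing-pixel lookup with no subpixel area
weighting — matching the mask's actual resolution.

## STORM molecule calling

Localizations are filtered to the astigmatic calibration range z ∈
[−300, 300] nm (closed interval) and an optional photon floor (no default
is claimed; it is instrument-dependent). Molecules are DBSCAN clusters —
3 or more points within 100 nm, the point itself counted — in 3D nm
coordinates (an xy-only switch exists). The implementation labels clusters
as connected components of core points and attaches border points to their
*nearest* core point, making the partition invariant to point order; the
reference scan-order DBSCAN is used as a cross-check in tests on
unambiguous data. Cluster ids are ordered by centroid lexicographic order.
An optional local-density pre-filter (< k neighbors within r; defaults
k = 2, r = 150 nm) is provided but off by default. Molecule centers are
unweighted means of member coordinates; ROI counting uses even-odd
point-in-polygon with the boundary counted inside.

## Group statistics

Per-trajectory D̂ distributions are compared by the two-sample KS test
(asymptotic two-sided p); two-group location by Mann-Whitney U (exact p for
min(n) ≤ 8 without ties); multi-group by Kruskal-Wallis with tie correction
followed by Dunn's z from pooled midranks, Holm-adjusted by default
(Bonferroni and unadjusted available — the correction is a reporting
choice, so all raw values are emitted). Percent-of-vehicle scales each
treated value by the vehicle mean; its SEM ignores the vehicle mean's own
uncertainty, matching the plotting convention of treatment-response
figures.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use deliberately chosen sizes:
10⁵ steps for covariance fidelity (3 SE criterion), N = 256–512 for the
circulant oracle (<1%), 300–500 tracks per condition for ensemble recovery
(bias < 10%), 10⁴ steps for MLE/CVE concordance (<2%), 200 tracks for
motion-classification accuracy, and a two-condition power study (400 + 400
tracks per replicate, D ratio 0.45 emulating a 55% treatment slowdown from
a vehicle D of 0.058 µm²/s) with 100 replicates in the test suite and 50 in
the acceptance script. The KS test at those sizes rejects at p < 0.001 in
essentially every replicate, and the null rejection rate at α = 0.05 stays
in [0.01, 0.10].

## Known limitations

- Per-trajectory fits assume a single constant D; no state switching or
  drift.
- The QC band assumes the group shares one true σ; heterogeneous optics
  across a field of view would widen it.
- The circulant route should not be trusted below N ≈ 8.
- DBSCAN parameters (100 nm, 3 points) are taken as given; no
  cluster-shape or Ripley statistics are computed.
- Statistical tests pool trajectories; recording-level clustering
  (pseudo-replication) is reported as n at both levels but not modeled.
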