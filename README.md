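# trackdiff

Single-particle tracking analysis for live-cell receptor mobility studies:
from fluorescence movies to diffusion coefficients, synaptic dwell times,
STORM molecule counts, and group statistics — with a synthetic-data module
that generates every input with known ground truth.

The package targets the kind of experiment where surface receptors
(e.g., AMPA-type glutamate receptors) are labeled with single fluorophores,
imaged under TIRF/HILO illumination at ~33 ms exposures, tracked for tens of
frames, and compared between treatment conditions by the distribution of
their diffusion coefficients.

## The core estimator

For a trajectory observed at frame interval Δt with static localization
noise σ and continuous-illumination motion blur, the per-step displacements
Δx, Δy are *not* independent. Their covariance is the symmetric tridiagonal
Toeplitz matrix

```
Σ_ij = 2DΔt − 2(2DRΔt − σ²)   i = j
       2DRΔt − σ²             i = j ± 1
       0                      otherwise
```

with R = 1/6 for continuous illumination. The per-trajectory log-likelihood

```
L(Δx, Δy) = −log|Σ| − ½ Δxᵀ Σ⁻¹ Δx − ½ Δyᵀ Σ⁻¹ Δy
```

is maximized over (D, σ²). Ignoring the off-diagonal structure biases D
(noise inflates, blur deflates apparent mobility); the MLE corrects both.
Two likelihood evaluation routes are provided — exact (banded Cholesky,
O(N)) and the circulant/FFT approximation — plus the closed-form
covariance-based estimator (CVE) as an independent cross-check, and a
group-level quality screen that excludes trajectories whose σ̂ falls outside
±90% of the group mean.

Downstream, the package provides per-trajectory MSD curves with
Brownian/confined classification, synaptic vs extrasynaptic classification
against a binary synapse mask (dwell time, synaptic content), DBSCAN
molecule calling on 3D STORM localization clouds with per-ROI two-channel
ratios, and the usual nonparametric group statistics (ECDF,
Kolmogorov-Smirnov, Mann-Whitney, Kruskal-Wallis + Dunn,
percent-of-vehicle normalization).

## Worked example

```python
import numpy as np
from trackdiff import AcquisitionParams, DiffusionMLE
from trackdiff.simulate import MotionModel, simulate_trajectory

acq = AcquisitionParams(frame_interval=0.033, exposure=0.033, pixel_size=0.16)
_, traj = simulate_trajectory(
    MotionModel("brownian", D_true=0.1), acq,
    n_frames=10001, sigma_loc=0.03, seed=7,
)
res = DiffusionMLE.from_trajectory(traj, acq).fit()
print(res.summary())
```

prints

```
Diffusion MLE Results
==============================================
likelihood method                        exact
displacement steps N                     10000
frame interval dt (s)                    0.033
blur coefficient R                      0.1667
----------------------------------------------
D_hat (um^2/s)                        0.101814
  se(D_hat)                            0.00172
sigma_hat (um)                       0.0295626
sigma_hat^2 (um^2)                 0.000873949
  se(sigma_hat^2)                     3.02e-05
log-likelihood                         40803.1
converged                                 True
at D bound                               False
==============================================
```

The simulated molecule diffused at D = 0.1 µm²/s and was observed with
30 nm localization noise; the fit recovers both within two standard errors
(D̂ = 0.102 ± 0.002 µm²/s, σ̂ = 29.6 nm). The log-likelihood is reported
without the additive Gaussian constant, which does not affect the
maximizer.

The same chain is available from the shell:

```sh
trackdiff simulate trajectories --seed 1 --out-dir vehicle/
trackdiff diffuse --tracks vehicle/tracks.csv --dt 0.033 --out-dir vehicle/
trackdiff report --estimates vehicle/estimates.csv --labels vehicle --out-dir report/
```

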