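# Methods

## Model

`csdgp` treats the current source density (CSD) as a latent spatiotemporal
field `g(s, t)` and the recorded local field potential (LFP) as its image
under a biophysical forward operator plus white noise:

    phi_r(s, t)       = A_s[ mu + eta1_r + eta2_r ](s, t)
    phi~_r(s, t)      = phi_r(s, t) + eps_r(s, t),      eps ~ N(0, sigma^2)

per trial `r`, with trials independent and identically distributed.  The mean
`mu` carries stimulus-locked (evoked) activity and is held fixed during
hyperparameter estimation (zero by default).  The steady activity is the sum
of two independent zero-mean stationary Gaussian processes with a separable
space-time covariance

    k(s, t; s', t') = k_s(s, s') [ k_t1(t, t') + k_t2(t, t') ]

where

* `k_s` is a unit-variance squared exponential (SE), one lengthscale per
  measured spatial dimension (microns).  Fixing its variance at 1 removes an
  exact non-identifiability with the temporal marginal variances.
* `k_t1(dt) = var1 * exp(-|dt| / ell_t1)` — exponential, continuous but
  rough paths ("fast" component; can absorb oscillatory structure).
* `k_t2(dt) = var2 * exp(-dt^2 / (2 ell_t2^2))` — SE, smooth paths ("slow"
  component).

The slow/fast split is encouraged by priors on the two temporal
lengthscales, not enforced by constraints; the two components are not always
cleanly separated at a likelihood maximum (see Limitations).

## Forward models

Volume-conductor physics in a homogeneous, isotropic medium with scalar
conductivity (fixed at 1; all CSD amplitudes are arbitrary units, defined up
to a multiplicative constant) gives the LFP as an integral operator on the
CSD.  Two reduced geometries are implemented:

* **1D laminar probe** — the CSD is assumed constant on a cylinder of radius
  `R` around the probe axis and supported on a depth interval `[a, b]`
  (the electrode span, optionally extended by a per-side margin; the
  auditory-probe preset uses 200 um).  Weight kernel:
  `a(dz; R) = -(R/2) [ sqrt((dz/R)^2 + 1) - |dz/R| ]`.
* **2D planar probe** — the CSD is assumed constant in a slab of thickness
  `R` in front of the probe face after a zero-charge gap `tau` (default:
  half the minimum electrode spacing; `tau > 0` avoids the kernel's log
  singularity).  Weight kernel:
  `a(r; R, tau) = -(1/4pi) log[(R+tau+sqrt((R+tau)^2+r^2)) /
  (tau+sqrt(tau^2+r^2))]`.

`R` is a model hyperparameter estimated jointly with the covariance
parameters.

### Quadrature

The model's covariance integrals (`A k_s A^T`, `k_s A^T`) use Gauss-Legendre
quadrature over the CSD support with 100 nodes per dimension, one shared
node set for both integration variables of the double integral.  The 1D
weight kernel has a derivative kink at `z' = z`, which limits the plain rule
to ~1e-4 relative accuracy at 100 nodes; this plain rule is nevertheless the
package's covariance-path default because the dipole benchmark's reference
hyperparameter values are tied to it.  `apply_forward` — used for data
generation and consistency checks — instead splits the rule at the electrode
depths (composite Gauss-Legendre), restoring spectral accuracy (~1e-7
against a 1e5-node trapezoid).  The 2D slab kernel is smooth and uses a
plain tensor rule.  Node sets and weight matrices are cached per geometry.

## Likelihood, priors, fitting

With electrodes `s` (n_s) and times `t` (n_t), the marginal LFP covariance
is Kronecker-structured:

    Sigma = (A K_s A^T) (x) (K_t1 + K_t2) + sigma^2 I.

Eigendecomposing the two factors gives
`Sigma = (Q_s (x) Q_t) diag(lam_s (x) lam_t + sigma^2) (Q_s (x) Q_t)^T`, so
the log determinant, quadratic forms, conditional means and the per-trial
solve all cost `O(n_s^3 + n_t^3 + n_s n_t (n_s + n_t))`; the full `Sigma`
(n_s n_t square) is never formed.  Kronecker and dense paths agree to 1e-8
relative on small grids (tested).

Hyperparameters `theta = [R, ell_s, ell_t1, ell_t2, var1, var2, sigma^2]`
are estimated by MAP: L-BFGS-B over `log theta` on the sum of the log
marginal likelihood and log priors.  Defaults, derived from the observed
grid:

| parameter | prior | bounds |
|---|---|---|
| R | inverse-Gamma, 1%/99% quantiles at (min spacing, max span / 2) | [min spacing / 2, 0.8 max span] |
| ell_s | inverse-Gamma, quantiles (1.2 min spacing, 0.8 max span) | [min spacing / 2, max span] |
| ell_t1, ell_t2 | inverse-Gamma, quantiles (1.2 min dt, 0.8 time span) | [dt / 2, time span] |
| var1, var2 | half-Normal, sd 2 | [1e-15, 1e5] |
| sigma^2 | half-Normal, sd 0.5 | [1e-8, 1e2] |

Inverse-Gamma shape/scale are solved by 1D root-finding so the CDF hits both
quantile targets to < 1e-6.  The half-Normal priors are effectively flat
when the LFP is rescaled to roughly unit variance before fitting (the
recommended convention).  Because the forward operator's overall scale is
arbitrary, fitted signal variances compensate and can be many orders of
magnitude below 1; the variance boxes are therefore wide open downward.  The
noise floor 1e-8 (noise SD 1e-4 of a unit-scale signal) is a jitter level
that keeps noise-free data from driving the marginal density to a spike.

Numerical choices: gradients are two-point finite differences with step 1e-4
in log-parameter space (large enough to clear the eigendecomposition's
reproducibility floor, still a ~0.01% parameter change), polished at 1e-5;
the first restart starts at the prior medians and the rest at prior draws;
the top three restart endpoints are re-polished and the best polished point
wins (ties within 1e-9 go to the earlier restart, for determinism).
Defaults: 10 restarts, maxiter 1000.  Fits are deterministic given the seed.
Symmetric factors whose smallest eigenvalue is below `-1e-10 trace/n` raise;
small negative eigenvalues from quadrature round-off are clipped to zero.

## Prediction

The CSD conditional mean at arbitrary `(s', t')` is

    mu* = mu_{s',t'} + (A K_{s',s} (x) K_{t',t}) Sigma^{-1} (phi~ - A mu),

computed per trial with one shared factorization of `Sigma` (it does not
depend on the trial).  Splitting `K_{t',t}` into its exponential and SE
terms while reusing the same solve vector yields the fast and slow
components; `total = mean_part + slow + fast` then holds to the last bit,
and the containers re-validate it.  The denoised LFP (conditional mean of
`phi` given `phi~`) shrinks each eigencomponent by
`lam / (lam + sigma^2)` and returns the data unchanged when `sigma^2 = 0`.

## Synthetic data

Two generators define the package's validation conditions.

**Dipole template.**  Four signed Gaussian bumps (sources at depths 200 and
1600 um, sinks at 800 and 2200 um; spatial SD 150 um; temporal centers 25
and 30 with SDs 3 and 4 on a 50-step, unit-spaced time grid), evaluated on a
2400-point spatial grid, forwarded with `R = 150` um (trapezoid rule on the
dense grid) to 24 electrodes spanning 0-2400 um.  The noiseless LFP is
rescaled to max |value| = 1 — the scale on which the default variance priors
are calibrated and on which reconstruction comparisons are made — and the
noisy variant adds white noise of variance 7e-5.

**GP trials.**  I.i.d. draws from `N(0, K_s (x) (K_t1 + K_t2))` by
Kronecker-factored sampling (`L_s Z L_t^T`).  The multi-trial benchmark uses
the package default theta `(R=150, ell_s=200 um, ell_t1=15 ms, ell_t2=40 ms,
var1=var2=0.5, sigma^2=1e-4)` — an implementer-chosen setting, since no
canonical generating values exist for this benchmark — with 50 training and
50 test trials on 24 electrodes x 50 time steps; the forwarded LFP is
globally rescaled by its ensemble SD before noise is added.  Reconstructions
are scored at the interior electrode depths by per-trial MSE after
rescaling each field to max |value| = 1 (CSD estimators agree only up to a
constant), with a closed-form paired t-test between estimators.  Only the
ordering (GPCSD beating the second-difference traditional CSD by more than
10x) is asserted, not absolute MSE levels.

**Two-probe recordings.**  Emulates a dual laminar-probe experiment (two
24-channel probes, 100 um spacing, 1 kHz): per probe, CSD = a dipole-variant
evoked template whose timing shifts per trial (SD 2 ms, cross-probe shift
correlation 0.6 by default) + GP background + a planted 10 Hz source at a
chosen depth whose phase is shared across probes up to per-probe jitter
(coupling 0 = independent phases).  Forwarded, globally rescaled, noise
added; ground-truth shifts and phases are returned for end-to-end scoring.

What these generators do *not* emulate: non-stationary background, 1/f
spectra, spatially correlated or non-Gaussian noise, conductivity
inhomogeneity, or forward-model mismatch.  Passing tests therefore
demonstrate internal correctness and recoverability under the model's own
assumptions, not performance on arbitrary real recordings.

## Downstream analyses

* **Evoked components** — per-trial CSD predictions under baseline-fit
  hyperparameters are averaged into an evoked field (by linearity this
  equals predicting from the trial-mean LFP, which is how it is computed);
  local maxima of its absolute value seed a watershed (8-connectivity, no
  minimum basin size) on the negated magnitude.  Maxima outside the
  electrode depth range, and maxima below 10% of the global peak (finite-
  trial ripples in the near-zero background — a package choice, the
  detection step being otherwise underdetermined), still flood basins but
  those basins are folded into the background, which is held fixed across
  trials.  Per-trial component time shifts are estimated by maximizing the
  trial's Gaussian likelihood with the shifted, forwarded component
  templates as the mean: coordinate ascent over components (two sweeps),
  each a grid scan then bounded 1D refinement, shifts clamped to +/-20 ms;
  templates are shifted by linear interpolation on the time grid.  Shift
  relations across trials use Pearson correlation with Fisher-z normal
  p-values, Bonferroni-corrected over pairs; peak-time distributions use
  Gaussian KDEs and paired t-tests.
* **Spectra and coupling** — plain (untapered) per-trial periodograms with
  per-trial mean removal, averaged across trials, applied separately to the
  slow and fast prediction components; band power relative to the maximum
  channel; fourth-order Butterworth band-pass (center +/- 2 Hz), applied
  forward and backward, then Hilbert-transform phases; phase locking value
  PLV = |trial-mean unit phasor of the phase difference| (expected null
  level `sqrt(pi / 4 n)` at `n` trials); MUA envelope = 500-3000 Hz
  band-pass, rectify, 100 Hz low-pass.

## Problem sizes

Default test and benchmark sizes are chosen for fast, deterministic runs:
dipole fits on 24 x 50 grids (seconds per 10-restart fit), the multi-trial
benchmark at 50/50 trials, shift-recovery harnesses at 30-40 trials on
12-electrode probes, and the end-to-end coupling check at 500 trials with a
2-restart baseline fit.  The scaled-down shift-correlation truth check uses
400 trials with a +/-0.12 band (Fisher standard error at r=0.6 is ~0.03;
the band allows estimation noise on top).

## Known limitations

* The slow/fast decomposition is weakly identified when one component's
  variance collapses; the collapsed component's lengthscale is then decided
  by its prior and the optimizer's bounds rather than by data.  On the
  noiseless dipole benchmark the exponential lengthscale is exactly in this
  regime: its MAP value can sit anywhere between the prior mode and the
  time-span bound depending on restarts, and should not be interpreted.
* Noise-free data drive the noise variance to its floor and the marginal
  density toward a spike; estimates other than the noise variance remain
  stable, but log-posterior values are floor-dependent in that regime.
* Stationary covariances produce small ringing artifacts around strongly
  non-stationary sources, and predictions at the array edges are less
  constrained (visible as spurious low-amplitude evoked components near the
  edges; the segmentation threshold suppresses most of them).
* No charge-conservation constraint; sources and sinks need not balance.
* Anisotropic/inhomogeneous conductivity, method-of-images boundary
  corrections, non-separable kernels, and full posterior inference over
  hyperparameters are out of scope.
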