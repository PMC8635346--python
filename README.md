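# csdgp

Gaussian-process current source density estimation from multi-electrode
local field potentials.

LFPs recorded along laminar or planar probes mix contributions from many
current sources, which makes cross-population analyses on raw voltages
unreliable.  `csdgp` recovers the latent current source density (CSD) that
generated the LFP by combining a biophysical forward model with a
Gaussian-process prior on the CSD, then supports the analyses that become
possible once sources are decoupled: timescale-resolved spectra, phase
coupling between probes, and trial-to-trial timing of evoked components.

It is aimed at electrophysiologists working with 1D laminar probes (evenly
or unevenly spaced) or 2D planar probes, and at methodologists who want a
fully specified, testable reference for GP-based CSD estimation.

## Model

The observed LFP on trial `r` is

    phi~_r = A_s[ mu + eta1_r + eta2_r ] + eps_r,

where `A_s` is a linear forward operator derived from volume-conductor
physics (a cylinder model with radius `R` for laminar probes; a slab model
for planar probes), `mu` is a fixed evoked mean, `eta1`/`eta2` are
independent zero-mean GPs sharing a unit-variance squared-exponential
spatial kernel but carrying exponential (fast) and squared-exponential
(slow) temporal kernels, and `eps` is white noise.  The LFP covariance is
Kronecker-structured,

    Sigma = (A K_s A^T) (x) (K_t1 + K_t2) + sigma^2 I,

so likelihood evaluations and predictions run through the
eigendecompositions of the small spatial and temporal factors.
Hyperparameters `[R, ell_s, ell_t1, ell_t2, var1, var2, sigma^2]` are
estimated by MAP (inverse-Gamma priors on lengthscales and `R` set by
quantile matching, half-Normal priors on variances, L-BFGS-B with random
restarts), and the CSD is predicted as the GP conditional mean, decomposed
into slow and fast parts.  See `docs/methods.md` for the full account.

## Worked example

Fit the model to the built-in dipole benchmark — a four-bump CSD template
(two sources, two sinks) forwarded through the cylinder model with
`R = 150` um to a 24-electrode, 50-time-step LFP — and predict the CSD:

```python
import numpy as np
from csdgp import dipole_lfp, GPCSD1D

trials, truth = dipole_lfp()            # noiseless benchmark LFP
est = GPCSD1D(n_restarts=10, seed=1).fit(trials)
p = est.params_
print(f"R={p.R:.1f} um  ell_s={p.ell_s[0]:.1f} um  "
      f"ell_t_SE={p.ell_t2:.2f}  ell_t_exp={p.ell_t1:.2f}  "
      f"noise={p.noise_var:.2e}")

pred = est.predict(np.linspace(0, 2400, 48))   # trials x depths x times
```

Output:

```
R=165.3 um  ell_s=211.1 um  ell_t_SE=4.32  ell_t_exp=19.14  noise=1.00e-08
```

The fitted cylinder radius (~165 um) and spatial lengthscale (~211 um) are
the physically meaningful recoveries; the noise variance sits at its floor
because the input is noise-free.  With white noise of variance `7e-5` added
(`dipole_lfp(noise_var=7e-5)`), the same fit returns
`noise=6.67e-05` — the noise level is recovered from data.  The exponential
lengthscale belongs to a component whose variance collapses on this
benchmark and is weakly identified (see `docs/methods.md`, Limitations).

On the repeated-trials benchmark (50/50 train/test trials drawn from the GP
prior itself):

```
trial-mean MSE: gpcsd=1.032e-04 tcsd=4.081e-01 paired-t p=7.69e-39
```

i.e. GP-based reconstruction beats the traditional second-difference CSD by
more than three orders of magnitude on noisy data.

A command-line interface covers the same workflow
(`csdgp simulate | fit | predict | evoked | coupling | benchmark`); every
subcommand threads one seed and logs its resolved parameters.

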