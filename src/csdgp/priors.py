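"""Hyperparameter priors and the default prior/bound rules.

Lengthscales and the forward extent R get inverse-Gamma priors whose shape and
scale are solved so that the 1% and 99% quantiles land on stated values
(typically the minimum and maximum resolvable distances in space or time).
Marginal variances get broad half-Normal priors, which are close to flat as
long as the LFP is rescaled to roughly unit variance.  Every parameter also
carries a box bound used by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .geometry import ElectrodeGeometry

__all__ = [
    "InverseGammaPrior",
    "HalfNormalPrior",
    "FixedPrior",
    "make_invgamma_prior",
    "log_prior",
    "default_priors",
]


@dataclass(frozen=True)
class InverseGammaPrior:
    """Inverse-Gamma prior, parameterised by shape/scale with box bounds."""

    shape: float
    scale: float
    bounds: tuple[float, float]

    kind = "inverse-gamma"

    def logpdf(self, x: float) -> float:
        if x < self.bounds[0] or x > self.bounds[1]:
            return -np.inf
        return float(stats.invgamma.logpdf(x, self.shape, scale=self.scale))

    def sample(self, rng: np.random.Generator) -> float:
        x = stats.invgamma.rvs(self.shape, scale=self.scale, random_state=rng)
        return float(np.clip(x, self.bounds[0], self.bounds[1]))

    def median(self) -> float:
        x = stats.invgamma.ppf(0.5, self.shape, scale=self.scale)
        return float(np.clip(x, self.bounds[0], self.bounds[1]))


@dataclass(frozen=True)
class HalfNormalPrior:
    """Half-Normal prior with standard deviation ``sd`` and box bounds."""

    sd: float
    bounds: tuple[float, float]

    kind = "half-normal"

    def logpdf(self, x: float) -> float:
        if x < self.bounds[0] or x > self.bounds[1]:
            return -np.inf
        return float(stats.halfnorm.logpdf(x, scale=self.sd))

    def sample(self, rng: np.random.Generator) -> float:
        x = stats.halfnorm.rvs(scale=self.sd, random_state=rng)
        return float(np.clip(x, self.bounds[0], self.bounds[1]))

    def median(self) -> float:
        x = stats.halfnorm.ppf(0.5, scale=self.sd)
        return float(np.clip(x, self.bounds[0], self.bounds[1]))


@dataclass(frozen=True)
class FixedPrior:
    """Degenerate prior pinning a parameter to a single value."""

    value: float

    kind = "fixed"

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.value, self.value)

    def logpdf(self, x: float) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator) -> float:
        return self.value

    def median(self) -> float:
        return self.value


def make_invgamma_prior(
    q01: float, q99: float, bounds: tuple[float, float] | None = None
) -> InverseGammaPrior:
    """Inverse-Gamma prior with 1%/99% quantiles at ``q01``/``q99``.

    The quantile ratio ``ppf(0.99)/ppf(0.01)`` is strictly decreasing in the
    shape parameter, so the shape is found by 1D bracketing root-finding and
    the scale follows from the 1% quantile (the family is closed under
    scaling).  The resulting CDF hits both quantiles to well under 1e-6.
    """
    if not (0 < q01 < q99):
        raise ValueError("require 0 < q01 < q99")
    target = q99 / q01

    def log_ratio_gap(a):
        return (
            np.log(stats.invgamma.ppf(0.99, a))
            - np.log(stats.invgamma.ppf(0.01, a))
            - np.log(target)
        )

    lo, hi = 1e-3, 1e5
    with np.errstate(divide="ignore"):
        if log_ratio_gap(lo) < 0 or log_ratio_gap(hi) > 0:
            raise ValueError(f"quantile ratio {target} outside solvable range")
        shape = optimize.brentq(log_ratio_gap, lo, hi, xtol=1e-13, rtol=1e-15)
    scale = q01 / stats.invgamma.ppf(0.01, shape)
    if bounds is None:
        bounds = (q01 / 10.0, q99 * 10.0)
    return InverseGammaPrior(shape=shape, scale=scale, bounds=bounds)


def log_prior(params, specs: dict) -> float:
    """Sum of log prior densities over the parameter dict.

    ``specs`` maps parameter names (as in ``GPCSDParams``) to prior objects;
    spatial lengthscales use keys ``ell_s0``, ``ell_s1``.  Returns -inf if any
    parameter violates its bounds.
    """
    total = 0.0
    for name, spec in specs.items():
        if name.startswith("ell_s") and name not in ("ell_t1", "ell_t2"):
            d = int(name[5:]) if len(name) > 5 else 0
            val = float(np.atleast_1d(params.ell_s)[d])
        else:
            val = float(getattr(params, name))
        total += spec.logpdf(val)
    return float(total)


# the forward operator's overall scale is arbitrary (conductivity is in
# arbitrary units), so the marginal variances compensating for it can be many
# orders of magnitude below 1; the signal boxes must be wide enough never to
# bind.  The noise floor is a numerical jitter level (noise SD 1e-4 of a
# unit-scale signal) that keeps noise-free data from degenerating the fit.
VARIANCE_BOUNDS = (1e-15, 1e5)
NOISE_BOUNDS = (1e-8, 1e2)


def default_priors(
    geometry: ElectrodeGeometry,
    times,
    ell_t1_quantiles: tuple[float, float] | None = None,
    ell_t2_quantiles: tuple[float, float] | None = None,
) -> dict:
    """Default priors/bounds derived from the observed space-time grid.

    * R: inverse-Gamma with quantiles (min electrode spacing, max span / 2),
      bounded to [min spacing / 2, 0.8 * max span].
    * spatial lengthscales: quantiles (1.2 * min spacing, 0.8 * max span),
      bounds [min spacing / 2, max span].
    * temporal lengthscales (both components): quantiles (1.2 * min dt,
      0.8 * time span), bounds [min dt / 2, time span]; pass explicit
      quantile pairs to pull the two components toward separate timescales.
    * variances: half-Normal sd 2 (signal), sd 0.5 (noise).
    """
    times = np.asarray(times, dtype=float).ravel()
    ds_min, ds_max = geometry.min_spacing, geometry.max_span
    dt_min = float(np.diff(times).min()) if len(times) > 1 else 1.0
    dt_max = float(times[-1] - times[0]) if len(times) > 1 else 1.0

    t_q_default = (1.2 * dt_min, 0.8 * dt_max)
    t_bounds = (dt_min / 2.0, dt_max)

    specs = {
        "R": make_invgamma_prior(
            ds_min, ds_max / 2.0, bounds=(ds_min / 2.0, 0.8 * ds_max)
        ),
        "ell_t1": make_invgamma_prior(
            *(ell_t1_quantiles or t_q_default), bounds=t_bounds
        ),
        "ell_t2": make_invgamma_prior(
            *(ell_t2_quantiles or t_q_default), bounds=t_bounds
        ),
        "var1": HalfNormalPrior(sd=2.0, bounds=VARIANCE_BOUNDS),
        "var2": HalfNormalPrior(sd=2.0, bounds=VARIANCE_BOUNDS),
        "noise_var": HalfNormalPrior(sd=0.5, bounds=NOISE_BOUNDS),
    }
    for d in range(geometry.dims):
        specs[f"ell_s{d}"] = make_invgamma_prior(
            1.2 * ds_min, 0.8 * ds_max, bounds=(ds_min / 2.0, ds_max)
        )
    return specs
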