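"""Separable spatiotemporal covariance of the CSD prior and its forward images.

The CSD prior is a zero-mean Gaussian process with covariance

    k(s, t; s', t') = k_s(s, s') * [k_t1(t, t') + k_t2(t, t')]

where ``k_s`` is a unit-variance squared exponential (one lengthscale per
measured spatial dimension; the unit variance avoids an identifiability clash
with the temporal marginal variances), ``k_t1`` an exponential (fast, rougher
paths) and ``k_t2`` a squared exponential (slow, smooth paths).  The fast and
slow processes are distinguished through priors on the lengthscales, not hard
constraints.

Because the forward operator acts on space only, the LFP covariance inherits
the Kronecker structure: ``(A k_s A^T) (x) (K_t1 + K_t2) + noise``.  The
forward images ``A k_s A^T`` and ``k_s A^T`` are evaluated by Gauss-Legendre
quadrature over the CSD support, sharing one node set for both integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ForwardConfig1D, forward_weight_matrix, quad_nodes
from .geometry import ElectrodeGeometry

__all__ = [
    "GPCSDParams",
    "k_spatial_se",
    "k_temporal_se",
    "k_temporal_exp",
    "lfp_spatial_cov",
    "csd_lfp_cross_cov",
]

#: relative tolerance for "jitter-correctable" negative eigenvalues
PSD_RTOL = 1e-10


@dataclass
class GPCSDParams:
    """Hyperparameters theta of the GPCSD model.

    Attributes
    ----------
    R : float
        Forward-model extent parameter in microns (cylinder radius for 1D,
        slab depth for 2D).
    ell_s : ndarray
        Spatial SE lengthscales, microns, one per measured dimension.
    ell_t1 : float
        Exponential (fast) temporal lengthscale, ms.
    ell_t2 : float
        Squared-exponential (slow) temporal lengthscale, ms.
    var1, var2 : float
        Marginal variances of the fast / slow temporal processes.
    noise_var : float
        LFP white-noise variance (on the scale of the modelled LFP).
    """

    R: float
    ell_s: np.ndarray
    ell_t1: float
    ell_t2: float
    var1: float
    var2: float
    noise_var: float

    def __post_init__(self):
        self.ell_s = np.atleast_1d(np.asarray(self.ell_s, dtype=float))
        vals = [self.R, *self.ell_s, self.ell_t1, self.ell_t2,
                self.var1, self.var2, self.noise_var]
        if any(v <= 0 for v in vals[:-1]) or self.noise_var < 0:
            raise ValueError(f"all GPCSD parameters must be positive; got {self}")

    @property
    def dims(self) -> int:
        return len(self.ell_s)

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.R, *self.ell_s, self.ell_t1, self.ell_t2,
             self.var1, self.var2, self.noise_var]
        )

    @classmethod
    def from_vector(cls, x, dims: int = 1) -> "GPCSDParams":
        x = np.asarray(x, dtype=float)
        return cls(
            R=x[0],
            ell_s=x[1 : 1 + dims],
            ell_t1=x[1 + dims],
            ell_t2=x[2 + dims],
            var1=x[3 + dims],
            var2=x[4 + dims],
            noise_var=x[5 + dims],
        )


def k_spatial_se(s, s2, ell_s) -> np.ndarray:
    """Unit-variance squared-exponential spatial kernel.

    ``s``, ``s2``: coordinate arrays of shape ``(n, D)`` (or ``(n,)`` for 1D);
    ``ell_s``: lengthscale per dimension, microns.
    """
    s = np.asarray(s, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    if s2.ndim == 1:
        s2 = s2[:, None]
    ell = np.atleast_1d(np.asarray(ell_s, dtype=float))
    if s.shape[1] != s2.shape[1] or s.shape[1] != len(ell):
        raise ValueError("dimensionality mismatch between coords and lengthscales")
    d2 = np.zeros((s.shape[0], s2.shape[0]))
    for d in range(len(ell)):
        d2 += ((s[:, d][:, None] - s2[:, d][None, :]) / ell[d]) ** 2
    return np.exp(-0.5 * d2)


def k_temporal_se(t, t2, ell_t2, var2) -> np.ndarray:
    """Slow-timescale squared-exponential temporal kernel (diagonal = var2)."""
    t = np.asarray(t, dtype=float).ravel()
    t2 = np.asarray(t2, dtype=float).ravel()
    dt = t[:, None] - t2[None, :]
    return var2 * np.exp(-0.5 * (dt / ell_t2) ** 2)


def k_temporal_exp(t, t2, ell_t1, var1) -> np.ndarray:
    """Fast-timescale exponential temporal kernel, ``var1 * exp(-|dt|/ell)``.

    Exponential paths are continuous but rough (Markov in 1D time), which is
    what lets this component absorb fast oscillatory structure.
    """
    t = np.asarray(t, dtype=float).ravel()
    t2 = np.asarray(t2, dtype=float).ravel()
    dt = np.abs(t[:, None] - t2[None, :])
    return var1 * np.exp(-dt / ell_t1)


class NotPSDError(np.linalg.LinAlgError):
    pass


def ensure_psd_eigh(K: np.ndarray, name: str = "covariance"):
    """Eigendecompose a symmetric matrix, clipping jitter-scale negatives.

    Eigenvalues below ``-PSD_RTOL * trace / n`` raise; small negatives from
    quadrature round-off are clipped to zero.
    """
    Ksym = 0.5 * (K + K.T)
    lam, Q = np.linalg.eigh(Ksym)
    floor = -PSD_RTOL * max(np.trace(Ksym), 1e-300) / Ksym.shape[0]
    scale = max(abs(lam).max(), 1e-300)
    if lam.min() < min(floor, -1e-12 * scale):
        raise NotPSDError(
            f"{name} is not PSD: min eigenvalue {lam.min():.3e}"
        )
    return np.clip(lam, 0.0, None), Q


def lfp_spatial_cov(
    geometry: ElectrodeGeometry, params: GPCSDParams, cfg
) -> np.ndarray:
    """Spatial LFP covariance factor ``A k_s A^T`` at the electrode positions.

    Double Gauss-Legendre quadrature of ``a(s,u) k_s(u,v) a(s',v)`` over the
    CSD support, sharing one node set for both integration variables.
    """
    cfg = cfg.replace_R(params.R)
    F = forward_weight_matrix(geometry, cfg)
    nodes, _ = quad_nodes(geometry, cfg.quad_points)
    if geometry.dims == 1 or isinstance(cfg, ForwardConfig1D):
        K = k_spatial_se(nodes, nodes, params.ell_s)
        out = F @ K @ F.T
    else:
        # exploit k_s = k_y (x) k_z on the tensor-product node grid
        y_nodes = np.unique(nodes[:, 0])
        z_nodes = np.unique(nodes[:, 1])
        Ky = k_spatial_se(y_nodes, y_nodes, params.ell_s[:1])
        Kz = k_spatial_se(z_nodes, z_nodes, params.ell_s[1:])
        Fg = F.reshape(geometry.n_electrodes, len(y_nodes), len(z_nodes))
        T = np.einsum("eyz,yu->euz", Fg, Ky)
        T = np.einsum("euz,zv->euv", T, Kz)
        out = np.einsum("euv,fuv->ef", T, Fg)
    out = 0.5 * (out + out.T)
    ensure_psd_eigh(out, name="A k_s A^T")
    return out


def csd_lfp_cross_cov(
    pred_locs, geometry: ElectrodeGeometry, params: GPCSDParams, cfg
) -> np.ndarray:
    """Cross-covariance ``k_s(pred, .) A^T``: CSD at ``pred_locs`` (rows)
    against noiseless LFP at the electrodes (columns).  Single quadrature."""
    cfg = cfg.replace_R(params.R)
    pred_locs = np.asarray(pred_locs, dtype=float)
    if pred_locs.ndim == 1:
        pred_locs = pred_locs[:, None]
    F = forward_weight_matrix(geometry, cfg)
    nodes, _ = quad_nodes(geometry, cfg.quad_points)
    Kc = k_spatial_se(pred_locs, nodes, params.ell_s)
    return Kc @ F.T
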