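"""Biophysical forward models mapping CSD to LFP.

Volume-conductor physics (Poisson equation with homogeneous scalar
conductivity) gives the LFP as a linear integral operator applied to the CSD.
Two reduced geometries are implemented:

* 1D laminar probe: the CSD is assumed constant on a cylinder of radius ``R``
  around the probe and supported on a depth interval, which collapses the 3D
  integral to a 1D operator with weight

  ``a(z, z'; R) = -(R / 2 sigma_c) * [sqrt((dz/R)^2 + 1) - |dz/R|]``.

* 2D planar probe (Neuropixels-style): the CSD is assumed constant for a slab
  of thickness ``R`` in front of the probe face, after a zero-charge gap of
  width ``tau`` (which keeps the kernel finite at zero separation):

  ``a(r; R, tau) = -(1 / 4 pi sigma_c) *
      log[(R + tau + sqrt((R+tau)^2 + r^2)) / (tau + sqrt(tau^2 + r^2))]``

  with ``r^2 = ry^2 + rz^2``.

The traditional-CSD (second spatial difference) baseline lives here too.

All CSD amplitudes are in arbitrary units: the conductivity is fixed at 1 by
default, so estimates are defined up to a multiplicative constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline

from .geometry import ElectrodeGeometry

__all__ = [
    "ForwardConfig1D",
    "ForwardConfig2D",
    "weight_1d",
    "weight_2d",
    "apply_forward",
    "tcsd",
    "forward_weight_matrix",
    "quad_nodes",
]


@dataclass(frozen=True)
class ForwardConfig1D:
    """1D cylinder forward model: radius ``R`` (microns), conductivity
    ``sigma_c`` (arbitrary units), ``quad_points`` Gauss-Legendre nodes."""

    R: float = 150.0
    sigma_c: float = 1.0
    quad_points: int = 100

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.quad_points < 2:
            raise ValueError("quad_points must be >= 2")

    def replace_R(self, R: float) -> "ForwardConfig1D":
        return ForwardConfig1D(R=R, sigma_c=self.sigma_c, quad_points=self.quad_points)


@dataclass(frozen=True)
class ForwardConfig2D:
    """2D slab forward model: slab depth ``R`` in the unmeasured direction,
    zero-charge gap ``tau`` in front of the probe face (both microns)."""

    R: float = 150.0
    tau: float = 10.0
    sigma_c: float = 1.0
    quad_points: int = 100

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive (tau=0 is singular)")
        if self.quad_points < 2:
            raise ValueError("quad_points must be >= 2")

    def replace_R(self, R: float) -> "ForwardConfig2D":
        return ForwardConfig2D(
            R=R, tau=self.tau, sigma_c=self.sigma_c, quad_points=self.quad_points
        )


def default_forward_config(geometry: ElectrodeGeometry, R: float | None = None):
    """Geometry-appropriate forward config.

    The 2D gap ``tau`` defaults to half the minimum electrode spacing
    (positive and geometry-scaled, keeping the kernel well away from its
    ``tau -> 0`` singularity).
    """
    if R is None:
        R = geometry.min_spacing
    if geometry.dims == 1:
        return ForwardConfig1D(R=R)
    return ForwardConfig2D(R=R, tau=geometry.min_spacing / 2.0)


def weight_1d(dz, cfg: ForwardConfig1D = ForwardConfig1D()):
    """Cylinder-model weight ``a(z, z'; R)`` at separation ``dz`` (microns).

    Strictly negative; magnitude decreases with ``|dz|`` and vanishes in the
    far field like ``-R^2 / (4 sigma_c |dz|)``.
    """
    u = np.abs(np.asarray(dz, dtype=float)) / cfg.R
    return -(cfg.R / (2.0 * cfg.sigma_c)) * (np.sqrt(u * u + 1.0) - u)


def weight_2d(ry, rz, cfg: ForwardConfig2D):
    """Slab-model weight ``a(y, y', z, z'; R, tau)`` at in-plane separation
    ``(ry, rz)`` in microns."""
    r2 = np.asarray(ry, dtype=float) ** 2 + np.asarray(rz, dtype=float) ** 2
    Rt = cfg.R + cfg.tau
    num = Rt + np.sqrt(Rt * Rt + r2)
    den = cfg.tau + np.sqrt(cfg.tau * cfg.tau + r2)
    return -np.log(num / den) / (4.0 * np.pi * cfg.sigma_c)


@lru_cache(maxsize=64)
def _gl_nodes_1d(a: float, b: float, n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    nodes = 0.5 * (b - a) * x + 0.5 * (a + b)
    weights = 0.5 * (b - a) * w
    return nodes, weights


@lru_cache(maxsize=64)
def _composite_gl_1d(a: float, b: float, breaks: tuple, n_total: int):
    """Composite Gauss-Legendre with interior breakpoints.

    The 1D forward weight has a derivative kink at each electrode depth, so a
    single Gauss rule over the support converges slowly; splitting at the
    electrode positions restores spectral accuracy with the same node budget.
    """
    edges = np.unique(
        np.concatenate([[a, b], [x for x in breaks if a < x < b]])
    )
    lengths = np.diff(edges)
    alloc = np.maximum(3, np.round(n_total * lengths / lengths.sum()).astype(int))
    nodes, weights = [], []
    for (lo, hi), m in zip(zip(edges[:-1], edges[1:]), alloc):
        nd, wt = _gl_nodes_1d(float(lo), float(hi), int(m))
        nodes.append(nd)
        weights.append(wt)
    return np.concatenate(nodes), np.concatenate(weights)


def quad_nodes(geometry: ElectrodeGeometry, quad_points: int, split: bool = False):
    """Quadrature nodes/weights over the CSD support.

    1D: Gauss-Legendre over the support (the model's covariance integrals use
    this plain rule with one shared node set); with ``split=True``, a
    composite rule with breakpoints at the electrode depths is used instead,
    which restores spectral accuracy against the C0 kink of the cylinder
    weight kernel and is the default for :func:`apply_forward`.  2D:
    tensor-product Gauss-Legendre with ``quad_points`` per dimension (the
    slab kernel is smooth).  Returns ``(nodes, weights)`` with nodes of shape
    ``(n, dims)``; cached.
    """
    b = geometry.csd_bounds
    if geometry.dims == 1:
        if split:
            nodes, weights = _composite_gl_1d(
                b[0, 0], b[0, 1], tuple(geometry.coords[:, 0]), quad_points
            )
        else:
            nodes, weights = _gl_nodes_1d(b[0, 0], b[0, 1], quad_points)
        return nodes[:, None], weights
    ny, wy = _gl_nodes_1d(b[0, 0], b[0, 1], quad_points)
    nz, wz = _gl_nodes_1d(b[1, 0], b[1, 1], quad_points)
    Y, Z = np.meshgrid(ny, nz, indexing="ij")
    nodes = np.column_stack([Y.ravel(), Z.ravel()])
    weights = np.outer(wy, wz).ravel()
    return nodes, weights


def forward_weight_matrix(geometry: ElectrodeGeometry, cfg) -> np.ndarray:
    """Quadrature-discretised forward operator ``F`` (electrodes x nodes).

    ``F @ g(nodes)`` approximates the forward integral; the quadrature weights
    are folded into ``F``.
    """
    nodes, weights = quad_nodes(geometry, cfg.quad_points)
    return _weights_at(geometry.coords, nodes, cfg) * weights[None, :]


def _weights_at(targets: np.ndarray, sources: np.ndarray, cfg) -> np.ndarray:
    """Raw kernel values a(target, source), shape (n_targets, n_sources)."""
    if isinstance(cfg, ForwardConfig1D):
        dz = targets[:, 0][:, None] - sources[:, 0][None, :]
        return weight_1d(dz, cfg)
    ry = targets[:, 0][:, None] - sources[:, 0][None, :]
    rz = targets[:, 1][:, None] - sources[:, 1][None, :]
    return weight_2d(ry, rz, cfg)


def apply_forward(g, geometry: ElectrodeGeometry, cfg, grid=None, method="gauss"):
    """Push a CSD field through the forward model.

    Parameters
    ----------
    g : callable or ndarray
        Either a callable ``g(points) -> values`` evaluated at ``(n, dims)``
        spatial points (time-independent snapshot returns shape ``(n,)``, or
        ``(n, n_t)``), or an array of CSD values sampled on ``grid`` with the
        spatial axis first: shape ``(n_grid,)``, ``(n_grid, n_t)``, or for 2D
        ``(ny, nz[, n_t])``.
    grid : ndarray, optional
        Spatial sample points of ``g`` when it is an array.  1D: increasing
        coordinates covering the CSD support.  2D: tuple ``(y_grid, z_grid)``.
    method : {"gauss", "trapezoid"}
        "gauss" evaluates the integral by Gauss-Legendre quadrature over the
        CSD support (interpolating array input onto the nodes with a cubic
        spline); "trapezoid" integrates array input directly on its grid.

    Returns
    -------
    ndarray, LFP at the electrode positions (same trailing time axis as g).
    """
    if callable(g):
        nodes, weights = quad_nodes(geometry, cfg.quad_points, split=True)
        vals = np.asarray(g(nodes), dtype=float)
        A = _weights_at(geometry.coords, nodes, cfg) * weights[None, :]
        return A @ vals

    g = np.asarray(g, dtype=float)
    if grid is None:
        raise ValueError("grid is required when g is an array")

    if geometry.dims == 1:
        grid = np.asarray(grid, dtype=float).ravel()
        b = geometry.csd_bounds[0]
        if grid[0] > b[0] + 1e-9 or grid[-1] < b[1] - 1e-9:
            raise ValueError(
                f"CSD grid [{grid[0]}, {grid[-1]}] does not cover the CSD "
                f"support [{b[0]}, {b[1]}]"
            )
        if method == "trapezoid":
            A = _weights_at(geometry.coords, grid[:, None], cfg)
            dw = _trapezoid_weights(grid)
            return (A * dw[None, :]) @ g
        nodes, weights = quad_nodes(geometry, cfg.quad_points, split=True)
        spline = CubicSpline(grid, g, axis=0)
        vals = spline(nodes[:, 0])
        A = _weights_at(geometry.coords, nodes, cfg) * weights[None, :]
        return A @ vals

    # 2D: g sampled on a (y_grid x z_grid) lattice
    y_grid, z_grid = (np.asarray(a, dtype=float).ravel() for a in grid)
    if g.shape[:2] != (len(y_grid), len(z_grid)):
        raise ValueError("2D g must have shape (ny, nz[, n_t])")
    b = geometry.csd_bounds
    if (
        y_grid[0] > b[0, 0] + 1e-9
        or y_grid[-1] < b[0, 1] - 1e-9
        or z_grid[0] > b[1, 0] + 1e-9
        or z_grid[-1] < b[1, 1] - 1e-9
    ):
        raise ValueError("CSD grid does not cover the 2D CSD support")
    if method != "trapezoid":
        raise NotImplementedError("2D array input supports method='trapezoid'")
    wyz = np.outer(_trapezoid_weights(y_grid), _trapezoid_weights(z_grid))
    weighted = g * (wyz if g.ndim == 2 else wyz[..., None])
    flat = weighted.reshape(len(y_grid) * len(z_grid), -1)
    pts = np.column_stack(
        [np.repeat(y_grid, len(z_grid)), np.tile(z_grid, len(y_grid))]
    )
    A = _weights_at(geometry.coords, pts, cfg)
    out = A @ flat
    if g.ndim == 2:
        return out[:, 0]
    return out.reshape(geometry.n_electrodes, *g.shape[2:])


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    w[:-1] += np.diff(x) / 2.0
    w[1:] += np.diff(x) / 2.0
    return w


def tcsd(lfp: np.ndarray, spacing: float) -> np.ndarray:
    """Traditional CSD: negative discrete second spatial difference.

    Parameters
    ----------
    lfp : ndarray, shape (..., electrodes, time)
        LFP on an evenly spaced 1D array (spacing in microns).

    Returns
    -------
    ndarray, shape (..., electrodes - 2, time): CSD estimate at the interior
    electrode positions (the Poisson-equation sign convention, so a current
    sink between two sources appears negative).
    """
    lfp = np.asarray(lfp, dtype=float)
    if lfp.shape[-2] < 3:
        raise ValueError("tcsd needs at least 3 electrodes")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return -(
        lfp[..., :-2, :] - 2.0 * lfp[..., 1:-1, :] + lfp[..., 2:, :]
    ) / spacing**2


def check_even_spacing(coords: np.ndarray, rtol: float = 1e-6) -> float:
    """Return the common spacing of a 1D electrode array or raise."""
    z = np.asarray(coords, dtype=float).ravel()
    d = np.diff(z)
    if np.any(np.abs(d - d[0]) > rtol * abs(d[0])):
        raise ValueError("traditional CSD requires evenly spaced electrodes")
    return float(d[0])
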