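"""Data containers for electrode geometry, LFP trials, and CSD predictions.

Canonical units throughout the package: microns for space, milliseconds for
time, Hz for sampling rates.  Coordinates are physical positions, never
indices, so unevenly spaced arrays are handled transparently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeGeometry", "LFPTrials", "CSDPrediction"]


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def _as_coords(coords) -> np.ndarray:
    c = np.asarray(coords, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.ndim != 2 or c.shape[1] not in (1, 2):
        raise ValidationError(
            f"coords must be (n,) or (n, 1) or (n, 2); got shape {c.shape}"
        )
    return c


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Measurement-site coordinates plus the spatial support of the CSD.

    Parameters
    ----------
    coords : array-like
        Electrode positions in microns.  Shape ``(n,)`` or ``(n, 1)`` for a
        laminar (depth-only) probe, ``(n, 2)`` for a planar (width, depth)
        array.  Must be sorted lexicographically and strictly increasing along
        the last listed axis within each block.
    extension : float
        Margin in microns added on each side of the electrode span when
        forming the CSD support (the integration interval of the forward
        model).  Zero by default; the auditory-probe preset uses 200.
    csd_bounds : array-like, optional
        Explicit ``(dims, 2)`` lower/upper support limits.  Defaults to the
        electrode span extended by ``extension`` per side.
    """

    coords: np.ndarray
    extension: float = 0.0
    csd_bounds: np.ndarray | None = None

    def __post_init__(self):
        coords = _as_coords(self.coords)
        object.__setattr__(self, "coords", coords)
        if self.extension < 0:
            raise ValidationError("extension must be >= 0")
        order = np.lexsort(coords.T[::-1])
        if not np.array_equal(order, np.arange(len(coords))):
            raise ValidationError("electrode coordinates must be sorted increasing")
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValidationError("electrode coordinates must be distinct")
        if self.csd_bounds is None:
            lo = coords.min(axis=0) - self.extension
            hi = coords.max(axis=0) + self.extension
            bounds = np.stack([lo, hi], axis=1)
        else:
            bounds = np.asarray(self.csd_bounds, dtype=float)
            if bounds.ndim == 1:
                bounds = bounds[None, :]
            if bounds.shape != (coords.shape[1], 2):
                raise ValidationError(
                    f"csd_bounds must have shape ({coords.shape[1]}, 2); "
                    f"got {bounds.shape}"
                )
            if np.any(bounds[:, 0] > coords.min(axis=0)) or np.any(
                bounds[:, 1] < coords.max(axis=0)
            ):
                raise ValidationError("csd_bounds must contain all electrodes")
        object.__setattr__(self, "csd_bounds", bounds)

    @property
    def dims(self) -> int:
        return self.coords.shape[1]

    @property
    def n_electrodes(self) -> int:
        return self.coords.shape[0]

    @property
    def min_spacing(self) -> float:
        """Smallest nonzero inter-electrode distance (microns)."""
        d = np.linalg.norm(self.coords[:, None, :] - self.coords[None, :, :], axis=-1)
        return float(d[d > 0].min())

    @property
    def max_span(self) -> float:
        """Largest inter-electrode distance (microns)."""
        d = np.linalg.norm(self.coords[:, None, :] - self.coords[None, :, :], axis=-1)
        return float(d.max())


@dataclass
class LFPTrials:
    """Multi-trial LFP data: ``data[trial, electrode, time]``.

    The voltage scale is arbitrary; rescaling to roughly unit variance before
    model fitting is recommended so the default variance priors stay
    uninformative.
    """

    data: np.ndarray
    times: np.ndarray
    geometry: ElectrodeGeometry
    sample_rate: float  # Hz
    units: str = "arbitrary"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be trials x electrodes x time; got shape {self.data.shape}"
            )
        n_tr, n_e, n_t = self.data.shape
        if n_e != self.geometry.n_electrodes:
            raise ValidationError(
                f"electrode axis has length {n_e} but geometry lists "
                f"{self.geometry.n_electrodes} electrodes"
            )
        if self.times.shape != (n_t,):
            raise ValidationError(
                f"times has shape {self.times.shape}; expected ({n_t},)"
            )
        if n_t > 1:
            dt = np.diff(self.times)
            if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-9 * max(dt.max(), 1.0):
                raise ValidationError("time stamps must be uniform and increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        if len(self.times) > 1:
            return float(self.times[1] - self.times[0])
        return 1000.0 / self.sample_rate


@dataclass
class CSDPrediction:
    """Per-trial CSD prediction decomposed into timescale components.

    ``total = mean_part + slow + fast`` elementwise (shared solve vector, so
    the identity holds to machine precision).
    """

    locations: np.ndarray
    times: np.ndarray
    total: np.ndarray
    slow: np.ndarray
    fast: np.ndarray
    mean_part: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.locations = _as_coords(self.locations)
        self.times = np.asarray(self.times, dtype=float)
        for name in ("total", "slow", "fast"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.mean_part is None:
            self.mean_part = np.zeros_like(self.total)
        else:
            self.mean_part = np.broadcast_to(
                np.asarray(self.mean_part, dtype=float), self.total.shape
            ).copy()
        shp = self.total.shape
        if shp != self.slow.shape or shp != self.fast.shape:
            raise ValidationError("total/slow/fast shapes differ")
        if shp[-2:] != (len(self.locations), len(self.times)):
            raise ValidationError(
                f"component shape {shp} does not match (locations, times) = "
                f"({len(self.locations)}, {len(self.times)})"
            )
        recon = self.mean_part + self.slow + self.fast
        scale = max(np.abs(self.total).max(), 1.0)
        if np.abs(self.total - recon).max() > 1e-8 * scale:
            raise ValidationError("total != mean_part + slow + fast")

    @property
    def n_trials(self) -> int:
        return self.total.shape[0]
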