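"""Readers/writers for LFP trials and CSD predictions.

Canonical container: HDF5 with datasets ``/lfp`` (trials x electrodes x
time), ``/coords`` (microns), ``/times`` (ms) and attributes
``sample_rate_hz`` and ``units``.  A delimited-text fallback (one CSV per
trial, electrodes x time) covers small single-trial exchanges.  Round trips
are bit-exact for 64-bit floats.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .geometry import CSDPrediction, ElectrodeGeometry, LFPTrials

__all__ = [
    "save_lfp_trials",
    "load_lfp_trials",
    "load_lfp_trials_csv",
    "save_prediction",
    "load_prediction",
]

_LAYOUT_AXES = {"trials": 0, "electrodes": 1, "time": 2}


def save_lfp_trials(lfp: LFPTrials, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=lfp.data)
        f.create_dataset("coords", data=lfp.geometry.coords)
        f.create_dataset("times", data=lfp.times)
        f.create_dataset("csd_bounds", data=lfp.geometry.csd_bounds)
        f.attrs["sample_rate_hz"] = lfp.sample_rate
        f.attrs["units"] = lfp.units
        f.attrs["extension_um"] = lfp.geometry.extension


def load_lfp_trials(path, layout: str = "trials,electrodes,time") -> LFPTrials:
    """Load LFP trials from HDF5.

    ``layout`` names the axis order of the stored ``/lfp`` dataset, e.g.
    ``"electrodes,time,trials"``; axes are permuted to the canonical
    (trials, electrodes, time).  Validation errors name the offending axis.
    """
    axes = [a.strip() for a in layout.split(",")]
    if sorted(axes) != sorted(_LAYOUT_AXES):
        raise ValueError(f"layout must permute {list(_LAYOUT_AXES)}; got {axes}")
    with h5py.File(path, "r") as f:
        data = np.asarray(f["lfp"], dtype=float)
        coords = np.asarray(f["coords"], dtype=float)
        times = np.asarray(f["times"], dtype=float)
        bounds = np.asarray(f["csd_bounds"], dtype=float) if "csd_bounds" in f else None
        rate = float(f.attrs.get("sample_rate_hz", 1000.0))
        units = str(f.attrs.get("units", "arbitrary"))
        ext = float(f.attrs.get("extension_um", 0.0))
    data = np.transpose(data, [axes.index(k) for k in _LAYOUT_AXES])
    geom = ElectrodeGeometry(coords, extension=ext, csd_bounds=bounds)
    n_e = coords.shape[0] if coords.ndim > 0 else len(coords)
    if data.shape[1] != n_e:
        raise ValueError(
            f"electrode axis of /lfp has length {data.shape[1]} but /coords "
            f"lists {n_e} electrodes"
        )
    return LFPTrials(data=data, times=times, geometry=geom, sample_rate=rate,
                     units=units)


def load_lfp_trials_csv(
    trial_paths,
    coords,
    times,
    sample_rate: float,
    delimiter: str = ",",
) -> LFPTrials:
    """Load one delimited-text file per trial (each electrodes x time)."""
    arrays = [np.loadtxt(p, delimiter=delimiter, ndmin=2) for p in trial_paths]
    data = np.stack(arrays)
    geom = ElectrodeGeometry(coords)
    return LFPTrials(data=data, times=np.asarray(times, dtype=float),
                     geometry=geom, sample_rate=sample_rate)


def save_prediction(pred: CSDPrediction, path) -> None:
    """Write a CSDPrediction to HDF5 (total/slow/fast/mean_part datasets)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in ("total", "slow", "fast", "mean_part"):
            f.create_dataset(name, data=getattr(pred, name))
        f.create_dataset("locations", data=pred.locations)
        f.create_dataset("times", data=pred.times)


def load_prediction(path) -> CSDPrediction:
    """Load a CSDPrediction; the component-sum invariant is re-validated."""
    with h5py.File(path, "r") as f:
        kw = {
            name: np.asarray(f[name], dtype=float)
            for name in ("total", "slow", "fast", "mean_part", "locations", "times")
        }
    return CSDPrediction(**kw)
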