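"""Steady-activity spectral analysis and phase coupling.

Per-trial periodograms (plain, untapered, per-trial mean removed) averaged
across trials; Butterworth band-pass + Hilbert instantaneous phase; phase
locking value (PLV, the modulus of the trial-averaged unit phasor of a phase
difference); and the multi-unit activity (MUA) envelope from wideband data.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "trial_periodograms",
    "relative_band_power",
    "bandpass_phase",
    "plv",
    "plv_timecourse",
    "mua_envelope",
]


def trial_periodograms(x: np.ndarray, sample_rate: float):
    """Trial-averaged power spectra.

    ``x``: (trials, channels, time), sample_rate in Hz.  Each trial/channel
    gets a plain (boxcar) periodogram with per-trial mean removal, scaled as
    one-sided power spectral density; the trial mean is returned.

    Returns ``(freqs_hz, psd)`` with psd of shape (channels, n_freqs).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (trials, channels, time)")
    freqs, psd = signal.periodogram(
        x, fs=sample_rate, window="boxcar", detrend="constant",
        scaling="density", axis=-1,
    )
    return freqs, psd.mean(axis=0)


def relative_band_power(
    freqs: np.ndarray, spectra: np.ndarray, band_center: float,
    band_halfwidth: float,
):
    """Band-integrated power per channel, normalized to the maximum channel.

    Returns values in (0, 1] (channels with no power give 0).
    """
    freqs = np.asarray(freqs, dtype=float)
    spectra = np.asarray(spectra, dtype=float)
    sel = (freqs >= band_center - band_halfwidth) & (
        freqs <= band_center + band_halfwidth
    )
    if not np.any(sel):
        raise ValueError("band contains no frequency bins")
    if sel.sum() == 1:
        power = spectra[..., sel].sum(axis=-1)
    else:
        power = np.trapezoid(spectra[..., sel], freqs[sel], axis=-1)
    m = power.max()
    return power / m if m > 0 else power


def _butter_band(center_hz, halfwidth_hz, order, sample_rate):
    nyq = sample_rate / 2.0
    lo, hi = center_hz - halfwidth_hz, center_hz + halfwidth_hz
    if lo <= 0 or hi >= nyq:
        raise ValueError(
            f"band ({lo}, {hi}) Hz outside the open interval (0, {nyq}) Hz"
        )
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sample_rate,
                         output="sos")


def bandpass_phase(
    x: np.ndarray,
    center_hz: float,
    halfwidth_hz: float = 2.0,
    order: int = 4,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Instantaneous phase of a band-limited component.

    Butterworth band-pass of the given order centred at ``center_hz`` +/-
    ``halfwidth_hz``, applied forward and backward (zero phase distortion),
    then the analytic-signal angle, radians in (-pi, pi].  Operates on the
    last axis.
    """
    sos = _butter_band(center_hz, halfwidth_hz, order, sample_rate)
    filt = signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)
    return np.angle(signal.hilbert(filt, axis=-1))


def plv(phase_a: np.ndarray, phase_b: np.ndarray, axis: int = 0):
    """Phase locking value: ``|mean exp(i (phase_a - phase_b))|`` over trials.

    Always in [0, 1]; invariant to any fixed phase offset between the two
    signals.  ``axis`` is the trial axis.
    """
    d = np.asarray(phase_a, dtype=float) - np.asarray(phase_b, dtype=float)
    return np.abs(np.mean(np.exp(1j * d), axis=axis))


def plv_timecourse(phases: np.ndarray) -> np.ndarray:
    """Mean pairwise PLV per time point.

    ``phases``: (trials, channels, time).  Computes the PLV between every
    unordered channel pair at each time point and averages over pairs.
    """
    phases = np.asarray(phases, dtype=float)
    n_r, n_c, n_t = phases.shape
    z = np.exp(1j * phases)
    # pairwise trial-mean phasor products: (channels, channels, time)
    M = np.einsum("rct,rdt->cdt", z, np.conj(z)) / n_r
    iu = np.triu_indices(n_c, k=1)
    return np.abs(M[iu[0], iu[1], :]).mean(axis=0)


def mua_envelope(
    wideband: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = (500.0, 3000.0),
    lowpass_hz: float = 100.0,
    order: int = 4,
) -> np.ndarray:
    """Multi-unit activity envelope from wideband extracellular data.

    Band-pass (default 500-3000 Hz), full-wave rectify, then low-pass at
    ``lowpass_hz``.  Requires ``sample_rate > 2 * band[1]``.
    """
    if sample_rate <= 2 * band[1]:
        raise ValueError(
            f"sample_rate {sample_rate} too low for the {band} Hz band"
        )
    sos_bp = signal.butter(order, list(band), btype="bandpass", fs=sample_rate,
                           output="sos")
    sos_lp = signal.butter(order, lowpass_hz, btype="lowpass", fs=sample_rate,
                           output="sos")
    x = signal.sosfiltfilt(sos_bp, np.asarray(wideband, dtype=float), axis=-1)
    return signal.sosfiltfilt(sos_lp, np.abs(x), axis=-1)
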