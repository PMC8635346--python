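"""Synthetic two-probe recording generator.

Emulates the shape of a dual laminar-probe experiment (two 24-channel probes,
100 um spacing, 1 kHz sampling): on each probe the CSD is the sum of

* a planted evoked template (a scaled dipole-template variant) whose timing
  shifts from trial to trial with a stated SD and a stated cross-probe shift
  correlation;
* steady GP background activity from the separable prior; and
* a planted 10 Hz oscillatory source at a chosen depth whose phase is shared
  across probes up to per-probe jitter, controlling coupling strength.

The CSD is forwarded through the 1D cylinder model, globally rescaled, and
corrupted with white noise.  Ground truth (shifts, phases, depths) is
returned so recovery can be scored end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import ForwardConfig1D, apply_forward
from .geometry import ElectrodeGeometry, LFPTrials
from .kernels import GPCSDParams, k_spatial_se, k_temporal_exp, k_temporal_se
from .simulate import DipoleTemplateSpec, dipole_template, sample_gp_csd_trials

__all__ = ["TwoProbeSpec", "make_two_probe_fixture"]


@dataclass(frozen=True)
class TwoProbeSpec:
    """Study conditions of the synthetic two-probe recording."""

    n_trials: int = 500
    n_electrodes: int = 24
    spacing_um: float = 100.0
    sample_rate_hz: float = 1000.0
    t_start_ms: float = -100.0
    t_stop_ms: float = 300.0
    # evoked timing variability
    shift_sd_ms: float = 2.0
    shift_corr: float = 0.6
    evoked_amplitude: float = 1.0
    # steady GP background
    gp_params: GPCSDParams = field(
        default_factory=lambda: GPCSDParams(
            R=150.0, ell_s=200.0, ell_t1=5.0, ell_t2=40.0,
            var1=0.3, var2=0.3, noise_var=1e-4,
        )
    )
    # planted oscillation
    osc_freq_hz: float = 10.0
    osc_amplitude: float = 1.0
    osc_depth_um: float = 1200.0
    osc_width_um: float = 200.0
    coupling: float = 1.0  # 1 = shared phase, 0 = independent phases
    phase_jitter_sd: float = 0.3  # radians, applied when coupling > 0
    noise_var: float = 1e-4


def make_two_probe_fixture(spec: TwoProbeSpec | None = None, seed: int = 0):
    """Generate two simultaneous synthetic probe recordings.

    Returns ``(probes, truth)`` where ``probes`` is a list of two
    :class:`LFPTrials` and ``truth`` records per-probe shifts, oscillation
    phases, the ground-truth CSD grid, and the per-probe CSD fields.
    """
    spec = spec or TwoProbeSpec()
    rng = np.random.default_rng(seed)
    coords = np.arange(spec.n_electrodes) * spec.spacing_um
    geom = ElectrodeGeometry(coords)
    span = coords[-1]
    dt = 1000.0 / spec.sample_rate_hz
    times = np.arange(spec.t_start_ms, spec.t_stop_ms, dt)
    n_t = len(times)
    grid = np.linspace(0.0, span, 4 * (spec.n_electrodes - 1) + 1)
    cfg = ForwardConfig1D(R=spec.gp_params.R)

    # evoked template: dipole variant compressed onto the probe span
    tpl_spec = DipoleTemplateSpec(
        space_min=0.0, space_max=span, n_times=120,
        pos_space_means=(0.1 * span, 0.65 * span),
        neg_space_means=(0.35 * span, 0.9 * span),
        time_means=(30.0, 45.0), time_sds=(5.0, 8.0), space_sd=0.08 * span,
    )
    _, tpl_t, tpl = dipole_template(tpl_spec, n_space=len(grid))
    # embed template at t=0..120 ms on the trial time axis
    template = np.zeros((len(grid), n_t))
    for i, tt in enumerate(tpl_t):
        j = int(round((tt - spec.t_start_ms) / dt))
        if 0 <= j < n_t:
            template[:, j] = spec.evoked_amplitude * tpl[:, i]

    # correlated per-trial shifts across the two probes
    cov = spec.shift_sd_ms**2 * np.array(
        [[1.0, spec.shift_corr], [spec.shift_corr, 1.0]]
    )
    shifts = rng.multivariate_normal(np.zeros(2), cov, size=spec.n_trials)

    # oscillation phases
    common = rng.uniform(-np.pi, np.pi, size=spec.n_trials)
    phases = np.empty((2, spec.n_trials))
    for p in range(2):
        if spec.coupling <= 0:
            phases[p] = rng.uniform(-np.pi, np.pi, size=spec.n_trials)
        else:
            phases[p] = common + spec.phase_jitter_sd * rng.standard_normal(
                spec.n_trials
            )
    bump = np.exp(-0.5 * ((grid - spec.osc_depth_um) / spec.osc_width_um) ** 2)

    probes = []
    truth = {
        "grid": grid,
        "times": times,
        "shifts": shifts.T,
        "phases": phases,
        "template": template,
        "osc_depth_um": spec.osc_depth_um,
        "csd": [],
    }
    for p in range(2):
        gp = sample_gp_csd_trials(
            spec.gp_params, grid, times, spec.n_trials,
            seed=int(rng.integers(2**31 - 1)),
        )
        csd = gp
        for r in range(spec.n_trials):
            shifted = np.empty_like(template)
            for gi in range(len(grid)):
                shifted[gi] = np.interp(
                    times - shifts[r, p], times, template[gi], left=0.0, right=0.0
                )
            osc = (
                spec.osc_amplitude
                * bump[:, None]
                * np.sin(
                    2 * np.pi * spec.osc_freq_hz * times[None, :] / 1000.0
                    + phases[p, r]
                )
            )
            csd[r] += shifted + osc
        lfp = np.stack(
            [
                apply_forward(csd[r], geom, cfg, grid=grid, method="trapezoid")
                for r in range(spec.n_trials)
            ]
        )
        lfp /= lfp.std()
        lfp += rng.normal(0.0, np.sqrt(spec.noise_var), size=lfp.shape)
        probes.append(
            LFPTrials(data=lfp, times=times, geometry=geom,
                      sample_rate=spec.sample_rate_hz)
        )
        truth["csd"].append(csd)
    return probes, truth
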