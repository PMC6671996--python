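"""Synthetic stand-ins for the experimental corticosterone calibration data.

The pipeline is calibrated against cosinor parameters of a measured CORT
circadian profile.  This module generates that calibration input from the
model itself: simulate the entrained cycle at a known generating triple,
fit its cosinor, optionally perturb the parameters by seeded Gaussian noise,
and attach acceptance standard deviations.  The defaults mimic the study
phenotype qualitatively — a 24 h entrained rhythm under a 14 h light / 10 h
dark schedule with a clear amplitude — and the SD half-widths (10% of mesor
and amplitude, 1 h of acrophase) are explicitly surrogate values chosen as
plausible inter-animal variability, not transcriptions of any experimental
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cosinor import CalibrationTarget, CosinorFit, fit_cosinor
from .params import LightSchedule, ModelParameters, default_parameters
from .simulate import integrate_to_limit_cycle

__all__ = ["SyntheticTargetSpec", "make_calibration_target", "make_noisy_cort_series"]


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Recipe for a synthetic calibration target.

    ``params`` carries the full model parameter set whose (K_p1, K_p2,
    k_p3) triple is the generating triple.  ``noise_sd`` are the seeded
    Gaussian perturbations applied to the fitted (mesor, amplitude,
    acrophase); at zero noise the generating triple is guaranteed to pass
    its own target.  ``sd`` are the acceptance half-widths attached to the
    target, given as (fraction of mesor, fraction of amplitude, hours).
    """

    params: ModelParameters = field(default_factory=default_parameters)
    schedule: LightSchedule = field(default_factory=LightSchedule)
    noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sd: tuple[float, float, float] = (0.10, 0.10, 1.0)
    seed: int = 0
    transient_days: int = 40
    tol: float = 1e-4

    @property
    def triple(self) -> tuple[float, float, float]:
        p = self.params
        return (p.K_p1, p.K_p2, p.k_p3)


def _entrained_fit(spec: SyntheticTargetSpec) -> CosinorFit:
    cyc = integrate_to_limit_cycle(
        spec.params,
        spec.schedule,
        transient_days=spec.transient_days,
        tol=spec.tol,
    )
    return fit_cosinor(cyc.times, cyc.cort, period=spec.schedule.period)


def make_calibration_target(spec: SyntheticTargetSpec) -> CalibrationTarget:
    """Simulate the generating triple, fit its cosinor, add seeded noise.

    The Gaussian perturbation of the amplitude is truncated (redrawn) to
    keep the amplitude positive; the acrophase wraps modulo the period.
    Identical specs produce bit-identical targets.
    """
    fit = _entrained_fit(spec)
    rng = np.random.default_rng(spec.seed)
    m_sd, a_sd, p_sd = spec.noise_sd
    mesor = fit.mesor + (rng.normal(0.0, m_sd) if m_sd > 0 else 0.0)
    amplitude = fit.amplitude
    if a_sd > 0:
        for _ in range(100):
            cand = fit.amplitude + rng.normal(0.0, a_sd)
            if cand > 0:
                amplitude = cand
                break
    acrophase = fit.acrophase
    if p_sd > 0:
        acrophase = float((fit.acrophase + rng.normal(0.0, p_sd)) % fit.period)
    target = CosinorFit(
        mesor=mesor, amplitude=amplitude, acrophase=acrophase, period=fit.period
    )
    return CalibrationTarget(
        target=target,
        sd_mesor=spec.sd[0] * abs(target.mesor),
        sd_amplitude=spec.sd[1] * target.amplitude,
        sd_acrophase=spec.sd[2],
    )


def make_noisy_cort_series(
    spec: SyntheticTargetSpec,
    sampling_interval: float = 1.0,
    obs_noise_sd: float = 0.0,
    n_days: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Entrained CORT sampled on a grid plus seeded observation noise.

    Emulates a measured time series suitable for cosinor analysis: the
    entrained cycle tiled over ``n_days`` days, sampled every
    ``sampling_interval`` hours, with i.i.d. Gaussian noise of SD
    ``obs_noise_sd`` added.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be positive")
    cyc = integrate_to_limit_cycle(
        spec.params,
        spec.schedule,
        transient_days=spec.transient_days,
        tol=spec.tol,
    )
    period = spec.schedule.period
    t_rel = cyc.times - cyc.times[0]
    times = np.arange(0.0, n_days * period - 1e-9, sampling_interval)
    values = np.interp(times % period, t_rel, cyc.cort)
    if obs_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, obs_noise_sd, size=len(values))
    return times, values
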