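"""Synthetic compensatory eye-movement sessions with known gain/phase."""

from __future__ import annotations

import numpy as np

from ..eyemov import EyeTrace
from .params import EyeSimParams


def simulate_eye_session(params: EyeSimParams) -> EyeTrace:
    """Sinusoidal stimulus plus an eye trace of known gain/phase.

    The stimulus is ``A·sin(2πft)``.  For ``condition="VOR"`` the eye is
    generated opposite to the stimulus (compensatory direction), so that
    :func:`cerebquant.eyemov.gain_phase` recovers exactly
    ``(true_gain, true_phase)``.  Optional quick phases are step
    displacements at Poisson times with sign-symmetric normal magnitudes.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate
    w = 2 * np.pi * params.frequency
    phi = np.radians(params.true_phase)
    stim = params.stim_amplitude * np.sin(w * t)
    eye = params.true_gain * params.stim_amplitude * np.sin(w * t + phi)
    if params.condition == "VOR":
        eye = -eye
    if params.saccade_rate > 0:
        n_sac = rng.poisson(params.saccade_rate * params.duration)
        times = rng.uniform(0.0, params.duration, size=n_sac)
        amps = rng.normal(params.saccade_amp, 0.3 * params.saccade_amp, size=n_sac)
        signs = rng.choice([-1.0, 1.0], size=n_sac)
        for ts, a, s in zip(times, amps, signs):
            eye[t >= ts] += s * abs(a)
    if params.noise_sd > 0:
        eye = eye + rng.normal(0.0, params.noise_sd, size=n)
    return EyeTrace(
        time=t,
        eye=eye,
        stim=stim,
        frequency=params.frequency,
        stimulus_amplitude=params.stim_amplitude,
        condition=params.condition,
    )
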