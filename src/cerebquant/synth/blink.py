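"""Synthetic eyeblink-conditioning sessions with known CR ground truth.

Each trial runs from −500 to +1000 ms around CS onset.  Conditioned
responses are raised-cosine eyelid closures with onset and peak latencies
drawn inside the configured windows and amplitude well above the 0.05
detection criterion; unconditioned responses rise ~5 ms after the air
puff to the full-blink amplitude.  Paired-trial traces take the pointwise
maximum of the CR and UR components (closure saturates; it does not add).
Noise is Gaussian, temporally smoothed with a 10 ms kernel and rescaled
to the requested SD, mimicking the slow fluctuations of a real eyelid
trace rather than per-frame pixel noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ..eyeblink import CS_ONLY, PAIRED, US_ONLY, EyelidTrial, SessionProtocol, build_protocol
from .params import BlinkSimParams

TRIAL_START_MS = -500.0
TRIAL_END_MS = 1000.0


@dataclass
class TrialSet:
    """Simulated session: trials in protocol order plus ground truth."""

    trials: List[EyelidTrial]
    truth: pd.DataFrame  # per-trial: trial, type, has_cr, cr_onset_ms, cr_peak_ms, cr_amp


def _raised_cosine_rise(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """0 before t0, smooth rise to 1 at t1, 1 afterwards."""
    out = np.zeros_like(t)
    rising = (t >= t0) & (t < t1)
    out[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - t0) / (t1 - t0)))
    out[t >= t1] = 1.0
    return out


def _decay(t: np.ndarray, t0: float, tau_ms: float) -> np.ndarray:
    """1 before t0, smooth raised-cosine fall to 0 over tau_ms."""
    out = np.ones_like(t)
    falling = (t >= t0) & (t < t0 + tau_ms)
    out[falling] = 0.5 * (1 + np.cos(np.pi * (t[falling] - t0) / tau_ms))
    out[t >= t0 + tau_ms] = 0.0
    return out


def _smoothed_noise(rng: np.random.Generator, n: int, sd: float, dt_ms: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, size=n)
    smooth = gaussian_filter1d(white, sigma=10.0 / dt_ms)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def simulate_eyeblink_session(
    params: BlinkSimParams, protocol: Optional[SessionProtocol] = None
) -> TrialSet:
    """Generate a full conditioning session with retained CR flags."""
    if protocol is None:
        protocol = build_protocol()
    rng = np.random.default_rng(params.seed)
    dt_ms = 1000.0 / params.sampling_rate
    t = np.arange(TRIAL_START_MS, TRIAL_END_MS + 0.5 * dt_ms, dt_ms)
    us_on = protocol.cs_us_interval
    cs_end = protocol.cs_duration

    trials: List[EyelidTrial] = []
    rows = []
    for k, ttype in enumerate(protocol.trial_types):
        fec = np.zeros_like(t)
        has_cr = False
        cr_onset = cr_peak = cr_amp = np.nan

        if ttype in (PAIRED, CS_ONLY) and rng.uniform() < params.cr_prob:
            has_cr = True
            cr_onset = rng.uniform(*params.cr_onset_range)
            lo = max(params.cr_peak_range[0], cr_onset + 40.0)
            cr_peak = rng.uniform(lo, max(params.cr_peak_range[1], lo + 1.0))
            cr_amp = float(np.clip(rng.normal(params.cr_amp_mean, params.cr_amp_sd), 0.1, 1.0))
            cr = cr_amp * _raised_cosine_rise(t, cr_onset, cr_peak)
            cr = cr * _decay(t, cs_end + 120.0, 250.0)  # release after CS offset
            fec = np.maximum(fec, cr)

        if ttype in (PAIRED, US_ONLY):
            ur = params.ur_amp * _raised_cosine_rise(t, us_on + 5.0, us_on + 60.0)
            ur = ur * _decay(t, us_on + 100.0, 300.0)
            fec = np.maximum(fec, ur)

        fec = fec + _smoothed_noise(rng, t.size, params.noise_sd, dt_ms)
        us_onset_ms = us_on if ttype in (PAIRED, US_ONLY) else None
        trials.append(EyelidTrial(t.copy(), fec, ttype, us_onset_ms))
        rows.append(
            {
                "trial": k,
                "type": ttype,
                "has_cr": has_cr,
                "cr_onset_ms": cr_onset,
                "cr_peak_ms": cr_peak,
                "cr_amp": cr_amp,
            }
        )
    return TrialSet(trials=trials, truth=pd.DataFrame(rows))
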