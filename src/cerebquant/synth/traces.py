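"""Render labeled spike trains into raw extracellular-like traces.

Each event contributes a stereotyped waveform (a short biphasic one for
simple spikes; a longer multiphasic one with spikelets for complex
spikes), placed so that the template's absolute-peak sample lands on the
event time, plus white Gaussian noise.  The ground-truth train is kept by
the caller, so the detection/classification stage can be scored exactly.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..spiketrain import CS, SS, LabeledSpikeTrain, RawTrace
from .params import TraceSimParams


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def make_ss_template(sampling_rate: float) -> np.ndarray:
    """Biphasic simple-spike waveform (~1.5 ms), peak-normalized to 1."""
    t = np.arange(-0.6e-3, 1.2e-3, 1.0 / sampling_rate)
    w = _gauss(t, 0.0, 0.12e-3) - 0.45 * _gauss(t, 0.45e-3, 0.28e-3)
    return w / np.max(np.abs(w))


def make_cs_template(sampling_rate: float) -> np.ndarray:
    """Multiphasic complex-spike waveform (~5 ms) with trailing spikelets."""
    t = np.arange(-0.6e-3, 4.5e-3, 1.0 / sampling_rate)
    w = _gauss(t, 0.0, 0.15e-3)
    for mu, amp in [(1.1e-3, 0.30), (2.2e-3, 0.24), (3.3e-3, 0.18)]:
        w += amp * _gauss(t, mu, 0.25e-3)
    w += 0.15 * _gauss(t, 1.8e-3, 1.2e-3)  # slow depolarization envelope
    w -= 0.30 * _gauss(t, 4.0e-3, 0.4e-3)
    return w / np.max(np.abs(w))


def render_trace(train: LabeledSpikeTrain, params: TraceSimParams) -> RawTrace:
    """Sum templates at event times and add white Gaussian noise.

    Emits an explicit ``UserWarning`` when neighboring events are closer
    than a template length (waveform overlap); waveforms are still summed,
    never clipped.
    """
    fs = params.sampling_rate
    ss_tpl = params.ss_template if params.ss_template is not None else make_ss_template(fs)
    cs_tpl = params.cs_template if params.cs_template is not None else make_cs_template(fs)
    rng = np.random.default_rng(params.seed)

    n = int(np.ceil(train.duration * fs))
    x = np.zeros(n)

    max_len = max(ss_tpl.size, cs_tpl.size)
    if train.n_events >= 2:
        min_isi_samples = np.min(np.diff(train.times)) * fs
        n_overlap = int(np.sum(np.diff(train.times) * fs < max_len))
        if min_isi_samples < max_len:
            warnings.warn(
                f"{n_overlap} event pair(s) closer than a template length; "
                "waveforms overlap additively",
                UserWarning,
                stacklevel=2,
            )

    for tpl, label in ((ss_tpl, SS), (cs_tpl, CS)):
        peak = int(np.argmax(np.abs(tpl)))
        for t in train.times_of(label):
            i0 = int(round(t * fs)) - peak
            lo, hi = max(i0, 0), min(i0 + tpl.size, n)
            if lo < hi:
                x[lo:hi] += tpl[lo - i0 : hi - i0]

    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, size=n)
    return RawTrace(x, fs)
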