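"""Gamma-renewal spike-train simulator with climbing-fiber pauses.

Simple-spike ISIs are drawn from a gamma distribution with mean
``1/ss_rate`` and shape ``ss_shape`` (so ISI CV = 1/sqrt(shape)); complex
spikes form an independent homogeneous Poisson process.  Every SS landing
within ``cf_pause`` seconds after a CS is deleted, which reproduces the
pause in SS firing that follows each CS in vivo.  As a consequence the
surviving SS rate converges to ``ss_rate * (1 - cs_rate * cf_pause)`` for
Poisson-like trains.
"""

from __future__ import annotations

import numpy as np

from ..spiketrain import LabeledSpikeTrain, merge_labeled
from .params import SpikeSimParams


def _renewal_times(rng: np.random.Generator, rate: float, shape: float, duration: float) -> np.ndarray:
    """Event times of a gamma renewal process on [0, duration)."""
    scale = 1.0 / (rate * shape)
    times = []
    t = 0.0
    # draw in chunks to avoid per-event Python overhead
    chunk = max(64, int(rate * duration * 1.2) + 32)
    while t < duration:
        isis = rng.gamma(shape, scale, size=chunk)
        cum = t + np.cumsum(isis)
        times.append(cum[cum < duration])
        t = cum[-1]
    return np.concatenate(times) if times else np.empty(0)


def simulate_spike_train(params: SpikeSimParams) -> LabeledSpikeTrain:
    """Simulate a labeled SS/CS train with enforced post-CS pauses.

    Returns a :class:`LabeledSpikeTrain`; the parameters themselves are the
    ground truth for downstream estimator tests.
    """
    rng = np.random.default_rng(params.seed)
    ss = _renewal_times(rng, params.ss_rate, params.ss_shape, params.duration)

    if params.cs_rate > 0:
        n_cs = rng.poisson(params.cs_rate * params.duration)
        cs = np.sort(rng.uniform(0.0, params.duration, size=n_cs))
        # drop pathological coincidences so times stay strictly increasing
        if cs.size:
            keep = np.ones(cs.size, dtype=bool)
            keep[1:] = np.diff(cs) > 0
            cs = cs[keep]
    else:
        cs = np.empty(0)

    if cs.size and params.cf_pause > 0 and ss.size:
        # delete every SS in (cs, cs + cf_pause]
        idx = np.searchsorted(cs, ss)  # number of CS at or before each SS
        has_prev = idx > 0
        prev_cs = np.where(has_prev, cs[np.maximum(idx - 1, 0)], -np.inf)
        in_pause = has_prev & (ss - prev_cs <= params.cf_pause) & (ss > prev_cs)
        ss = ss[~in_pause]

    if cs.size and ss.size:
        # exact SS/CS coincidences would break strict monotonicity
        coincident = np.isin(ss, cs)
        ss = ss[~coincident]

    return merge_labeled(ss, cs, params.duration)
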