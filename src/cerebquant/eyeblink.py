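"""Eyeblink-conditioning protocol, FEC traces and CR/UR detection.

A session delivers 20 blocks of [1 US-only, 10 paired, 1 CS-only] trials
(240 in total).  The conditioned stimulus (LED) lasts 280 ms; the
unconditioned stimulus (corneal air puff) lasts 30 ms and starts 250 ms
after CS onset, co-terminating with the CS.  Eyelid position is expressed
as the fraction of eyelid closure (FEC): 0 = fully open, 1 = fully
closed.

A conditioned response is an eyelid movement on a valid paired/CS-only
trial that is larger than 0.05 FEC, starts 50–250 ms and peaks 100–250 ms
after CS onset, and rises (positive slope) over the 150 ms before US
time.  All latency windows are closed intervals; boundary samples count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import CalibrationError, ParameterError, UndefinedStatisticError

PAIRED = "paired"
CS_ONLY = "cs_only"
US_ONLY = "us_only"

CS_US_INTERVAL_MS = 250.0
CS_DURATION_MS = 280.0
US_DURATION_MS = 30.0


@dataclass
class SessionProtocol:
    """Ordered trial-type blocks plus stimulus timing (ms)."""

    blocks: List[List[str]]
    cs_duration: float = CS_DURATION_MS
    us_duration: float = US_DURATION_MS
    cs_us_interval: float = CS_US_INTERVAL_MS

    @property
    def trial_types(self) -> List[str]:
        return [t for block in self.blocks for t in block]

    def counts(self) -> dict:
        types = self.trial_types
        return {
            PAIRED: types.count(PAIRED),
            CS_ONLY: types.count(CS_ONLY),
            US_ONLY: types.count(US_ONLY),
            "total": len(types),
        }


def build_protocol(n_blocks: int = 20) -> SessionProtocol:
    """Standard acquisition session: 20 × [1 US-only, 10 paired, 1 CS-only]."""
    block = [US_ONLY] + [PAIRED] * 10 + [CS_ONLY]
    return SessionProtocol(blocks=[list(block) for _ in range(n_blocks)])


@dataclass
class EyelidTrial:
    """One trial's FEC time series, aligned to CS onset (t = 0 ms).

    ``us_onset_ms`` is the US onset relative to CS onset (None for
    CS-only trials).  ``valid`` is None until :func:`validate_trial`
    runs.
    """

    time_ms: np.ndarray
    fec: np.ndarray
    trial_type: str
    us_onset_ms: Optional[float] = CS_US_INTERVAL_MS
    valid: Optional[bool] = None

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.fec = np.asarray(self.fec, dtype=float)
        if self.time_ms.shape != self.fec.shape:
            raise ParameterError("time_ms and fec must have equal shapes")
        if not np.all(np.isfinite(self.fec)):
            raise ParameterError("fec must be finite")
        dt = np.diff(self.time_ms)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ParameterError("sampling must be uniform")
        if self.time_ms.size and self.time_ms[0] > -500.0:
            raise ParameterError("trial must include >= 500 ms pre-CS baseline")
        if self.trial_type not in (PAIRED, CS_ONLY, US_ONLY):
            raise ParameterError(f"unknown trial type {self.trial_type!r}")

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Indices with t0 <= time <= t1 (closed)."""
        return np.flatnonzero((self.time_ms >= t0) & (self.time_ms <= t1))


@dataclass
class CROutcome:
    is_cr: bool
    amplitude: float  # peak FEC in the CR window
    onset_latency: Optional[float]  # ms after CS onset, None if never crossed
    peak_latency: float  # ms after CS onset
    pre_us_slope: float  # FEC/ms over the 150 ms before US time


def fec_from_pixels(
    fur_area: np.ndarray, open_ref: float, closed_ref: float
) -> Tuple[np.ndarray, int]:
    """Convert summed fur-pixel area to FEC units.

    ``FEC(t) = (area(t) − open_ref) / (closed_ref − open_ref)``, clipped
    to [−0.1, 1.1]; returns the trace and the number of clipped samples.
    """
    if closed_ref <= open_ref:
        raise ParameterError("closed_ref must exceed open_ref")
    fec = (np.asarray(fur_area, dtype=float) - open_ref) / (closed_ref - open_ref)
    n_clip = int(np.sum((fec < -0.1) | (fec > 1.1)))
    return np.clip(fec, -0.1, 1.1), n_clip


def _ur_peak(time_ms: np.ndarray, fec: np.ndarray, us_onset: float) -> float:
    post = fec[time_ms >= us_onset]
    if post.size == 0:
        raise CalibrationError("US-containing trial has no post-US samples")
    return float(post.max())


def normalize_session(trials: Sequence[EyelidTrial]) -> List[EyelidTrial]:
    """Baseline-align and full-blink-calibrate a session of raw trials.

    Each trial's 500-ms pre-CS baseline mean is subtracted; all traces are
    then divided by the session's full-blink size, taken as the median UR
    peak across US-containing trials (robust to outlier blinks).
    """
    aligned = []
    ur_peaks = []
    for tr in trials:
        base = tr.fec[(tr.time_ms >= -500.0) & (tr.time_ms < 0.0)]
        shifted = tr.fec - float(base.mean())
        aligned.append(shifted)
        if tr.trial_type in (PAIRED, US_ONLY) and tr.us_onset_ms is not None:
            ur_peaks.append(_ur_peak(tr.time_ms, shifted, tr.us_onset_ms))
    if not ur_peaks:
        raise CalibrationError("no US-containing trial to calibrate full-blink size")
    full_blink = float(np.median(ur_peaks))
    if full_blink <= 1e-9:  # FEC is O(1); anything smaller is no blink at all
        raise CalibrationError("non-positive full-blink size")
    return [
        EyelidTrial(tr.time_ms.copy(), shifted / full_blink, tr.trial_type, tr.us_onset_ms)
        for tr, shifted in zip(trials, aligned)
    ]


def validate_trial(trial: EyelidTrial, pre_cs_threshold: float = 0.05) -> bool:
    """A trial is invalid if the pre-CS FEC range exceeds the threshold.

    "Significant activity" in the 500-ms pre-CS window is operationalized
    as max−min strictly greater than ``pre_cs_threshold`` (default 0.05,
    the CR amplitude scale); a threshold-equal excursion stays valid.
    """
    pre = trial.fec[(trial.time_ms >= -500.0) & (trial.time_ms < 0.0)]
    rng = float(pre.max() - pre.min()) if pre.size else 0.0
    trial.valid = rng <= pre_cs_threshold
    return trial.valid


def detect_cr(
    trial: EyelidTrial,
    amp_threshold: float = 0.05,
    onset_window: Tuple[float, float] = (50.0, 250.0),
    peak_window: Tuple[float, float] = (100.0, 250.0),
    slope_window_ms: float = 150.0,
) -> CROutcome:
    """Classify a normalized paired/CS-only trial as CR or not.

    Onset is the first sample after CS onset where FEC exceeds the
    amplitude threshold; the peak is the FEC maximum in [0 ms, US time];
    the pre-US slope is the least-squares slope over the
    ``slope_window_ms`` before US time.  ``is_cr`` requires all four
    criteria: amplitude, onset latency, peak latency, positive slope.
    """
    if trial.trial_type == US_ONLY:
        raise ParameterError("CR detection applies to paired or CS-only trials")
    us_time = trial.us_onset_ms if trial.us_onset_ms is not None else CS_US_INTERVAL_MS
    if trial.time_ms[-1] < us_time:
        raise ParameterError("trial ends before US time; cannot score CR")

    post = trial.window(0.0, us_time)
    crossed = post[trial.fec[post] > amp_threshold]
    onset = float(trial.time_ms[crossed[0]]) if crossed.size else None

    peak_idx = post[np.argmax(trial.fec[post])]
    amplitude = float(trial.fec[peak_idx])
    peak_latency = float(trial.time_ms[peak_idx])

    sl = trial.window(us_time - slope_window_ms, us_time)
    slope = float(np.polyfit(trial.time_ms[sl], trial.fec[sl], 1)[0])

    is_cr = (
        amplitude > amp_threshold
        and onset is not None
        and onset_window[0] <= onset <= onset_window[1]
        and peak_window[0] <= peak_latency <= peak_window[1]
        and slope > 0
    )
    return CROutcome(
        is_cr=bool(is_cr),
        amplitude=amplitude,
        onset_latency=onset,
        peak_latency=peak_latency,
        pre_us_slope=slope,
    )


def cr_percentage(trials: Sequence[EyelidTrial], **detect_kwargs) -> float:
    """Percent CR among valid paired and CS-only trials of a session.

    Trials with ``valid=None`` are validated in place first.
    """
    eligible = [t for t in trials if t.trial_type in (PAIRED, CS_ONLY)]
    for t in eligible:
        if t.valid is None:
            validate_trial(t)
    valid = [t for t in eligible if t.valid]
    if not valid:
        raise UndefinedStatisticError("no-valid-trials", "no valid eligible trial in session")
    n_cr = sum(detect_cr(t, **detect_kwargs).is_cr for t in valid)
    return 100.0 * n_cr / len(valid)


@dataclass
class URMetrics:
    onset_ms: Optional[float]  # relative to US onset
    peak_ms: Optional[float]
    status: str = "ok"


def ur_metrics(trial: EyelidTrial, threshold: float = 0.05) -> URMetrics:
    """UR onset and peak time relative to US onset on a US-containing trial.

    Onset is the first post-US sample exceeding the pre-US level (mean of
    the 50 ms before US) by ``threshold``; peak time is the FEC argmax
    after the US.  A flat post-US trace yields an explicit no-response
    status.
    """
    if trial.trial_type == CS_ONLY or trial.us_onset_ms is None:
        raise ParameterError("UR metrics require a US-containing trial")
    us = trial.us_onset_ms
    pre = trial.fec[(trial.time_ms >= us - 50.0) & (trial.time_ms < us)]
    level = float(pre.mean()) if pre.size else 0.0
    post = np.flatnonzero(trial.time_ms > us)
    above = post[trial.fec[post] > level + threshold]
    if above.size == 0:
        return URMetrics(None, None, status="no-response")
    onset = float(trial.time_ms[above[0]] - us)
    peak_idx = post[np.argmax(trial.fec[post])]
    return URMetrics(onset, float(trial.time_ms[peak_idx] - us))
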