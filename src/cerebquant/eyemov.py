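"""Gain/phase of compensatory eye movements and VOR phase-reversal learning.

The stimulus (drum or turntable) is a known sinusoid; motor performance is
the gain (fitted eye velocity / fitted stimulus velocity) and phase (eye
to stimulus difference, degrees).  Quick phases (saccadic resets) are
masked by a robust velocity threshold before fitting.  For the VOR the
phase is reported relative to the perfectly compensatory direction: a
perfect VOR is (gain 1, phase 0) and a fully reversed VOR approaches
phase 180°.

Overnight consolidation of an adaptive change is
``100 · (dx_t0 − dx_next_t0) / (dx_t0 − dx_t30)`` where ``dx_t0`` is the
value before training on day d, ``dx_t30`` the last value on day d, and
``dx_next_t0`` the value before training on day d+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import warnings
from scipy import signal as sps

from .exceptions import ParameterError, UndefinedStatisticError


@dataclass
class EyeTrace:
    """Paired eye/stimulus position records (degrees) for one condition."""

    time: np.ndarray  # s, uniform
    eye: np.ndarray  # degrees
    stim: np.ndarray  # degrees
    frequency: float  # Hz, stimulus-controlled, never estimated
    stimulus_amplitude: float  # degrees
    condition: str = "VOR"  # OKR | VOR | VVOR

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.eye = np.asarray(self.eye, dtype=float)
        self.stim = np.asarray(self.stim, dtype=float)
        if not (self.time.shape == self.eye.shape == self.stim.shape):
            raise ParameterError("time, eye and stim must have equal shapes")
        dt = np.diff(self.time)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ParameterError("sampling must be uniform")
        if (self.time[-1] - self.time[0]) * self.frequency < 5:
            raise ParameterError("trace must cover >= 5 stimulus cycles")
        if self.stimulus_amplitude <= 0:
            raise ParameterError("stimulus_amplitude must be > 0")
        if self.condition not in ("OKR", "VOR", "VVOR"):
            raise ParameterError("condition must be OKR, VOR or VVOR")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class GainPhase:
    gain: float
    phase: Optional[float]  # degrees in (-180, 180]; None when undefined
    fit_r2: float
    status: str = "ok"  # "ok" | "phase-undefined"


@dataclass
class SineFit:
    amplitude: float
    phase_deg: float  # phase of a·sin + b·cos = A·sin(ωt + φ)
    offset: float
    r2: float


def wrap_deg(angle: float) -> float:
    """Wrap an angle to (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def remove_quick_phases(
    trace: EyeTrace, velocity_k: float = 5.0, margin_s: float = 0.025
) -> np.ndarray:
    """Boolean mask of samples to exclude from fitting (True = masked).

    Samples whose eye velocity deviates from the median by more than
    ``velocity_k`` times the MAD-based robust scale are masked, together
    with a ±``margin_s`` margin.  Warns when more than half the trace is
    masked.
    """
    v = np.gradient(trace.eye, trace.time)
    med = np.median(v)
    scale = 1.4826 * np.median(np.abs(v - med))
    if scale == 0:
        mask = np.zeros(v.size, dtype=bool)
    else:
        mask = np.abs(v - med) > velocity_k * scale
        if mask.any() and margin_s > 0:
            m = int(round(margin_s * trace.sampling_rate))
            if m > 0:
                mask = np.convolve(mask.astype(int), np.ones(2 * m + 1, dtype=int), "same") > 0
    if mask.mean() > 0.5:
        warnings.warn("more than 50% of samples masked as quick phases",
                      UserWarning, stacklevel=2)
    return mask


def fit_sine(
    signal: np.ndarray,
    frequency: float,
    time: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> SineFit:
    """Least-squares fit of ``a·sin(2πft) + b·cos(2πft) + c`` on unmasked samples."""
    signal = np.asarray(signal, dtype=float)
    time = np.asarray(time, dtype=float)
    keep = np.ones(signal.size, dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    if keep.sum() < 4:
        raise ParameterError("too few unmasked samples for a sine fit")
    w = 2 * np.pi * frequency
    design = np.column_stack([np.sin(w * time[keep]), np.cos(w * time[keep]), np.ones(keep.sum())])
    coef, _, rank, _ = np.linalg.lstsq(design, signal[keep], rcond=None)
    if rank < 3:
        raise ParameterError("rank-deficient sine design (signal all masked or constant)")
    a, b, c = coef
    pred = design @ coef
    ss_res = float(np.sum((signal[keep] - pred) ** 2))
    ss_tot = float(np.sum((signal[keep] - signal[keep].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SineFit(
        amplitude=float(np.hypot(a, b)),
        phase_deg=float(np.degrees(np.arctan2(b, a))),
        offset=float(c),
        r2=r2,
    )


def gain_phase(
    trace: EyeTrace,
    velocity_k: float = 5.0,
    margin_s: float = 0.025,
    lowpass_hz: float = 6.0,
) -> GainPhase:
    """Gain and phase of the eye response to sinusoidal stimulation.

    Pipeline: mask quick phases from the raw velocity, zero-phase low-pass
    both position traces, differentiate numerically, and fit sines at the
    stimulus frequency on the unmasked velocity samples.  Gain is the
    ratio of fitted velocity amplitudes; phase is the fitted eye-minus-
    stimulus phase difference (VOR: reported relative to the compensatory
    direction).  The mask margin is widened by the low-pass response time
    so that filter smear of quick phases stays excluded.
    """
    mask = remove_quick_phases(trace, velocity_k=velocity_k, margin_s=margin_s)
    fs = trace.sampling_rate
    eye, stim = trace.eye, trace.stim
    if lowpass_hz and lowpass_hz < fs / 2:
        if mask.any():
            # widen mask to cover the filter's impulse-response spread
            m = int(round((1.0 / lowpass_hz) * fs))
            mask = np.convolve(mask.astype(int), np.ones(2 * m + 1, dtype=int), "same") > 0
        sos = sps.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
        eye = sps.sosfiltfilt(sos, eye)
        stim = sps.sosfiltfilt(sos, stim)
    v_eye = np.gradient(eye, trace.time)
    v_stim = np.gradient(stim, trace.time)
    fit_e = fit_sine(v_eye, trace.frequency, trace.time, mask)
    fit_s = fit_sine(v_stim, trace.frequency, trace.time)
    gain = fit_e.amplitude / fit_s.amplitude
    if fit_e.amplitude < 1e-12 * max(fit_s.amplitude, 1.0):
        return GainPhase(gain=0.0, phase=None, fit_r2=fit_e.r2, status="phase-undefined")
    phase = fit_e.phase_deg - fit_s.phase_deg
    if trace.condition == "VOR":
        # 0° = eye exactly opposite the head (perfect compensation)
        phase -= 180.0
    return GainPhase(gain=float(gain), phase=wrap_deg(phase), fit_r2=fit_e.r2)


@dataclass
class DayPlan:
    day: int
    n_sessions: int
    drum_amplitude: float  # degrees
    table_amplitude: float  # degrees
    frequency: float  # Hz


@dataclass
class ReversalProtocol:
    days: List[DayPlan]


def reversal_protocol() -> ReversalProtocol:
    """The 5-day VOR phase-reversal training schedule.

    Six 5-min training sessions per day with VOR probes before, between
    and after; drum and table in phase at 0.6 Hz.  Drum amplitude 5° on
    day 1, 7.5° on day 2 and 10° on days 3–5; table amplitude 5°
    throughout.
    """
    amps = {1: 5.0, 2: 7.5, 3: 10.0, 4: 10.0, 5: 10.0}
    return ReversalProtocol(
        days=[
            DayPlan(day=d, n_sessions=6, drum_amplitude=amps[d], table_amplitude=5.0, frequency=0.6)
            for d in range(1, 6)
        ]
    )


def consolidation(dx_t0: float, dx_next_t0: float, dx_t30: float) -> float:
    """Percentage of a day's adaptive change retained overnight."""
    denom = dx_t0 - dx_t30
    if denom == 0:
        raise UndefinedStatisticError("zero-denominator", "dx_t0 == dx_t30: no change to retain")
    return 100.0 * (dx_t0 - dx_next_t0) / denom


@dataclass
class LearningCurveResult:
    table: pd.DataFrame  # columns: day, session, gain, phase
    consolidation: dict  # e.g. {"gain_day1_to_2": float, ...}
    gaps: List[str]  # flagged missing probes / undefined entries


def analyze_learning_curve(
    probes: Sequence[Tuple[int, int, EyeTrace]],
    protocol: Optional[ReversalProtocol] = None,
) -> LearningCurveResult:
    """Gain/phase per labeled probe plus per-transition consolidation.

    ``probes`` is a sequence of ``(day, session, trace)`` VOR probes
    ordered within days.  Consolidation follows the phase-reversal
    read-out: gain from day 1 to 2, phase from day 2 to 3 and from 3 to
    4.  Missing probes are flagged in ``gaps``, never imputed.
    """
    rows = []
    for day, session, trace in probes:
        gp = gain_phase(trace)
        rows.append({"day": day, "session": session, "gain": gp.gain, "phase": gp.phase})
    table = pd.DataFrame(rows, columns=["day", "session", "gain", "phase"])
    table = table.sort_values(["day", "session"]).reset_index(drop=True)

    cons: dict = {}
    gaps: List[str] = []

    def first_last(day: int):
        sub = table[table["day"] == day]
        if len(sub) == 0:
            return None
        return sub.iloc[0], sub.iloc[-1]

    for quantity, d in (("gain", 1), ("phase", 2), ("phase", 3)):
        key = f"{quantity}_day{d}_to_{d + 1}"
        here, there = first_last(d), first_last(d + 1)
        if here is None or there is None or len(table[table["day"] == d]) < 2:
            gaps.append(key + ": missing probes")
            cons[key] = float("nan")
            continue
        dx_t0, dx_t30 = here[0][quantity], here[1][quantity]
        dx_next_t0 = there[0][quantity]
        try:
            cons[key] = consolidation(dx_t0, dx_next_t0, dx_t30)
        except UndefinedStatisticError:
            gaps.append(key + ": no within-day change (zero denominator)")
            cons[key] = float("nan")
    return LearningCurveResult(table=table, consolidation=cons, gaps=gaps)
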