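"""Parameter dataclasses for the synthetic-data generators.

Defaults describe an adult ZebrinII-negative Purkinje cell and the
behavioral protocols used throughout the package: SS ~60 Hz with CV ≈ 0.5
(gamma shape 4), CS ~1 Hz with a 20 ms climbing-fiber pause, 50 kHz
acquisition, 5° sinusoidal stimulation at 0.6 Hz, and eyeblink sessions of
20 blocks.  Every generator takes an explicit integer seed and owns a
single ``numpy.random.Generator``; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from ..exceptions import ParameterError


@dataclass
class SpikeSimParams:
    """Gamma-renewal SS train + independent Poisson CS train + CF pause.

    ``ss_shape`` is the gamma shape parameter; the ISI coefficient of
    variation is 1/sqrt(ss_shape), so shape 1 is Poisson-like and large
    shapes approach clockwork regularity.  Every SS falling within
    ``cf_pause`` seconds after a CS is deleted, emulating the
    climbing-fiber pause.
    """

    ss_rate: float = 60.0  # events/s
    ss_shape: float = 4.0  # dimensionless, > 0
    cs_rate: float = 1.0  # events/s
    cf_pause: float = 0.020  # s of SS suppression after each CS
    duration: float = 120.0  # s
    seed: int = 0

    def __post_init__(self):
        if self.ss_rate <= 0:
            raise ParameterError("ss_rate must be > 0")
        if self.ss_shape <= 0:
            raise ParameterError("ss_shape must be > 0")
        if self.cs_rate < 0:
            raise ParameterError("cs_rate must be >= 0")
        if self.cf_pause < 0:
            raise ParameterError("cf_pause must be >= 0")
        if self.cs_rate > 0 and not self.cf_pause < 1.0 / self.cs_rate:
            raise ParameterError("cf_pause must be < 1/cs_rate")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")


@dataclass
class TraceSimParams:
    """Rendering of a labeled train into a raw extracellular trace.

    Templates are peak-normalized to 1; noise is white Gaussian.  The
    default 50 kHz matches the higher-rate acquisition setup; anything
    below 10 kHz would undersample the spike waveforms and is rejected.
    """

    sampling_rate: float = 50_000.0  # Hz
    ss_template: Optional[np.ndarray] = None  # built from sampling_rate if None
    cs_template: Optional[np.ndarray] = None
    noise_sd: float = 0.1  # template peak units
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate < 10_000:
            raise ParameterError("sampling_rate must be >= 10 kHz")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        for name in ("ss_template", "cs_template"):
            tpl = getattr(self, name)
            if tpl is not None:
                tpl = np.asarray(tpl, dtype=float)
                if not np.isclose(np.max(np.abs(tpl)), 1.0, atol=1e-6):
                    raise ParameterError(f"{name} must be peak-normalized to 1")
                setattr(self, name, tpl)


@dataclass
class TreeSimParams:
    """Stochastic branching growth of a neuronal arbor.

    ``planar=True`` grows in the xy-plane (Purkinje dendrites are nearly
    planar); ``planar=False`` grows in 3-D (axon terminal arbors in the
    cerebellar nuclei).
    """

    branch_prob: float = 0.3  # per-segment bifurcation probability
    segment_len_mean: float = 20.0  # µm
    segment_len_sd: float = 5.0  # µm
    max_depth: int = 8  # segments from the root
    planar: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.branch_prob <= 1:
            raise ParameterError("branch_prob must be in [0, 1]")
        if self.segment_len_mean <= 0:
            raise ParameterError("segment_len_mean must be > 0")
        if self.segment_len_sd < 0:
            raise ParameterError("segment_len_sd must be >= 0")
        if self.max_depth < 1:
            raise ParameterError("max_depth must be >= 1")


@dataclass
class EyeSimParams:
    """Sinusoidal compensatory eye-movement session with known truth.

    The stimulus is A·sin(2πft).  In the VOR convention the perfectly
    compensatory eye moves exactly opposite the head, so for
    ``condition="VOR"`` the generated eye is
    ``-gain·A·sin(2πft + phase)``; for OKR/VVOR it follows the stimulus.
    Quick phases are step displacements at Poisson times.
    """

    frequency: float = 0.6  # Hz
    stim_amplitude: float = 5.0  # degrees
    true_gain: float = 0.8
    true_phase: float = 5.0  # degrees, positive = eye leads
    noise_sd: float = 0.1  # degrees
    saccade_rate: float = 0.0  # events/s
    saccade_amp: float = 3.0  # degrees (|step| mean)
    duration: float = 40.0  # s
    sampling_rate: float = 120.0  # Hz
    condition: str = "VOR"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.frequency <= 10:
            raise ParameterError("frequency must be in (0, 10] Hz")
        if self.stim_amplitude <= 0:
            raise ParameterError("stim_amplitude must be > 0")
        if self.true_gain < 0:
            raise ParameterError("true_gain must be >= 0")
        if self.noise_sd < 0 or self.saccade_rate < 0:
            raise ParameterError("noise_sd and saccade_rate must be >= 0")
        if self.duration * self.frequency < 5:
            raise ParameterError("duration must cover >= 5 stimulus cycles")
        if self.condition not in ("OKR", "VOR", "VVOR"):
            raise ParameterError("condition must be OKR, VOR or VVOR")


@dataclass
class BlinkSimParams:
    """Eyeblink-conditioning session generator parameters.

    CRs occur with probability ``cr_prob`` on paired and CS-only trials;
    onset and peak latencies are drawn uniformly inside the stated windows
    (ms after CS onset) so that generated CRs satisfy the detection
    criteria by construction.  Noise is temporally smoothed (10 ms
    Gaussian kernel) — eyelid position is a slow signal and per-sample
    independent noise would be unphysical.
    """

    cr_prob: float = 0.5
    cr_amp_mean: float = 0.5  # FEC units
    cr_amp_sd: float = 0.15
    cr_onset_range: Tuple[float, float] = (100.0, 180.0)  # ms after CS onset
    cr_peak_range: Tuple[float, float] = (180.0, 250.0)  # ms after CS onset
    ur_amp: float = 1.0  # FEC units (full blink)
    noise_sd: float = 0.01  # FEC units
    sampling_rate: float = 1000.0  # Hz
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.cr_prob <= 1:
            raise ParameterError("cr_prob must be in [0, 1]")
        if not 0 < self.cr_amp_mean <= 1:
            raise ParameterError("cr_amp_mean must be in (0, 1]")
        for name in ("cr_onset_range", "cr_peak_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ParameterError(f"{name} must be ordered and positive")
        if self.cr_onset_range[0] < 50:
            raise ParameterError("cr_onset_range must start at >= 50 ms")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
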