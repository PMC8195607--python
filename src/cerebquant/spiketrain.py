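"""Event-time containers for Purkinje cell recordings.

A Purkinje cell emits two kinds of action potentials: simple spikes (SS,
tens of Hz, intrinsic/parallel-fiber driven) and complex spikes (CS, ~1 Hz,
each triggered by a climbing-fiber discharge and followed by a pause in SS
firing).  All spike statistics in this package operate on a
:class:`LabeledSpikeTrain` — an ordered sequence of event times with an
SS/CS label per event and a known recording duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

SS = "SS"
CS = "CS"
LABELS = (SS, CS)


@dataclass
class LabeledSpikeTrain:
    """Ordered spike times (s) with per-event SS/CS labels.

    Parameters
    ----------
    times:
        Strictly increasing event times in seconds, all in ``[0, duration)``.
    labels:
        One of ``"SS"``/``"CS"`` per event.
    duration:
        Recording length in seconds.
    """

    times: np.ndarray
    labels: np.ndarray
    duration: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U2")
        if self.times.ndim != 1 or self.labels.shape != self.times.shape:
            raise ParameterError("times and labels must be 1-D and the same length")
        if self.duration <= 0:
            raise ParameterError("duration must be > 0")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ParameterError("times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ParameterError("times must lie in [0, duration)")
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise ParameterError(f"unknown labels: {sorted(bad)}")

    @property
    def n_events(self) -> int:
        return self.times.size

    def times_of(self, label: str) -> np.ndarray:
        return self.times[self.labels == label]

    def isis(self, label: str = SS) -> np.ndarray:
        """Inter-spike intervals (s) between consecutive events of ``label``."""
        return np.diff(self.times_of(label))

    def ss_isi_spans_cs(self) -> np.ndarray:
        """For each SS inter-spike interval, whether a CS falls inside it.

        The climbing-fiber pause stretches the SS interval that contains a
        CS; flagging those intervals lets SS regularity measures exclude
        them (see :mod:`cerebquant.spikestats`).
        """
        ss = self.times_of(SS)
        cs = self.times_of(CS)
        if ss.size < 2:
            return np.zeros(0, dtype=bool)
        if cs.size == 0:
            return np.zeros(ss.size - 1, dtype=bool)
        # count of CS before each SS; interval i spans a CS iff the count
        # changes between its endpoints
        counts = np.searchsorted(cs, ss)
        return np.diff(counts) > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "label": self.labels})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, duration: float) -> "LabeledSpikeTrain":
        return cls(
            times=frame["time_s"].to_numpy(dtype=float),
            labels=frame["label"].to_numpy(dtype="U2"),
            duration=duration,
        )


@dataclass
class RawTrace:
    """A raw extracellular voltage-like trace (unitless samples)."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be 1-D")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


def merge_labeled(ss_times: np.ndarray, cs_times: np.ndarray, duration: float) -> LabeledSpikeTrain:
    """Merge separate SS and CS time arrays into one labeled train."""
    times = np.concatenate([ss_times, cs_times])
    labels = np.concatenate(
        [np.full(len(ss_times), SS, dtype="U2"), np.full(len(cs_times), CS, dtype="U2")]
    )
    order = np.argsort(times, kind="stable")
    return LabeledSpikeTrain(times[order], labels[order], duration)
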