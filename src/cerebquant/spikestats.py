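"""Spike-train statistics: rate, CV, CV2, regularity index, CF pause.

CV is the SD/mean of inter-spike intervals (sample SD, n−1 denominator).
CV2 is the pairwise local irregularity ``2·|ISIn+1 − ISIn| /
(ISIn+1 + ISIn)``, one value per adjacent ISI pair; it is bounded in
[0, 2) and equals 0 for clockwork firing.  The regularity index is the
fraction of spikes participating in at least one locally regular pattern,
i.e. a CV2 value below 0.2 (each CV2 value covers three consecutive
spikes).  The climbing-fiber pause is the time from each CS to the next
SS, reported in ms.

Cells are flagged as excluded when the recording is shorter than the
90-s inclusion gate; statistics are still computed, only marked.
By default the simple-spike CV and CV2 skip ISIs that contain a CS — the
CF pause stretches those intervals and would otherwise masquerade as
irregularity; the exclusion is toggleable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import UndefinedStatisticError
from .sorting import UnitValidation, validate_single_unit
from .spiketrain import CS, SS, LabeledSpikeTrain

MIN_DURATION_S = 90.0
CV2_REGULAR_THRESHOLD = 0.2


@dataclass
class SpikeStats:
    rate: float  # Hz
    cv: Optional[float]
    cv2_mean: Optional[float]
    cv2_series: Optional[np.ndarray]  # one per adjacent ISI pair (NaN where excluded)
    regularity_index: Optional[float]
    n_events: int
    duration: float
    included: bool
    status: str = "ok"


@dataclass
class CFPauseStats:
    mean_pause: float  # ms
    median_pause: float  # ms
    per_cs_pauses: np.ndarray  # ms
    n_skipped: int  # CSs with no subsequent SS


@dataclass
class CellSummary:
    ss: SpikeStats
    cs: SpikeStats
    cf_pause: Optional[CFPauseStats]
    validation: UnitValidation
    included: bool


def firing_rate(train: LabeledSpikeTrain, label: str = SS) -> float:
    """Event count of ``label`` divided by the recording duration (Hz)."""
    return train.times_of(label).size / train.duration


def isi_cv(isis: np.ndarray) -> float:
    """SD/mean of the ISIs (sample SD, n−1 denominator)."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        raise UndefinedStatisticError("too-few-isis", "CV needs >= 2 ISIs")
    return float(np.std(isis, ddof=1) / np.mean(isis))


def cv2_values(isis: np.ndarray) -> np.ndarray:
    """CV2 per adjacent ISI pair: 2·|ISIn+1 − ISIn| / (ISIn+1 + ISIn)."""
    isis = np.asarray(isis, dtype=float)
    a, b = isis[:-1], isis[1:]
    return 2.0 * np.abs(b - a) / (b + a)


def isi_cv2(isis: np.ndarray):
    """CV2 series (train order) and its mean.

    Returns ``(series, mean)``; needs at least two consecutive ISIs.
    NaN entries (excluded pairs) are skipped in the mean.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        raise UndefinedStatisticError("too-few-isis", "CV2 needs >= 2 consecutive ISIs")
    series = cv2_values(isis)
    if np.all(np.isnan(series)):
        raise UndefinedStatisticError("no-valid-pairs", "all CV2 pairs excluded")
    return series, float(np.nanmean(series))


def _label_isis(train: LabeledSpikeTrain, label: str, exclude_cs_spanning: bool) -> np.ndarray:
    """ISIs of a label; SS ISIs spanning a CS become NaN when excluded."""
    isis = train.isis(label)
    if label == SS and exclude_cs_spanning:
        spans = train.ss_isi_spans_cs()
        isis = isis.copy()
        isis[spans] = np.nan
    return isis


def _cv2_series_with_exclusions(isis: np.ndarray) -> np.ndarray:
    """CV2 per adjacent pair; pairs touching an excluded (NaN) ISI are NaN."""
    with np.errstate(invalid="ignore"):
        return cv2_values(isis)


def regularity_index(
    train: LabeledSpikeTrain,
    label: str = SS,
    cv2_threshold: float = CV2_REGULAR_THRESHOLD,
    exclude_cs_spanning: bool = True,
) -> float:
    """Fraction of spikes participating in a locally regular pattern.

    A CV2 value below ``cv2_threshold`` marks its three consecutive
    spikes as regular; the index is (spikes in >= 1 regular pattern) /
    (all spikes of the label).
    """
    n = train.times_of(label).size
    if n < 3:
        raise UndefinedStatisticError("too-few-spikes", "regularity index needs >= 3 spikes")
    isis = _label_isis(train, label, exclude_cs_spanning)
    series = _cv2_series_with_exclusions(isis)
    regular = np.zeros(n, dtype=bool)
    hits = np.flatnonzero(series < cv2_threshold)  # NaN compares False
    for i in hits:
        regular[i : i + 3] = True
    return float(regular.sum()) / n


def cf_pause(train: LabeledSpikeTrain) -> CFPauseStats:
    """Per-CS pause (time from CS to the next SS), in ms."""
    cs = train.times_of(CS)
    ss = train.times_of(SS)
    if cs.size == 0 or ss.size == 0:
        raise UndefinedStatisticError("no-cs", "CF pause needs >= 1 CS followed by an SS")
    idx = np.searchsorted(ss, cs, side="right")
    has_next = idx < ss.size
    if not has_next.any():
        raise UndefinedStatisticError("no-cs", "no CS has a subsequent SS")
    pauses_ms = (ss[idx[has_next]] - cs[has_next]) * 1e3
    return CFPauseStats(
        mean_pause=float(pauses_ms.mean()),
        median_pause=float(np.median(pauses_ms)),
        per_cs_pauses=pauses_ms,
        n_skipped=int((~has_next).sum()),
    )


def _stats_for_label(
    train: LabeledSpikeTrain, label: str, included: bool, exclude_cs_spanning: bool
) -> SpikeStats:
    n = train.times_of(label).size
    rate = firing_rate(train, label)
    cv = cv2_mean = reg = None
    series = None
    status = "ok"
    isis = _label_isis(train, label, exclude_cs_spanning)
    try:
        cv = float(np.nanstd(isis, ddof=1) / np.nanmean(isis)) if np.sum(~np.isnan(isis)) >= 2 else None
        if cv is None:
            raise UndefinedStatisticError("too-few-isis")
        series = _cv2_series_with_exclusions(isis) if isis.size >= 2 else None
        if series is None or np.all(np.isnan(series)):
            raise UndefinedStatisticError("too-few-isis")
        cv2_mean = float(np.nanmean(series))
        reg = regularity_index(train, label, exclude_cs_spanning=exclude_cs_spanning)
    except UndefinedStatisticError as exc:
        status = exc.status
    return SpikeStats(
        rate=rate,
        cv=cv,
        cv2_mean=cv2_mean,
        cv2_series=series,
        regularity_index=reg,
        n_events=n,
        duration=train.duration,
        included=included,
        status=status,
    )


def summarize(
    train: LabeledSpikeTrain,
    min_duration: float = MIN_DURATION_S,
    exclude_cs_spanning: bool = True,
) -> CellSummary:
    """Per-label statistics + CF pause + single-unit validation for a cell.

    Recordings shorter than ``min_duration`` are marked excluded but the
    statistics are computed all the same.
    """
    included = train.duration >= min_duration
    ss_stats = _stats_for_label(train, SS, included, exclude_cs_spanning)
    cs_stats = _stats_for_label(train, CS, included, exclude_cs_spanning=False)
    try:
        pause = cf_pause(train)
    except UndefinedStatisticError:
        pause = None
    return CellSummary(
        ss=ss_stats,
        cs=cs_stats,
        cf_pause=pause,
        validation=validate_single_unit(train),
        included=included,
    )
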