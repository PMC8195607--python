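"""Spike detection, SS/CS separation and single-unit validation.

Detection thresholds the absolute signal at ``threshold_k`` times a
robust noise scale (1.4826 × median absolute deviation), keeps one event
per refractory window and aligns a waveform snippet on the absolute-peak
sample.  Classification projects snippets onto the first two principal
components and partitions them with 2-means using a deterministic
farthest-point initialization; the sparser cluster with the larger
waveform integral is the complex-spike cluster (complex spikes are ~1 Hz
and much longer than simple spikes).

Single-unit identity is validated by the climbing-fiber pause: in a true
single unit the interval from each CS to the following SS exceeds the
ordinary SS inter-spike interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.decomposition import PCA

from .exceptions import ParameterError, UndefinedStatisticError
from .spiketrain import CS, SS, LabeledSpikeTrain, RawTrace, merge_labeled


@dataclass
class DetectedEvents:
    times: np.ndarray  # s, aligned on the absolute-peak sample
    snippets: np.ndarray  # (n_events, n_samples)
    indices: np.ndarray  # peak sample indices
    noise_scale: float


@dataclass
class ClassifiedEvents:
    labels: np.ndarray  # "SS"/"CS" per event
    pcs: np.ndarray  # (n_events, 2) principal-component coordinates
    needs_review: bool  # count and waveform-integral cues disagree


@dataclass
class UnitValidation:
    mean_cs_to_ss: Optional[float]  # s
    mean_ss_isi: Optional[float]  # s
    is_single_unit: Optional[bool]
    status: str = "ok"  # "ok" | "no-cs" | "insufficient"
    per_cs_pauses: Optional[np.ndarray] = None  # s, for QC


def mad_scale(x: np.ndarray) -> float:
    """Robust noise scale: 1.4826 × median absolute deviation."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detect_events(
    trace: RawTrace,
    threshold_k: float = 4.5,
    refractory_ms: float = 1.0,
    snippet_ms: Tuple[float, float] = (1.0, 3.0),
    merge_window_ms: float = 5.0,
    dominance: float = 0.6,
) -> DetectedEvents:
    """Threshold crossings of |signal| with per-event aligned snippets.

    A complex spike is one multiphasic event lasting several ms whose
    spikelets can themselves cross a noise-scaled threshold; a secondary
    peak is therefore merged into a preceding event when it falls within
    ``merge_window_ms`` of it *and* its amplitude is below ``dominance``
    times the earlier peak's (full-size spikes following a large event
    are kept).  Set ``merge_window_ms=0`` to disable.

    A zero-variance trace yields an empty result rather than a failure.
    Events too close to the trace edges for a full snippet are dropped.
    """
    if threshold_k <= 0:
        raise ParameterError("threshold_k must be > 0")
    if trace.samples.size == 0:
        raise ParameterError("trace is empty")
    x = trace.samples - np.median(trace.samples)
    scale = mad_scale(x)
    fs = trace.sampling_rate
    pre = int(round(snippet_ms[0] * 1e-3 * fs))
    post = int(round(snippet_ms[1] * 1e-3 * fs))
    if scale == 0:
        return DetectedEvents(np.empty(0), np.empty((0, pre + post)), np.empty(0, int), 0.0)
    distance = max(1, int(round(refractory_ms * 1e-3 * fs)))
    peaks, _ = find_peaks(np.abs(x), height=threshold_k * scale, distance=distance)
    if merge_window_ms > 0 and peaks.size:
        window = merge_window_ms * 1e-3 * fs
        amps = np.abs(x[peaks])
        kept: list = []
        for j in range(peaks.size):
            swallowed = any(
                peaks[j] - peaks[i] < window and amps[j] < dominance * amps[i]
                for i in reversed(kept)
                if peaks[j] - peaks[i] < window
            )
            if not swallowed:
                kept.append(j)
        peaks = peaks[kept]
    peaks = peaks[(peaks >= pre) & (peaks + post <= x.size)]
    snippets = np.stack([x[p - pre : p + post] for p in peaks]) if peaks.size else np.empty((0, pre + post))
    return DetectedEvents(peaks / fs, snippets, peaks, scale)


def _farthest_point_kmeans(points: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """2-means with deterministic farthest-point initialization.

    First center: the point farthest from the data mean; second: the
    point farthest from the first.  Ties break toward the lower event
    index (argmax convention).  Assignment ties break toward cluster 0.
    """
    center0 = points[np.argmax(np.linalg.norm(points - points.mean(axis=0), axis=1))]
    center1 = points[np.argmax(np.linalg.norm(points - center0, axis=1))]
    centers = np.stack([center0, center1])
    assign = np.zeros(len(points), dtype=int)
    for _ in range(max_iter):
        d = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
        new_assign = np.argmin(d, axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for c in (0, 1):
            if np.any(assign == c):
                centers[c] = points[assign == c].mean(axis=0)
    return assign


def classify_events(snippets: np.ndarray, smooth_sigma: Optional[float] = None) -> ClassifiedEvents:
    """Partition waveform snippets into SS and CS clusters.

    Snippets are low-pass smoothed (Gaussian kernel, default sigma 1/20 of
    the snippet length) before the PCA projection: the complex-spike
    signature — spikelets riding a slow depolarization — is a
    low-frequency feature, while per-sample noise and one-sample
    alignment jitter are high-frequency and would otherwise dominate the
    leading principal components.  Pass ``smooth_sigma=0`` to disable.

    All-identical snippets collapse to a single cluster: everything is
    labeled SS and a warning is emitted.  When the sparser cluster does
    not also carry the larger waveform integral the result is flagged for
    manual review instead of silently guessing.
    """
    snippets = np.asarray(snippets, dtype=float)
    if snippets.ndim != 2 or snippets.shape[0] < 2:
        raise ParameterError("need at least 2 snippets to classify")
    if smooth_sigma is None:
        smooth_sigma = snippets.shape[1] / 20.0
    if smooth_sigma > 0:
        snippets = gaussian_filter1d(snippets, smooth_sigma, axis=1)
    centered = snippets - snippets.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-12):
        warnings.warn("all snippets identical: single cluster, all labeled SS",
                      UserWarning, stacklevel=2)
        return ClassifiedEvents(
            labels=np.full(len(snippets), SS, dtype="U2"),
            pcs=np.zeros((len(snippets), 2)),
            needs_review=False,
        )
    n_comp = min(2, snippets.shape[0], snippets.shape[1])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(snippets)
    if pcs.shape[1] < 2:
        pcs = np.column_stack([pcs, np.zeros(len(pcs))])
    assign = _farthest_point_kmeans(pcs)

    counts = np.array([np.sum(assign == 0), np.sum(assign == 1)])
    if counts.min() == 0:
        warnings.warn("degenerate clustering (one empty cluster); all labeled SS",
                      UserWarning, stacklevel=2)
        return ClassifiedEvents(np.full(len(snippets), SS, dtype="U2"), pcs, needs_review=False)
    integrals = np.array(
        [np.mean(np.sum(np.abs(snippets[assign == c]), axis=1)) for c in (0, 1)]
    )
    sparser = int(np.argmin(counts)) if counts[0] != counts[1] else int(np.argmax(integrals))
    bigger = int(np.argmax(integrals))
    needs_review = sparser != bigger
    cs_cluster = sparser
    labels = np.where(assign == cs_cluster, CS, SS).astype("U2")
    return ClassifiedEvents(labels=labels, pcs=pcs, needs_review=needs_review)


def to_spike_train(times: np.ndarray, labels: np.ndarray, duration: float) -> LabeledSpikeTrain:
    """Assemble detection + classification output into a labeled train."""
    labels = np.asarray(labels, dtype="U2")
    return merge_labeled(times[labels == SS], times[labels == CS], duration)


def validate_single_unit(train: LabeledSpikeTrain) -> UnitValidation:
    """Climbing-fiber-pause check of single-unit identity.

    ``mean_cs_to_ss`` averages, over CSs with a subsequent SS, the time
    from the CS to the next SS; ``mean_ss_isi`` averages SS-to-SS
    intervals that do not contain a CS.  The unit passes when the former
    exceeds the latter.
    """
    cs = train.times_of(CS)
    ss = train.times_of(SS)
    if cs.size == 0:
        return UnitValidation(None, None, None, status="no-cs")
    if ss.size < 2:
        return UnitValidation(None, None, None, status="insufficient")
    idx = np.searchsorted(ss, cs, side="right")
    has_next = idx < ss.size
    if not has_next.any():
        return UnitValidation(None, None, None, status="insufficient")
    pauses = ss[idx[has_next]] - cs[has_next]
    spans = train.ss_isi_spans_cs()
    isis = np.diff(ss)[~spans]
    if isis.size == 0:
        return UnitValidation(None, None, None, status="insufficient")
    mean_pause = float(pauses.mean())
    mean_isi = float(isis.mean())
    return UnitValidation(
        mean_cs_to_ss=mean_pause,
        mean_ss_isi=mean_isi,
        is_single_unit=mean_pause > mean_isi,
        per_cs_pauses=pauses,
    )
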