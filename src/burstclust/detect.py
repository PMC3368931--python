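"""Interval-rule burst detection and descriptive spike-train statistics.

A burst is a short episode of high-rate firing bounded by silence.  The
detector scans a spike train left to right and opens a candidate at any
spike that is preceded by at least ``pre_silence`` seconds without a spike
(the recording start counts as silence) and whose next spike follows within
``second_spike_max``.  Spikes accrue while every interspike interval (ISI)
stays below ``end_isi`` and no two consecutive ISIs sum to more than
``end_pair_sum``; the burst ends at the last spike before the terminating
interval(s).  Candidates with fewer than ``min_spikes`` spikes or a span
not exceeding ``min_duration`` are discarded, but their spikes still count
against the pre-silence requirement of later candidates.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "DetectorParams",
    "Burst",
    "StimulusEvent",
    "RateSeries",
    "BurstDetector",
    "detect_bursts",
    "associate_stimuli",
    "joint_isi",
    "interburst_histogram",
    "rate_series",
    "rate_correlation",
    "psth",
]

NOISE_LABEL = "N"
#: closed label alphabet for bursts: noise plus the five stimulus classes.
LABELS = ("1", "2", "3", "4", "5", NOISE_LABEL)


@dataclass
class SpikeTrain:
    """Absolute spike times (s) of one continuous recording."""

    times: np.ndarray
    duration: float
    id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.times.size:
            d = np.diff(self.times)
            if np.any(d <= 0):
                i = int(np.argmax(d <= 0))
                raise ValueError(
                    f"spike times must be strictly increasing; violation at "
                    f"index {i + 1} (t={self.times[i + 1]:.6f})"
                )
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class DetectorParams:
    """Interval thresholds of the burst detector (all seconds/counts)."""

    pre_silence: float = 0.060
    second_spike_max: float = 0.015
    end_isi: float = 0.030
    end_pair_sum: float = 0.045
    min_spikes: int = 5
    min_duration: float = 0.008

    def __post_init__(self) -> None:
        for name in ("pre_silence", "second_spike_max", "end_isi", "end_pair_sum",
                     "min_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.second_spike_max >= self.end_isi:
            raise ValueError("second_spike_max must be < end_isi")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")


@dataclass
class Burst:
    """One detected burst: absolute onset plus onset-relative spike times."""

    onset: float
    rel_times: np.ndarray
    label: str | None = None
    recording_id: str = ""
    trigger_onset: float | None = None

    def __post_init__(self) -> None:
        self.rel_times = np.asarray(self.rel_times, dtype=np.float64)
        if self.rel_times.size and abs(self.rel_times[0]) > 1e-12:
            raise ValueError("rel_times must start at 0")
        if self.rel_times.size > 1 and np.any(np.diff(self.rel_times) <= 0):
            raise ValueError("rel_times must be strictly increasing")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_spikes(self) -> int:
        return self.rel_times.size

    @property
    def span(self) -> float:
        return float(self.rel_times[-1]) if self.rel_times.size else 0.0

    @property
    def times(self) -> np.ndarray:
        """Absolute spike times."""
        return self.onset + self.rel_times


@dataclass(frozen=True)
class StimulusEvent:
    """A stimulus trigger: onset time (s) and class id 1-5."""

    onset: float
    class_id: int

    def __post_init__(self) -> None:
        if self.class_id not in range(1, 6):
            raise ValueError(f"class_id must be in 1..5, got {self.class_id}")


@dataclass
class RateSeries:
    """Event rate per contiguous time bin (Hz)."""

    bin_width: float
    bin_start_times: np.ndarray
    values: np.ndarray


class BurstDetector:
    """Stateful wrapper around :func:`detect_bursts` with stored parameters."""

    def __init__(self, params: DetectorParams | None = None, **kwargs):
        self.params = params or DetectorParams(**kwargs)

    def detect(self, train: SpikeTrain) -> list[Burst]:
        return detect_bursts(train, self.params)


def detect_bursts(train: SpikeTrain, params: DetectorParams | None = None) -> list[Burst]:
    """Extract bursts from a spike train by the interval rules.

    Returns onset-sorted, non-overlapping bursts.  Inside every returned
    burst all ISIs are < ``end_isi`` and every pair of consecutive ISIs
    sums to <= ``end_pair_sum``.
    """
    p = params or DetectorParams()
    if not isinstance(train, SpikeTrain):
        train = SpikeTrain(np.asarray(train, dtype=float),
                           duration=float(np.max(train)) + 1e-9 if len(train) else 0.0)
    t = train.times
    n = t.size
    bursts: list[Burst] = []
    i = 0
    while i < n - 1:
        gap_before = t[i] - t[i - 1] if i > 0 else np.inf
        if gap_before >= p.pre_silence and t[i + 1] - t[i] <= p.second_spike_max:
            # accrue spikes; j = index of current last spike in candidate
            j = i + 1
            while j < n - 1:
                nxt = t[j + 1] - t[j]
                if nxt >= p.end_isi:
                    break
                prv = t[j] - t[j - 1]
                if prv + nxt > p.end_pair_sum:
                    # pair rule: end before the first of the two intervals
                    j -= 1
                    break
                j += 1
            count = j - i + 1
            span = t[j] - t[i]
            if count >= p.min_spikes and span > p.min_duration:
                bursts.append(
                    Burst(onset=float(t[i]), rel_times=t[i : j + 1] - t[i],
                          recording_id=train.id)
                )
            i = j + 1
        else:
            i += 1
    return bursts


def associate_stimuli(
    bursts: list[Burst],
    events: list[StimulusEvent],
    window: float = 0.050,
) -> list[Burst]:
    """Label bursts by the nearest stimulus trigger within ``+-window``.

    Each burst whose onset falls within the window of an event is a
    candidate for that event's class; when several bursts fall in one
    event's window only the burst with the nearest onset receives the
    class, and when several events could claim one burst the nearest event
    wins (ties broken toward the earlier event).  All other bursts are
    labeled noise ("N").
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    events = sorted(events, key=lambda e: e.onset)
    ev_onsets = np.array([e.onset for e in events])
    chosen: dict[int, int] = {}  # burst index -> event index
    for bi, b in enumerate(bursts):
        if not ev_onsets.size:
            break
        k = int(np.searchsorted(ev_onsets, b.onset))
        best, best_d = None, np.inf
        for cand in (k - 1, k):
            if 0 <= cand < len(events):
                d = abs(b.onset - ev_onsets[cand])
                if d <= window and d < best_d:  # earlier event wins ties
                    best, best_d = cand, d
        if best is not None:
            chosen[bi] = best
    # per event keep only the nearest-onset burst
    winners: dict[int, int] = {}
    for bi, ei in chosen.items():
        d = abs(bursts[bi].onset - ev_onsets[ei])
        if ei not in winners or d < abs(bursts[winners[ei]].onset - ev_onsets[ei]):
            winners[ei] = bi
    out = []
    for bi, b in enumerate(bursts):
        ei = chosen.get(bi)
        if ei is not None and winners.get(ei) == bi:
            out.append(
                dataclasses.replace(
                    b, label=str(events[ei].class_id),
                    trigger_onset=float(ev_onsets[ei]),
                )
            )
        else:
            out.append(dataclasses.replace(b, label=NOISE_LABEL))
    return out


def joint_isi(train) -> list[tuple[float, float]]:
    """Successive ISI pairs (ISI_k, ISI_{k+1}); empty for < 3 spikes."""
    t = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if t.size < 3:
        return []
    isis = np.diff(t)
    return list(zip(isis[:-1].tolist(), isis[1:].tolist()))


def interburst_histogram(
    bursts: list[Burst], bin: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (counts, bin_edges) of onset-to-onset burst gaps."""
    if bin <= 0:
        raise ValueError("bin must be positive")
    if len(bursts) < 2:
        return np.array([], dtype=int), np.array([])
    onsets = np.array(sorted(b.onset for b in bursts))
    gaps = np.diff(onsets)
    edges = np.arange(0.0, gaps.max() + bin, bin)
    if edges.size < 2 or edges[-1] <= gaps.max():
        edges = np.append(edges, edges[-1] + bin)
    counts, edges = np.histogram(gaps, bins=edges)
    return counts, edges


def rate_series(event_times, bin: float, duration: float) -> RateSeries:
    """Event rate per contiguous bin; the final partial bin uses its own width."""
    if bin <= 0:
        raise ValueError("bin must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(event_times, dtype=float)
    n_bins = int(np.ceil(duration / bin))
    edges = np.arange(n_bins + 1) * bin
    edges[-1] = duration
    counts, _ = np.histogram(t, bins=edges)
    widths = np.diff(edges)
    return RateSeries(
        bin_width=bin,
        bin_start_times=edges[:-1].copy(),
        values=counts / widths,
    )


def rate_correlation(a: RateSeries, b: RateSeries) -> float:
    """Pearson correlation of two equally-binned rate series.

    Returns NaN (with a warning) when either series has zero variance.
    """
    if a.bin_width != b.bin_width or a.values.size != b.values.size:
        raise ValueError("rate series must share binning and length")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        warnings.warn("rate_correlation undefined for zero-variance series",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a.values, b.values)[0, 1])


def psth(
    bursts: list[Burst],
    bin: float = 0.002,
    window: tuple[float, float] = (-0.050, 0.200),
) -> tuple[np.ndarray, np.ndarray]:
    """Peri-stimulus time histogram of burst spikes around their triggers.

    Bin edges are aligned so that 0 (the trigger onset) is an edge.
    Returns (counts, edges); counts are summed over bursts.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    lo = np.floor(window[0] / bin) * bin
    hi = np.ceil(window[1] / bin) * bin
    edges = np.arange(lo, hi + bin / 2, bin)
    counts = np.zeros(edges.size - 1, dtype=int)
    for b in bursts:
        if b.trigger_onset is None:
            raise ValueError("psth requires bursts with trigger_onset set")
        rel = b.times - b.trigger_onset
        c, _ = np.histogram(rel, bins=edges)
        counts += c
    return counts, edges
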