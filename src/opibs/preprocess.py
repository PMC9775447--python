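"""Pulse-waveform front end: peak detection, interval extraction, artifact
correction and epoch segmentation.

The unit of analysis throughout the package is the :class:`PPISeries` — the
sequence of pulse-to-pulse (PP) intervals in seconds, the PPG analogue of the
ECG RR tachogram.  Raw photoplethysmograms are reduced to a ``PPISeries`` by
systolic-peak detection (:func:`detect_peaks`) followed by differencing
(:func:`intervals_from_beats`); beat-interval exports from wearables enter the
pipeline directly.  Recordings are then cleaned with a local median filter and
cut into consecutive 5-minute epochs, the standard short-term window for
heart-rate-variability analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "PPGSignal",
    "PPISeries",
    "SegmentSet",
    "detect_peaks",
    "intervals_from_beats",
    "local_median_filter",
    "segment",
]

log = logging.getLogger(__name__)

_TIME_TOL = 1e-9  # beat-time / interval consistency tolerance, seconds


@dataclass(frozen=True)
class PPGSignal:
    """A uniformly sampled photoplethysmogram.

    Parameters
    ----------
    samples : ndarray
        Waveform amplitudes (arbitrary units); must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PPG samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class PPISeries:
    """A beat-interval series in seconds, optionally with beat timestamps.

    ``beat_times`` (when present) holds the cumulative times of the beats that
    delimit the intervals, so ``len(beat_times) == len(intervals) + 1`` and
    ``diff(beat_times) == intervals``.
    """

    intervals: np.ndarray
    beat_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if len(self.intervals) and not np.all(self.intervals > 0):
            raise ValueError("all intervals must be positive")
        if self.beat_times is not None:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if len(self.beat_times) != len(self.intervals) + 1:
                raise ValueError(
                    "beat_times must have one more entry than intervals"
                )
            if not np.allclose(
                np.diff(self.beat_times), self.intervals, rtol=0, atol=_TIME_TOL
            ):
                raise ValueError("beat_times differences do not match intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum())


@dataclass
class SegmentSet:
    """Ordered, non-overlapping fixed-duration epochs of one recording."""

    segments: list[PPISeries]
    segment_length_s: float = 300.0
    recording_id: str = ""

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def detect_peaks(
    sig: PPGSignal,
    w1_s: float = 0.111,
    w2_s: float = 0.667,
    beta: float = 0.02,
) -> np.ndarray:
    """Locate systolic peaks with the two-moving-average scheme of Elgendi et al.

    The waveform is band-passed (0.5–8 Hz, zero-phase Butterworth), clipped at
    zero and squared; a short moving average (window ``w1_s``, the scale of a
    systolic peak) is compared against a long one (window ``w2_s``, the scale
    of a full beat) offset by ``beta`` times the mean squared signal.  Runs
    where the short average exceeds the threshold and that are at least one
    peak-width long become blocks of interest; the band-passed maximum of each
    block is reported as a beat.

    Returns beat times in seconds, strictly increasing.  Raises ``ValueError``
    if the signal is shorter than two beat windows.
    """
    x = sig.samples
    n = len(x)
    if n < 2 * w2_s * sig.fs:
        raise ValueError(
            f"signal too short for peak detection: {n} samples "
            f"< 2 * {w2_s} s * {sig.fs} Hz"
        )

    nyq = sig.fs / 2.0
    hi = min(8.0, 0.9 * nyq)
    b, a = butter(2, [0.5 / nyq, hi / nyq], btype="band")
    filt = filtfilt(b, a, x)
    clipped = np.clip(filt, 0.0, None)
    squared = clipped**2

    w1 = max(1, int(round(w1_s * sig.fs)))
    w2 = max(1, int(round(w2_s * sig.fs)))
    ma_peak = np.convolve(squared, np.ones(w1) / w1, mode="same")
    ma_beat = np.convolve(squared, np.ones(w2) / w2, mode="same")
    thr = ma_beat + beta * squared.mean()

    above = ma_peak > thr
    if not above.any():
        return np.empty(0)

    # contiguous runs of `above`
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks], [idx[-1]]))  # inclusive

    peaks = []
    for s0, e0 in zip(run_starts, run_ends):
        if e0 - s0 + 1 >= w1:
            peaks.append(s0 + int(np.argmax(filt[s0 : e0 + 1])))
    return np.asarray(peaks, dtype=float) / sig.fs


def intervals_from_beats(beat_times: np.ndarray) -> PPISeries:
    """Difference strictly increasing beat times into a :class:`PPISeries`."""
    t = np.asarray(beat_times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least two beats to form intervals")
    if not np.all(np.diff(t) > 0):
        raise ValueError("beat times must be strictly increasing")
    return PPISeries(intervals=np.diff(t), beat_times=t)


def _median_pass(x: np.ndarray, window: int, k: float) -> np.ndarray:
    n = len(x)
    if window > n:
        med = np.full(n, np.median(x))
    else:
        half = window // 2
        pad = np.concatenate((np.full(half, x[0]), x, np.full(half, x[-1])))
        med = np.median(
            np.lib.stride_tricks.sliding_window_view(pad, window), axis=1
        )
    out = x.copy()
    bad = np.abs(x - med) > k * med
    out[bad] = med[bad]
    return out


def local_median_filter(
    ppi: PPISeries, window: int = 11, k: float = 0.2, max_passes: int = 100
) -> PPISeries:
    """Replace artifact intervals by the local median.

    An interval deviating from the median of its ``window``-beat neighbourhood
    (edge-replicated) by more than the fraction ``k`` of that median is
    replaced by the median.  The rule is applied repeatedly until a fixpoint is
    reached, so the correction is idempotent: removing a gross outlier can
    lower a neighbourhood median enough to expose a second, milder artifact
    that a single pass would leave in place.  A window wider than the series
    degrades to the global median.  Beat timestamps are dropped from the
    output because replaced intervals no longer match the raw beat times.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = ppi.intervals.copy()
    for _ in range(max_passes):
        nxt = _median_pass(x, window, k)
        if np.array_equal(nxt, x):
            break
        x = nxt
    return PPISeries(intervals=x, beat_times=None)


def segment(
    ppi: PPISeries,
    segment_length_s: float = 300.0,
    min_beats: int = 60,
    recording_id: str = "",
) -> SegmentSet:
    """Cut a recording into consecutive fixed-duration epochs.

    Intervals are packed greedily by cumulative interval time: interval *j*
    belongs to the window containing its start time.  A trailing window whose
    data end before the full ``segment_length_s`` has elapsed is dropped, as is
    any completed window with fewer than ``min_beats`` beats (too few beats to
    support coarse-graining and pattern embedding).
    """
    if len(ppi) == 0:
        raise ValueError("cannot segment an empty interval series")
    ends = np.cumsum(ppi.intervals)
    starts = ends - ppi.intervals
    win = np.floor(starts / segment_length_s).astype(int)
    total = ends[-1]
    segments: list[PPISeries] = []
    for w in range(win[-1] + 1):
        mask = win == w
        # window is complete only if the recording extends past its right edge
        if total < (w + 1) * segment_length_s:
            break
        if mask.sum() < min_beats:
            log.warning(
                "dropping segment %d of %s: only %d beats",
                w,
                recording_id or "<recording>",
                int(mask.sum()),
            )
            continue
        segments.append(PPISeries(intervals=ppi.intervals[mask]))
    return SegmentSet(
        segments=segments,
        segment_length_s=segment_length_s,
        recording_id=recording_id,
    )
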