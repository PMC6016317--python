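"""Afterdischarge detection by the amplitude-ratio / minimum-duration rule.

An afterdischarge (AD) is scored when the EEG amplitude envelope stays at or
above ``ratio`` × baseline RMS (default 2.5) for at least ``min_duration``
seconds (default 6 s). "Amplitude" is operationalized as a sliding-RMS
envelope over 0.5 s windows with 50 % overlap: RMS is robust to isolated
sample spikes, and the window is short relative to the 6 s minimum.
Sub-threshold dips of up to ``bridge_gap`` seconds inside an event are
bridged before the duration rule is applied, because spike-train ADs dip
between consecutive spikes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import AnnotationError, InsufficientDataError, ParameterError
from .records import ADSegment, EEGRecord, StageEvent


@dataclass
class BaselineStats:
    """Baseline amplitude statistics.

    ``rms`` is the root-mean-square voltage of the baseline window;
    ``envelope_series`` the sliding sub-window RMS values used for
    diagnostics; ``window_length`` the sub-window length in seconds.
    """

    rms: float
    envelope_series: np.ndarray
    window_length: float


def sliding_rms(
    samples: np.ndarray, sampling_rate: float, window: float = 0.5, overlap: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """RMS in sliding windows; returns (window start times, RMS values).

    Windows are full-length only (no partial trailing window); start times
    step by ``window * (1 - overlap)`` seconds.
    """
    w = int(round(window * sampling_rate))
    hop = max(1, int(round(w * (1.0 - overlap))))
    x = np.asarray(samples, dtype=float)
    if x.size < w:
        raise InsufficientDataError("record shorter than one envelope window")
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(0, x.size - w + 1, hop)
    rms = np.sqrt((csum[starts + w] - csum[starts]) / w)
    return starts / sampling_rate, rms


def baseline_stats(
    record: EEGRecord, window: float = 7.0, subwindow: float = 0.5
) -> BaselineStats:
    """Amplitude statistics of the first ``window`` seconds of a record."""
    if record.duration < window:
        raise InsufficientDataError(
            f"record of {record.duration:.2f} s shorter than the {window:.2f} s baseline window"
        )
    n = int(round(window * record.sampling_rate))
    x = record.samples[:n]
    rms = float(np.sqrt(np.mean(x * x)))
    _, env = sliding_rms(x, record.sampling_rate, window=subwindow)
    return BaselineStats(rms=rms, envelope_series=env, window_length=subwindow)


def detect_ad_events(
    record: EEGRecord,
    baseline: BaselineStats,
    ratio: float = 2.5,
    min_duration: float = 6.0,
    window: float = 0.5,
    overlap: float = 0.5,
    bridge_gap: float = 0.5,
) -> list[tuple[float, float]]:
    """Detect AD intervals as maximal super-threshold envelope runs.

    Returns sorted, non-overlapping ``(onset, duration)`` pairs in seconds
    relative to the record start time, using the half-open convention
    [onset, onset + duration). Onset is the start of the first
    super-threshold window.
    """
    if ratio <= 0 or min_duration <= 0:
        raise ParameterError("ratio and min_duration must be positive")
    starts, env = sliding_rms(record.samples, record.sampling_rate, window, overlap)
    threshold = ratio * baseline.rms
    above = env >= threshold
    # A window straddling an AD edge can pass on partial overlap, which
    # would stretch the measured extent by up to a full window per side;
    # crediting each super-threshold window only the hop-length interval
    # centred on it keeps the onset/offset error below half a window.
    hop = window * (1.0 - overlap)
    intervals: list[list[float]] = []
    for t, ok in zip(starts, above):
        if not ok:
            continue
        lo = t + (window - hop) / 2.0
        hi = lo + hop
        if intervals and lo <= intervals[-1][1] + bridge_gap:
            intervals[-1][1] = max(intervals[-1][1], hi)
        else:
            intervals.append([lo, hi])
    intervals = [
        _refine_bounds(record, lo, hi, threshold, window, hop)
        for lo, hi in intervals
    ]
    events = [
        (record.start_time + lo, hi - lo)
        for lo, hi in intervals
        if hi - lo >= min_duration
    ]
    return events


def _refine_bounds(
    record: EEGRecord,
    lo: float,
    hi: float,
    threshold: float,
    window: float,
    hop: float,
    step: float = 0.01,
) -> list[float]:
    """Sub-hop refinement of one event's boundaries.

    Re-scans the same ``window``-length RMS at ``step`` resolution near each
    coarse boundary and places the boundary at the first (last) passing
    window's *center*; the center convention makes the residual localization
    error independent of how far the AD amplitude exceeds the threshold
    (bounded by ~window/2 · |1 − 2·f| with f the passing overlap fraction).
    """
    fs = record.sampling_rate
    x = record.samples
    w = int(round(window * fs))
    ds = max(1, int(round(step * fs)))
    csum = np.concatenate(([0.0], np.cumsum(x * x)))

    def _scan(t0: float, t1: float) -> tuple[np.ndarray, np.ndarray]:
        i0 = max(0, int(round(t0 * fs)))
        i1 = min(x.size - w, int(round(t1 * fs)))
        if i1 < i0:
            return np.array([]), np.array([])
        starts = np.arange(i0, i1 + 1, ds)
        rms = np.sqrt((csum[starts + w] - csum[starts]) / w)
        return starts, rms

    margin = window + hop
    starts, rms = _scan(lo - margin, lo + margin)
    passing = np.flatnonzero(rms >= threshold)
    new_lo = (starts[passing[0]] + w / 2.0) / fs if passing.size else lo
    starts, rms = _scan(hi - window - margin, hi - window + margin)
    passing = np.flatnonzero(rms >= threshold)
    new_hi = (starts[passing[-1]] + w / 2.0) / fs if passing.size else hi
    if new_hi <= new_lo:
        return [lo, hi]
    return [new_lo, new_hi]


def label_segments(
    events: list[tuple[float, float]],
    annotations: list[StageEvent],
    tolerance: float = 1.0,
) -> list[ADSegment]:
    """Match detected events to stage annotations by maximal temporal overlap.

    ADD (afterdischarge duration) is taken from the detected extent; stage,
    phase, animal and group from the matched annotation. Events whose best
    overlap is below ``tolerance`` seconds are returned flagged
    ``matched=False`` and should be excluded downstream.
    """
    anns = sorted(annotations, key=lambda a: a.onset_s)
    for a, b in zip(anns[:-1], anns[1:]):
        if b.onset_s < a.end_s:
            raise AnnotationError(
                f"annotations overlap: [{a.onset_s}, {a.end_s}) and [{b.onset_s}, {b.end_s})"
            )
    segments: list[ADSegment] = []
    for onset, duration in events:
        end = onset + duration
        best, best_overlap = None, 0.0
        for ann in anns:
            ov = min(end, ann.end_s) - max(onset, ann.onset_s)
            if ov > best_overlap:
                best, best_overlap = ann, ov
        if best is None or best_overlap < tolerance:
            segments.append(
                ADSegment(
                    onset=onset,
                    add=duration,
                    racine_stage=0,
                    phase="",
                    animal_id="",
                    group="",
                    matched=False,
                )
            )
        else:
            segments.append(
                ADSegment(
                    onset=onset,
                    add=duration,
                    racine_stage=best.racine_stage,
                    phase=best.phase,
                    animal_id=best.animal_id,
                    group=best.group,
                    matched=True,
                )
            )
    return segments
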