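"""Transcriptional burst detection on baseline-zeroed traces.

A burst starts when the smoothed trace (5-frame centered moving average)
exceeds a fixed start threshold, and ends when the signal drops below
55% of the local peak — the running maximum since the burst started.
Candidates shorter than 5 frames are discarded as detection noise, as
are candidates whose opening frames decrease monotonically (a decaying
signal inherited from before the window, not a new activation event).
Surviving intervals are shifted two frames later to better center the
underlying event. The same threshold must be used across all conditions
of one experiment set; by default it is tied to the signal scale of the
control condition (10% of its pooled 99th-percentile smoothed value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ms2burst.spot_quant import TraceSet


@dataclass
class BurstCallConfig:
    """Burst-calling rule parameters.

    ``start_threshold`` is a per-experiment constant in trace intensity
    units; ``None`` means "derive from the control condition" via
    :func:`default_start_threshold`. ``decreasing_start_len`` of ``None``
    defaults to ``smooth_window``.
    """

    smooth_window: int = 5
    start_threshold: float | None = None
    end_fraction: float = 0.55
    min_duration: int = 5
    shift: int = 2
    decreasing_start_len: int | None = None

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if not (0 < self.end_fraction < 1):
            raise ValueError("end_fraction must be in (0, 1)")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.decreasing_start_len is None:
            self.decreasing_start_len = self.smooth_window


@dataclass
class Burst:
    """One detected burst (frames inclusive, post-shift)."""

    track_id: int
    start_frame: int
    end_frame: int
    amplitude: float  # peak of the smoothed trace within the burst
    local_peak: float  # running max used by the termination rule

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def duration_s(self, frame_interval: float) -> float:
        return self.duration_frames * frame_interval


@dataclass
class BurstSummary:
    """Per-nucleus burst statistics.

    ``mean_amplitude`` / ``mean_duration`` are NaN when the nucleus had
    no bursts; ``total_output`` (area under the raw trajectory over the
    analysis window, intensity x frames) is always defined.
    """

    track_id: int
    n_bursts: int
    mean_amplitude: float
    mean_duration_frames: float
    mean_duration_s: float
    total_output: float


def smooth_trace(trace: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; edges average the available samples."""
    trace = np.asarray(trace, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > trace.size:
        raise ValueError("window longer than trace")
    half = window // 2
    kernel = np.ones(window)
    num = np.convolve(trace, kernel, mode="same")
    den = np.convolve(np.ones_like(trace), kernel, mode="same")
    out = num / den
    # guard against fp drift at the exact edges
    for k in range(half):
        out[k] = trace[: k + half + 1].mean()
        out[-(k + 1)] = trace[-(k + half + 1) :].mean()
    return out


def detect_bursts(
    smoothed: np.ndarray,
    config: BurstCallConfig,
    track_id: int = 0,
    frame_offset: int = 0,
) -> list[Burst]:
    """Run the burst state machine over one smoothed, baseline-zeroed trace.

    OFF -> ON at the first frame above ``start_threshold``; while ON the
    local peak is the running maximum since burst start; ON -> OFF at
    the first frame below ``end_fraction * local_peak`` (the burst ends
    on the frame before it). Candidates are then length-filtered,
    rejected when strictly decreasing over their opening
    ``decreasing_start_len`` frames, and shifted ``shift`` frames later
    (clamped to the trace). ``frame_offset`` maps index 0 of the trace
    onto the movie frame axis.
    """
    if config.start_threshold is None:
        raise ValueError("start_threshold must be set (see default_start_threshold)")
    v = np.asarray(smoothed, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("trace contains non-finite values; split segments first")
    n = v.size
    thr = config.start_threshold

    candidates: list[tuple[int, int, float]] = []  # (start, end, local_peak)
    state_on = False
    start = 0
    peak = 0.0
    for t in range(n):
        if not state_on:
            if v[t] > thr:
                state_on = True
                start = t
                peak = v[t]
        else:
            peak = max(peak, v[t])
            if v[t] < config.end_fraction * peak:
                candidates.append((start, t - 1, peak))
                state_on = False
    if state_on:
        candidates.append((start, n - 1, peak))

    bursts: list[Burst] = []
    for s, e, peak in candidates:
        if e - s + 1 < config.min_duration:
            continue
        head = v[s : s + config.decreasing_start_len]
        if head.size >= 2 and np.all(np.diff(head) < 0):
            continue
        s2, e2 = s + config.shift, min(e + config.shift, n - 1)
        if s2 > n - 1 or s2 > e2:
            continue
        bursts.append(
            Burst(
                track_id=track_id,
                start_frame=s2 + frame_offset,
                end_frame=e2 + frame_offset,
                amplitude=float(v[s2 : e2 + 1].max()),
                local_peak=float(peak),
            )
        )
    return bursts


def burst_properties(
    raw: np.ndarray,
    smoothed: np.ndarray,
    bursts: list[Burst],
    frame_interval: float = 16.8,
    track_id: int = 0,
) -> BurstSummary:
    """Per-nucleus summary: count, mean amplitude/duration, total output.

    Total output is the area under the *raw* trajectory over the whole
    analysis window (simple sum, one frame per sample); missing frames
    are excluded.
    """
    raw = np.asarray(raw, dtype=float)
    total = float(np.nansum(raw))
    if bursts:
        amps = [b.amplitude for b in bursts]
        durs = [b.duration_frames for b in bursts]
        mean_amp = float(np.mean(amps))
        mean_dur = float(np.mean(durs))
    else:
        mean_amp = float("nan")
        mean_dur = float("nan")
    return BurstSummary(
        track_id=track_id,
        n_bursts=len(bursts),
        mean_amplitude=mean_amp,
        mean_duration_frames=mean_dur,
        mean_duration_s=mean_dur * frame_interval if bursts else float("nan"),
        total_output=total,
    )


def default_start_threshold(
    control_traces: list[np.ndarray],
    smooth_window: int = 5,
    quantile: float = 0.99,
    fraction: float = 0.10,
) -> float:
    """Per-experiment start threshold tied to the control's signal scale.

    Returns ``fraction`` x the pooled ``quantile`` of smoothed control
    trace values. One value is used for every condition of an
    experiment set.
    """
    pooled = []
    for tr in control_traces:
        tr = np.asarray(tr, dtype=float)
        tr = tr[np.isfinite(tr)]
        if tr.size >= smooth_window:
            pooled.append(smooth_trace(tr, smooth_window))
        elif tr.size:
            pooled.append(tr)
    if not pooled:
        raise ValueError("no finite control trace values")
    allv = np.concatenate(pooled)
    return float(fraction * np.quantile(allv, quantile))


def _valid_segments(trace: np.ndarray) -> list[tuple[int, np.ndarray]]:
    """Split a trace with missing (NaN) frames into contiguous segments."""
    finite = np.isfinite(trace)
    segs = []
    start = None
    for i, ok in enumerate(finite):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            segs.append((start, trace[start:i]))
            start = None
    if start is not None:
        segs.append((start, trace[start:]))
    return segs


def call_traceset(
    traces: TraceSet, config: BurstCallConfig
) -> tuple[list[Burst], list[BurstSummary], pd.DataFrame, pd.DataFrame]:
    """Burst-call every track of a trace set.

    Missing frames split a track into independently processed segments.
    Returns bursts, per-nucleus summaries, and both as tables.
    """
    if config.start_threshold is None:
        config = BurstCallConfig(
            smooth_window=config.smooth_window,
            start_threshold=default_start_threshold(
                [traces.baseline_sub[t] for t in traces.track_ids],
                config.smooth_window,
            ),
            end_fraction=config.end_fraction,
            min_duration=config.min_duration,
            shift=config.shift,
            decreasing_start_len=config.decreasing_start_len,
        )
    all_bursts: list[Burst] = []
    summaries: list[BurstSummary] = []
    for tid in traces.track_ids:
        trace = traces.baseline_sub[tid]
        offset = traces.start_frame[tid]
        bursts_t: list[Burst] = []
        for seg_start, seg in _valid_segments(trace):
            if seg.size < config.smooth_window:
                continue
            sm = smooth_trace(seg, config.smooth_window)
            bursts_t.extend(
                detect_bursts(sm, config, track_id=tid, frame_offset=offset + seg_start)
            )
        finite = trace[np.isfinite(trace)]
        sm_full = (
            smooth_trace(finite, config.smooth_window)
            if finite.size >= config.smooth_window
            else finite
        )
        summaries.append(
            burst_properties(
                traces.raw[tid], sm_full, bursts_t, traces.frame_interval, track_id=tid
            )
        )
        all_bursts.extend(bursts_t)

    burst_table = pd.DataFrame(
        [
            (
                b.track_id,
                b.start_frame,
                b.end_frame,
                b.duration_frames,
                b.duration_s(traces.frame_interval),
                b.amplitude,
            )
            for b in all_bursts
        ],
        columns=[
            "track_id",
            "start_frame",
            "end_frame",
            "duration_frames",
            "duration_s",
            "amplitude",
        ],
    )
    summary_table = pd.DataFrame(
        [
            (
                s.track_id,
                s.n_bursts,
                s.mean_amplitude,
                s.mean_duration_s,
                s.total_output,
            )
            for s in summaries
        ],
        columns=["track_id", "n_bursts", "mean_amplitude", "mean_duration_s", "total_output"],
    )
    return all_bursts, summaries, burst_table, summary_table
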