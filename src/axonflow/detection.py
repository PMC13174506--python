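"""Threshold spike detection on raw traces.

The detector thresholds the absolute voltage at a multiple of each trace's
RMS (default 3.5x), keeps the largest-|v| sample of every contiguous
supra-threshold run, and then removes inter-spike-interval violations
closer than 1 ms with a greedy earliest-first rule. Detection operates on
the unfiltered trace by default; a robust RMS estimate
(median absolute deviation / 0.6745) can be selected in the config for
traces where large spikes inflate the plain RMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AnalysisConfig, RawRecording, SpikeTable, validate_config


@dataclass(frozen=True)
class DetectionResult:
    """Detected spikes plus the per-electrode baseline bookkeeping."""

    spikes: SpikeTable
    rms_uv: dict[int, float]
    threshold_uv: dict[int, float]
    counts_before_isi: dict[int, int]
    counts_after_isi: dict[int, int]


def estimate_rms(trace: np.ndarray, robust: bool = False) -> float:
    """Baseline scale of a trace.

    Plain root-mean-square over the full trace by default; with
    ``robust=True`` the normalised median absolute deviation
    (MAD / 0.6745), which estimates the noise sigma unbiased by spikes.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size == 0:
        raise ValueError("empty trace")
    if robust:
        return float(np.median(np.abs(trace - np.median(trace))) / 0.6745)
    return float(np.sqrt(np.mean(trace**2)))


def detect_spikes(
    trace: np.ndarray, sampling_rate_hz: float, threshold_uv: float
) -> list[tuple[float, float]]:
    """Local-extremum events where |v| strictly exceeds the threshold.

    Within any contiguous supra-threshold run only the largest-|v| sample
    is reported; the event time is that sample index over the sampling
    rate and the amplitude is the signed voltage there.
    """
    if not (threshold_uv > 0):
        raise ValueError("threshold must be > 0")
    trace = np.asarray(trace, dtype=np.float64)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    above = np.abs(trace) > threshold_uv
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [len(trace)]])
    events = []
    for s, e in zip(starts, stops):
        idx = s + int(np.argmax(np.abs(trace[s:e])))
        events.append((idx / sampling_rate_hz, float(trace[idx])))
    return events


def apply_isi_filter(times: np.ndarray, min_isi_s: float) -> np.ndarray:
    """Greedy earliest-first duplicate removal.

    Keeps the first event and discards any event closer than ``min_isi_s``
    to the last kept one, so all consecutive gaps in the output are
    >= ``min_isi_s``.
    """
    times = np.asarray(times, dtype=np.float64)
    if len(times) == 0:
        return times
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_isi_s:
            kept.append(t)
    return np.asarray(kept)


def firing_rate(times: np.ndarray, duration_s: float) -> float:
    """Events per second: count / duration."""
    if not (duration_s > 0):
        raise ValueError("duration must be > 0")
    return len(times) / duration_s


def detect_recording(
    recording: RawRecording, cfg: AnalysisConfig | None = None
) -> DetectionResult:
    """Run detection plus the ISI filter on every electrode of a recording."""
    cfg = validate_config(cfg)
    ids, times, amps = [], [], []
    rms_map: dict[int, float] = {}
    thr_map: dict[int, float] = {}
    before: dict[int, int] = {}
    after: dict[int, int] = {}
    for eid in recording.layout.electrode_ids:
        trace = recording.trace(int(eid))
        rms = estimate_rms(trace, robust=cfg.robust_rms)
        thr = cfg.rms_threshold_multiple * rms
        rms_map[int(eid)] = rms
        thr_map[int(eid)] = thr
        events = detect_spikes(trace, recording.sampling_rate_hz, thr) if thr > 0 else []
        before[int(eid)] = len(events)
        if events:
            t = np.array([ev[0] for ev in events])
            a = np.array([ev[1] for ev in events])
            kept_t = apply_isi_filter(t, cfg.isi_min_s)
            keep_idx = np.searchsorted(t, kept_t)
            t, a = t[keep_idx], a[keep_idx]
        else:
            t = np.empty(0)
            a = np.empty(0)
        after[int(eid)] = len(t)
        ids.append(np.full(len(t), eid))
        times.append(t)
        amps.append(a)
    spikes = SpikeTable(
        np.concatenate(ids) if ids else np.empty(0),
        np.concatenate(times) if times else np.empty(0),
        np.concatenate(amps) if amps else np.empty(0),
        duration_s=recording.duration_s,
    )
    return DetectionResult(spikes, rms_map, thr_map, before, after)
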