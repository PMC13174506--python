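"""Action-potential propagation reconstruction along a microchannel.

A propagation event is a source-electrode spike followed by a
target-electrode spike inside the closed 1-2 ms latency window. Channels
with at least 30 such paired events qualify for propagation analysis.
Intermediary electrodes near 25/50/75% of the principal axis that fire in
strictly more than 80% of the paired windows anchor a latency trace —
ordered (axial distance, median latency) points — whose least-squares
slope is the conduction velocity in mm/ms. Running the pipeline in both
orientations classifies each channel as forward-only, backward-only,
bidirectional or silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AnalysisConfig, ElectrodeLayout, MicrochannelSpec, SpikeTable, validate_config
from .geometry import AxialMap, axial_map, band_filter


@dataclass(frozen=True)
class PairedEvents:
    """Greedily matched source/target spike pairs for one orientation."""

    source_electrode: int
    target_electrode: int
    t_source_s: np.ndarray
    t_target_s: np.ndarray
    min_paired_events: int

    def __post_init__(self):
        ts = np.asarray(self.t_source_s, dtype=np.float64)
        tt = np.asarray(self.t_target_s, dtype=np.float64)
        if len(ts) != len(tt):
            raise ValueError("source/target pair arrays must align")
        object.__setattr__(self, "t_source_s", ts)
        object.__setattr__(self, "t_target_s", tt)

    @property
    def latency_s(self) -> np.ndarray:
        return self.t_target_s - self.t_source_s

    @property
    def n_pairs(self) -> int:
        return len(self.t_source_s)

    @property
    def qualified(self) -> bool:
        return self.n_pairs >= self.min_paired_events


@dataclass(frozen=True)
class LatencyTrace:
    """Ordered (electrode, axial position, median latency) points."""

    electrode_ids: tuple[int, ...]
    axial_um: np.ndarray
    median_latency_s: np.ndarray

    def __post_init__(self):
        ax = np.asarray(self.axial_um, dtype=np.float64)
        lat = np.asarray(self.median_latency_s, dtype=np.float64)
        if not (len(self.electrode_ids) == len(ax) == len(lat)):
            raise ValueError("trace arrays must align")
        if np.any(np.diff(ax) <= 0):
            raise ValueError("axial positions must be strictly increasing")
        if len(lat) and lat[0] != 0.0:
            raise ValueError("source latency must be 0")
        object.__setattr__(self, "axial_um", ax)
        object.__setattr__(self, "median_latency_s", lat)

    def __len__(self) -> int:
        return len(self.electrode_ids)


@dataclass(frozen=True)
class VelocityEstimate:
    """Least-squares conduction velocity from a latency trace."""

    velocity_mm_per_ms: float
    intercept_mm: float
    residual_rms_mm: float
    n_points: int


@dataclass(frozen=True)
class DirectionReport:
    """Per-channel propagation directionality."""

    channel_id: str
    forward_qualified: bool
    backward_qualified: bool
    forward_n_pairs: int
    backward_n_pairs: int
    forward_velocity: VelocityEstimate | None = None
    backward_velocity: VelocityEstimate | None = None

    @property
    def classification(self) -> str:
        return {
            (True, True): "both",
            (True, False): "forward_only",
            (False, True): "backward_only",
            (False, False): "none",
        }[(self.forward_qualified, self.backward_qualified)]


def find_paired_events(
    source_times: np.ndarray,
    target_times: np.ndarray,
    window_s: tuple[float, float] = (0.001, 0.002),
    min_paired_events: int = 30,
    source_electrode: int = -1,
    target_electrode: int = -1,
) -> PairedEvents:
    """Pair source spikes with target spikes in the closed latency window.

    Scanning source events in time order, each is matched to the earliest
    unused target event with latency in ``[window_s[0], window_s[1]]``;
    every target event is used at most once. Both inputs must be sorted.
    """
    src = np.asarray(source_times, dtype=np.float64)
    tgt = np.asarray(target_times, dtype=np.float64)
    lo, hi = window_s
    ps, pt = [], []
    j = 0
    n = len(tgt)
    for t in src:
        while j < n and tgt[j] < t + lo:
            j += 1
        if j < n and tgt[j] <= t + hi:
            ps.append(t)
            pt.append(tgt[j])
            j += 1
    return PairedEvents(
        source_electrode=source_electrode,
        target_electrode=target_electrode,
        t_source_s=np.asarray(ps),
        t_target_s=np.asarray(pt),
        min_paired_events=min_paired_events,
    )


def cooccurrence_fraction(pairs: PairedEvents, candidate_times: np.ndarray) -> float:
    """Fraction of paired windows [t_source, t_target] containing a candidate event."""
    if pairs.n_pairs == 0:
        raise ValueError("no paired events")
    cand = np.asarray(candidate_times, dtype=np.float64)
    left = np.searchsorted(cand, pairs.t_source_s, side="left")
    right = np.searchsorted(cand, pairs.t_target_s, side="right")
    return float(np.mean(right > left))


def select_intermediaries(
    amap: AxialMap,
    band_electrodes: np.ndarray,
    pairs: PairedEvents,
    spikes: SpikeTable,
    anchors=(0.25, 0.50, 0.75),
    min_fraction: float = 0.80,
) -> dict[float, int]:
    """Choose at most one intermediary electrode per anchor fraction.

    Among band electrodes whose co-occurrence fraction strictly exceeds
    ``min_fraction``, each anchor takes the electrode with axial fraction
    closest to it (ties: smaller electrode id). Anchors with no passing
    candidate are skipped.
    """
    passing = []
    for eid in band_electrodes:
        frac = cooccurrence_fraction(pairs, spikes.times_for(int(eid)))
        if frac > min_fraction:
            passing.append((int(eid), amap.fraction_of(int(eid))))
    chosen: dict[float, int] = {}
    for anchor in sorted(anchors):
        if not passing:
            break
        eid, _ = min(passing, key=lambda p: (abs(p[1] - anchor), p[0]))
        chosen[anchor] = eid
    return chosen


def build_latency_trace(
    pairs: PairedEvents,
    intermediaries,
    spikes: SpikeTable,
    amap: AxialMap,
) -> LatencyTrace:
    """Median per-window latency at each intermediary, bracketed by endpoints.

    Intermediary latency in one paired window is the first candidate event
    in the closed [t_source, t_target] interval minus t_source; the point
    value is the median over windows. The source contributes (0, 0) and the
    target its median pair latency.
    """
    if not pairs.qualified:
        raise ValueError(
            f"unqualified pairing ({pairs.n_pairs} < {pairs.min_paired_events} events)"
        )
    inter_ids = sorted(
        set(intermediaries.values() if isinstance(intermediaries, dict) else intermediaries)
    )
    points: list[tuple[int, float, float]] = [
        (pairs.source_electrode, amap.axial_of(pairs.source_electrode), 0.0)
    ]
    for eid in inter_ids:
        cand = spikes.times_for(int(eid))
        left = np.searchsorted(cand, pairs.t_source_s, side="left")
        right = np.searchsorted(cand, pairs.t_target_s, side="right")
        has = right > left
        if not has.any():
            continue
        lat = cand[left[has]] - pairs.t_source_s[has]
        points.append((int(eid), amap.axial_of(int(eid)), float(np.median(lat))))
    points.append(
        (
            pairs.target_electrode,
            amap.axial_of(pairs.target_electrode),
            float(np.median(pairs.latency_s)),
        )
    )
    points.sort(key=lambda p: p[1])
    ids = tuple(p[0] for p in points)
    return LatencyTrace(
        electrode_ids=ids,
        axial_um=np.array([p[1] for p in points]),
        median_latency_s=np.array([p[2] for p in points]),
    )


def fit_velocity(trace: LatencyTrace) -> VelocityEstimate:
    """Ordinary least squares of axial position (mm) on latency (ms).

    The slope is the conduction velocity in mm/ms. With exactly two points
    this degenerates to the two-point slope. Raises on zero latency spread.
    """
    if len(trace) < 2:
        raise ValueError("need >= 2 trace points")
    lat_ms = trace.median_latency_s * 1e3
    pos_mm = trace.axial_um * 1e-3
    if np.ptp(lat_ms) == 0:
        raise ValueError("zero latency spread; velocity undefined")
    slope, intercept = np.polyfit(lat_ms, pos_mm, 1)
    resid = pos_mm - (slope * lat_ms + intercept)
    return VelocityEstimate(
        velocity_mm_per_ms=float(slope),
        intercept_mm=float(intercept),
        residual_rms_mm=float(np.sqrt(np.mean(resid**2))),
        n_points=len(trace),
    )


def _endpoint_electrodes(
    layout: ElectrodeLayout, spec: MicrochannelSpec
) -> tuple[int, int]:
    """Member electrodes nearest the channel entry and exit."""
    members = np.asarray(spec.member_electrode_ids)
    pos = np.vstack([layout.position_of(int(e)) for e in members])
    d_entry = np.linalg.norm(pos - np.asarray(spec.entry_xy_um), axis=1)
    d_exit = np.linalg.norm(pos - np.asarray(spec.exit_xy_um), axis=1)
    return int(members[np.argmin(d_entry)]), int(members[np.argmin(d_exit)])


def analyze_orientation(
    spikes: SpikeTable,
    layout: ElectrodeLayout,
    spec: MicrochannelSpec,
    cfg: AnalysisConfig,
    reverse: bool = False,
):
    """Full pairing -> intermediaries -> trace -> velocity for one orientation.

    Returns ``(pairs, trace_or_None, velocity_or_None)``; trace and
    velocity are None when the pairing does not qualify or the fit fails.
    """
    entry_eid, exit_eid = _endpoint_electrodes(layout, spec)
    src_eid, tgt_eid = (exit_eid, entry_eid) if reverse else (entry_eid, exit_eid)
    amap = axial_map(
        layout,
        source_xy_um=layout.position_of(src_eid),
        target_xy_um=layout.position_of(tgt_eid),
        electrode_ids=spec.member_electrode_ids,
    )
    pairs = find_paired_events(
        spikes.times_for(src_eid),
        spikes.times_for(tgt_eid),
        window_s=cfg.latency_window_s,
        min_paired_events=cfg.min_paired_events,
        source_electrode=src_eid,
        target_electrode=tgt_eid,
    )
    if not pairs.qualified:
        return pairs, None, None
    band = band_filter(amap, cfg.band_half_width_um)
    inter = select_intermediaries(
        amap, band, pairs, spikes,
        anchors=cfg.intermediary_anchors,
        min_fraction=cfg.cooccurrence_min_fraction,
    )
    trace = build_latency_trace(pairs, inter, spikes, amap)
    try:
        velocity = fit_velocity(trace)
    except ValueError:
        return pairs, trace, None
    if not np.isfinite(velocity.velocity_mm_per_ms) or velocity.velocity_mm_per_ms <= 0:
        return pairs, trace, None
    return pairs, trace, velocity


def classify_direction(
    spikes: SpikeTable,
    layout: ElectrodeLayout,
    spec: MicrochannelSpec,
    cfg: AnalysisConfig | None = None,
) -> DirectionReport:
    """Run the pipeline in both orientations and classify the channel.

    An orientation qualifies iff its pairing reaches the event floor and a
    positive finite velocity can be fitted.
    """
    cfg = validate_config(cfg)
    fwd_pairs, _, fwd_vel = analyze_orientation(spikes, layout, spec, cfg, reverse=False)
    bwd_pairs, _, bwd_vel = analyze_orientation(spikes, layout, spec, cfg, reverse=True)
    return DirectionReport(
        channel_id=spec.channel_id,
        forward_qualified=fwd_pairs.qualified and fwd_vel is not None,
        backward_qualified=bwd_pairs.qualified and bwd_vel is not None,
        forward_n_pairs=fwd_pairs.n_pairs,
        backward_n_pairs=bwd_pairs.n_pairs,
        forward_velocity=fwd_vel,
        backward_velocity=bwd_vel,
    )
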