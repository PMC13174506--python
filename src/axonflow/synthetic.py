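"""Synthetic MEA and neurite datasets emulating microchannel experiments.

Generates the inputs every downstream stage consumes: a row of electrodes
along a microchannel, spontaneous Poisson firing from the axon populations
occupying the channel, injected action-potential propagation sequences with
a known conduction velocity, rendered raw voltage traces, and hourly
neurite-track tables with axial fluorescence-intensity profiles.

The directional (asymmetric-geometry) condition is modelled after what the
imaging shows about axon occupancy: channel entries carry axons only from
the proximal organoid, while channel exits additionally carry axons that
grew in from the distal organoid and accumulated near the exit. Firing from
the extra distal population is therefore added only on electrodes within a
configurable axial fraction of the exit end (default: the exit-side half).
Straight control channels carry one statistically identical population
everywhere and propagate action potentials in both directions.

Every generator is a pure function of its configuration and seed. The
master seed is split per (stream, electrode) through a
``numpy.random.SeedSequence`` counter scheme so that adding electrodes or
populations does not reshuffle previously generated trains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ElectrodeLayout, MicrochannelSpec, RawRecording, SpikeTable

# fixed stream tags for the seed counter scheme
_STREAM_POISSON = 1
_STREAM_PROPAGATION = 2
_STREAM_RENDER = 3
_STREAM_NEURITE = 4

DEFAULT_SPIKE_AMPLITUDE_UV = -60.0
TEMPLATE_SUPPORT_S = 0.001  # biphasic extracellular template width


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated microchannel dataset.

    ``proximal_rate_hz`` is the spontaneous Poisson rate per electrode of
    the entry-side axon population (present along the whole channel);
    ``distal_rate_hz`` is the additional rate contributed by distal-organoid
    axons, present only on electrodes within ``distal_extent_fraction`` of
    the exit end and only for directional channels. Exactly one of
    ``propagation_velocity_um_per_ms`` / ``total_latency_ms`` fixes the
    conduction speed of injected propagation events.
    """

    channel_length_um: float = 910.0
    pitch_um: float = 17.5
    kind: str = "directional"
    duration_s: float = 600.0
    sampling_rate_hz: float = 20000.0
    proximal_rate_hz: float = 2.6
    distal_rate_hz: float = 5.1
    distal_extent_fraction: float = 0.5
    propagation_velocity_um_per_ms: float | None = 650.0
    total_latency_ms: float | None = None
    propagation_rate_hz: float = 1.0
    latency_jitter_ms: float = 0.0
    detection_dropout_prob: float = 0.0
    spike_amplitude_uv: float = DEFAULT_SPIKE_AMPLITUDE_UV
    noise_sd_uv: float = 5.0
    render_raw: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("straight", "directional"):
            raise ValueError(f"kind must be straight|directional, got {self.kind!r}")
        if self.proximal_rate_hz < 0 or self.distal_rate_hz < 0:
            raise ValueError("firing rates must be >= 0")
        if self.propagation_rate_hz < 0:
            raise ValueError("propagation_rate_hz must be >= 0")
        if self.latency_jitter_ms < 0:
            raise ValueError("latency_jitter_ms must be >= 0")
        if not (0.0 <= self.detection_dropout_prob <= 1.0):
            raise ValueError("detection_dropout_prob must be in [0, 1]")
        if not (0.0 <= self.distal_extent_fraction <= 1.0):
            raise ValueError("distal_extent_fraction must be in [0, 1]")
        given = (
            self.propagation_velocity_um_per_ms is not None,
            self.total_latency_ms is not None,
        )
        if sum(given) != 1:
            raise ValueError(
                "exactly one of propagation_velocity_um_per_ms / total_latency_ms required"
            )

    def velocity_um_per_ms(self, span_um: float) -> float:
        if self.propagation_velocity_um_per_ms is not None:
            return float(self.propagation_velocity_um_per_ms)
        return span_um / float(self.total_latency_ms)


@dataclass(frozen=True)
class GroundTruth:
    """Injected events with population labels and the true velocity."""

    electrode_id: np.ndarray
    time_s: np.ndarray
    label: tuple[str, ...]  # per event: proximal | distal
    velocity_mm_per_ms: float
    config: SimulationConfig

    def __post_init__(self):
        if not (self.velocity_mm_per_ms > 0):
            raise ValueError("true velocity must be > 0")
        t = np.asarray(self.time_s, dtype=np.float64)
        if len(t) and (t.min() < 0 or t.max() > self.config.duration_s):
            raise ValueError("ground-truth events must lie within [0, duration_s]")
        object.__setattr__(self, "electrode_id", np.asarray(self.electrode_id, dtype=np.int64))
        object.__setattr__(self, "time_s", t)

    def __len__(self) -> int:
        return len(self.time_s)

    def to_hdf5_group(self, group) -> None:
        group.create_dataset("electrode_id", data=self.electrode_id)
        group.create_dataset("time_s", data=self.time_s)
        group.create_dataset(
            "label", data=np.array([s.encode() for s in self.label])
        )
        group.attrs["velocity_mm_per_ms"] = self.velocity_mm_per_ms
        group.attrs["config_json"] = json.dumps(asdict(self.config), sort_keys=True)


def _rng(seed: int, stream: int, key: int = 0) -> np.random.Generator:
    """Deterministic per-(stream, key) generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, key)))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def build_channel_layout(
    length_um: float, pitch_um: float, kind: str, channel_id: str = "ch0"
) -> tuple[ElectrodeLayout, MicrochannelSpec]:
    """Place electrodes collinearly along a channel at the given pitch.

    Electrodes sit at axial 0, pitch, 2*pitch, ... with
    ``floor(length/pitch) + 1`` sites; the channel spec's endpoints are the
    first and last electrode, so the spec length is the spanned distance
    (which is less than ``length_um`` when pitch does not divide it).
    """
    if length_um <= 0 or pitch_um <= 0:
        raise ValueError("length_um and pitch_um must be > 0")
    n = int(np.floor(length_um / pitch_um + 1e-9)) + 1
    if n < 2:
        raise ValueError("pitch larger than channel length leaves < 2 electrodes")
    x = np.arange(n) * pitch_um
    positions = np.column_stack([x, np.zeros(n)])
    layout = ElectrodeLayout(
        electrode_ids=np.arange(n), positions_um=positions, pitch_um=pitch_um
    )
    spec = MicrochannelSpec(
        channel_id=channel_id,
        kind=kind,
        entry_xy_um=(0.0, 0.0),
        exit_xy_um=(float(x[-1]), 0.0),
        length_um=float(x[-1]),
        member_electrode_ids=tuple(range(n)),
    )
    return layout, spec


# ---------------------------------------------------------------------------
# spike-train generation
# ---------------------------------------------------------------------------


def simulate_poisson_trains(
    layout: ElectrodeLayout,
    rate_map: Mapping[int, float] | float,
    duration_s: float,
    seed: int,
    amplitude_uv: float = DEFAULT_SPIKE_AMPLITUDE_UV,
    _stream_key_offset: int = 0,
) -> SpikeTable:
    """Homogeneous Poisson spike trains, one independent stream per electrode.

    ``rate_map`` is either a scalar rate (Hz) applied to every electrode or
    a mapping electrode_id -> Hz.
    """
    ids, times = [], []
    for eid in layout.electrode_ids:
        rate = rate_map if np.isscalar(rate_map) else rate_map.get(int(eid), 0.0)
        if rate < 0:
            raise ValueError(f"negative rate for electrode {eid}")
        if rate == 0:
            continue
        rng = _rng(seed, _STREAM_POISSON, int(eid) + _stream_key_offset)
        n = rng.poisson(rate * duration_s)
        if n == 0:
            continue
        t = np.sort(rng.uniform(0.0, duration_s, size=n))
        ids.append(np.full(n, eid))
        times.append(t)
    if not ids:
        return SpikeTable.empty(duration_s)
    eid = np.concatenate(ids)
    t = np.concatenate(times)
    return SpikeTable(eid, t, np.full(len(t), amplitude_uv), duration_s)


def inject_propagating_events(
    layout: ElectrodeLayout,
    spec: MicrochannelSpec,
    source_times: np.ndarray,
    duration_s: float,
    velocity_um_per_ms: float | None = None,
    total_latency_ms: float | None = None,
    jitter_ms: float = 0.0,
    dropout_prob: float = 0.0,
    seed: int = 0,
    reverse: bool = False,
    amplitude_uv: float = DEFAULT_SPIKE_AMPLITUDE_UV,
) -> SpikeTable:
    """Re-emit each source event down the channel with distance-linear delay.

    Each source event (at the entry electrode, or the exit electrode when
    ``reverse``) appears at every downstream electrode after
    ``axial_distance / velocity`` milliseconds, plus optional independent
    Gaussian jitter; downstream re-emissions are independently dropped with
    ``dropout_prob`` (source events are never dropped). Events whose
    delayed time would exceed the recording duration are discarded.
    """
    source_times = np.asarray(source_times, dtype=np.float64)
    if len(source_times) and (source_times.min() < 0 or source_times.max() > duration_s):
        raise ValueError("source times must lie within [0, duration_s]")
    entry = np.asarray(spec.entry_xy_um)
    exit_ = np.asarray(spec.exit_xy_um)
    if reverse:
        entry, exit_ = exit_, entry
    axis = exit_ - entry
    span = float(np.linalg.norm(axis))
    if velocity_um_per_ms is None:
        if total_latency_ms is None:
            raise ValueError("give velocity_um_per_ms or total_latency_ms")
        velocity_um_per_ms = span / total_latency_ms
    if velocity_um_per_ms <= 0:
        raise ValueError("velocity must be > 0")
    unit = axis / span
    ids, times = [], []
    for eid in spec.member_electrode_ids:
        pos = layout.position_of(eid)
        axial_um = float(np.dot(pos - entry, unit))
        if axial_um < -1e-9 or axial_um > span + 1e-9:
            continue
        delay_s = (axial_um / velocity_um_per_ms) * 1e-3
        t = source_times + delay_s
        if axial_um > 1e-9:  # downstream electrodes get jitter and dropout
            rng = _rng(seed, _STREAM_PROPAGATION, int(eid) + (10_000 if reverse else 0))
            if jitter_ms > 0:
                t = t + rng.normal(0.0, jitter_ms * 1e-3, size=len(t))
            if dropout_prob > 0:
                t = t[rng.uniform(size=len(t)) >= dropout_prob]
        t = t[(t >= 0.0) & (t <= duration_s)]
        if len(t):
            ids.append(np.full(len(t), eid))
            times.append(t)
    if not ids:
        return SpikeTable.empty(duration_s)
    eid = np.concatenate(ids)
    t = np.concatenate(times)
    return SpikeTable(eid, t, np.full(len(t), amplitude_uv), duration_s)


def merge_spike_tables(*tables: SpikeTable) -> SpikeTable:
    """Concatenate spike tables sharing a duration into one canonical table."""
    tables = [t for t in tables if t is not None]
    if not tables:
        raise ValueError("no tables to merge")
    duration = tables[0].duration_s
    for t in tables:
        if t.duration_s != duration:
            raise ValueError("cannot merge tables with different durations")
    return SpikeTable(
        np.concatenate([t.electrode_id for t in tables]),
        np.concatenate([t.time_s for t in tables]),
        np.concatenate([t.amplitude_uv for t in tables]),
        duration,
    )


# ---------------------------------------------------------------------------
# raw-trace rendering
# ---------------------------------------------------------------------------


def spike_template(sampling_rate_hz: float, amplitude_uv: float) -> tuple[np.ndarray, int]:
    """Fixed biphasic extracellular template with 1 ms support.

    Negative-dominant trough followed by a smaller repolarisation hump;
    scaled so the trough sample equals ``amplitude_uv`` exactly. Returns
    ``(samples, trough_index)``.
    """
    n = max(int(round(TEMPLATE_SUPPORT_S * sampling_rate_hz)) + 1, 3)
    x = np.linspace(0.0, 1.0, n)
    # positive lobe kept below 0.29x the trough so a template clears a
    # 3.5x-RMS threshold (17.5 uV at 5 uV noise, -60 uV trough) exactly once
    shape = -np.exp(-((x - 0.35) ** 2) / (2 * 0.08**2)) + 0.25 * np.exp(
        -((x - 0.65) ** 2) / (2 * 0.12**2)
    )
    trough = int(np.argmin(shape))
    shape = shape / abs(shape[trough])  # trough == -1 exactly
    # negative amplitude -> negative-dominant waveform whose trough sample is
    # exactly amplitude_uv; positive amplitude flips polarity (peak == amplitude).
    return shape * (-amplitude_uv), trough


def render_raw_recording(
    spikes: SpikeTable,
    layout: ElectrodeLayout,
    sampling_rate_hz: float,
    noise_sd_uv: float = 5.0,
    seed: int = 0,
    amplitude_from_table: bool = True,
) -> RawRecording:
    """Render spike events into sampled voltage traces plus Gaussian noise.

    Each event adds the fixed biphasic template at the sample nearest its
    time (trough aligned to that sample); overlapping events on one
    electrode simply sum. Noise is independent per sample and electrode.
    """
    if sampling_rate_hz < 2.0 / TEMPLATE_SUPPORT_S:
        raise ValueError("sampling rate too low to resolve the spike template")
    n_samples = int(round(spikes.duration_s * sampling_rate_hz))
    signals = np.zeros((len(layout), n_samples))
    template_unit, trough = spike_template(sampling_rate_hz, -1.0)
    for row, eid in enumerate(layout.electrode_ids):
        mask = spikes.electrode_id == eid
        t = spikes.time_s[mask]
        amp = spikes.amplitude_uv[mask] if amplitude_from_table else None
        centers = np.round(t * sampling_rate_hz).astype(np.int64)
        for k, c in enumerate(centers):
            a = amp[k] if amp is not None else DEFAULT_SPIKE_AMPLITUDE_UV
            start = c - trough
            stop = start + len(template_unit)
            ts, te = max(start, 0), min(stop, n_samples)
            if ts >= te:
                continue
            # template_unit has trough -1; scaling by -a gives extremum == a
            signals[row, ts:te] += -a * template_unit[ts - start : te - start]
        if noise_sd_uv > 0:
            rng = _rng(seed, _STREAM_RENDER, int(eid))
            signals[row] += rng.normal(0.0, noise_sd_uv, size=n_samples)
    return RawRecording(layout=layout, signals=signals, sampling_rate_hz=sampling_rate_hz)


# ---------------------------------------------------------------------------
# end-to-end channel dataset
# ---------------------------------------------------------------------------


def simulate_channel_dataset(
    cfg: SimulationConfig,
) -> tuple[RawRecording | None, SpikeTable, MicrochannelSpec, GroundTruth]:
    """Simulate one microchannel experiment.

    Straight channels receive the proximal population's rate on every
    electrode and propagation events injected in both directions.
    Directional channels receive the proximal population everywhere, the
    distal population on exit-side electrodes only, and propagation
    entry -> exit only (the permissive direction).

    When ``cfg.render_raw`` is false the raw recording is skipped (returned
    as ``None``) — spike-table-level analyses do not need it and rendering
    dominates the cost for long recordings.
    """
    layout, spec = build_channel_layout(cfg.channel_length_um, cfg.pitch_um, cfg.kind)
    span = spec.length_um
    velocity = cfg.velocity_um_per_ms(span)

    # spontaneous populations
    proximal = simulate_poisson_trains(
        layout, cfg.proximal_rate_hz, cfg.duration_s, cfg.seed,
        amplitude_uv=cfg.spike_amplitude_uv,
    )
    labels = ["proximal"] * len(proximal)
    parts = [proximal]
    if cfg.kind == "directional" and cfg.distal_rate_hz > 0:
        cutoff = span * (1.0 - cfg.distal_extent_fraction)
        distal_rates = {
            int(eid): cfg.distal_rate_hz
            for eid, x in zip(layout.electrode_ids, layout.positions_um[:, 0])
            if x >= cutoff - 1e-9
        }
        distal = simulate_poisson_trains(
            layout, distal_rates, cfg.duration_s, cfg.seed,
            amplitude_uv=cfg.spike_amplitude_uv, _stream_key_offset=100_000,
        )
        labels += ["distal"] * len(distal)
        parts.append(distal)

    # propagation events
    directions = [(False, "proximal")]
    if cfg.kind == "straight":
        directions.append((True, "distal"))
    rng_prop = _rng(cfg.seed, _STREAM_PROPAGATION, 999_999)
    for reverse, label in directions:
        if cfg.propagation_rate_hz <= 0:
            continue
        n_src = rng_prop.poisson(cfg.propagation_rate_hz * cfg.duration_s)
        src = np.sort(rng_prop.uniform(0.0, cfg.duration_s, size=n_src))
        prop = inject_propagating_events(
            layout, spec, src, cfg.duration_s,
            velocity_um_per_ms=velocity,
            jitter_ms=cfg.latency_jitter_ms,
            dropout_prob=cfg.detection_dropout_prob,
            seed=cfg.seed, reverse=reverse,
            amplitude_uv=cfg.spike_amplitude_uv,
        )
        labels += [label] * len(prop)
        parts.append(prop)

    spikes = merge_spike_tables(*parts)
    # labels must follow the canonical sort applied inside merge; rebuild by sorting
    eid = np.concatenate([p.electrode_id for p in parts])
    t = np.concatenate([p.time_s for p in parts])
    a = np.concatenate([p.amplitude_uv for p in parts])
    order = np.lexsort((-a, t, eid))
    labels = tuple(np.array(labels, dtype=object)[order].tolist())

    gt = GroundTruth(
        electrode_id=spikes.electrode_id,
        time_s=spikes.time_s,
        label=labels,
        velocity_mm_per_ms=velocity * 1e-3,
        config=cfg,
    )
    recording = None
    if cfg.render_raw:
        recording = render_raw_recording(
            spikes, layout, cfg.sampling_rate_hz,
            noise_sd_uv=cfg.noise_sd_uv, seed=cfg.seed,
        )
    return recording, spikes, spec, gt


# ---------------------------------------------------------------------------
# neurite outgrowth data
# ---------------------------------------------------------------------------


def simulate_neurite_dataset(
    n_tracks_per_condition: int,
    mean_step_um_per_hr: Mapping[str, float],
    step_sd_um: float = 1.0,
    hours: int = 16,
    channel_length_um: float = 900.0,
    seed: int = 0,
    profile_spacing_um: float = 5.0,
    intensity_scale_au: float = 50.0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate hourly neurite growth-cone tracks and intensity profiles.

    Each track advances by non-negative hourly axial steps (Gaussian with
    the condition's mean, truncated at zero) and is capped at the channel
    length. The per-condition intensity profile counts, at each axial
    position, the tracks whose final tip has passed that position, scaled
    to arbitrary fluorescence units — a stylised stand-in for cumulative
    fluorescence along the channel.

    Returns ``(track_table, profiles)`` where the track table has columns
    ``track_id, condition, hour, axial_position_um`` and each profile has
    columns ``channel_id, axial_um, intensity_red, intensity_green``.
    """
    if step_sd_um < 0:
        raise ValueError("step_sd_um must be >= 0")
    if hours < 1:
        raise ValueError("hours must be >= 1")
    rows = []
    profiles: dict[str, pd.DataFrame] = {}
    positions = np.arange(0.0, channel_length_um + profile_spacing_um / 2, profile_spacing_um)
    for ci, (condition, mean_step) in enumerate(sorted(mean_step_um_per_hr.items())):
        rng = _rng(seed, _STREAM_NEURITE, ci)
        steps = rng.normal(mean_step, step_sd_um, size=(n_tracks_per_condition, hours))
        steps = np.maximum(steps, 0.0)
        tips = np.minimum(np.cumsum(steps, axis=1), channel_length_um)
        for k in range(n_tracks_per_condition):
            track_id = f"{condition}_{k:03d}"
            rows.append((track_id, condition, 0, 0.0))
            for h in range(hours):
                rows.append((track_id, condition, h + 1, float(tips[k, h])))
        final = tips[:, -1]
        counts = (final[None, :] >= positions[:, None]).sum(axis=1).astype(float)
        intensity = counts * intensity_scale_au
        profiles[condition] = pd.DataFrame(
            {
                "channel_id": condition,
                "axial_um": positions,
                "intensity_red": intensity,
                "intensity_green": intensity,
            }
        )
    tracks = pd.DataFrame(
        rows, columns=["track_id", "condition", "hour", "axial_position_um"]
    )
    return tracks, profiles
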