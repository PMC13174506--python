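"""Shared data model and on-disk formats.

All quantities carry fixed units throughout the package: times in seconds
(double precision), positions in micrometres, voltages in microvolts.
Spike tables are kept in a canonical sort order — (electrode_id, time_s),
ties in time broken by descending amplitude — so that writes are
deterministic and diffable.

On-disk layouts:

* raw recordings — HDF5 with datasets ``/signals`` (n_electrodes x
  n_samples, float32 uV), ``/electrode_ids``, ``/positions_um`` and the
  attribute ``sampling_rate_hz``; simulated recordings may carry a
  ``/ground_truth`` group,
* spike tables — CSV with header ``electrode_id,time_s,amplitude_uv``
  preceded by ``# format_version=…`` and ``# duration_s=…`` comment lines,
* channel specs and analysis configuration — YAML.

Every file embeds a format version string; loaders reject unknown
versions rather than guess.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

FORMAT_VERSION = "1.0"

RECORDING_FILENAME = "recording.h5"
SPIKES_FILENAME = "spikes.csv"
CHANNELS_FILENAME = "channels.yaml"
LAYOUT_FILENAME = "layout.csv"

CHANNEL_KINDS = ("straight", "directional")


class FormatVersionError(ValueError):
    """Raised when a file declares an unsupported format version."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeLayout:
    """Planar positions of the recording electrodes used for one channel.

    The full array exposes tens of thousands of sites; an analysis works on
    the small subset routed into a microchannel, which is what a layout
    describes.

    Parameters
    ----------
    electrode_ids
        Unique integer labels, one per electrode.
    positions_um
        ``(n, 2)`` planar positions in micrometres.
    pitch_um
        Nominal inter-electrode spacing in micrometres (metadata).
    """

    electrode_ids: np.ndarray
    positions_um: np.ndarray
    pitch_um: float

    def __post_init__(self):
        ids = np.asarray(self.electrode_ids, dtype=np.int64)
        pos = np.asarray(self.positions_um, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions_um must have shape (n, 2)")
        if len(ids) != len(pos):
            raise ValueError("electrode_ids and positions_um length mismatch")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("electrode ids must be unique")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")
        if not (self.pitch_um > 0):
            raise ValueError("pitch_um must be > 0")
        object.__setattr__(self, "electrode_ids", ids)
        object.__setattr__(self, "positions_um", pos)

    def __len__(self) -> int:
        return len(self.electrode_ids)

    def index_of(self, electrode_id: int) -> int:
        hits = np.flatnonzero(self.electrode_ids == electrode_id)
        if len(hits) == 0:
            raise KeyError(f"electrode {electrode_id} not in layout")
        return int(hits[0])

    def position_of(self, electrode_id: int) -> np.ndarray:
        return self.positions_um[self.index_of(electrode_id)]


@dataclass(frozen=True)
class RawRecording:
    """Per-electrode sampled voltage traces.

    ``signals`` is ``(n_electrodes, n_samples)`` in uV, row order matching
    ``layout.electrode_ids``.
    """

    layout: ElectrodeLayout
    signals: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self):
        sig = np.asarray(self.signals, dtype=np.float64)
        if sig.ndim != 2:
            raise ValueError("signals must be 2-D (n_electrodes, n_samples)")
        if sig.shape[0] != len(self.layout):
            raise ValueError("one trace per layout electrode required")
        if not (self.sampling_rate_hz > 0):
            raise ValueError("sampling_rate_hz must be > 0")
        object.__setattr__(self, "signals", sig)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def trace(self, electrode_id: int) -> np.ndarray:
        return self.signals[self.layout.index_of(electrode_id)]


@dataclass(frozen=True)
class SpikeTable:
    """Discrete spike events — the pipeline's central exchange format.

    Stored column-wise, canonically sorted by (electrode_id, time_s) with
    ties in time broken by descending amplitude.
    """

    electrode_id: np.ndarray
    time_s: np.ndarray
    amplitude_uv: np.ndarray
    duration_s: float

    def __post_init__(self):
        eid = np.asarray(self.electrode_id, dtype=np.int64)
        t = np.asarray(self.time_s, dtype=np.float64)
        a = np.asarray(self.amplitude_uv, dtype=np.float64)
        if not (len(eid) == len(t) == len(a)):
            raise ValueError("column length mismatch")
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be > 0")
        if len(t) and (t.min() < 0 or t.max() > self.duration_s):
            raise ValueError("spike times must lie within [0, duration_s]")
        order = np.lexsort((-a, t, eid))
        eid, t, a = eid[order], t[order], a[order]
        same = eid[1:] == eid[:-1]
        if np.any(same & (np.diff(t) <= 0)):
            raise ValueError("per-electrode spike times must be strictly increasing")
        object.__setattr__(self, "electrode_id", eid)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "amplitude_uv", a)

    def __len__(self) -> int:
        return len(self.time_s)

    @classmethod
    def empty(cls, duration_s: float) -> "SpikeTable":
        z = np.empty(0)
        return cls(z, z, z, duration_s)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, float, float]], duration_s: float
    ) -> "SpikeTable":
        rec = list(records)
        if not rec:
            return cls.empty(duration_s)
        eid, t, a = map(np.asarray, zip(*rec))
        return cls(eid, t, a, duration_s)

    def times_for(self, electrode_id: int) -> np.ndarray:
        """Sorted spike times of one electrode."""
        return self.time_s[self.electrode_id == electrode_id]

    def counts_by_electrode(self, electrode_ids: Sequence[int]) -> np.ndarray:
        ids = np.asarray(electrode_ids)
        return np.array([(self.electrode_id == e).sum() for e in ids], dtype=np.int64)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "electrode_id": self.electrode_id,
                "time_s": self.time_s,
                "amplitude_uv": self.amplitude_uv,
            }
        )


@dataclass(frozen=True)
class MicrochannelSpec:
    """Geometry of one microchannel.

    ``entry_xy_um`` is the proximal-organoid end; for directional channels
    entry -> exit is the permissive growth direction.
    """

    channel_id: str
    kind: str
    entry_xy_um: tuple[float, float]
    exit_xy_um: tuple[float, float]
    length_um: float
    member_electrode_ids: tuple[int, ...]

    def __post_init__(self):
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"kind must be one of {CHANNEL_KINDS}, got {self.kind!r}")
        entry = (float(self.entry_xy_um[0]), float(self.entry_xy_um[1]))
        exit_ = (float(self.exit_xy_um[0]), float(self.exit_xy_um[1]))
        dist = float(np.hypot(exit_[0] - entry[0], exit_[1] - entry[1]))
        if abs(dist - self.length_um) > 1e-6:
            raise ValueError(
                f"length_um={self.length_um} inconsistent with endpoint distance {dist}"
            )
        members = tuple(int(e) for e in self.member_electrode_ids)
        if len(members) < 2:
            raise ValueError("a channel needs at least 2 member electrodes")
        object.__setattr__(self, "entry_xy_um", entry)
        object.__setattr__(self, "exit_xy_um", exit_)
        object.__setattr__(self, "member_electrode_ids", members)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters with the study's operating defaults.

    Detection thresholds at 3.5x the trace RMS with sub-millisecond
    duplicate removal; propagation pairing uses a closed 1-2 ms latency
    window with a 30-event qualification floor; intermediary electrodes are
    searched in a 17.5 um orthogonal band (one electrode pitch) and must
    co-occur in strictly more than 80% of paired windows.
    """

    rms_threshold_multiple: float = 3.5
    isi_min_s: float = 0.001
    latency_window_s: tuple[float, float] = (0.001, 0.002)
    min_paired_events: int = 30
    band_half_width_um: float = 17.5
    intermediary_anchors: tuple[float, ...] = (0.25, 0.50, 0.75)
    cooccurrence_min_fraction: float = 0.80
    n_quartiles: int = 4
    profile_bin_fraction: float = 0.05
    alpha: float = 0.05
    robust_rms: bool = False
    random_seed: int = 0


def validate_config(cfg: AnalysisConfig | dict | None = None) -> AnalysisConfig:
    """Fill defaults and enforce invariants; returns a fully explicit config.

    Raises ``ValueError`` naming the offending field for out-of-range values.
    """
    if cfg is None:
        cfg = AnalysisConfig()
    elif isinstance(cfg, dict):
        known = {f.name for f in dataclasses.fields(AnalysisConfig)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(cfg)
        if "latency_window_s" in d:
            d["latency_window_s"] = tuple(float(v) for v in d["latency_window_s"])
        if "intermediary_anchors" in d:
            d["intermediary_anchors"] = tuple(
                float(v) for v in d["intermediary_anchors"]
            )
        cfg = AnalysisConfig(**d)

    def _positive(name: str, value: float) -> None:
        if not (value > 0):
            raise ValueError(f"{name} must be > 0, got {value}")

    _positive("rms_threshold_multiple", cfg.rms_threshold_multiple)
    _positive("isi_min_s", cfg.isi_min_s)
    if cfg.band_half_width_um < 0:
        raise ValueError(f"band_half_width_um must be >= 0, got {cfg.band_half_width_um}")
    lo, hi = cfg.latency_window_s
    if not (0 < lo < hi):
        raise ValueError(
            f"latency_window_s lower bound must be positive and < upper, got {cfg.latency_window_s}"
        )
    if cfg.min_paired_events < 1:
        raise ValueError(f"min_paired_events must be >= 1, got {cfg.min_paired_events}")
    if not (0 < cfg.cooccurrence_min_fraction < 1):
        raise ValueError(
            f"cooccurrence_min_fraction must be in (0, 1), got {cfg.cooccurrence_min_fraction}"
        )
    for a in cfg.intermediary_anchors:
        if not (0 < a < 1):
            raise ValueError(f"intermediary_anchors must be in (0, 1), got {a}")
    if cfg.n_quartiles != 4:
        raise ValueError(f"n_quartiles is fixed at 4, got {cfg.n_quartiles}")
    n_bins = 1.0 / cfg.profile_bin_fraction
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"profile_bin_fraction must evenly divide 1, got {cfg.profile_bin_fraction}"
        )
    if not (0 <= cfg.alpha <= 1):
        raise ValueError(f"alpha must be in [0, 1], got {cfg.alpha}")
    return cfg


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------


def save_recording(recording: RawRecording, path: str | Path, ground_truth=None) -> None:
    """Write a recording container (HDF5); signals stored as float32."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["sampling_rate_hz"] = float(recording.sampling_rate_hz)
        f.attrs["pitch_um"] = float(recording.layout.pitch_um)
        f.create_dataset("signals", data=recording.signals.astype(np.float32))
        f.create_dataset("electrode_ids", data=recording.layout.electrode_ids)
        f.create_dataset("positions_um", data=recording.layout.positions_um)
        if ground_truth is not None:
            ground_truth.to_hdf5_group(f.create_group("ground_truth"))


def load_recording(path: str | Path):
    """Read a recording container; returns ``(RawRecording, ground_truth_or_None)``.

    The ground-truth payload (if present) is returned as a plain dict; the
    synthetic module re-hydrates it into its own type.
    """
    with h5py.File(path, "r") as f:
        _check_version(str(f.attrs.get("format_version", "")), path)
        layout = ElectrodeLayout(
            electrode_ids=f["electrode_ids"][:],
            positions_um=f["positions_um"][:],
            pitch_um=float(f.attrs["pitch_um"]),
        )
        rec = RawRecording(
            layout=layout,
            signals=f["signals"][:].astype(np.float64),
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
        )
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = {
                "electrode_id": g["electrode_id"][:],
                "time_s": g["time_s"][:],
                "label": [s.decode() for s in g["label"][:]],
                "velocity_mm_per_ms": float(g.attrs["velocity_mm_per_ms"]),
                "config_json": str(g.attrs["config_json"]),
            }
    return rec, gt


def save_spike_table(spikes: SpikeTable, path: str | Path) -> None:
    with open(path, "w") as f:
        f.write(f"# format_version={FORMAT_VERSION}\n")
        f.write(f"# duration_s={float(spikes.duration_s)!r}\n")
        f.write("electrode_id,time_s,amplitude_uv\n")
        for e, t, a in zip(spikes.electrode_id, spikes.time_s, spikes.amplitude_uv):
            # repr of a Python float round-trips exactly
            f.write(f"{int(e)},{float(t)!r},{float(a)!r}\n")


def load_spike_table(path: str | Path) -> SpikeTable:
    meta: dict[str, str] = {}
    with open(path) as f:
        pos = f.tell()
        while True:
            line = f.readline()
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = f.tell()
        f.seek(pos)
        # exact float round-trip: pandas' default parser can be off by 1 ulp
        df = pd.read_csv(f, float_precision="round_trip")
    _check_version(meta.get("format_version", ""), path)
    if "duration_s" not in meta:
        raise ValueError(f"{path}: missing '# duration_s=' header")
    expected = {"electrode_id", "time_s", "amplitude_uv"}
    if set(df.columns) != expected:
        raise ValueError(f"{path}: columns {sorted(df.columns)} != {sorted(expected)}")
    return SpikeTable(
        electrode_id=df["electrode_id"].to_numpy(),
        time_s=df["time_s"].to_numpy(),
        amplitude_uv=df["amplitude_uv"].to_numpy(),
        duration_s=float(meta["duration_s"]),
    )


def save_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    with open(path, "w") as f:
        f.write(f"# format_version={FORMAT_VERSION}\n")
        f.write(f"# pitch_um={float(layout.pitch_um)!r}\n")
        f.write("electrode_id,x_um,y_um\n")
        for e, (x, y) in zip(layout.electrode_ids, layout.positions_um):
            f.write(f"{int(e)},{float(x)!r},{float(y)!r}\n")


def load_layout(path: str | Path) -> ElectrodeLayout:
    meta: dict[str, str] = {}
    with open(path) as f:
        pos = f.tell()
        while True:
            line = f.readline()
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = f.tell()
        f.seek(pos)
        df = pd.read_csv(f, float_precision="round_trip")
    _check_version(meta.get("format_version", ""), path)
    if "pitch_um" not in meta:
        raise ValueError(f"{path}: missing '# pitch_um=' header")
    return ElectrodeLayout(
        electrode_ids=df["electrode_id"].to_numpy(),
        positions_um=df[["x_um", "y_um"]].to_numpy(),
        pitch_um=float(meta["pitch_um"]),
    )


def save_channel_specs(channels: Sequence[MicrochannelSpec], path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "channels": [
            {
                "channel_id": c.channel_id,
                "kind": c.kind,
                "entry_xy_um": list(c.entry_xy_um),
                "exit_xy_um": list(c.exit_xy_um),
                "length_um": c.length_um,
                "member_electrode_ids": list(c.member_electrode_ids),
            }
            for c in channels
        ],
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_channel_specs(path: str | Path) -> list[MicrochannelSpec]:
    with open(path) as f:
        doc = yaml.safe_load(f)
    _check_version(str(doc.get("format_version", "")), path)
    out = []
    for c in doc["channels"]:
        out.append(
            MicrochannelSpec(
                channel_id=str(c["channel_id"]),
                kind=c["kind"],
                entry_xy_um=tuple(c["entry_xy_um"]),
                exit_xy_um=tuple(c["exit_xy_um"]),
                length_um=float(c["length_um"]),
                member_electrode_ids=tuple(c["member_electrode_ids"]),
            )
        )
    return out


def save_analysis_config(cfg: AnalysisConfig, path: str | Path) -> None:
    doc = {"format_version": FORMAT_VERSION}
    doc.update(dataclasses.asdict(validate_config(cfg)))
    doc["latency_window_s"] = list(cfg.latency_window_s)
    doc["intermediary_anchors"] = list(cfg.intermediary_anchors)
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    with open(path) as f:
        doc = yaml.safe_load(f)
    _check_version(str(doc.pop("format_version", "")), path)
    return validate_config(doc)


def save_bundle(
    out_dir: str | Path,
    *,
    recording: RawRecording | None = None,
    spikes: SpikeTable | None = None,
    channels: Sequence[MicrochannelSpec] = (),
    ground_truth=None,
    layout: ElectrodeLayout | None = None,
) -> dict[str, Path]:
    """Write a dataset bundle (recording and/or spikes, plus channel specs).

    Returns the mapping of artifact name -> written path.
    """
    if recording is None and spikes is None:
        raise ValueError("at least one of recording/spikes must be given")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if recording is not None:
        p = out_dir / RECORDING_FILENAME
        save_recording(recording, p, ground_truth=ground_truth)
        written["recording"] = p
    if spikes is not None:
        p = out_dir / SPIKES_FILENAME
        save_spike_table(spikes, p)
        written["spikes"] = p
    if layout is not None:
        p = out_dir / LAYOUT_FILENAME
        save_layout(layout, p)
        written["layout"] = p
    p = out_dir / CHANNELS_FILENAME
    save_channel_specs(list(channels), p)
    written["channels"] = p
    return written


def load_bundle(bundle_dir: str | Path):
    """Load a bundle directory; returns ``(recording?, spikes?, channels, ground_truth?)``."""
    bundle_dir = Path(bundle_dir)
    recording = gt = spikes = None
    rec_path = bundle_dir / RECORDING_FILENAME
    if rec_path.exists():
        recording, gt = load_recording(rec_path)
    spk_path = bundle_dir / SPIKES_FILENAME
    if spk_path.exists():
        spikes = load_spike_table(spk_path)
    chan_path = bundle_dir / CHANNELS_FILENAME
    channels = load_channel_specs(chan_path) if chan_path.exists() else []
    if recording is None and spikes is None:
        raise FileNotFoundError(f"no recording or spike table found in {bundle_dir}")
    return recording, spikes, channels, gt


def load_bundle_layout(bundle_dir: str | Path) -> ElectrodeLayout | None:
    """Electrode layout of a bundle: the recording's if raw traces exist,
    otherwise the standalone layout file, otherwise ``None``."""
    bundle_dir = Path(bundle_dir)
    rec_path = bundle_dir / RECORDING_FILENAME
    if rec_path.exists():
        recording, _ = load_recording(rec_path)
        return recording.layout
    layout_path = bundle_dir / LAYOUT_FILENAME
    if layout_path.exists():
        return load_layout(layout_path)
    return None


def config_to_json(cfg) -> str:
    return json.dumps(dataclasses.asdict(cfg), default=list, sort_keys=True)


def _check_version(version: str, path) -> None:
    if version != FORMAT_VERSION:
        raise FormatVersionError(
            f"{path}: format version {version!r} not supported (expected {FORMAT_VERSION})"
        )
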