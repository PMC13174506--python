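"""Neurite outgrowth quantification from traced tracks and intensity profiles.

Per-track velocity is the net axial displacement over the elapsed imaging
time (robust to missed frames). The cohort-level growth law comes from an
ordinary least-squares fit of the per-hour median position. Channel
traversal is read off an axial fluorescence-intensity profile: the extent
is the farthest position whose intensity exceeds a background threshold
(background mean + 3 SD, background taken from the distal window of a
reference profile), expressed as a percent of channel length; a channel
counts as fully crossed at >= 95% by default because profiles pixelate at
the exit. Group comparisons use Welch's t for pairs and Dunnett's
many-to-one adjustment against a control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

NEURITE_CONDITIONS = ("permissive", "prohibitive", "control_straight")


@dataclass(frozen=True)
class NeuriteTrack:
    """One manually traced growth-cone trajectory (hourly tip positions)."""

    track_id: str
    condition: str
    hours: np.ndarray
    positions_um: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.hours, dtype=np.int64)
        p = np.asarray(self.positions_um, dtype=np.float64)
        if len(h) != len(p):
            raise ValueError("hours and positions must align")
        if np.any(np.diff(h) <= 0):
            raise ValueError("hours must be strictly increasing")
        if len(p) and p.min() < 0:
            raise ValueError("positions must be >= 0")
        object.__setattr__(self, "hours", h)
        object.__setattr__(self, "positions_um", p)


@dataclass(frozen=True)
class IntensityProfile:
    """Axial fluorescence-intensity profile of one channel."""

    channel_id: str
    axial_um: np.ndarray
    intensity: np.ndarray
    channel_length_um: float

    def __post_init__(self):
        x = np.asarray(self.axial_um, dtype=np.float64)
        y = np.asarray(self.intensity, dtype=np.float64)
        if len(x) != len(y):
            raise ValueError("axial_um and intensity must align")
        if np.any(np.diff(x) <= 0):
            raise ValueError("axial positions must be strictly ascending")
        if len(y) and y.min() < 0:
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "axial_um", x)
        object.__setattr__(self, "intensity", y)


@dataclass(frozen=True)
class OutgrowthFit:
    """Linear growth law of the per-hour median position."""

    slope_um_per_hr: float
    intercept_um: float
    r_squared: float
    n_timepoints: int


def tracks_from_table(table: pd.DataFrame) -> list[NeuriteTrack]:
    """Build track objects from a long-format table
    (``track_id, condition, hour, axial_position_um``)."""
    out = []
    for (tid, cond), grp in table.groupby(["track_id", "condition"], sort=True):
        grp = grp.sort_values("hour")
        out.append(
            NeuriteTrack(
                track_id=str(tid),
                condition=str(cond),
                hours=grp["hour"].to_numpy(),
                positions_um=grp["axial_position_um"].to_numpy(),
            )
        )
    return out


def track_velocity(track: NeuriteTrack) -> float:
    """Net displacement over elapsed time, in um/hr."""
    if len(track.hours) < 2:
        raise ValueError("need >= 2 observations")
    dt = track.hours[-1] - track.hours[0]
    return float((track.positions_um[-1] - track.positions_um[0]) / dt)


def outgrowth_regression(tracks: Sequence[NeuriteTrack]) -> OutgrowthFit:
    """OLS of per-hour median position against hour."""
    by_hour: dict[int, list[float]] = {}
    for tr in tracks:
        for h, p in zip(tr.hours, tr.positions_um):
            by_hour.setdefault(int(h), []).append(float(p))
    hours = np.array(sorted(by_hour))
    if len(hours) < 2:
        raise ValueError("need >= 2 time points")
    medians = np.array([np.median(by_hour[h]) for h in hours])
    res = stats.linregress(hours, medians)
    return OutgrowthFit(
        slope_um_per_hr=float(res.slope),
        intercept_um=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_timepoints=len(hours),
    )


def traversal_extent(
    profile: IntensityProfile,
    background_window_fraction: float = 0.05,
    reference: IntensityProfile | None = None,
    sd_multiple: float = 3.0,
) -> float:
    """Percent of channel length with above-background fluorescence.

    The background window is the distal ``background_window_fraction`` of
    the reference profile (a prohibitive-side channel by convention; the
    profile itself when no reference is given — only valid when its distal
    end is signal-free). Threshold = background mean + ``sd_multiple`` x
    background SD; the extent is the farthest axial position with
    intensity strictly above threshold, as % of ``channel_length_um``,
    or 0 when nothing exceeds it.
    """
    ref = reference if reference is not None else profile
    cutoff = ref.channel_length_um * (1.0 - background_window_fraction)
    bg = ref.intensity[ref.axial_um >= cutoff]
    if len(bg) < 5:
        raise ValueError("background window contains fewer than 5 samples")
    threshold = float(np.mean(bg) + sd_multiple * np.std(bg))
    above = profile.axial_um[profile.intensity > threshold]
    if len(above) == 0:
        return 0.0
    return 100.0 * float(above.max()) / profile.channel_length_um


def success_rate(extents_pct: Sequence[float], full_crossing_threshold_pct: float = 95.0) -> float:
    """Percent of channels whose traversal extent reaches the full-crossing bar."""
    extents = np.asarray(extents_pct, dtype=np.float64)
    if len(extents) == 0:
        raise ValueError("no extents given")
    return 100.0 * float(np.mean(extents >= full_crossing_threshold_pct))


@dataclass(frozen=True)
class GroupComparison:
    """Pairwise Welch t tests and Dunnett many-to-one adjusted p-values."""

    pairwise_t: dict[tuple[str, str], tuple[float, float]]
    dunnett_p: dict[str, float]
    control_label: str | None


def group_comparison(
    groups: Mapping[str, Sequence[float]],
    control_label: str | None = None,
) -> GroupComparison:
    """Compare outcome distributions (velocities or extents) across groups.

    Every group pair gets a two-sided Welch t statistic and p-value; if a
    control label is given, the remaining groups additionally get
    Dunnett-adjusted p-values against the control.
    """
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has < 2 observations")
    labels = sorted(arrays)
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            res = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
            pairwise[(a, b)] = (float(res.statistic), float(res.pvalue))
    dunnett_p: dict[str, float] = {}
    if control_label is not None:
        if control_label not in arrays:
            raise ValueError(f"control group {control_label!r} missing")
        others = [k for k in labels if k != control_label]
        if others:
            res = stats.dunnett(*[arrays[k] for k in others], control=arrays[control_label])
            dunnett_p = {k: float(p) for k, p in zip(others, res.pvalue)}
    return GroupComparison(
        pairwise_t=pairwise, dunnett_p=dunnett_p, control_label=control_label
    )
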