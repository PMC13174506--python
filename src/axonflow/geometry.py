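"""Channel principal-axis geometry: axial projection, band filter, binning.

The principal axis is the straight line from the source (entry) to the
target (exit) electrode. Each electrode decomposes into a signed axial
projection onto that axis and an unsigned orthogonal offset from it; the
axial fraction (projection / axis length) is the coordinate everything
downstream bins on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ElectrodeLayout, MicrochannelSpec


@dataclass(frozen=True)
class AxialMap:
    """Per-electrode coordinates relative to a channel's principal axis."""

    electrode_ids: np.ndarray
    axial_um: np.ndarray          # signed projection onto entry->exit axis
    axial_fraction: np.ndarray    # axial_um / axis length
    orthogonal_offset_um: np.ndarray
    axis_length_um: float

    def __len__(self) -> int:
        return len(self.electrode_ids)

    def _idx(self, electrode_id: int) -> int:
        hits = np.flatnonzero(self.electrode_ids == electrode_id)
        if len(hits) == 0:
            raise KeyError(f"electrode {electrode_id} not in axial map")
        return int(hits[0])

    def fraction_of(self, electrode_id: int) -> float:
        return float(self.axial_fraction[self._idx(electrode_id)])

    def axial_of(self, electrode_id: int) -> float:
        return float(self.axial_um[self._idx(electrode_id)])

    def offset_of(self, electrode_id: int) -> float:
        return float(self.orthogonal_offset_um[self._idx(electrode_id)])

    def interior_ids(self) -> np.ndarray:
        """Electrodes strictly between the endpoints (0 < fraction < 1)."""
        mask = (self.axial_fraction > 0.0) & (self.axial_fraction < 1.0)
        return self.electrode_ids[mask]


def axial_map(
    layout: ElectrodeLayout,
    spec: MicrochannelSpec | None = None,
    source_xy_um=None,
    target_xy_um=None,
    electrode_ids=None,
) -> AxialMap:
    """Orthogonal decomposition of electrode positions onto the principal axis.

    The axis runs source -> target; pass either a channel spec (entry/exit
    endpoints) or explicit positions. Electrodes beyond the endpoints get
    fractions outside [0, 1] (kept, so callers can flag them).
    """
    if spec is not None:
        source_xy_um = spec.entry_xy_um
        target_xy_um = spec.exit_xy_um
        if electrode_ids is None:
            electrode_ids = spec.member_electrode_ids
    src = np.asarray(source_xy_um, dtype=np.float64)
    tgt = np.asarray(target_xy_um, dtype=np.float64)
    axis = tgt - src
    length = float(np.linalg.norm(axis))
    if length <= 0:
        raise ValueError("source and target positions coincide")
    unit = axis / length
    if electrode_ids is None:
        electrode_ids = layout.electrode_ids
    ids = np.asarray(electrode_ids, dtype=np.int64)
    pos = np.vstack([layout.position_of(int(e)) for e in ids])
    rel = pos - src
    axial = rel @ unit
    ortho = np.abs(rel[:, 0] * (-unit[1]) + rel[:, 1] * unit[0])
    return AxialMap(
        electrode_ids=ids,
        axial_um=axial,
        axial_fraction=axial / length,
        orthogonal_offset_um=ortho,
        axis_length_um=length,
    )


def band_filter(amap: AxialMap, half_width_um: float) -> np.ndarray:
    """Interior electrodes within the orthogonal search band.

    Inclusive at exactly ``half_width_um`` (so the adjacent-electrode row at
    one pitch is captured); endpoints (fraction 0 or 1) are always excluded.
    """
    if half_width_um < 0:
        raise ValueError("half_width_um must be >= 0")
    mask = (
        (amap.orthogonal_offset_um <= half_width_um)
        & (amap.axial_fraction > 0.0)
        & (amap.axial_fraction < 1.0)
    )
    return amap.electrode_ids[mask]


def bin_index(axial_fraction: float, n_bins: int) -> int:
    """Half-open bins [i/n, (i+1)/n) over [0, 1]; fraction 1.0 falls in the last."""
    if not (0.0 <= axial_fraction <= 1.0):
        raise ValueError(f"axial_fraction must be in [0, 1], got {axial_fraction}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    return min(int(axial_fraction * n_bins), n_bins - 1)
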