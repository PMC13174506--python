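"""Quartile firing rates, flux ratios, binned profiles and asymmetry tests.

The flux ratio of a channel is the mean firing rate over electrodes in the
exit quartile (Q4) of the principal axis divided by that of the entry
quartile (Q1). A symmetric channel has flux ratio ~1; a channel whose exit
carries axons from both organoids shows ratios well above 1. Per-channel
asymmetry is tested by a two-sided Mann-Whitney U on the per-electrode
rates of Q1 vs Q4 at alpha = 0.05, with no multiple-testing correction
across channels by default (a Benjamini-Hochberg option is available for
condition summaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import SpikeTable
from .geometry import AxialMap, bin_index

UNDEFINED_RATE_FLOOR_HZ = 1e-6


@dataclass(frozen=True)
class QuartileRates:
    """Per-quartile mean electrode firing rates for one channel."""

    quartile_mean_hz: np.ndarray          # length 4
    electrode_rates_hz: dict[int, list[tuple[int, float]]]  # quartile -> [(eid, Hz)]

    def rates_in(self, quartile: int) -> np.ndarray:
        return np.array([r for _, r in self.electrode_rates_hz[quartile]])


@dataclass(frozen=True)
class FluxReport:
    """Flux ratio and Q1-vs-Q4 asymmetry test for one channel."""

    channel_id: str
    kind: str
    quartile_mean_hz: np.ndarray
    flux_ratio: float           # NaN when undefined (silent entry quartile)
    flux_defined: bool
    q1_rates_hz: np.ndarray
    q4_rates_hz: np.ndarray
    u_statistic: float
    p_value: float
    significant: bool
    alpha: float


@dataclass(frozen=True)
class ProfileReport:
    """Firing-rate profile in axial-fraction bins, normalised to Q1."""

    bin_fraction: float
    bin_lower_edges: np.ndarray
    normalized_rate: np.ndarray   # NaN for bins with no electrodes
    q1_mean_hz: float


def quartile_rates(
    spikes: SpikeTable, amap: AxialMap, duration_s: float | None = None
) -> QuartileRates:
    """Mean firing rate per quartile of axial fraction.

    The per-electrode rate is count / duration and the quartile value is
    the unweighted mean over its electrodes; a quartile containing no
    electrodes is an error.
    """
    duration_s = spikes.duration_s if duration_s is None else duration_s
    per_quartile: dict[int, list[tuple[int, float]]] = {q: [] for q in range(4)}
    for eid, frac in zip(amap.electrode_ids, amap.axial_fraction):
        if not (0.0 <= frac <= 1.0):
            continue  # beyond the endpoints; not part of the channel span
        q = bin_index(float(frac), 4)
        rate = len(spikes.times_for(int(eid))) / duration_s
        per_quartile[q].append((int(eid), rate))
    means = np.empty(4)
    for q in range(4):
        if not per_quartile[q]:
            raise ValueError(f"quartile {q + 1} has no electrodes")
        means[q] = float(np.mean([r for _, r in per_quartile[q]]))
    return QuartileRates(quartile_mean_hz=means, electrode_rates_hz=per_quartile)


def flux_ratio(q1_rate_hz: float, q4_rate_hz: float) -> tuple[float, bool]:
    """Q4/Q1 rate ratio; flagged undefined for a silent entry quartile.

    Returns ``(ratio, defined)``; undefined ratios (Q1 below 1e-6 Hz)
    come back as NaN and are excluded from cross-channel statistics.
    """
    if q1_rate_hz < 0 or q4_rate_hz < 0:
        raise ValueError("rates must be >= 0")
    if q1_rate_hz < UNDEFINED_RATE_FLOOR_HZ:
        return float("nan"), False
    return q4_rate_hz / q1_rate_hz, True


def binned_profile(
    spikes: SpikeTable,
    amap: AxialMap,
    duration_s: float | None = None,
    bin_fraction: float = 0.05,
) -> ProfileReport:
    """Mean electrode rate per axial bin, normalised by the Q1 mean rate.

    Bins of width ``bin_fraction`` tile [0, 1]; empty bins are NaN, not
    zero. The denominator is the mean rate over electrodes with axial
    fraction in [0, 0.25).
    """
    n_bins_f = 1.0 / bin_fraction
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError(f"bin_fraction must evenly divide 1, got {bin_fraction}")
    n_bins = int(round(n_bins_f))
    duration_s = spikes.duration_s if duration_s is None else duration_s
    rates: dict[int, list[float]] = {b: [] for b in range(n_bins)}
    q1_rates: list[float] = []
    for eid, frac in zip(amap.electrode_ids, amap.axial_fraction):
        if not (0.0 <= frac <= 1.0):
            continue
        rate = len(spikes.times_for(int(eid))) / duration_s
        rates[bin_index(float(frac), n_bins)].append(rate)
        if frac < 0.25:
            q1_rates.append(rate)
    if not q1_rates:
        raise ValueError("no electrodes in the first quartile; profile undefined")
    q1_mean = float(np.mean(q1_rates))
    if q1_mean < UNDEFINED_RATE_FLOOR_HZ:
        raise ValueError("silent first quartile; normalised profile undefined")
    values = np.array(
        [np.mean(rates[b]) / q1_mean if rates[b] else np.nan for b in range(n_bins)]
    )
    return ProfileReport(
        bin_fraction=bin_fraction,
        bin_lower_edges=np.arange(n_bins) / n_bins,
        normalized_rate=values,
        q1_mean_hz=q1_mean,
    )


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration for small tie-free samples (both n <= 12),
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def channel_asymmetry(
    channel_id: str,
    kind: str,
    qr: QuartileRates,
    alpha: float = 0.05,
) -> FluxReport:
    """Flux ratio plus Q1-vs-Q4 rate asymmetry test for one channel."""
    q1 = qr.rates_in(0)
    q4 = qr.rates_in(3)
    ratio, defined = flux_ratio(float(qr.quartile_mean_hz[0]), float(qr.quartile_mean_hz[3]))
    u, p = mann_whitney_u(q1, q4)
    return FluxReport(
        channel_id=channel_id,
        kind=kind,
        quartile_mean_hz=qr.quartile_mean_hz,
        flux_ratio=ratio,
        flux_defined=defined,
        q1_rates_hz=q1,
        q4_rates_hz=q4,
        u_statistic=u,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


@dataclass(frozen=True)
class ConditionSummary:
    """Cross-channel summary of flux ratios per condition."""

    flux_ratios: dict[str, np.ndarray]
    n_channels: dict[str, int]
    n_undefined: dict[str, int]
    percent_significant: dict[str, float]
    cross_condition_p: dict[tuple[str, str], float]
    bh_adjusted: bool = False


def condition_summary(
    reports_by_condition: dict[str, list[FluxReport]],
    benjamini_hochberg: bool = False,
) -> ConditionSummary:
    """Aggregate per-channel flux reports across conditions.

    Undefined ratios are excluded from the ratio distributions (their
    count is reported); percent significant counts all channels. With
    ``benjamini_hochberg`` the per-channel p-values are FDR-adjusted
    within each condition before counting significance.
    """
    ratios: dict[str, np.ndarray] = {}
    n_channels: dict[str, int] = {}
    n_undef: dict[str, int] = {}
    pct_sig: dict[str, float] = {}
    for cond, reports in reports_by_condition.items():
        if not reports:
            raise ValueError(f"condition {cond!r} has no channels")
        vals = np.array([r.flux_ratio for r in reports if r.flux_defined])
        n_channels[cond] = len(reports)
        n_undef[cond] = len(reports) - len(vals)
        ratios[cond] = vals
        if benjamini_hochberg:
            p = np.array([r.p_value for r in reports])
            adj = stats.false_discovery_control(p, method="bh")
            sig = adj < reports[0].alpha
        else:
            sig = np.array([r.significant for r in reports])
        pct_sig[cond] = 100.0 * float(np.mean(sig))
    if all(len(v) == 0 for v in ratios.values()):
        raise ValueError("all flux ratios undefined; nothing to summarise")
    cross: dict[tuple[str, str], float] = {}
    conds = sorted(reports_by_condition)
    for i, c1 in enumerate(conds):
        for c2 in conds[i + 1 :]:
            if len(ratios[c1]) and len(ratios[c2]):
                _, p = mann_whitney_u(ratios[c1], ratios[c2])
                cross[(c1, c2)] = p
    return ConditionSummary(
        flux_ratios=ratios,
        n_channels=n_channels,
        n_undefined=n_undef,
        percent_significant=pct_sig,
        cross_condition_p=cross,
        bh_adjusted=benjamini_hochberg,
    )
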