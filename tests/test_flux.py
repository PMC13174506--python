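"""Quartile rates, flux ratios, binned profiles, asymmetry statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

import axonflow as af
from axonflow.flux import QuartileRates, channel_asymmetry, condition_summary


def mwu_exact_oracle(a, b):
    """Full enumeration of rank assignments; two-sided p."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    obs = u_of(range(n1))
    us = np.array(
        [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    )
    p = 2 * min((us <= obs).mean(), (us >= obs).mean())
    return obs, min(p, 1.0)


def _uniform_channel(rate_hz=2.0, duration=600.0, seed=0, kind="straight"):
    layout, spec = af.build_channel_layout(910.0, 17.5, kind)
    spikes = af.simulate_poisson_trains(layout, rate_hz, duration, seed)
    amap = af.axial_map(layout, spec=spec)
    return spikes, amap, spec


class TestQuartileRates:
    def test_uniform_rates_everywhere(self):
        layout, spec = af.build_channel_layout(910.0, 17.5, "straight")
        # 2 Hz deterministic: one spike every 0.5 s per electrode
        records = [
            (int(e), 0.25 + k * 0.5, -50.0)
            for e in layout.electrode_ids
            for k in range(20)
        ]
        spikes = af.SpikeTable.from_records(records, duration_s=10.0)
        amap = af.axial_map(layout, spec=spec)
        qr = af.quartile_rates(spikes, amap)
        np.testing.assert_allclose(qr.quartile_mean_hz, 2.0)

    def test_silent_quartile_rate_zero(self):
        layout, spec = af.build_channel_layout(910.0, 17.5, "straight")
        records = [(0, 0.5, -50.0), (1, 0.5, -50.0)]
        spikes = af.SpikeTable.from_records(records, duration_s=10.0)
        amap = af.axial_map(layout, spec=spec)
        qr = af.quartile_rates(spikes, amap)
        assert qr.quartile_mean_hz[3] == 0.0

    def test_poisson_estimates_within_ci(self):
        cfg = af.SimulationConfig(
            kind="directional", duration_s=600, proximal_rate_hz=2.6,
            distal_rate_hz=5.1, propagation_rate_hz=0.0, render_raw=False, seed=2,
        )
        _, spikes, spec, _ = af.simulate_channel_dataset(cfg)
        layout, _ = af.build_channel_layout(910, 17.5, "directional")
        qr = af.quartile_rates(spikes, af.axial_map(layout, spec=spec))
        sem1 = np.sqrt(2.6 / 600 / 13)
        sem4 = np.sqrt(7.7 / 600 / 14)
        assert qr.quartile_mean_hz[0] == pytest.approx(2.6, abs=4 * sem1)
        assert qr.quartile_mean_hz[3] == pytest.approx(7.7, abs=4 * sem4)

    def test_empty_quartile_is_an_error(self):
        layout = af.ElectrodeLayout([0, 1], [[0, 0], [910, 0]], 17.5)
        spikes = af.SpikeTable.from_records([(0, 0.5, -50.0)], 10.0)
        amap = af.axial_map(layout, source_xy_um=(0, 0), target_xy_um=(910, 0),
                            electrode_ids=[0, 1])
        with pytest.raises(ValueError, match="quartile"):
            af.quartile_rates(spikes, amap)


class TestFluxRatio:
    @pytest.mark.parametrize(
        "q1,q4,expected",
        [(2.6, 7.7, 7.7 / 2.6), (2.1, 2.2, 2.2 / 2.1), (3.3, 3.3, 1.0)],
    )
    def test_ratio(self, q1, q4, expected):
        ratio, defined = af.flux_ratio(q1, q4)
        assert defined
        assert ratio == pytest.approx(expected)

    def test_representative_channel_is_threefold(self):
        ratio, _ = af.flux_ratio(2.6, 7.7)
        assert ratio == pytest.approx(2.96, abs=0.01)

    def test_silent_entry_is_undefined(self):
        ratio, defined = af.flux_ratio(0.0, 5.0)
        assert not defined and np.isnan(ratio)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            af.flux_ratio(-1.0, 2.0)

    def test_orientation_flip_inverts_ratio_exactly(self):
        # 927.5 um puts no electrode exactly on a quartile boundary, so
        # quartile membership is symmetric under the flip and the inversion
        # holds to machine precision
        layout, spec = af.build_channel_layout(927.5, 17.5, "straight")
        spikes = af.simulate_poisson_trains(layout, 2.0, 600.0, seed=5)
        amap = af.axial_map(layout, spec=spec)
        flipped = af.axial_map(
            layout, source_xy_um=spec.exit_xy_um, target_xy_um=spec.entry_xy_um,
            electrode_ids=spec.member_electrode_ids,
        )
        qr = af.quartile_rates(spikes, amap)
        qr_f = af.quartile_rates(spikes, flipped)
        r, _ = af.flux_ratio(qr.quartile_mean_hz[0], qr.quartile_mean_hz[3])
        r_f, _ = af.flux_ratio(qr_f.quartile_mean_hz[0], qr_f.quartile_mean_hz[3])
        assert r_f == pytest.approx(1.0 / r, rel=1e-12)


class TestBinnedProfile:
    def _spikes_with_rates(self, layout, rate_of_x, duration=100.0):
        records = []
        for e, x in zip(layout.electrode_ids, layout.positions_um[:, 0]):
            n = int(rate_of_x(x) * duration)
            for k in range(n):
                records.append((int(e), (k + 0.5) * duration / max(n, 1), -50.0))
        return af.SpikeTable.from_records(records, duration)

    def test_uniform_rates_normalise_to_one(self):
        layout, spec = af.build_channel_layout(910.0, 17.5, "straight")
        spikes = self._spikes_with_rates(layout, lambda x: 2.0)
        prof = af.binned_profile(spikes, af.axial_map(layout, spec=spec))
        assert len(prof.normalized_rate) == 20
        valid = ~np.isnan(prof.normalized_rate)
        np.testing.assert_allclose(prof.normalized_rate[valid], 1.0)

    def test_doubled_last_quartile(self):
        layout, spec = af.build_channel_layout(910.0, 17.5, "straight")
        spikes = self._spikes_with_rates(
            layout, lambda x: 4.0 if x / 910.0 >= 0.75 else 2.0
        )
        prof = af.binned_profile(spikes, af.axial_map(layout, spec=spec))
        last_bins = prof.normalized_rate[15:]
        np.testing.assert_allclose(last_bins[~np.isnan(last_bins)], 2.0)

    def test_q1_weighted_mean_is_unity(self):
        layout, spec = af.build_channel_layout(910.0, 17.5, "straight")
        spikes = self._spikes_with_rates(
            layout, lambda x: 1.0 + 2.0 * (x / 910.0)
        )
        amap = af.axial_map(layout, spec=spec)
        prof = af.binned_profile(spikes, amap)
        # electrode-count-weighted mean of first-quartile bins equals 1 by definition
        weights, values = [], []
        fracs = amap.axial_fraction
        for b in range(5):
            mask = (fracs >= b / 20) & (fracs < (b + 1) / 20) & (fracs < 0.25)
            if mask.sum() and not np.isnan(prof.normalized_rate[b]):
                weights.append(mask.sum())
                values.append(prof.normalized_rate[b])
        assert np.average(values, weights=weights) == pytest.approx(1.0)

    def test_bad_bin_fraction_rejected(self):
        spikes, amap, _ = _uniform_channel(duration=10.0)
        with pytest.raises(ValueError):
            af.binned_profile(spikes, amap, bin_fraction=0.07)


class TestMannWhitneyU:
    def test_identical_samples_no_separation(self):
        _, p = af.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p >= 0.99

    def test_fully_separated_small_samples(self):
        u, p = af.mann_whitney_u([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            n1, n2 = rng.integers(2, 9, size=2)
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            u, p = af.mann_whitney_u(a, b)
            u_o, p_o = mwu_exact_oracle(a, b)
            assert u == pytest.approx(u_o)
            assert p == pytest.approx(p_o)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            af.mann_whitney_u([], [1.0])


class TestChannelAsymmetry:
    def _null_report(self, seed, duration=60.0):
        spikes, amap, spec = _uniform_channel(duration=duration, seed=seed)
        qr = af.quartile_rates(spikes, amap)
        return channel_asymmetry(spec.channel_id, spec.kind, qr)

    def test_symmetric_channels_rarely_significant(self):
        sig = sum(self._null_report(seed).significant for seed in range(50))
        assert sig <= 5  # ~alpha x 50 with headroom

    def test_directional_effect_detected_with_power(self):
        hits = 0
        for seed in range(50):
            cfg = af.SimulationConfig(
                kind="directional", duration_s=600, proximal_rate_hz=2.6,
                distal_rate_hz=5.1, propagation_rate_hz=0.0,
                render_raw=False, seed=seed,
            )
            _, spikes, spec, _ = af.simulate_channel_dataset(cfg)
            layout, _ = af.build_channel_layout(910, 17.5, "directional")
            qr = af.quartile_rates(spikes, af.axial_map(layout, spec=spec))
            hits += channel_asymmetry(spec.channel_id, spec.kind, qr).significant
        assert hits >= 48  # >= 95% power at the threefold effect

    def test_alpha_zero_never_significant(self):
        rep = self._null_report(seed=1)
        rep0 = channel_asymmetry(
            rep.channel_id, rep.kind,
            QuartileRates(
                quartile_mean_hz=rep.quartile_mean_hz,
                electrode_rates_hz={
                    0: [(i, r) for i, r in enumerate(rep.q1_rates_hz)],
                    1: [(100, 1.0)], 2: [(200, 1.0)],
                    3: [(300 + i, r) for i, r in enumerate(rep.q4_rates_hz)],
                },
            ),
            alpha=0.0,
        )
        assert not rep0.significant


class TestConditionSummary:
    def _reports(self, n, kind, seeds, directional=False):
        out = []
        for seed in seeds:
            cfg = af.SimulationConfig(
                kind=kind, channel_length_um=910.0, duration_s=300,
                proximal_rate_hz=2.0,
                distal_rate_hz=4.0 if directional else 0.0,
                propagation_rate_hz=0.0, render_raw=False, seed=seed,
            )
            _, spikes, spec, _ = af.simulate_channel_dataset(cfg)
            layout, _ = af.build_channel_layout(910, 17.5, kind)
            qr = af.quartile_rates(spikes, af.axial_map(layout, spec=spec))
            out.append(channel_asymmetry(f"{kind}{seed}", kind, qr))
        return out

    def test_straight_condition_median_near_one(self):
        reports = self._reports(20, "straight", range(20))
        summary = condition_summary({"straight": reports})
        med = np.median(summary.flux_ratios["straight"])
        assert 0.8 <= med <= 1.25

    def test_percent_significant_arithmetic(self):
        reports = self._reports(13, "straight", range(13))
        # fabricate exactly 7 significant of 13
        import dataclasses as dc

        fixed = [
            dc.replace(r, significant=(i < 7)) for i, r in enumerate(reports)
        ]
        summary = condition_summary({"c": fixed})
        assert summary.percent_significant["c"] == pytest.approx(53.8, abs=0.1)

    def test_identical_conditions_not_distinguished(self):
        reports = self._reports(15, "straight", range(15))
        summary = condition_summary({"a": reports, "b": list(reports)})
        assert summary.cross_condition_p[("a", "b")] >= 0.9

    def test_directional_vs_straight_separated(self):
        s = self._reports(12, "straight", range(12))
        d = self._reports(12, "directional", range(100, 112), directional=True)
        summary = condition_summary({"straight": s, "directional": d})
        assert summary.cross_condition_p[("directional", "straight")] < 0.001
        assert summary.percent_significant["directional"] > 80.0
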