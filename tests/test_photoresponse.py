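"""Motion-mode fraction series, bootstrap aggregation, pulse statistics."""

import numpy as np
import pytest

from plateworm.photoresponse import (UNDEF, MotionFractionSeries, aggregate_bootstrap,
                                     baseline_shift, downsample_prevalent,
                                     mode_fractions_from_arrays, pulse_response_delta)
from plateworm.schedule import build_schedule
from plateworm.synthetic import BW, FW, ST, WormKinematics, simulate_modes


class TestModeFractions:
    def test_counts_and_fractions(self):
        # one well, three worms, modes (fw, fw, st) at t0
        modes = np.array([[FW], [FW], [ST]])
        s = mode_fractions_from_arrays(modes, ["A1"] * 3, np.array([0.0]))
        assert s.fractions[FW, 0, 0] == pytest.approx(2 / 3)
        assert s.fractions[ST, 0, 0] == pytest.approx(1 / 3)
        assert s.fractions[BW, 0, 0] == 0.0
        assert s.counts[0, 0] == 3

    def test_zero_tracked_worms_is_undefined_not_zero(self):
        modes = np.array([[FW, UNDEF]])
        s = mode_fractions_from_arrays(modes, ["A1"], np.array([0.0, 0.04]))
        assert s.counts[0, 1] == 0
        assert np.isnan(s.fractions[:, 0, 1]).all()

    def test_fractions_sum_to_one_where_defined(self):
        kin = WormKinematics()
        modes, _ = simulate_modes(kin, n_wells=4, n_frames=200, schedule=None, seed=0)
        wells = [f"W{i // 3}" for i in range(modes.shape[0])]
        s = mode_fractions_from_arrays(modes, wells, np.arange(200) / 25)
        total = np.nansum(s.fractions, axis=0)
        assert np.allclose(total[s.counts > 0], 1.0, atol=1e-9)

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MotionFractionSeries(times=np.array([0.0]), wells=["A1"],
                                 fractions=np.full((3, 1, 1), 0.5),
                                 counts=np.array([[2]]))

    def test_light_bias_raises_forward_fraction_during_pulses(self):
        """With light_bias > 1, mean forward fraction in pulses exceeds the
        pre-pulse mean (one-sided comparison by construction)."""
        kin = WormKinematics(light_bias=4.0)
        sched = build_schedule("custom", pulses=[(20.0, 10.0, 100.0)],
                               total_duration=40.0)
        n_frames = 1000
        modes, light = simulate_modes(kin, n_wells=24, n_frames=n_frames,
                                      schedule=sched, seed=1)
        wells = [f"W{i // 3}" for i in range(modes.shape[0])]
        times = np.arange(n_frames) / kin.frame_rate
        s = mode_fractions_from_arrays(modes, wells, times)
        mean_fw = np.nanmean(s.fractions[FW], axis=0)
        during = mean_fw[light].mean()
        before = mean_fw[times < 20.0].mean()
        assert during > before


class TestAggregateBootstrap:
    def test_identical_wells_zero_width_ci(self):
        modes = np.tile(np.array([[FW, ST, ST]]), (6, 1))
        s = mode_fractions_from_arrays(modes, [f"W{i}" for i in range(6)],
                                       np.arange(3) / 25)
        agg = aggregate_bootstrap(s, n_boot=100, seed=0)
        assert np.allclose(agg["ci_high"] - agg["ci_low"], 0.0)

    def test_ci_contains_point_mean(self):
        kin = WormKinematics()
        modes, _ = simulate_modes(kin, n_wells=8, n_frames=100, schedule=None, seed=2)
        wells = [f"W{i // 3}" for i in range(modes.shape[0])]
        s = mode_fractions_from_arrays(modes, wells, np.arange(100) / 25)
        agg = aggregate_bootstrap(s, n_boot=300, seed=1)
        ok = ~np.isnan(agg["mean"])
        assert np.all(agg["ci_low"][ok] <= agg["mean"][ok] + 1e-12)
        assert np.all(agg["ci_high"][ok] >= agg["mean"][ok] - 1e-12)

    def test_single_well_rejected(self):
        modes = np.array([[FW, FW]])
        s = mode_fractions_from_arrays(modes, ["A1"], np.arange(2) / 25)
        with pytest.raises(ValueError, match="2 wells"):
            aggregate_bootstrap(s, n_boot=10, seed=0)

    def test_fixed_seed_reproducible(self):
        kin = WormKinematics()
        modes, _ = simulate_modes(kin, n_wells=5, n_frames=50, schedule=None, seed=3)
        wells = [f"W{i // 3}" for i in range(modes.shape[0])]
        s = mode_fractions_from_arrays(modes, wells, np.arange(50) / 25)
        a = aggregate_bootstrap(s, n_boot=50, seed=9)
        b = aggregate_bootstrap(s, n_boot=50, seed=9)
        assert np.array_equal(a["ci_low"], b["ci_low"], equal_nan=True)


class TestDownsamplePrevalent:
    def test_majority_wins(self):
        series = np.array([FW] * 30 + [ST] * 20)
        out = downsample_prevalent(series, frame_rate=25.0, window_s=2.0)
        assert out.tolist() == [FW]

    def test_tie_breaks_to_stationary(self):
        series = np.array([FW] * 25 + [ST] * 25)
        out = downsample_prevalent(series, frame_rate=25.0, window_s=2.0)
        assert out.tolist() == [ST]

    def test_constant_series_unchanged(self):
        series = np.full(150, BW)
        out = downsample_prevalent(series, frame_rate=25.0, window_s=2.0)
        assert np.all(out == BW) and out.shape == (3,)

    def test_all_undefined_window_stays_undefined(self):
        series = np.full(50, UNDEF)
        out = downsample_prevalent(series, frame_rate=25.0, window_s=2.0)
        assert out.tolist() == [UNDEF]

    def test_fractional_window_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            downsample_prevalent(np.zeros(10, int), frame_rate=7.0, window_s=0.5)


class TestPulseDelta:
    def test_constant_series_zero_deltas(self):
        sched = build_schedule("standard")
        times = np.arange(0, 960, 0.5)
        series = np.tile(np.array([[0.5], [0.1], [0.4]]), (1, len(times)))
        deltas, used = pulse_response_delta(series, times, sched)
        assert used == [0, 1, 2]
        assert np.allclose(deltas, 0.0)

    def test_deltas_sum_to_zero_across_modes(self):
        kin = WormKinematics(light_bias=3.0)
        sched = build_schedule("custom", pulses=[(10.0, 10.0, 100.0)],
                               total_duration=40.0)
        modes, _ = simulate_modes(kin, n_wells=6, n_frames=1000, schedule=sched, seed=4)
        wells = [f"W{i // 3}" for i in range(modes.shape[0])]
        times = np.arange(1000) / 25
        s = mode_fractions_from_arrays(modes, wells, times)
        mean = np.nanmean(s.fractions, axis=1)
        deltas, _ = pulse_response_delta(mean, times, sched)
        assert np.allclose(deltas.sum(axis=1), 0.0, atol=1e-9)

    def test_pulse_past_recording_end_skipped_with_warning(self):
        sched = build_schedule("custom", pulses=[(5.0, 5.0, 100.0)],
                               total_duration=12.0)
        times = np.arange(0, 12, 0.04)
        series = np.tile(np.array([[0.5], [0.1], [0.4]]), (1, len(times)))
        with pytest.warns(UserWarning, match="skipped"):
            deltas, used = pulse_response_delta(series, times, sched, window=10.0)
        assert used == [] and deltas.shape == (0, 3)

    def test_increasing_light_bias_gives_increasing_fw_deltas(self):
        """Sensitisation: pulses with growing bias yield forward-response
        deltas that increase with pulse index (Spearman rho > 0)."""
        from scipy.stats import spearmanr

        kin = WormKinematics()
        frame_rate = kin.frame_rate
        n_pulses, period = 6, 60.0
        total = n_pulses * period
        n_frames = int(total * frame_rate)
        times = np.arange(n_frames) / frame_rate
        rng_seed = 7
        # growing per-pulse bias: simulate piecewise with increasing bias
        modes = []
        rng = np.random.default_rng(rng_seed)
        from plateworm.synthetic import _evolve_modes
        import dataclasses
        light = np.zeros(n_frames, dtype=bool)
        pulses = [(k * period + 30.0, 10.0, 100.0) for k in range(n_pulses)]
        for start, dur, _ in pulses:
            light[(times >= start) & (times < start + dur)] = True
        seg_modes = np.empty((72, n_frames), dtype=np.int8)
        pos = 0
        for k in range(n_pulses):
            kin_k = dataclasses.replace(kin, light_bias=1.5 + 1.2 * k)
            n_seg = int(period * frame_rate)
            seg = _evolve_modes(kin_k, light[pos:pos + n_seg], 72, rng)
            seg_modes[:, pos:pos + n_seg] = seg
            pos += n_seg
        wells = [f"W{i // 3}" for i in range(72)]
        s = mode_fractions_from_arrays(seg_modes, wells, times)
        mean = np.nanmean(s.fractions, axis=1)
        sched = build_schedule("custom", pulses=pulses, total_duration=total)
        deltas, used = pulse_response_delta(mean, times, sched)
        assert len(used) == n_pulses
        rho, p = spearmanr(np.arange(n_pulses), deltas[:, FW])
        assert rho > 0 and p < 0.05


class TestBaselineShift:
    def test_null_simulation_shifts_within_3se(self):
        """No light: final-minus-initial window differences are within 3
        standard errors of zero."""
        kin = WormKinematics()
        n_frames = int(600 * kin.frame_rate) + 1
        modes, _ = simulate_modes(kin, n_wells=20, n_frames=n_frames,
                                  schedule=None, seed=6)
        wells = [f"W{i // 3}" for i in range(modes.shape[0])]
        times = np.arange(n_frames) / kin.frame_rate
        s = mode_fractions_from_arrays(modes, wells, times)
        # per-well shifts give the standard error directly
        first = np.nanmean(s.fractions[:, :, times <= 300.0], axis=2)
        last = np.nanmean(s.fractions[:, :, times > times[-1] - 300.0], axis=2)
        per_well = last - first
        se = per_well.std(axis=1, ddof=1) / np.sqrt(per_well.shape[1])
        mean_series = np.nanmean(s.fractions, axis=1)
        shift = baseline_shift(mean_series, times)
        assert np.all(np.abs(shift) < 3 * se + 1e-12)
        assert shift.sum() == pytest.approx(0.0, abs=1e-9)

    def test_short_recording_rejected(self):
        times = np.arange(0, 400, 0.5)
        series = np.tile(np.array([[0.5], [0.1], [0.4]]), (1, len(times)))
        with pytest.raises(ValueError, match="shorter"):
            baseline_shift(series, times)

    def test_stationary_biased_chain_after_pulses_gives_positive_st_shift(self):
        """Post-series fatigue (stationary-biased chain in the second half)
        produces a positive stationary shift."""
        import dataclasses

        from plateworm.synthetic import _evolve_modes

        kin = WormKinematics()
        tired = dataclasses.replace(
            kin, mode_transition_matrix=np.array([
                [0.970, 0.002, 0.028],
                [0.020, 0.955, 0.025],
                [0.002, 0.001, 0.997]]))
        frame_rate = kin.frame_rate
        half = int(320 * frame_rate)
        rng = np.random.default_rng(8)
        first = _evolve_modes(kin, np.zeros(half, bool), 48, rng)
        second = _evolve_modes(tired, np.zeros(half, bool), 48, rng)
        modes = np.concatenate([first, second], axis=1)
        times = np.arange(modes.shape[1]) / frame_rate
        wells = [f"W{i // 3}" for i in range(48)]
        s = mode_fractions_from_arrays(modes, wells, times)
        shift = baseline_shift(np.nanmean(s.fractions, axis=1), times)
        assert shift[ST] > 0
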