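"""Occupancy binning, information content, shuffle test, maps, cross-correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hippodecode as hd
from hippodecode.errors import EmptyResultError, InvalidParameterError, ShapeError
from hippodecode.tuning import OccupancyBinning


def two_bin_binning(p, frame_to_bin):
    return OccupancyBinning("state", 2, ["a", "b"], np.asarray(p, float), np.asarray(frame_to_bin))


class TestBinOccupancy:
    def test_track_bin_count(self, behavior_12_trials):
        binning = hd.bin_occupancy(behavior_12_trials, 2.0)
        assert binning.k == 80  # 160 cm / 2 cm
        assert binning.p.sum() == pytest.approx(1.0)

    def test_uniform_dwell_two_bins(self):
        track = hd.BehaviorTrack(np.arange(4), [1.0, 1.0, 3.0, 3.0], 30.0, 4.0)
        binning = hd.bin_occupancy(track, 2.0)
        np.testing.assert_allclose(binning.p, [0.5, 0.5])

    def test_visual_schedule_half_and_half(self):
        sched = hd.simulate_stimulus_schedule("visual", 30, 10, seed=0)
        binning = hd.bin_occupancy(sched)
        np.testing.assert_allclose(binning.p, [0.5, 0.5])

    def test_track_end_lands_in_last_bin(self):
        track = hd.BehaviorTrack(np.arange(2), [0.0, 160.0], 30.0, 160.0)
        binning = hd.bin_occupancy(track, 2.0)
        assert binning.frame_to_bin[1] == 79

    def test_auditory_epoch_vs_tone_on_modes(self):
        sched = hd.simulate_stimulus_schedule("auditory", 30, 6, seed=0)
        epoch = hd.bin_occupancy(sched)
        strict = hd.bin_occupancy(sched, auditory_frames="tone_on")
        assert np.all(epoch.frame_to_bin >= 0)  # every frame carries its epoch's label
        assert (strict.frame_to_bin == -1).sum() == 6 * 3 * 30  # mute frames excluded

    def test_spatial_without_bin_width_raises(self, behavior_12_trials):
        with pytest.raises(InvalidParameterError):
            hd.bin_occupancy(behavior_12_trials, None)


class TestInformationContent:
    def test_uniform_rate_gives_zero(self):
        binning = two_bin_binning([0.5, 0.5], [0, 1, 0, 1])
        assert hd.information_content(np.array([3.0, 3.0, 3.0, 3.0]), binning) == 0.0

    def test_hand_computed_one_bit(self):
        # p=[1/2,1/2], r=[2,0]: rbar=1, I = 0.5*2*log2(2) = 1 bit
        binning = two_bin_binning([0.5, 0.5], [0, 1, 0, 1])
        i = hd.information_content(np.array([2.0, 0.0, 2.0, 0.0]), binning)
        assert i == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_bits(self):
        # p=[1/4,3/4], r=[4,0]: rbar=1, I = 0.25*4*log2(4) = 2 bits
        binning = two_bin_binning([0.25, 0.75], [0, 1, 1, 1])
        i = hd.information_content(np.array([4.0, 0.0, 0.0, 0.0]), binning)
        assert i == pytest.approx(2.0, abs=1e-12)

    def test_zero_trace_gives_zero(self):
        binning = two_bin_binning([0.5, 0.5], [0, 1, 0, 1])
        assert hd.information_content(np.zeros(4), binning) == 0.0

    def test_length_mismatch_raises(self):
        binning = two_bin_binning([0.5, 0.5], [0, 1, 0, 1])
        with pytest.raises(ShapeError):
            hd.information_content(np.zeros(5), binning)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_information_is_nonnegative_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        t = int(rng.integers(k * 2, 60))
        idx = rng.integers(0, k, size=t)
        counts = np.bincount(idx, minlength=k)
        p = counts / counts.sum()
        binning = OccupancyBinning("state", k, list(range(k)), p, idx)
        trace = rng.random(t) * 10
        i1 = hd.information_content(trace, binning)
        assert i1 >= -1e-12
        i2 = hd.information_content(trace * 7.3, binning)
        assert i2 == pytest.approx(i1, abs=1e-9)

    def test_per_bin_contributions_sum_to_total(self):
        binning = two_bin_binning([0.25, 0.75], [0, 1, 1, 1])
        total, contributions = hd.information_content(
            np.array([4.0, 0.0, 0.0, 0.0]), binning, return_contributions=True
        )
        assert contributions.sum() == pytest.approx(total)


class TestShuffleTest:
    def test_constant_trace_is_not_sensitive(self, spatial_binning):
        result = hd.shuffle_test(
            np.ones(spatial_binning.n_frames), spatial_binning, n_shuffles=50, seed=0
        )
        assert result.i_obs == 0.0
        assert not result.sensitive

    def test_strong_place_cell_is_sensitive(self, behavior_12_trials, spatial_binning):
        cells = [
            hd.GroundTruthTuning(0, "place", field_center_cm=60.0, field_width_cm=10.0, gain=5.0)
        ]
        traces, _ = hd.simulate_tuned_traces(
            cells, behavior=behavior_12_trials, noise_sd=0.02, seed=3
        )
        result = hd.shuffle_test(traces.values[0], spatial_binning, n_shuffles=200, seed=4)
        assert result.sensitive

    def test_type_one_error_near_nominal(self, behavior_12_trials, spatial_binning):
        cells = hd.make_untuned_cells(100)
        traces, _ = hd.simulate_tuned_traces(cells, behavior=behavior_12_trials, seed=5)
        results = hd.population_shuffle_test(
            traces, spatial_binning, n_shuffles=200, seed=6
        )
        rejections = np.mean([r.sensitive for r in results])
        assert rejections < 0.15  # nominal 5%; loose bound at n=100

    def test_permute_on_exchangeable_data_is_calibrated(self, spatial_binning):
        # white-noise traces are exchangeable, so permutation rejection -> 5%
        rng = np.random.default_rng(7)
        n = 200
        values = rng.random((n, spatial_binning.n_frames))
        traces = hd.TraceMatrix(values, np.arange(n), 30.0)
        results = hd.population_shuffle_test(
            traces, spatial_binning, n_shuffles=200, method="permute", seed=8
        )
        rejections = np.mean([r.sensitive for r in results])
        assert 0.01 <= rejections <= 0.10

    def test_determinism(self, place_population, spatial_binning):
        traces, _ = place_population
        a = hd.population_shuffle_test(traces, spatial_binning, n_shuffles=20, seed=9)
        b = hd.population_shuffle_test(traces, spatial_binning, n_shuffles=20, seed=9)
        assert [r.sensitive for r in a] == [r.sensitive for r in b]
        np.testing.assert_array_equal(a[0].null_i, b[0].null_i)


class TestRateMaps:
    def test_single_active_bin_peaks_there(self, behavior_12_trials, spatial_binning):
        trace = np.zeros(spatial_binning.n_frames)
        trace[spatial_binning.frame_to_bin == 40] = 2.0
        traces = hd.TraceMatrix(trace[None], np.array([0]), 30.0)
        rate_map = hd.place_field_map(traces, spatial_binning, sort=False)
        assert np.argmax(rate_map.raw[0]) == 40
        assert np.argmax(rate_map.zscore[0]) == 40

    def test_sorted_map_is_a_diagonal_ridge(self, behavior_12_trials, place_population, spatial_binning):
        traces, _ = place_population
        tuned = hd.TraceMatrix(traces.values[:60], traces.neuron_ids[:60], 30.0)
        rate_map = hd.place_field_map(tuned, spatial_binning, sort=True)
        argmaxes = np.argmax(rate_map.zscore, axis=1)
        assert np.all(np.diff(argmaxes) >= 0)

    def test_zscored_rows_are_standardized(self, place_population, spatial_binning):
        traces, _ = place_population
        rate_map = hd.place_field_map(traces, spatial_binning, sort=False)
        live = rate_map.raw.std(axis=1) > 0
        np.testing.assert_allclose(rate_map.zscore[live].mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(rate_map.zscore[live].std(axis=1), 1, atol=1e-9)

    def test_zero_variance_row_zscores_to_zero(self, spatial_binning):
        traces = hd.TraceMatrix(np.ones((1, spatial_binning.n_frames)), np.array([0]), 30.0)
        with pytest.warns(UserWarning):
            rate_map = hd.place_field_map(traces, spatial_binning, sort=False)
        assert np.all(rate_map.zscore == 0)


class TestEventTriggeredMap:
    def test_deterministic_pulse_is_recovered(self):
        sched = hd.simulate_stimulus_schedule("auditory", 30, 5, seed=0)
        pulse = np.exp(-np.arange(150) / 20.0)
        trace = np.zeros(sched.n_frames)
        for onset in sched.epoch_onsets():
            trace[onset : onset + 150] += pulse
        traces = hd.TraceMatrix(trace[None], np.array([0]), 30.0)
        etm = hd.event_triggered_map(traces, sched, window=(0.0, 5.0))
        expected = (pulse - pulse.mean()) / pulse.std()
        np.testing.assert_allclose(etm.zscore[0], expected, atol=1e-9)

    def test_auditory_window_has_150_columns(self, auditory_session):
        traces, sched = auditory_session
        etm = hd.event_triggered_map(traces, sched, window=(0.0, 5.0))
        assert etm.raw.shape[1] == 150  # 5 s x 30 fps

    def test_no_onsets_raises(self):
        sched = hd.StimulusSchedule(np.arange(5), np.array(["off"] * 5, dtype=object), 30.0, "auditory")
        traces = hd.TraceMatrix(np.zeros((1, 5)), np.array([0]), 30.0)
        with pytest.raises(EmptyResultError):
            hd.event_triggered_map(traces, sched)


class TestRateMapCrossCorr:
    def brute_force(self, m, n):
        """Literal double-loop evaluation of the normalized cross-correlation."""
        m, n = np.asarray(m, float), np.asarray(n, float)
        h, w = m.shape
        nbar = n.mean()
        out = {}
        for u in range(-(h - 1), h):
            for v in range(-(w - 1), w):
                num = sm2 = sn2 = 0.0
                count = 0
                mvals = []
                for x in range(h):
                    for y in range(w):
                        if 0 <= x - u < h and 0 <= y - v < w:
                            mvals.append(m[x, y])
                            count += 1
                if count < 4:
                    continue
                mbar = float(np.mean(mvals))
                for x in range(h):
                    for y in range(w):
                        if 0 <= x - u < h and 0 <= y - v < w:
                            num += (m[x, y] - mbar) * (n[x - u, y - v] - nbar)
                            sm2 += (m[x, y] - mbar) ** 2
                            sn2 += (n[x - u, y - v] - nbar) ** 2
                if sm2 > 0 and sn2 > 0:
                    out[(u, v)] = num / np.sqrt(sm2 * sn2)
        return out

    def test_matches_double_loop_reference(self, rng):
        m = rng.normal(size=(5, 5))
        n = rng.normal(size=(5, 5))
        cc = hd.rate_map_crosscorr(m, n)
        reference = self.brute_force(m, n)
        for (u, v), r_ref in reference.items():
            iu = np.flatnonzero(cc.shifts_u == u)[0]
            iv = np.flatnonzero(cc.shifts_v == v)[0]
            assert cc.r[iu, iv] == pytest.approx(r_ref, abs=1e-12)

    def test_identical_maps_peak_at_origin(self, rng):
        m = rng.normal(size=(6, 6))
        cc = hd.rate_map_crosscorr(m, m)
        assert cc.peak_shift == (0, 0)
        assert cc.peak_value == pytest.approx(1.0, abs=1e-12)

    def test_translated_map_peaks_at_the_shift(self, rng):
        m = rng.normal(size=(8, 8))
        n = np.roll(m, (-2, 0), axis=(0, 1))  # n(x, y) = m(x+2, y)
        cc = hd.rate_map_crosscorr(m, n, max_shift=(4, 4))
        assert cc.peak_shift[0] == 2
        assert cc.peak_value > 0.8

    def test_anticorrelated_maps(self, rng):
        m = rng.normal(size=(5, 5))
        cc = hd.rate_map_crosscorr(m, -m)
        iu = np.flatnonzero(cc.shifts_u == 0)[0]
        iv = np.flatnonzero(cc.shifts_v == 0)[0]
        assert cc.r[iu, iv] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_map_raises(self):
        with pytest.raises(InvalidParameterError):
            hd.rate_map_crosscorr(np.ones((5, 5)), np.ones((5, 5)))
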