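"""Calcium-trace operations against analytic and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypoquant import DffParams, SpikeTrain, TraceSet
from hypoquant.traces import (
    anticorr_rank_stat,
    average_sides,
    compute_dff,
    crosscorrelogram,
    detect_spikes,
    detrend_quadratic,
    downsample_movie,
    epoch_metrics,
    spike_triggered_average,
)


class TestDff:
    def test_constant_raw_gives_zero(self):
        raw = np.full((120, 2), 5.0)
        ts = compute_dff(raw, DffParams(f0_window_s=30), fps=1.0)
        np.testing.assert_allclose(ts.values, 0.0, atol=1e-12)

    def test_step_recovers_fractional_change(self):
        raw = np.full(300, 2.0)
        raw[150:160] = 2.0 * 1.25
        ts = compute_dff(raw[:, None], DffParams(f0_percentile=10,
                                                 f0_window_s=60), fps=1.0)
        np.testing.assert_allclose(ts.values[152:158, 0], 0.25, atol=1e-9)

    def test_epoch_mean_mode(self):
        raw = np.concatenate([np.full(50, 4.0), np.full(50, 6.0)])[:, None]
        ts = compute_dff(raw, DffParams(f0_mode="epoch_mean", f0_epoch="base"),
                         fps=1.0, epochs={"base": (0.0, 50.0)})
        np.testing.assert_allclose(ts.values[60:, 0], 0.5)

    def test_running_percentile_matches_windowed_oracle(self, rng):
        raw = 5 + np.cumsum(rng.standard_normal(200)) * 0.01
        raw = np.abs(raw)[:, None] + 1
        params = DffParams(f0_percentile=10, f0_window_s=30)
        ts = compute_dff(raw, params, fps=1.0)
        win = 30
        for i in (0, 57, 120, 199):  # spot-check frames incl. edges
            lo, hi = max(0, i - win // 2), min(200, i - win // 2 + win)
            # 'nearest' edge handling pads with the boundary value
            seg = raw[max(0, lo): hi, 0]
            pad_lo = max(0, -(i - win // 2))
            pad_hi = max(0, (i - win // 2 + win) - 200)
            seg = np.concatenate([np.full(pad_lo, raw[0, 0]), seg,
                                  np.full(pad_hi, raw[-1, 0])])
            f0 = np.percentile(seg, 10, method="nearest")
            assert ts.values[i, 0] == pytest.approx(
                (raw[i, 0] - f0) / f0, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(k=st.floats(0.01, 1e4), seed=st.integers(0, 2 ** 16))
    def test_scale_invariance(self, k, seed):
        raw = np.random.default_rng(seed).random((100, 1)) + 1.0
        p = DffParams(f0_window_s=20)
        a = compute_dff(raw, p, fps=1.0)
        b = compute_dff(raw * k, p, fps=1.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_nonpositive_f0_names_roi(self):
        raw = np.zeros((50, 1))
        with pytest.raises(ValueError, match="roi0"):
            compute_dff(raw, DffParams(f0_window_s=20), fps=1.0)


class TestDetrend:
    def test_exact_quadratic_removed(self):
        t = np.arange(200) / 2.0
        y = 3 - 0.05 * t + 0.002 * t ** 2
        out = detrend_quadratic(y, fps=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_constant_removed(self):
        np.testing.assert_allclose(detrend_quadratic(np.full(50, 3.3)), 0.0,
                                   atol=1e-10)

    def test_idempotent(self, rng):
        y = rng.standard_normal(300)
        once = detrend_quadratic(y)
        twice = detrend_quadratic(once)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_sparse_spikes_preserved(self, rng):
        t = np.arange(600)
        drift = 1 + 0.003 * t - 4e-6 * t ** 2
        spikes = np.zeros(600)
        kernel = np.exp(-np.arange(30) / 4.0)
        for at in (100, 290, 480):
            spikes[at:at + 30] += 0.5 * kernel
        out = detrend_quadratic(drift + spikes)
        for at in (100, 290, 480):
            local_base = out[at - 5]
            peak = out[at: at + 2].max() - local_base
            assert peak == pytest.approx(0.5, rel=0.05)


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        st_ = detect_spikes(np.zeros(100), fps=1.0)
        assert len(st_) == 0

    def test_injected_transients_recovered(self, rng):
        sigma = 0.02
        trace = rng.standard_normal(600) * sigma
        kernel = np.exp(-np.arange(40) / 4.0)
        truth = np.arange(50, 600, 50)
        ev = np.zeros(600)
        ev[truth] = 6 * sigma
        trace += np.convolve(ev, kernel)[:600]
        st_ = detect_spikes(trace, fps=1.0)
        det = np.round(st_.times).astype(int)
        hits = sum(any(abs(d - t) <= 1 for d in det) for t in truth)
        assert hits >= len(truth) - 1
        assert all(any(abs(d - t) <= 1 for t in truth) for d in det)

    def test_count_monotone_in_threshold(self, rng):
        trace = rng.standard_normal(400) * 0.05
        counts = [len(detect_spikes(trace, 1.0, k_mad=k)) for k in (1, 2, 3, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_time_shift_equivariance(self, rng):
        sigma = 0.02
        base = rng.standard_normal(500) * sigma
        kernel = np.exp(-np.arange(40) / 4.0)
        ev = np.zeros(500)
        ev[[100, 250, 400]] = 8 * sigma
        trace = base + np.convolve(ev, kernel)[:500]
        shifted = np.roll(trace, 20)
        a = detect_spikes(trace[:460], 1.0)
        b = detect_spikes(shifted[20:480], 1.0)
        np.testing.assert_allclose(a.times, b.times)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            detect_spikes(np.zeros(3), fps=1.0, min_separation_s=5.0)


class TestEpochMetrics:
    def _ts(self, dff, fps=1.0):
        return TraceSet(dff[:, None], fps=fps, roi_labels=("lLH",),
                        epochs={"base": (0.0, 300.0)})

    def test_frequency_arithmetic(self):
        ts = self._ts(np.zeros(400))
        spikes = SpikeTrain(np.linspace(5, 295, 15), np.ones(15), "lLH")
        m = epoch_metrics(ts, spikes, "base")
        assert m.freq_per_min == pytest.approx(3.0)

    def test_zero_dff_zero_sum(self):
        ts = self._ts(np.zeros(400))
        m = epoch_metrics(ts, SpikeTrain([], [], "lLH"), "base")
        assert m.sum_dff == 0.0 and np.isnan(m.amplitude)

    def test_matches_bruteforce(self, rng):
        dff = rng.standard_normal(400) * 0.1
        ts = self._ts(dff)
        times = np.sort(rng.choice(np.arange(1, 395), 12, replace=False)).astype(float)
        amps = rng.random(12) + 0.1
        m = epoch_metrics(ts, SpikeTrain(times, amps, "lLH"), "base")
        sel = (times >= 0) & (times < 300)
        assert m.sum_dff == pytest.approx(dff[:300].sum(), rel=1e-12)
        assert m.n_spikes == sel.sum()
        assert m.amplitude == pytest.approx(amps[sel].mean(), rel=1e-12)

    def test_unknown_epoch_rejected(self):
        ts = self._ts(np.zeros(400))
        with pytest.raises(ValueError, match="missing"):
            epoch_metrics(ts, SpikeTrain([], [], "lLH"), "missing")


class TestAverageSides:
    def _ts(self, left, right):
        return TraceSet(np.column_stack([left, right]), fps=1.0,
                        roi_labels=("cH_left", "cH_right"))

    def test_identical_sides_unchanged(self, rng):
        x = rng.standard_normal(50)
        out = average_sides(self._ts(x, x))
        assert out.roi_labels == ("cH",)
        np.testing.assert_allclose(out.values[:, 0], x)

    def test_opposite_sides_cancel(self, rng):
        x = rng.standard_normal(50)
        out = average_sides(self._ts(x, -x))
        np.testing.assert_allclose(out.values[:, 0], 0.0)

    def test_elementwise_mean(self, rng):
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        out = average_sides(self._ts(a, b))
        np.testing.assert_allclose(out.values[:, 0], (a + b) / 2)

    def test_unpaired_passthrough_warns(self, rng):
        ts = TraceSet(rng.standard_normal((30, 3)), fps=1.0,
                      roi_labels=("cH_left", "cH_right", "PVO"))
        with pytest.warns(UserWarning, match="PVO"):
            out = average_sides(ts)
        assert set(out.roi_labels) == {"cH", "PVO"}


class TestSta:
    def test_self_trigger_peaks_at_zero_lag(self, rng):
        sigma = 0.01
        trace = rng.standard_normal(900) * sigma
        kernel = np.exp(-np.arange(40) / 4.0)
        ev = np.zeros(900)
        truth = np.arange(80, 820, 60)
        ev[truth] = 0.5
        trace += np.convolve(ev, kernel)[:900]
        spikes = detect_spikes(trace, 1.0)
        sta = spike_triggered_average(spikes, trace, 1.0, (30, 60))
        assert sta.lags_s[np.argmax(sta.mean)] == pytest.approx(0.0, abs=1.0)
        assert sta.mean.max() == pytest.approx(0.5, rel=0.1)

    def test_sign_flip_gives_trough(self, rng):
        sigma = 0.01
        trace = rng.standard_normal(900) * sigma
        kernel = np.exp(-np.arange(40) / 4.0)
        ev = np.zeros(900)
        ev[np.arange(80, 820, 60)] = 0.5
        trace += np.convolve(ev, kernel)[:900]
        spikes = detect_spikes(trace, 1.0)
        up = spike_triggered_average(spikes, trace, 1.0, (30, 60))
        down = spike_triggered_average(spikes, -trace, 1.0, (30, 60))
        np.testing.assert_allclose(down.mean, -up.mean, atol=1e-12)
        assert down.lags_s[np.argmin(down.mean)] == pytest.approx(0.0, abs=1.0)

    def test_clipped_triggers_dropped_and_counted(self, rng):
        trace = rng.standard_normal(200)
        spikes = SpikeTrain([5.0, 100.0, 198.0], [1.0, 1.0, 1.0], "x")
        sta = spike_triggered_average(spikes, trace, 1.0, (30, 60))
        assert sta.n_used == 1 and sta.n_dropped == 2

    def test_no_usable_triggers_rejected(self):
        spikes = SpikeTrain([1.0], [1.0], "x")
        with pytest.raises(ValueError, match="window"):
            spike_triggered_average(spikes, np.zeros(50), 1.0, (30, 60))


class TestDownsample:
    def test_identity_at_cell_size_one(self, rng):
        movie = rng.random((5, 6, 8))
        traces, labels, coords = downsample_movie(movie, 1)
        np.testing.assert_allclose(traces, movie.reshape(5, -1))

    def test_constant_movie(self):
        movie = np.full((12, 8, 8), 2.0)
        traces, _, _ = downsample_movie(movie, 4)
        np.testing.assert_allclose(traces, 2.0)
        assert traces.shape == (12, 4)

    def test_matches_block_mean_oracle(self, rng):
        movie = rng.random((7, 8, 10))
        traces, _, coords = downsample_movie(movie, 2)
        k = 0
        for y in range(4):
            for x in range(5):
                block = movie[:, 2*y:2*y+2, 2*x:2*x+2].mean(axis=(1, 2))
                np.testing.assert_allclose(traces[:, k], block, rtol=1e-12)
                assert coords[k].tolist() == [2 * y, 2 * x]
                k += 1

    def test_tiles_outside_masks_dropped(self, rng):
        movie = rng.random((11, 8, 8))
        mask = np.zeros((8, 8), bool)
        mask[:, :4] = True
        traces, labels, _ = downsample_movie(movie, 4, {"cH": mask})
        assert traces.shape[1] == 2
        assert set(labels) == {"cH"}


class TestCrossCorrelogram:
    def test_self_and_negation(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([x, -x, rng.standard_normal(50)])
        cmap = crosscorrelogram(X, np.array(["a", "a", "b"]))
        assert cmap.r[0, 0] == pytest.approx(1.0)
        assert cmap.r[0, 1] == pytest.approx(-1.0)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(a=st.floats(0.01, 100), b=st.floats(-10, 10),
           seed=st.integers(0, 2 ** 16))
    def test_affine_invariance(self, a, b, seed):
        X = np.random.default_rng(seed).standard_normal((40, 4))
        labels = np.array(["r1", "r1", "r2", "r2"])
        c1 = crosscorrelogram(X, labels)
        X2 = X.copy()
        X2[:, 2] = a * X2[:, 2] + b
        c2 = crosscorrelogram(X2, labels)
        np.testing.assert_allclose(c1.r, c2.r, atol=1e-9)

    def test_zero_variance_voxel_dropped(self, rng):
        X = np.column_stack([rng.standard_normal(30), np.full(30, 2.0),
                             rng.standard_normal(30)])
        with pytest.warns(UserWarning, match="zero-variance"):
            cmap = crosscorrelogram(X, np.array(["a", "a", "b"]))
        assert cmap.n_voxels == 2

    def test_block_ordering_by_region(self, rng):
        X = rng.standard_normal((30, 4))
        cmap = crosscorrelogram(X, np.array(["z", "a", "z", "a"]))
        assert cmap.voxel_labels.tolist() == ["a", "a", "z", "z"]


def brute_force_rank_stat(r, labels, max_rank):
    """Independent sort-and-count oracle for the rank enrichment."""
    n = r.shape[0]
    regions = sorted(set(labels))
    out = {}
    for src in regions:
        for rank in range(1, max_rank + 1):
            for tgt in regions:
                hits, tot = 0, 0
                for i in range(n):
                    if labels[i] != src:
                        continue
                    order = sorted([j for j in range(n) if j != i],
                                   key=lambda j: (r[i, j], j))
                    tot += 1
                    hits += labels[order[rank - 1]] == tgt
                chance = (sum(labels == tgt) - (tgt == src)) / (n - 1)
                out[(src, tgt, rank)] = (hits / tot) / chance
    return out


class TestRankStat:
    def test_matches_bruteforce_oracle(self, rng):
        n = 24
        r = rng.uniform(-1, 1, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        labels = np.array(["cH"] * 10 + ["mLH"] * 6 + ["lLH"] * 8)
        from hypoquant.datatypes import CorrMap
        cmap = CorrMap(r, labels)
        df = anticorr_rank_stat(cmap, 3)
        oracle = brute_force_rank_stat(r, labels, 3)
        for _, row in df.iterrows():
            key = (row["source"], row["target"], row["rank"])
            assert row["ratio"] == pytest.approx(oracle[key], rel=1e-10)

    def test_forced_partner_gives_inverse_chance(self):
        # every source voxel's most negative partner is in region B
        n = 10
        r = np.full((n, n), 0.5)
        np.fill_diagonal(r, 1.0)
        labels = np.array(["A"] * 8 + ["B"] * 2)
        r[:, 8] = r[8, :] = -0.9  # voxel 8 (B) most anti-correlated with all
        r[8, 8] = 1.0
        from hypoquant.datatypes import CorrMap
        cmap = CorrMap(r, labels)
        df = anticorr_rank_stat(cmap, 1)
        row = df[(df.source == "A") & (df.target == "B")].iloc[0]
        chance = 2 / 9
        assert row["ratio"] == pytest.approx(1.0 / chance)

    def test_probabilities_sum_to_one_per_source_rank(self, rng):
        n = 30
        r = rng.uniform(-1, 1, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        labels = np.array(["a"] * 12 + ["b"] * 10 + ["c"] * 8)
        from hypoquant.datatypes import CorrMap
        df = anticorr_rank_stat(CorrMap(r, labels), 4)
        sums = df.groupby(["source", "rank"])["prob"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_single_region_rejected(self, rng):
        r = np.eye(4)
        from hypoquant.datatypes import CorrMap
        with pytest.raises(ValueError, match="regions"):
            anticorr_rank_stat(CorrMap(r, np.array(["a"] * 4)), 1)
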