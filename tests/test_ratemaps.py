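"""Rate-map pipeline: speed filter, binning, smoothing, SI, sessions."""

import numpy as np
import pytest

from hippoquant import ratemaps as rm
from hippoquant import synthetic_data as synth
from hippoquant.core import ArenaConfig, SpikeTrain, Trajectory

from conftest import make_path_trajectory


def brute_force_si(rate: np.ndarray, dwell: np.ndarray) -> float:
    """Direct double-sum SI oracle, independent of the implementation."""
    total = 0.0
    tot_dwell = 0.0
    lam_bar = 0.0
    for i in range(rate.shape[0]):
        for j in range(rate.shape[1]):
            if dwell[i, j] > 0 and np.isfinite(rate[i, j]):
                tot_dwell += dwell[i, j]
    for i in range(rate.shape[0]):
        for j in range(rate.shape[1]):
            if dwell[i, j] > 0 and np.isfinite(rate[i, j]):
                lam_bar += dwell[i, j] / tot_dwell * rate[i, j]
    if lam_bar <= 0:
        return float("nan")
    for i in range(rate.shape[0]):
        for j in range(rate.shape[1]):
            if dwell[i, j] > 0 and np.isfinite(rate[i, j]):
                p = dwell[i, j] / tot_dwell
                r = rate[i, j] / lam_bar
                if r > 0:
                    total += p * r * np.log2(r)
    return total


class TestSpeed:
    def test_uniform_motion(self):
        # 10 cm over 1 s at 0.1-s sampling
        pts = [(x, 0.0) for x in np.linspace(0, 10, 11)]
        tr = make_path_trajectory(pts, dt=0.1)
        sp = rm.compute_speed(tr, smooth_window=0.0)
        assert np.allclose(sp, 10.0)

    def test_stationary(self):
        tr = make_path_trajectory([(5.0, 5.0)] * 20, dt=0.1)
        assert np.allclose(rm.compute_speed(tr), 0.0)

    def test_sawtooth_speed_away_from_turns(self):
        # slope +-5 cm/s triangle wave
        t = np.arange(0, 8, 0.1)
        x = 5.0 * np.abs(((t / 4.0 + 0.5) % 2) - 1) * 4.0
        tr = Trajectory(t=t, x=x, y=np.zeros_like(t))
        sp = rm.compute_speed(tr, smooth_window=0.0)
        interior = np.ones_like(t, dtype=bool)
        # mask samples near the turning points (every 2 s)
        for turn in np.arange(0, 8.1, 2.0):
            interior &= np.abs(t - turn) > 0.25
        assert np.allclose(sp[interior], 5.0, atol=1e-9)

    def test_single_sample_rejected(self):
        tr = make_path_trajectory([(0.0, 0.0)])
        with pytest.raises(ValueError, match="2 samples"):
            rm.compute_speed(tr)


class TestOccupancy:
    def test_stationary_animal_filtered_out(self, small_arena):
        tr = make_path_trajectory(
            [(5.0, 5.0)] * 1000, dt=0.1, arena=small_arena
        )
        occ = rm.compute_occupancy(tr, small_arena)
        assert occ.total_time == 0.0
        assert not occ.visited.any()

    def test_dwell_accumulates_with_supplied_speed(self, small_arena):
        # 10 s in one bin while "moving" at 5 cm/s
        tr = make_path_trajectory(
            [(1.0, 1.0)] * 100, dt=0.1, arena=small_arena
        )
        occ = rm.compute_occupancy(
            tr, small_arena, speed=np.full(100, 5.0)
        )
        assert occ.dwell[0, 0] == pytest.approx(10.0)
        assert occ.total_time == pytest.approx(10.0)
        assert occ.visited.sum() == 1

    def test_edge_position_goes_to_higher_bin(self, small_arena):
        # bin width 2 cm: x = 2.0 is the edge between bins 0 and 1
        tr = make_path_trajectory(
            [(2.0, 1.0)] * 10, dt=0.1, arena=small_arena
        )
        occ = rm.compute_occupancy(tr, small_arena, speed=np.full(10, 5.0))
        assert occ.dwell[0, 1] > 0 and occ.dwell[0, 0] == 0

    def test_last_bin_closed(self, small_arena):
        tr = make_path_trajectory(
            [(10.0, 10.0)] * 10, dt=0.1, arena=small_arena
        )
        occ = rm.compute_occupancy(tr, small_arena, speed=np.full(10, 5.0))
        assert occ.dwell[4, 4] > 0


class TestRateMap:
    def test_rate_is_count_over_dwell(self, small_arena):
        tr = make_path_trajectory(
            [(1.0, 1.0)] * 100, dt=0.1, arena=small_arena
        )
        speed = np.full(100, 5.0)
        occ = rm.compute_occupancy(tr, small_arena, speed=speed)
        spikes = SpikeTrain("u0", np.linspace(0.1, 9.0, 20))
        rmap = rm.compute_ratemap(spikes, tr, occ, speed=speed)
        assert rmap.rate[0, 0] == pytest.approx(2.0)

    def test_zero_spikes_all_zero_over_visited(self, small_arena):
        tr = make_path_trajectory(
            [(1.0, 1.0), (3.0, 1.0)] * 50, dt=0.1, arena=small_arena
        )
        speed = np.full(100, 5.0)
        occ = rm.compute_occupancy(tr, small_arena, speed=speed)
        rmap = rm.compute_ratemap(SpikeTrain("u0"), tr, occ, speed=speed)
        assert np.all(rmap.rate[occ.visited] == 0)
        assert np.all(np.isnan(rmap.rate[~occ.visited]))

    def test_spike_conservation(self, small_arena):
        # sum(rate * dwell) over bins == number of kept speed-filtered spikes
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 500
            t = np.arange(n) * 0.1
            x = rng.uniform(0, 10, n)
            y = rng.uniform(0, 10, n)
            tr = Trajectory(t=t, x=x, y=y, arena=small_arena)
            speed = rng.uniform(0, 10, n)
            occ = rm.compute_occupancy(tr, small_arena, speed=speed)
            spikes = SpikeTrain(
                "u0", np.sort(rng.uniform(0, t[-1], 200))
            )
            rmap = rm.compute_ratemap(spikes, tr, occ, speed=speed)
            vis = occ.visited
            total = float((rmap.rate[vis] * occ.dwell[vis]).sum())
            assert total == pytest.approx(rmap.n_spikes_used, abs=1e-9)

    def test_out_of_range_spikes_dropped(self, small_arena):
        tr = make_path_trajectory(
            [(1.0, 1.0)] * 100, dt=0.1, arena=small_arena
        )
        speed = np.full(100, 5.0)
        occ = rm.compute_occupancy(tr, small_arena, speed=speed)
        spikes = SpikeTrain("u0", np.array([-5.0, 1.0, 2.0, 99.0]))
        rmap = rm.compute_ratemap(spikes, tr, occ, speed=speed)
        assert rmap.n_spikes_dropped == 2
        assert rmap.n_spikes_used == 2


class TestSmoothing:
    def test_uniform_map_unchanged(self, small_arena):
        occ = rm.OccupancyMap(np.ones((5, 5)), small_arena)
        rmap = rm.RateMap(np.full((5, 5), 3.0), occ)
        sm = rm.smooth_ratemap(rmap)
        assert np.allclose(sm.rate, 3.0)

    def test_single_bin_center_mass(self, small_arena):
        # all bins visited, a single hot bin: the center keeps the
        # discrete-Gaussian center mass of the 2-D kernel
        n = 11
        arena = ArenaConfig(side_length=11.0, n_bins_per_side=n)
        occ = rm.OccupancyMap(np.ones((n, n)), arena)
        grid = np.zeros((n, n))
        grid[5, 5] = 1.0
        sm = rm.smooth_ratemap(rm.RateMap(grid, occ), sigma_bins=1.0)
        k = np.arange(-4, 5)
        w = np.exp(-(k**2) / 2.0)
        w /= w.sum()
        assert sm.rate[5, 5] == pytest.approx(w[4] ** 2, rel=1e-6)

    def test_hole_renormalization_matches_bruteforce(self, small_arena):
        rng = np.random.default_rng(1)
        grid = rng.uniform(0, 5, (5, 5))
        grid[2, 2] = np.nan  # unvisited hole
        dwell = (np.isfinite(grid)).astype(float)
        occ = rm.OccupancyMap(dwell, small_arena)
        sm = rm.smooth_ratemap(rm.RateMap(grid, occ), sigma_bins=1.0)
        # brute-force renormalized-kernel convolution
        k = np.arange(-4, 5)
        w1 = np.exp(-(k**2) / 2.0)
        w1 /= w1.sum()
        kern = np.outer(w1, w1)
        for i in range(5):
            for j in range(5):
                if not np.isfinite(grid[i, j]):
                    assert np.isnan(sm.rate[i, j])
                    continue
                num = den = 0.0
                for di in k:
                    for dj in k:
                        ii, jj = i + di, j + dj
                        if 0 <= ii < 5 and 0 <= jj < 5 and np.isfinite(
                            grid[ii, jj]
                        ):
                            wgt = kern[di + 4, dj + 4]
                            num += wgt * grid[ii, jj]
                            den += wgt
                assert sm.rate[i, j] == pytest.approx(num / den, rel=1e-9)

    def test_bad_sigma_rejected(self, small_arena):
        occ = rm.OccupancyMap(np.ones((5, 5)), small_arena)
        with pytest.raises(ValueError, match="sigma"):
            rm.smooth_ratemap(rm.RateMap(np.ones((5, 5)), occ), sigma_bins=0)


class TestSpatialInformation:
    def test_uniform_rate_zero_information(self):
        rate = np.full((5, 5), 2.0)
        dwell = np.random.default_rng(0).uniform(0.5, 2.0, (5, 5))
        for mode in ("skaggs", "literal"):
            assert rm.spatial_information(rate, dwell, mode=mode) == (
                pytest.approx(0.0, abs=1e-12)
            )

    def test_two_bins_hand_value(self):
        # equal occupancy, rates (2, 0): lam = 1, SI = 1 bit/spike
        rate = np.array([[2.0, 0.0]])
        dwell = np.array([[1.0, 1.0]])
        assert rm.spatial_information(rate, dwell) == pytest.approx(1.0)

    def test_four_bins_hand_value(self):
        rate = np.array([[4.0, 0.0], [0.0, 0.0]])
        dwell = np.ones((2, 2))
        assert rm.spatial_information(rate, dwell) == pytest.approx(2.0)

    def test_silent_map_undefined(self):
        rate = np.zeros((3, 3))
        dwell = np.ones((3, 3))
        assert np.isnan(rm.spatial_information(rate, dwell))

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        rate = rng.uniform(0, 10, (5, 5))
        dwell = rng.uniform(0.1, 3, (5, 5))
        for mode in ("skaggs", "literal"):
            si1 = rm.spatial_information(rate, dwell, mode=mode)
            si2 = rm.spatial_information(7.3 * rate, dwell, mode=mode)
            assert si2 == pytest.approx(si1, rel=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            rate = rng.uniform(0, 10, (5, 5))
            dwell = rng.uniform(0, 2, (5, 5))
            dwell[rng.uniform(size=(5, 5)) < 0.2] = 0.0
            si = rm.spatial_information(rate, dwell)
            oracle = brute_force_si(rate, dwell)
            if np.isnan(oracle):
                assert np.isnan(si)
            else:
                assert si == pytest.approx(oracle, rel=1e-12, abs=1e-14)

    def test_nonnegative_skaggs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            rate = rng.uniform(0, 10, (4, 4))
            dwell = rng.uniform(0.01, 2, (4, 4))
            assert rm.spatial_information(rate, dwell) >= -1e-14


class TestQuadrants:
    def test_odd_grid_partition_sizes(self):
        part = rm.QuadrantPartition.for_grid(15)
        counts = [(part.labels == q).sum() for q in range(4)]
        assert counts == [49, 49, 49, 49]
        assert (part.labels == -1).sum() == 29  # central row + column

    def test_even_grid_no_exclusion(self):
        part = rm.QuadrantPartition.for_grid(4)
        assert (part.labels == -1).sum() == 0
        assert [(part.labels == q).sum() for q in range(4)] == [4] * 4

    def test_uniform_within_quadrants_gives_zero(self):
        part = rm.QuadrantPartition.for_grid(4)
        rate = np.zeros((4, 4))
        for q, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            rate[part.mask(q)] = v
        dwell = np.ones((4, 4))
        si = rm.quadrant_si(rate, dwell, part)
        assert np.allclose(si, 0.0, atol=1e-12)

    def test_field_confined_to_one_quadrant(self):
        part = rm.QuadrantPartition.for_grid(4)
        rate = np.zeros((4, 4))
        rate[0, 0] = 5.0  # single hot bin in quadrant 0
        dwell = np.ones((4, 4))
        si = rm.quadrant_si(rate, dwell, part)
        assert si[0] == pytest.approx(2.0)  # 4 bins, one active
        assert all(np.isnan(si[q]) for q in (1, 2, 3))  # silent: undefined

    def test_quadrant_equals_restricted_whole_map(self):
        rng = np.random.default_rng(5)
        part = rm.QuadrantPartition.for_grid(6)
        rate = rng.uniform(0, 8, (6, 6))
        dwell = rng.uniform(0.1, 2, (6, 6))
        si = rm.quadrant_si(rate, dwell, part)
        for q in range(4):
            m = part.mask(q)
            restricted_rate = np.where(m, rate, np.nan)
            restricted_dwell = np.where(m, dwell, 0.0)
            assert si[q] == pytest.approx(
                rm.spatial_information(restricted_rate, restricted_dwell),
                rel=1e-12,
            )


class TestInclusionFilter:
    @staticmethod
    def _uniform_train(rate_hz: float, duration: float = 3600.0):
        n = int(round(rate_hz * duration))
        return SpikeTrain("u", np.linspace(1e-3, duration - 1e-3, n))

    def test_low_rate_excluded(self):
        out = rm.apply_inclusion_filter(
            [self._uniform_train(0.1)], 0.0, 3600.0
        )
        assert out == []

    def test_silent_tail_excluded(self):
        st = self._uniform_train(2.0)
        st = SpikeTrain("u", st.spike_times[st.spike_times < 2700.0])
        out = rm.apply_inclusion_filter([st], 0.0, 3600.0)
        assert out == []

    def test_boundary_rate_included(self):
        out = rm.apply_inclusion_filter(
            [self._uniform_train(0.2)], 0.0, 3600.0
        )
        assert len(out) == 1

    def test_high_rate_excluded(self):
        out = rm.apply_inclusion_filter(
            [self._uniform_train(5.5)], 0.0, 3600.0
        )
        assert out == []

    def test_short_session_rejected(self):
        with pytest.raises(ValueError, match="edge windows"):
            rm.apply_inclusion_filter([self._uniform_train(1.0)], 0.0, 900.0)


class TestSessionComparison:
    @staticmethod
    def _si_result(uid, label, quad):
        return rm.SIResult(uid, label, float(np.nansum(quad)),
                           np.asarray(quad, float), 1.0)

    def test_identical_sessions_p_one(self):
        res = {
            lab: [
                self._si_result(f"u{k}", lab, [0.5, 0.4, 0.3, 0.2])
                for k in range(6)
            ]
            for lab in ("S1", "S2", "S3")
        }
        cmp = rm.compare_sessions(res, 0)
        assert np.all(cmp.delta_inside_s2 == 0)
        assert cmp.p_s2 == 1.0 and cmp.p_s3 == 1.0

    def test_exact_small_sample_p(self):
        # inside deltas (1, 2) vs outside (3, 4): exact two-sided p = 1/3
        a = np.array([1.0, 2.0])
        b = np.array([3.0, 4.0])
        _, p = rm.rank_sum_test(a, b)
        assert p == pytest.approx(1.0 / 3.0)

    def test_missing_session_unit_dropped(self):
        res = {
            "S1": [self._si_result("u0", "S1", [1, 1, 1, 1]),
                   self._si_result("u1", "S1", [1, 1, 1, 1])],
            "S2": [self._si_result("u0", "S2", [1, 1, 1, 1])],
            "S3": [self._si_result("u0", "S3", [1, 1, 1, 1]),
                   self._si_result("u1", "S3", [1, 1, 1, 1])],
        }
        cmp = rm.compare_sessions(res, 0)
        assert cmp.n_dropped == 1
        assert cmp.unit_ids == ["u0"]


class TestEndToEndRecovery:
    def test_degradation_shifts_only_inside_quadrant(self):
        # single-seed version of the multi-seed acceptance experiment
        from hippoquant.pipeline import run_quadrant_inhibition_experiment

        cmp = run_quadrant_inhibition_experiment(
            n_units=40, degradation=0.8, seed=12,
            n_recording_sessions=8, session_duration=900.0,
        )
        assert cmp.median_delta_inside_s2 < cmp.median_delta_outside_s2
        assert cmp.p_s2 < 0.01
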