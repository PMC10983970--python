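"""Migration metrics: linking, speed, MSD, gating, spider plots, gradients."""

import math

import numpy as np
import pytest

import adhesioquant as aq
from adhesioquant.images import PlaneImage
from adhesioquant.motility import (
    LinkParams,
    chemotaxis_gate,
    gradient_profile,
    link_tracks,
    msd,
    spider_coordinates,
    track_speed,
)
from adhesioquant.synthetic import PRWParams, gen_tracks
from adhesioquant.tracks import Track, TrackSet


def straight_track(tid, n, v_um_per_frame, dt=5.0, start=(0.0, 0.0), direction=(1.0, 0.0)):
    d = np.asarray(direction, float) / np.hypot(*direction)
    xy = np.asarray(start, float) + np.outer(np.arange(n) * v_um_per_frame, d)
    return Track(tid, np.arange(n), np.arange(n) * dt, xy)


class TestLinkTracks:
    def test_single_drifting_detection(self):
        dets = [np.array([[1.0 * f, 0.0]]) for f in range(10)]
        ts = link_tracks(dets, dt_s=5.0)
        assert len(ts) == 1
        assert len(ts.tracks[0]) == 10

    def test_gap_beyond_limit_splits_track(self):
        dets = [np.array([[1.0 * f, 0.0]]) if (f < 5 or f >= 11) else np.empty((0, 2))
                for f in range(16)]
        ts = link_tracks(dets, LinkParams(gap_max_frames=5), dt_s=5.0)
        assert len(ts) == 2  # 6-frame hole > 5-frame gap limit

    def test_gap_within_limit_closes(self):
        dets = [np.array([[1.0 * f, 0.0]]) if (f < 5 or f >= 9) else np.empty((0, 2))
                for f in range(14)]
        ts = link_tracks(dets, LinkParams(gap_max_frames=5), dt_s=5.0)
        assert len(ts) == 1
        assert len(ts.tracks[0]) == 10

    def test_link_distance_limit(self):
        dets = [np.array([[0.0, 0.0]]), np.array([[30.0, 0.0]])]
        ts = link_tracks(dets, LinkParams(link_max_um=25.0, min_track_frames=1), dt_s=5.0)
        assert len(ts) == 2  # 30 um jump exceeds linking max

    def test_min_track_frames_filter(self):
        dets = [np.array([[0.0, 0.0]]), np.empty((0, 2)) , np.empty((0, 2)),
                np.empty((0, 2)), np.empty((0, 2)), np.empty((0, 2)),
                np.empty((0, 2))]
        ts = link_tracks(dets, LinkParams(min_track_frames=2), dt_s=5.0)
        assert len(ts) == 0

    @pytest.mark.parametrize("method", ["greedy", "hungarian"])
    @pytest.mark.parametrize("seed", range(25))
    def test_two_point_geometry_against_assignment_oracle(self, seed, method):
        """Two constant-velocity walkers: frame-to-frame assignments must
        match the brute-force minimal-total-distance choice whenever it is
        unambiguous."""
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(0, 100, 2)
        p1 = p0 + rng.uniform(20, 60, 2)          # well separated starts
        v0, v1 = rng.uniform(-2, 2, 2), rng.uniform(-2, 2, 2)
        n = 8
        truth = [np.stack([p0 + f * v0, p1 + f * v1]) for f in range(n)]
        # skip ambiguous geometries where the walkers come close
        min_sep = min(np.linalg.norm(fr[0] - fr[1]) for fr in truth)
        if min_sep < 10.0:
            pytest.skip("ambiguous geometry")
        ts = link_tracks(truth, LinkParams(method=method), dt_s=5.0)
        assert len(ts) == 2
        for tr in ts:
            # each track follows exactly one walker
            start = tr.xy_um[0]
            walker = 0 if np.allclose(start, truth[0][0]) else 1
            expected = np.stack([truth[f][walker] for f in range(n)])
            np.testing.assert_allclose(tr.xy_um, expected)


class TestTrackSpeed:
    def test_one_um_per_five_seconds_is_twelve_per_minute(self):
        tr = straight_track(0, 10, 1.0, dt=5.0)
        assert track_speed(tr) == pytest.approx(12.0)

    def test_stationary(self):
        tr = straight_track(0, 5, 0.0)
        assert track_speed(tr) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        xy = rng.normal(0, 3, (20, 2))
        tr = Track(0, np.arange(20), np.arange(20) * 5.0, xy)
        steps = [
            math.hypot(*(xy[i + 1] - xy[i])) / 5.0 * 60.0
            for i in range(19)
        ]
        assert track_speed(tr) == pytest.approx(sum(steps) / len(steps))

    def test_single_sample_raises(self):
        tr = Track(0, [0], [0.0], [[1.0, 2.0]])
        with pytest.raises(ValueError):
            track_speed(tr)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        xy = rng.normal(0, 3, (15, 2))
        tr = Track(0, np.arange(15), np.arange(15) * 5.0, xy)
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        tr2 = Track(0, tr.frames, tr.t_s, xy @ rot.T + np.array([11.0, -4.0]))
        assert track_speed(tr2) == pytest.approx(track_speed(tr))


class TestMSD:
    @staticmethod
    def brute_force(tracks, frac=0.5):
        out = {}
        for tr in tracks:
            m = len(tr)
            max_n = max(int(math.floor(frac * (m - 1))), 1)
            for n in range(1, max_n + 1):
                sqs = [float(np.sum((tr.xy_um[i + n] - tr.xy_um[i]) ** 2))
                       for i in range(m - n)]
                out.setdefault(n, []).append(sum(sqs) / len(sqs))
        return {n: sum(v) / len(v) for n, v in out.items()}

    def test_stationary_is_zero(self):
        ts = TrackSet([straight_track(i, 12, 0.0) for i in range(3)], 5.0)
        assert msd(ts).msd_um2.max() == 0.0

    def test_ballistic_closed_form(self):
        v = 0.25  # um/s
        ts = TrackSet([straight_track(0, 30, v * 5.0, dt=5.0, direction=(3, 4))], 5.0)
        curve = msd(ts)
        expected = (v * curve.lags_s) ** 2
        nz = curve.lags_s > 0
        rel = np.abs(curve.msd_um2[nz] - expected[nz]) / expected[nz]
        assert rel.max() <= 1e-9

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(12)
        trs = []
        for tid in range(50):
            m = int(rng.integers(4, 30))
            xy = np.cumsum(rng.normal(0, 1, (m, 2)), axis=0)
            trs.append(Track(tid, np.arange(m), np.arange(m) * 5.0, xy))
        ts = TrackSet(trs, 5.0)
        curve = msd(ts)
        oracle = self.brute_force(ts)
        for lag_s, val in zip(curve.lags_s, curve.msd_um2):
            n = int(round(lag_s / 5.0))
            if n == 0:
                assert val == 0.0
            else:
                assert val == pytest.approx(oracle[n], abs=1e-12)

    def test_isotropic_random_walk_scaling(self):
        """Ensemble MSD of a diffusive walk grows ~ 2*sigma^2*n at small lags."""
        rng = np.random.default_rng(13)
        sigma = 1.5
        trs = []
        for tid in range(500):
            xy = np.cumsum(rng.normal(0, sigma, (40, 2)), axis=0)
            trs.append(Track(tid, np.arange(40), np.arange(40) * 5.0, xy))
        curve = msd(TrackSet(trs, 5.0))
        for n in (1, 2, 3):
            i = int(np.nonzero(curve.lags_s == n * 5.0)[0][0])
            assert curve.msd_um2[i] == pytest.approx(2 * sigma ** 2 * n, rel=0.05)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(14)
        trs = [Track(i, np.arange(10), np.arange(10) * 5.0,
                     np.cumsum(rng.normal(0, 1, (10, 2)), axis=0))
               for i in range(5)]
        ts = TrackSet(trs, 5.0)
        th = 1.1
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        ts2 = TrackSet([Track(t.track_id, t.frames, t.t_s,
                              t.xy_um @ rot.T + np.array([5.0, 5.0]))
                        for t in trs], 5.0)
        np.testing.assert_allclose(msd(ts).msd_um2, msd(ts2).msd_um2, atol=1e-9)


class TestChemotaxisGate:
    def test_all_toward_passes(self):
        ts = TrackSet([straight_track(i, 5, 1.0) for i in range(10)], 15.0)
        g = chemotaxis_gate(ts)
        assert g.fraction_toward == 1.0 and g.passed

    def test_seven_of_ten_fails_at_eighty_percent(self):
        trs = [straight_track(i, 5, 1.0, direction=(1, 0) if i < 7 else (-1, 0))
               for i in range(10)]
        g = chemotaxis_gate(TrackSet(trs, 15.0))
        assert g.fraction_toward == pytest.approx(0.7)
        assert not g.passed

    def test_zero_net_displacement_counts_against(self):
        # out and back: net displacement zero -> strictly-positive rule fails
        xy = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 0.0]])
        tr = Track(0, np.arange(3), np.arange(3) * 15.0, xy)
        g = chemotaxis_gate(TrackSet([tr], 15.0))
        assert g.fraction_toward == 0.0

    def test_biased_generator_always_passes(self):
        for seed in range(20):
            ts = gen_tracks(PRWParams(bias_strength=1.0, n_tracks=10, seed=seed))
            assert chemotaxis_gate(ts).passed

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            chemotaxis_gate(TrackSet([], 15.0))

    def test_positional_noise_never_decreases_mean_speed(self):
        """Localization noise inflates per-step displacements on average."""
        base = gen_tracks(PRWParams(n_tracks=20, seed=100))
        clean = np.mean([track_speed(t) for t in base])
        worse = 0
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            noisy = TrackSet([
                Track(t.track_id, t.frames, t.t_s,
                      t.xy_um + rng.normal(0, 0.3, t.xy_um.shape))
                for t in base], base.dt_s)
            if np.mean([track_speed(t) for t in noisy]) < clean:
                worse += 1
        assert worse == 0


class TestSpider:
    def test_origin_shift(self):
        tr = straight_track(0, 6, 2.0, start=(5.0, 7.0))
        out = spider_coordinates(TrackSet([tr], 5.0))
        np.testing.assert_allclose(out.tracks[0].xy_um[0], [0.0, 0.0])

    def test_translation_invariance(self):
        rng = np.random.default_rng(15)
        trs = [Track(i, np.arange(8), np.arange(8) * 5.0, rng.normal(0, 5, (8, 2)))
               for i in range(4)]
        shifted = [Track(t.track_id, t.frames, t.t_s, t.xy_um + 13.0) for t in trs]
        a = spider_coordinates(TrackSet(trs, 5.0))
        b = spider_coordinates(TrackSet(shifted, 5.0))
        for ta, tb in zip(a, b):
            np.testing.assert_allclose(ta.xy_um, tb.xy_um, atol=1e-9)

    def test_endpoint_is_net_displacement(self):
        rng = np.random.default_rng(16)
        tr = Track(0, np.arange(9), np.arange(9) * 5.0, rng.normal(0, 5, (9, 2)))
        out = spider_coordinates(TrackSet([tr], 5.0))
        np.testing.assert_allclose(out.tracks[0].xy_um[-1], tr.net_displacement_um)


class TestGradientProfile:
    def test_uniform_is_flat(self):
        img = PlaneImage(np.full((50, 80), 300, dtype=np.uint16), 0.1)
        profile, slope, increasing = gradient_profile(img, "x")
        assert np.ptp(profile) == 0.0
        assert slope == 0.0 and not increasing

    def test_linear_ramp_slope(self):
        ramp = np.tile(np.arange(100, dtype=np.uint16), (40, 1))
        _, slope, increasing = gradient_profile(PlaneImage(ramp, 0.1), "x")
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert increasing

    def test_y_axis(self):
        ramp = np.tile(np.arange(60, dtype=np.uint16)[:, None], (1, 30))
        _, slope, _ = gradient_profile(PlaneImage(ramp, 0.1), "y")
        assert slope == pytest.approx(1.0, abs=1e-9)

    def test_noisy_ramp_slope_recovery(self):
        n_cols, n_rows, true_slope = 120, 60, 0.8
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            base = 200 + true_slope * np.arange(n_cols)
            arr = np.clip(rng.normal(base, 10.0, (n_rows, n_cols)), 0, 65535)
            _, slope, _ = gradient_profile(PlaneImage(arr.astype(np.uint16), 0.1), "x")
            x = np.arange(n_cols)
            se = (10.0 / math.sqrt(n_rows)) / math.sqrt(np.sum((x - x.mean()) ** 2))
            if abs(slope - true_slope) < 3 * se:
                hits += 1
        assert hits >= 95
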