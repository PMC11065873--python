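"""Angle maps on the annular track: alpha convention, travel direction,
tuning metrics, autocorrelogram and session labeling."""

import numpy as np
import pytest

import socialvec as sv
from socialvec.errors import ParameterError
from socialvec.pursuit import N_HALF_BINS, AngleMap, peak_metrics
from socialvec.synth import generate_events, pursuit_population


def _rotating_session(annulus_arena, offset_deg, ccw=True, n=600, fr=30.0):
    """Subject rotating at 60 deg/s; partner at a fixed angular offset."""
    omega = np.deg2rad(60.0) * (1 if ccw else -1)
    t = np.arange(n) / fr
    th_s = omega * t
    th_o = th_s + np.deg2rad(offset_deg)
    r = 30.0

    def traj(th, hd=None):
        return sv.Trajectory(frame_rate=fr, t=t,
                             pos=np.stack([r * np.cos(th), r * np.sin(th)], 1),
                             head_dir=hd)

    hd = th_s + (np.pi / 2 if ccw else -np.pi / 2)
    from socialvec.geometry import wrap_angle
    return sv.Session(arena=annulus_arena,
                      trajectories={"m0": traj(th_s, wrap_angle(hd)),
                                    "m1": traj(th_o)},
                      raster=np.zeros((1, n), np.uint8), subject="m0", seed=0)


class TestAlpha:
    def test_ccw_partner_ahead_is_positive(self, annulus_arena):
        ses = _rotating_session(annulus_arena, +90.0, ccw=True)
        alpha, travel, valid = sv.compute_alpha(ses)
        assert (travel[30:] == 1).all()
        np.testing.assert_allclose(alpha[valid][30:], 90.0, atol=1e-6)

    def test_cw_partner_ahead_is_negative(self, annulus_arena):
        # ahead along clockwise travel = at -90 deg arena offset
        ses = _rotating_session(annulus_arena, -90.0, ccw=False)
        alpha, travel, valid = sv.compute_alpha(ses)
        assert (travel[30:] == -1).all()
        np.testing.assert_allclose(alpha[valid][30:], -90.0, atol=1e-6)

    def test_ccw_partner_behind_unwraps_toward_360(self, annulus_arena):
        ses = _rotating_session(annulus_arena, -10.0, ccw=True)
        alpha, travel, valid = sv.compute_alpha(ses)
        np.testing.assert_allclose(alpha[valid][30:], 350.0, atol=1e-6)

    def test_alpha_invariant_to_rigid_rotation_and_flips_with_direction(
            self, annulus_arena):
        ses = _rotating_session(annulus_arena, 45.0, ccw=True)
        alpha, _, valid = sv.compute_alpha(ses)
        rot = _rotating_session(annulus_arena, 45.0, ccw=True)
        for traj in rot.trajectories.values():
            phi = 1.1
            c, s = np.cos(phi), np.sin(phi)
            traj.pos = traj.pos @ np.array([[c, s], [-s, c]])
        alpha_rot, _, _ = sv.compute_alpha(rot)
        np.testing.assert_allclose(alpha_rot[valid][30:], alpha[valid][30:],
                                   atol=1e-6)

        flipped = _rotating_session(annulus_arena, -45.0, ccw=False)
        alpha_f, _, valid_f = sv.compute_alpha(flipped)
        np.testing.assert_allclose(alpha_f[valid_f][30:],
                                   -alpha[valid][30:], atol=1e-6)

    def test_alpha_requires_annulus(self, pair_session):
        with pytest.raises(ParameterError):
            sv.compute_alpha(pair_session)


class TestTravelDirection:
    def test_pure_rotations(self, annulus_arena):
        for ccw in (True, False):
            ses = _rotating_session(annulus_arena, 30.0, ccw=ccw)
            travel = sv.travel_direction(ses)
            assert (travel[30:] == (1 if ccw else -1)).all()

    def test_reversal_detected_within_smoothing_window(self, annulus_arena):
        fr, n = 30.0, 1200
        t = np.arange(n) / fr
        omega = np.deg2rad(60.0)
        th = np.where(t < 20.0, -omega * t, omega * (t - 40.0))
        r = 30.0
        traj = sv.Trajectory(frame_rate=fr, t=t,
                             pos=np.stack([r * np.cos(th), r * np.sin(th)], 1),
                             head_dir=np.zeros(n))
        ses = sv.Session(arena=annulus_arena,
                         trajectories={"m0": traj, "m1": traj},
                         raster=np.zeros((1, n), np.uint8), subject="m0", seed=0)
        travel = sv.travel_direction(ses)
        switches = np.flatnonzero(np.diff(travel))
        assert len(switches) == 1
        assert abs(switches[0] - 600) <= 20  # within ~0.5 s window of the flip


class TestAngleMaps:
    def test_events_at_45_ahead_peak_near_45(self, annulus_arena):
        ses = _rotating_session(annulus_arena, 45.0, ccw=True, n=3000)
        row = (np.random.default_rng(1).random(3000) < 0.5).astype(np.uint8)
        amap = sv.build_angle_map(ses, row)
        peak = np.nanargmax(amap.smoothed_rate)
        assert abs(amap.centers_deg[peak] - 45.0) <= 15.0

    def test_constant_cell_yields_flat_halves(self, pursuit_session):
        row = np.ones(pursuit_session.n_frames, dtype=np.uint8)
        amap = sv.build_angle_map(pursuit_session, row)
        vis = np.isfinite(amap.smoothed_rate)
        np.testing.assert_allclose(amap.smoothed_rate[vis], 30.0, rtol=1e-9)

    def test_total_events_conserved_per_half(self, pursuit_session):
        alpha, travel, valid = sv.compute_alpha(pursuit_session)
        for c in (0, 1):
            amap = sv.build_angle_map(pursuit_session, c)
            row = pursuit_session.raster[c]
            ccw_events = ((row > 0) & valid & (travel > 0)).sum()
            assert amap.event_count[N_HALF_BINS:].sum() == ccw_events

    def test_sharper_tuning_carries_more_information(self, annulus_arena):
        ses = sv.simulate_annular_pursuit(annulus_arena, n_trials=20,
                                          latency_profile=[8.0] * 20, seed=41)
        broad = pursuit_population(20, 50.0, 1.5, 0.02, seed=1)
        narrow = pursuit_population(20, 15.0, 1.5, 0.02, seed=1)
        infos = {}
        for name, cells in (("broad", broad), ("narrow", narrow)):
            ses.raster = generate_events(cells, ses, seed=5)
            maps = [sv.build_angle_map(ses, c) for c in range(20)]
            infos[name] = np.nanmean([sv.angle_map_information(m) for m in maps])
        assert infos["narrow"] > infos["broad"]


def _map_from_rates(rates):
    rates = np.asarray(rates, float)
    nb = len(rates)
    return AngleMap(bin_edges_deg=np.linspace(-360, 360, nb + 1),
                    occupancy_s=np.ones(nb), event_count=rates.copy(),
                    rate=rates.copy(), smoothed_rate=rates.copy())


class TestPeakMetrics:
    def test_single_active_bin(self):
        rates = np.zeros(48)
        rates[30] = 2.0
        pm = peak_metrics(_map_from_rates(rates))
        assert pm.half_width_deg == 15.0
        assert pm.signal_fraction == pytest.approx(1.0)
        assert not pm.untuned

    def test_flat_map_is_flagged_untuned(self):
        pm = peak_metrics(_map_from_rates(np.ones(48)))
        assert pm.untuned
        assert pm.half_width_deg == 360.0

    def test_halfwidth_tracks_tuning_width(self):
        centers = np.linspace(-352.5, 352.5, 48)
        widths = {}
        for sd in (60.0, 20.0):
            rates = 0.05 + np.exp(-0.5 * ((centers - 120.0) / sd) ** 2)
            widths[sd] = peak_metrics(_map_from_rates(rates)).half_width_deg
        assert widths[20.0] < widths[60.0]

    def test_signal_fraction_tracks_offfield_suppression(self):
        centers = np.linspace(-352.5, 352.5, 48)
        fractions = {}
        for base in (0.2, 0.02):
            rates = base + np.exp(-0.5 * ((centers - 120.0) / 30.0) ** 2)
            fractions[base] = peak_metrics(_map_from_rates(rates)).signal_fraction
        assert fractions[0.02] > fractions[0.2]


class TestAutocorrelogram:
    def test_unity_at_zero_shift(self, pursuit_session):
        maps = [sv.build_angle_map(pursuit_session, c) for c in range(10)]
        shifts, corr, auc = sv.population_autocorrelogram(maps)
        assert corr[list(shifts).index(0.0)] == pytest.approx(1.0)

    def test_single_bin_population_decorrelates_at_one_bin(self):
        rng = np.random.default_rng(2)
        maps = []
        for _ in range(30):
            rates = np.zeros(48)
            rates[rng.integers(0, 48)] = 1.0
            maps.append(_map_from_rates(rates))
        shifts, corr, _ = sv.population_autocorrelogram(maps)
        z = list(shifts).index(0.0)
        assert corr[z] == pytest.approx(1.0)
        assert max(abs(corr[z - 1]), abs(corr[z + 1])) < 0.2

    def test_symmetric_for_mirror_symmetric_population(self):
        rng = np.random.default_rng(3)
        maps = []
        for _ in range(20):
            half = rng.random(24)
            maps.append(_map_from_rates(np.concatenate([half, half])))
            maps.append(_map_from_rates(np.concatenate([half[::-1], half[::-1]])))
        shifts, corr, _ = sv.population_autocorrelogram(maps)
        np.testing.assert_allclose(corr, corr[::-1], atol=0.05)


class TestSessionLabels:
    def test_latency_rule(self):
        labels = sv.label_sessions([[100.0, 80.0], [25.0, 26.0]])
        assert labels[0].label == "naive"
        assert labels[1].label == "trained"      # median 25.5 < 0.3 * 100

    def test_above_threshold_stays_naive(self):
        labels = sv.label_sessions([[100.0, 80.0], [35.0, 36.0]])
        assert labels[1].label == "naive"

    def test_first_session_always_naive_and_training_sticks(self):
        labels = sv.label_sessions([[10.0], [2.0], [50.0]])
        assert [l.label for l in labels] == ["naive", "trained", "trained"]


class TestExperienceCurve:
    def test_progressive_narrowing_gives_negative_trend(self, annulus_arena):
        ses = sv.simulate_annular_pursuit(annulus_arena, n_trials=20,
                                          latency_profile=[8.0] * 20, seed=43)
        maps_per_session = []
        for k, sd in enumerate(np.linspace(60.0, 12.0, 10)):
            cells = pursuit_population(12, sd, 1.5, 0.02, seed=100 + k)
            ses.raster = generate_events(cells, ses, seed=200 + k)
            maps_per_session.append(
                [sv.build_angle_map(ses, c) for c in range(12)])
        aucs, r, p = sv.experience_curve(maps_per_session, group_size=2)
        assert len(aucs) == 5
        assert r < -0.5
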