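"""Rate maps: binning, smoothing oracle, information oracle, fields,
stability and radial profiles."""

import numpy as np
import pytest

import socialvec as sv
from socialvec.errors import EmptyMapError
from socialvec.ratemaps import MapGrid, PlaceField, RateMap, detect_fields


# ---------------------------------------------------------------- oracles

def information_oracle(p, lam):
    """Direct summation of I = sum_i p_i (lam_i/lbar) log2(lam_i/lbar)."""
    p = np.asarray(p, float)
    lam = np.asarray(lam, float)
    p = p / p.sum()
    lbar = float((p * lam).sum())
    total = 0.0
    for pi, li in zip(p, lam):
        if li > 0:
            total += pi * (li / lbar) * np.log2(li / lbar)
    return total


def smoothing_oracle(counts2d, occ2d, visited2d, sd):
    """Occupancy-weighted renormalized Gaussian convolution by direct summation.

    smoothed(i) = sum_j w_ij counts_j / sum_j w_ij occ_j with truncated
    Gaussian weights; kernel normalization cancels in the ratio.
    """
    ny, nx = counts2d.shape
    radius = int(4.0 * sd + 0.5)
    out = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            if not visited2d[i, j]:
                continue
            num = den = 0.0
            for di in range(-radius, radius + 1):
                for dj in range(-radius, radius + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < ny and 0 <= jj < nx:
                        w = np.exp(-(di**2 + dj**2) / (2 * sd**2))
                        num += w * counts2d[ii, jj]
                        den += w * occ2d[ii, jj]
            out[i, j] = num / den
    return out


def _grid_session(positions, raster_rows, frame_rate=30.0, arena=None):
    """Session whose subject walks through the given positions."""
    arena = arena or sv.ArenaGeometry.square(20.0)
    pos = np.asarray(positions, float)
    n = len(pos)
    traj = sv.Trajectory(frame_rate=frame_rate, t=np.arange(n) / frame_rate,
                         pos=pos, head_dir=np.zeros(n))
    return sv.Session(arena=arena, trajectories={"m0": traj},
                      raster=np.asarray(raster_rows, dtype=np.uint8),
                      subject="m0", seed=0)


# ---------------------------------------------------------------- binning

def test_rate_is_count_over_occupancy_in_single_bin():
    """All events in one bin with exactly 1 s of occupancy: raw rate = count."""
    fr = 30.0
    pos = np.concatenate([np.tile([1.0, 1.0], (30, 1)),       # 1 s in one bin
                          np.tile([-5.0, -5.0], (60, 1))])
    row = np.zeros(90, dtype=np.uint8)
    row[:30][[2, 9, 20]] = 1                                   # 3 events in that second
    ses = _grid_session(pos, [row], frame_rate=fr)
    from socialvec.config import AnalysisConfig
    cfg = AnalysisConfig(min_occupancy_s=0.0)
    rm = sv.build_rate_map(ses, 0, ses.frame_spec("self_allo"), cfg)
    iy, ix = np.unravel_index(np.nanargmax(rm.rate), rm.rate.shape)
    assert rm.occupancy[iy, ix] == pytest.approx(1.0)
    assert rm.rate[iy, ix] == pytest.approx(3.0)
    assert rm.event_count.sum() == row.sum()


def test_total_events_conserved_across_bins(pair_session):
    spec = pair_session.frame_spec("rel_ego")
    grid = MapGrid(pair_session, spec)
    for c in range(pair_session.n_cells):
        rm = sv.build_rate_map(pair_session, c, spec, grid=grid)
        on_grid = (grid.frame_bin >= 0) & (pair_session.raster[c] > 0)
        assert rm.event_count.sum() == on_grid.sum()


def test_uniform_rate_cell_gives_flat_smoothed_map(pair_session):
    """A cell firing on every frame has rate = frame_rate in every visited bin,
    and smoothing preserves constant maps exactly."""
    row = np.ones(pair_session.n_frames, dtype=np.uint8)
    rm = sv.build_rate_map(pair_session, row, pair_session.frame_spec("self_allo"))
    vis = rm.visited
    np.testing.assert_allclose(rm.rate[vis], 30.0, rtol=1e-9)
    np.testing.assert_allclose(rm.smoothed_rate[vis], 30.0, rtol=1e-9)
    assert rm.information == pytest.approx(0.0, abs=1e-9)


def test_empty_map_raises(pair_session):
    spec = pair_session.frame_spec("self_allo")
    with pytest.raises(EmptyMapError):
        sv.build_rate_map(pair_session, 0, spec,
                          frames_mask=np.zeros(pair_session.n_frames, bool))


# ---------------------------------------------------------------- smoothing

def test_smoothing_matches_direct_summation_oracle_with_holes(pair_session):
    """Visited-bin values of the smoothed map equal the brute-force
    occupancy-weighted renormalized convolution, including around unvisited
    holes in the effective arena."""
    spec = pair_session.frame_spec("rel_ego")
    grid = MapGrid(pair_session, spec)
    rm = sv.build_rate_map(pair_session, 12, spec, grid=grid)
    oracle = smoothing_oracle(rm.event_count, rm.occupancy,
                              rm.visited, grid.config.smooth_sd_bins)
    vis = rm.visited
    np.testing.assert_allclose(rm.smoothed_rate[vis], oracle[vis], rtol=1e-9)


def test_impulse_smooths_to_a_gaussian_bump():
    """Single-bin impulse under uniform occupancy: smoothed map peaks at the
    impulse and decays monotonically with a sigma = 2 bin profile."""
    side = np.arange(-9.0, 10.0, 2.0)  # 10 bins of 2 cm in a 20 cm box
    centers = [(x, y) for y in side for x in side]
    pos = np.repeat(np.asarray(centers), 6, axis=0)  # 0.2 s per bin
    n = len(pos)
    row = np.zeros(n, dtype=np.uint8)
    target = centers.index((1.0, 1.0))
    row[target * 6] = 1
    ses = _grid_session(pos, [row])
    from socialvec.config import AnalysisConfig
    cfg = AnalysisConfig(min_occupancy_s=0.0)
    rm = sv.build_rate_map(ses, 0, ses.frame_spec("self_allo"), cfg)
    iy, ix = np.unravel_index(np.nanargmax(rm.smoothed_rate), rm.smoothed_rate.shape)
    assert (rm.grid.centers[ix], rm.grid.centers[iy]) == (1.0, 1.0)
    profile = rm.smoothed_rate[iy, ix:]
    interior = profile[: len(profile) - 1]
    assert (np.diff(interior) < 0).all()
    # one sigma (2 bins) away the profile is ~exp(-0.5) of the peak
    assert profile[2] / profile[0] == pytest.approx(np.exp(-0.5), rel=0.15)


# ---------------------------------------------------------------- information

def test_information_matches_oracle_on_random_maps():
    rng = np.random.default_rng(0)
    for _ in range(100):
        nvis = rng.integers(4, 100)
        p = rng.random(nvis) + 1e-3
        lam = rng.random(nvis) * 3.0
        lam[rng.random(nvis) < 0.2] = 0.0
        if (p * lam).sum() == 0:
            lam[0] = 1.0
        grid = _tiny_grid(p)
        ours = grid.information(lam)
        assert ours == pytest.approx(information_oracle(p, lam), rel=1e-12, abs=1e-12)


def _tiny_grid(p):
    """Minimal stand-in exposing the information() interface of MapGrid."""
    g = MapGrid.__new__(MapGrid)
    nvis = len(p)
    g.visited = np.ones(nvis, dtype=bool)
    g.p = np.asarray(p, float) / np.asarray(p, float).sum()
    return g


def test_information_closed_form_two_bins():
    """p = (1/2, 1/2), rates (2, 0): I = 0.5 * 2 * log2(2) = 1 bit/event."""
    grid = _tiny_grid([0.5, 0.5])
    assert grid.information(np.array([2.0, 0.0])) == pytest.approx(1.0)


def test_information_nonnegative_and_zero_iff_constant():
    rng = np.random.default_rng(3)
    for _ in range(50):
        p = rng.random(30) + 1e-3
        lam = rng.random(30)
        grid = _tiny_grid(p)
        assert grid.information(lam) >= -1e-12
    grid = _tiny_grid(rng.random(30) + 1e-3)
    assert grid.information(np.full(30, 0.7)) == pytest.approx(0.0, abs=1e-12)


def test_silent_cell_information_is_undefined():
    grid = _tiny_grid([0.4, 0.6])
    assert np.isnan(grid.information(np.zeros(2)))


# ---------------------------------------------------------------- fields

def _fabricated_map(smoothed, pair_session):
    spec = pair_session.frame_spec("self_allo")
    grid = MapGrid(pair_session, spec)
    sm = np.asarray(smoothed, float)
    occ = np.where(np.isfinite(sm), 1.0, 0.0)
    return RateMap(spec=spec, bin_edges=np.arange(sm.shape[1] + 1) * 2.0,
                   occupancy=occ, event_count=np.zeros_like(occ),
                   rate=sm, smoothed_rate=sm, overall_rate_hz=1.0, grid=grid)


def test_flat_subthreshold_map_has_no_fields(pair_session):
    rm = _fabricated_map(np.full((8, 8), 0.3), pair_session)
    assert detect_fields(rm) == []


def test_single_bump_field_area_follows_sixty_percent_contour(pair_session):
    sm = np.full((9, 9), 0.1)
    yy, xx = np.mgrid[0:9, 0:9]
    bump = 1.0 * np.exp(-((xx - 4) ** 2 + (yy - 4) ** 2) / (2 * 1.5**2))
    sm = np.maximum(sm, bump)
    rm = _fabricated_map(sm, pair_session)
    fields = detect_fields(rm)
    assert len(fields) == 1
    f = fields[0]
    assert f.peak_bin == (4, 4)
    expected_area = {tuple(rc) for rc in np.argwhere(sm > 0.6 * sm[4, 4])}
    assert set(f.area_bins) == expected_area
    assert f.size_cm2 == len(expected_area) * 4.0


def test_two_bumps_with_deep_trough_yield_disjoint_fields(pair_session):
    sm = np.full((7, 12), 0.05)
    sm[3, 2] = 1.0
    sm[3, 1] = sm[3, 3] = sm[2, 2] = sm[4, 2] = 0.7
    sm[3, 9] = 0.9
    sm[3, 8] = sm[3, 10] = sm[2, 9] = sm[4, 9] = 0.6
    rm = _fabricated_map(sm, pair_session)
    fields = detect_fields(rm)
    assert len(fields) == 2
    areas = [set(f.area_bins) for f in fields]
    assert areas[0].isdisjoint(areas[1])


def test_planted_field_recovered_within_one_bin(circle_arena):
    cell = sv.GroundTruthCell(frame="self_allo", field_centers=((10.0, -5.0),),
                              field_sd_cm=8.0, peak_rate_hz=3.0)
    ses = sv.make_session(circle_arena, [cell], duration_s=600.0, seed=21)
    rm = sv.build_rate_map(ses, 0, ses.frame_spec("self_allo"))
    fields = detect_fields(rm)
    assert fields
    top = max(fields, key=lambda f: f.peak_rate_hz)
    iy, ix = top.peak_bin
    assert abs(rm.grid.centers[ix] - 10.0) <= 3.0
    assert abs(rm.grid.centers[iy] + 5.0) <= 3.0


# ---------------------------------------------------------------- stability

def test_duplicated_halves_are_perfectly_stable(circle_arena):
    cell = sv.GroundTruthCell(frame="self_allo", field_centers=((5.0, 5.0),),
                              field_sd_cm=8.0, peak_rate_hz=3.0)
    base = sv.make_session(circle_arena, [cell], duration_s=300.0, seed=23)
    traj = base.trajectories["m0"]
    doubled = sv.Session(
        arena=circle_arena,
        trajectories={"m0": sv.Trajectory(
            frame_rate=traj.frame_rate,
            t=np.arange(2 * traj.n_frames) / traj.frame_rate,
            pos=np.tile(traj.pos, (2, 1)),
            head_dir=np.tile(traj.head_dir, 2),
            valid=np.tile(traj.valid, 2))},
        raster=np.tile(base.raster, (1, 2)),
        subject="m0", seed=0,
    )
    r = sv.split_half_stability(doubled, 0, doubled.frame_spec("self_allo"))
    assert r == pytest.approx(1.0, abs=1e-9)


def test_untuned_cells_have_near_zero_stability(pair_session):
    rs = [sv.split_half_stability(pair_session, c, pair_session.frame_spec("self_allo"))
          for c in range(16, 20)]
    assert abs(np.nanmean(rs)) < 0.2


def test_planted_field_exceeds_stability_cutoff(pair_session):
    r = sv.split_half_stability(pair_session, 0, pair_session.frame_spec("self_allo"))
    assert r > 0.3


# ---------------------------------------------------------------- radial profiles

def test_radial_density_flat_for_uniform_peaks(pair_session):
    spec = pair_session.frame_spec("rel_allo")
    grid = MapGrid(pair_session, spec)
    rng = np.random.default_rng(5)
    n_pts = 4000
    r = 40.0 * np.sqrt(rng.random(n_pts))
    th = rng.uniform(0, 2 * np.pi, n_pts)
    fields = []
    for x, y in zip(r * np.cos(th), r * np.sin(th)):
        ix = int(np.clip(np.searchsorted(grid.edges, x) - 1, 0, grid.shape[1] - 1))
        iy = int(np.clip(np.searchsorted(grid.edges, y) - 1, 0, grid.shape[0] - 1))
        fields.append([PlaceField(peak_bin=(iy, ix), peak_rate_hz=1.0,
                                  area_bins=frozenset([(iy, ix)]), size_cm2=16.0)])
    prof = sv.radial_field_density(fields, grid)
    interior = prof[prof.r_hi_cm <= 40.0]["density_per_cm2"]
    assert interior.std() / interior.mean() < 0.25

    empty = sv.radial_field_density([[]], grid)
    assert (empty["density_per_cm2"] == 0).all()
    beyond = prof[prof.r_lo_cm >= 100.0]
    assert (beyond["coverage"] == 0).all()
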