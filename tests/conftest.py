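import pytest

import socialvec as sv


@pytest.fixture(scope="session")
def circle_arena():
    return sv.ArenaGeometry.circle(70.0)


@pytest.fixture(scope="session")
def pair_session(circle_arena):
    """600 s two-mouse session with a few planted cells of every category."""
    truth = (
        sv.planted_population(circle_arena, "self_allo", 4, peak_rate_hz=2.0, seed=11)
        + sv.planted_population(circle_arena, "other_allo", 4, peak_rate_hz=2.0, seed=12)
        + sv.planted_population(circle_arena, "rel_allo", 4, peak_rate_hz=2.0, seed=13)
        + sv.planted_population(circle_arena, "rel_ego", 4, peak_rate_hz=2.0, seed=14)
        + sv.untuned_population(4, 0.1)
    )
    return sv.make_session(circle_arena, truth, duration_s=600.0, seed=101)


@pytest.fixture(scope="session")
def short_session(circle_arena):
    """Quick 120 s session for I/O and plumbing tests."""
    truth = sv.planted_population(circle_arena, "self_allo", 3, peak_rate_hz=2.0, seed=5)
    return sv.make_session(circle_arena, truth, duration_s=120.0, seed=7)


@pytest.fixture(scope="session")
def annulus_arena():
    return sv.ArenaGeometry.annulus(70.0, 50.0)


@pytest.fixture(scope="session")
def pursuit_session(annulus_arena):
    from socialvec.synth import generate_events, pursuit_population

    ses = sv.simulate_annular_pursuit(annulus_arena, n_trials=25,
                                      latency_profile=[8.0] * 25, seed=31)
    cells = pursuit_population(30, sd_deg=30.0, peak_rate_hz=1.5,
                               baseline_rate_hz=0.03, seed=32)
    ses.raster = generate_events(cells, ses, seed=33)
    ses.truth = cells
    return ses
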