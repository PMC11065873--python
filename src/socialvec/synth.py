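"""Synthetic sessions with known ground truth.

Emulates the study conditions the analysis was designed for: 10-minute
free-foraging sessions at 30 Hz in a 70 cm arena, two or three mice, head
direction aligned to motion with noise, and binarized calcium events drawn as
Bernoulli-per-frame thinning of a rate built from Gaussian tuning fields
planted in any of the four reference frames.

Seeding is hierarchical: a single session seed fans out through
``numpy.random.SeedSequence`` spawn keys so that adding cells never perturbs
trajectories and per-cell event trains are independent of cell ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .geometry import ArenaGeometry, Trajectory, frame_coordinates, wrap_angle
from .session import Session

_TRAJ_STREAM = 0
_EVENT_STREAM = 1


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


@dataclass(frozen=True)
class GroundTruthCell:
    """A planted cell: Gaussian tuning fields in one reference frame.

    ``referent_gains`` maps partner id -> gain in [0, 1]; for social frames the
    cell responds to each partner's position in its frame scaled by that gain
    (1 = fully tuned to that partner, 0 = blind to it).  ``self_allo`` cells
    ignore the mapping.
    """

    frame: str
    field_centers: tuple          # ((x, y), ...) cm, in the frame's coordinates
    field_sd_cm: float
    peak_rate_hz: float
    baseline_rate_hz: float = 0.02
    referent_gains: Optional[dict] = None

    def __post_init__(self):
        if not (self.peak_rate_hz >= self.baseline_rate_hz >= 0):
            raise ParameterError("require peak_rate >= baseline_rate >= 0")
        if self.field_sd_cm <= 0:
            raise ParameterError("field_sd must be positive")


@dataclass(frozen=True)
class AngleTunedCell:
    """A planted pursuit cell tuned to the signed track angle alpha (degrees).

    ``preferred_deg`` is signed: positive values tune counter-clockwise-travel
    frames, negative values clockwise ones (cells specialize in one direction).
    """

    preferred_deg: float
    sd_deg: float
    peak_rate_hz: float
    baseline_rate_hz: float = 0.02


def simulate_trajectory(
    arena: ArenaGeometry,
    duration_s: float = 600.0,
    frame_rate: float = 30.0,
    speed_target: float = 8.0,
    turning_sd: float = 1.6,
    head_dir_noise_sd: float = 0.25,
    seed: int = 0,
    _key: tuple = (),
) -> Trajectory:
    """Smooth confined foraging: correlated random walk with boundary avoidance.

    Heading performs a random walk (sd ``turning_sd`` rad/sqrt(s)) with a
    mean-reverting speed around ``speed_target``; steps that would leave the
    arena are redirected toward the arena-interior. Head direction is the
    motion heading plus Gaussian noise.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    if speed_target <= 0:
        raise ParameterError("speed_target must be positive")
    rng = _rng(seed, _TRAJ_STREAM, *_key)
    n = int(round(duration_s * frame_rate))
    dt = 1.0 / frame_rate

    if arena.shape == "annulus":
        r_mid = (arena.size_params[0] + arena.size_params[1]) / 4.0
        start = np.array([r_mid, 0.0])
    else:
        start = np.zeros(2)

    pos = np.empty((n, 2))
    heading = np.empty(n)
    pos[0] = start
    heading[0] = rng.uniform(-np.pi, np.pi)
    speed = speed_target
    dturn = rng.normal(0.0, turning_sd * np.sqrt(dt), size=n)
    dspeed = rng.normal(0.0, 0.35 * speed_target * np.sqrt(dt), size=n)
    margin = 1.0  # keep this far inside the wall, cm

    for i in range(1, n):
        speed += (speed_target - speed) * (dt / 0.5) + dspeed[i]
        speed = min(max(speed, 0.0), 4.0 * speed_target)
        h = heading[i - 1] + dturn[i]
        step = speed * dt * np.array([np.cos(h), np.sin(h)])
        cand = pos[i - 1] + step
        if not arena.contains(cand[None, :], margin=-margin)[0]:
            # turn toward the interior: arena center, or mid-track radius for annuli
            target = np.zeros(2)
            if arena.shape == "annulus":
                r = np.hypot(*pos[i - 1])
                r_mid = (arena.size_params[0] + arena.size_params[1]) / 4.0
                target = pos[i - 1] * (r_mid / max(r, 1e-9))
            h = np.arctan2(target[1] - pos[i - 1, 1], target[0] - pos[i - 1, 0])
            h += rng.normal(0.0, 0.3)
            cand = pos[i - 1] + speed * dt * np.array([np.cos(h), np.sin(h)])
            if not arena.contains(cand[None, :], margin=-margin)[0]:
                cand = pos[i - 1]
        pos[i] = cand
        heading[i] = h

    head_dir = wrap_angle(heading + rng.normal(0.0, head_dir_noise_sd, size=n))
    t = np.arange(n) * dt
    return Trajectory(frame_rate=frame_rate, t=t, pos=pos, head_dir=head_dir,
                      valid=np.ones(n, dtype=bool))


def simulate_pair(
    arena: ArenaGeometry,
    duration_s: float = 600.0,
    frame_rate: float = 30.0,
    attraction: float = 0.3,
    speed_target: float = 8.0,
    seed: int = 0,
) -> Dict[str, Trajectory]:
    """Two foraging mice; the second is biased toward the first.

    ``attraction`` in [0, 1] sets the fraction of the partner's heading drawn
    toward the imaged mouse each second; 0 yields independent walks.
    """
    if not (0.0 <= attraction <= 1.0):
        raise ParameterError("attraction must lie in [0, 1]")
    a = simulate_trajectory(arena, duration_s, frame_rate, speed_target=speed_target,
                            seed=seed, _key=(0,))
    b = simulate_trajectory(arena, duration_s, frame_rate, speed_target=speed_target,
                            seed=seed, _key=(1,))
    if attraction > 0.0:
        b = _steer_toward(b, a, arena, attraction, seed)
    return {"m0": a, "m1": b}


def _steer_toward(
    traj: Trajectory, target: Trajectory, arena: ArenaGeometry,
    attraction: float, seed: int,
) -> Trajectory:
    """Re-integrate a walk, blending its step directions toward another animal."""
    rng = _rng(seed, _TRAJ_STREAM, 2)
    n = traj.n_frames
    dt = 1.0 / traj.frame_rate
    steps = np.diff(traj.pos, axis=0)
    pos = np.empty_like(traj.pos)
    pos[0] = traj.pos[0]
    gain = attraction * dt / 0.5  # full re-orientation time constant 0.5 s
    for i in range(1, n):
        step = steps[i - 1]
        to_target = target.pos[i - 1] - pos[i - 1]
        d = np.hypot(*to_target)
        if d > 1e-9:
            step_len = np.hypot(*step)
            step = (1 - gain) * step + gain * (to_target / d) * step_len
        cand = pos[i - 1] + step
        if not arena.contains(cand[None, :], margin=-1.0)[0]:
            cand = pos[i - 1]
        pos[i] = cand
    heading = np.arctan2(*np.diff(pos, axis=0, prepend=pos[:1]).T[::-1])
    head_dir = wrap_angle(heading + rng.normal(0.0, 0.25, size=n))
    return Trajectory(frame_rate=traj.frame_rate, t=traj.t.copy(), pos=pos,
                      head_dir=head_dir, valid=np.ones(n, dtype=bool))


def simulate_multi(
    arena: ArenaGeometry,
    n_mice: int = 3,
    duration_s: float = 600.0,
    frame_rate: float = 30.0,
    speed_target: float = 8.0,
    seed: int = 0,
) -> Dict[str, Trajectory]:
    """Independent foraging walks for ``n_mice`` animals (m0 = imaged)."""
    return {
        f"m{i}": simulate_trajectory(
            arena, duration_s, frame_rate, speed_target=speed_target,
            seed=seed, _key=(i,),
        )
        for i in range(n_mice)
    }


def simulate_annular_pursuit(
    arena: ArenaGeometry,
    n_trials: int = 10,
    latency_profile: Optional[Sequence[float]] = None,
    frame_rate: float = 30.0,
    leader_speed_deg_s: float = 60.0,
    seed: int = 0,
) -> Session:
    """Leader/follower session on the annular track.

    The leader advances at a fixed angular speed whose sign (travel direction)
    varies across trials; the follower wanders until the trial's latency has
    elapsed, then locks a small trailing gap. Returns a session with
    trajectories and a trial table; the raster is empty (add cells with
    :func:`generate_events`).
    """
    if arena.shape != "annulus":
        raise ParameterError("pursuit simulation requires an annular arena")
    rng = _rng(seed, _TRAJ_STREAM, 9)
    if latency_profile is None:
        latency_profile = [10.0] * n_trials
    latencies = np.asarray(list(latency_profile), dtype=float)[:n_trials]
    if len(latencies) < n_trials:
        latencies = np.pad(latencies, (0, n_trials - len(latencies)), mode="edge")

    dt = 1.0 / frame_rate
    r_out, r_in = arena.size_params[0] / 2.0, arena.size_params[1] / 2.0
    r_mid = (r_out + r_in) / 2.0
    trial_pad_s = 5.0  # post-catch chase time per trial

    phi_leader, phi_follow, rows = [], [], []
    t0 = 0.0
    for k in range(n_trials):
        direction = 1 if rng.random() < 0.5 else -1
        omega = direction * np.deg2rad(leader_speed_deg_s)
        dur = latencies[k] + trial_pad_s
        m = int(round(dur * frame_rate))
        tt = np.arange(m) * dt
        pl = rng.uniform(-np.pi, np.pi) + omega * tt
        # follower: random drift during the search phase, then trailing lock
        search = tt < latencies[k]
        drift = np.cumsum(rng.normal(0.0, np.deg2rad(40) * np.sqrt(dt), size=m))
        pf = np.where(
            search,
            pl[0] + np.pi + drift,
            pl - direction * np.deg2rad(20.0),  # 20 deg behind along travel
        )
        phi_leader.append(pl)
        phi_follow.append(pf)
        rows.append(
            {"trial": k, "start_s": t0, "end_s": t0 + dur, "latency_s": latencies[k],
             "direction": "ccw" if direction > 0 else "cw"}
        )
        t0 += dur

    pl = np.concatenate(phi_leader)
    pf = np.concatenate(phi_follow)
    n = len(pl)
    t = np.arange(n) * dt
    r_noise = rng.normal(0.0, 0.8, size=(2, n))
    r_l = np.clip(r_mid + r_noise[0], r_in + 0.5, r_out - 0.5)
    r_f = np.clip(r_mid + r_noise[1], r_in + 0.5, r_out - 0.5)

    def polar(phi, r):
        return np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)

    # follower is the imaged mouse; head direction = tangent along its motion
    dphi = np.gradient(np.unwrap(pf))
    hd = wrap_angle(pf + np.sign(dphi + 1e-12) * np.pi / 2
                    + rng.normal(0.0, 0.15, size=n))
    follow = Trajectory(frame_rate=frame_rate, t=t, pos=polar(pf, r_f), head_dir=hd,
                        valid=np.ones(n, dtype=bool))
    leader = Trajectory(frame_rate=frame_rate, t=t, pos=polar(pl, r_l), head_dir=None,
                        valid=np.ones(n, dtype=bool))
    return Session(
        arena=arena,
        trajectories={"m0": follow, "m1": leader},
        raster=np.zeros((0, n), dtype=np.uint8),
        subject="m0",
        seed=seed,
        trial_table=pd.DataFrame(rows),
    )


def cell_rate_trace(cell, session: Session) -> np.ndarray:
    """Instantaneous event rate (Hz) of a planted cell along the session."""
    if isinstance(cell, AngleTunedCell):
        from .pursuit import compute_alpha

        alpha, travel, valid = compute_alpha(session)
        want_ccw = cell.preferred_deg >= 0
        match = valid & ((travel == 1) if want_ccw else (travel == -1))
        d = np.abs(alpha - cell.preferred_deg)
        bump = np.exp(-0.5 * (d / cell.sd_deg) ** 2)
        rate = cell.baseline_rate_hz + np.where(
            match, (cell.peak_rate_hz - cell.baseline_rate_hz) * bump, 0.0
        )
        return rate

    if cell.frame == "self_allo":
        referents = [None]
        gains = [1.0]
    else:
        gains_map = cell.referent_gains or {p: 1.0 for p in session.partners}
        referents = list(gains_map)
        gains = [gains_map[r] for r in referents]

    n = session.n_frames
    bump = np.zeros(n)
    for ref, gain in zip(referents, gains):
        if gain == 0.0:
            continue
        spec = session.frame_spec(cell.frame, ref)
        coords, valid = frame_coordinates(session.trajectories, spec)
        if cell.frame == "rel_ego" and session.trajectories[spec.subject].head_dir is None:
            raise ConfigError("egocentric truth cell but subject has no head direction")
        g = np.zeros(n)
        for c in cell.field_centers:
            d2 = ((coords - np.asarray(c, dtype=float)) ** 2).sum(axis=1)
            g = np.maximum(g, np.exp(-0.5 * d2 / cell.field_sd_cm**2))
        bump = np.maximum(bump, np.where(valid, gain * g, 0.0))
    return cell.baseline_rate_hz + (cell.peak_rate_hz - cell.baseline_rate_hz) * bump


def generate_events(
    truth: Sequence, session: Session, seed: int = 0
) -> np.ndarray:
    """Bernoulli-per-frame event raster from planted cells' rate traces.

    Per frame the event probability is ``min(rate * dt, 1)``; this matches the
    binarized frame raster the analysis consumes (at most one event per frame).
    """
    dt = session.dt
    raster = np.zeros((len(truth), session.n_frames), dtype=np.uint8)
    for i, cell in enumerate(truth):
        rng = _rng(seed, _EVENT_STREAM, i)
        p = np.clip(cell_rate_trace(cell, session) * dt, 0.0, 1.0)
        raster[i] = rng.random(session.n_frames) < p
    return raster


def make_session(
    arena: ArenaGeometry,
    truth: Sequence,
    duration_s: float = 600.0,
    frame_rate: float = 30.0,
    n_mice: int = 2,
    attraction: float = 0.3,
    seed: int = 0,
) -> Session:
    """Trajectories + events for a planted population, in one call."""
    if n_mice == 2:
        trajectories = simulate_pair(arena, duration_s, frame_rate,
                                     attraction=attraction, seed=seed)
    else:
        trajectories = simulate_multi(arena, n_mice, duration_s, frame_rate, seed=seed)
    session = Session(
        arena=arena,
        trajectories=trajectories,
        raster=np.zeros((0, int(round(duration_s * frame_rate))), dtype=np.uint8),
        subject="m0",
        seed=seed,
    )
    session.raster = generate_events(truth, session, seed=seed)
    session.truth = list(truth)
    return session


def planted_population(
    arena: ArenaGeometry,
    frame: str,
    n_cells: int,
    peak_rate_hz: float = 1.0,
    field_sd_cm: float = 8.0,
    baseline_rate_hz: float = 0.02,
    max_center_radius_cm: Optional[float] = None,
    referent_gains: Optional[dict] = None,
    seed: int = 0,
) -> List[GroundTruthCell]:
    """Cells of one category with field centers sampled uniformly in the frame.

    Relative-frame centers default to a disc of radius 25 cm around the animal,
    where relative positions are actually visited often enough to map.
    """
    rng = _rng(seed, _EVENT_STREAM, 99, {"self_allo": 0, "other_allo": 1,
                                         "rel_allo": 2, "rel_ego": 3}[frame])
    if frame in ("self_allo", "other_allo"):
        r_max = max_center_radius_cm or (arena.half_extent_cm - 2 * field_sd_cm)
    else:
        r_max = max_center_radius_cm or 25.0
    cells = []
    for _ in range(n_cells):
        r = r_max * np.sqrt(rng.random())
        th = rng.uniform(0, 2 * np.pi)
        cells.append(
            GroundTruthCell(
                frame=frame,
                field_centers=((r * np.cos(th), r * np.sin(th)),),
                field_sd_cm=field_sd_cm,
                peak_rate_hz=peak_rate_hz,
                baseline_rate_hz=baseline_rate_hz,
                referent_gains=referent_gains,
            )
        )
    return cells


def pursuit_population(
    n_cells: int,
    sd_deg: float,
    peak_rate_hz: float,
    baseline_rate_hz: float,
    seed: int = 0,
) -> List[AngleTunedCell]:
    """Angle-tuned cells with preferred angles covering both travel directions.

    Cells alternate between clockwise and counter-clockwise specialization;
    preferred |alpha| is uniform over (15, 345) degrees.  A "trained"
    population is modeled as sharper tuning (smaller ``sd_deg``) with
    suppressed off-field activity (lower baseline, higher peak), which keeps
    the mean event rate roughly constant while concentrating activity in the
    signal region.
    """
    rng = _rng(seed, _EVENT_STREAM, 98)
    cells = []
    for i in range(n_cells):
        pref = float(rng.uniform(15.0, 345.0))
        sign = 1.0 if i % 2 == 0 else -1.0
        cells.append(
            AngleTunedCell(preferred_deg=sign * pref, sd_deg=sd_deg,
                           peak_rate_hz=peak_rate_hz,
                           baseline_rate_hz=baseline_rate_hz)
        )
    return cells


def untuned_population(n_cells: int, rate_hz: float = 0.1) -> List[GroundTruthCell]:
    """Homogeneous Poisson-like cells with no spatial tuning (null model)."""
    return [
        GroundTruthCell(frame="self_allo", field_centers=((0.0, 0.0),),
                        field_sd_cm=1.0, peak_rate_hz=rate_hz, baseline_rate_hz=rate_hz)
        for _ in range(n_cells)
    ]
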