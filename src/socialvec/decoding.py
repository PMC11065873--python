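"""Naive-Bayes population decoding of position in any reference frame.

Under independent Poisson event counts, the posterior over spatial bins X for
a window with per-cell counts n is

    P(X | n) = C P(X) (prod_i f_i(X)^{n_i}) exp(-tau sum_i f_i(X))

with f_i(X) the cell's mean event rate per bin estimated from training data,
P(X) the training occupancy prior and tau the window length.  The decoded bin
is the maximum a posteriori; ties resolve to the lowest flat (row-major) bin
index.  Cross-validation uses five consecutive session segments, and baselines
come from re-running the full pipeline on circularly time-shifted positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import EmptyMapError, ParameterError
from .geometry import FrameSpec, Trajectory
from .ratemaps import MapGrid, _SubgridView
from .session import Session


@dataclass
class DecoderModel:
    spec: FrameSpec
    grid: MapGrid = field(repr=False)
    log_prior: np.ndarray          # (n_visited,)
    log_rates: np.ndarray          # (n_cells, n_visited)
    sum_rates: np.ndarray          # (n_visited,)
    visited_flat: np.ndarray       # flat indices into the full grid
    tau_s: float
    cells: np.ndarray


@dataclass
class DecodingResult:
    spec: FrameSpec
    mae_cm: float
    decoded_bin: np.ndarray        # flat grid index per window
    true_pos: np.ndarray           # (n_windows, 2) cm
    window_center: np.ndarray      # frame index per window
    shuffled_mae_cm: Optional[np.ndarray] = None
    status: str = "ok"


def fit_decoder(
    session: Session,
    cells: Sequence[int],
    spec: FrameSpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
    train_mask: Optional[np.ndarray] = None,
    grid: Optional[MapGrid] = None,
) -> DecoderModel:
    """Per-cell smoothed rate maps and occupancy prior from training frames."""
    cells = np.asarray(list(cells), dtype=int)
    if cells.size == 0:
        raise ParameterError("no cells to fit the decoder on")
    if grid is None:
        grid = MapGrid(session, spec, config)
    g = grid if train_mask is None else _SubgridView(grid, train_mask)
    if not g.visited.any():
        raise EmptyMapError("no visited bins in training data")
    vis = g.visited
    counts = np.stack([g.counts(session.raster[c]) for c in cells])
    rates = g.smooth_rate(counts)[:, vis]
    rates = np.maximum(np.nan_to_num(rates), config.rate_floor_hz)
    prior = g.occupancy[vis] / g.occupancy[vis].sum()
    return DecoderModel(
        spec=spec,
        grid=grid,
        log_prior=np.log(prior),
        log_rates=np.log(rates),
        sum_rates=rates.sum(axis=0),
        visited_flat=np.flatnonzero(vis),
        tau_s=config.tau_s,
        cells=cells,
    )


def decode_windows(model: DecoderModel, counts: np.ndarray) -> np.ndarray:
    """MAP bin (flat index into the full grid) per window.

    ``counts`` is (n_windows, n_cells) events per window.  The normalization C
    is irrelevant to the argmax.  Ties resolve to the lowest visited flat
    index, i.e. row-major order.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    logpost = (
        model.log_prior[None, :]
        + counts @ model.log_rates
        - model.tau_s * model.sum_rates[None, :]
    )
    return model.visited_flat[np.argmax(logpost, axis=1)]


def bin_centers_xy(grid: MapGrid, flat_idx: np.ndarray) -> np.ndarray:
    """Center-of-bin coordinates (cm) for flat grid indices."""
    n = grid.shape[1]
    r, c = np.divmod(np.asarray(flat_idx), n)
    return np.stack([grid.centers[c], grid.centers[r]], axis=-1)


def _window_counts(raster: np.ndarray, win: int) -> np.ndarray:
    """Sliding event counts: (n_frames - win + 1, n_cells), stride one frame."""
    cs = np.concatenate(
        [np.zeros((raster.shape[0], 1)), np.cumsum(raster, axis=1)], axis=1
    )
    return (cs[:, win:] - cs[:, :-win]).T


def _fold_bounds(n_frames: int, n_folds: int) -> List[tuple]:
    edges = np.linspace(0, n_frames, n_folds + 1).astype(int)
    return list(zip(edges[:-1], edges[1:]))


def cross_validated_decode(
    session: Session,
    cells: Sequence[int],
    spec: FrameSpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
    n_shuffles: Optional[int] = None,
    seed: Optional[int] = None,
    _grid: Optional[MapGrid] = None,
) -> DecodingResult:
    """5-fold contiguous cross-validated decoding with a position-shuffle baseline.

    Each fold's model is fit on the other four segments; every window lying
    entirely inside the held-out segment (and with a valid true position at its
    center frame) is decoded.  The baseline repeats the whole procedure on
    ``n_shuffles`` sessions whose positions were circularly displaced in time.
    """
    cells = list(cells)
    if len(cells) == 0:
        return DecodingResult(spec, np.nan, np.empty(0, int), np.empty((0, 2)),
                              np.empty(0, int), status="skipped: no cells")
    if n_shuffles is None:
        n_shuffles = config.n_position_shuffles
    if seed is None:
        seed = session.seed or 0

    mae, decoded, true_pos, centers = _cv_decode_once(session, cells, spec, config, _grid)

    shuffled = None
    if n_shuffles > 0:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(4,)))
        min_shift = int(round(config.min_shift_s * session.frame_rate))
        shuffled = np.empty(n_shuffles)
        for k in range(n_shuffles):
            shift = int(rng.integers(min_shift, session.n_frames - min_shift))
            shifted = _shift_positions(session, shift)
            shuffled[k] = _cv_decode_once(shifted, cells, spec, config, None)[0]
    return DecodingResult(spec, mae, decoded, true_pos, centers,
                          shuffled_mae_cm=shuffled)


def _shift_positions(session: Session, shift: int) -> Session:
    """Displace all trajectories circularly in time; the raster stays put."""
    traj = {
        k: Trajectory(
            frame_rate=v.frame_rate,
            t=v.t,
            pos=np.roll(v.pos, shift, axis=0),
            head_dir=None if v.head_dir is None else np.roll(v.head_dir, shift),
            valid=np.roll(v.valid, shift),
        )
        for k, v in session.trajectories.items()
    }
    return Session(arena=session.arena, trajectories=traj, raster=session.raster,
                   subject=session.subject, seed=session.seed,
                   metadata=session.metadata)


def _cv_decode_once(session, cells, spec, config, grid):
    if grid is None:
        grid = MapGrid(session, spec, config)
    win = max(int(round(config.tau_s * session.frame_rate)), 1)
    half_w = win // 2
    counts_all = _window_counts(session.raster[cells], win)   # start index t -> [t, t+win)
    n = session.n_frames

    decoded_parts, true_parts, center_parts = [], [], []
    for lo, hi in _fold_bounds(n, config.n_folds):
        train = np.ones(n, dtype=bool)
        train[lo:hi] = False
        try:
            model = fit_decoder(session, cells, spec, config,
                                train_mask=train, grid=grid)
        except EmptyMapError:
            continue
        starts = np.arange(lo, hi - win + 1)
        if starts.size == 0:
            continue
        centers = starts + half_w
        ok = grid.frame_bin[centers] >= 0
        starts, centers = starts[ok], centers[ok]
        if starts.size == 0:
            continue
        dec = decode_windows(model, counts_all[starts])
        decoded_parts.append(dec)
        center_parts.append(centers)
        true_parts.append(bin_centers_xy(grid, grid.frame_bin[centers]))

    if not decoded_parts:
        return np.nan, np.empty(0, int), np.empty((0, 2)), np.empty(0, int)
    decoded = np.concatenate(decoded_parts)
    true_pos = np.concatenate(true_parts)
    centers = np.concatenate(center_parts)
    err = np.linalg.norm(bin_centers_xy(grid, decoded) - true_pos, axis=1)
    return float(err.mean()), decoded, true_pos, centers


@dataclass
class CrossReferentResult:
    same_mae_cm: float
    cross_mae_cm: float
    shuffled_mae_cm: Optional[np.ndarray]


def cross_referent_decode(
    session: Session,
    cells: Sequence[int],
    frame: str = "rel_ego",
    train_referent: Optional[str] = None,
    test_referent: Optional[str] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    n_shuffles: int = 0,
    seed: Optional[int] = None,
) -> CrossReferentResult:
    """Identity decoding: train on one partner's relative position, test on both.

    Same-partner error is cross-validated; cross-partner error is a full
    transfer of the model fit on all of the training partner's data.  The
    optional shuffle baseline applies to the cross decode.
    """
    partners = session.partners
    if len(partners) < 2:
        raise ParameterError("cross-referent decoding needs two partners")
    a = train_referent or partners[0]
    b = test_referent or partners[1]
    spec_a = session.frame_spec(frame, a)
    spec_b = session.frame_spec(frame, b)

    same = cross_validated_decode(session, cells, spec_a, config,
                                  n_shuffles=0, seed=seed)
    cross_mae = _transfer_decode(session, cells, spec_a, spec_b, config)

    shuffled = None
    if n_shuffles > 0:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed or 0),
                                                           spawn_key=(5,)))
        min_shift = int(round(config.min_shift_s * session.frame_rate))
        shuffled = np.empty(n_shuffles)
        for k in range(n_shuffles):
            shift = int(rng.integers(min_shift, session.n_frames - min_shift))
            shifted = _shift_positions(session, shift)
            shuffled[k] = _transfer_decode(shifted, cells, spec_a, spec_b, config)
    return CrossReferentResult(same.mae_cm, cross_mae, shuffled)


def _transfer_decode(session, cells, spec_train, spec_test, config) -> float:
    model = fit_decoder(session, cells, spec_train, config)
    grid_test = MapGrid(session, spec_test, config)
    win = max(int(round(config.tau_s * session.frame_rate)), 1)
    counts = _window_counts(session.raster[cells], win)
    centers = np.arange(counts.shape[0]) + win // 2
    ok = grid_test.frame_bin[centers] >= 0
    if not ok.any():
        return np.nan
    dec = decode_windows(model, counts[ok])
    true_pos = bin_centers_xy(grid_test, grid_test.frame_bin[centers[ok]])
    err = np.linalg.norm(bin_centers_xy(model.grid, dec) - true_pos, axis=1)
    return float(err.mean())
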