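"""Shuffle-calibrated cell classification and the shuffling-in-place control.

A cell belongs to a category (selfPC / socialPC / alloSVC / egoSVC, one per
reference frame and referent, non-exclusive) when the spatial information of
its map exceeds the 95th percentile of the information distribution obtained
from 1000 circular time-shifts of its event train, and the split-half
stability of the map exceeds 0.3.

Shuffling-in-place is the false-positive control for social categories: it
permutes events within episodes of identical self-location (10 cm bins), which
preserves the self-place map at that resolution while destroying any
relative-position tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import ParameterError
from .geometry import FrameSpec
from .ratemaps import MapGrid, build_rate_map, split_half_stability
from .session import Session


def temporal_shuffle(row: np.ndarray, shift: int) -> np.ndarray:
    """Circularly displace an event train in time, wrapping around the end."""
    n = len(row)
    if not 0 < shift < n:
        raise ParameterError("shift must lie strictly between 0 and n_frames")
    return np.roll(row, shift)


def _shuffle_shifts(n_frames: int, n_shuffles: int, min_shift: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform circular shifts staying at least ``min_shift`` frames from identity."""
    lo = min(min_shift, max(n_frames // 4, 1))
    hi = n_frames - lo
    if hi <= lo:
        lo, hi = 1, n_frames - 1
    return rng.integers(lo, hi + 1, size=n_shuffles)


def _cell_frame_rng(session_seed: Optional[int], cell: int, frame_idx: int
                    ) -> np.random.Generator:
    """One independent stream per (cell, frame), so results do not depend on
    the order in which cells are processed."""
    base = 0 if session_seed is None else int(session_seed)
    return np.random.default_rng(
        np.random.SeedSequence(base, spawn_key=(2, int(cell), int(frame_idx)))
    )


@dataclass
class FrameResult:
    """Per-(cell, frame) classification evidence."""

    spec: FrameSpec
    information: float
    cutoff: float
    stability: float
    member: bool
    shuffle_values: Optional[np.ndarray] = field(default=None, repr=False)


@dataclass
class CellClassification:
    cell: int
    frames: Dict[str, FrameResult]      # keyed by "<frame>" or "<frame>:<referent>"
    n_events: int

    @property
    def categories(self) -> List[str]:
        out = []
        for key, res in self.frames.items():
            if res.member:
                cat = res.spec.category
                if res.spec.referent is not None and ":" in key:
                    out.append(f"{cat}:{res.spec.referent}")
                else:
                    out.append(cat)
        return out


def _frame_key(spec: FrameSpec, multi_referent: bool) -> str:
    if spec.referent is None or not multi_referent:
        return spec.frame
    return f"{spec.frame}:{spec.referent}"


def classify_cells(
    session: Session,
    specs: Optional[Sequence[FrameSpec]] = None,
    cells: Optional[Sequence[int]] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    seed: Optional[int] = None,
    keep_shuffles: bool = False,
) -> List[CellClassification]:
    """Classify cells in every requested reference frame.

    For each (cell, frame): information of the true (smoothed) map, the
    shuffle cutoff from ``config.n_shuffles`` circular shifts, split-half
    stability, and membership = information > cutoff and stability > cutoff.
    Cells with no events are members of nothing and carry NaN evidence.
    """
    if specs is None:
        specs = session.all_frame_specs()
    if cells is None:
        cells = range(session.n_cells)
    if seed is None:
        seed = session.seed
    multi_ref = len({s.referent for s in specs if s.referent}) > 1

    grids = {id(s): MapGrid(session, s, config) for s in specs}
    min_shift = int(round(config.min_shift_s * session.frame_rate))
    frame_order = {s.frame: i for i, s in
                   enumerate(session.all_frame_specs())}  # stable per-frame stream ids

    results: Dict[int, Dict[str, FrameResult]] = {c: {} for c in cells}
    for spec in specs:
        grid = grids[id(spec)]
        fidx = frame_order.get(spec.frame, 0) + 10 * (
            0 if spec.referent is None else session.partners.index(spec.referent)
        )
        for c in cells:
            row = session.raster[c]
            n_events = int(row.sum())
            if n_events == 0:
                results[c][_frame_key(spec, multi_ref)] = FrameResult(
                    spec, np.nan, np.nan, np.nan, False
                )
                continue
            rm = build_rate_map(session, c, spec, config, grid=grid)
            info = rm.information
            rng = _cell_frame_rng(seed, c, fidx)
            shifts = _shuffle_shifts(session.n_frames, config.n_shuffles, min_shift, rng)
            shuffled = grid.shuffled_information(row, shifts)
            cutoff = float(np.nanpercentile(shuffled, config.shuffle_percentile))
            stab = split_half_stability(session, c, spec, config, grid=grid)
            member = bool(
                np.isfinite(info) and info > cutoff
                and np.isfinite(stab) and stab > config.stability_cutoff
            )
            results[c][_frame_key(spec, multi_ref)] = FrameResult(
                spec, float(info), cutoff, float(stab), member,
                shuffled if keep_shuffles else None,
            )

    return [
        CellClassification(cell=c, frames=results[c],
                           n_events=int(session.raster[c].sum()))
        for c in cells
    ]


def classification_table(classifications: Sequence[CellClassification]) -> pd.DataFrame:
    """Long-format per-(cell, frame) summary table."""
    rows = []
    for cc in classifications:
        for key, res in cc.frames.items():
            rows.append(
                {"cell": cc.cell, "frame": key, "category": res.spec.category,
                 "referent": res.spec.referent, "information": res.information,
                 "cutoff": res.cutoff, "stability": res.stability,
                 "member": res.member, "n_events": cc.n_events}
            )
    return pd.DataFrame(rows)


def overlap_index(n_a: int, n_b: int, n_ab: int, n_total: int
                  ) -> tuple[float, float]:
    """Co-membership of two categories relative to independence.

    index = n_ab / (N * (n_a/N) * (n_b/N)); the p-value is a two-tailed exact
    binomial test of n_ab out of N at probability (n_a/N)(n_b/N).
    """
    if not (0 <= n_ab <= min(n_a, n_b) <= n_total):
        raise ParameterError("require n_ab <= min(n_a, n_b) <= n_total")
    if n_a == 0 or n_b == 0:
        return np.nan, np.nan
    p_ind = (n_a / n_total) * (n_b / n_total)
    index = n_ab / (n_total * p_ind)
    pval = stats.binomtest(n_ab, n_total, p_ind, alternative="two-sided").pvalue
    return float(index), float(pval)


def shuffle_in_place(
    session: Session,
    cell: int | np.ndarray,
    n_instances: Optional[int] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Permute an event train within episodes of identical self-location.

    The physical arena is divided into 10 cm bins; for each bin, the frames the
    imaged animal spent there are stitched in temporal order and the event
    values on them circularly shifted by a random amount at circular distance
    of at least 5 s from identity (or by the maximum-distance shift where the
    stitched array is too short).  Returns ``(n_instances, n_frames)`` rows.
    """
    row = session.raster[cell] if np.isscalar(cell) else np.asarray(cell)
    if n_instances is None:
        n_instances = config.sip_n_instances
    if seed is None:
        seed = session.seed or 0
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(3,)))

    subj = session.trajectories[session.subject]
    half = session.arena.half_extent_cm
    bs = config.sip_bin_cm
    n_side = int(np.ceil(2 * half / bs))
    ix = np.floor((subj.pos[:, 0] + half) / bs).astype(int)
    iy = np.floor((subj.pos[:, 1] + half) / bs).astype(int)
    inside = subj.valid & (ix >= 0) & (ix < n_side) & (iy >= 0) & (iy < n_side)
    flat = np.where(inside, iy * n_side + ix, -1)

    min_shift = int(round(config.sip_min_shift_s * session.frame_rate))
    out = np.tile(row, (n_instances, 1)).astype(row.dtype)
    for b in np.unique(flat[flat >= 0]):
        frames_b = np.flatnonzero(flat == b)
        length = len(frames_b)
        if length < 2:
            continue
        values = row[frames_b]
        feasible = np.arange(1, length)
        feasible = feasible[np.minimum(feasible, length - feasible) >= min_shift]
        for inst in range(n_instances):
            s = int(rng.choice(feasible)) if feasible.size else length // 2
            out[inst, frames_b] = np.roll(values, s)
    return out
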