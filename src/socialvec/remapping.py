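"""Identity, familiarity and context comparisons of social-vector maps.

Two complementary tools: split-half map correlations, where the two half-maps
may refer to the same or to different partners (identity coding), and the
normalized population-vector dot product, which compares mean event rates
across contexts whose maps are not geometrically commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import EmptyMapError, ParameterError
from .ratemaps import build_rate_map, map_correlation
from .session import Session


def session_half_splitter(session: Session) -> tuple[Session, Session]:
    """Contiguous halves with all channels sliced consistently; an odd frame
    count leaves the extra frame in the first half."""
    return session.half_sessions()


def half_map_correlation(
    session: Session,
    cell: int,
    referent_first_half: str,
    referent_second_half: str,
    frame: str = "rel_ego",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Pearson r between smoothed half-maps, same- or cross-referent.

    The first half-map uses the relative position of ``referent_first_half``,
    the second that of ``referent_second_half``; both maps live on the same
    effective-arena grid, so cross-referent pairings are directly comparable.
    """
    spec1 = session.frame_spec(frame, referent_first_half)
    spec2 = session.frame_spec(frame, referent_second_half)
    n = session.n_frames
    cut = (n + 1) // 2
    first = np.zeros(n, dtype=bool)
    first[:cut] = True
    try:
        m1 = build_rate_map(session, cell, spec1, config, frames_mask=first)
        m2 = build_rate_map(session, cell, spec2, config, frames_mask=~first)
    except EmptyMapError:
        return np.nan
    return map_correlation(m1.smoothed_rate, m2.smoothed_rate)


@dataclass
class PopulationVector:
    """Per-cell mean event rates of one condition, normalized for comparison.

    Construct matched vectors with :func:`population_vectors`; ``values`` is
    unit-norm with per-cell entries in [0, 1] before the vector normalization.
    """

    cell_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_ids.shape != self.values.shape:
            raise ParameterError("cell ids and values must align")


def mean_event_rates(session: Session, cells: Sequence[int]) -> np.ndarray:
    """Mean event rate (Hz) per cell: total events / session duration."""
    return session.raster[list(cells)].sum(axis=1) / session.duration_s


def population_vectors(
    rate_sets: Sequence[np.ndarray],
    cell_ids: Optional[Sequence] = None,
) -> list[PopulationVector]:
    """Normalized population vectors for a set of matched conditions.

    Each cell's rates are divided by that cell's maximum across *these*
    conditions, then each condition's vector by its Euclidean norm.  Cells
    silent in every condition are dropped (they carry no comparison signal).
    """
    rates = np.stack([np.asarray(r, dtype=float) for r in rate_sets])
    if cell_ids is None:
        cell_ids = np.arange(rates.shape[1])
    cell_ids = np.asarray(cell_ids)
    cell_max = rates.max(axis=0)
    keep = cell_max > 0
    rates = rates[:, keep] / cell_max[keep]
    out = []
    for cond in rates:
        norm = np.linalg.norm(cond)
        if norm == 0:
            raise ParameterError("population vector is all-zero after normalization")
        out.append(PopulationVector(cell_ids[keep], cond / norm))
    return out


def population_dot_product(vec_a: PopulationVector, vec_b: PopulationVector) -> float:
    """Cosine similarity of two matched population vectors (in [0, 1])."""
    if vec_a.values.shape != vec_b.values.shape or \
            not np.array_equal(vec_a.cell_ids, vec_b.cell_ids):
        raise ParameterError("population vectors must share the same cells")
    return float(np.dot(vec_a.values, vec_b.values))


def context_similarity(
    session_a: Session,
    session_b: Session,
    cells: Sequence[int],
) -> dict:
    """Within- vs cross-context similarity from session halves.

    Splits both sessions in halves, builds mean-rate vectors per half
    (normalizing each cell over the union of the four halves), and returns the
    dot products between first and second halves of the same session and
    across sessions.
    """
    halves = list(session_a.half_sessions()) + list(session_b.half_sessions())
    rates = [mean_event_rates(h, cells) for h in halves]
    vecs = population_vectors(rates)
    a1, a2, b1, b2 = vecs
    return {
        "within_a": population_dot_product(a1, a2),
        "within_b": population_dot_product(b1, b2),
        "cross_ab": population_dot_product(a1, b2),
        "cross_ba": population_dot_product(b1, a2),
    }
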