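"""Annular-track analysis: signed angle alpha, 1-D angle maps, tuning metrics,
population autocorrelogram and naive/trained session labeling.

On the annulus the geometry collapses to one dimension: alpha is the angular
separation between the two animals measured along the track *in the direction
of travel* of the imaged mouse, unwrapped to [0, 360) degrees, and negated for
clockwise travel.  Values near 0 mean the partner is just ahead; absolute
values near 360 mean just behind.  Each cell's angle map has two halves of 24
15-degree bins — clockwise (-360, 0] and counter-clockwise [0, 360) — each
smoothed circularly with a Gaussian of sd one bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import ParameterError
from .session import Session

N_HALF_BINS = 24  # per travel direction, at 15 degrees per bin


def travel_direction(session: Session, config: AnalysisConfig = DEFAULT_CONFIG
                     ) -> np.ndarray:
    """Per-frame travel direction of the imaged mouse: +1 ccw, -1 cw.

    Sign of the angular velocity about the arena center, boxcar-smoothed over
    ``omega_smooth_s``; frames below the dead-band inherit the last confident
    direction (the first confident one at the session start).
    """
    subj = session.trajectories[session.subject]
    theta = np.unwrap(np.arctan2(subj.pos[:, 1], subj.pos[:, 0]))
    omega = np.gradient(theta) * session.frame_rate  # rad/s
    win = max(int(round(config.omega_smooth_s * session.frame_rate)), 1)
    kernel = np.ones(win) / win
    omega = np.convolve(omega, kernel, mode="same")
    confident = np.abs(omega) >= np.deg2rad(config.omega_deadband_deg_s)
    direction = np.where(omega >= 0, 1, -1).astype(np.int8)
    if not confident.any():
        return direction
    idx = np.where(confident, np.arange(len(omega)), -1)
    last = np.maximum.accumulate(idx)
    first_conf = np.flatnonzero(confident)[0]
    last[last < 0] = first_conf
    return direction[last]


def compute_alpha(
    session: Session,
    config: AnalysisConfig = DEFAULT_CONFIG,
    referent: Optional[str] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed along-track angle per frame.

    Returns ``(alpha_deg, travel, valid)``: alpha in [0, 360) on ccw frames and
    (-360, 0] on cw frames, travel in {+1 ccw, -1 cw}, and a validity mask
    (both animals on the track).
    """
    if session.arena.shape != "annulus":
        raise ParameterError("alpha is defined on the annular track")
    subj = session.trajectories[session.subject]
    other = session.trajectories[referent or session.partners[0]]
    r_out = session.arena.size_params[0] / 2.0
    r_in = session.arena.size_params[1] / 2.0

    r_s = np.hypot(subj.pos[:, 0], subj.pos[:, 1])
    r_o = np.hypot(other.pos[:, 0], other.pos[:, 1])
    on_track = (r_s >= r_in) & (r_s <= r_out) & (r_o >= r_in) & (r_o <= r_out)
    valid = subj.valid & other.valid & on_track

    th_s = np.arctan2(subj.pos[:, 1], subj.pos[:, 0])
    th_o = np.arctan2(other.pos[:, 1], other.pos[:, 0])
    delta = np.rad2deg(th_o - th_s)
    travel = travel_direction(session, config)
    ccw_alpha = np.mod(delta, 360.0)            # [0, 360)
    cw_alpha = -np.mod(-delta, 360.0)           # (-360, 0]
    alpha = np.where(travel > 0, ccw_alpha, cw_alpha)
    return alpha, travel, valid


@dataclass
class AngleMap:
    """Two-half 1-D tuning curve: 24 cw bins (-360, 0], then 24 ccw bins [0, 360)."""

    bin_edges_deg: np.ndarray       # 49 edges from -360 to 360
    occupancy_s: np.ndarray         # (48,)
    event_count: np.ndarray
    rate: np.ndarray                # Hz, NaN on unvisited bins
    smoothed_rate: np.ndarray

    @property
    def centers_deg(self) -> np.ndarray:
        return (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:]) / 2.0

    @property
    def halves(self) -> tuple[np.ndarray, np.ndarray]:
        return self.smoothed_rate[:N_HALF_BINS], self.smoothed_rate[N_HALF_BINS:]


def _circular_smooth(rate: np.ndarray, occupied: np.ndarray, sd_bins: float
                     ) -> np.ndarray:
    """Occupancy-aware circular Gaussian smoothing of one half-map."""
    filled = np.where(occupied, rate, 0.0)
    num = ndimage.gaussian_filter1d(filled, sd_bins, mode="wrap")
    den = ndimage.gaussian_filter1d(occupied.astype(float), sd_bins, mode="wrap")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[~occupied] = np.nan
    return out


def build_angle_map(
    session: Session,
    cell: int | np.ndarray,
    config: AnalysisConfig = DEFAULT_CONFIG,
    referent: Optional[str] = None,
    alpha_cache: Optional[tuple] = None,
) -> AngleMap:
    """Occupancy-normalized event rate per 15-degree alpha bin, per travel half."""
    row = session.raster[cell] if np.isscalar(cell) else np.asarray(cell)
    alpha, travel, valid = alpha_cache or compute_alpha(session, config, referent)
    edges = np.linspace(-360.0, 360.0, 2 * N_HALF_BINS + 1)

    idx = np.clip(np.floor((alpha + 360.0) / config.angle_bin_deg), 0,
                  2 * N_HALF_BINS - 1).astype(int)
    idx = np.where(valid, idx, -1)
    nb = 2 * N_HALF_BINS
    occ = np.bincount(idx[idx >= 0], minlength=nb) * session.dt
    ev = (idx >= 0) & (row > 0)
    counts = np.bincount(idx[ev], minlength=nb).astype(float)
    occupied = occ > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occupied, counts / np.where(occupied, occ, np.inf), np.nan)

    smoothed = np.full(nb, np.nan)
    for sl in (slice(0, N_HALF_BINS), slice(N_HALF_BINS, nb)):
        if occupied[sl].any():
            smoothed[sl] = _circular_smooth(
                np.nan_to_num(rate[sl]), occupied[sl], config.angle_smooth_sd_bins
            )
    return AngleMap(bin_edges_deg=edges, occupancy_s=occ, event_count=counts,
                    rate=rate, smoothed_rate=smoothed)


def angle_map_information(amap: AngleMap) -> float:
    """Information per event of the full (both-halves) smoothed angle map."""
    occupied = np.isfinite(amap.smoothed_rate) & (amap.occupancy_s > 0)
    if not occupied.any():
        return np.nan
    p = amap.occupancy_s[occupied] / amap.occupancy_s[occupied].sum()
    lam = amap.smoothed_rate[occupied]
    lbar = lam @ p
    if lbar <= 0:
        return np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(lam > 0, lam * np.log2(lam / lbar), 0.0)
    return float((term @ p) / lbar)


@dataclass
class PeakMetrics:
    peak_angle_deg: float
    half_width_deg: float
    signal_fraction: float
    untuned: bool

    @property
    def snr_activity_ratio(self) -> float:
        """Signal-region activity against the rest: f / (1 - f)."""
        if self.signal_fraction >= 1.0:
            return np.inf
        return self.signal_fraction / (1.0 - self.signal_fraction)


def peak_metrics(amap: AngleMap) -> PeakMetrics:
    """Peak angle, half-decay width, and fraction of activity in the signal region.

    The signal region is the contiguous run of bins around the peak (circular
    within the peak's travel half) whose rate stays at or above half the peak
    rate; a region spanning the whole half marks the map as untuned.
    """
    sm = np.nan_to_num(amap.smoothed_rate, nan=-np.inf)
    if not np.isfinite(sm).any() or np.nanmax(amap.smoothed_rate) <= 0:
        raise ParameterError("peak metrics of an all-zero or empty map")
    peak = int(np.argmax(sm))
    half = slice(0, N_HALF_BINS) if peak < N_HALF_BINS else slice(N_HALF_BINS, None)
    hvals = np.nan_to_num(amap.smoothed_rate[half])
    p = peak % N_HALF_BINS
    thr = 0.5 * hvals[p]
    in_region = np.zeros(N_HALF_BINS, dtype=bool)
    in_region[p] = True
    for step in (1, -1):
        i = p
        for _ in range(N_HALF_BINS - 1):
            i = (i + step) % N_HALF_BINS
            if hvals[i] >= thr and not in_region[i]:
                in_region[i] = True
            else:
                break
    untuned = in_region.all()
    total = np.nansum(np.where(np.isfinite(amap.smoothed_rate),
                               amap.smoothed_rate, 0.0))
    region_total = hvals[in_region].sum()
    bin_width = 720.0 / (2 * N_HALF_BINS)
    return PeakMetrics(
        peak_angle_deg=float(amap.centers_deg[peak]),
        half_width_deg=float(in_region.sum() * bin_width),
        signal_fraction=float(region_total / total) if total > 0 else np.nan,
        untuned=bool(untuned),
    )


def population_autocorrelogram(
    maps: Sequence[AngleMap],
    max_shift_bins: int = 12,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Correlation of stacked angle maps with per-half circular shifts.

    Returns ``(shifts_deg, correlation, auc)`` for shifts from -180 to +180
    degrees; each half shifts independently (circularly within its 24 bins) and
    the Pearson correlation pools both halves of all cells.  The AUC is the
    mean correlation over the shift range, so it is comparable across grids.
    """
    if len(maps) < 2:
        raise ParameterError("population autocorrelogram needs at least two maps")
    mat = np.stack([m.smoothed_rate for m in maps])          # (cells, 48)
    cw, ccw = mat[:, :N_HALF_BINS], mat[:, N_HALF_BINS:]
    shifts = np.arange(-max_shift_bins, max_shift_bins + 1)
    corr = np.empty(len(shifts))
    for j, s in enumerate(shifts):
        shifted = np.concatenate(
            [np.roll(cw, s, axis=1), np.roll(ccw, s, axis=1)], axis=1
        )
        a, b = mat.ravel(), shifted.ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        corr[j] = np.corrcoef(a[ok], b[ok])[0, 1]
    return shifts * 15.0, corr, float(np.mean(corr))


@dataclass(frozen=True)
class SessionLabel:
    day: int
    median_latency_s: float
    label: str  # 'naive' | 'trained'


def label_sessions(latencies_per_day: Sequence[Sequence[float]],
                   config: AnalysisConfig = DEFAULT_CONFIG) -> List[SessionLabel]:
    """Naive/trained labels from daily latency profiles.

    The first day is always naive; the first day whose median latency falls
    below 30% of the previous day's maximum latency is day 0 of training, and
    that day and all later ones are trained.
    """
    if len(latencies_per_day) == 0:
        raise ParameterError("need at least one day of latencies")
    labels: List[SessionLabel] = []
    trained = False
    prev_max = None
    for day, lats in enumerate(latencies_per_day):
        lats = np.asarray(list(lats), dtype=float)
        med = float(np.median(lats))
        if day > 0 and not trained and prev_max is not None:
            if med < config.trained_latency_fraction * prev_max:
                trained = True
        labels.append(SessionLabel(day=day, median_latency_s=med,
                                   label="trained" if trained else "naive"))
        prev_max = float(np.max(lats))
    return labels


def experience_curve(
    maps_per_session: Sequence[Sequence[AngleMap]],
    group_size: Optional[int] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, float, float]:
    """Autocorrelogram AUC for non-overlapping groups of consecutive sessions.

    Returns ``(auc_per_group, pearson_r, p_value)`` where the trend test is a
    two-tailed Pearson correlation of AUC against group index.
    """
    gs = group_size or config.session_group_size
    groups = [maps_per_session[i:i + gs]
              for i in range(0, len(maps_per_session), gs)]
    groups = [g for g in groups if sum(len(m) for m in g) >= 2]
    if len(groups) < 2:
        raise ParameterError("need at least two groups of sessions")
    aucs = []
    for g in groups:
        pooled = [m for sess in g for m in sess]
        aucs.append(population_autocorrelogram(pooled)[2])
    aucs = np.asarray(aucs)
    r, p = stats.pearsonr(np.arange(len(aucs)), aucs)
    return aucs, float(r), float(p)
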