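"""Occupancy and event-rate maps in any reference frame.

A rate map bins the session's coordinates-in-frame into a square grid
(2 cm bins in physical frames; 4 cm bins in the doubled effective arena of
relative positions), accumulates occupancy time and event counts over valid
frames, and smooths the rate with a visitation-renormalized 2-D Gaussian
kernel (sd 2 bins).  Unvisited bins stay NaN throughout; they never enter the
information sum or map correlations.

The spatial information content per event is

    I = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda)

with p_i the normalized occupancy, lambda_i the bin rate and lambda the
occupancy-weighted mean rate, so I is a weighted KL divergence and is
non-negative by construction.

``MapGrid`` caches everything that is constant across cells and shuffles of a
given (session, frame): per-frame bin indices, occupancy, the visited mask and
the smoothing-kernel normalization.  ``shuffled_information`` evaluates the
information of many circularly time-shifted event trains in one vectorized
pass; the shuffle machinery in :mod:`socialvec.classify` is built on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import EmptyMapError
from .geometry import FrameSpec, effective_arena, frame_coordinates
from .session import Session


def _gauss_smooth(stack: np.ndarray, sd_bins: float) -> np.ndarray:
    """Gaussian filter over the last two axes, zero-padded boundaries."""
    sigma = (0,) * (stack.ndim - 2) + (sd_bins, sd_bins)
    return ndimage.gaussian_filter(stack, sigma=sigma, mode="constant", cval=0.0)


class MapGrid:
    """Binning geometry plus per-session accumulators for one reference frame."""

    def __init__(self, session: Session, spec: FrameSpec,
                 config: AnalysisConfig = DEFAULT_CONFIG):
        self.spec = spec
        self.config = config
        if spec.is_relative:
            eff = effective_arena(session.arena, config.bin_size_cm)
            half, bin_size = eff.half_extent_cm, config.rel_bin_size_cm
        else:
            half, bin_size = session.arena.half_extent_cm, config.bin_size_cm
        self.bin_size_cm = float(bin_size)
        n = int(np.ceil(2 * half / bin_size - 1e-9))
        self.shape = (n, n)                      # (rows=y, cols=x)
        self.edges = -half + bin_size * np.arange(n + 1)
        self.centers = self.edges[:-1] + bin_size / 2.0
        self.dt = session.dt

        coords, valid = frame_coordinates(session.trajectories, spec)
        ix = np.floor((coords[:, 0] + half) / bin_size).astype(np.int64)
        iy = np.floor((coords[:, 1] + half) / bin_size).astype(np.int64)
        inside = valid & (ix >= 0) & (ix < n) & (iy >= 0) & (iy < n)
        flat = np.where(inside, iy * n + ix, -1)
        self.frame_bin = flat                    # (n_frames,), -1 where unusable
        self.n_bins = n * n

        occ_counts = np.bincount(flat[inside], minlength=self.n_bins)
        self._finish_init(occ_counts)

    def _finish_init(self, occ_counts: np.ndarray) -> None:
        self.occupancy = occ_counts.astype(float) * self.dt       # seconds, flat
        thr = self.config.min_occupancy_s
        self.visited = (self.occupancy >= thr - 1e-12) if thr > 0 else occ_counts > 0
        self._occ_safe = np.where(self.visited, self.occupancy, np.inf)
        tot = self.occupancy[self.visited].sum()     # p normalized over analyzed bins
        self.p = np.where(self.visited, self.occupancy / tot, 0.0) if tot > 0 \
            else np.zeros(self.n_bins)
        # occupancy-weighted kernel normalization: smoothed rate = G(counts)/G(occ)
        sm_occ = _gauss_smooth(self.occupancy.reshape(self.shape),
                               self.config.smooth_sd_bins).ravel()
        self._sm_occ_vis = sm_occ[self.visited]
        self._vis_idx = np.flatnonzero(self.visited)
        self._p_vis = self.p[self.visited].astype(np.float32)

    # ------------------------------------------------------------------ counts
    def counts(self, row: np.ndarray,
               frames_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Event count per bin (flat) for one raster row."""
        fb = self.frame_bin
        sel = (fb >= 0) & (row > 0)
        if frames_mask is not None:
            sel &= frames_mask
        return np.bincount(fb[sel], minlength=self.n_bins).astype(float)

    def smooth_rate(self, counts: np.ndarray) -> np.ndarray:
        """Occupancy-weighted smoothed rate map(s): G(counts)/G(occupancy).

        The kernel mass is renormalized over visited bins weighted by the time
        spent there, so constant-rate maps are preserved exactly and
        single-frame visits do not blow up.  NaN off visited bins.  Accepts a
        flat (n_bins,) vector or a (k, n_bins) stack; smoothing is linear so
        stacks share one filter call.
        """
        counts = np.asarray(counts, dtype=float)
        single = counts.ndim == 1
        stack = counts[None, :] if single else counts
        num = _gauss_smooth(stack.reshape(-1, *self.shape), self.config.smooth_sd_bins)
        sm = np.full(stack.shape, np.nan)
        sm[:, self._vis_idx] = num.reshape(stack.shape[0], self.n_bins)[:, self._vis_idx] \
            / self._sm_occ_vis
        return sm[0] if single else sm

    def _smoothed_vis(self, counts: np.ndarray) -> np.ndarray:
        """Smoothed rates over visited bins only (fused fast path)."""
        num = _gauss_smooth(counts.reshape(-1, *self.shape),
                            self.config.smooth_sd_bins)
        return num.reshape(counts.shape[0], self.n_bins)[:, self._vis_idx] \
            / self._sm_occ_vis

    def information(self, rates: np.ndarray) -> np.ndarray:
        """Spatial information (bits/event) of rate map(s) over visited bins.

        Returns NaN where the map has zero mean rate.
        """
        rates = np.asarray(rates, dtype=float)
        single = rates.ndim == 1
        lam = (rates[None, :] if single else rates)[:, self.visited]
        p = self.p[self.visited]
        lbar = lam @ p
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(lam > 0, lam * np.log2(lam / lbar[:, None]), 0.0)
            info = (term @ p) / lbar
        info = np.where(lbar > 0, info, np.nan)
        return float(info[0]) if single else info

    # --------------------------------------------------------------- shuffles
    def shuffled_information(self, row: np.ndarray, shifts: np.ndarray) -> np.ndarray:
        """Information of circular time-shifts of an event train, one per shift.

        Single-precision fused path: counts are binned per shift in one
        bincount, smoothed in one separable filter call, and reduced to the
        information statistic without materializing full maps.
        """
        ev = np.flatnonzero(row)
        n_frames = len(self.frame_bin)
        shifts = np.asarray(shifts, dtype=np.int64)
        k = len(shifts)
        if ev.size == 0:
            return np.full(k, np.nan)
        idx = self.frame_bin[(ev[None, :] + shifts[:, None]) % n_frames]
        flat = (np.arange(k, dtype=np.int64)[:, None] * self.n_bins + idx)[idx >= 0]
        counts = np.bincount(flat, minlength=k * self.n_bins).astype(np.float32)
        num = _gauss_smooth(counts.reshape(k, *self.shape), self.config.smooth_sd_bins)
        lam = num.reshape(k, self.n_bins)[:, self._vis_idx]
        lam /= self._sm_occ_vis.astype(np.float32)
        p = self._p_vis
        lbar = lam @ p
        good = lbar > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            term = lam * np.log2(lam / lbar[:, None])
        term[lam <= 0] = 0.0
        info = np.full(k, np.nan)
        info[good] = (term @ p)[good] / lbar[good]
        return info


@dataclass
class RateMap:
    """Occupancy, counts, raw and smoothed rate for one cell in one frame."""

    spec: FrameSpec
    bin_edges: np.ndarray            # shared by both axes
    occupancy: np.ndarray            # seconds, 2-D (ny, nx)
    event_count: np.ndarray          # 2-D
    rate: np.ndarray                 # Hz, NaN off visited bins
    smoothed_rate: np.ndarray        # Hz, NaN off visited bins
    overall_rate_hz: float
    grid: MapGrid = field(repr=False, default=None)

    @property
    def bin_size_cm(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def visited(self) -> np.ndarray:
        return np.isfinite(self.rate)

    @property
    def information(self) -> float:
        src = self.smoothed_rate if self.grid.config.info_on_smoothed else self.rate
        return self.grid.information(np.where(np.isfinite(src), src, 0.0).ravel())


def build_rate_map(
    session: Session,
    cell: int | np.ndarray,
    spec: FrameSpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
    frames_mask: Optional[np.ndarray] = None,
    grid: Optional[MapGrid] = None,
) -> RateMap:
    """Rate map of one cell (index or raster row) in one reference frame."""
    row = session.raster[cell] if np.isscalar(cell) else np.asarray(cell)
    if grid is None:
        grid = MapGrid(session, spec, config)
    if frames_mask is None:
        occ_flat, visited, p = grid.occupancy, grid.visited, None
        sub = grid
    else:
        sub = _SubgridView(grid, frames_mask)
        occ_flat, visited = sub.occupancy, sub.visited
    if not visited.any():
        raise EmptyMapError("no valid frames fall inside the map grid")
    counts = grid.counts(row, frames_mask)
    with np.errstate(invalid="ignore"):
        rate = np.where(visited, counts / np.where(visited, occ_flat, np.inf), np.nan)
    smoothed = sub.smooth_rate(counts)
    shape = grid.shape
    total_time = occ_flat.sum()
    return RateMap(
        spec=spec,
        bin_edges=grid.edges,
        occupancy=occ_flat.reshape(shape),
        event_count=counts.reshape(shape),
        rate=rate.reshape(shape),
        smoothed_rate=smoothed.reshape(shape),
        overall_rate_hz=float(counts.sum() / total_time) if total_time > 0 else np.nan,
        grid=sub,
    )


class _SubgridView(MapGrid):
    """A MapGrid restricted to a subset of frames (folds, session halves)."""

    def __init__(self, parent: MapGrid, frames_mask: np.ndarray):
        # rebuild only the frame-dependent accumulators; geometry is shared
        self.spec = parent.spec
        self.config = parent.config
        self.bin_size_cm = parent.bin_size_cm
        self.shape = parent.shape
        self.edges = parent.edges
        self.centers = parent.centers
        self.dt = parent.dt
        self.n_bins = parent.n_bins
        self.frame_bin = np.where(frames_mask, parent.frame_bin, -1)
        occ_counts = np.bincount(self.frame_bin[self.frame_bin >= 0],
                                 minlength=self.n_bins)
        self._finish_init(occ_counts)


def spatial_information(rate_map: RateMap) -> float:
    """Eq.-1 information (bits/event) of a map; NaN when the cell is silent."""
    return rate_map.information


@dataclass(frozen=True)
class PlaceField:
    peak_bin: tuple                 # (row, col)
    peak_rate_hz: float
    area_bins: frozenset            # {(row, col), ...}
    size_cm2: float

    @property
    def n_bins(self) -> int:
        return len(self.area_bins)


def detect_fields(
    rate_map: RateMap,
    peak_threshold_hz: Optional[float] = None,
    contour_fraction: Optional[float] = None,
) -> List[PlaceField]:
    """Fields = local maxima of the smoothed map above 0.5 Hz, with the
    4-connected area above 60% of each peak; overlapping candidates merge into
    the higher peak."""
    cfg = rate_map.grid.config
    thr = peak_threshold_hz if peak_threshold_hz is not None else cfg.field_peak_threshold_hz
    frac = contour_fraction if contour_fraction is not None else cfg.field_contour_fraction
    sm = rate_map.smoothed_rate
    filled = np.where(np.isfinite(sm), sm, -np.inf)
    footprint = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    local_max = (
        (filled >= ndimage.maximum_filter(filled, footprint=footprint,
                                          mode="constant", cval=-np.inf))
        & np.isfinite(sm) & (sm > thr)
    )
    peaks = sorted(zip(*np.nonzero(local_max)),
                   key=lambda rc: (-sm[rc], rc))
    claimed = np.zeros(sm.shape, dtype=bool)
    fields: List[PlaceField] = []
    structure = footprint
    for rc in peaks:
        if claimed[rc]:
            continue  # merged into a higher field
        region_mask = np.isfinite(sm) & (sm > frac * sm[rc])
        labels, _ = ndimage.label(region_mask, structure=structure)
        comp = labels == labels[rc]
        if (comp & claimed).any():
            claimed |= comp
            continue
        claimed |= comp
        area = frozenset(zip(*np.nonzero(comp)))
        fields.append(
            PlaceField(
                peak_bin=(int(rc[0]), int(rc[1])),
                peak_rate_hz=float(sm[rc]),
                area_bins=area,
                size_cm2=len(area) * rate_map.bin_size_cm**2,
            )
        )
    return fields


def split_half_stability(
    session: Session,
    cell: int | np.ndarray,
    spec: FrameSpec,
    config: AnalysisConfig = DEFAULT_CONFIG,
    grid: Optional[MapGrid] = None,
) -> float:
    """Pearson correlation between smoothed maps of the two session halves.

    Computed over bins visited in both halves; NaN when fewer than two common
    bins or either half is constant.
    """
    if grid is None:
        grid = MapGrid(session, spec, config)
    n = session.n_frames
    cut = (n + 1) // 2
    first = np.zeros(n, dtype=bool)
    first[:cut] = True
    try:
        m1 = build_rate_map(session, cell, spec, config, frames_mask=first, grid=grid)
        m2 = build_rate_map(session, cell, spec, config, frames_mask=~first, grid=grid)
    except EmptyMapError:
        return np.nan
    return map_correlation(m1.smoothed_rate, m2.smoothed_rate)


def map_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between two maps over their commonly visited bins."""
    common = np.isfinite(a) & np.isfinite(b)
    if common.sum() < 2:
        return np.nan
    x, y = a[common], b[common]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def radial_field_density(
    fields_per_cell: Sequence[Sequence[PlaceField]],
    rate_map_grid: MapGrid,
    ring_width_cm: Optional[float] = None,
) -> "pd.DataFrame":
    """Density of field peaks and visited coverage in rings around the origin.

    For relative-frame maps the origin is the imaged animal; density is
    peaks per cm^2 of ring area, coverage the fraction of each ring's bins that
    were visited.
    """
    import pandas as pd

    width = ring_width_cm or rate_map_grid.config.ring_width_cm
    half = -rate_map_grid.edges[0]
    n_rings = int(np.ceil(half / width))
    edges = width * np.arange(n_rings + 1)

    cx, cy = np.meshgrid(rate_map_grid.centers, rate_map_grid.centers)
    bin_r = np.hypot(cx, cy).ravel()
    visited = rate_map_grid.visited

    peak_r = []
    for fields in fields_per_cell:
        for f in fields:
            r, c = f.peak_bin
            peak_r.append(np.hypot(rate_map_grid.centers[c], rate_map_grid.centers[r]))
    peak_r = np.asarray(peak_r)

    rows = []
    for i in range(n_rings):
        lo, hi = edges[i], edges[i + 1]
        area = np.pi * (hi**2 - lo**2)
        in_ring = (bin_r >= lo) & (bin_r < hi)
        n_peaks = int(((peak_r >= lo) & (peak_r < hi)).sum()) if peak_r.size else 0
        coverage = float(visited[in_ring].mean()) if in_ring.any() else 0.0
        rows.append(
            {"r_lo_cm": lo, "r_hi_cm": hi, "n_peaks": n_peaks,
             "density_per_cm2": n_peaks / area, "coverage": coverage}
        )
    return pd.DataFrame(rows)
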