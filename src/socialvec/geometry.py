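"""Arena geometry and the four reference frames of social-spatial analysis.

A cell can be tuned to the position of the imaged animal in the arena
(``self_allo``), to the partner's position in the arena (``other_allo``), or
to the partner's position *relative* to the imaged animal, either in axes
fixed to the arena (``rel_allo``) or in axes that rotate with the imaged
animal's head (``rel_ego``).  Relative positions live in an "effective arena"
whose linear extent is twice that of the physical arena.

Conventions: x to the right, y up, centimetres; angles in radians,
counter-clockwise from +x, wrapped to (-pi, pi].  In the egocentric frame
"directly ahead" maps to +x and "left" to +y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import InvalidTrajectoryError, ParameterError

FRAMES = ("self_allo", "other_allo", "rel_allo", "rel_ego")
#: frames whose coordinates are relative to the imaged animal
RELATIVE_FRAMES = ("rel_allo", "rel_ego")
#: conventional category name for cells tuned in each frame
FRAME_CATEGORY = {
    "self_allo": "selfPC",
    "other_allo": "socialPC",
    "rel_allo": "alloSVC",
    "rel_ego": "egoSVC",
}


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena shape and size; the origin is always the arena center.

    ``size_params``: circle -> (diameter,); square -> (side,);
    annulus -> (outer_diameter, inner_diameter).
    """

    shape: str
    size_params: tuple

    def __post_init__(self):
        if self.shape not in ("circle", "square", "annulus"):
            raise ParameterError(f"unknown arena shape {self.shape!r}")
        params = tuple(float(p) for p in self.size_params)
        if any(p <= 0 for p in params):
            raise ParameterError("arena size parameters must be positive")
        if self.shape == "annulus":
            if len(params) != 2 or params[1] >= params[0]:
                raise ParameterError("annulus requires inner diameter < outer diameter")
        object.__setattr__(self, "size_params", params)

    @property
    def half_extent_cm(self) -> float:
        """Half the linear extent of the bounding square, in cm."""
        if self.shape == "square":
            return self.size_params[0] / 2.0
        return self.size_params[0] / 2.0  # circle / annulus: outer radius

    def contains(self, pos: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """Boolean mask of positions inside the arena (+ optional margin, cm)."""
        pos = np.asarray(pos, dtype=float)
        x, y = pos[..., 0], pos[..., 1]
        if self.shape == "square":
            h = self.half_extent_cm + margin
            return (np.abs(x) <= h) & (np.abs(y) <= h)
        r = np.hypot(x, y)
        if self.shape == "circle":
            return r <= self.half_extent_cm + margin
        outer = self.size_params[0] / 2.0 + margin
        inner = max(self.size_params[1] / 2.0 - margin, 0.0)
        return (r <= outer) & (r >= inner)

    @classmethod
    def circle(cls, diameter_cm: float) -> "ArenaGeometry":
        return cls("circle", (diameter_cm,))

    @classmethod
    def square(cls, side_cm: float) -> "ArenaGeometry":
        return cls("square", (side_cm,))

    @classmethod
    def annulus(cls, outer_cm: float, inner_cm: float) -> "ArenaGeometry":
        return cls("annulus", (outer_cm, inner_cm))


@dataclass
class Trajectory:
    """Per-animal time series at a fixed frame rate.

    ``head_dir`` may be ``None`` for partners that carry no head tracking.
    """

    frame_rate: float
    t: np.ndarray          # seconds, (n,)
    pos: np.ndarray        # cm, (n, 2)
    head_dir: Optional[np.ndarray] = None  # radians in (-pi, pi], (n,)
    valid: np.ndarray = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.head_dir is not None:
            self.head_dir = np.asarray(self.head_dir, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.pos).all(axis=1)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if self.pos.shape != (n, 2) or self.valid.shape != (n,):
            raise ParameterError("trajectory series lengths disagree")
        if self.head_dir is not None and self.head_dir.shape != (n,):
            raise ParameterError("head_dir length disagrees with positions")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def slice(self, sl: slice) -> "Trajectory":
        return Trajectory(
            frame_rate=self.frame_rate,
            t=self.t[sl],
            pos=self.pos[sl],
            head_dir=None if self.head_dir is None else self.head_dir[sl],
            valid=self.valid[sl],
        )


@dataclass(frozen=True)
class FrameSpec:
    """Which reference frame, anchored on which animals.

    ``referent`` identifies the partner for the three social frames and must
    be ``None`` for ``self_allo``.
    """

    frame: str
    subject: str
    referent: Optional[str] = None

    def __post_init__(self):
        if self.frame not in FRAMES:
            raise ParameterError(f"unknown frame {self.frame!r}")
        if self.frame == "self_allo" and self.referent is not None:
            raise ParameterError("self_allo takes no referent")
        if self.frame != "self_allo" and self.referent is None:
            raise ParameterError(f"{self.frame} requires a referent")

    @property
    def is_relative(self) -> bool:
        return self.frame in RELATIVE_FRAMES

    @property
    def category(self) -> str:
        return FRAME_CATEGORY[self.frame]


@dataclass(frozen=True)
class EffectiveArena:
    """Domain of all possible relative positions: twice the physical extent."""

    half_extent_cm: float
    bin_size_cm: float


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(-a + np.pi, 2 * np.pi)
    return np.pi - w


def to_relative(self_pos: np.ndarray, other_pos: np.ndarray) -> np.ndarray:
    """Partner position relative to the imaged animal, arena-fixed axes."""
    return np.asarray(other_pos, dtype=float) - np.asarray(self_pos, dtype=float)


def to_egocentric(
    self_pos: np.ndarray, other_pos: np.ndarray, head_dir: np.ndarray
) -> np.ndarray:
    """Partner position in axes rotating with the imaged animal's head.

    Rotates the relative vector by -head_dir: a partner directly ahead lands
    on +x, a partner to the left on +y.
    """
    rel = to_relative(self_pos, other_pos)
    hd = np.asarray(head_dir, dtype=float)
    c, s = np.cos(hd), np.sin(hd)
    x = c * rel[..., 0] + s * rel[..., 1]
    y = -s * rel[..., 0] + c * rel[..., 1]
    return np.stack([x, y], axis=-1)


def effective_arena(arena: ArenaGeometry, base_bin_cm: float = 2.0) -> EffectiveArena:
    """Relative-position domain: linear extent doubled, bins doubled."""
    return EffectiveArena(
        half_extent_cm=2.0 * arena.half_extent_cm,
        bin_size_cm=2.0 * base_bin_cm,
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _interpolate_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation over invalid samples; edges held at nearest valid."""
    out = x.astype(float).copy()
    idx = np.arange(len(x))
    out[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return out


def clean_and_smooth_trajectory(
    raw: Trajectory, arena: ArenaGeometry, filter_frames: int = 15
) -> Trajectory:
    """Remove out-of-arena/flagged points, interpolate, and mean-filter.

    Invalid samples (non-finite, pre-flagged, or outside the arena with a
    small tolerance) are linearly interpolated before a centered
    ``filter_frames``-point moving average is applied to each position axis.
    Head direction is smoothed circularly by averaging unit vectors over the
    same window.
    """
    if raw.n_frames < filter_frames:
        raise ParameterError(f"trajectory shorter than the {filter_frames}-point filter")
    finite = np.isfinite(raw.pos).all(axis=1)
    inside = np.zeros(raw.n_frames, dtype=bool)
    inside[finite] = arena.contains(raw.pos[finite], margin=1e-9)
    valid = raw.valid & finite & inside
    if not valid.any():
        raise InvalidTrajectoryError("no valid samples in trajectory")

    x = _interpolate_invalid(raw.pos[:, 0], valid)
    y = _interpolate_invalid(raw.pos[:, 1], valid)
    pos = np.stack(
        [_moving_average(x, filter_frames), _moving_average(y, filter_frames)], axis=1
    )

    head_dir = None
    if raw.head_dir is not None:
        hd_valid = valid & np.isfinite(raw.head_dir)
        if hd_valid.any():
            cx = _interpolate_invalid(np.where(hd_valid, np.cos(raw.head_dir), 0.0), hd_valid)
            sx = _interpolate_invalid(np.where(hd_valid, np.sin(raw.head_dir), 0.0), hd_valid)
            head_dir = np.arctan2(
                _moving_average(sx, filter_frames), _moving_average(cx, filter_frames)
            )
            head_dir = wrap_angle(head_dir)

    return Trajectory(
        frame_rate=raw.frame_rate, t=raw.t.copy(), pos=pos, head_dir=head_dir, valid=valid
    )


def frame_coordinates(
    trajectories: Mapping[str, Trajectory],
    spec: FrameSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame coordinates of a session in a given reference frame.

    Returns ``(coords, valid)`` where ``coords`` is (n, 2) in cm and ``valid``
    marks frames usable for map accumulation: both animals tracked, and for
    the egocentric frame a finite head direction.
    """
    subj = trajectories[spec.subject]
    if spec.frame == "self_allo":
        return subj.pos.copy(), subj.valid.copy()
    other = trajectories[spec.referent]
    valid = subj.valid & other.valid
    if spec.frame == "other_allo":
        return other.pos.copy(), valid
    if spec.frame == "rel_allo":
        return to_relative(subj.pos, other.pos), valid
    # rel_ego
    if subj.head_dir is None:
        raise ParameterError("egocentric frame requires head direction of the subject")
    hd_ok = np.isfinite(subj.head_dir)
    coords = to_egocentric(subj.pos, other.pos, np.where(hd_ok, subj.head_dir, 0.0))
    return coords, valid & hd_ok
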