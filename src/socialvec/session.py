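"""Session container: trajectories, event raster and metadata for one recording."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError
from .geometry import ArenaGeometry, FrameSpec, Trajectory


@dataclass
class Session:
    """One recording session.

    ``raster`` is the binarized calcium-event matrix, cells x frames, where an
    event marks a frame on which the deconvolved signal exceeded threshold.
    ``subject`` names the imaged animal; the remaining trajectory keys are its
    partners.
    """

    arena: ArenaGeometry
    trajectories: Dict[str, Trajectory]
    raster: np.ndarray
    subject: str
    seed: Optional[int] = None
    metadata: dict = field(default_factory=dict)
    truth: Optional[list] = None            # ground-truth cells, synthetic sessions only
    trial_table: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2:
            raise ConfigError("raster must be 2-D (cells x frames)")
        if self.subject not in self.trajectories:
            raise ConfigError(f"subject {self.subject!r} has no trajectory")
        n = self.n_frames
        for name, traj in self.trajectories.items():
            if traj.n_frames != n:
                raise AlignmentError(
                    f"trajectory {name!r} has {traj.n_frames} frames, raster has {n}"
                )

    @property
    def n_cells(self) -> int:
        return self.raster.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raster.shape[1]

    @property
    def frame_rate(self) -> float:
        return self.trajectories[self.subject].frame_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt

    @property
    def partners(self) -> List[str]:
        return [k for k in self.trajectories if k != self.subject]

    def frame_spec(self, frame: str, referent: Optional[str] = None) -> FrameSpec:
        """Convenience constructor defaulting the referent to the first partner."""
        if frame != "self_allo" and referent is None:
            if not self.partners:
                raise ConfigError("session has no partner trajectory")
            referent = self.partners[0]
        return FrameSpec(frame=frame, subject=self.subject, referent=referent)

    def all_frame_specs(self, referent: Optional[str] = None) -> List[FrameSpec]:
        """The four canonical frames for one referent."""
        return [
            self.frame_spec("self_allo"),
            self.frame_spec("other_allo", referent),
            self.frame_spec("rel_allo", referent),
            self.frame_spec("rel_ego", referent),
        ]

    def half_sessions(self) -> tuple["Session", "Session"]:
        """Contiguous first/second halves; the first half takes the extra frame."""
        n = self.n_frames
        cut = (n + 1) // 2
        return self.slice(slice(0, cut)), self.slice(slice(cut, n))

    def slice(self, sl: slice) -> "Session":
        return Session(
            arena=self.arena,
            trajectories={k: v.slice(sl) for k, v in self.trajectories.items()},
            raster=self.raster[:, sl],
            subject=self.subject,
            seed=self.seed,
            metadata=dict(self.metadata),
            truth=self.truth,
            trial_table=self.trial_table,
        )
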