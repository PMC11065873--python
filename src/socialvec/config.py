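"""Analysis configuration with the defaults used throughout the pipeline.

Every tunable of the analysis lives here so that a run is fully described by
(config, seed).  Defaults follow the standard miniscope place-cell workflow:
2 cm bins in physical frames, 4 cm bins in the doubled "effective arena" of
relative positions, Gaussian smoothing with sigma = 2 bins, 1000 temporal
shuffles cut at the 95th percentile, and a split-half stability floor of 0.3.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class AnalysisConfig:
    # map construction
    bin_size_cm: float = 2.0          # physical frames (self / other allocentric)
    rel_bin_size_cm: float = 4.0      # relative frames (effective arena, 2x bins)
    smooth_sd_bins: float = 2.0       # 2-D Gaussian kernel sd, in bins
    info_on_smoothed: bool = True     # information from smoothed (vs raw) maps
    min_occupancy_s: float = 0.1      # a bin below this is unreliable: flagged unvisited
    relative_origin: str = "body"     # 'body' or 'head'; which tracked point anchors
                                      # relative coordinates (upstream tracking choice)

    # field detection
    field_peak_threshold_hz: float = 0.5
    field_contour_fraction: float = 0.6

    # classification
    n_shuffles: int = 1000
    shuffle_percentile: float = 95.0
    stability_cutoff: float = 0.3
    min_shift_s: float = 20.0         # floor for temporal-shuffle displacement

    # shuffling-in-place control
    sip_bin_cm: float = 10.0
    sip_min_shift_s: float = 5.0
    sip_n_instances: int = 10

    # decoding
    tau_s: float = 0.5                # decoding window length
    n_folds: int = 5
    rate_floor_hz: float = 1e-4
    n_position_shuffles: int = 100

    # radial profiles
    ring_width_cm: float = 5.0

    # pursuit / angle maps
    angle_bin_deg: float = 15.0
    angle_smooth_sd_bins: float = 1.0
    omega_deadband_deg_s: float = 3.0
    omega_smooth_s: float = 0.5
    trained_latency_fraction: float = 0.3
    session_group_size: int = 5

    # trajectory cleaning
    position_filter_frames: int = 15

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable hash identifying this configuration in output metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_CONFIG = AnalysisConfig()
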