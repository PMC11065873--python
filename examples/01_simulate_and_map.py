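"""Simulate a two-mouse session and build the four reference-frame maps.

Plants one egocentric social-vector cell (field 20 cm ahead of the animal's
head) and prints each map's peak rate and spatial information: the cell should
be informative only in the egocentric frame.
"""

import numpy as np

import socialvec as sv

arena = sv.ArenaGeometry.circle(70.0)
cell = sv.GroundTruthCell(frame="rel_ego", field_centers=((20.0, 0.0),),
                          field_sd_cm=8.0, peak_rate_hz=2.0)
session = sv.make_session(arena, [cell], duration_s=600.0, seed=1)
print(f"session: {session.n_frames} frames at {session.frame_rate:.0f} Hz, "
      f"{session.raster.sum()} calcium events")

for frame in ("self_allo", "other_allo", "rel_allo", "rel_ego"):
    spec = session.frame_spec(frame)
    rm = sv.build_rate_map(session, 0, spec)
    print(f"{frame:>11}: peak {np.nanmax(rm.smoothed_rate):.2f} Hz, "
          f"information {rm.information:.3f} bits/event")

# The rel_ego row should dominate: the cell is tuned to the partner's
# position relative to the head, not to any arena-fixed coordinate.
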