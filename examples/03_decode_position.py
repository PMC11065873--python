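"""Naive-Bayes decoding of self-position with a shuffled baseline.

Fifty planted place cells, 5-fold contiguous cross-validation, and a baseline
from 20 sessions whose positions were circularly displaced in time.  Real
tuning should put the decoding error well below the whole baseline
distribution.
"""

import numpy as np

import socialvec as sv

arena = sv.ArenaGeometry.circle(70.0)
truth = sv.planted_population(arena, "self_allo", 50, peak_rate_hz=1.0,
                              field_sd_cm=8.0, seed=5)
session = sv.make_session(arena, truth, duration_s=600.0, seed=6)

result = sv.cross_validated_decode(session, range(50),
                                   session.frame_spec("self_allo"),
                                   n_shuffles=20, seed=7)
print(f"cross-validated m.a.e.: {result.mae_cm:.1f} cm "
      f"over {len(result.decoded_bin)} windows")
print(f"position-shuffle baseline: {np.mean(result.shuffled_mae_cm):.1f} cm "
      f"(min {result.shuffled_mae_cm.min():.1f})")
# The decoder reads position from 0.5 s windows of binarized calcium events;
# beating the shuffle floor shows the population carries positional structure.
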