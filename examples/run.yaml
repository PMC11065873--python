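# Minimal run configuration: simulate a two-mouse open-field session with
# planted populations, then classify and decode (see `socialvec report`).
simulate:
  arena: {shape: circle, size_params: [70.0]}
  duration_s: 600.0
  frame_rate: 30.0
  n_mice: 2
  populations:
    - {frame: self_allo, n_cells: 10, peak_rate_hz: 1.0, field_sd_cm: 8.0}
    - {frame: rel_ego, n_cells: 10, peak_rate_hz: 1.0, field_sd_cm: 8.0}
decode: [selfPC, egoSVC]
n_position_shuffles: 20
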