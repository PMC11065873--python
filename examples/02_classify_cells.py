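"""Shuffle-calibrated classification of a mixed synthetic population.

Plants five cells per category plus five untuned cells, classifies every cell
in all four reference frames (1000 temporal shuffles, 95th-percentile cutoff,
stability > 0.3) and prints the member counts per category together with the
overlap index between the selfPC and egoSVC populations.
"""

import socialvec as sv

arena = sv.ArenaGeometry.circle(70.0)
truth = []
for frame in ("self_allo", "other_allo", "rel_allo", "rel_ego"):
    truth += sv.planted_population(arena, frame, 5, peak_rate_hz=2.0, seed=3)
truth += sv.untuned_population(5, 0.1)

session = sv.make_session(arena, truth, duration_s=600.0, seed=4)
table = sv.classification_table(sv.classify_cells(session, seed=4))

counts = table[table.member].groupby("category")["cell"].nunique()
print("member cells per category (5 planted each, 5 untuned):")
print(counts.to_string())

self_cells = set(table[(table.category == "selfPC") & table.member].cell)
ego_cells = set(table[(table.category == "egoSVC") & table.member].cell)
idx, p = sv.overlap_index(len(self_cells), len(ego_cells),
                          len(self_cells & ego_cells), session.n_cells)
print(f"selfPC/egoSVC overlap index {idx:.2f} (binomial p = {p:.3f}); "
      "1 = co-membership at chance level")
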