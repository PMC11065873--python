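# socialvec

Analysis of how hippocampal CA1 populations represent the position of
conspecifics during social behavior, from miniscope calcium imaging of freely
interacting mice. The package takes per-session multi-animal tracking and a
binarized calcium-event raster and asks, for every cell, *in which coordinate
system* its activity is organized:

- **selfPC** — the classical place cell, tuned to the imaged animal's own
  arena position;
- **socialPC** — tuned to the partner's arena position;
- **alloSVC** — tuned to the partner's position *relative to the imaged
  animal* in arena-fixed axes;
- **egoSVC** — the same relative tuning in axes that rotate with the imaged
  animal's head.

It is written for systems-neuroscience labs running social-interaction
sessions (open field, multi-partner, or a pursuit task on an annular track)
downstream of video pose tracking and calcium-source extraction.

## The statistics at its core

Rate maps bin each frame's coordinates-in-frame (2 cm bins; 4 cm in the
doubled "effective arena" of relative positions), divide event counts by
occupancy, and smooth with an occupancy-weighted Gaussian kernel (σ = 2 bins).
Tuning is quantified by the spatial information per event,

    I = Σᵢ pᵢ (λᵢ/λ) log₂(λᵢ/λ),

and a cell joins a category when I exceeds the 95th percentile of 1000
circular time-shifts of its event train and its split-half map stability
exceeds 0.3. Population decoding is naive-Bayes under independent Poisson
counts,

    P(X|n) ∝ P(X) (Πᵢ fᵢ(X)^{nᵢ}) e^{−τ Σᵢ fᵢ(X)},

with 5-fold *contiguous* cross-validation and baselines from position-shuffled
sessions. Dedicated tools cover the shuffling-in-place false-positive control
(event permutation within 10 cm self-location bins), overlap indices with
exact binomial tests, population-vector remapping across contexts, and the
annular-track angle-map analysis (signed angle α, 15° bins, population
autocorrelograms, naive/trained latency labeling). A synthetic-session
generator with planted ground-truth tuning makes the whole chain testable
end to end; see `docs/methods.md` for the full model description.

## Worked example

```bash
python examples/03_decode_position.py
```

```
cross-validated m.a.e.: 18.6 cm over 17930 windows
position-shuffle baseline: 31.9 cm (min 28.8)
```

Fifty synthetic place cells (peak 1 event/s, field σ 8 cm) recorded for 10
minutes at 30 Hz decode the animal's position with a mean error of ~19 cm —
far below every one of the 20 position-shuffled baselines (~32 cm), which is
the signature of genuine positional coding at calcium-event data rates. The
other scripts in `examples/` walk through map construction in the four frames,
shuffle-calibrated classification and overlap indices, identity coding in
three-mouse sessions, context remapping, and pursuit-task angle maps.

A thin CLI wraps the same functions for shell use:

```bash
socialvec simulate --config examples/run.yaml --seed 1 --out session/
socialvec classify --session session/ --seed 1 --out classification.csv
```

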