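# moonwalk

Stimulus synthesis and computational analysis of **depth order from
dynamic occlusion** (accretion-deletion), built around the "Moonwalk"
display: an irregular central disc of random dots translating behind a
static outline, surrounded by an annulus of random dots whose
frame-to-frame survival probability (temporal coherence) is manipulated
independently. When the surround is static the center is seen as the far,
occluded surface — the geometrically correct reading of the
accretion-deletion (AD) cue. When the surround flickers, human observers
reverse and see the center as near, even though the center's pixels are
identical. The package provides the computational side of that story for
vision scientists: the AD cue alone *is* sufficient for an ideal decision
rule, so the human reversal implicates missing segmentation
("occluder-delineation") information, not missing depth information.

## What is in the box

- **`moonwalk.stimgen`** — seeded, parametric movie synthesis
  (`StimulusSpec`, `generate_sequence`): 50% per-pixel Bernoulli dot
  density, Michelson contrast 1.0 with luminance levels symmetric about
  the mean, 6 deg/s integer-pixel translation at 75 Hz, surround temporal
  coherence in [50%, 100%], per-region independent RNG streams, contrast
  manipulations that preserve mean luminance, space-time plots, and
  measurement probes (`measure_density`, `measure_michelson`,
  `measure_survival`).
- **`moonwalk.ideal_observer`** — the Bayes decision between the two
  depth-order models, F (center far) and N (center near), from the
  deletion band only ("area 3": center pixels whose content has no
  destination inside the outline on the next frame). Per frame pair it
  accumulates, over area-3 pixels *i*,

  ```
  LLR = sum_i [ log P(x_i^{t+1} | x_i^t, F) - log P(x_i^{t+1} | x_i^t, N) ]
  ```

  with F a fresh Bernoulli draw at the dot density (deletion +
  replacement) and N persistence with switch probability r. Decision F if
  the cumulative LLR is positive, N if negative, "no-evidence" on a tie.
- **`moonwalk.optic_flow`** — a Horn–Schunck estimator (brightness
  constancy + α²-weighted smoothness, Jacobi averaging updates, 2×2×2
  cube derivatives) plus an accretion-deletion-zone detector based on
  warped-difference aggregation, used to show that surround flicker
  leaves the center's flow and its AD zone essentially unchanged.
- **`moonwalk.psychophysics`** — simulated observers (logistic
  psychometric function of temporal coherence, per-subject random
  intercepts, optional segmentation-cue gating), maximum-likelihood
  logistic fits with Wald intervals, an exact two-sided binomial
  proportions test, a chi-square residual-normality check, and the
  six-condition contrast-gating experiment.
- **`moonwalk.pipeline` / `moonwalk` CLI** — one-config orchestration of
  all four stages with a JSON manifest and per-stage derived seeds.

## Worked example

```python
import dataclasses, numpy as np
from moonwalk import StimulusSpec, generate_sequence, decide

spec = StimulusSpec(rng_seed=7)                  # 256x256, 300 frames, static surround
static  = generate_sequence(spec)
flicker = generate_sequence(dataclasses.replace(spec, surround_temporal_coherence=0.5))

d1, t1 = decide(static)
d2, t2 = decide(flicker)
print(d1, d2, np.array_equal(t1.cumulative, t2.cumulative))
```

prints

```
F F True
```

— the Ideal Observer reports the center as **far** (cumulative LLR
+98,322 over 299 frame pairs for this seed) in both conditions, and the
two log-likelihood-ratio traces are *bit-identical*, because its evidence
region excludes the surround entirely. Running
`python examples/ideal_observer_demo.py` adds the explicit near-model
movie, whose cumulative LLR is −58,805: the sign of the LLR tracks the
generating depth-order model. The other scripts in `examples/` walk
through stimulus verification, the flow comparison (center endpoint error
0.05 px/frame between conditions versus 0.63 px/frame in the surround),
the psychometric fit, and the contrast-gating experiment.

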