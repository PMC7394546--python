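# cometpol

Directional statistics and event classification for EB1-GFP comet tracks in
the somas of *Drosophila* dendritic-arborisation (da) neurons.

EB1-GFP marks growing microtubule plus ends as fluorescent "comets", so the
trajectory of a comet reports the direction of microtubule growth.  In da
neurons, microtubules nucleated at somatic Golgi stacks grow with a bias
toward the axon, are guided toward (and into) the axon as they grow, and are
largely excluded from dendrites — the behaviours that maintain plus-end-out
axons and minus-end-out proximal dendrites.  `cometpol` turns manually
tracked comet tables into the quantitative summaries that support those
statements:

- **Initial growth angle** θ ∈ (−180°, 180°] of each comet, measured at the
  comet origin between the ray to the axon entry site and the comet's
  initial direction (total-least-squares over the first *k* positions);
  folded to |θ| ∈ [0°, 180°] when left/right of the axon is irrelevant.
- **Per-Golgi-stack resultant vectors.**  Each comet angle becomes a unit
  vector (sin θ, cos θ) — cosine on the Y axis, so "up" means toward the
  axon — and the vectors of the n ≥ 2 comets from one stack are averaged.
  The resultant length d = ‖mean vector‖ ∈ [0, 1] measures how similar the
  stack's comet directions are (d = 1 identical, d = 0 cancelling).
- **Monte-Carlo uniform null**: every comet angle replaced by an independent
  draw from Uniform(−180°, 180°), keeping per-stack comet counts, to ask
  whether observed d values and the upper-quadrant excess exceed chance.
- **Event classification**: whether each soma-origin comet *approached* a
  neurite (touched the ~0.5 μm entry zone across its mouth), *entered* it
  (crossed the zone's outer gate), displayed *turning* (≥45° direction
  change away from cortex and nucleus, on comets that grew >2 μm without
  travelling along the cortex), and the *anterograde/retrograde* polarity of
  comets within proximal dendrites.
- **Inference**: every proportion k/n with a Wilson-score 95% CI; one-way
  chi-squared goodness-of-fit against chance distributions; 2×2 Pearson
  chi-squared (no continuity correction) between conditions; exact binomial
  tail probabilities for quadrant skew.
- **A synthetic comet-track generator** (Golgi-anchored von Mises nucleation
  bias, guided turns, cortex/nucleus reflection, Bernoulli entry gates, with
  per-comet ground truth) so the whole pipeline is testable without
  microscopy data, plus a deterministic fixture builder that reproduces any
  requested approach/entry count table.

## Worked example

Simulate seven neurons and analyse them:

```bash
cometpol simulate --n-neurons 7 --n-comets 51 --kappa 3 --seed 3 --out bundle
cometpol report bundle
```

which prints (abridged):

```
cometpol 0.1.0 bundle (seed 3)

condition simulated: 357 tracks
  stack resultants toward axon: 49/53 = 92.5% (binomial p=3.5e-11)
  approached_axon: 116/357 = 32.5% (95% CI 27.8-37.5)
  approached_dendrite: 67/357 = 18.8% (95% CI 15.1-23.1)
  entered_axon_of_approached: 51/116 = 44.0% (95% CI 35.3-53.0)
  entered_dendrite_of_approached: 21/67 = 31.3% (95% CI 21.5-43.2)
  entered_axon_of_all: 51/357 = 14.3% (95% CI 11.0-18.3)
  entered_dendrite_of_all: 21/357 = 5.9% (95% CI 3.9-8.8)
  turned_of_qualifying: 12/237 = 5.1% (95% CI 2.9-8.6)
```

Reading the output: 92.5% of the 53 informative Golgi stacks have their
mean comet direction in the upper quadrants (toward the axon) — far from
the 50% expected under uniform angles (exact binomial tail p ≈ 3×10⁻¹¹),
reflecting the κ = 3 nucleation bias injected by the simulator.  Comets
reach the axon mouth about 1.7× as often as a dendrite mouth, and the entry
percentages on arrival (44% axon, 31% dendrite) are single-run estimates of
the simulation's Bernoulli gate probabilities, 0.54 and 0.28; across 100
seeded replicates the Wilson 95% intervals cover those truths at the
nominal rate (recomputed by the acceptance script).

Real data enter through `cometpol analyze`, with track tables in the native
CSV, ImageJ Manual Tracking, or TrackMate dialect and a YAML neuron
geometry (soma polygon, optional nucleus, axon/dendrite entry points, Golgi
stack centres); see `cometpol analyze --help`.

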