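# canoncirc

Canonical cortical circuit computations for visual modelling: a simulator
for recurrent neural-field models built from a single computational motif —
driving feedforward filtering, lateral recurrence, modulatory top-down
feedback, divisive pool normalization, and dynamic synaptic adaptation —
instantiated as the classic ventral (contour grouping, texture
segregation) and dorsal (motion detection and integration) architectures.

It is written for computational neuroscientists and biologically-inspired
computer-vision researchers who want to study how recurrent
feedforward/feedback interaction disambiguates local visual measurements,
without committing to spiking-level detail.

## The model

Each layer is a sheet of excitatory–inhibitory nodes over space × feature
channels, evolving as shunting leaky integrators:

```
τ_r ṙ = −α r + (β − r)·P(F, r, z) − (δ + r)·(F ∗ Λ⁻) − r·g_q(q)
τ_q q̇ = −α_q q + β_q·(g(r) ∗ Λ^pool) + I_c
P(F, r, z) = [F + κ (g(r) ∗ Λ^lat)] · (1 + λ z)
```

Bottom-up input `F` *drives*; top-down input `z` only *modulates*
(`b·(1+λa)`: zero drive ⇒ zero output, for any feedback), and a
space–feature pool divisively normalizes responses.  Synaptic efficacies
adapt by transmitter depletion, `τ_w ẇ = α(1−w) − β w s(t)`, with steady
state `α/(α+βs)`.  Composing layers with these three mechanisms reproduces,
among others: contextual facilitation and suppression of a contour element,
texture figure–ground segregation that collapses under feedback ablation,
iterative solution of the aperture problem, speed read-out of rotating
patterns, perceptual hysteresis in ambiguous motion displays, and
timescale-specific motion adaptation.

## Worked example

Perceptual hysteresis in a random-dot kinematogram: 60 dots all move
rightward; one dot per frame reverses until all move leftward.  The
two-layer V1–MT model with intact modulatory feedback holds its decision
well past the 50% evidence crossover:

```python
from canoncirc import build_motion_model, rdk_sequence
from canoncirc.metrics import (RDK_MODEL, rdk_decision_trace,
                               hysteresis_switch_point)

stim = rdk_sequence(n_frames=60, n_dots=60, seed=0)
arch = build_motion_model(RDK_MODEL, include_mst=False)
trace = rdk_decision_trace(arch, stim, dt=5.0, steps_per_frame=4)
switch, status = hysteresis_switch_point(
    trace, stim.ground_truth["reversed_fraction"][1:])
print(f"stable switch at {switch:.1f}% of dots reversed ({status})")
```

```
stable switch at 70.0% of dots reversed (switch)
```

The decision flips only once ~70% of the dots have reversed; ablating the
MT→V1 feedback edge (`ablate(arch, [("MT", "V1", "modulatory_feedback")])`)
makes the decision track the dot fraction and cross near 50%.

Every experiment from the accompanying study is scripted:

```
canoncirc run rdk_hysteresis --seed 0 --outdir runs/rdk
canoncirc run texture_sweep  --seed 0 --outdir runs/texture
```

writes `metrics.csv`, provenance JSON and a content-hash manifest.
Available experiments: `kapadia`, `texture_sweep`, `aperture_bar`,
`windmill`, `ablation_motion`, `curveball`, `rdk_hysteresis`,
`adaptation`.

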