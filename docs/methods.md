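# Methods

## The canonical node

Every model layer in this package is a sheet of excitatory–inhibitory (E–I)
nodes indexed by 2-D position and a feature channel (orientation, motion
direction, direction×speed, or a scalar saliency).  The node follows
shunting leaky-integrator dynamics:

    tau_r dr/dt = -alpha r + (beta - r) P(F, r, z)
                  - (delta + r) [F * Lambda^-] - r g_q(q)
    tau_q dq/dt = -alpha_q q + beta_q [g(r) * Lambda^pool] + I_c

with the driving function

    P(F, r, z) = [F + kappa (g(r) * Lambda^lat)] (1 + lambda_fb z).

`F` is the bottom-up driving input (filter responses or the output of the
layer below), `z` the re-entered top-down field, `*` denotes
space(–feature) correlation with reflective spatial boundaries and circular
feature axes.  Three properties carry all the behavior studied here:

* **Driver/modulator asymmetry.**  Feedback enters only through the factor
  `(1 + lambda_fb z)`, so it can amplify but never create activity
  ("no-strong-loop"): wherever the driving input is zero the output is
  exactly zero for arbitrary feedback.
* **Shunting saturation.**  The multiplicative `(beta - r)` and
  `(delta + r)` terms confine `r` to `[-delta, beta]` for non-negative
  inputs, for any input trajectory.
* **Divisive pool normalization.**  The `r·g_q(q)` term divides the
  equilibrium response by the pooled activity of a space–feature
  neighborhood.  When `g_q(q)` dominates the denominator the response
  approximates each channel's *share* of the local pool — the operating
  regime in which modulatory feedback transfers channel ratios through the
  recurrent loop and competition between feature hypotheses becomes
  winner-take-most.

Integration is explicit Euler with a default step of `min(tau_r, tau_q)/20`
and a hard guard `dt <= tau/10`.  A second, per-step guard aborts when
`dt/tau_r (alpha + P + surround + g_q)` exceeds 1, because beyond that point
an Euler step could overshoot the shunting bounds; simulations additionally
abort when any `|r|` exceeds `beta + delta + 0.01`.  Firing-rate functions
`g`, `g_q` are configurable (rectified-linear, rectified-power, sigmoid);
reported outputs are always post-`g`.  Large time constants combined with
large pool gains are *not* slow: the effective relaxation rate is
`(alpha + P + g_q)/tau_r`, so deep-normalization configurations relax within
a few frames.

Synaptic efficacy (transmitter production/depletion) follows

    tau_w dw/dt = alpha_w (1 - w) - beta_w w s(t),
    w_eq = alpha_w / (alpha_w + beta_w s).

Because this ODE is linear in `w`, the default integrator uses the exact
per-step exponential solution, which preserves `w ∈ (0, 1]` for any step
size and any non-negative signal; a plain Euler scheme is available and
agrees at the fixed point.

## Filters and detectors

* **Oriented filters**: even/odd Gabor pairs; even kernels have their DC
  removed under the envelope so uniform fields give exactly zero.
* **Bipole fields**: two co-axial Gaussian-windowed lobes with angular
  falloff, zero center tap, optionally a blanked central disk
  (`inner_radius`) so long-range support starts beyond the classical
  receptive field — essential for collinear facilitation to escape the
  normalization pool of nearby flankers.
* **Pool kernels**: separable Gaussian over space × circular Gaussian over
  the feature axis, unit sum, so pool strength is controlled solely by the
  `g_q` gain.
* **Orientation-contrast units**: juxtaposed excitatory/inhibitory
  subfields (offset `scale/2`, blur `scale/2`) comparing the squared,
  spatially pooled activity of each orientation across the subfield
  boundary; responses are rectified and summed over orientations for four
  boundary axes.  The pooling radius must exceed the texture item spacing,
  otherwise the filter reads item placement rather than orientation
  statistics.
* **Motion detectors**: elaborated correlation (Reichardt) detectors.  For
  each direction×speed channel the band-passed current frame is multiplied
  with the previous frame translated along the channel's preferred
  displacement, minus the time-mirrored product, spatially smoothed,
  rectified, and opponent-subtracted across opposite directions.  Static
  input cancels exactly in the time-opponent stage.  Sub-pixel translations
  use Fourier shifts: bilinear interpolation would low-pass diagonal
  displacements more than axis-aligned ones and bias the bank across
  directions (an effect large enough to lock the aperture-problem dynamics
  onto the normal flow).
* **Event-based detection** evaluates the same correlations on
  exponentially age-weighted ON/OFF event surfaces, but only at pixels that
  carried an event in the current time bin; output support is exactly the
  event support.

## Architectures

Models are explicit layer graphs; every inter-layer or lateral connection
is an edge object that can be removed (`ablate`) without touching the rest.
Driving edges form a DAG; cycles exist only through modulatory feedback
edges, which are evaluated with exactly one integration-step latency.
Ascending stages run on coarser grids (block-mean pooling of driving input,
nearest-neighbor upsampling of feedback).  Motion feedback optionally
re-enters at positions displaced by each channel's preferred velocity ×
one frame (the linear forward prediction), with bilinear interpolation.

**Contour model (V1–V2).**  8 orientation channels at 128×128.  V1:
oriented filtering with a wide (σ=10 px), orientation-unspecific
normalization pool.  V2: long-range bipole grouping (reach 24 px, inner
radius 7 px) with lateral recurrence; topographic same-orientation feedback
into V1.  The contextual-modulation experiment probes the center cell under
the eight bar-display configurations at two feedback gains (λ = 2 and 6):
texture raises the pool and suppresses the center; a collinear chain raises
V2 grouping activity whose feedback more than compensates at the stronger
gain.

**Texture model (V1–V2–V4).**  Adds orientation-contrast units on a 4×
coarser grid (filter scale 24 px against a 16-px item grid) with V4→V2 and
V2→V1 feedback.  Segregation is the mean V4 response over
figure-plus-boundary divided by the background mean (boundary = one item
cell of dilation).  The V4↔V2 loop amplifies boundary responses relative to
background noise responses; V2 must sit in the divisive (non-saturated)
regime for the modulation to transfer — with V2 saturated at the shunting
ceiling, feedback paradoxically helps the background, which has headroom.

**Motion model (V1–MT–MSTl).**  Correlation-detector drive (8 directions ×
{1, 2} px/frame for the bar experiments), near-punctate deep normalization
at V1, Gaussian space integration into MT (4× coarser) with deep
space-velocity normalization and an expansive output nonlinearity
(`g(r) = r^3`), large-field direction integration with global competition
in MSTl, and displaced modulatory feedback MT→V1 and MSTl→MT.  Aperture
disambiguation emerges as a cooperative-competitive wave: line-end
responses are unambiguous and, after contrast normalization, stronger per
channel than the broad constraint-line responses of the bar interior; MT
integration near the ends tips toward the true direction, feedback
amplifies consistent V1 channels, normalization suppresses the rest, and
the frontier moves inward.  The MT output nonlinearity sets the contrast
amplification per loop circulation; with a linear MT output the wave stalls.
The saturating deep normalization also makes the dynamics insensitive to
how much total evidence a bar provides, so that disambiguation *time*
rather than signal strength scales with bar length.

**RDK configuration.**  The hysteresis experiment runs the two-layer model
in a fast-membrane regime (τ = 50 ms, 20-ms frames) so that without
feedback the whole-field decision tracks the dot fraction with only a
2–3-frame lag (crossing near 55–58%).  With feedback (gain 8 on the MT→V1
edge, λ = 10) the loop holds the established direction until roughly
two-thirds of the dots have reversed; the stable switch (3 consecutive
frames) lands at 63–72% of dots reversed across seeds, for both sequence
directions.  The decision pools the two horizontal opponent channels over
the whole field and applies a softmax whose temperature is 5% of the
pooled-activity scale.

**Adaptation variants 1–5.**  The two-layer RDK-style model at 48×48 with
per-channel adaptive efficacies: (1) feedforward-only graph, fast V1→MT
synapses; (2) feedforward-only, slow; (3) recurrent, fast V1→MT; (4)
recurrent, slow MT→V1; (5) recurrent, fast V1→MT + slow MT→V1
(τ_w = 50 ms vs 4 s).  The habituation signal for a synapse bank is each
channel's share of the total presynaptic activity (resource competition),
scaled by a drive gain; shares rather than absolute rates keep the five
graphs, whose overall activity levels differ by orders of magnitude, at
comparable synaptic operating points.  Exposure is a band-limited drifting
texture, vertically sheared ("up"/"down" skew) so that rightward motion
energy acquires a vertical component.  Blank gaps between exposure and
probe are applied as closed-form rest recovery (`s = 0`), since residual
numerically-nonzero network activity would otherwise keep the share-based
drive alive indefinitely.  Probes drift at ±24…0 degrees around horizontal
and are judged up/down by the softmax; synapses are frozen during probes so
the psychometric function reads the post-exposure efficacy state.  The PSE
shift is PSE(up-adapted) − PSE(down-adapted); depression of the exposed
direction predicts a positive (repulsive) shift.  Three schedules (15 ms
exposure/no gap; 250 ms/20 ms; 1.6 s/400 ms at simulation time) dissociate
the time constants: the brief schedule engages only fast synapses, the
prolonged schedule's gap (8 fast recovery constants) erases fast traces
while slow feedback traces survive.  A shift counts as "adapted sign" when
its 5-seed median exceeds 0.075°, the resolution floor of the psychometric
fit; genuine shifts are 0.1–2.5°, residual traces below 0.04°.

## Synthetic stimuli

All experiments run on generated stimuli (128×128 or smaller, anti-aliased
by 4× supersampling, every generator a pure function of parameters and an
integer seed).  Key conventions: texture displays place ~9×2-px bars on a
16-px grid with ±2-px position jitter; BN (background noise) is iid
per-item orientation jitter uniform in ±BN degrees, OC a coherent
orientation offset of the figure region; the RDK uses 60 dots with one
direction flip per motion frame (61 rendered images = 60 motion steps, 50%
reversed at step 30, 100% at step 60) and border wrap-around; the curveball
patch is a horizontally drifting carrier (λ = 6 px) under a vertically
moving Gaussian envelope (σ = 6 px), both at 2 px/frame; frame-to-event
conversion emits ON/OFF events at ±log-threshold crossings with
time-interpolation and a 10⁻³ luminance floor.

What the generators do *not* emulate: photometric noise, natural-scene
statistics (the adaptation corpus is replaced by controlled drifting
textures), occlusions, or sensor noise (DVS background events are off by
default).  Passing tests therefore demonstrate the circuit mechanisms under
controlled statistics, not performance on natural video.

## Numerical and design choices

* dt = 5 ms everywhere (τ/10 at the fastest membranes); motion experiments
  use 4 integration substeps per 20-ms frame, the adaptation experiment 1
  substep per frame.
* Feedback latency is exactly one integration step.
* Boundary handling: reflective padding for all spatial kernels; feature
  axes circular.
* Ties in the softmax decision retain the previous frame's choice.
* The windmill read-out samples an annulus (radius 10 px to rim−5 px):
  spokes crowd within the detector aperture near the hub.
* The stable-switch criterion requires 3 consecutive flipped frames.
* Curveball deviations are measured from the population velocity averaged
  over 1.5 envelope σ around the true envelope center, identically for V1
  and MT.
* Problem sizes (96–128 px grids, 8 directions, ≤2 speeds, 10 RDK seeds,
  5 adaptation seeds) are the package's default desk-scale study
  conditions; all are configurable.

## Known limitations

* The motion frontend has no second-order (feature-tracking) channels, so
  absolute curveball deviations are carrier-dominated; the tested
  prediction is the feedback dissociation (ablating MT→V1 changes MT far
  more than V1), not the absolute trajectory.
* Orientation-contrast filtering reads pooled channel activity, not a
  cue-invariant orientation estimate; very dense or very sparse item grids
  require re-tuning the filter scale.
* The event-based detector shares kernels with the frame-based one rather
  than using genuinely asynchronous updates; it processes binned event
  surfaces (10–20 ms bins).
* Per-experiment gain configurations (feedback gains, pool gains) are part
  of each model family's parametrization, as in the original circuit
  models; no single parameter set covers all tasks.
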