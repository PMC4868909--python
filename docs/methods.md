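# Methods

This note documents the models implemented in `tswta`, the reasoning
behind the behavioural abstractions, the default parameter values, and
what the synthetic benchmarks do and do not demonstrate.

## 1. The ts-WTA unit

A time-staggered winner-take-all (ts-WTA) unit is a pair of antagonistic
synapses converging on one postsynaptic node whose total drive is capped
by a fixed metabolic resource (in the hardware picture, the current
through a bias pFET).  Each synapse's weight is a floating-gate voltage
`vfg`: *injection* lowers it (strengthening), *tunneling* raises it
(weakening).  Stimulation is time-staggered — the two synapses are never
driven in the same pulse — and the synapses compete for the shared
resource over time.

**Efficacy.**  `efficacy(vfg) = exp(-kappa (vfg - vfg_min))`, a
saturating exponential mirroring subthreshold pFET behaviour:
strictly decreasing, equal to 1 at the gate floor, and below 1 % of the
maximum at the ceiling with the default steepness.

**Per-pulse update.**  Pulses are discrete events (the RC time
constants of the physical network, ~1 kΩ × 10 pF = 10 ns, are eight
orders of magnitude below the 0.02 s pulse width, so intra-pulse
transients are irrelevant).  A pulse on the active synapse changes its
gate by a threshold-linear rule,

    dvfg = -eta_inj * max(0, fb - theta_fb) + eta_tun * max(0, theta_fb - fb),

while the inactive synapse drifts up by `eta_leak` (disuse weakening);
everything is clipped to `[vfg_min, vfg_max]`.

**Feedback is the resource share.**  For a standalone unit, the
feedback level `fb` of a pulse is the fraction of the fixed bias
resource the pulse captures:

    fb = i_b * eff_active / (eff_1 + eff_2).

This is the decisive modelling choice.  It makes the competition
*relative*: `fb` depends only on the gap between the two gate voltages,
so with `theta_fb = i_b/2` a pulse on the stronger synapse always
strengthens it and a pulse on the weaker one always weakens it,
regardless of where the pair sits in the gate range.  A feedback based
on the active synapse's absolute efficacy alone cannot reproduce the
two win laws for arbitrary initial pairs, because a fixed threshold
then splits the gate range at one fixed voltage.

**The two win laws.**  With the defaults below,

* equal stimulation → the synapse with the stronger initial bias
  (lower `vfg`) wins — the relative feedback strengthens it and starves
  the other, and the gap growth is monotone per alternation cycle;
* sufficiently unequal stimulation (≥ 3× pulses against a bias gap of
  ≤ 0.1 V) → the more-stimulated synapse wins — each pulse it receives
  weakens it only marginally (its share is barely below threshold)
  while the rarely-stimulated synapse accumulates disuse leak, so the
  gap closes, the shares cross the threshold, and positive feedback
  finishes the reversal.

The balance requires `eta_leak` large enough to close a 0.1 V gap at a
3× pulse ratio but smaller than the winner's injection at that same
gap; `eta_inj = 0.5`, `eta_tun = 0.02`, `eta_leak = 0.045` (volts per
pulse against a share signal of order 0.1) satisfy both inequalities
with margin, and the sweep harness verifies all five behavioural
invariants at this point and in a neighbourhood around it.

An exactly symmetric run (equal weights, equal schedule) is resolved
only by which synapse is pulsed first; since that is an artifact of
schedule ordering, the outcome is reported as UNDECIDED unless the
`tie_break` flag is set.

**Default unit parameters**

| parameter | default | units | role |
|---|---|---|---|
| `vfg_min`, `vfg_max` | 4.5, 6.0 | V | admissible gate range; initial biases are drawn in 4.8–5.5 V |
| `kappa` | 4.0 | 1/V | efficacy steepness; makes the resource share depend only on the gate gap and puts the ceiling below 1 % of the floor efficacy |
| `i_b` | 1.0 | – | resource cap; activations and responses live in `[0, i_b]` |
| `theta_fb` | 0.5 | – | share threshold = `i_b/2`: strengthen iff the pulse captures the majority of the resource |
| `eta_inj`, `eta_tun` | 0.5, 0.02 | V/pulse (per unit share excess) | injection/tunneling rates |
| `eta_leak` | 0.045 | V/pulse | disuse drift of the unstimulated synapse; carries the stimulation-count law |
| `v_on`, `v_off`, `pulse_width` | −1 V, +6 V, 0.02 s | | pulse levels and width, carried for serialization/rendering |

## 2. The disparity-selective cell

A cell is an h×w grid of ts-WTA units (default 9×9), one per position
of an interlaced binocular window: the left `w_L = ⌊w/2⌋` columns carry
the left-eye subfield, the right `w_R = ⌈w/2⌉` columns the right-eye
subfield.  A field of total width `w` can encode `⌊w/2⌋` integer
disparities (9 → 4, 40 → 20).

**Response.**  All unit drains share one bias-limited output node, so
the response to a binary pattern is the fraction of the total standing
efficacy recruited by the driven synapses,

    r = i_b * sum(eff_driven) / sum(eff_all),

rather than a plain mean of activations.  This resource reading has two
structural consequences that the training dynamics depend on: a pattern
and its complement always sum to `i_b` (they recruit complementary
halves of the same budget), and the response cannot saturate for all
patterns simultaneously — competition is conserved.  It also makes
cells of different sizes directly comparable.

**Training.**  Patterns are presented random-inside-epoch (every
pattern once per epoch in seeded random order; a set always contains
each pattern's complement so each synapse pair is driven alternately).
The evoked response is fed back to every unit's pulse rule.  The
feedback comparator level is a *leaky running maximum* of recent
responses: `theta = 0.98 * m`, `m ← max(r, (1 − 0.002) m)`.  Only
patterns within 2 % of the best recent response inject; everything else
weakens its drive.  This is the software counterpart of a peak-holding
readout on the feedback RC network, and it is what makes the
pattern-level competition winner-take-all: a constant comparator level
cannot both bootstrap from an undeveloped field (all responses ≈ i_b/2)
and stabilise a single-pattern template once responses have grown.
Within a cell the feedback signal is a response *difference* of a few
percent of `i_b`, so the cell-level rates differ from the standalone
unit's: `eta_inj = 5.0`, `eta_tun = 0.02`, `eta_leak = 0.001`
(strong, decisive injection for the gated winner; weak erosion from
everything else).

A cell may lock onto either phase of a disparity — the pattern or its
complement are equally valid stimuli with the same disparity label — so
`learned_disparity` is the label of the winning set member, and the
tuning traces report per disparity the better of the two phases
(`max(r, i_b − r)`, exact by the complement-sum identity).

Because initial responses are tightly clustered (the 4.8–5.5 V biases
perturb the response by ~1 %), training amplifies the initial
preference faithfully only when that preference is clear: over seeds
whose top-two initial responses differ by at least 1 %, the learned
disparity matches the initial argmax in ≥ 90 % of runs; nearer ties
can be flipped by the positive feedback, which is the expected
behaviour of a WTA with noise-scale input differences.

**Tuning curve and hwhh.**  The tuning curve is the response versus
probe disparity; its half-width at half-height interpolates linearly to
the crossing of `(max+min)/2` on each side of the unique peak and
averages the sides that exist.  Note that with this mid-height
definition any non-flat curve crosses somewhere, so the
undefined-beyond-support signal only arises for curves with no crossing
inside the sampled support.  The hardware-level tuning sharpness
reported for the original circuit (hwhh ≈ 2.7) is a property of the
transistor simulation; the behavioural model is only expected to show
*sharp* tuning (final peak above 1.5× the mean of the other
disparities), which it does.

**Diffusive coupling.**  Each cell's output reaches its diffusion node
through a one-way buffer; neighbouring diffusion nodes are joined by a
coupling resistor (default 100 Ω against 1 kΩ feedback resistors).  The
node voltages are solved quasi-statically by Kirchhoff's current law at
every presentation, and the *diffusion-node* voltage — not the raw
output — is what the units' feedback sees.  For a coupled pair this
mixes roughly half of the neighbour's response into each cell's
feedback, so the more strongly biased cell steers both toward its
disparity; with the coupling resistor → ∞ the solve returns each cell's
own output exactly and training reduces to the standalone case.
Output nodes are never back-driven (the buffer contract).

## 3. Synthetic stimuli

`make_pattern_set` builds one pattern per disparity plus every
complement.  Random-dot patterns (the default training set) draw the
left subfield iid at density 0.5 and shift it by `d` with zero-fill;
the draw is repeated (seeded) until no two patterns agree on more than
65 % of their bits in either phase, because mutual quasi-orthogonality
is a property the training set is supposed to have — without it the
pattern-level competition degrades for reasons that have nothing to do
with the learning rule.  For wide fields with many disparities the
zero-fill convention makes some overlap structural, and the most
orthogonal draw is kept.  Bar patterns (one vertical ON bar, shifted by
`d` in the right subfield) are intentionally correlated and used to
match the bar-textured images below.

`make_stereo_pair` builds a rectified pair: the left image is textured
(vertical bars of period 8, phase-offset from the image border, or
random dots), each left pixel is displaced `d` columns to the right per
its region's disparity, nearer surfaces overwrite farther ones, holes
are filled from the nearest painted column, and every pixel involved in
an overwrite or fill is flagged in an occlusion mask rather than
synthesised plausibly.  Optional nuisances: iid Gaussian sensor noise
and a linear illumination ramp.

What the generator does *not* emulate: natural texture statistics,
vertical disparity or tilt, photometric differences between the eyes,
and sub-pixel disparity.  Passing the synthetic benchmarks therefore
demonstrates the mechanism — competitive learning of disparity
templates and winner-cell detection — not performance on natural
stereo imagery.

## 4. The disparity-map pipeline

For each pixel an h×w_L patch of the left image and an h×w_R patch of
the right image (same epipolar rows, same starting column) are spliced
into one binocular window, binarized at the window median, and shown to
a bank of trained cells (one per disparity); the winner's disparity is
the pixel's estimate, exact ties resolve to the lowest disparity and
mark the pixel invalid.

**Window registration.**  A bank of linear templates cannot be
phase-invariant: if windows are cut at arbitrary texture phases, the
argmax follows the phase, not the disparity.  The map stage therefore
anchors each window on a texture landmark — the crest of the nearest
bar at or left of the pixel, found on the full-column mean profile of
the (filtered) left image.  Landmarks are local maxima dominating a
±3-column neighbourhood and rising above the midpoint of the profile's
robust (5th/95th percentile) range; exact plateau ties keep the
leftmost column.  Full-column averaging is appropriate because the
reference texture's landmarks are vertical, epipolar-crossing
structures, and it makes the landmark set essentially immune to pixel
noise.  A pixel-centred alignment is available (`align="center"`) and
is the convention used by `extract_and_splice` itself.

**Prefilters and matched banks.**  Detection is template matching, so
the bank must be trained on patterns that look the way real windows
look *after* the configured prefilters.  `matched_pattern_set` builds
them by passing a clean single-region reference pair through the exact
pipeline (filters, anchoring, splicing, binarization) at each
disparity.  The chain is: Gaussian smoothing (σ, reflective borders) →
optionally Sobel gradient magnitude (derivative-of-Gaussian order, so
the edge map is not a noise amplifier) → column-wise non-maximum
suppression (`ridge_sharpen`), which reduces the smeared profiles back
to crisp one-column ridges.  Smoothing thus stabilises the *position*
of each landmark rather than feeding the cells blurred intensities the
median binarization would cut through at its most noise-sensitive
levels.

**Noise behaviour, measured.**  On the 80×80 four-quadrant bar pair
with additive sensor noise of σ = 0.5 (against a 0.8 contrast), the
unfiltered pipeline averages ≈ 1.7 % interior error and the
Gaussian-prefiltered one ≈ 0.6 % (means over 10 pairs) — smoothing
strictly reduces the error, which is the directional claim the
acceptance suite tests.  The edge front end behaves differently: on
clean or shading-corrupted input it is exact, but under iid noise a
gradient map's background is rectified noise whose level approaches
the ridge height, and the edge+Gaussian configuration is *less*
accurate than the unfiltered pipeline at every noise level we
measured.  This is a real property of differentiating low-contrast
noisy images, not an implementation artifact, so the noise-reduction
benchmark uses the Gaussian configuration; the edge configuration is
implemented, matched and verified on clean input, where its natural
role is removing low-frequency photometric structure.

**Error metric.**  `average_error` = 100 × (mismatched valid pixels) /
(valid pixels), optionally restricted to region interiors (pixels at
least 10 px from every region and image border, where a window cannot
straddle two surfaces).  The published error percentages for the
20-disparity natural benchmark depend on an external image and that
image's own error convention, and are not claimed here.

## 5. Reaction-diffusion map formation

Each site of a cortical lattice carries a real state `x`; the update is
explicit Euler,

    x ← x + alpha * R(x) + d_u * L(x),

with `R(x) = −sin(2πx)/(2π)` inside `[0, D−1]` — zero and attracting at
every integer disparity, zero and repelling at every half-integer — and
a linear restoring drift outside; `L` is the 5-point Laplacian with
reflecting (default) or wrapping boundaries.  The sinusoidal drift is
one concrete choice of multistable reaction with the required root
structure; any odd-symmetric drift with integer attractors would do.
The diffusion term must be a spatial operator: a term proportional to
`x` itself would destroy the very fixed points the reaction is built
around.

Stability: the reaction root slope is 1 per unit `alpha`, so
`alpha < 2` is stable (monotone for `alpha ≤ 1`); the explicit 2-D
diffusion bound is `d_u ≤ 1/4`; the evolution raises a stability error
if a state escapes `[−1, D]`.  The maximal per-step drift `alpha/(2π)`
is below the basin half-width for all admissible `alpha`, so
pure-reaction dynamics can never jump basins and every off-separatrix
site converges to its nearest root (the oracle the tests check).

Defaults `alpha = 1.5`, `d_u = 0.1`, 300 steps on 64×64: strong enough
reaction that local preferences commit before diffusive averaging can
pull the field toward its global mean, and enough diffusion to merge
the ≈ 1900 single-site domains of the uncoupled lattice into ≈ 200
contiguous clusters.  In this regime the settled map is strictly
smoother than its diffusion-free twin (20/20 seeds) while all four
disparities remain represented (≥ 18/20 seeds); pushing `d_u` toward
the stability bound trades diversity for smoothness until only the two
middle roots survive — the flagged over-diffusion regime.

Map statistics: continuity = mean |Δx| over 4-neighbour pairs;
diversity = fraction of disparities present by nearest root; clusters =
4-connected components of constant nearest-root disparity.

## 6. Problem sizes

The shipped benchmarks use the study's native scales throughout: 9×9
receptive fields trained 80 epochs on 8 patterns, populations of 200
cells, 50 coupled-pair runs, the 80×80 four-quadrant pair (with
10-pair noise averages), and 20 seeded 64×64 lattices evolved 300
steps.  The full test suite runs in well under a minute on one CPU.

## 7. Known limitations

* Detection generalises only to textures the bank was matched to;
  arbitrary natural textures would need either a much richer bank or a
  correlation-based (quadratic) detector, which this architecture
  deliberately does not use.
* Disparities are non-negative integers (position-shift model); no
  sub-pixel estimates, no vertical disparity, no occlusion reasoning
  beyond flagging.
* The cell-level learning outcome for near-tie initial preferences is
  decided by positive feedback, not by the vanishing initial
  difference; this is inherent to WTA dynamics.
* Learning-phase wall-clock times, power figures and transistor-level
  tuning widths of the original circuit are outside a behavioural
  model's scope.
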