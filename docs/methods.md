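# Methods

## Overview

`remotetae` reproduces, with a simulated observer, a psychophysical design
for measuring tilt aftereffects (TAEs) at a visual-field location that the
adapting stimulus never stimulated. The pipeline has four stages:

1. **geometry** — analytic orientation fields and the signal/noise
   geometry of annular layouts;
2. **synth** — rendering of the adapting textures and test patches;
3. **observer** — a phenomenological adaptation model emitting stochastic
   2AFC responses;
4. **psychofit / experiments** — constant-stimuli analysis (ML logistic
   fits, bootstrap SEs, TAE) and grid drivers.

The observer is a *response model*, not a cortical model: it encodes the
phenomenon's empirical signature (gradient-tuned, coherence-scaled remote
adaptation at the implied orientation) so that the analysis chain can be
validated end to end. No claim about mechanism is built in.

## Coordinate and orientation conventions

Degrees of visual angle, origin at fixation, x rightward, y upward.
Orientation is measured counter-clockwise from vertical and wrapped into
[−90, +90); −90 and +90 denote the same line and −90 is the canonical
representative. With these conventions the tangential orientation of a
circle centred on fixation equals the polar angle of the point, so the
test site (eccentricity 10°, polar angle 15°, Cartesian (9.66, 2.59)°)
carries an implied orientation of +15° and a gradient along the arc of
180/(π r) = 5.73 °/° at r = 10.

## Orientation fields

* **concentric / radial** — tangential / radial orientation about a
  centre; evaluation at the centre raises a degenerate-point error.
* **linear_gradient** — orientation a linear function of x (horizontal
  axis) or y (vertical axis), anchored so the field evaluates to the
  anchor orientation (default +15°) at the test site.
* **quantized_gradient** — the linear gradient space-averaged within
  bands of fixed width, one band centred on the anchor; because the
  underlying function is linear, each band's average equals its value at
  the band centre, and adjacent bands differ by `band_width × rate`
  (mod 180). A band width of one spatial period (180/rate; 36° at rate 5)
  leaves an iso-oriented texture.
* **iso** — constant orientation.
* **symmetry** — `about_gradient_axis_meridian` mirrors the hemifield
  containing the anchor into the other one (positions reflected,
  orientations negated mod 180). The anchor-side hemifield is the source,
  so the implied orientation at the test site is unaffected.

## Coherence geometry

Structure coherence is the expected fraction of *visible* elements
(outside the effective occlusion radius of the test point, under uniform
density on the 48×48° square) that carry the structured orientation. The
effective occlusion radius is occlusion radius + ramp width = 3.0 + 1.6 =
4.6°: elements centred anywhere inside the contrast ramp are treated as
not visible. This choice reproduces the printed layout pair (outer radius
9.53° ↔ 90% coherence) to rounding; with 3.0° the same radius gives
88.7%. The noise annulus starts at the effective occlusion radius
(elements inside are invisible either way; fixed for reproducibility).

Disc–square intersection areas are computed by adaptive quadrature of the
clipped chord length (with breakpoints where the circle crosses the square
edges); `solve_noise_radius` inverts coherence by Brent root finding on
the monotone radius→coherence map. A Monte-Carlo point-count oracle
agrees within 0.003 (tested at 10⁶ points).

Note the inversion gives ≈ 20.4° for 50% proximal coherence under this
geometry; no uniform-density variant we tried lands on a substantially
larger radius, so the solver is validated against its own area/Monte-Carlo
oracles rather than against any particular published radius.

## Texture synthesis

5000 elements, positions i.i.d. uniform on the square, phases uniform on
[0, 2π). Each element is a sinusoid (1 c/° for adaptors, 2 c/° for the
test) under an isotropic Hanning window `cos²(πr/D)` of diameter
D = 1.33°. Elements sum additively; the image is mean-subtracted and
scaled to 9% RMS contrast over the full square, *then* the occlusion
window (0 inside 3°, `sin²(π/2·(r−3)/1.6)` ramp, 1 beyond 4.6°) is
applied — RMS is therefore specified pre-occlusion. The adaptor element
diameter is inherited from the test patch (the adaptor differs only in
carrier frequency). Carrier phase 0 is a cosine at the element centre;
the test raster is aligned so a pixel falls exactly on the patch centre,
making the nominal 0.25 peak contrast exact. 8-bit export maps −1..+1 to
0..255 with 0 → 128 (round half up). Proximal/distal noise labels are
spatial (inside/outside the annulus), not quota-based, so element density
and contrast energy are identical across layouts. Dynamic adaptors
resample all elements every 100 ms with per-frame generators spawned from
a master seed (30 s initial adaptation = 300 frames; 3 s top-up = 30).

Rendering is a QC path only: the response simulation consumes field
descriptors analytically, which keeps a full three-experiment replication
to a few minutes of CPU.

## Observer model

```
TAE = A · c^q · G(g)  (+ γ·c, distal layouts only)
```

| parameter | default | meaning |
|---|---|---|
| A (`tae_peak_amplitude`) | 2.0° | TAE at full coherence, preferred gradient |
| `tuning_center` / `tuning_halfwidth` | 5.0 / 5.0 °/° | raised-cosine gradient tuning, support [0, 10] |
| q (`coherence_exponent`) | 1.0 | coherence scaling (linear) |
| `step_ambiguity_threshold` | 45° | largest readable inter-band step |
| γ (`local_adaptation_gain`) | 0.5° | extra PSE shift from structured elements adjacent to the test site (distal layouts) |
| `psychometric_slope` | 1.5° | logistic response slope |
| `lapse_rate` | 0.02 | stimulus-independent responses |

Only three anchors of the tuning curve are empirically constrained (zero
effect at gradient 0, peak near 5 °/°, ≈ zero near 10 °/°); the raised
cosine is the simplest smooth unimodal curve through them and adds no
free parameter. Under it, the concentric adaptor's gradient (5.73 °/°)
gives G ≈ 0.948, hence a full-coherence TAE of ≈ 1.90° — "approximately
2°". Coherence scaling is likewise a stand-in (linear by default); both
forms are explicitly *not* measured shapes. Quantized fields use a hard
readability threshold at 45° (half the 90° orientation-ambiguity limit):
steps of 40° (8° bands at rate 5) are readable, 60° (12° bands) are not,
and a step ≡ 0 mod 180 (full-period bands) means the texture carries no
gradient at all. Symmetry has no effect on the model, and proximal noise
placement behaves exactly like intermixed noise at equal coherence —
both encode null results. The distal local term is a single additive
gain; its default 0.5° encodes "larger than intermixed" without claiming
a measured magnitude.

Response probability: `P(CW) = λ/2 + (1−λ)·logistic((PSE − θ)/slope)`,
with clockwise = negative orientation under the CCW-positive convention.

## Psychometric analysis

Trials are aggregated to per-level binomial counts and fitted with a
lapse-free two-parameter logistic by Nelder-Mead on (PSE, log slope),
multi-started at slopes {0.5, 1.5, 5}° with a data-derived PSE start; the
best likelihood is kept, making the fit deterministic given the trials.
The fitted model omits the lapse deliberately: the fitted curve family is
the plain logistic, and the simulation's 2% lapse then acts as a
robustness stressor (it biases the PSE by < 0.05° at the default ±6°
level range — verified in the tests). Complete separation is flagged
non-converged with the PSE at the midpoint of the straddling levels;
all-identical responses raise an error.

Bootstrap SEs resample trials with replacement *within* each orientation
level (the constant-stimuli design is fixed), implemented as per-level
binomial resampling, which is exactly equivalent for exchangeable binary
responses. Degenerate resamples are dropped and counted; > 10% dropped
raises an error. Default 1000 resamples.

Constant-stimulus levels default to 7 values on [−6°, +6°]; the paper's
own level range is not printed, so this is a package choice, configurable
per condition.

## Experiments and problem sizes

Default grids: exp1 = {intermixed, proximal, distal} × coherence
{0.25, 0.5, 0.75, 1.0} (annulus radii from `solve_noise_radius`); exp2 =
rate {0, 1.25, 2.5, 5, 7.5, 10} × axis {horizontal, vertical} × symmetry
{off, on} at the 9.53°/90% proximal annulus; exp3 = band widths
{0.2, 2, 4, 8, 12, 24, 36}° at rate 5. Exact coherence and rate levels
are package defaults (the source data show levels only graphically) and
are config-overridable. Blocks per condition default to 4; the
summariser's "consistent effect" shorthand is TAE > 2 × (pooled bootstrap
SE). The ordering checks in the acceptance suite (proximal ≡ intermixed;
distal ≥ intermixed) use 8 blocks per condition: the distal local term
(≤ 0.5°) must be resolved against a TAE-difference SD of ≈ 0.4° at 4
blocks, so doubling the blocks is a power choice, not an effect-size one.

The acceptance script reports the full-pipeline TAE as the mean over six
simulated observers (the cohort size of the original design), each run
independently at 4 blocks per condition; a single 4-block run estimates
the same quantity with SD ≈ 0.42°, the six-observer mean with ≈ 0.17°.

## What the generator does and does not emulate

The synthetic observer reproduces the *findings* (magnitudes, tuning,
orderings, quantization collapse) by construction; passing tests
therefore validate the geometry, synthesis and analysis code, and the
internal consistency of the pipeline — they are not evidence about human
vision beyond what was encoded. Not modelled: fixational eye movements,
per-observer idiosyncrasies, sequential/adaptation-state dynamics across
trials, reaction times, display calibration, and any neural mechanism of
the extrapolation itself.

## Numerical notes

* Orientation wrap: `((θ + 90) mod 180) − 90`; ±90 identified, canonical −90.
* Area quadrature tolerance 1e-10 with edge-crossing breakpoints; root
  finding tolerance 1e-10 in radius.
* Fit convergence: Nelder-Mead `xatol` 1e-8, `fatol` 1e-10; probabilities
  clipped at 1e-12 in the likelihood.
* All stochastic stages take explicit seeds or `numpy` generators;
  per-condition and per-frame streams are spawned from master
  `SeedSequence`s, so grids rerun byte-identically.
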