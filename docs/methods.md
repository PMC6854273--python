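# Methods

`dynedge` models the discrimination of *dynamic-defined edges* — boundaries
between regions of a visual scene whose imagery differs in spatiotemporal
statistics rather than (only) in luminance — by a one-dimensional,
insect-inspired visual front end feeding a shallow trainable network.  This
note records the model, its parameters, the synthetic stimulus design, the
numerical choices, and the limitations of what the test suite can show.

## Visual front end

**Geometry.** Six or eight co-linear photoreceptors with an inter-receptor
viewing angle Δφ = 1°, each paired with a retinotopic "visual processing
unit" (column).  Fixed edges sit exactly midway between the two central
receptors; scene pixel grids are laid out so that this midpoint is a pixel
*boundary*, which makes left–right mirror symmetry exact in the discrete
representation (receptor centers then fall between pixels, so blur kernels
are sampled at half-integer pixel offsets).

**Optics.** A Gaussian modulation transfer function
`MTF = K·exp(−r²/r₀²)` blurs each high-resolution frame as it is
downsampled to receptor drives.  The FWHM is 1.4·Δφ, giving
r₀ = 1.4/(2√ln2) ≈ 0.8407°; the kernel has finite support ±2r₀ and is
normalized to unit sum, so uniform fields pass unchanged.  Blur is applied
along the receptor axis only, at every time step.

**Filter cascade.** Per column, in order:

| stage | dynamics | constants |
|---|---|---|
| photoreceptor | `U = Iᵏ/(Iᵏ + I₀ᵏ)`, `dI₀ = (dt/τ_U)(I − I₀)` | Lipetz exponent k = 0.7, τ_U = 750 ms |
| ON/OFF split | first-order high-pass of U, half-wave rectified both ways | τ_R = 200 ms |
| sustained path | "relaxed" high-pass passing 40% DC, rectified | τ_S = 50 ms |
| transient path | rectifying-transient-cell: 40 ms high-pass, rectify, subtract an adaptive state (fast rise 2 ms, slow decay 100 ms), rectify | τ_A = 40 ms, τ_Ad = 2 ms, τ_Ar = 100 ms |
| delay | unit-DC first-order low-pass on each of the four signals | τ_D = 50 ms |

The text introducing the relaxed high-pass reuses the symbol of the 200 ms
constant with a 50 ms value; we treat it as a distinct constant τ_S.  This
yields eight signals per column ({ON,OFF} × {sustained,transient} ×
{undelayed,delayed}), all nonnegative; a static input produces all zeros.
Lateral (spatial) inhibition is deliberately absent from the model.

**Integration and recording.** Forward Euler at dt = 200 µs (one tenth of
the fastest time constant).  Outputs are averaged over 10 ms windows —
successive for fixed-edge and full-field scenes, 50%-overlapped (5 ms
stride) for moving-edge scenes.  A 2 s burn-in (not stated by the source
study; > 2τ_U) is discarded so filter states reach operating conditions;
the photoreceptor's adaptive state is initialized to the first luminance
sample, all other states to zero.  Halving dt changes the 10 ms averages
by well under 2% RMS on smooth test drives (tested).

**Normalization.** Each of the four signal *types* is scaled so that the
standard deviation of its positive excursions is one over a calibration
corpus; delayed signals share the gain of their undelayed source
(equivalent to normalizing before the linear unit-DC delay).  Gains are
calibrated once on the fixed-edge corpus of a run — the largest and most
diverse stimulus set — then frozen and applied to every corpus of that
run, so training and test data, and data from different regimens compared
in cross-generalization, stay on one scale.

**Correlation products.** Optionally, features are all pairwise products
of the 8 signals within a column (C(8,2) = 28, squares excluded) plus all
8×8 = 64 products between adjacent columns: 120/304/488 features for 2/4/6
columns, versus 16/32/48 raw signals.

## Synthetic stimuli

The study that this package models used photographs; those are not
redistributable inputs, so the generator synthesizes textures with the
dominant first-order statistic of natural scenes: Gaussian fields with a
1/f amplitude spectrum (exponent 1.0, radially isotropic in 2-D), set to
mean 128, contrast-scaled to SD 45 so ±2.8σ spans most of the 8-bit range,
clipped and quantized to [0, 255].  Long strips are concatenations of
independently drawn 500-pixel blocks — the seams introduce luminance
discontinuities of the kind natural imagery contains — and any block with
more than 15% of samples at 0 or 255 (strict inequality) is redrawn.

Scenes are animated at 200 µs steps with the pixel pitch equal to the
distance traveled per step (speed × dt), so motion is exactly one pixel
per step.  Image-dynamics classes: motion left/right at 25, 50 or
100 deg/s; flicker, realized as texture animated *perpendicular* to the
array (columns of a 2-D texture streaming past the window — temporal
modulation with no cross-correlation peak at the receptor transit time);
and static patterns.

**Fixed-edge universe.**  3 unordered dynamic-class pairs × 2 sides ×
3 speeds = 18 scenarios, with the medium speed (50 deg/s) twice as
frequent as slow or fast; plus 3 dynamic classes × 2 sides against static
imagery at 50 deg/s, each as frequent as a medium-speed pair scenario —
24 scenario classes, 36 frequency units.  Full-field (no-edge) data match
each dynamic class's — and each speed's — frequency of hemifield occupancy
(20 units per class: 4 slow, 12 medium, 4 fast); static full field is
excluded because its output is identically zero.  At reference scale the
corpus is 72,000 edge + 72,000 full-field 10 ms outputs (1,440 s of
responses), i.e. equal 50% priors.  A corpus `scale` shrinks all counts
proportionally; the desk scale used by the tests and the acceptance script
is 0.15 (21,600 patterns).

**Moving-edge universe.** All pairwise combinations of {Fourier object,
theta object, flicker, static}, where Fourier texture moves with the
edges (rightward, 50 deg/s) and theta texture moves opposite at equal
speed.  A scene tiles the field with 3°-wide segments of the two classes
alternating, all boundaries sweeping rightward at 50 deg/s, so each class
appears alternately left and right of successive edges; the segment width
is a package choice (the source gives none) — wide enough that neighboring
edges mostly stay outside the central region during a crossing.  Outputs
are recorded only while an edge lies strictly between the two central
receptors (a 20 ms crossing at 50 deg/s over 1°; two overlapped windows
per crossing), with exact per-ordering quotas so both left/right
assignments are equally represented.  Full-field data are class-balanced
{motion right, motion left, flicker} at 50 deg/s.  Reference scale:
20,000 + 20,000 outputs.  Fixed-edge corpora use 8 receptors, moving-edge
corpora 6.

## Edge network and training

A two-layer logistic network (nominally 32 hidden units, one output) with
table-lookup activation: tables span arguments [−8, 8] at index scale
Is = 200 (step 0.005, the logistic is within 3·10⁻⁴ of its asymptote at
the ends); weighted sums are rounded to the nearest table index and clamp
beyond the range.  Weights and biases initialize from a zero-mean Gaussian
with σ = Is/(1.33·N) in index units (N = hidden count).  Training is pure
per-pattern SGD on half the summed squared error with targets 1/0, pattern
order re-permuted each epoch, and learning rate η = η₀/(1 + η_e·k_e) with
defaults η₀ = 1.0, η_e = 0.0075 (midpoints of the protocol's stated
ranges).  De-novo training is multi-start: five initializations × 50
epochs, the lowest-loss one continued (spec'd full protocol: 800–1,000
epochs total; desk scale: 5 × 25 then 200 total).  Because SSE training
with 0/1 targets estimates the posterior probability of the edge class,
classification is Bayes thresholding: "edge" iff output > ½ (strict; an
output of exactly ½ is "no edge").  Updates are applied to real-valued
weights; rounding happens only at table lookup.  Each dataset is split
¾ train / ¼ holdout, stratified by label; one split is shared by the five
networks of a sample, which differ in initialization and pattern-order
seeds.  The whole pipeline is deterministic given the master seed (the
per-pattern loop is sequential, compiled with numba).

A continuous-activation mode bypasses tables and rounding so gradients can
be verified against finite differences and outputs against exact logistic
arithmetic; it is a verification tool, not the reference semantics.  No
vectorized mini-batch variant is provided: the compiled per-pattern loop
is fast enough that a second, non-reference training semantics would add
risk without benefit.

**Regimens.** FIXED (raw or product features; 2/4/6 columns), MOVING (raw
only), COMBINED (the moving corpus plus an equal-sized scenario-stratified
subset of the fixed-edge data, full-field half doubled the same way), and
SINGLE_EDGE_TYPE (one class pair versus the full full-field mixture at
equal priors, trained from weights learned on the full corpus).
Cross-generalization evaluates a sample trained on one regimen against the
other regimen's training portion.

## Pruning and significance

Each remaining input (or hidden unit) is zeroed in turn; the one whose
omission least increases the training-set SSE is removed with its
parameters, the network retrains for 150 epochs (midpoint of the protocol's
100–200; the η schedule restarts each retrain), and the loop repeats down
to one component.  With product features a product term is removed as a
group across all columns at once.  Ties break to the first-listed
candidate.  Note that omission increments are not exactly nonnegative:
zeroing a noise input of a trained network can lower the SSE by a few
parts in 10⁶, and table quantization adds comparable jitter.

Significance over five independently pruned networks: per trace the
survivor scores 10, the last-removed component 9, … down to 1; components
absent from a trace's final ten score 0; means and occurrence counts are
reported.  Because every catalogued scenario appears with its left–right
reflection at equal weight, the selected input set should be closed under
reflection; the symmetry report pairs each component with its mirror
(ON/OFF, sustained/transient and delay preserved; columns reflected;
inter-column products also swap factor order) and tabulates |score −
mirror score|.  On synthetic runs the expected mirror pairing is treated
as a statistical tendency, not a hard assertion.

## What the synthetic corpus does and does not show

The generator reproduces the *second-order* spatial statistics of natural
imagery, the block-seam discontinuities, the 8-bit quantization and the
saturation screen, but not the phase structure of photographs — no
objects, no piecewise-smooth surfaces, no sharp internal contours.
Consequences observed at desk scale (0.15, 200 epochs), fixed seed:

* conditions dominated by *dynamics versus stillness* or by *edge-motion
  transients* replicate the reference scores closely: single static-pair
  networks reach 100%, dynamic-pair networks 97.7%, fixed→moving
  cross-generalization 65.0% and moving→fixed 57.8%, moving-edge holdout
  83.9%;
* discrimination among *kinds* of dynamics (flicker vs. motion, opposed
  motion directions) is genuinely harder on Gaussian-phase textures: the
  2-column fixed-edge holdout score is ~81% rather than ~90%, and the
  deficit persists with 4× longer training, concentrated in full-field
  flicker and opposed-motion scenarios;
* *training* scores on small corpora are inflated by overtraining
  (e.g. the jointly trained networks score ~93–95% on their training
  portions); holdout scores are the comparable quantity at desk scale.

Passing tests therefore certify the machinery — filters, corpus
composition, training, pruning — and the ordering structure of the
results; absolute scores on photographic imagery are expected to differ in
the directions just listed.

## Other numerical and design choices

* Scene widths cover the receptor span plus full ±2r₀ kernel support, with
  a 2-pixel margin; slow/medium/fast scenes use pitches 0.005/0.01/0.02°.
* Texture block RNG streams derive from per-scene seeds via
  `numpy.random.SeedSequence` spawning; every corpus, split, training run
  and pruning trace is reproducible bit-for-bit from one master seed.
* Flicker sources stream 500-row blocks on demand so long scenes never
  hold the full 2-D texture in memory; optics is a chunked matrix product.
* Multi-start selection uses final training *loss* (not score); the
  stated protocol does not distinguish them.
* `calibrate_gains` raises on a signal type with no positive excursions
  rather than producing infinite gains.
* Pruning rejects a chance-level network (training score < 0.55) —
  omission losses on an untrained network are meaningless.
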