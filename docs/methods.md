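# Methods

## The tracking model

The tracker estimates the per-frame position of a single, rigidly sized
lesion box. Its state is (box position, region-flow model, particle cloud);
the appearance model is a per-sequence CNN trained once on frame 0. The
per-frame loop is:

1. enhance the frame with MSRCP and take the (HSV) value channel;
2. compute dense Lucas–Kanade flow from the previous enhanced frame;
3. weight each particle's box by the cosine similarity between its summed
   region flow and the reference flow vector, through a Gaussian kernel on
   the gap to the best particle (width ε), and normalize;
4. extract the top-weighted distinct particle boxes as candidates, always
   adding the zero-innovation candidate (previous box advanced by the model
   mean flow);
5. score candidates with the CNN and select the argmax; if no candidate
   scores above 0.5 the tracker coasts on the motion model for that frame;
6. update the reference flow model from the selected region
   (`h_α = h_{s−1}(1−β) + β h_s`, `w_α = w_s`);
7. systematically resample the particles, jitter them (σ = 1 px), and
   anchor the cloud at the selected center advanced by the mean model flow.

Assumptions: one target, no scale change (the box keeps its annotated
size), small inter-frame motion (≲2 px/frame, the differential-flow
regime), and an appearance that stays close to the first frame (the CNN is
never re-trained during a sequence).

### Ordering and stabilizing choices

Several orderings of weight → resample → candidates are defensible; we
extract candidates from the *weighted* set and resample afterwards (classic
sampling-importance-resampling), because after resampling weights are
uniform and "top-k by weight" would be meaningless. Two further choices
proved load-bearing in development and are deliberate design decisions, not
tuning: the zero-innovation candidate is the *motion-predicted* box rather
than the raw previous box (the raw previous box systematically wins the
appearance vote and makes the tracker lag by the per-frame velocity), and
the particle cloud is re-anchored at the selected position each frame (pure
flow-similarity weighting lets the cloud collapse onto background particles
whose noise flow happens to align with the reference, after which the
target is lost irrecoverably).

A stationarity shortcut holds the box whenever the mean motion magnitude
over the tracked region falls below 0.02 px/frame; with genuinely static
input the flow is exactly zero and the box never moves, while any real
motion at the scales the tracker is designed for (≥0.1 px/frame) clears the
threshold easily.

### Interpreting the printed formulas

Four of the underlying equations are ambiguous or degenerate as commonly
printed, and the implementation fixes a reading in each case:

- **Similarity.** The particle/target similarity is implemented as the
  cosine of the two region-flow vectors, bounded in [−1, 1] — the only
  scalar, scale-free reading consistent with calling it a similarity.
- **Weight kernel.** `q^i = exp(−(Consi_i − Consi_max)²/2ε²)` up to a
  constant prefactor that cancels exactly under normalization and is
  dropped. ε defaults to 0.2 (dimensionless, on the cosine scale).
- **Model update.** The exponential moving average
  `h_α = h_{s−1}(1−β)+βh_s`; the β ∈ {0, 1} limits and the fixed-point
  property (constant input is preserved for every β) pin this reading and
  are tested.
- **Similarity index.** SI = 1 − Bhattacharyya coefficient of the
  normalized histograms. The verbatim ratio form
  `1 − ΣH₁H₂/(ΣH₁·ΣH₂)` is degenerate for normalized histograms (the
  denominator is 1 and SI(img, img) ≠ 0); it remains available via
  `si(..., literal=True)` for comparison.
- The motion-intensity divisor z is read as the region pixel count, making
  w the region's mean motion magnitude in px/frame.
- The HSV conversion follows the standard hexcone branches (the V=G branch
  uses (B−R)); it is verified against an independent converter to within
  1° of hue on random pixels.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| MSRCP scales | 15, 80, 250 | px | canonical small/medium/large surrounds |
| clip percentiles | 1 / 99 | % | simplest color balance, standard choice |
| flow window | 5×5 | px | locality vs. noise on speckle |
| flow presmoothing σ | 1 | px | suppresses speckle grain before gradients |
| flow iterations | 3 | — | warp-and-resolve refinement; recovers 2 px shifts to <0.05 px |
| β (model update) | 0.5 | — | equal trust in history and current frame |
| particles n | 100 | — | covers a ±1 box-diagonal search region densely |
| ε (kernel width) | 0.2 | cosine units | concentrates weight on well-aligned particles |
| init spread | half box diagonal | px | covers plausible first-frame offsets |
| jitter σ | 1 | px | diversity floor after resampling |
| candidates k | 10 | — | classifier budget per frame |
| patch size | 32×32 | px | smallest size that keeps edge structure |
| CNN | 2 conv (8, 16 @3×3) + pool → 64-d → 2-way | — | per-sequence discrimination needs little capacity |
| CNN training | 32+32 patches, 20 epochs, Adam 1e−3 | — | trains in ~2 s on one core |
| hold threshold | 0.02 | px/frame | static-scene stability (see above) |

The CNN is implemented directly on numpy (im2col convolutions, softmax
cross-entropy, Adam), which keeps training bit-deterministic under a fixed
seed; positives are jittered crops with IoU ≥ 0.7 against the annotation,
negatives random same-size crops with IoU ≤ 0.3.

## The synthetic scenes

The generator emulates the features of gastrointestinal-filling CEUS that
the tracker actually exploits: a bright tissue background with unit-mean
multiplicative speckle (low-pass-filtered squared Gaussian field,
correlation length 1.5 px), a hypoechoic ellipse (default contrast 0.4,
semi-axes 10×6 px) whose interior carries its *own* speckle texture moving
with it, a raised-cosine lesion edge (2 px), optional global gain drift for
contrast wash-in, and small per-frame additive sensor noise (σ = 1.5 gray
levels). The standard benchmark scene is 128×128 px, 50 frames, linear
drift (0.4, 0.9) px/frame.

It does **not** simulate acoustic physics: no point-spread anisotropy, no
shadowing or reverberation artifacts, no out-of-plane motion, no
deformation, no microbubble kinetics. Passing the synthetic benchmark
therefore shows that the pipeline's estimation machinery works under
speckle, drift and sensor noise — not that it would survive the full
artifact spectrum of clinical CEUS.

## Numerical choices

- Gaussian surrounds in MSRCP run through an FFT with reflective padding
  (3σ, capped at the image size); uniform inputs short-circuit (flat
  Retinex response → identity), as do all-zero images.
- Lucas–Kanade declares a pixel unsolvable when the normal-equation
  determinant is below 1e−4 and assigns zero flow there.
- Boxes are half-open integer pixel intervals; centers are continuous
  (row + h/2, col + w/2). Ground-truth centers are analytic floats, so even
  a perfect integer-box tracker carries a ≤½-px-per-axis quantization
  floor in CLE.
- Candidate ranking ties break by higher particle weight, then lower index;
  particle-weight ties break to the lower index (stable argsort).
- All randomness flows from `numpy.random.SeedSequence` spawns of a single
  user seed; sequences, trained weights and trajectories are bit-identical
  across runs with equal inputs.
- Histograms for SI use 64 bins over [0, 256).

## Problem sizes

The test suite exercises the full pipeline on the 50-frame standard scene
with 20 tracker seeds (full pipeline vs. flow-only ablation); the
acceptance script uses 5 seeds. Both finish in roughly a minute on one CPU
core. These sizes give the benchmark means a seed-to-seed spread well below
the margins they are compared at.

## Known limitations

- Single target, fixed box size, no occlusion handling or re-detection.
- The differential flow solver is windowed but non-pyramidal: motions much
  above ~2 px/frame leave its regime (the warp iterations stretch this, but
  not indefinitely).
- The CNN never adapts after frame 0, so slow appearance drift (e.g. strong
  wash-in without enhancement) degrades the score-based selection; the
  coasting fallback masks brief failures only.
- χ² modality comparisons treat per-stage detections as independent
  Bernoulli outcomes, which is the standard but not the only analysis of
  paired-design counts.
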