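# ceustrack

Lesion tracking for contrast-enhanced ultrasound (CEUS) image sequences,
plus the evaluation metrics and clinical staging statistics that go with it.

Gastric-wall lesions imaged with gastrointestinal-filling CEUS appear as
hypoechoic (darker) regions drifting through a bright, speckled tissue
background. `ceustrack` follows a manually annotated lesion box through such
a sequence by combining four ingredients per frame:

1. **MSRCP enhancement** — multiscale Retinex with chromaticity
   preservation: log-domain Retinex on the intensity channel with Gaussian
   surrounds (default scales 15, 80, 250 px), percentile-clipped range
   stretching, and a single per-pixel gain applied to all channels.
2. **HSV features** — V = max(R,G,B), S = (max−min)/max, H from the hexcone
   conditional branches; tracking runs on the (enhanced) V channel.
3. **Differential optical flow** — dense Lucas–Kanade flow from
   spatiotemporal gradients. For a region `R`, the summed components
   `h_s = (Σu, Σv)ᵀ` and the motion intensity `w_s = ‖h_s‖ / z` (z = pixel
   count) are maintained across frames by the exponential moving average
   `h_α = h_{s−1}(1−β) + β h_s`, `w_α = w_s`.
4. **Flow-weighted particle filter + CNN** — particles carrying candidate
   boxes are weighted by the cosine similarity `Consi(R'_α, R_k)` between
   their region flow `R_k` and the reference `R'_α = h_α`, through the
   Gaussian kernel `q^i ∝ exp(−(Consi_i − Consi_max)² / 2ε²)`, then
   systematically resampled. The top-weighted candidate regions
   `Q_1 … Q_n` are scale-normalized to 32×32 patches and scored by a small
   convolutional network trained on augmented crops of the annotated first
   frame; the argmax-score candidate becomes the new position.

Tracking quality is reported as center location error (CLE, mean Euclidean
pixel distance to the true center), target overlap area ratio
(TOAR = area(s_a∩s_b)/area(s_a∪s_b)), and similarity index
(SI = 1 − Σ_P √(H₁(P)H₂(P)), one minus the Bhattacharyya coefficient of
gray-level histograms; lower is better).

The `diagnostics` module computes the accompanying clinical statistics —
per-TNM-stage predicted positive rate (PPR) against a pathological gold
standard, resectability sensitivity/specificity/accuracy from 2×2 counts,
and continuity-corrected χ² comparison between imaging modalities — and
ships the study count tables it was built around as CSV fixtures.

Because no clinical sequences are distributable, the `synthetic` module
generates CEUS-like scenes (multiplicative speckle, a moving hypoechoic
ellipse with a raised-cosine edge, optional contrast wash-in drift) with
exact ground-truth trajectories, which the test suite uses throughout.

## Worked example

```python
import ceustrack as ct

# a 50-frame synthetic CEUS scene with a lesion drifting (0.4, 0.9) px/frame
frames, truth = ct.generate_sequence(ct.SceneConfig(seed=5))
traj = ct.track(frames, truth.boxes[0], seed=7)
rep = ct.evaluate(traj, truth, frames)
print(f"CLE  = {rep.mean_cle:.2f} px")
print(f"TOAR = {rep.mean_toar:.3f}")
print(f"SI   = {rep.mean_si:.3f}")

# resectability performance from 2x2 counts (TP, FN, TN, FP)
print(ct.binary_performance(87, 4, 9, 2))
```

prints

```
CLE  = 2.10 px
TOAR = 0.768
SI   = 0.075
(95.6, 81.82, 94.12)
```

The tracker stays within about two pixels of the true lesion center on
average, keeps roughly 77 % box overlap, and the tracked region's intensity
distribution stays close to the annotated appearance (SI near 0). The last
line is sensitivity/specificity/accuracy in percent for a modality that
called 87 of 91 resectable and 9 of 11 unresectable cases correctly.

The same pipeline is scriptable from the shell:

```sh
ceustrack simulate --out demo/ --seed 5
ceustrack track --frames demo/ --init "30,29,20,12" --seed 7 --out demo/traj.csv
ceustrack eval --pred demo/traj.csv --truth demo/ground_truth.csv \
    --frames demo/ --report demo/report.json
ceustrack stats --in counts.csv --out summary.json
```

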