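# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Reduced-dose CT simulation

CT quantum noise is Poisson and arises in projection space, so the
simulator injects noise into sinograms and reconstructs, never into the
image directly. Each axial slice of a full-dose volume in Hounsfield
Units (HU) is processed independently:

1. **HU → attenuation.** `μ = μ_water · (1 + HU/1000)`, clipped below at
   zero. Air (−1000 HU) maps to μ = 0, water (0 HU) to μ_water. The
   default `μ_water = 0.0195 mm⁻¹` is the ≈120 kVp water value;
   configurable because the effective scan energy is rarely known.
2. **Projection.** Parallel-beam Radon transform (`skimage.transform.radon`),
   180 angles uniformly over [0°, 180°) by default, line integrals in
   μ·mm (discrete sum × pixel spacing). Slices are padded with air to
   cover the detector diagonal.
3. **Transmission.** Beer–Lambert: `T_fd = exp(−p)`.
4. **Detector counts.** `counts ~ Poisson(I0 · T_fd)` with
   `I0 = round(fraction · I0_ref)`; the reference flux `I0_ref = 10000`
   photons/bin, so a 10 % dose uses I0 = 1000. Per-slice RNG streams are
   derived as `seed + slice_index` so parallel slice processing stays
   reproducible.
5. **Noisy projection.** `P_ld = ln(I0 / counts)` with counts clipped to
   `[min_counts, I0]` (default floor 1): the floor keeps the log finite
   when a bin records zero photons, the cap keeps projections
   nonnegative. The floor only matters at extreme attenuation
   (p > ln I0 ≈ 9.2, i.e. ≈47 cm of water at 100 % dose).
6. **Reconstruction.** Filtered backprojection with a Ram-Lak (ramp)
   filter and linear-interpolation backprojection, then μ → HU and a
   clip to the 12-bit CT range [−1024, 3071].

At `fraction = 1.0` the input volume is returned untouched — originals
are the 100 % reference; a flag forces reprocessing when the
projector/reconstructor round trip itself is under study.

**Numerical behaviour.** The projector satisfies the analytic chord
oracle on a uniform disk to < 2 % and conserves per-angle mass to < 1 %.
The FBP round trip on a 128² disk has interior RMSE < 5 % of μ_water.
At sharp ±1000 HU interfaces FBP exhibits Gibbs ringing; round-trip
error statements therefore exclude a 2-voxel band around interfaces —
this is intrinsic to ramp-filtered reconstruction, not an implementation
artifact. Noise in a uniform soft-tissue region rises strictly as the
dose fraction falls (≈39 HU at 100 % to ≈119 HU at 10 % for the 64²
test geometry).

## Synthetic lung phantom

Real screening data (LUNA16-like) cannot ship with the package, so every
stage is exercised on seeded synthetic volumes: an air background at
−1000 HU, a soft-tissue body ellipsoid (−50…50 HU), two lung ellipsoids
(−900…−700 HU), Gaussian texture noise (σ = 20 HU default) inside the
body, and two lesion classes inside the lungs:

* **nodules** — spheres, 4–20 mm diameter, −100…100 HU, optionally
  lobulated by a low-frequency radial perturbation (5–15 % amplitude);
* **non-nodules** — the confounders radiologists flag: vessel segments
  and bifurcations (cylinders, 1–4 mm radius, 10–25 mm length,
  0…100 HU) and calcified granulomas (2–6 mm spheres, 300…800 HU).

Placement is margin-aware (lesions fit inside the lung with a
distance-transform margin) and collision-free, with bounded retries.
One structural constraint matters for label quality: every *negative*
lesion centre keeps a minimum Euclidean distance (default 32 mm, half
the default patch side) from every nodule centre. Without it, patches
centred on confounders frequently contain a neighbouring nodule and the
negative class becomes mislabeled for a classifier with global average
pooling — a situation real data does not present, since whole scans
average roughly one nodule.

A second realism constraint is the attenuation scale. Dose-reduction
effects live in the photon-starved regime: a clinical chest attenuates
to line integrals p ≈ 5–7, so at 10 % dose (I0 = 1000) detector counts
approach zero and reconstructions degrade dramatically. A miniature
phantom body (< 100 mm) is nearly transparent (p ≈ 1.5, hundreds of
counts even at 10 % dose) and mutes the very effect under study. The
reduced protocol therefore uses a ~150 mm body (p ≈ 2.7, minimum counts
at 10 % dose in the tens), the largest geometry whose slice-wise
projection/reconstruction stays affordable on one CPU.

What the phantom does **not** emulate: airway trees, fissures, pleural
attachment, respiratory motion, scanner-specific texture, and the
long-tailed morphology of real nodules. Passing tests therefore
demonstrate that the pipeline's mechanics and relative dose effects are
correct, not that the trained weights transfer to clinical data.

## Preprocessing

Volumes are resampled to isotropic 1 mm spacing by trilinear
interpolation (centre-aligned grid convention), normalized linearly from
a fixed HU window — default (−1000, 400) — to [0, 1], and cropped to
cubic patches (default 64³) centred on lesion candidates. A fixed window
rather than per-image min/max keeps intensities comparable across dose
levels. Patches at the volume border are padded with the normalized air
value so the lesion stays centred; the centre voxel maps to index
`side // 2`.

## The classifier

A four-block 3D CNN: each block is convolution (3³ kernels, stride 1,
'same' padding) → batch normalization → ReLU → 2³ max pooling; filter
counts 64/128/192/256 (the 128/192 interpolate the stated 64→256
endpoints); head = global average pooling → dropout (0.3) → one sigmoid
unit. Label 1 = nodule. Training uses Adam on binary cross-entropy with
an exponential schedule `lr(e) = lr₀ · 0.96^e`, lr₀ = 1e-4, ~40 epochs,
batch 16, on a stratified 60/20/20 train/validation/test split; the
weights from the epoch with the lowest validation loss are retained.
One independent instance is trained per dose level
{100 %, 60 %, 40 %, 20 %, 10 %}, each seeing only its level's patches.

Because no deep-learning framework is assumed, the network and its
reverse-mode gradients (im2col convolution, batch-norm, pooling, Adam)
are implemented in numpy (`erbnet._nn`), float32, single-threaded and
bit-reproducible under a fixed seed. Gradients are verified against
central finite differences in float64, and the convolution against
`scipy.ndimage.correlate`.

### Reduced test preset

Full-size training is a GPU-scale job, so the test surface is a scaled
preset: 1/8 filter counts (8/16/24/32), 32³ patches, 50 patches per
class per dose level (five 160×160×40 phantoms of 20 lesions each),
10 epochs, 64 projection angles. Two recipe
adjustments compensate for the ~30× fewer optimizer steps relative to
the full-size recipe (≈3000 steps at 1200 patches × 40 epochs): the
learning rate is raised to 3e-3 (batch 8), and training data are
augmented with random cube symmetries (axis flips and in-plane
transposition), the standard remedy for 3D training sets this small.
Two further guards address small-sample instability: if the best
validation loss stays above 0.35 the fit restarts once from a fresh
derived init (the attempt with the lower validation loss wins —
selection touches only validation data), and max-pooling gradient ties
split evenly (relevant only in constant padding regions).

At this scale the classifier is sample-limited: tripling the training
set raises held-out accuracy from ≈0.80 to ≈0.88 while 10 epochs no
longer suffice to fit it. Numbers from the reduced preset demonstrate
ordering effects (dose degradation, dedicated-model advantage, ensemble
robustness), not the absolute accuracy attainable at full scale.

## The ensemble

The five per-dose models are combined by weighted averaging of their
nodule probabilities. The weight vector is selected by sampling the
probability simplex with Dirichlet(α = 1) draws — 20 000 candidates by
default — scoring each candidate on a labeled tuning set, and keeping
the argmax (ties to the first occurrence in sample order). The K one-hot
vectors are always appended to the candidate list, so on the tuning set
the ensemble can never underperform its best constituent. The selection
metric is accuracy at threshold 0.5; AUC is selectable but couples
poorly with a fixed decision threshold and is not the default. The
tuning set is carved from the validation splits (mixed over dose
levels); the test set stays untouched until the final mixed-dose
evaluation.

## Metrics

Sensitivity = TP/(TP+FN), specificity = TN/(FP+TN), precision =
TP/(TP+FP), accuracy = (TP+TN)/total, F1 = harmonic mean of precision
and sensitivity. Thresholding uses the `prob ≥ 0.5` rule (ties positive).
Metrics with empty denominators are reported as NaN rather than 0 or an
exception. ROC curves sweep every distinct score (no collinear-point
dropping), so the trapezoidal AUC equals the Mann–Whitney pairwise
statistic exactly, ties counted ½.

## Study protocol

`run_protocol` chains the stages: generate phantoms → simulate the four
reduced-dose levels → extract matched lesion-centred patches per level
(the same lesions at every dose, so cross-dose comparisons are paired)
→ split lesion indices once into 60/20/20 and reuse the partition at
every level → train the five models → evaluate every model on every
level's test patches (the cross-dose accuracy matrix) → search ensemble
weights on the mixed-dose validation pool → evaluate the ensemble on
the mixed-dose test pool, overall and per dose stratum. Every artifact
records the configuration hash and seed; a rerun with the same global
seed reproduces the report bit for bit.

## Known limitations

* 2D slice-wise parallel-beam geometry; no cone-beam, helical paths,
  beam hardening, scatter or electronic noise.
* The numpy engine is tuned for the reduced preset; full-size 64³
  training works but is slow and memory-hungry on one CPU.
* Per-stratum comparisons in the reduced protocol rest on 20-patch test
  cells; single-sample flips move those accuracies by 5 points, so only
  seed-averaged orderings are meaningful at this scale.
* The phantom's intensity model is piecewise-constant plus Gaussian
  texture; classifiers trained on it do not transfer to clinical CT.
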