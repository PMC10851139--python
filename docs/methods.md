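# Methods

## Design

The package benchmarks four training strategies on one task: slide-level
binary classification of invasive melanoma (IM) versus nevus from
patch-tessellated lesion images distributed across six sites. Sites 1–5
contribute training data and an in-distribution holdout test set; site 6 is
an external cohort that never touches training or tuning. All strategies
share one patch-training loop, one preprocessing path and one evaluation
path, so measured differences are attributable to the data-access pattern
(federated vs pooled vs per-site) rather than implementation detail.

## Synthetic slide generator

Clinical WSI cohorts of this kind are not publicly deposited, so the
generator emulates the statistical structure the comparison depends on, not
histological appearance:

* **Geometry.** Each slide is an RGB canvas (desk default 128 px, full
  default 896 px) with an elliptical lesion ROI covering 30–70% of the
  canvas on a pale tissue-tinted background.
* **Class signal.** Lesion texture is a variance-normalised Gaussian random
  field: correlation length ~1 px for IM (high-frequency, irregular) and
  ~6 px for nevi (low-frequency, regular blobs), at equal mean colour and
  amplitude (30 intensity units, ±15% per-slide jitter). Class identity is
  therefore carried by texture frequency, as measured by local-variance
  features. Contract, verified in tests: the mean 3×3 local-variance
  feature separates classes with Cohen's d > 1 over 50 renders, and a
  logistic model on mean patch colour+texture features reaches AUROC > 0.9
  within one site.
* **Site shift.** Each site applies a per-channel multiplicative stain gain
  in [0.5, 2]; sites 1–5 get modest mutually distinct gains, site 6 a
  clearly distinct gain (1.25, 0.85, 1.15) plus a different texture scale
  (1.2), making it genuinely out-of-distribution.
* **Cohort structure.** Default site sizes and melanoma fractions follow
  the six-hospital reference cohort (71/97/107/178/236/336 slides; IM
  fractions 19/71 … 142/336; 1025 slides total), optionally scaled.
  About 10% of slides reuse an existing patient id (~1.11 slides/patient).
  Categorical covariates (age band, lesion subtype, AJCC stage) are sampled
  from per-class marginal tables, with site 6 drawing from shifted tables;
  covariates feed only the χ² cohort-composition tests, never the
  classifier.
* **Artifacts.** A configurable fraction of each slide's area (default 5%)
  is replaced block-wise by a Gaussian-blurred copy; blocks default to a
  quarter of the canvas edge so that degraded area maps onto whole patches
  and the blur QC path is actually exercised.

What the generator does **not** emulate: nuclei, epidermis morphology,
stain chemistry, scanner noise, label noise, or realistic intra-class
heterogeneity. Passing tests therefore demonstrate that the pipeline's
machinery (protocols, statistics, QC, reproducibility) is correct and that
the strategies can learn a site-shifted texture task — not that any
strategy would reach a particular accuracy on clinical slides. Headline
clinical AUROCs are out of reach by construction, since they depend on
non-deposited patient data.

## Preprocessing

The ROI is tessellated on a non-overlapping grid after downscaling. A grid
square becomes a patch iff ≥ 50% of it lies inside the ROI mask (the
coverage threshold is a package choice). Sharpness is the variance of the
3×3 Laplacian of the ITU-R BT.601 grayscale patch with reflect padding;
"Laplacian below a threshold" is read as this variance-of-Laplacian focus
measure, the standard choice. The full-scale defaults are a 224-px patch
edge, 0.25 µm/px source resolution and a 1.84× downscale — chosen so the
printed physical patch edge 224 × 0.25 × 1.84 = 103.04 µm is reproduced
exactly, since only the physical size, not the downscale factor, is
specified — a blur threshold of 510, and a 50-kept-patch inclusion rule.
The 510 threshold is meaningful only on the intensity scale of real scans;
the desk profile uses 10.0, calibrated once to the generator's statistics
(sharp synthetic patches score ≳30, Gaussian-blurred blocks ≲5) and then
frozen. Coordinates are 0-based, row-major, half-open.

## Training

`tiny_cnn` (three conv/ReLU/pool blocks, global average pooling, linear
head; ~6.1k parameters) is the default backbone: large enough to learn the
texture task, small enough that the 8-model desk experiment trains in
seconds per model on one CPU. A structural `resnet18` (random init, 2-class
head) exists for parity with larger studies; no pretrained weights ship
with the package. The forward/backward passes are implemented in numpy,
which makes single-threaded training bitwise reproducible under a fixed
seed — the reproducibility mode all identity tests rely on.

Optimisation is SGD with momentum 0.9 (the 1-cycle policy's usual
companion; the optimiser is a package choice) and unweighted cross-entropy.
The 1-cycle schedule ramps linearly from lr_max/25 to lr_max over the first
half of training and cosine-anneals to lr_max/2500 over the second half.
Each epoch draws `ceil(fraction × n_kept)` patches per slide without
replacement, re-sampled fresh every epoch ("amount of data per WSI in one
epoch"); batches shuffle patches across slides and sites, which is also why
centralized pooling needs no extra interleaving step.

## Federation

Per round every site advances the current global model by
`max(1, round(sync_factor × n_k))` local steps — intervals count optimizer
steps, the most reproducible reading of a "time interval" — and the models
are merged with weights proportional to per-site *slide* counts (patch-count
weighting is available behind a flag; slide counts are robust to per-slide
patch variance). Two deliberate choices: the 1-cycle schedule spans each
site's whole federated run rather than each interval, avoiding repeated
learning-rate restarts; and per-site optimizer state (RNG, epoch buffer,
momentum velocity) persists across rounds, which makes a single-site
federation bitwise identical to one uninterrupted local run — an exact
identity the test suite asserts. Sites train sequentially on one process; a
transport layer is explicitly out of scope.

The linear-probe backbone (an affine score on seven fixed colour/texture
features) exists because its prediction is linear in the parameters, so
"prediction of the merged model = merge-weighted average of member
predictions" holds exactly and is tested at 1e-10.

## Evaluation

The slide (lesion) is the evaluation unit. AUROC is computed in its
Mann–Whitney form (ties ½); secondary metrics threshold the slide
probability at 0.5 (no operating point is prescribed; 0.5 is the neutral
choice). The paired bootstrap resamples slides with replacement (default
1000 replicates; single-class replicates are redrawn) and scores every
model on the identical index set per replicate; summaries are replicate
means with nonparametric percentile 95% CIs. Patient-level resampling is
available behind a flag for cohorts where patients contribute two slides.

Model pairs are compared with two-sided Wilcoxon signed-rank tests applied
to the paired bootstrap replicate series — following the design being
benchmarked, which pairs comparisons over the bootstrap iterations. Such
p-values are conditional on the resampling and are flagged as such in
reports: with replicate noise redrawn per replicate the procedure is
calibrated (verified at ~nominal type-I level in the suite), but for two
fixed prediction vectors it tests the *consistency* of an observed
difference across resamples, not the sampling variability of that
difference. Zero differences are dropped and ties mid-ranked; the exact
null distribution is used for ≤25 non-zero pairs without rank ties (the
exact distribution is undefined under mid-ranked ties, so ties fall back to
the normal approximation with continuity correction). Bonferroni adjustment
uses the number of comparisons in each family: federated vs
centralized/ensemble (m=2, threshold 0.025) and federated vs each
leave-one-site-out model (m=5, threshold 0.01). χ² cohort tests are Pearson
without continuity correction, "Unknown" categories excluded.

## Tuning

Validation splits are lesion-level and label-stratified within each site
(30% default), with largest-remainder rounding and a never-empty-train
guard. The TPE sampler is a compact in-package implementation (random
start-up, top-25% good/bad split, per-dimension Gaussian KDEs in
transformed space, best of 24 candidates by density ratio); the tests pin
down the search contract — determinism, no stale best, convergence to
within 10% on an analytic objective — not sampler internals. A fairness
check refuses cross-strategy comparisons with unequal trial budgets unless
overridden.

## Problem sizes and defaults

The desk profile — the configuration the test suite and the acceptance
script run — uses 1/8-scaled site sizes (128 slides), 128-px canvases,
32-px patches, a 4-kept-patch inclusion rule, 15% holdout fraction
(mirroring a 103-of-689-lesion holdout), lr_max 0.05, 4 epochs, per-WSI
fraction 0.5, batch 32, and for federation sync_factor 0.25 with 8 rounds —
the round count, like the other training defaults, stands in for the
per-strategy tuned values of a full study and was chosen so every strategy,
including FL, converges on the default generator across seeds. Bootstrap
defaults to 1000 replicates. The full profile restores paper-scale geometry
and cohort sizes.

## Known limitations

* Synthetic realism as above; no augmentation, class weighting, or
  pretrained initialisation.
* Batch normalisation statistics (resnet18) are merged by the same weighted
  average as trainable parameters — standard FedAvg practice, but an
  approximation.
* The momentum buffer persists across federated rounds locally and is never
  aggregated; other FL optimizer-state conventions exist.
* Bitwise reproducibility holds for single-threaded numpy; multi-threaded
  BLAS may change floating-point summation order across machines.
* The Wilcoxon-on-replicates comparison inherits the conditionality caveat
  above; DeLong-style variance estimates are deliberately out of scope.
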