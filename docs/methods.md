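# Methods

`octcvd` implements an end-to-end analysis for predicting five-year
myocardial-infarction/stroke risk from retinal optical coherence tomography
(OCT): phantom data generation, scan-quality filtering, matched-cohort
construction, per-eye variational-autoencoder (VAE) representation
learning, multimodal random-forest (RF) classification over seven
data-channel combinations, and dual global/local explainability including
a latent-traversal vector-field method. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
experiments do and do not show.

## The synthetic OCT phantom

Real macular OCT volumes with linked cardiovascular outcomes cannot be
redistributed, so the package generates phantom cohorts carrying the
statistical structure the analysis relies on. Each subject contributes two
eyes; each eye is a stack of B-scans (128 per volume at the default
protocol) rendered as horizontal reflectivity bands for the ten named
retinal boundaries (ILM, RNFL, GCL, IPL, INL, OPL, BMEIS, IB_OPR, IB_RPE,
OB_RPE) plus a choroidal band ending at a lower choroidal boundary.

Geometry and appearance:

* **Band stack.** Per-scan band thicknesses are Gaussian around defaults
  that scale linearly with image height (choroid: 24 px at 128-px height).
  All boundaries share a smooth undulation (sum of up to three
  low-frequency sinusoids with random phases, anatomy-proportional
  amplitude of 2 px at 128-px height), so ground-truth band thickness is
  exactly the sampled value in every column. Rare tail draws that would
  overflow the image are rescaled proportionally; a *mean* stack that
  cannot fit raises a configuration error.
* **Choroidal texture.** The choroid carries a deterministic
  depth-relative sinusoidal texture (amplitude 0.15, one cycle across the
  band) emulating its vascular lamination. The texture is tied to
  band-relative depth, so a thickness change stretches the pattern through
  the whole band — this is what lets a displacement-field explanation
  attribute change to the choroid *as a region* rather than to a single
  moving edge, mirroring how choroidal remodelling presents in real OCT.
* **Noise.** Multiplicative gamma speckle (mean 1, SD = `speckle_level`,
  the standard OCT speckle model) plus an additive detector-noise floor
  whose SD grows as per-eye quality falls. Per-eye nominal quality is
  Gaussian; the left eye draws a higher mean (0.75 vs 0.65), emulating
  acquisition-order effects in which left eyes are scanned second and
  move less.
* **Planted signal.** The CVD+ group's mean choroidal thickness is scaled
  by `1 + choroid_effect`; an optional RNFL/GCL thinning toggle is off by
  default so the choroid is the unique recoverable target. The literature
  does not quantify the real effect size, so it is a free parameter; the
  end-to-end study uses +35%, a deliberately strong planted effect chosen
  so that signal recovery, not statistical power, is what the study tests.
  Both eyes share a subject-level anatomy latent with correlation 0.8
  (same-subject anatomy is correlated but not identical).
* **Metadata.** Age (60.78 ± 6.47 y, identical across groups so matching
  is testable), sex (29.7% female), ethnicity, alcohol status, and the
  per-group BMI/SBP/DBP/HbA1c means and SDs are calibrated to the
  published CVD+/CVD− cohort characteristics. CVD+ event offsets are
  uniform on (0, 5] years. Diabetes (5%) and cardiomyopathy (1%) flags
  feed the exclusion stage.

What the phantom does **not** model: optical point-spread and attenuation
physics, vessel shadowing, motion artefacts, pathology other than the
planted effect, and any genuine anatomical covariance between metadata and
retinal structure. Passing end-to-end tests therefore shows that the
pipeline *recovers a known planted signal under realistic noise*, not that
it would achieve any particular performance on clinical data.

## Quality index

The QI of a [0, 1]-normalised B-scan is the product of an **intensity
ratio** and a **tissue signal ratio**, both referenced to the scan's own
noise level. Noise statistics (mean, SD) come from the pre-retinal
vitreous band — the top rows of the scan, dark by acquisition geometry and
the standard reference region for OCT noise estimation. The intensity
ratio divides the mean of the pixels at or above the saturation-free upper
histogram mode by the noise ceiling (vitreous mean + 3 SD); the tissue
signal ratio counts unsaturated pixels above a noise-adapted reflectivity
threshold (0.55 + 3 SD) against all remaining pixels. Two properties drove
this design, both verified empirically in the test suite:

1. QI must *fall* monotonically as speckle or detector noise grows. A
   purely fixed-threshold count ratio does the opposite: noise lifts dark
   pixels across the low threshold and inflates the ratio.
2. QI must rank *acquisition quality*, not anatomy. Every image-global
   noise statistic we tried (median splits, Laplacian-based estimators,
   background-mode windows) was confounded by choroidal thickness, which
   changes the image's intensity composition; a 20% QI filter then
   preferentially discarded thick-choroid (CVD+) subjects. The vitreous
   band is anatomy-free by construction and removes the confound (residual
   case/control QI gap ≤ 3%).

Explicit `tau_hi`/`tau_lo` arguments switch to the classical
fixed-threshold, hand-computable form used in calibration tests. Volume
QI is the median over B-scans (whether the source protocol scored
per-scan or per-volume is unstated; per-scan with a median roll-up is the
more granular choice). Filtering excludes the `floor(0.2 N)` lowest-QI
items with stable-order tie-breaking; in the pipeline a subject is scored
by the worse eye.

## Cohort construction

CVD+ eligibility requires the first event in the half-open window
(0, 5] years after imaging ("within five years" read inclusively;
pre-imaging events excluded). Diabetes and cardiomyopathy are exclusion
criteria (retinal/choroidal confounders). Matching is 1:3 on a logistic
propensity score over age and sex with exact sex stratification, greedy
nearest-neighbour selection without replacement in seeded-random case
order, and a 2-year age caliper (3 years in the end-to-end study, whose
control pool is smaller). The matcher refuses silent partial matching: it
raises an error listing every unmatched case. The pipeline then drops
those cases *explicitly* — as its own STROBE ledger step — and retries.
Every stage appends to the ledger, whose counts must chain exactly
(n_after = n_before − n_excluded, step to step).

## VAE representation learning

One VAE per eye, trained on B-scans as independent images and used
deterministically at inference (posterior mean; no sampling). The loss is

    L = L_MSE + beta * L_KL,
    L_MSE = mean squared pixel error,
    L_KL  = 0.5 * sum_d (sigma_d^2 + mu_d^2 - 1 - log sigma_d^2),

the standard nonnegative Gaussian KL to the unit prior summed over latent
dimensions (the sign convention that makes minimising L equivalent to
maximising the evidence lower bound). Beta is annealed linearly from
0.001 at epoch 0 to 0.01 at epoch 20 and held constant thereafter — the
ramp shape between the stated endpoints is the simplest monotone choice.
Reparameterised sampling is used only during training, with a seeded
generator; identical seeds give bit-identical training runs.

Architecture: stride-2 convolutions (kernel 4, padding 1, channels
doubling from `base_channels`, ReLU) ending in a dense layer that emits
mean and log-variance of a 128-dimensional latent at the default
protocol; the decoder mirrors with transposed convolutions, LeakyReLU
(0.2) activations and a sigmoid output. Exact channel widths, batch size,
learning rate and weight decay are configuration-driven. The layers are
implemented directly on numpy (im2col convolutions, manual
backpropagation, Adam) and finite-difference gradient-checked in the test
suite; log-variances are clamped to ±15 for numerical safety.

Per-eye, per-subject representation: the mean of per-B-scan posterior
means over **all** B-scans (a `central_slice` / explicit-subset mode
exists; whole-volume aggregation is the default because restricting to a
few slices discards most of the volume). The internal data split for VAE
training is 6:2:2.

## Classification

Seven feature sets over the same subjects: left-eye latents (LE),
right-eye latents (RE), both (BE), metadata only (MTDT), and the three
latent+metadata combinations; columns are concatenated in the fixed order
[zl | zr | metadata]. The eight clinical variables are sex, age, HbA1c,
SBP, DBP, alcohol, BMI and ethnicity; categoricals are integer-coded
(forests are invariant to any monotone coding) and missing continuous
values are imputed as 0, matching the gap-handling convention of the
clinical comparator. Subjects split ~5:2:3 into train/validation/test,
stratified by label and seeded; the held-out test split is pinned by an
id hash asserted at every evaluation.

Each mode's features are reduced by recursive feature elimination with
forest importances (dropping 10% per round; top 10 kept, top 5 for RE),
then a random forest is tuned by seeded stratified 5-fold grid search on
AUROC and refit. Evaluation at probability threshold 0.5 reports
accuracy, sensitivity, specificity (with confusion counts) and the
rank-statistic AUROC (ties count one half — the all-pairs probability
comparison), with 95% percentile-bootstrap CIs over test subjects.
Classifier pairs are compared with McNemar's test on the discordant
correctness counts without continuity correction, df = 1 (a
contingency-table chi-squared variant is available behind a flag; which
of the two the original comparison used is not stated).

## Explainability

**Global.** Mean Gini importance per feature from the fitted forest
(normalised to 1), rolled up into percentage shares per data channel
(zl / zr / metadata).

**Local (latent traversal).** For the best latent-bearing classifier,
z_max is the most important latent feature (ties break to the lowest
index). The perturbation multiplies that single latent component by
sigma_max, its population SD over the training subjects' representations
— multiplicative exactly as specified, with additive ±k·sigma variants
available for sensitivity analysis. Both latent vectors are decoded and a
single-level Lucas–Kanade solver estimates the displacement field between
the two reconstructions (default) or between the original image and the
perturbed reconstruction (configurable; the default cancels shared
reconstruction error). Lucas–Kanade uses a 5×5 window, central-difference
spatial gradients, and masks pixels whose windowed structure tensor has
minimum eigenvalue below 1e-4 — perturbation displacements are sub-pixel
to a few pixels, so a single pyramid level suffices. The magnitude field
is overlaid on the original B-scan with a 16×16 quiver of landmarks.

With phantom ground truth available, per-band mean magnitudes and a
**choroid enrichment** score are computed: the fraction of top-decile
magnitude pixels inside the choroidal band divided by the band's area
fraction (1 = no localisation). The identity perturbation (scale 1)
yields bit-identical reconstructions and an exactly zero magnitude map —
a null exercised in the tests.

**Occlusion comparator.** A mean-intensity patch slides over the image;
saliency is the drop in predicted CVD+ probability when the patch covers
each location, normalised to [0, 1].

## End-to-end study conditions

The scaled-down recovery study (also what `scripts/acceptance.py` runs)
uses: 75 cases and 300 controls generated; 16 B-scans per eye at 64×64;
+35% planted choroidal effect; 20% quality exclusion; 1:3 matching with a
3-year caliper (~200 matched subjects); per-eye VAEs with 32 latent
dimensions, 4 conv layers, base 16 channels, 40 epochs at batch 32 with
the standard annealing endpoints (trained on every second B-scan; latents
extracted from all 16); RFE to 10 features (5 for RE); a small RF grid;
1000-sample bootstrap CIs. These sizes keep a full run within minutes on
a single CPU while leaving the planted signal recoverable: image-bearing
channels decisively beat metadata alone. The vector-field explanation
concentrates above the area-fraction null in the choroidal band for most
case subjects, but the concentration is partial at this scale — see the
limitations below for why.

## Known limitations

* The phantom's layer geometry is banded and noise-stationary; no
  segmentation of real OCT is attempted, and ground-truth boundaries come
  from the generator.
* MSE-trained VAE reconstructions are blurry at desk scale; the
  explanation stage depends on the decoder rendering the choroidal
  texture, which needs sufficient training data and epochs. The blurred
  lower choroidal edge also spreads part of the displacement-field
  support just below the band, where an in-band pixel count does not
  credit it.
* Latents are not explicitly disentangled: z_max may co-encode nuisance
  geometry (boundary undulation), which leaks some vector-field magnitude
  onto bright inner-retina edges; which latent dimension carries the
  cleanest choroidal content varies between training runs. Both effects
  dilute the top-decile concentration of the flow magnitude inside the
  choroidal band, and the perturbation strength (multiplicative sigma_max)
  scales with each subject's own latent deviation, so near-mean subjects
  contribute weak, noisy maps.
* The QI reproduces the *ingredients* of the cited quality index, not its
  exact numerics (the original algorithm is not public).
* Published cohort counts, QRISK3 scoring and device specifics are out of
  scope; the metadata-only classifier is the in-repo baseline.
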