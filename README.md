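# octcvd

Predicting five-year myocardial-infarction/stroke risk from retinal
optical coherence tomography (OCT), as a tested, reusable pipeline:

1. **Synthetic OCT phantoms** — macular volumes (stacks of B-scans with
   the ten named retinal boundaries plus a choroidal band), speckle and
   detector noise, two eyes per subject, and clinical metadata calibrated
   to published CVD+/CVD− cohort characteristics. A parameterised
   choroidal-thickening effect is planted in the CVD+ group, so every
   downstream stage can be tested against a known ground truth.
2. **Quality filtering** — a noise-referenced quality index (intensity
   ratio × tissue signal ratio) with exclusion of the lowest 20%.
3. **Cohort construction** — 5-year event window, diabetes/cardiomyopathy
   exclusions, 1:3 age/sex propensity matching, and a STROBE-style ledger
   whose counts chain exactly.
4. **Representation learning** — one convolutional variational
   autoencoder (VAE) per eye, loss `L = L_MSE + β·L_KL` with β annealed
   0.001 → 0.01 over the first 20 epochs, 128-dimensional latents at the
   default protocol, deterministic posterior-mean inference.
5. **Classification** — random forests over seven data-channel
   combinations (left eye, right eye, both eyes, metadata, and the three
   latent+metadata mixes), recursive feature elimination (top 10; top 5
   for right-eye-only), seeded 5-fold grid search, evaluation on a fixed
   held-out split at threshold 0.5 with bootstrap CIs, and McNemar
   comparison between classifiers.
6. **Explainability** — global Gini feature/modality importance, plus a
   local latent-traversal method: multiply the most classifier-important
   latent dimension z_max by its population SD σ_max, decode both latent
   vectors, and compute the displacement field between the
   reconstructions with a Lucas–Kanade solver, overlaid on the original
   B-scan. An occlusion-saliency comparator is included.

It is aimed at researchers who want to study or extend this class of
imaging-plus-metadata risk models without access to the original cohort
data: the phantom module stands in for the unavailable volumes, and the
planted effect makes recovery quantifiable.

## Worked example

A desk-scale end-to-end run (tiny cohort, shallow VAE, ~1 minute):

```python
from octcvd.pipeline import smoke_config, run_pipeline

result = run_pipeline(smoke_config(seed=1), verbose=True)
print(result.metrics[["classifier", "accuracy", "auroc"]].to_string(index=False))
print(result.ledger.to_text())
```

prints the per-stage log, a 7-row metrics table, and the cohort ledger:

```
 classifier  accuracy  auroc
      LE-RF  1.000000    1.0
      RE-RF  1.000000    1.0
      BE-RF  1.000000    1.0
    MTDT-RF  0.666667    1.0
 LE-MTDT-RF  1.000000    1.0
 RE-MTDT-RF  1.000000    1.0
 BE-MTDT-RF  1.000000    1.0
[ n = 60 ]
  |-- excluded 12: lowest 20% per-volume QI
[ n = 48 ]  (quality_filter)
  |-- excluded 2: diabetes present
[ n = 46 ]  (exclude_diabetes)
  |-- excluded 2: cardiomyopathy present
[ n = 44 ]  (exclude_cardiomyopathy)
  |-- excluded 0: CVD+ event outside (0, 5.0] years
[ n = 44 ]  (event_window)
  |-- excluded 1: cases without 3 controls within caliper
[ n = 43 ]  (unmatchable_cases)
  |-- excluded 23: unmatched after 1:3 propensity matching
[ n = 20 ]  (matching)
```

(At this toy size the test split holds only six subjects, so the metrics
are coarse; they demonstrate the plumbing, not performance. The
`recovery_study_config` preset — ~200 matched subjects, 16 B-scans per
eye at 64×64, +35% planted choroidal effect — is the configuration at
which the planted signal is genuinely recovered: image-bearing channels
clearly beat metadata alone, and the vector-field explanation
concentrates on the choroidal band.)

The same stages are exposed on the command line:

```bash
octcvd simulate --cases 10 --controls 30 --bscans 8 --size 64 --out scratch/cohort
octcvd quality --in scratch/cohort --out scratch/scores.csv
octcvd cohort --in scratch/cohort --out scratch/matched.csv
octcvd train-vae --in scratch/cohort --eye L --epochs 20 --out scratch/vae_L.npz
octcvd run --seed 1 --out scratch/results       # full pipeline
```

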