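# petradiomics

A tested, reusable implementation of a PET radiomics survival-analysis
pipeline for solid tumors: from a 3D PET-like uptake volume to texture
features, feature selection and concordance-based survival models — exercised
entirely on synthetic phantoms and synthetic cohorts, so every stage is
reproducible without access to patient images.

It is written for medical physicists and biostatisticians who want the full
chain — segmentation convention, grey-level quantization, texture-matrix
definitions, selection protocol and model comparison — as explicit, unit-
tested code rather than as a black-box toolbox.

## What it computes

**Segmentation.** The tumor VOI is the 26-connected component of
`{v : SUV(v) ≥ 0.4 · SUVmax}` containing the hottest voxel. Tumors smaller
than 2.6 ml are excluded (texture statistics are unstable on few voxels;
2.6 ml is the volume of the third-smallest NEMA IEC sphere, 17 mm inner
diameter).

**Features.** SUVs inside the VOI are digitized into B = 64 min–max bins;
texture matrices are accumulated over the 13 unique 3D directions. With
p(i,j) the run-length counts (grey level i, run length j), N_r = Σ p(i,j),
N the voxel count and D the direction count:

    run percentage  RP    = N_r / (D·N)
    LILRE                 = (1/N_r) Σ_{i,j} p(i,j) · j² / i²

LILRE (low-intensity long-run emphasis) up-weights long runs (j²) at low
grey levels (1/i²) — large values mean long homogeneous stretches of faint
uptake, the signature of a smooth, Gaussian-like tumor border. The analogous
zone statistic (LILZE), co-occurrence homogeneity/contrast, neighbourhood
grey-tone coarseness, texture-spectrum code similarity, first-order
histogram statistics and the SUV/SUL peak complete the feature vector.
Every matrix builder is verified against brute-force enumeration.

**Selection.** LASSO-penalized Cox regression is repeated (default 1000
runs) on bootstrap resamples, the penalty chosen per run by 10-fold
cross-validated partial-likelihood deviance (one-standard-error rule);
features active in more than half the runs are selected. Spearman/Pearson
screens flag redundant or clinically entangled features.

**Survival models.** Cox proportional-hazards fits (Efron ties), Harrell's
c-index `(concordant + ½·tied) / comparable`, 10-fold cross-validated
c-index, paired-bootstrap comparison of two models' c-indexes, Kaplan–Meier
curves split at the feature median with a log-rank test, Wilcoxon rank-sum
group tests, and the in-field / marginal / out-field recurrence-pattern rule.

**Synthetic data.** Spherical lesions on the clinical grid (2.73 × 2.73 mm
pixels, 3.27 mm slices) with a single border-falloff parameter sweeping
between a sharp ("spiculated") and a Gaussian-like phenotype, plus cohorts
with head-and-neck-like covariates and exponential proportional-hazards
survival times driven by a chosen image feature.

## Worked example

```python
from petradiomics import RunConfig, run_pipeline, make_report

cfg = RunConfig(n_subjects=40, stability_runs=200, n_boot=1000, seed=7)
report = run_pipeline(cfg, "demo_run")
print(make_report(report))
```

prints

```
# Pipeline run report

Subjects synthesized: 40
Excluded for small volume: 0

## Stability selection

- LILRE: frequency 0.83

## Model comparison (cross-validated Harrell c-index)

- clinical-only model: c = 0.525
- clinical + imaging model: c = 0.748
- difference: +0.224 (paired bootstrap p = 0.024)

## Kaplan-Meier median split on LILRE

- log-rank p = 2.66e-06
```

Here the synthetic cohort's hazard truly depends on the LILRE extracted from
each phantom (log HR −1 per standard deviation), and the pipeline recovers
exactly that structure: LILRE is the only feature selected in >50% of the
stability runs; the clinical covariates are pure noise, so the clinical-only
model cross-validates near chance (c ≈ 0.5) while adding the image feature
lifts discrimination to c ≈ 0.75, a significant paired-bootstrap difference;
and the median-LILRE split separates the survival curves.

The same stages are available as CLI subcommands:

```bash
petradiomics synth --seed 3 --out vol.nii.gz
petradiomics segment --input vol.nii.gz --fraction 0.4 --out mask.nii.gz
petradiomics features --volume vol.nii.gz --mask mask.nii.gz --out feats.csv
petradiomics run --seed 7 --out demo_run
```

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults, what
the synthetic generators do and do not emulate, and the numerical
conventions (tie handling, boundary rules, tolerances).
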