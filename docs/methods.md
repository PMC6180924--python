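# Methods

This note documents the scientific conventions the package implements, the
defaults and why they were chosen, what the synthetic generators emulate,
and the numerical decisions that were genuinely open.

## Image model and segmentation

A volume is a 3D grid of body-weight-normalized standardized uptake values
(SUV) with physical voxel spacing; the default grid mirrors a clinical PET
reconstruction (2.73 × 2.73 mm pixels, 3.27 mm slices). Segmentation is the
relative-threshold isocontour rule: all voxels at or above a fraction
(default 0.40) of the global maximum, restricted to the 26-connected
component containing the hottest voxel.

* The threshold is inclusive (≥), which makes the constant image well
  defined (the whole grid is selected).
* Connectivity is 26, matching the intent of delineating one whole lesion;
  an 18-connectivity variant is a one-line change of the structuring
  element in `segmentation.py`.
* Thresholding is voxel-wise; no sub-voxel marching surface is fitted, and
  no morphological post-processing is applied (a human "visual inspection"
  step cannot be automated).
* Ties for the global maximum anchor at the first tied voxel in array
  order; every tied voxel is above threshold, so the choice only matters if
  tied maxima sit in different components, in which case the first one wins.

Tumors below 2.6 ml are excluded before feature extraction, with a strict
`<` comparison. The threshold is the volume of a 17 mm inner-diameter
sphere ((4/3)π·8.5³ mm³ = 2.57 ml, i.e. 2.6 to one decimal), the
third-smallest sphere of the NEMA IEC image-quality phantom: below this
size, run/zone statistics rest on too few voxels to be stable.

## Quantization and texture features

SUVs inside the VOI are digitized into B = 64 equal-width bins between the
VOI minimum and maximum: `level = min(B, floor((v − vmin)/(vmax − vmin)·B) + 1)`.
Assigning vmax to bin B via `min` keeps the formula closed and the top bin
non-empty. A degenerate VOI (vmax = vmin) maps to level 1 everywhere.
Because binning is min–max relative, all quantized-domain features are
invariant under positive affine rescaling of the uptake values; only
SUVmean, SUVmax and the SUV/SUL peaks scale with the image.

Texture structure is enumerated over the 13 unique directions of the 3D
26-neighbourhood (one per antipodal pair):

* **GLRLM** — maximal collinear runs of equal level; runs break at the mask
  boundary. Matrices are summed over directions before feature computation
  (the per-direction-average alternative is available via
  `FeatureConfig(glrlm_aggregate=False)`); summing is stabler on small VOIs
  because sparse per-direction matrices make ratio features noisy.
  Features: run percentage N_r/(13·N) and LILRE (1/N_r)·Σ p(i,j)·j²/i².
* **GLCM** — symmetric co-occurrence at distance 1, both orderings of each
  pair counted, normalized to sum 1; homogeneity Σ P/(1+|i−j|) and contrast
  Σ P·(i−j)².
* **NGTDM** — per level, occurrence probability and the summed absolute
  difference between a voxel and the mean of its in-mask 26-neighbours.
  Neighbourhoods are truncated at the mask boundary; voxels with no in-mask
  neighbour are skipped. Coarseness = 1/(ε + Σ pᵢsᵢ) with ε = 1e−6, so a
  perfectly uniform VOI reports the cap 1e6 rather than dividing by zero.
  Note the cap makes coarseness non-monotone across the uniform limit: a
  zero-falloff, zero-noise lesion is uniform inside its contour and jumps to
  the cap, while among non-degenerate lesions coarseness increases with
  border smoothness.
* **GLSZM** — 26-connected zones of constant level; LILZE
  (1/N_z)·Σ z(i,s)·s²/i².
* **Texture-spectrum codes** — each voxel is compared with its 26 neighbours
  (0 lower / 1 equal / 2 higher on quantized levels); neighbours outside the
  mask or grid are coded "equal". Code similarity is the probability that
  two distinct VOI voxels share an identical code (the Simpson index of the
  code distribution). This family has no single published 3D convention;
  the encoding and the similarity statistic are therefore defined explicitly
  here and isolated behind `matrices.texture_codes` / `features.code_similarity`.

First-order statistics (mean, max, Pearson skewness m₃/m₂^{3/2} and
kurtosis m₄/m₂², not excess) are computed on raw SUV, not quantized levels.
SUV peak is the largest mean uptake in a 1 cm³ sphere (radius
(3/(4π))^{1/3} cm ≈ 6.2 mm, built from voxel-centre offsets) centred at a
VOI voxel; SUL peak rescales it to lean body mass with the sex-specific
James formula. Degenerate VOIs yield per-feature missing values (NaN),
never an exception, from `extract_all`.

Every matrix builder is tested for exact agreement with an independent
brute-force enumeration on 100 seeded random 4×4×4 masked grids, and the
partition identities (Σ p(i,j)·j = 13·N, Σ z(i,s)·s = N, Σ P = 1, Σ pᵢ = 1)
are asserted as properties.

## Synthetic phantoms

A lesion is a sphere (optionally ellipsoid) of radius r: intensity is
`background + (peak − background)·profile(d)` with profile 1 inside r and
`exp(−(d − r)²/(2σ²))` outside (a step when σ = 0). The single border
parameter σ encodes the two uptake phenotypes of interest: small σ gives a
sharp, "spiculated" border; large σ a Gaussian-like falloff whose faint rim
creates long low-level runs, i.e. high LILRE. Noise is additive truncated
Gaussian (clipped at 0) — a controllable heterogeneity knob, not a model of
Poisson reconstruction noise; scanner PSF, scatter and attenuation are
deliberately out of scope. Defaults: 48×48×32 grid at (2.73, 2.73, 3.27) mm,
radius 12 mm, peak SUV 10, background 0.5, noise sd 0.5 (5% of peak).

Consequences for interpretation: passing tests show the pipeline recovers
the structure this generator encodes (border-smoothness → LILRE → hazard);
they do not show that LILRE is prognostic in real tumors, which have
irregular shapes, heterogeneous interior uptake and reconstruction-
correlated noise none of which are simulated.

## Synthetic cohorts

Covariates mirror a locally-advanced head-and-neck population: 75% male,
age uniform 40–80 y, 65% stage IV, 55% oropharynx primary, 75% concurrent
chemotherapy; anthropometrics (for SUL) are drawn per sex. Event times are
exponential proportional hazards: hazard = h₀·exp(Σ β_f·z_f) with
standardized feature values z and baseline h₀ = 0.02/month (median ~35
months at β = 0, a realistic failure tempo in months). Censoring is
independent uniform on (0, U), with U solved by bisection so the expected
censored fraction equals the requested rate — for exponential times with
hazard λ, P(censored) = (1 − e^{−λU})/(λU), averaged over subjects. The
effect size used in recovery experiments (log HR −3 per SD) is a free
parameter of the simulation: the clinical literature reports this feature's
hazard ratio only on raw units, where it is numerically degenerate, so no
calibration to a published effect is possible.

## Selection protocol

Each stability run: bootstrap-resample subjects (resampling can be disabled
to re-randomize only the CV folds), standardize features within the
resample, fit the LASSO-Cox path (glmnet-style coordinate descent,
scikit-survival) on an automatically scaled 50-point log grid, pick the
penalty by 10-fold cross-validated partial-likelihood deviance
(Verweij–Van Houwelingen held-out deviance, folds stratified on the event
indicator), refit on the whole resample, record the active set. Features
active in strictly more than half the runs (the ">500 of 1000" reading)
are selected.

The penalty rule is the **one-standard-error rule**: the largest penalty
whose CV deviance is within one SE of the minimum. The plain
deviance-minimizing rule is available (`lambda_rule="min"`) but is not the
default because the CV-deviance curve is nearly flat at small penalties, so
its minimizer drifts into the overfitted tail and pure-noise features reach
selection frequencies far above one half — defeating the majority threshold
the protocol relies on. With the 1-SE rule, noise-feature frequencies stay
well below 0.5 while a genuinely prognostic feature is selected in
essentially every run.

All-censored resamples are redrawn (logged). The λ = 0 limit of
`fit_lasso_cox` is an unpenalized BFGS maximization of the Breslow partial
likelihood, cross-checked against an independent Cox implementation.

## Survival statistics

* **Cox fits** maximize the partial likelihood with Efron tie handling;
  hazard ratios with Wald 95% intervals. Monotone likelihood (perfect
  separation) is detected by an escaping coefficient or an exploding Wald
  standard error (either exceeding 50 on the working scale) and flagged via
  `converged=False` rather than raised — degenerate hazard-ratio scales are
  a real failure mode of small-cohort radiomics models and should surface,
  not crash.
* **c-index**: a pair is comparable iff the shorter observed time is an
  event (time ties are not comparable); tied risk scores count ½. This is
  Harrell's original definition; it is invariant under strictly monotone
  transforms of the risk score.
* **Cross-validation**: fold assignment is seeded and stratified on the
  event indicator so every training fold contains events; the c-index is
  computed once on the pooled out-of-fold linear predictors rather than
  averaged over folds (per-fold c-indexes are unstable on small folds).
* **Model comparison**: paired bootstrap over subjects of Δc; percentile
  95% CI; two-sided p as twice the smaller tail probability of 0 (floored
  at 1/n_boot). Identical risk scores short-circuit to Δc = 0, p = 1. The
  bootstrap is the assumption-light default for comparing concordances of
  nested, cross-validated models.
* **Kaplan–Meier**: product-limit curves, right-continuous evaluation,
  median splits assign ties to the low group, two-sample log-rank test.
* **Rank-sum test**: exact null distribution when both groups have ≤ 20
  tie-free observations, otherwise normal approximation with tie and
  continuity corrections.
* **Recurrence patterns**: fraction of the recurrent lesion inside the
  prescription 95% isodose > 0.8 → in-field, 0.2–0.8 → marginal, < 0.2 →
  out-field.

## Pipeline

Stages exchange only files (NIfTI, CSV, JSON); one global seed derives all
stage seeds through a seed sequence, so a rerun with the same config is
byte-identical on every CSV. Each CSV carries a provenance comment line
(package version, config hash, seed), and feature extraction writes a JSON
sidecar recording bins, connectivity, direction count, ε and aggregation
mode. The final models are clinical-only versus clinical (age, stage
force-included) plus the stability-selected imaging features, compared by
cross-validated c-index with the paired bootstrap.

## Problem sizes

Defaults used in the shipped experiments: recovery/comparison cohorts of
n = 300 with 200 stability runs; phenotype-separation groups of 30 phantoms
per arm; c-index endpoint simulations at n = 2000; pipeline demo of 40
subjects. The library default for stability selection remains 1000 runs.

## Known limitations

* Spherical/ellipsoidal lesions only; no irregular shapes, necrotic cores
  or reconstruction noise.
* The texture catalogue covers the named feature families, not a full
  75-feature package, and is not IBSI-certified.
* Coarseness-ε, texture-code and GLRLM-aggregation conventions vary between
  toolboxes; absolute feature values are comparable only within this
  implementation (the JSON sidecar records the conventions used).
* No competing risks, time-varying covariates, or proportional-hazards
  diagnostics beyond the convergence flag.
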