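# Methods

`radsurv` implements a comprehensive prognostic-modeling workflow for
locoregional recurrence after radiotherapy: high-dimensional radiomic
features from a planning-CT tumor region and dosiomic features from the
3D dose distribution are stability-filtered, reduced by PCA, and fed —
together with conventional clinical covariates — into a suite of Cox
proportional-hazards models compared by AIC and concordance index.
Because no patient imaging is distributed with the package, the entire
workflow is exercised on synthetic CT/dose phantoms whose prognostic
structure is known exactly, so every statistical property the pipeline
claims can be verified against ground truth.

## Synthetic cohort model

Each simulated patient consists of a CT-like volume (HU), a dose volume
(Gy), an ellipsoidal VOI mask, four clinical covariates and a censored
survival outcome.

**Geometry.** The VOI is an ellipsoid with per-axis radii drawn
uniformly from `tumor_radius_range` (default 8–14 mm), centered near
the grid center with sub-voxel jitter. If the ellipsoid plus the 5 mm
boost margin would touch the grid boundary, radii are shrunk by 20% and
the placement retried; an impossible geometry raises an error naming
the constraint. The default desk-scale grid is 48³ voxels at 2 mm
isotropic spacing; the generator is configurable up to clinical matrix
sizes.

**CT intensity model.** Background is uniform soft tissue (40 HU). The
tumor interior is `tumor_mean_hu` plus a Gaussian random field
(white noise smoothed to a configurable correlation length, rescaled to
unit variance, scaled by `texture_amplitude`), plus i.i.d. Gaussian
acquisition noise everywhere (default 10 HU). Two sources of
between-patient variation are deliberate: the tumor mean is offset per
patient by N(0, `tumor_hu_sd`² = 15²) and the texture amplitude jittered
uniformly by ±15%. Without them, a cohort of near-identical phantoms has
almost no between-patient feature variance, and intraclass correlations
— which compare perturbation-induced variance against between-patient
variance — are uninformative; real cohorts are strongly heterogeneous in
exactly these ways.

**Dose model.** The VOI expanded isotropically by 5 mm (distance
transform) receives the prescription (default 70 Gy), emulating a
simultaneous-integrated-boost plateau; outside, dose falls off as a
Gaussian of the distance to the plateau (`penumbra_sigma`, default
5 mm). A smooth heterogeneity field (correlation length 10 mm, standard
deviation `dose_heterogeneity_amplitude`) is added inside the plateau
after subtracting its minimum, so heterogeneity appears as hot spots
above the prescription. Two consequences are intentional: with zero
amplitude every VOI voxel receives exactly the prescription, and the
coverage constraint D95 ≥ prescription holds by construction for every
patient.

**Latent prognostic classes.** Each patient carries two independent
Bernoulli(½) classes. The *texture class* multiplies the CT texture
correlation length by 3 and its amplitude by 1.4 (a coarse,
high-amplitude, necrosis-like pattern); the *dose class* multiplies the
dose heterogeneity amplitude by 3 (a hot, heterogeneous boost). The
hazard acts on the class pair, so radiomic and dosiomic features carry
genuinely complementary prognostic information. Texture class was
originally encoded through correlation length alone; amplitude coupling
was added because band-energy features — the ones robust enough to
survive the stability filter — respond to amplitude much more strongly
than to correlation length at desk-scale resolution.

**Clinical covariates** are sampled to match the published cohort
marginals (92.2% male, P(age ≥ 58) = 0.61 via N(60.2, 8²), 71.4%
peripheral invasion, 28.6% stage IVB). By default they are independent
of the hazard. `HazardSpec.stage_coupling` optionally shifts the logit
of P(stage IVB) by the centered latent risk, tying the stage covariate
to outcome while approximately preserving its marginal; the acceptance
cohorts use coupling 1.5 so that the clinical block carries real signal,
mirroring the cohort result in which stage IVB was the one informative
clinical covariate.

**Outcomes.** Event times follow a Weibull baseline (shape 1.3, scale
60 months) accelerated by exp(β·x) on the latent classes. Censoring is
the minimum of an exponential time with scale
`baseline_scale·(1−r)/r` (an approximate device for hitting a target
censoring fraction r) and an administrative horizon of 81.4 months,
matching the maximum follow-up of the cohort the marginals are drawn
from. Default β = (0.8, 0.8); the acceptance cohorts use (1.5, 1.5) so
that per-cohort significance of the principal components is reliable at
n = 60.

## Feature extraction

The pool mirrors the standard radiomics families: 18 first-order
intensity statistics, 14 mesh/principal-moment shape features and 75
texture features from the five gray-level matrices (GLCM 24, GLRLM 16,
GLSZM 16, NGTDM 5, GLDM 14), all computed in 3D on the discretized
masked region. A filter bank of Laplacian-of-Gaussian images (default
σ ∈ {1,…,5} mm, spacing-aware, DC-corrected so constants map to zero)
and the 8 sub-bands of a single-level undecimated bior6.8 wavelet
decomposition (symmetric boundaries; implemented by separable
correlation with the PyWavelets analysis filters, since `pywt.swtn`
supports only periodic wrapping) adds first-order + texture on each
derived image: 107 + 13×93 = 1316 features per modality. Dose volumes
go through the identical code path with a 0.5 Gy bin width instead of
25 HU.

Conventions that matter to reproducibility:

* Discretization: fixed bin width on absolute intensity edges
  (`floor(x/w)` relabeled to 1..Ng), so bins are comparable across
  patients; fixed bin count is available.
* GLCM/GLRLM use the 13 unique distance-1 directions with symmetric
  accumulation and feature values averaged over directions; GLSZM zones
  and GLDM/NGTDM neighborhoods are 26-connected; GLDM dependence uses
  α = 0.
* Degenerate regions emit documented values rather than NaN: a single
  gray level gives GLCM Correlation 1, MCC 1, NGTDM contrast 0 and
  Coarseness capped at 10⁶; a constant region gives Entropy 0,
  Uniformity 1, Skewness/Kurtosis 0.
* Shape features mesh the 0.5 iso-surface of a lightly smoothed
  (σ = 1 voxel) mask indicator; meshing the raw binary mask
  overestimates surface area by ~10% even for large spheres, which
  would bias sphericity down. Axis lengths use 4·√λ of the
  voxel-center covariance eigenvalues.
* Every base-image feature is invariant to background voxel values;
  filtered-image features are not (the convolution mixes a boundary
  shell into the region), which is inherent to filter-bank radiomics.

All 75 texture features are verified to 1e-9 against an independent
pure-Python matrix-counting oracle on small fixtures; the oracle shares
no code with the vectorized implementation.

## Stability filtering

Features are recomputed under perturbations of the inputs — additive
Gaussian image noise at 10/50/100 HU and random VOI boundary
deformations with RMS magnitude 0.5/1.0 voxel pitches (a smoothed
random displacement field, smoothing length 4 voxels, resampled
nearest-neighbor) — and summarized per feature and condition by two
one-way-ANOVA intraclass correlations over the patients × raters
matrix (original + perturbed recomputations; default one realization
per condition, so k = 2):

    ICC1 = (MSR − MSW) / (MSR + (k+1)·MSW)
    ICC2 = (MSR − MSW) / MSR

The `(k+1)` weight in ICC1's denominator follows the source workflow
as printed; the textbook ICC(1,1) uses `(k−1)` and is available as
`formula="standard"` (the two agree whenever MSW = 0; wherever the
coefficient is non-negative the printed form is the more conservative
of the two). A feature is *reproducible* iff
ICC1 > 0.7 and ICC2 > 0.95 — strict inequalities — in **every**
condition of its modality; dose features are tested under boundary
perturbation only, since planned dose is free of acquisition noise.
Degenerate (non-finite) feature values fail stability outright; an
all-constant rating matrix is defined as ICC1 = 1 (and passes), which
makes the zero-amplitude perturbation case exact.

At desk scale this filter is harsh on CT texture: 100 HU noise exceeds
the ~40–56 HU texture amplitude, so matrix features decorrelate and
mostly intensity-level and large-σ LoG features survive — a faithful
small-scale analogue of the motivating workflow, where only a quarter
of radiomic features but two thirds of dosiomic features passed.

## Reduction and modeling

Stable features are z-scored (constant columns dropped with a warning)
and projected onto the first five principal components per modality
(RPC0–4, DPC0–4), signs fixed so each loading's largest-magnitude entry
is positive. An optional pre-PCA univariate screen dichotomizes each
feature at its Youden-index cutoff and keeps those whose two-group
log-rank p < 0.05 (no multiplicity correction); the default pipeline
order is stability → PCA, with the screen behind a config switch.
A caveat the tests document: because the Youden cutoff is optimized on
the same data the log-rank then tests, the screen's null selection rate
is ~12%, not the nominal 5% (a fixed median split is calibrated); the
procedure is implemented as described in its source, optimism included.

The model suite fits six Cox models (Efron ties, Newton iterations to
1e-10 precision via lifelines): Clinical (gender, age continuous,
stage-IVB indicator, peripheral invasion), RPC (5 components), DPC
(5 components), and the three combined models, which carry forward only
the components with significant hazard ratios (Wald p < 0.05) from the
single-modality fits plus all clinical covariates. If nothing is
significant the combined models degrade to clinical with a warning.
Each fit reports per-covariate HR with 95% Wald CI, z and p; model AIC
= 2k − 2·ln L̂ on the partial likelihood; and the in-sample Harrell
C-index of the linear predictor with a seeded percentile-bootstrap 95%
CI. The C-index counts pairs (i, j) with T_j < T_i and δ_j = 1 as
comparable and η_j > η_i as concordant; risk ties count ½ by default
(`half`) or 0 (`strict`, the strict-inequality reading of the
definition). Kaplan–Meier curves and the two-group log-rank test are
exposed for the univariate stratification plots; both are cross-checked
against hand-computed product-limit and O/E/V tables in the tests.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at reduced
scale, chosen as the smallest sizes at which each property is stably
measurable: oracle checks on ≤6³ regions; calibration by 500 log-rank
null replicates (n = 60) and 200 Wald-coverage cohorts (n = 500);
parameter recovery at n = 1000; and the model-ordering experiment on 20
cohorts of 60 patients on 32³ grids with a reduced LoG(2, 5 mm) bank —
full-bank extraction is exercised separately on a single default
phantom. Every random draw descends from a single master seed through
`numpy.random.SeedSequence`, so cohorts, perturbations and bootstraps
are bit-reproducible; the pipeline manifest records the config hash and
per-file checksums and a re-run with the same config reproduces
identical files.

## Limitations

The phantoms are geometric idealizations: single ellipsoidal lesions in
uniform background, stationary Gaussian texture, isotropic grids, no
anatomy, no imaging physics beyond additive noise. Passing tests
demonstrate that the *pipeline* is correct and calibrated and that its
qualitative conclusions (stability filtering behavior, signal
additivity of combined models) hold when its assumptions hold — not
that any specific clinical cohort would reproduce particular hazard
ratios or C-index values. Cohort-specific published numbers are
therefore treated as structural templates, not numeric targets. The
C-index is reported in-sample, as in the motivating workflow;
cross-validated discrimination would be systematically lower.
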