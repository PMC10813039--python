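# Methods

This note documents the models, defaults and numerical choices behind
`vitrehaze`, and what the synthetic validation does and does not show.

## The haze score

The vitreous haze score of an eye is the ratio of the mean raw OCT
intensity of all vitreous pixels (strictly above the segmented ILM) to
the mean intensity of all pixels at or below the ILM, pooled across
every non-failed A-scan of the macular volume (grand means, not
per-B-scan averages). Design choices:

* **Denominator.** "Below the vitreous" is read as the full complement
  of the vitreous within the scan (retina plus sub-retinal signal).
  A `retina_only` variant restricted to a band under the ILM is
  available behind a flag for sensitivity analysis; the default is the
  complement reading because the vitreous itself is defined as
  everything above the ILM.
* **Log transform.** Natural log of `ratio + eps`, `eps = 1e-6`.
  The base only rescales regression coefficients; the epsilon keeps a
  zero ratio finite at `ln(1e-6) ≈ -13.8`. Both constants are part of
  the score definition and printed with it.
* **Raw data only.** `compute_vh` refuses contrast-adjusted volumes
  unless explicitly overridden for demonstration. Any monotone concave
  display map (the package implements a max-normalised gamma map,
  default gamma 0.5) strictly increases the score of a volume whose
  vitreous is darker than its retina, so display images are never a
  valid input.
* **Invariances.** As a ratio of means the score is invariant to a
  global intensity gain; this is tested, as is exact agreement with a
  naive per-pixel double loop.
* Multiple volumes of one eye, if present, are averaged on the log
  scale.

## ILM detection

The device software that segmented the ILM in clinical practice is
proprietary, so the package defines its own detector and validates it
on phantoms:

1. median-smooth each A-scan along depth (window 3);
2. track a running vitreous baseline and spread in a trailing window of
   16 samples: baseline = median, spread = 1.4826 × MAD, floored at 5%
   of the baseline (the floor is relative, preserving gain invariance,
   and guards against MAD collapse in small windows);
3. the ILM is the first depth, from sample 8 onward, whose smoothed
   intensity exceeds `baseline + k × spread` (k = 4) at two consecutive
   depths (the persistence requirement rejects isolated speckle spikes
   without shifting a genuine boundary);
4. median-filter the surface across neighbouring A-scans (5 × 5),
   ignoring failed entries.

A-scans with no qualifying rise are flagged failed (depth −1) and
excluded from the haze means rather than interpolated — conservative,
since interpolation would fabricate vitreous pixels. A volume with
>50% failed A-scans raises a volume-level failure signal that QC
treats as an unusable scan. On zero-noise phantoms the detector equals
the ground truth exactly; at 5% multiplicative speckle the mean
absolute depth error is ~0.1–0.3 px (requirement: ≤ 2 px). Boundaries
shallower than 8 samples cannot be detected by construction; phantom
geometry keeps the ILM well below that.

## Phantom model

A phantom volume is a stack of piecewise-constant A-scans: vitreous at
baseline 0.05 (arbitrary raw units) plus a non-negative haze offset;
RNFL/GCIPL/INL/ONL segments at 0.75/0.55/0.40/0.20; 2-px bright peaks
at the IS/OS junction (1.0) and RPE (0.95); choroid 0.35. The ILM
follows a foveal-pit surface (or any explicit depth map). Depth index
0 is the vitreous side. Noise is multiplicative log-normal speckle
with unit mean — so expected intensities, and hence the expected haze
ratio, are unchanged — plus optional additive Gaussian read noise;
intensities are clipped at zero. The default raster (12 × 64 × 128) is
a downsampled 20° × 20° field with the full ~6 mm lateral extent
(300 µm/degree), chosen so a volume renders in milliseconds while the
ETDRS grid still fits; the acceptance checks use 49-B-scan rasters.

This is an intensity phantom, not a physical light-propagation
simulation: no attenuation with depth, no shadowing, no motion or
blink artefacts, no real speckle correlation structure. Passing tests
therefore show the *estimators* are correct on data satisfying the
model assumptions, not that the scores are accurate on any particular
device's scans.

## Cohort generator

`generate_cohort` simulates subjects (demographics, disease course,
EDSS, brain volumes) and two eyes per subject (layer thicknesses, haze
scores). Covariate means and SDs default to the included study cohort
(290 patients / 85 controls: age 51.5 ± 10.1 vs 49.3 ± 8.2 y, pRNFL
84.6 ± 14.4 vs 95.1 ± 7.9 µm, mGCIPL 77.5 ± 14.3 vs 92.2 ± 6.0 µm,
mINL 40.4 ± 3.3 vs 39.4 ± 2.9 µm, NGMV 759.0 ± 58.4 vs 795.5 ± 53.3 mL,
NWMV 665.2 ± 43.8 vs 696.3 ± 33.8 mL, 2:1 female:male, disease
duration 17.9 ± 7.0 y, phenotype 200/59/31 RRMS/SPMS/PPMS). Covariates
are drawn mutually independently given group; no empirical
between-covariate correlation structure is available to emulate, and
independence makes each configured coefficient exactly the estimand of
its own age/sex-adjusted univariate model.

The outcome model, on the analysis (natural log) scale:

```
log VH = lp(covariates) + u_subject + e_eye
u ~ N(0, rho sd^2),  e ~ N(0, (1-rho) sd^2)
```

so `corr(eye1, eye2 | covariates) = rho` (default 0.6, a typical
inter-eye correlation) and the total residual SD is `sd` (default
0.35, back-derived from the reported CI widths of the eye-level
models; e.g. an age coefficient SE of ~0.002 at 520 eyes with
sd(age) = 10.1 implies a residual SD near 0.33). Note that matching
the analysis-scale spread leaves the raw-ratio SD smaller than the
reported raw-scale SD (0.21 at mean 0.17, implying heavier tails than
a lognormal with sigma 0.35); the log scale is where all modelling
happens, so it takes precedence. Default effect sizes are the reported
eye-level estimates: age −0.007, disease duration −0.009, male +0.014,
pRNFL +0.004, mGCIPL +0.006, NGMV +0.001, NWMV +0.001 (per year / µm /
mL of deviation from the patient reference means).

Two quantities are configured as *marginal adjusted estimands* rather
than structural coefficients, because that is how they are reported:
the MS-vs-control haze difference (+9.58% after age/sex adjustment)
and the disability-stratum contrasts (severe vs mild −23.56%, severe
vs moderate −28.86%). The group model adjusts only for age and sex,
so the group mean gaps in the *unadjusted* covariates (layer
thicknesses, brain volumes) load onto its coefficient; the generator
therefore derives the structural group coefficient by subtracting
those gap contributions from the target, and centres the stratum
shifts to mean zero within patients. An age/sex-adjusted GEE on a
generated cohort then recovers the configured percentages directly.
The intercept is anchored so the marginal control-eye mean haze ratio
is 0.16 (lognormal mean correction by the residual variance; the small
extra variance from covariate spread is neglected).

EDSS is drawn per stratum (weights from the published stratum counts,
normalised — the printed counts 164/64/63 sum to 291 for 290 patients,
an inconsistency of the source table; percentages are computed over
the printed denominator) and uniformly on the half-point lattice
within a stratum. EDSS is independent of the other covariates apart
from the stratum haze shifts; the generator makes no claim about the
joint disability–atrophy distribution.

QC emulation: per-eye pass/fail with configurable probability plus a
subject-level ocular-pathology flag. A subject is excluded only if
both eyes fail or the pathology flag is set, mirroring the study's
accounting.

## GEE estimation

Gaussian family, identity link, exchangeable working correlation.
Estimation alternates a weighted estimating-equation update of beta
with moment re-estimation of the dispersion and of rho from Pearson
residuals (`rho = sum of within-cluster cross-products / ((N_pairs − p)
phi)`), until the max coefficient change is below 1e-8 (cap 100
iterations; the convergence flag is reported honestly). The
exchangeable inverse `V^-1 = (I − c J)/(phi(1−rho))`,
`c = rho/(1+(n_i−1)rho)`, reduces every cluster to vectorised cluster
sums, so fits on tens of thousands of eyes take milliseconds. rho is
clipped to (−0.99, 0.99).

Standard errors are the robust sandwich estimator — valid under
working-correlation misspecification — with `CI = beta ± 1.96 se` and
two-sided Wald p-values. With singleton clusters the estimator reduces
to OLS exactly; with balanced clusters and subject-constant covariates
it equals closed-form compound-symmetry GLS; both reductions, the
sandwich formula and an independent GEE implementation (statsmodels)
are test oracles. Rank-deficient designs raise an error naming the
collinear columns; rows with missing model variables are dropped
listwise with the remaining counts reported per model.

One caveat surfaced by the examples: the *working* `rho_hat` of a
sparse model (e.g. log VH ~ age + sex) exceeds the structural
inter-eye correlation, because subject-level covariate effects left
out of that model also end up in the within-cluster covariance. The
structural value is recovered when the residual model is correct;
`rho_hat` is reported as what it is, a working-correlation estimate.

The association suite mirrors the study layout: one age/sex-adjusted
model per covariate (the age model adjusts for sex only, the sex model
for age only), run separately for patients and controls, re-run per
disability stratum, plus pairwise group/phenotype/stratum contrasts
reported as percent differences. Strata with fewer than 3 subjects,
constant covariates, or degenerate designs are flagged not-estimable
rather than fitted. No multiple-testing correction is applied (alpha
0.05), matching the reporting convention of the analysis it mirrors.

Subject-level comparisons: simple linear regression for approximately
normal variables, Mann–Whitney U (tie-corrected normal approximation,
0.5 continuity correction, p = 1 by convention when all values tie)
for skewed ones, Pearson chi-square for categorical tables.

## ETDRS sector averaging

Pixels are assigned by radius around the fovea (0.5 < r ≤ 1.11 mm
inner ring, 1.11 < r ≤ 1.7 mm outer ring; r ≤ 0.5 mm and r > 1.7 mm
excluded) and by quadrant with boundaries on the 45° diagonals. The
summary is the unweighted mean of the 8 sector means ("mean of sector
means", not pixel-weighted — the two differ when sectors contain
unequal pixel counts). Degrees are converted at 300 µm/degree, a
documented constant; nasal/temporal orientation mirrors with eye
laterality (for a right eye the nasal quadrants lie toward decreasing
A-scan index in the default display orientation). The grid must fit
inside the scanned raster and every sector must be non-empty, else an
error is raised. Deeper layer boundaries are taken from phantom ground
truth; segmenting them from images is out of scope (clinically they
come from manufacturer software).

## Pipeline

`run_pipeline` chains simulate → QC → stratify → analyse → report with
a per-stage JSON manifest (inputs, parameters, seed, version, timing);
a run is reproducible byte-for-byte from (config, seed). The
`tabular` profile emits haze scores directly from the cohort model and
runs in seconds at study scale; the `image` profile additionally
renders a reduced-size phantom per eye whose expected haze ratio
matches the eye's generated score, segments it and replaces the
generated score with the measured one (capped at `max_image_eyes`,
default 40, to keep default runs fast).

## Problem sizes used in validation

The recovery study uses 200 replicates of 500-patient cohorts (about
half a minute); oracle and arithmetic checks are instantaneous; image
checks use 8–100 phantoms between 4×32×96 and 49×64×128 voxels. The
acceptance script simulates 8 000–26 000 subjects per section so that
sampling noise is small relative to the quantities reported.

## Known limitations

* The haze-score definition is a documented, testable variant of the
  published ratio; bit-for-bit agreement with the original
  (unavailable) implementation is not claimed, and whether the
  original denominator included sub-RPE pixels is unknown.
* The phantom omits device physics (attenuation, roll-off, artefacts);
  real-data accuracy claims require real data.
* The cohort generator's covariate independence and lognormal haze
  distribution are modelling conveniences, not estimated properties of
  the clinical cohort.
* Brain volumes are scalar covariates; no MRI processing is performed.
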