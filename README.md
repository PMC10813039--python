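# vitrehaze

Quantification of **vitreous haze (VH)** from OCT macular volume scans and
eye-level association analysis for clustered ophthalmic data, together with a
synthetic OCT phantom and cohort generator used to validate every step.

Vitreous haze — subtle clouding of the vitreous body by suspended
metabolites — is invisible to fundoscopy but measurable on spectral-domain
OCT. In multiple sclerosis (MS), haze levels have been related to markers of
neurodegeneration (retinal layer thinning, brain atrophy, disability),
plausibly through glymphatic clearance of waste into and out of the vitreous.
This package implements the measurement and the statistics needed to study
such associations, for researchers who have raw OCT intensity volumes (or
want to simulate them) and subject-level clinical covariates.

## What it computes

**The haze score.** For a raw macular volume with a segmented internal
limiting membrane (ILM), the score of an eye is

```
VH = mean(I[z <  z_ILM]) / mean(I[z >= z_ILM])
```

the ratio of the mean raw intensity of all vitreous pixels (above the ILM)
to the mean of all pixels at or below it, pooled over every usable A-scan of
the volume. The score must be computed on **raw** data: display contrast
transforms are concave and inflate the relative vitreous signal
(`contrast_adjust` demonstrates this). Analyses use `log(VH + 1e-6)`.

**ILM segmentation.** Per A-scan, the first depth whose median-smoothed
intensity rises more than *k* robust SDs (default k = 4) above a running
vitreous baseline; the surface is then median-filtered laterally. Failed
A-scans are excluded from the score, never interpolated.

**Layer summaries.** mGCIPL / mINL as the unweighted mean of the 8 ETDRS
quadrant sectors (1.0 / 2.22 / 3.4 mm circles, central circle excluded);
pRNFL as the global mean of a circular peripapillary scan.

**Eye-level statistics.** Marginal linear models of log VH fitted by
generalized estimating equations with an **exchangeable working
correlation** (two eyes per subject share a cluster):

```
E[log VH_ij] = x_ij' beta,   Cov_working = phi * R(rho),   R_jk = rho (j != k)
```

with robust (sandwich) standard errors, Wald 95% CIs
(`beta ± 1.96 se`), adjustment for age and sex, EDSS disability strata
(mild 0.0–3.5, moderate 4.0–5.5, severe ≥ 6.0), QC accounting, and
group contrasts reported as percent differences `(exp(beta) − 1) · 100`.

**Synthetic data.** `generate_volume` renders raw-intensity phantoms (dark
vitreous + configurable haze, piecewise-constant retinal layers, bright
IS/OS and RPE peaks, multiplicative speckle) with exact ground truth;
`generate_cohort` simulates an MS/control cohort with configurable covariate
distributions, log-scale effect sizes and inter-eye correlation.

## Worked example

```python
import vitrehaze as vz

spec = vz.PhantomSpec(haze_level=0.02, noise_sigma=0.05)
volume, truth = vz.generate_volume(spec, seed=1)
surface = vz.segment_ilm(volume)
score = vz.compute_vh(volume, surface)
print(score.ratio, score.log_ratio)
```

prints `0.1667 -1.7918`: the measured haze ratio (closed-form expectation
0.1664 for this phantom) and its log — a vitreous about 6× darker than the
retina, typical of a mildly hazy eye. Running
`python examples/04_cohort_gee_recovery.py` simulates 2000 patients and 600
controls and recovers the generating coefficients, e.g.

```
covariate           estimate                 95% CI  generating
age                  -0.0080     [-0.0096, -0.0064]     -0.0070
gcipl_um             +0.0056     [+0.0046, +0.0065]     +0.0060
adjusted MS-vs-control haze difference: +9.13% (p = 0.000)
```

each estimate from an age/sex-adjusted exchangeable GEE of log VH on two
correlated eyes per subject. The `examples/` directory has one short script
per capability; the `vitrehaze` CLI (`simulate`, `segment-ilm`, `score-vh`,
`metrics`, `analyze`, `run`) exposes the same operations on files.

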