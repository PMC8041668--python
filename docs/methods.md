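# Methods

## Imaging model and delineation procedure

The imaging substrate is a 3D grid of standardized uptake values (SUV,
dimensionless) with physical voxel spacing in mm. All physical
measurements derive from the spacing; the voxel volume in ml
(`dx·dy·dz / 1000`) is the single source of truth for every volume sum, so
the axis convention never affects a metric. Volumes and masks are
exchanged as NIfTI-1; DICOM ingestion, registration and resampling are out
of scope, and SUV calibration (decay/weight correction) is assumed done
upstream.

Delineation is the two-step threshold scheme used in whole-body PSMA-PET
burden quantification:

1. **Selection.** The liver reference mask (which the caller must supply
   tumor-free) yields `threshold = (c / SUVmean) · (SUVmean + SUVsd)` with
   `c = 4.3` by default. The standard deviation is the population
   (n-divisor) sd over the liver ROI voxels; the difference from the
   sample sd is negligible for realistic ROIs but is fixed for exactness.
   The constant `c` is reconstruction-dependent and therefore exposed in
   the configuration rather than hard-coded. Candidates are 26-connected
   components of the supra-threshold set outside the liver mask and an
   optional physiologic-uptake exclusion mask (kidneys, bladder, salivary
   glands — encoding the operator's metastasis judgment); a candidate is
   retained when the SUVpeak at its hottest voxel exceeds the threshold.
2. **Segmentation.** Each candidate is grown as the connected component,
   containing its hottest voxel, of `{SUV ≥ 0.5 · local SUVmax}`, where
   the local SUVmax is the maximum inside the candidate's supra-threshold
   component. Lesions strictly below 0.5 ml are then discarded (a lesion
   of exactly 0.5 ml is kept — the literal reading of "smaller than");
   the same rule is applied to manual lesions for uniformity. Manual
   lesions are supplied as full masks and are *not* re-thresholded: their
   uptake is below the global threshold, so a half-max region seeded from
   them is ill-defined.

**SUVpeak** is defined as the mean SUV over all voxels whose physical
centers lie within a 1.0 ml sphere centered on the hottest voxel's center
(an EANM-style convention; kernel volume configurable). At grid borders
the sphere is clipped and the mean renormalized. When several voxels tie
at SUVmax — routine in synthetic uniform spheres, rare in real noisy
data — the tie is broken toward the most central tied voxel, matching the
peaked profiles of real tracer uptake; scan-order tie-breaking would
center the sphere on the lesion boundary and systematically depress the
peak.

Two candidates whose half-max regions overlap are merged into one lesion
whose statistics are recomputed from the union mask (so its SUVmax is the
larger of the two); without merging, overlapping regions would be
double-counted in the whole-body sums. A uniform background at exactly
half of a candidate's SUVmax floods the whole connected supra-half-max
region — a documented property of the 50 % rule itself, excluded from the
accuracy phantoms by construction.

## Burden metrics

Per patient, over all retained lesions: PSMA-TV = Σ TV,
PSMA-TLU = Σ TV·SUVmean, PSMA-TLQ = Σ TV/SUVmean. A lesion with
SUVmean ≤ 0 is a hard error (the TLQ term divides by it) rather than a
silent drop; it cannot arise from automatic segmentation, only from a
pathological manual mask. Metrics are stored on the raw scale; the log2
transform is applied only in the statistical stage. Useful exact
identities, enforced by tests: per lesion `TLU·TLQ = TV²`; metric-wise
additivity under list concatenation; scaling all SUVmeans by `c`
multiplies TLU by `c`, divides TLQ by `c`, and leaves TV unchanged.

## Survival statistics

Covariates enter regressions as log2(value), so hazard ratios are per
doubling; non-positive raw values are a transform error. Analysis is
complete-case (no imputation).

* **Cox regression** is maximum partial likelihood with Breslow tie
  handling by default (the convention of the major commercial package for
  this workflow) and Efron as an option; the fit itself is delegated to
  `statsmodels.PHReg`. Collinear designs are rejected by a rank check
  before fitting, and non-finite or runaway estimates (monotone
  likelihood) raise a fit error. Wald 95 % CIs are
  `exp(coef ± 1.96·SE)`.
* **Backward elimination** starts from the full model and repeatedly
  removes the covariate whose single-term removal has the largest
  likelihood-ratio p, while that p ≥ 0.10; there is no re-entry step, and
  the model may empty. Rows are frozen to the complete cases of the
  initial covariate set so nested likelihoods stay comparable. The
  removal order is returned as a trace and is deterministic.
* **Kaplan-Meier** is implemented directly: product-limit estimator,
  Greenwood variance, pointwise 95 % CIs on the log(−log S) scale
  (`S^exp(±1.96·se)`), median as the earliest event time with S ≤ 0.5 and
  median CI from the crossings of the CI curves with 0.5; curves that
  never cross are reported as "NR" (encoded as infinity). The log-rank
  test (2-group and global k-group, hypergeometric covariance) is also
  implemented directly because the cutoff finder needs a fast inner loop;
  both are cross-checked against `lifelines` in the test suite.
* **Quantile stratification** uses empirical quantile cut points with an
  inclusive-left convention (a value equal to a cut point joins the lower
  stratum), so boundary ties never straddle strata; the pooled scheme
  merges quintiles 2–4 into one stratum. All-identical inputs produce a
  single stratum with a warning, never an error.
* **Ideal cutoffs** are maximally selected log-rank thresholds: every
  midpoint between consecutive distinct covariate values whose two groups
  both hold ≥ 10 % of patients is scanned exhaustively, and the p-minimal
  cutoff is returned. The minimum group fraction of 0.10 admits the
  unbalanced splits seen in practice (down to ~15 % of a cohort) while
  preventing degenerate groups. The reported p is unadjusted — the
  selection makes it anti-conservative, which the result object flags —
  and a Bonferroni-over-candidates value is reported alongside.
* Spearman correlation (average ranks, t-approximation) and the
  two-sided Mann-Whitney U (exact for small tie-free samples) come from
  `scipy.stats`.

Throughout: 95 % CIs, two-sided tests, α = 0.05.

## Synthetic data

**Phantoms.** A phantom is Gaussian background plus a liver ellipsoid
whose voxels are drawn i.i.d. from N(liver mean, liver sd), plus spherical
lesions with uniform, linear-falloff or Gaussian (σ = R/2) radial
profiles; structures may not overlap. Ground truth records each lesion's
*analytic* sphere volume and the analytic volume of its half-maximum
isocontour (the full sphere for uniform profiles, R/2 for linear,
σ·√(2 ln 2) for Gaussian), so segmentation accuracy is measured against
geometry rather than against voxel counts. The accuracy phantom holds
five noise-free uniform spheres of 1–20 ml (peak SUV 8–25) around a liver
with mean 4.3 / sd 0.4 on a 2 mm grid (optionally 1 mm); measured
volume-recovery error is ≤ 15 % at 2 mm and ≤ 7 % at 1 mm on this suite.
The end-to-end fixture phantoms are 48³ voxels with 0–3 Gaussian lesions
each, sized for seconds-scale tests. What the phantoms deliberately omit:
attenuation/scatter artifacts, reconstruction point-spread beyond the
Gaussian profile, respiratory motion, and anatomy beyond the liver
ellipsoid — so passing accuracy tests bounds voxelization and algorithmic
error, not scanner physics.

**Cohorts.** Patient lesion counts are negative-binomial (mean 10,
dispersion 1.2; zero draws are bumped to one lesion, since every patient
referred to radioligand therapy has avid disease), per-lesion volumes
log-normal (median 3 ml, σ_log = 1) truncated at the 0.5 ml filter, and
per-lesion SUVmeans log-normal (median 8, σ_log = 0.35). Burden metrics
are computed through `compute_burden` from the sampled lesion lists, so
the whole-body sums sit on the data path rather than being short-cut.
Survival is exponential with hazard
`λ · exp(Σ β_k (log2 x_k − median log2 x_k))`; centering at the cohort
median makes λ the hazard of the median patient, set to ln 2 / 11 months
to give a realistic ~11-month median OS. The default effect is on
PSMA-TLQ at HR 1.33 per doubling. Administrative censoring is uniform on
6–42 months, yielding ≈ 30 % censoring. PSA and LDH are log-linear in
log2(TV): the standardized signal is mixed with independent Gaussian noise
at the latent Pearson weight `r = 2 sin(π·ρ/6)` (the bivariate-normal
rank-correlation identity) and rescaled to each marker's own log2 spread
(PSA 2.5, LDH 0.6) around realistic medians (231 ng/ml, 317 U/l), so the
Spearman correlation with tumor volume hits its target (0.6 / 0.4) by
construction while marker scales stay physiologic.

All generators use numpy's PCG64 `default_rng`; identical seeds give
bit-identical volumes, tables and fixture files (the NIfTI writer produces
deterministic bytes), which the pipeline inherits end to end.

## Problem sizes and numerical choices

The test suite and the acceptance script run the statistics at moderate
Monte-Carlo sizes chosen to keep sampling error well inside the asserted
bands: 500 cohorts of n = 500 for Cox bias/coverage, 200 seeds of n = 800
for the stepwise driver/proxy selection rate, n = 2000 for the exponential
Kaplan-Meier check, n = 110 (a realistic bicentric cohort size) for the
correlation regime. Spacing-dependent tolerances (15 % at 2 mm, 7 % at
1 mm) reflect voxelization error of sphere surfaces. Floating point:
threshold and metric identities are exact to machine rounding; CI
construction uses the two-sided 95 % normal quantile to full precision.

## Known limitations

No partial-volume correction or CT guidance; lesion/organ classification
is out of scope (the exclusion mask stands in for operator judgment).
The maximally selected cutoff p-values are anti-conservative by design and
flagged as such. The cohort generator produces proportional hazards by
construction, so it cannot probe robustness to non-proportionality; and
phantom realism bounds what volume-recovery results imply about scanner
data (see above).
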