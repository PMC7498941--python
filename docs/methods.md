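# Methods

`netthin` implements, end to end and on fully synthetic data with known
ground truth, the analysis chain of a longitudinal neuroimaging design in
preclinical Alzheimer's disease: does low baseline default-mode-network
(DMN) functional connectivity, in the presence of elevated amyloid burden,
predict faster cortical thinning within the DMN?  This note documents the
models, the generator, the numerical choices, and what passing tests do and
do not establish.

## The analysis chain

### Template-based connectivity (TBR)

Given fixed spatial network templates `IC` (voxels x components) and a
session's data matrix `X` (voxels x volumes), the network time courses are
the least-squares solution

    M = pinv(X) . IC        (volumes x components)

i.e. the per-volume weights whose template-weighted volume sum best
recapitulates each spatial pattern.  Whole-network connectivity is the mean
Pearson correlation, over voxels above 40% of the template's maximum
(strict inequality), between the voxel time series of the cleaned data and
the network's own TBR time course.  The frontoparietal (FPCN) measure
averages left and right templates; cross-network variants (FPCN-within-DMN
and the converse) correlate intersection voxels with the enclosing
network's time course.  Across subjects, variance tied to head motion
(mean framewise displacement) and data dimensionality (retained nuisance-PC
count) is removed by OLS residualization before modelling.

Numerical choice — pseudo-inverse truncation.  After zero-phase bandpass
filtering, the data matrix has a long tail of transition-band singular
values (10^-1 .. 10^-11 of sigma_1).  The pseudo-inverse amplifies each
direction by 1/sigma, so at desk-scale voxel counts those noise-only
directions dominate `M` unless truncated; `tbr_timecourses` therefore
exposes a relative cutoff `rcond` (the pipeline uses 0.1; `None` gives
numpy's machine-precision cutoff, appropriate for unfiltered data).  On
well-conditioned inputs all cutoffs agree, which is what the oracle
equivalence tests exercise.

The "average correlation strength" is implemented as the arithmetic mean of
Pearson r, with Fisher-z averaging available behind a flag; correlating
against the network's own TBR time course is an interpretive choice (it is
the only per-network time series the method produces).

### Preprocessing

Per session: fourth-order Butterworth bandpass, applied forward-backward
(zero phase, magnitude response squared); 33 nuisance regressors — the top
5 temporal principal components of the voxels whose maximum tissue
probability is white matter, CSF, or bone respectively (15), plus the 6
motion parameters, their first differences (first row backfilled with 0),
and their squares (18); all 33 filtered identically, z-scored, reduced by
PCA to the minimal leading set reaching 90% cumulative variance, and
removed from every voxel by OLS with an intercept.  Ties in tissue
assignment break WM > CSF > bone > GM; PCA components orient their
largest-magnitude element positive; mean framewise displacement is the mean
over volume pairs of the summed absolute parameter changes, rotations
converted to arc length at a 50 mm radius (the quantity's exact formula is
a convention; this one is configurable).

Band presets.  Two passbands ship: `narrow` (0.08-0.10 Hz, the figure
printed in the emulated protocol) and `wide` (0.008-0.10 Hz, the
conventional resting-state band).  The default is `wide`: at TR 3 s and
120 volumes a 0.02 Hz band retains only ~14 temporal dimensions, and the
90%-variance nuisance projection then removes ~9-10 of them, annihilating
any in-band signal — a 0.02 Hz analysis band is not a usable design, which
is why the printed figure is treated as a plausible typo.  The band is a
single config key either way.

Stage order: filter BOLD -> build nuisance (tissue PCs from the filtered
series, motion terms from the raw table) -> filter nuisance identically ->
z-score, reduce -> remove.  Whether z-scoring precedes or follows filtering
is not determined by the protocol text; this package filters first.

### Cortical composites

Node masks become cortical composites in four steps: (1) a group modal-label
atlas (per-voxel mode over individual labellings; ties to the smallest
label id, with the undefined label 0 never beating a defined label on a
tie); (2) cubic-interpolation upsampling with the 0.25 inclusion threshold,
gated by the gray-matter partition, overlaps resolved by highest
interpolated value (the 0.5 mm target of the original protocol is
impractical on toy grids, so the resampling factor is configurable while
the 0.25 threshold is kept); (3) vertex labelling by the modal label of
voxels within 2 mm (voxel-center to vertex, world coordinates through the
NIfTI affine, 0-based indices); (4) unweighted mean thickness over a
network's vertices per visit.  Synthetic "surfaces" are jittered point
clouds around labelled voxels — enough to exercise the radius logic without
real meshes.

### PET quantification

The continuous amyloid measure is the FLR DVR: the unweighted mean uptake
over 16 Desikan-Killiany ROIs (precuneus, rostral anterior cingulate,
medial orbitofrontal, superior frontal, rostral middle frontal, inferior
parietal, inferior temporal, middle temporal; both hemispheres) divided by
cerebellar-gray uptake.  Volume weighting is available as a switch but the
unweighted mean is the default reading.  Tau is proxied by the bilateral
inferior-temporal SUVR over the same reference.  Groups are dichotomised at
a fixed cutoff of 1.186 (strictly above -> high; the boundary classifies
low); a cutoff can instead be re-derived as the equal-posterior crossing
point of a two-component Gaussian mixture fitted by EM (k-means init, 10
restarts, tolerance 1e-8, <= 500 iterations, seeded).

Known gap: for the published mixture (means 1.08/1.46, SDs 0.1/0.1,
weights 87:33) the crossing point is analytically

    x* = (mu1 + mu2)/2 + sigma^2 ln(w1/w2) / (mu2 - mu1) = 1.2955,

and EM on 5000 draws recovers ~1.29 — not the published 1.186.  Two reasons:
the published threshold came from a different sample and an unspecified
mixture-derived rule, and the published group moments are
post-dichotomization (truncated) moments, not mixture components — indeed a
1.186 threshold applied to this mixture would flag ~38% of subjects high,
not the 27.5% observed.  The package reports the crossing point it actually
computes; the fixed-cutoff path is the default for reproducing the
published grouping.

### Longitudinal models

The primary model is a linear mixed-effects regression of time-varying DMN
composite thickness with correlated random intercept and slope per subject:

    thickness ~ FC * PiB * time + (age + sex + education) * time
                + (time | subject)

The Wilkinson crossing expands to 14 fixed effects (including covariate
main effects).  This expansion — not the 11-term interaction-only variant —
is adopted because it reproduces the full set of published residual degrees
of freedom simultaneously: with ~118 high-amyloid rows the stratified model
(PiB terms removed, 10 terms) gives df 108, and the augmented designs give
106 (add FPCN FC + its time interaction), 107 (add time-varying FPCN
thickness), 106 (add IT tau + its time interaction), and 103 (all five
extra terms), each matching the printed values.  Continuous predictors are
demeaned over the whole analysis sample before fitting (stratified fits
inherit whole-sample demeaning); sex is a 0/1 indicator (male reference).

Inference: REML by default (ML switchable); t = estimate/SE referred to
Student t with residual df = observations - fixed effects, the convention
that reproduces the printed df (Satterthwaite is deliberately not the
default); standardized effect sizes are reconstructed as d = 2t/sqrt(df),
which reproduces every published (t, df, d) triple to one unit in the
second decimal (the printed t values are themselves rounded).  No
multiple-comparison correction is applied, matching the emulated analysis.
Missing optional covariates drop rows listwise with a warning.

The residual-df t reference is mildly anti-conservative for subject-level
terms in small cohorts (their effective df is closer to the subject count):
measured type-I error of the three-way term is ~7.4% at 48 subjects and
6.0% at 80, against 5% nominal.  This is a property of the df convention,
not of the estimator; at the study size (120 subjects) the three-way
coefficient is recovered with negligible bias (<1% over 200 replicates).

Group-level descriptive comparisons use the pooled-variance two-sample t on
the absolute mean difference (df = n1 + n2 - 2) and Pearson chi-square
without continuity correction (df = 1); these reproduce the published
demographic statistics at printed precision.  One published value (the sex
effect size of 0.03) is not reproduced by Pearson, continuity-corrected, or
phi statistics on the printed counts and is left unreplicated.

## The synthetic-data generator

The generator emulates the study's statistical structure, not its physics.

Sessions.  BOLD = sum_k a_k map_k(v) s_k(t) + tissue-localized,
motion-correlated nuisance + white Gaussian noise, 120 volumes at TR 3 s
(one six-minute run after dummy discard; the pipeline averages two runs per
subject, matching the 1-2 run protocol).  Templates are compactly supported
blobs (clipped Gaussians) with a DMN analog overlapping two FPCN analogs;
the zero skirt keeps sources out of the nuisance tissue classes, otherwise
the tissue PCs would absorb the planted signal.  Planted time courses are
band-limited inside 0.08-0.10 Hz so they survive either analysis band.
Tissue probability maps form concentric shells (GM on template support, WM
interior, CSF and bone peripheral).  Per-subject connectivity ground truth
is the coupling amplitude a of the DMN source — the real-data measure is an
emergent correlation, the generator needs a controllable knob.

Cohort.  120 subjects by default; visit counts over 2-8 drawn to match the
reported distribution (probabilities 4:56:47:9:2:1:1, mean 3.6), visits
~1.94 years apart with +/-0.3 y uniform jitter; age ~ N(73.35, 6.0), 58%
female, education ~ N(16.02, 2.9); amyloid from the two-component mixture
(1.08/1.46, SD 0.1/0.1, weights 87:33).  Baseline connectivity is Gaussian
with SD 0.1 (the cohort FC distribution is not published; Gaussian,
demeaned, is a modelling choice).  Thickness follows the growth model with
coefficients applied to population-centered predictors; defaults (intercept
2.55 mm; time -0.01 mm/y; FC x time 0.03; PiB x time -0.018;
FC x PiB x time 0.2; random intercept/slope SD 0.12 mm / 0.01 mm/y;
residual SD 0.05 mm) are calibrated so the three-way t statistic at study
size is in the low single digits, matching the published effect scale.

What the generator does not emulate: MR physics, motion-induced image
artifacts (motion enters only through the nuisance model), spatial
autocorrelation of real BOLD noise, skewed amyloid distributions, cortical
geometry.  Passing tests therefore establish that the implementation
computes the intended quantities and that the estimator is calibrated under
the stated generative model — not that the scientific result would
replicate on real data.

## Problem sizes and reproducibility

Simulation studies are sized for a desk-scale single-CPU run: 200 recovery
replicates at 120 subjects; 500 null replicates at 80 subjects (see the
type-I note above for why the null size is not pushed lower); the demo
pipeline uses 40 subjects on a 12^3 grid with two runs each (~5 s) — chosen
by an explicit power check so that a single run identifies the sign of the
planted three-way coefficient with a wide margin.  The ordering test for
the connectivity chain (rank correlation > 0.9 between planted coupling and
adjusted connectivity) is run once at its stated condition: 16^3 grid, two
averaged runs, session noise 0.3, couplings uniform on [0.4, 2.2], n = 60.
Session noise matters non-monotonically there: Pearson correlation is scale
invariant, so in the low-noise limit every subject's connectivity saturates
near 1 and between-subject discrimination vanishes; "moderate noise" is the
informative regime.

Every stochastic step takes an explicit seed; the pipeline fans a single
global seed out to stages by fixed offsets and writes a manifest with
SHA-256 checksums of all outputs — identical config and seed reproduce
identical checksums.

## Known limitations

- The GMM crossing-point cutoff does not reproduce the published 1.186
  threshold for the reasons quantified above; the fixed-cutoff path exists
  for exact replication of the grouping.
- TBR time-course recovery is bounded away from 1 even noiselessly (~0.96)
  by chance correlation between band-limited planted sources at 120
  volumes; this is inherent to the dual-basis solution, not a defect.
- The residual-df t reference inflates type-I error in small cohorts
  (quantified above).
- Surface machinery operates on synthetic point clouds, not meshes; no
  FreeSurfer formats are read or written.
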