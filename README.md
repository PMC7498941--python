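# netthin

Network connectivity, amyloid burden, and longitudinal cortical thinning —
a tested, reusable implementation of the analysis chain behind a
preclinical-Alzheimer's neuroimaging design, exercised end to end on
synthetic data with known ground truth.

## The problem

In clinically normal older adults, does low baseline functional integrity
of the default-mode network (DMN), combined with elevated amyloid-β burden,
presage faster cortical thinning within the DMN?  Answering this requires a
chain of quantitative steps, each of which this package implements as a
tested library function:

1. **Template-based rotation (TBR)** — given fixed spatial network
   templates `IC` (voxels × components) and a session's BOLD data matrix
   `X` (voxels × volumes), the network time courses are the least-squares
   projection `M = pinv(X)·IC`; whole-network connectivity is the mean
   Pearson correlation between a network's time course and its mask voxels
   (voxels > 40% of the template maximum), residualized across subjects on
   head motion and data dimensionality.
2. **fMRI preprocessing** — fourth-order zero-phase Butterworth bandpass;
   33 nuisance regressors (top-5 temporal PCs of white-matter, CSF, and
   bone voxels + 6 motion parameters with derivatives and squares), PCA-
   reduced to 90% variance and removed by OLS.
3. **Cortical composites** — modal-label atlases, cubic-resampled node
   masks (0.25 inclusion threshold inside the gray partition), 2 mm modal
   vertex labelling, and per-visit mean composite thickness.
4. **Amyloid PET** — the FLR DVR (mean uptake of 16 frontal/lateral/
   retrosplenial ROIs over cerebellar gray), inferior-temporal tau SUVR,
   and low/high dichotomization at a DVR cutoff of 1.186 (or re-derived as
   the crossing point of a two-component Gaussian mixture).
5. **Longitudinal mixed models** —

       thickness ~ FC * PiB * time + (age + sex + education) * time + (time | subject)

   with correlated random intercept and slope, t statistics on residual
   degrees of freedom, effect sizes d = 2t/√df, amyloid-stratified and
   covariate-augmented variants.
6. **Synthetic cohort generator** — every input above (templates, 4D BOLD
   with planted band-limited sources, motion tables, tissue maps,
   longitudinal thickness trajectories, amyloid mixtures, ROI uptake
   tables) generated with known ground truth, so recovery can be asserted.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

Run the demo pipeline (40 synthetic subjects, 12³ voxel grid, two
six-minute runs per subject, a planted *negative* connectivity × amyloid ×
time interaction) from simulation through model fitting:

```bash
netthin run-all --outdir results/demo --seed 7
```

or equivalently, step by step with the numbered analysis drivers:

```bash
python analysis/01_simulate.py      # cohort + imaging sessions
python analysis/02_preprocess.py    # filtering + nuisance removal
python analysis/03_connectivity.py  # TBR connectivity
python analysis/04_composites.py    # cortical composites
python analysis/05_pet.py           # amyloid DVR + grouping
python analysis/06_fit_models.py    # mixed-effects models
python analysis/07_calibration.py   # estimator calibration summary
```

Output of the final two steps on this machine:

```
primary three-way term: estimate -1.232, t(123) = -2.80, p = 0.0060,
d = -0.50 (planted sign: negative)

recovery (n=120, 50 reps): relative bias -5.3%, power 64% at alpha 0.05
null (n=80, 100 reps): type-I error 5.0% (MC SE 2.2%)
```

Reading this: the pipeline measured each subject's DMN connectivity from
the synthetic BOLD (not from the planted values), fed it into the mixed
model, and recovered the planted negative three-way interaction — lower
baseline connectivity with higher amyloid burden predicts faster composite
thinning — with the correct sign and conventional significance.  The
calibration lines summarize replicate simulations of the estimator at
study size (120 subjects, 2–8 visits).

The intermediate drivers print their own checks, e.g. adjusted
connectivity tracking the planted coupling (`03`, Pearson r ≈ 0.72 at demo
noise), composite thickness matching the generative trajectories to the
vertex-noise floor (`04`), and exact DVR recovery from ROI tables (`05`).

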