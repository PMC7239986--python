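# Methods

## Problem and model

Semi-quantitative analysis of dopamine-transporter (DAT) SPECT reduces a
scan to the putaminal specific binding ratio (SBR): the mean tracer signal
in a putamen region divided by a reference level, minus 1. A scan is called
neurodegenerative when its SBR, expressed as a z-score against a *normal
database* (scans without nigrostriatal deficit), falls below a fixed
cutoff:

    z = (Ln(SBR) − μ_db) / σ_db,   positive ⇔ z < −2.5

where μ_db, σ_db are the mean and sample standard deviation (n−1
denominator) of the Ln-transformed SBR over the database. The package
studies how the *size* of that database affects classification accuracy,
sensitivity and specificity, by Monte-Carlo resampling of databases from a
cohort's normal group.

## Synthetic cohorts

Normal putaminal SBR distributions are right-skewed. The generator models
each group's SBR as i.i.d. log-normal, `Ln(SBR) ~ Normal(ln_mu, ln_sigma)`,
and calibrates the normal group's `ln_sigma` by inverting the closed-form
log-normal skewness

    skew(σ) = (e^{σ²} + 2) · √(e^{σ²} − 1)

with Brent root finding (the function is strictly increasing, so the root
is unique; round-trip agreement is better than 1e−10). Calibration is
against the *population* skewness, not a bias-corrected finite-sample
estimator.

Defaults (all exposed in `GroupSpec` / the cohort presets):

| parameter | default | why |
|---|---|---|
| normal-group skewness target | 0.877 | largest reported normal-group SBR skewness (iterative reconstruction with resolution recovery, anatomical ROI) → σ ≈ 0.279 |
| normal median SBR | 5.0 | typical high-contrast reconstruction scale; only the shape matters after z-scoring |
| disease median SBR | 1.6 | implementer-chosen to give the clear normal/disease separation seen in published cohorts; the disease distribution is never printed numerically, only box-plotted |
| disease `ln_sigma` | 1.3 × normal's | disease groups are more heterogeneous |
| group sizes | 207/438 ("ppmi-like") or 186/186 ("clinical-like") | the two study populations emulated |

With these defaults the benchmark classifier (full 186-subject normal
database) reaches accuracy ≈ 0.95, sensitivity ≈ 0.90, specificity ≈ 0.99 —
deliberately in the regime where database-size effects are visible rather
than saturated.

Sampling uses one root seed per cohort; group streams are spawned in fixed
order (normal first), and the two SBR columns (`aal`, `hv`) are drawn
independently from the same group distribution — the generator makes no
claim about the correlation between quantification methods, which the
resampling study never uses (it analyses one method at a time).

What the generator does *not* emulate: age/sex effects (deliberately, the
emulated analysis ignores them), SWEDD-like mislabelled subjects,
between-method correlation, scanner drift, or any image-level artefact.
Passing tests therefore show correctness of the statistical machinery under
the stated log-normal model, not robustness to real-data pathologies.

## Phantoms and SBR quantification

The phantom module renders a brain ellipsoid at uniform background
intensity with four disjoint striatal ellipsoids (left/right caudate and
putamen, ~3.9 ml per putamen) on an MNI-like grid (91×109×91 voxels, 2 mm
isotropic, configurable). Noiseless structure intensity is
`background · (1 + r)` for true binding ratio `r`; an isotropic Gaussian
PSF (separable convolution, reflective boundary) emulates reconstruction
smoothness (7 mm "iterative + resolution recovery"–like vs 12 mm "filtered
backprojection"–like), and optional post-blur Poisson noise emulates
reconstructed-image noise. Projection-domain physics (attenuation, scatter,
reconstruction algorithms) is out of scope. Masks are drawn on the
unblurred geometry: exact structures, enlarged putamen masks (2× semi-axes,
~31 ml) for hottest-voxels analysis, and a reference region (brain minus
enlarged striatal structures minus a central thalamus/brain-stem/ventricle
stand-in).

Quantification: volumes are scaled voxel-wise to the 75th percentile of the
reference-region intensity (making every SBR invariant under global
rescaling), then

* anatomical-ROI SBR = mean scaled intensity over the putamen mask − 1;
* hottest-voxels SBR = mean of the k highest scaled intensities inside the
  big mask − 1, with k = round(10 ml / voxel volume) = 1250 on the default
  grid;
* the bilateral putaminal SBR is the minimum over hemispheres.

Numerical conventions, chosen where the emulated procedure is silent:

* all percentiles (reference scaling and study summaries) use linear
  interpolation between order statistics (numpy/R type 7);
* ties at the k-th hottest rank are broken by ascending flat voxel index,
  for platform-independent determinism;
* a volume/mask grid mismatch is an error, never a silent resample;
* a z-score exactly at the cutoff is negative (strict inequality; a
  measure-zero event under the model);
* non-positive SBR under the Ln transform raises, rather than clipping —
  the generator guarantees positivity, so a violation signals bad input;
* skewness is the bias-adjusted Fisher–Pearson G1 (flag for plain g1).

## Resampling study

For each size n in {5, 10, …, 50} (grid configurable), 10,000 databases are
drawn uniformly without replacement from the normal group, independently
across repeats and sizes. Each database yields a z-score transform; the
*whole* cohort — database members included — is classified, matching the
emulated design (the members are < 13.5% of the test set; a flag excludes
them for sensitivity analyses). Per size the study records mean, 5th
percentile and SD of accuracy/sensitivity/specificity over repeats, plus

    relative loss (%) = 100 · (benchmark acc − acc) / benchmark acc

against the full-normal-group benchmark; the "maximum" loss is that
formula evaluated at the 5th percentile of accuracy (a downside-risk
summary, not the literal worst repeat). Losses may be negative — a lucky
small database can beat the benchmark — and are passed through unclipped.

RNG: one root seed; a `SeedSequence` child is spawned per size and the
repeats of that size are drawn in one vectorized block. This keeps the
study exactly reproducible and sizes mutually independent; per-repeat
substreams were rejected as they force a Python-level loop with no
statistical benefit. The 10-size × 10,000-repeat study on a 372-subject
cohort runs in ~1.5 s.

The effective-sample-size helper implements
`n_eff = 2·n1·n2/(n1+n2)` — the equal-group size with approximately the
same two-sample power — which for a single subject against a database of n
reduces to `2n/(n+1) < 2`, the heuristic explanation for why mean accuracy
plateaus by n ≈ 10–15 while its *variability* keeps shrinking to n ≈ 40.

## Problem sizes in the shipped tests

The test suite runs the full-scale replication (10,000 repeats, sizes
5..50, clinical-like cohort) once as a shared fixture; convergence checks
use 10⁵-subject groups and 10⁶ generator draws with batch-estimated
Monte-Carlo standard errors (50 batches of 20,000; tolerance 3 SE).
Volume-mode pipeline tests use 4 phantoms on the default grid. The entire
suite completes in well under a minute on one CPU.

## Known limitations

* The log-normal cohort model and the implementer-chosen disease
  separation reproduce the *structure* of the emulated analysis, not its
  dataset-specific benchmark accuracies; only bound-type claims (losses
  below 1%/5%) and calibration targets are meaningfully comparable.
* Phantoms are geometric idealizations; partial-volume behaviour of the
  HV method is qualitative only.
* No age/sex correction, no ROC-derived cutoffs, no comparison of
  normal-database composition types — all out of scope by design.
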