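# datsbr

How large does a normal database need to be for reliable semi-quantitative
classification of dopamine-transporter (DAT) SPECT?

In FP-CIT SPECT, a scan is reduced to the putaminal **specific binding
ratio** — SBR = (mean scaled intensity in a putamen ROI) − 1, after scaling
the image to the 75th percentile of a reference region — and classified as
neurodegenerative when its z-score against a database of normal scans falls
below a fixed cutoff:

    z = (Ln(SBR) − μ_db) / σ_db,    positive ⇔ z < −2.5

Because normal SBR distributions are right-skewed, SBR values are
Ln-transformed before z-scoring. Sites building such a database face a
practical question: how many normal scans are enough? `datsbr` answers it
by simulation. It provides:

* **synthetic cohorts** — log-normal SBR groups, with the normal group's
  log-scale SD calibrated so the SBR skewness matches reported values
  (e.g. 0.877) by inverting the closed-form log-normal skewness;
* **digital striatal phantoms** — ellipsoidal caudate/putamen with known
  binding ratios, Gaussian PSF and Poisson noise, plus matched ROI masks
  (NIfTI-1 in/out);
* **SBR quantification** — reference-percentile scaling, anatomical-ROI
  SBR, hottest-voxels SBR (mean of the k hottest voxels totalling 10 ml in
  a generous putamen mask), bilateral minimum;
* **the resampling study** — for each database size n ∈ {5, 10, …, 50},
  draw 10,000 random normal databases from the cohort's normal group,
  classify the whole cohort with each, and summarize accuracy, sensitivity
  and specificity by their mean and 5th percentile, against the
  full-normal-group benchmark, with
  relative loss (%) = 100 · (benchmark − accuracy) / benchmark. The
  "maximum" loss is the relative loss at the 5th percentile of accuracy.

It is aimed at nuclear-medicine physicists and methodologists planning or
auditing normal databases, and at anyone wanting a fully synthetic,
ground-truth-known test bed for SBR pipelines.

## Worked example

```python
import datsbr as d

cohort = d.sample_cohort(d.clinical_like_spec(seed=0))   # 186 normal + 186 disease
summary = d.run_study(cohort, d.StudyGrid(repeats=10_000, seed=1), method="aal")

b = summary.benchmark
print(f"benchmark: acc={b.accuracy:.4f} sens={b.sensitivity:.4f} spec={b.specificity:.4f}")
cols = ["size", "acc_mean", "acc_p5", "mean_loss_pct", "max_loss_pct"]
print(summary.per_size[cols].to_string(index=False, float_format="%.4f"))
print("n_eff(1, 15) =", round(d.effective_sample_size(1, 15), 3))
```

prints

```
benchmark: acc=0.9489 sens=0.9032 spec=0.9946
 size  acc_mean  acc_p5  mean_loss_pct  max_loss_pct
    5    0.9195  0.7796         3.0981       17.8470
   10    0.9365  0.8575         1.3086        9.6317
   15    0.9413  0.8817         0.8033        7.0822
   20    0.9436  0.9059         0.5581        4.5326
   25    0.9448  0.9165         0.4373        3.4136
   30    0.9458  0.9194         0.3339        3.1161
   35    0.9462  0.9247         0.2860        2.5496
   40    0.9464  0.9247         0.2610        2.5496
   45    0.9466  0.9301         0.2499        1.9830
   50    0.9466  0.9328         0.2456        1.6997
n_eff(1, 15) = 1.875
```

Reading the table: with only 5 normal subjects the classifier loses 3.1%
accuracy on average and 17.8% in the unlucky 5th-percentile database; by
size 15 the *mean* loss is under 1%, but the downside ("maximum") loss only
drops below 5% around size 20–30, and improvements beyond size 40 are
marginal. The effective-sample-size heuristic
n_eff = 2n/(n+1) < 2 for a single subject versus a database of n explains
the early plateau of the mean: the single test subject, not the database,
dominates the comparison once n ≈ 10–15.

The same study is available from the shell:

```sh
datsbr simulate-cohort --preset clinical --seed 0 --out cohort.csv
datsbr study --cohort cohort.csv --method aal --sizes 5:50:5 \
       --repeats 10000 --seed 1 --out summary.csv --plot summary.png
datsbr neff 15
```

and a full phantom-based run (render → quantify → study) via
`datsbr run --config run.yaml` or, per stage, `simulate-volumes`,
`quantify` and `zscore`. See `docs/methods.md` for the model, parameter
defaults and numerical conventions.

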