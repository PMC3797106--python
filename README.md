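# breakscan

Chromosomal breakpoint counting in SNP-array copy-number profiles as a
prognostic marker of genomic instability, with the full validation
pipeline around it.

Early luminal breast carcinomas (ER+, HER2−, node-negative) are mostly
good-prognosis tumors, and the clinical challenge is spotting the minority
that will relapse.  One proposed marker is *genomic complexity*: the number
of chromosomal breakpoints — boundaries between segments of differing
copy-number signal — tallied genome-wide.  `breakscan` implements that
marker end-to-end:

1. **Segmentation.**  Per chromosome, the normalized log-signal is modelled
   as piecewise constant with Gaussian noise, `y_i = μ_j + ε_i`.  For every
   candidate breakpoint number k the globally optimal least-squares
   segmentation is found by exact dynamic programming (a vectorized
   segment-neighbourhood engine, plus a functionally pruned engine that
   returns the identical optimum).
2. **Model selection.**  k is chosen by a modified BIC for change-point
   models, `(n/2)·log(RSS₀/RSS_k) − (3k/2)·log n + ½·Σ log(n_j/n)`; a first
   liberal screening round discards outlier probes that land in singleton
   segments before the final fit.
3. **Classification.**  Counts are dichotomized at a strict cut-off
   (reference: > 34 breakpoints ⇒ high-risk); the cut-off is trainable by
   the Youden index with ROC/AUC, DeLong confidence intervals and Wald
   intervals on sensitivity/specificity.
4. **Comparators.**  Genomic grade index (112/16 probe-set contrast,
   anchored so grade-1/grade-3 cohort means sit at −1/+1), KI67 ≥ 14%
   dichotomization, and the IHC3 score (IHC4 without its HER2 term).
5. **Survival validation.**  Kaplan-Meier, log-rank, univariate and
   multivariate Cox fits (Efron ties, via lifelines) for disease-free and
   metastasis-free intervals.
6. **Synthetic data.**  Generators for probe-level profiles with known
   breakpoints and for two-group cohorts matching the reference study's
   statistics (count medians 7 / 40.5, Spearman(GGI, count) ≈ 0.54, hazard
   ratio 3.5 for the high-count class), so everything runs without any
   download.

See `docs/methods.md` for the model, the criterion derivation, calibration
choices and limitations.

## Worked example

Run the whole chain — simulate a 109-tumor cohort, synthesize each tumor's
probe-level genome, segment, count, classify at > 34, and validate — with
one command:

```sh
breakscan pipeline --out-dir demo --n-good 79 --n-poor 30 --seed 1
```

```
pipeline complete: 109 tumors, trained threshold 18, artifacts in demo
```

`demo/counts.csv` holds the per-tumor tally (measured vs simulated truth):

```
tumor_id,n_probes_removed,n_breakpoints,true_breakpoints,risk_class
P0001,39,9,9,low_risk
P0002,86,13,13,low_risk
P0003,60,9,9,low_risk
```

Here 98% of tumors land within ±2 of their true breakpoint count.
`demo/fits_dfi.json` carries the disease-free-interval validation on the
measured counts: log-rank χ² = 14.98 (p = 1.1 × 10⁻⁴) and a univariate Cox
relative risk for the > 34-breakpoint class of **3.74 (95% CI 1.83–7.67)**
— the cohort was simulated at a true hazard ratio of 3.5, so the fit
recovers the generating effect.  `demo/model.json` is the Youden-trained
threshold on this cohort (18 breakpoints, sensitivity 1.00, specificity
0.97, AUC 0.996): with only 109 patients the trained cut-off moves with
the sample; classification at the reference cut-off uses
`breakscan classify --threshold 34`.

The individual stages are available as separate commands
(`breakscan simulate profile|cohort`, `segment`, `train-threshold`,
`classify`, `scores`, `survival`) and as plain library calls
(`breakscan.optimal_segmentation`, `breakscan.select_k`,
`breakscan.youden_threshold`, `breakscan.cox_fit`, ...).

As a quick statistics check, the reference 2×2 classification table
(74/5 low/high in the good-prognosis group, 13/17 in the poor group)
reproduces its printed operating characteristics:

```python
>>> from breakscan import contingency_stats
>>> s = contingency_stats(74, 5, 13, 17)
>>> round(s["specificity"], 2), round(s["sensitivity"], 2)
(0.94, 0.57)
>>> [round(100 * x) for x in s["sensitivity_ci"]]
[39, 74]
```

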