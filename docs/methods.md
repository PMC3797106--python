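# Methods

## Problem and model

`breakscan` quantifies genomic instability in tumor copy-number profiles as
the genome-wide number of chromosomal breakpoints, and evaluates that count
as a prognostic marker for early luminal (ER+/HER2−, node-negative) breast
carcinoma.  The probe-level model is the standard mean-shift formulation:
within one chromosome the normalized log-scale signal

    y_i = mu_j + e_i,   e_i ~ N(0, sigma^2)  for  tau_{j-1} < i <= tau_j,

is piecewise constant with homoscedastic Gaussian noise; a breakpoint is a
boundary tau_j between two segments of differing mean.  Only the *number*
of breakpoints matters downstream — the classifier deliberately ignores
which regions are gained or lost and whether segments are gains or losses.

## Segmentation

For each chromosome and each candidate breakpoint number k = 0..k_max,
`optimal_segmentation` finds the *global* least-squares optimum

    RSS(k) = min over tau_1 < ... < tau_k  of  sum_j sum_{i in seg j} (y_i - ybar_j)^2

by dynamic programming.  Two exact engines are provided and property-tested
against each other and against exhaustive enumeration:

* `dp` — segment-neighbourhood recursion `D_k(j) = min_s D_{k-1}(s-1) + C(s, j)`
  vectorized over split points; O(k_max n^2) time using a precomputed
  interval-cost table (probes are centred first and costs clipped at zero
  against cancellation).  Practical up to ~20k probes per chromosome.
* `pruned` — functional pruning: the layer-k cost is carried as the lower
  envelope of per-candidate quadratics in the current segment mean;
  candidates whose quadratic leaves the envelope are discarded.  This is
  the almost-linear formulation used by exact copy-number segmenters and
  returns the identical optimum (asserted for n ≤ 200 in the tests).

Ties between equally optimal placements break deterministically toward the
smallest split index.  Segmentation is per chromosome; the genome-wide
count is Σ_chrom (segments − 1), so chromosome junctions never count.
Per-chromosome `k_max` defaults to min(⌈n/4⌉, 60): far above counts seen in
this disease setting, while bounding runtime.

## Choosing the number of breakpoints

The final k per chromosome maximizes a modified Bayes information
criterion for change-point models (see the `mbic_criterion` docstring for
the derivation):

    mBIC(k) = (n/2) log(RSS(0)/RSS(k)) − (3k/2) log n + (1/2) Σ_j log(n_j / n)

with n_j the optimal segment lengths.  The first term is the profile
Gaussian log-likelihood gain (variance profiled out, so the criterion is
shift- and scale-invariant — selection does not change when the signal is
rescaled, which the tests assert).  Each breakpoint is charged (3/2) log n:
(1/2) log n for its new mean parameter plus log n for its discrete location
under a uniform prior — more than the (2/2) log n of naive parameter
counting, which is what makes the criterion conservative on pure noise.
The relative-length term additionally penalizes uneven segmentations, most
strongly singletons.  `RSS(k)` is floored at `1e-12 · RSS(0)` so noiseless
toys stay finite; an exactly constant signal selects k = 0.

## Outlier screening (round 1)

Isolated probe-level artifacts would otherwise each contribute two spurious
breakpoints.  Each chromosome therefore passes a first segmentation round
whose only purpose is to flag probes that land in length-1 (singleton)
segments; those probes are discarded and the cleaned signal is segmented
afresh.  There is exactly one screening round and one final round.

The screening round selects its k with a deliberately *liberal* penalty,
(1/2) log n per breakpoint and no length term.  The rationale is an
asymmetric loss: over-segmentation in round 1 is harmless (only singleton
segments trigger removal, and a false singleton still requires roughly a
3.6σ excursion at n = 500, keeping false removals at ~0.2% in simulation),
whereas a missed outlier corrupts the final count.  Under the mBIC penalty
a 6σ singleton costs ≈ 2·(3/2)·log 500 + 3 ≈ 22 but gains only ≈ 18 in
expected log-likelihood, so an mBIC-screened round misses most genuine 6σ
spikes; the screening penalty removes ≥ 95% of them in simulation.  The
rule is configurable (`SegmentationParams.round1_rule = "mbic"` restores a
uniform criterion for both rounds).

## Classifier

The count is dichotomized by a strict rule: more than `threshold`
breakpoints ⇒ high-risk genomic complexity (reference cut-off 34, so a
count of exactly 34 is low-risk).  Training scans every achievable strict
cut-off (observed distinct counts plus a −1 sentinel) and picks the Youden
optimum, the threshold maximizing sensitivity + specificity, smallest
threshold on ties.  The positive class is poor prognosis and higher counts
indicate positivity.  Sensitivity and specificity carry Wald 95% intervals
p ± 1.96·√(p(1−p)/n) truncated to [0, 1] — chosen because the Wald form
reproduces the reference report's printed intervals, which exact binomial
intervals do not.  The AUC is the empirical Mann-Whitney statistic (ties
counted ½) with a DeLong interval by default (midrank placements) or a
seeded stratified bootstrap (2000 replicates); which method the original
report used is not stated.

## Proliferation comparators

* **Genomic grade index.**  raw GGI = Σ expression(112 probe sets up in
  grade 3) − Σ expression(16 probe sets up in grade 1), per sample, with
  user-supplied panel files (the commercial panel identities are not
  shipped; sizes other than 112/16 load with a warning).  Standardization
  is affine: scale = 2/(m3 − m1), offset = (m3 + m1)/2 from the raw
  grade-1/grade-3 cohort means, anchoring those means at −1 and +1.
  Grade-2 tumors are scored by the anchor-fitted model.  Genomic grade GG3
  iff standardized GGI > 0; exactly 0 is GG1 (conservative tie rule).
* **KI67.**  High iff stained fraction ≥ 14% (the boundary value defines
  the high group).
* **IHC3.**  The published IHC4 immunohistochemistry combination with the
  HER2 term dropped for HER2-negative tumors:
  94.7·(−0.100·ER10 − 0.079·PR10 + 0.240·ln(1 + 10·Ki67)).  Coefficients
  live in one citable constant block.  Manual KI67 reads may be divided by
  a calibration factor (`ki67_rescale`, default 1, always logged) because
  the original rescaling constant is not published.

## Survival analysis

Kaplan-Meier product-limit curves, the two-group log-rank chi-square
(1 df), and Cox proportional-hazards fits are delegated to lifelines
behind the module surface, with event-time ties handled by the Efron
approximation (the original tie handling is unstated; Efron is the modern
default).  Hazard ratios are reported as relative risks with Wald 95%
intervals and Wald p-values.  The reference multivariate set is grade
II/III vs I, KI67 class, genomic grade, and breakpoint class.  Constant or
collinear covariates, event counts at or below the parameter count, and
non-convergence raise explicit errors.  The tests validate the delegated
fits against hand product-limit arithmetic, a direct log-rank tabulation
oracle, and parameter-recovery/null simulations.

## Synthetic data: what it emulates, what it does not

`simulate_profile` draws exactly the signal model the segmentation assumes
(piecewise-constant means, iid Gaussian noise, iid ±spike outliers), so
segmentation tests are *internal-consistency* checks: they show the
estimator recovers truth under its own model at the stated signal-to-noise,
not that real SNP 6.0 arrays satisfy the model.  Real arrays add GC waves,
allele-specific structure, spatially correlated noise and probe-quality
heterogeneity, none of which are emulated; segmentation accuracy on real
data will be lower at equal jump/σ.

`simulate_cohort` reproduces the reported cohort statistics rather than
the biology: negative-binomial breakpoint counts per prognosis group
calibrated so the distribution medians hit 7 (good) and 40.5 (poor); a
rank-based Gaussian copula links the genomic grade index to the realized
cohort-wide count ranks with latent correlation ρ_z = 2 sin(π·ρ_S/6) so the
Spearman target (0.54) holds in expectation; KI67 and histologic grade are
noisy monotone transforms of the same latent (calibrated to ~55% KI67-high
and ~46/39/15% grade I/II/III); ER/PR are skewed-high categorical draws
befitting an ER+ cohort.  Event times are exponential with hazard ratio
`hr_highclass` (default 3.5) for tumors above 34 breakpoints, baseline
hazards set so the expected low-class event fractions over the 10.5-year
horizon equal the reference tallies (19/83 disease-free events, 4/83
metastasis events), and administrative censoring at the horizon (an
optional exponential censoring rate is off by default).  The two endpoints
are generated independently, so a patient can have a metastasis time
without the corresponding disease-free event — adequate for per-endpoint
analyses, wrong for joint modelling.  NB dispersions (size 2.0 good /
25.0 poor) are free calibration knobs the source statistics do not pin
down: the good group keeps a heavy tail (~6% of good tumors above 34
breakpoints), and the poor group's 30-patient sample median stays
reproducibly near 40.5.

## Numerical and design choices

* Probe indices are 1-based inclusive internally; BED output is 0-based
  half-open.  Segments tile the probed interval: each boundary sits
  immediately after the last probe of the left segment, so consecutive BED
  rows share a coordinate.
* Duplicate probe positions are averaged (deterministic and
  order-independent); non-finite signal rows are dropped at load;
  chromosomes with fewer than two retained probes contribute zero
  breakpoints with a warning.  Within a tumor, chromosomes follow the
  1..22, X, Y order; sex chromosomes are not special-cased (whether the
  original tally included them is unknown — flagged, not guessed).
* Whether the original analysis segmented per chromosome or genome-wide is
  unstated; per chromosome is the physically coherent choice (junction
  artifacts must not count) and is what this package does.
* Problem sizes used by the test-suite simulations (e.g. 500-probe
  chromosomes, 50-seed batteries, 100-simulation coverage runs, 150-probe
  chromosomes in the end-to-end pipeline) were chosen as the smallest
  scales at which the binomial noise of the checked proportions is well
  inside the asserted margins.

## Known limitations

* The `dp` engine's O(n²) cost table caps chromosomes at ~20k probes; the
  `pruned` engine is exact at any n but is pure Python and slower per
  probe at desk scale.
* The mBIC constants are transcribed from the published criterion for the
  single-sample Gaussian mean-shift model; platform-specific adjustments
  used by the original pipeline, if any, are not public and are not
  replicated.
* Wald intervals for sensitivity/specificity degenerate at p ∈ {0, 1};
  they are truncated, not replaced by exact intervals, to stay consistent
  with the reference report's convention.
* The synthetic cohort's covariate structure is a copula sketch: it matches
  the reported medians, one rank correlation, and marginal class
  frequencies, not the full joint distribution of a real cohort.
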