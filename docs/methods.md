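# Methods

`pretermbiome` models the risk of spontaneous preterm birth (sPTB, delivery
before 37 completed weeks) as a function of cervicovaginal microbiota
features, with explicit propagation of the measurement error that afflicts
amplicon relative abundances of rare taxa. This note documents the models,
the numerical choices, and what the synthetic cohorts do and do not emulate.

## Data model and filters

The central object is a `TaxaTable`: a samples x taxa matrix of raw read
counts and/or relative abundances (RA), with per-sample metadata (subject,
visit 1–3, race group, gestational age at sampling and delivery, outcome,
optional qPCR total 16S copies/swab and visit-1 beta-defensin-2 in pg/ml).
Outcome and gestational age at delivery must be mutually consistent; a
34-week sensitivity cutoff is a recoding parameter, not a second field.

Filters follow strict-inequality conventions: samples are kept with *more
than* 1000 reads; taxa are kept whose study-wide pooled frequency (total
taxon reads / total reads; an unweighted per-sample-mean variant is a flag)
is at least 1e-5; the per-taxon risk models are gated on detection
(RA > 0) in *more than* 25% of samples. Six known reagent-contaminant
phylotypes are removed by name (configurable list). Rows are by default
**not** renormalised after taxon removal, so the log10 RA of retained taxa
is unchanged going into the risk models; renormalisation is available as an
option. Absolute abundances are qPCR total x RA, with missing totals giving
missing values rather than failures.

## Community state types

Samples from all visits are clustered jointly: pairwise Jensen–Shannon
divergence (base 2) between compositions, Ward linkage on sqrt(JSD) (a true
metric; raw JSD is available for sensitivity), cut at k = 6. Clusters are
named from mean compositions — dominance by *L. crispatus* / *L. gasseri* /
*L. iners* / *L. jensenii* gives CSTs I/II/III/V; if two clusters claim the
same species the more dominated one wins and the other joins the IV pool;
among *Lactobacillus*-poor clusters the one with the highest mean BVAB1 is
IV-A, the rest IV-B. Out-of-batch samples can be assigned by nearest
centroid in JSD. Per-visit CST-vs-outcome differences use ordinary logistic
regression on the CST-membership indicator (separated or empty cells are
reported as inestimable); a mixed-effects all-visit comparison is out of
scope.

## Replicate measurement-error model

Repeated sequencing of one pooled control specimen shows replicate spread
of log10 RA that grows as abundance falls. Per taxon (detected in >= 2
replicates) we take the replicate mean and sd of log10 RA; the sd-vs-mean
relation is LOWESS-smoothed (frac 0.5; each raw sd carries sampling noise
~ sd/sqrt(2(n-1)) at n replicates) and projected onto the non-increasing
cone by isotonic regression, with flat extrapolation beyond the fitted
support. A log-linear alternative is a config option. The perturbation
sampler draws x' ~ Normal(x, sd(x)) independently per taxon — values are
deliberately not re-closed to the simplex, matching the univariate
per-taxon risk models, and values perturbed below the detection floor are
kept (they correspond to observed-detected samples).

## Bayesian adaptive-spline risk model

For each eligible taxon, using only samples in which it was detected,

    y_i ~ Bernoulli(expit(theta_b(i)))

with one latent logit per covariate position. Positions are the unique
log10 RA values, quantile-binned to at most 100 bins for tractability (the
sampler's cost grows with the number of latent positions; 100 bins retain
curve resolution). The prior is horseshoe trend filtering of order 2:
second differences of theta receive independent horseshoe priors with
local scales lambda_j ~ C+(0,1) and global scale tau ~ C+(0, tau0),
tau0 = n^-1/2 by default (trend-filtering heuristic; exposed in config).
The level and slope null space carry weak normal priors (scales 3 and 2
logit units, level centred at logit of the observed sPTB proportion). This
family yields locally adaptive curves that can bend sharply where data
demand and remain stable at the extremes of the covariate range.

Posterior computation is an exact blocked Gibbs sampler rather than
generic HMC: Polya-Gamma augmentation of the logistic likelihood (one
PG(n_b, theta_b) variable per bin, drawn via the truncated sum-of-gammas
series, 128 terms, the tail replaced by its expectation — the sampler's
mean is verified against the analytic E[PG(b,c)] = b tanh(c/2)/(2c));
inverse-gamma auxiliary updates for the horseshoe scales; and a single
multivariate-normal draw for the whole latent curve from its banded-
precision full conditional (dense Cholesky; B <= 100). Defaults are 4
chains x 1000 warmup + 1000 draws; split-Rhat on the latent curve above
1.05 flags (never silently passes) the fit. All-0/all-1 outcome vectors
produce a degenerate flat fit at the observed proportion.

### Measurement-error averaging

The model is refitted `n_resamples = 5` times on covariates perturbed by
the replicate-error model, and the five posterior-mean curves are averaged
on the unperturbed covariate grid. Credible bands come from the pooled
posterior draws of all component fits. Because perturbation is widest at
low abundance, the averaged curve relaxes toward the baseline risk (the
sPTB proportion among detected samples) exactly where measurement error
makes the signal untrustworthy — this attenuation is a designed property,
not a bug, and it slightly shrinks recovered effect sizes when the
covariate noise is large.

### Effect size, threshold, significance

* Effect size gEff = max(f) − min(f) of the averaged curve, signed
  positive when the maximum sits at larger abundance than the minimum
  (ties at extrema break leftmost).
* Risk threshold: the crossing of f with y* = min(f) + 0.1·|gEff| —
  the leftmost crossing to the right of the global argmin for positive
  associations (mirror image for negative), linearly interpolated between
  grid points. Taxa with |gEff| < 0.10 get no threshold and are excluded
  from downstream significance.
* Association evidence: P = posterior probability (pooled draws) that risk
  at the high-abundance end of the grid exceeds risk at the low end;
  p = 2·min(P, 1−P), floored at 1/(number of draws). How a q-value should
  arise from a Bayesian fit is genuinely open; this tail-probability
  construction is our documented choice. Benjamini–Hochberg FDR is applied
  across the taxon family; significance requires q < 0.05 **and**
  |gEff| >= 0.10.
* Absolute-abundance fits reuse the machinery with covariate
  log10(total) + log10(RA); the perturbation is applied on the RA
  component (the error model's domain) and the qPCR offset added after,
  preserving the log-scale conservation identity.

Samples are treated as independent (no per-subject random effects), the
same simplification the analysis design assumes.

## Downstream analyses

* **Gestational-age trends** (Shannon diversity, log10 bacterial load):
  OLS on a restricted-cubic-spline basis (Harrell's knot quantiles),
  knot count in {3,4,5,6} selected by AIC. "Thin-plate" smoothing in a
  univariate OLS setting is realised as this restricted cubic basis — a
  documented divergence from the verbatim term.
* **Survival**: Kaplan–Meier curves for time to delivery; Cox models with
  the above/below-threshold indicator as a time-varying covariate in
  counting-process form. Covariates are carried forward from the most
  recent visit until the next visit or delivery; contiguous same-state
  intervals are collapsed; the final interval ends at delivery with
  event = 1. Efron tie handling; constant covariates short-circuit to
  HR = 1 exactly; separation is flagged, not raised.
* **beta-defensin-2**: Welch t-test on log10 values (pooled-variance
  option for strict replication), stratifiable by CST and race group.
* **Two-proportion comparisons**: independent Beta(x+1, n−x+1) posteriors
  (uniform priors); P(p1 > p2) by adaptive quadrature of one density
  against the other's CDF; the reported "p-value analog" is
  2·min(P, 1−P).
* **Modulation**: sPTB proportions within beta-defensin-2 quartiles over
  samples where a risk taxon is detected (Q1 vs Q4 compared as above);
  and the 3x3 beta-defensin-2 x *Lactobacillus* tertile grid, each cell
  compared to the visit-1 design baseline (102/521 = 19.58% by default),
  annotated with CST composition and above-threshold *M. curtisii/
  mulieris* counts, with cell pooling supported. Tertile/quartile cuts
  use sample quantiles with ties to the lower bin so cuts are reproducible
  on discrete data. All analyses are complete-case; the non-randomness of
  missingness after preterm delivery is not modelled.

## Synthetic cohorts

The generator emulates the features the analyses rely on: six CST profiles
(four *Lactobacillus*-dominated, two diverse anaerobic, IV-A marked by
BVAB1) mixed with race-group-dependent weights (AA-predominant cohort);
logistic-normal composition draws (sigma = 1.2 natural-log units) around
profile means with a 3e-5 detection floor — producing the bimodal log10 RA
distributions and realistic prevalence patterns; multinomial read
resampling at ~40k mean depth; ~20% case fraction via an intercept
calibrated after composing log-odds-additive injected risk curves over
chosen taxa (evaluated on visit-1 latent abundances); preterm deliveries
drawn around 33 +- 4 weeks causing later-visit attrition; replicate
positive controls with sd growing from 0.05 to ~0.35 as log10 RA falls
from -2 to -4 (padded control taxa span [1e-4, 10^-1.5]; a 20-specimen
pooled control rarely carries consistently detected taxa below 1e-4);
and visit-1 beta-defensin-2 as lognormal values floored at 15.6 pg/ml with
outcome/CST-dependent location — the location defaults are
order-of-magnitude choices, not literature values. `SyntheticTruth`
records, before any censoring, the per-subject risk probabilities, latent
log10 abundances, CST labels, and each injected taxon's realised
(post-calibration) risk curve with its effect size and threshold.

Not emulated: sequence-level artefacts (chimeras, run/batch effects beyond
the replicate error model), within-subject compositional autocorrelation
beyond CST persistence (0.85/visit), correlated multi-taxon risk, and
informative missingness other than delivery-driven attrition. Passing
recovery tests therefore demonstrates correctness of the estimators under
these idealised conditions, not robustness to batch effects or confounding
in real cohorts.

## Problem sizes and tolerances

Verification uses desk-scale experiments chosen as the smallest sizes at
which the targeted properties are statistically resolvable: effect-size
and threshold recovery on 1500 detected samples averaged over 5 replicate
cohorts with the full 5-resample pipeline (2 chains x 500+500 draws per
component fit); the zero-noise consistency check at 4 chains x 2000 draws
(Monte-Carlo error must sit well under the 0.02 sup-norm band); null
calibration with 20 taxa x 40 replicate families at 300 samples per taxon
(1 chain x 200+200, 40 bins, single resample); error-model recovery from
14 replicates x 80 control taxa. Quadrature and closed-form comparisons
are checked to 1e-6 or tighter; Monte-Carlo oracles to ~3 standard errors.

## Known limitations

* The Gibbs sampler's PG draws use a truncated series (K = 128) with a
  deterministic tail correction; the induced bias is far below Monte-Carlo
  noise at the scales used but the sampler is not exact in the strict
  Devroye sense.
* Short chains (as used in some scaled-down experiments) can trip the
  split-Rhat 1.05 warning; fits are flagged, and production settings
  (4 x 1000+1000) converge cleanly in our experiments.
* gEff is a max-minus-min functional of a posterior-mean curve and is
  mildly biased downward by shrinkage and by covariate-noise attenuation;
  thresholds inherit uncertainty from flat regions of the curve, where the
  crossing point is weakly identified.
* The beta-binomial grid performs nine dependent comparisons against a
  shared baseline without multiplicity adjustment, mirroring the intended
  exploratory use.
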