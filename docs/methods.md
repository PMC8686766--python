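# Methods

This note documents the statistical procedures implemented in `proteotype`,
the defaults they ship with, and what the synthetic-cohort tests do and do
not establish.

## Data model

The unit of analysis is the aptamer **probe**; abundance is a positive RFU
(relative fluorescence unit) analysed throughout on the log2 scale. A probe
may measure several proteins (isoform- or complex-ambiguous reagents): it is
kept as one row of the matrix, and contributes *each* of its protein symbols
at enrichment/overlap time. The hypergeometric universe is the distinct
symbol set of the QC-passing probes.

## Normalization

Median signal normalization rescales each sample so the median of its
probe-wise ratios to the per-probe median reference equals 1. Because the
reference moves when samples are rescaled, the scheme is **iterated to a
fixed point** (tolerance 1e-13 on the per-sample factors, with
geometric-series extrapolation of the factor sequence for speed), and the
global scale is **anchored so the median cumulative per-sample correction is
1**. Consequences: the operation is idempotent to machine precision, and
rescaling any minority of samples by arbitrary positive constants is removed
exactly (a doubled sample gets factor 0.5 and the output equals the
original). Vendor-side hybridization/plate calibration is assumed already
applied to real inputs; this step exists for synthetic data and
re-normalization.

## Differential abundance

Per-probe Welch two-sample *t* on log2 RFU; with covariates, a per-probe OLS
model `log2RFU ~ group + covariates` with the group coefficient tested
(shared design matrix, vectorized across probes). Constant probes get p = 1
with a flag rather than being dropped, so downstream probe universes stay
stable. BH adjustment is applied within each named comparison. Two
calibration facts worth knowing:

- under the global null, BH yields at least one rejection with probability
  exactly α (Simes), so a "0 significant" outcome recurs in ~95 % of null
  cohorts at α = 0.05, not always;
- adding *c* pure-noise covariates perturbs each t statistic by ~√(c/df), so
  adjusted and unadjusted p-value ranks correlate at ≈0.93 (not 1) at
  n = 80 with two covariates.

Storage-time and confounder scans use Spearman rank correlation for
continuous covariates (robust to monotone drift of unknown shape) and
Welch's *t* for binary ones, with counts at unadjusted p ≤ α and one-sided
hypergeometric over-representation of the associated probes within a
selected set.

## Endotype discovery

Probes are z-scored before PCA and k-means so each contributes on a common
scale. K-means is Euclidean over all probes, best of `n_restarts` (default
25) by within-cluster sum of squares; when *k* is not fixed it is chosen
from 2..8 by maximal mean silhouette. Cluster labels are deterministic:
relabeled 1..k by decreasing size, ties broken by lowest member index.
Signatures are the union over all cluster pairs of probes at BH q ≤ 0.05
(Welch per probe, BH within each pair); singleton clusters are skipped with
a warning. Blocks come from average-linkage hierarchical clustering of the
signature probes on (1 − Pearson r) distance over z-scored profiles, cut at
a configured count or by silhouette.

High-dimensional k-means needs enough co-varying signal: with 1233 probes
and ~15 subjects per cluster, per-cluster blocks of ~118 probes shifted by
1 residual SD are recovered essentially perfectly (ARI ≥ 0.9) at 50
restarts, while 40-probe blocks are not — restart count matters because the
failures are local minima, not lack of signal.

## Set enrichment

**Directional NES.** Probes ranked by the signed statistic; running sum
increments by |s|^w (normalized over in-set probes, default w = 1) at hits
and decrements uniformly at misses; ES is the signed extremum. The null
permutes probe-set *membership*: R random sets of identical size (default
R = 1000, seed mandatory). NES = ES / mean(|null ES| of matching sign);
p = (1 + #{matching-sign null with |ES'| ≥ |ES|}) / (R + 1). At w = 0 the
statistic is purely rank-based and small cases are exactly enumerable.

**EMD ratio.** The non-directional score is the 1-D Wasserstein-1 distance
between in-set and out-of-set statistic values, normalized as
observed / mean(random-set null), with p = (1 + #{null ≥ obs}) / (R + 1).
The *mean* null ratio is calibrated at 1 (±0.15 over 500 null draws); a
single draw has the full sampling CV of the EMD statistic, so per-draw
ratios legitimately scatter well beyond ±15 %.

Enrichment networks connect sets with p ≤ 0.001 whose shared members exceed
50 % of the *smaller* set (the caption convention "…>50 % of genes in
common" names no denominator; min is the configurable choice here);
clusters are connected components labelled by their lowest-p member.

## Origin and trait association

The tissue atlas is z-scored within each tissue across genes, which removes
any affine rescaling of a tissue's raw expression. Per tissue, group genes
are compared to background genes by a one-sided Mann–Whitney test (the
threshold, not the test, is fixed by convention; a rank test was chosen as
the robust default), BH across tissues. Trait association is per-probe
simple linear regression of the trait on log2 abundance (r, slope, two-sided
p; r is symmetric in the two variables). Group-wise |r| distributions are
compared by one-sided Mann–Whitney dominance tests.

## Clinical statistics

Two-sample *t* works identically from raw values or printed (n, mean, SD)
summaries; the pooled variant is the default because the cohort tables it
mirrors use Student's *t*. Fisher's exact test uses the common two-sided
convention (sum of fixed-margin tables with probability ≤ observed).
Mann–Whitney is exact for groups of ≤ 20 and a tie-corrected normal
approximation (no continuity correction, so the two-group Kruskal–Wallis
agrees to 1e-6) otherwise. Survival uses Kaplan–Meier product-limit
estimates and the standard event-time-aggregated log-rank test (via
lifelines). **Annual change** is the per-subject OLS slope of a visit
variable on time — a deliberate simplification of a linear mixed-effects
model that is unbiased for balanced visit schedules; the recovery tests
bound the cost (mean slope bias < 0.0003 at visit noise SD 0.05 over years
0–5).

## The synthetic world

The generator emits log2 RFU as
`mu_p + sd·(delta_p·disease + shift_pb·endotype + beta_pc·z(covariate) +
lambda_p·f + gamma_p·storage/1000) + eps`, `eps ~ N(0, sd)`, with **every
effect in units of the residual SD** so two-sample power has the closed
noncentral-t form, then exponentiates and applies per-sample lognormal scale
factors (SD 0.1) for the normalizer to remove. The latent factor `f` is one
standard normal scalar per subject shared by the exosome-marker block, which
reproduces the empirical signature that exosomal probes correlate with each
other far above background.

Defaults mirror the motivating cohort: 1233 probes; 34 + 51 subjects with
endotype sizes (10, 19, 5) and (21, 19, 7, 4); 365 disease-shifted probes at
1 SD with random sign; asthma signature blocks A–F of 74/31/31/31/31/32
probes with ±1 SD per-endotype patterns; COPD blocks G (118 probes, gradient
+1/0/−1 across endotypes) and H (3 probes, −1/0/+1.5); 33 exosome markers =
30 probes of block A plus the 3 of block H; covariate-linked probe counts
3/5/7 (age/BMI/sex, 0.5 SD per covariate SD); no storage drift (observed
storage correlations in the motivating data behaved like type-I noise, so
the default world omits them; a drift term is available). Clinical
covariates are drawn from the published per-disease summary distributions
(age, sex ratio, BMI, pack-years, lung function, eosinophils, storage-day
ranges). Longitudinal Kco uses per-endotype annual slopes (COPD
−0.08/−0.08/−0.005 units/year from the cohort table; asthma slopes, not
reported there, default to small declines) with visit noise SD 0.05 at years
0–5; exacerbation times are exponential with per-endotype rates (COPD
0.10/0.05/0.40 events/year around the reported medians; asthma
0.15/0.35/0.15/0.25 chosen once so that the second endotype has the poorer
exacerbation-free course). Residual SD defaults to 0.5 on the log2 scale, a
typical within-group spread for plasma affinity proteomics.

What the simulated world does **not** contain: the real cohort's full
probe–probe covariance (only block and latent-factor structure), absolute
RFU ranges, plate/batch structure, missingness, or informative censoring.
A green recovery test therefore establishes that the pipeline finds the kind
of structure it models, at the stated effect sizes — not that it would
reproduce any particular real-data probe count, which also depends on
unstated choices (the exact per-probe test and the clustering scale) in the
motivating analysis.

## Numerical conventions

- Permutation p-values use the +1-corrected estimator and live on
  {1/(R+1), …, 1}; enumerated (exhaustive) nulls use the exact tail
  fraction with no correction.
- Spearman/linear-association p-values use the t approximation; exact-fit
  p-values are floored at the smallest positive float to keep p ∈ (0, 1].
- Zero-overlap hypergeometric results report log2 fold = −inf and p = 1.
- k-means ties and cluster numbering are made deterministic by size-then-
  first-member relabeling; all stochastic stages require a seed and the
  pipeline is byte-reproducible for a fixed (inputs, config, seed).
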