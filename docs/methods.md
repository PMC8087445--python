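# Methods

## The model

`methclock` implements a DNA-methylation "epigenetic clock" analysis for
reduced-representation bisulfite sequencing (RRBS) data from a wild primate
population with known chronological ages. The clock is a penalized linear
model

    age_i = b0 + Σ_s w_s · x_si + e_i

where `x_si` is the normalized methylation score of CpG site `s` in sample
`i` and the weights `w` are fit with an elastic-net penalty
`λ (α‖w‖₁ + (1−α)/2 ‖w‖₂²)` (glmnet parameterization: `α ∈ [0,1]` mixes
ridge into lasso). λ is chosen on a log-spaced path by minimizing mean
squared error in seeded internal cross-validation, stratified by age tertile
to stabilize the selection at modest n; α is chosen by grid search over
{0, 0.1, …, 1.0}, maximizing the squared correlation between leave-one-out
predictions and chronological age, with ties broken toward the smaller
(denser, more stable) α. Sites with nonzero weights are the "clock sites".

Downstream statistics derive from the predictions: Δ_age = predicted −
chronological age; relative epigenetic age = residual of the best-fit line
of predicted on chronological age, fit within the analysis group in use
(e.g. males only), so it is mean-zero within that group.

## Leakage-free normalization

Raw inputs are methylation ratios (methylated / effective total counts).
Normalization is two-stage: (1) each sample's ratios are quantile-normalized
across its own sites to a standard normal; (2) each site is
quantile-normalized across the *training* samples. The quantile convention
is the plotting position Φ⁻¹((i − 0.5)/n); ties receive the mean of the
scores of their tied ranks (so a constant vector maps to all zeros, and
degenerate sites are flagged rather than erroring).

A held-out sample never contributes to training statistics. It is stage-1
normalized on its own, and each site's value is passed through the training
samples' empirical CDF (right-continuous; ties count as ≤) and mapped to the
matching standard-normal quantile. The ECDF quantile is clamped to
[1/(n+1), n/(n+1)] so projected scores are always finite. Because stage 1 is
rank-based, projection is invariant to any strictly monotone transformation
of the held-out sample's raw ratios.

One consequence of stage 1 worth noting: it discretizes each sample to the
same n_sites score values, so two samples can hold identical stage-1 values
at a site. Stage 2 then averages the tied ranks' scores, meaning a site's
training scores are a permutation of the target quantile vector only where
no such collision occurs. The test suite checks the permutation property on
tie-free columns and the tie rule explicitly elsewhere.

Leave-one-out prediction refits *everything* per fold — both normalization
stages, the λ path, and the elastic net — on the training samples only. The
suite verifies, exhaustively on a 12-sample toy, that perturbing a held-out
sample's ratios changes neither the fold's fitted model nor any other
sample's projection. Predictors are variance-~1 by construction after stage
2, so no further internal standardization is applied in the solver.

## Preprocessing

Sites are retained when (1) mean methylation ratio over observed entries is
strictly between 0.1 and 0.9, (2) mean effective coverage is ≥ 5× (computed
from effective total counts, mean over observed entries), and (3) the
fraction of samples missing the site is < 5%. Missingness is counted per
sample (repeat samples of an individual are not collapsed). The ratio-bound
exclusivity is a choice: the bounds exclude exactly-0.1/0.9 sites, which are
measure-zero for real data.

Remaining missing entries are imputed by k-nearest neighbours between sites
(default k = 10): distances are root-mean-square differences over
pairwise-complete samples; a missing entry takes the mean ratio, at that
sample, of the k nearest sites observed there, falling back to the site's
own observed mean if no neighbour is observed at that sample (effectively
impossible after the < 5% missingness filter). Imputation runs once on the
full matrix before leave-one-out prediction; fold-level leakage control
applies to normalization and model fitting, which are refit per fold.

## Covariates

- **Age-adjusted BMI**: residuals of a continuous two-segment ("hinge")
  regression of BMI (mass in kg / crown-rump length in m, squared) on age,
  fit per sex. The breakpoint is profiled over a 0.1-year grid spanning the
  data range and chosen by least squares, with exact ties broken toward the
  sex-specific anchor (8 years for males, 10 for females — the expected peak
  ages). The grid profile is deterministic and directly checkable against a
  brute-force oracle, which is why it is used instead of iterative local
  refinement.
- **Rank-for-age**: residuals of ordinal dominance rank (1 = alpha) on age
  and age²; captures being higher- or lower-ranked than expected for one's
  age. Constant rank gives all-zero residuals rather than an error.
- **Cumulative early adversity**: count (0–5) of binary conditions —
  first-year rainfall ≤ 200 mm, maternal rank in the dataset's lowest
  quartile, a younger sibling within 1.5 years, birth-group size in the top
  quartile (quantifying "large group" by the same quartile rule as maternal
  rank, since no absolute threshold is established), and maternal death
  before age 4. Records with an unresolvable indicator are flagged missing
  and drop out of complete-case models.
- **DSI_F (female social bond strength)**: per dyad-year, the grooming rate
  R = grooming count / coresidence days is regressed (log-log, OLS) on
  observer effort E; residuals are z-scored globally across dyad-years, and
  DSI_F for a focal female is the mean residual of her top-3 partners among
  dyad-years overlapping the 365 days before sampling. Observer effort
  defaults to E = s / (c·f) — focal samples per coresident-day per group
  female — encoding that smaller groups receive more observation per dyad;
  the combination of (c, s, f) is configurable (`effort_mode`). Dyad-years
  with zero grooming are excluded from the log-log fit. A zero-variance
  residual vector z-scores to 0 so degenerate inputs stay well-defined.
- **Comparison clocks**: leave-one-out linear models of age on molar percent
  dentine exposure (M1+M2+M3), on blood cell-type proportions (one redundant
  category dropped when proportions sum to 1), or on BMI via the sex-specific
  hinge model inverted by nearest fitted value.

## Association models

Δ_age is modeled per sex by OLS on dominance rank at sampling, cumulative
early adversity, age-adjusted BMI, and chronological age (whose inclusion
controls for the clock's compression of young/old predictions); the female
model adds DSI_F. Complete cases only; the reported n is auditable against
the input. Inference uses standard OLS t-statistics. Ordinal rank enters as
a numeric covariate (proportional rank can be substituted). Mutual
adjustment variants (rank adjusted for raw BMI and vice versa) use
residual-on-residual regression, which the tests check against the joint
model via the Frisch–Waugh property.

Longitudinal analyses use repeat-sampled males: a paired t-test of relative
epigenetic age at the higher- vs lower-rank sample of each male, and an OLS
of within-male change in Δ_age on change in rank controlling for
chronological age. For males with three samples the two farthest apart in
time are used unless a required covariate is missing, in which case the
earliest complete pair substitutes. Constant-difference inputs to the paired
test are flagged degenerate (t = 0, p = 1 for all-zero differences; infinite
t otherwise) instead of propagating NaNs.

The longitudinal ordering statistic is an exact two-sided binomial test at
null 0.5 that later-collected samples are predicted older, computed by
symmetric tail doubling capped at 1 (26/30 gives p = 5.95×10⁻⁵); the
min-likelihood convention is available behind a flag, and ties count as
failures (conservative).

## Enrichment

Clock sites are tested against the complement of the background candidate
set for membership in annotation interval sets (gene bodies, exons, CpG
islands, shores, promoters, plus any user-supplied BED tracks) by two-sided
Fisher's exact tests on point-overlap 2×2 tables. Shores are the 2,000 bp
flanking each CpG island, excluding island interiors; promoters are the
2,000 bp upstream of each gene's 5'-most TSS, strand-aware, truncated at
contig start; derived intervals are merged within a source and no
promoter/gene-body exclusion is applied. Site labels carry 1-based
positions; conversion to 0-based half-open coordinates is centralized. The
odds ratio is the sample cross-product ratio, with Haldane's 0.5 correction
applied (and flagged) only when a table cell is zero; the exact p is never
corrected. Requiring the clock set to be a *proper* subset of the background
keeps the 2×2 rows disjoint.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the sequencing process. Defaults define the package's reference conditions:

| parameter | default | meaning |
|---|---|---|
| n_individuals | 150 | individuals; ~10% resampled longitudinally |
| n_sites / n_age_sites | 4000 / 300 | candidate CpGs / age-associated CpGs |
| age_effect_scale | 0.05 | logit-units of methylation drift per year |
| noise_sd | 0.3 | residual logit s.d. per site-sample |
| old_female_extra_sd | 0.3 | added residual s.d., females > 10 yr |
| rank_acceleration | 0.1 | apparent years per rank step, adult males |
| mean_coverage | 30 | negative-binomial mean reads (dispersion 5) |
| missing_rate | 0.014 | masked entries (≈ the observed RRBS missingness) |
| n_batches | 2 | additive logit shifts at 10% of sites |

Ages mix uniform(0, 8) and uniform(8, 25) half-and-half to populate the
juvenile and adult regimes. Sexes are balanced. Male expected rank follows a
parabola with its best (smallest) values at ages 7–12; female ranks are
stable within individuals (nepotistic inheritance). Adult males (≥ 8 years)
carry a latent biological age of chronological age +
rank_acceleration × (max_rank − rank), so the alpha position accrues the
largest acceleration; this latent age, together with per-site baselines and
slopes, is recorded exactly as sampled for parameter-recovery tests.
Methylation probabilities are inverse-logit linear in biological age with
per-entry Gaussian noise (inflated for older females), observed through
binomial counts at negative-binomial coverage; coverage-zero entries and a
random `missing_rate` fraction are masked. BMI is a continuous two-segment
function of age (breakpoints 8/10 by sex) plus a rank term and noise.
Longitudinal male ranks take a bounded random-walk step so both rises and
falls occur. Grooming records are dyad-year Poisson counts with rate
proportional to a latent dyadic affinity times observer effort.

What the generator does *not* emulate: read-level chemistry (bisulfite
conversion, trimming, mapping), genetic ancestry effects on methylation
calls, spatial correlation between neighbouring CpGs, non-linear age
trajectories, and group structure/migration in the behavioral records.
Passing recovery tests therefore demonstrates correctness of the estimators
under the generative assumptions, not performance on real RRBS data.

## Problem sizes and numerical choices

The reference recovery runs use 150 individuals × 4,000 sites (clock
accuracy) and 120 × 1,200 (rank-effect recovery), with α = 0.1, five
internal CV folds and a 20-value λ path (λ_min/λ_max = 0.01): on these
problem sizes the selected λ is identical to the denser default settings
(10 folds, 30 values), and a full leave-one-out pass runs in minutes on one
core. Elastic-net fits use coordinate descent with tol 1e-3 and the λ path
supplied explicitly (anchored at the data-driven λ_max; the ridge end of the
α grid anchors the path at a small mixing weight, as glmnet does).

Expected behavior on the reference run: leave-one-out Pearson r ≈ 0.99,
MAD well under a year, and a predicted~chronological slope below 1 — the
regression-to-the-mean compression that motivates including chronological
age in the Δ_age models. The injected male rank coefficient is recovered
with the correct (negative) sign and a 95% CI covering the oracle value
computed from latent biological age; under a null injection the CI covers
zero.

## Known limitations

- The ECDF projection is step-wise; with few training samples, projected
  scores are coarse near the tails (mitigated by clamping).
- `filter_sites` mean-coverage uses observed entries only, so heavily
  missing sites are judged on their observed coverage (they are mostly
  removed by the missingness rule anyway).
- The DSI window is resolved at calendar-year granularity (dyad-year records
  overlapping the 365-day look-back), not exact days, and z-scoring is
  global across dyad-years rather than within-year.
- `predict` with a serialized clock applies the model to already-normalized
  scores; cross-platform portability of a trained clock is out of scope.
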