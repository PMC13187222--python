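# Methods

`scalenet` implements a measure-development-and-validation pipeline for
two-group questionnaire data: network-based item reduction, exploratory
factor analysis (EFA) for ordinal ratings, ordinal confirmatory factor
analysis (CFA) with cross-group measurement invariance testing, and
ROC-based discriminative validation. This note documents the models, the
estimation choices, and what the synthetic-data experiments do and do not
show.

## Data-generating model (synthetic module)

Responses are simulated from a graded factor model. For participant j and
item i,

    y*_ij = lambda_i' f_j + delta_i * 1[case_j] + e_ij,

with correlated standard-normal factors f ~ N(0, Phi), independent normal
residuals scaled so Var(y*) = 1 in the comparison group, and six ordered
thresholds tau_i1 < ... < tau_i6 cutting y* into the observed categories
1..7. Reverse-coded items are emitted as 8 - x. This is exactly the latent
family assumed by polychoric correlations and weighted-least-squares
ordinal factor analysis, so parameter-recovery experiments have a
well-defined ground truth.

Choices and defaults:

* **Thresholds** default to six equally spaced cuts, symmetric about zero,
  spanning ±2.5 latent SD. Real questionnaire items have irregular,
  item-specific thresholds; the symmetric default is a neutral placeholder
  and fully configurable. No published item-level thresholds were
  available to calibrate against.
* **Group differences** act on the latent item means only, i.e. the
  generator is scalar-invariant by construction unless explicit
  non-invariance perturbations (loading or threshold deltas for the case
  group) are supplied. Passing a zero perturbation reproduces the
  invariant output bit-for-bit.
* **Effect-size calibration.** The observed-scale standardized mean
  difference implied by a latent shift has a closed form obtained by
  integrating the category probabilities of the thresholded normal;
  `induce_d_profile` inverts it per item by root bracketing (tolerance
  1e-3 on d). Targets beyond the saturation ceiling (everyone at category
  7) raise an error naming the item.
* **Study-shaped fixtures** emulate the published design: 65 items on
  7-point scales, two correlated factors (r = 0.58), per-item
  discriminations spanning d = 0.80–2.44, matched groups of 196/196
  (online sample) or 30/30 (laboratory sample), and reverse-coded items
  6, 13, 21, 55. The invariance fixtures use the published 12+6 item
  two-factor structure at n = 500 per group.

What the generator does **not** emulate: item nonresponse, response styles
(acquiescence, straightlining), floor/ceiling asymmetries beyond what the
thresholds encode, and non-normal latent traits. Passing tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to real-data pathologies.

## Item reduction (network module)

Items whose pairwise Pearson correlation exceeds 0.70 (strict inequality)
form a weighted graph; items below threshold stay in the candidate pool as
"isolated" items. Communities are found by the walktrap algorithm (via
python-igraph): random-walk distances drive an agglomerative merge, and
the maximum weighted-modularity cut of the dendrogram is returned. Because
walks longer than the mixing time wash out structure on small dense
graphs, merge paths for every walk length from 1 up to the configured
ceiling (default 4) are scanned and the best-modularity partition kept.
Degree and per-component max-normalized eigenvector centralities describe
hubness. Four selection strategies are
combined by union: the best discriminator per community (communities of
size ≥ 2), the top-5 isolated discriminators, the top-8 eigenvector hubs,
and the top-10 discriminators overall. Defaults were sized so the default
65-item synthetic fixture yields an 18-item selection; they are
configuration, not a claim about how any published instrument was derived.
Ties break by higher d, then lexicographic item id, making the selection
invariant to item order.

The correlation coefficient feeding the network is configurable in
principle (Pearson on raw scores is the default); all item-level analyses
operate on recoded scores (reverse-coded items flipped) so every item
discriminates in the same direction.

## EFA (efa module)

* **Factorability**: Kaiser-Meyer-Olkin index from anti-image partial
  correlations (the degenerate identity-matrix case is defined as 0), and
  Bartlett's sphericity test.
* **Factor count**: parallel analysis on principal-axis eigenvalues
  (squared multiple correlations on the diagonal), reference curve = 95th
  percentile of 1,000 column-permutation resamples by default. Permuting
  columns preserves the ordinal marginals exactly, which is why it is
  preferred over normal-deviate resampling here.
* **Extraction**: principal axis factoring, communalities iterated to
  max |change| < 1e-6 (at most 1,000 iterations); Heywood communalities
  are clipped at 1 with a warning.
* **Rotation**: direct oblimin (quartimin, gamma = 0) by gradient
  projection with 10 starts (identity + 9 random orthonormal); the
  model-implied matrix Lambda Phi Lambda' is preserved identically by
  construction of oblique rotation.
* **Fit**: chi-square from the ML discrepancy of the factor model to the
  sample correlation matrix with the Bartlett correction factor
  (n - 1 - (2p+5)/6 - 2k/3); TLI against the independence baseline; RMSEA
  with a 90% CI by inverting the noncentral chi-square. These indices
  reproduce the *style* of standard EFA software without claiming its
  exact internals.
* **Scores**: Thurstone regression scores; score reliability is the
  multiple R² of each factor on the items, with its square root reported
  as the expected correlation with the factor. Note that regression
  scores of correlated factors over-correlate slightly relative to the
  latent factor correlation; this is a property of the estimator, not a
  bug.

## Ordinal CFA and measurement invariance (cfa module)

Polychoric correlations use the classic two-step estimator: thresholds
from marginal proportions via the normal quantile, then the correlation
maximizing the contingency-table likelihood (bounded scalar optimization,
estimates clipped at ±0.999 with a warning at the boundary). Bivariate
normal rectangle probabilities are computed by 32-node Gauss-Legendre
quadrature of the single-integral identity for the bivariate CDF, accurate
to ~1e-9 over the useful correlation range.

Models are estimated by **diagonally weighted least squares (DWLS)**: the
weighted squared distance between sample and model-implied polychoric
correlations, with weights equal to the estimated asymptotic variance of
each two-step estimate. The variance is the influence-function (sandwich)
form that propagates threshold-estimation noise — verified by calibration
against empirical sampling variance (ratio 0.96–1.02 across rho = 0.3–0.7
at n = 500). The chi-square is the minimized weighted discrepancy without
the mean-and-variance robust adjustment of full WLSMV; every report is
flagged accordingly. CFI/TLI are computed against the zero-correlation
baseline, RMSEA from the excess chi-square, SRMR from the raw residual
correlations. TLI is capped at 1. McDonald's omega per factor is
(sum lambda)² / ((sum lambda)² + sum theta + 2 sum error-covariances).

Identification fixes factor variances to 1 (standardized loadings), in
every group and at every invariance level. The sequence is:

* **configural** — same factor pattern, all parameters free per group;
* **metric** — loadings equal across groups. Because factor variances
  stay fixed at 1 in both groups, this tests equality of *standardized*
  loadings; the common alternative (free group-2 factor variances, as
  lavaan does) tests a weaker hypothesis and, in our Monte Carlo, has
  materially lower power against the planted loading violation;
* **scalar** — additionally, ordinal thresholds (the ordinal analog of
  intercepts) are constrained equal, with group-2 factor means freed.
  Shared thresholds enter the weighted objective linearly and are profiled
  out in closed form. Residual variances are implied (1 - communality)
  throughout.

Degrees of freedom strictly increase and chi-square weakly increases
across levels (nested constraints under a fixed weight matrix). Decisions
follow the conventional change-in-fit rule: a level passes when the CFI
drop from the previous level is at most 0.01; the RMSEA change (threshold
0.015) and the chi-square difference test are reported alongside but do
not drive the decision, mirroring common practice where the CFI rule
dominates. Modification indices are not computed; error covariances enter
the model only as given options in the model specification.

Thresholds whose cumulative proportion is 0 or 1 in either group (empty
extreme categories) are dropped from the moment vector in both groups so
the levels stay comparable.

## Classification (classify module)

AUC is the tie-corrected Mann-Whitney rank statistic; the threshold grid
sits at midpoints between adjacent distinct scores (hence half-integer
cutoffs for integer sum scores) plus sentinels; prediction is
"case iff score > t" with the direction auto-detected from group means
(overridable). The Youden-optimal point maximizes sensitivity +
specificity - 1, with ties broken toward balanced sensitivity/specificity
and then the lower threshold.

## Statistics (stats module)

Cohen's d uses the pooled-SD denominator so effect sizes recomputed from
published group means/SDs/ns match printed values; the two-group test is
Welch's t with Satterthwaite df; Cronbach's alpha uses sample (n-1)
variances; robust regression inference uses HC3 sandwich standard errors
(via statsmodels, with leverages computed directly and an explicit error
when any leverage reaches 1).

## Problem sizes used in tests and the acceptance script

Monte-Carlo experiments use the fixture sizes stated above (n = 500 per
group for invariance and CFA recovery, 100 seeds for the detection-rate
experiments; 196/196 and 30/30 for the study-shaped fixtures; up to
20,000 per group for the effect-size round trips, where only two items
are simulated). These sizes were chosen to keep each experiment's
Monte-Carlo error far below the margins being asserted.

## Known limitations

* The DWLS chi-square is unadjusted: it is under-dispersed relative to
  its degrees of freedom, and absolute fit indices from it are not
  comparable to WLSMV-scaled values published elsewhere. Relative
  (delta) comparisons across nested invariance levels are the supported
  use.
* Polychoric estimation assumes the latent bivariate normal family; the
  generator satisfies it, real data may not.
* The EFA chi-square treats the Pearson correlation matrix of ordinal
  ratings as if continuous, as classical EFA software does; polychoric
  input is available via configuration.
* Walktrap is a heuristic; on small graphs it is verified to land within
  0.05 modularity of the exhaustive optimum, not to equal it.
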