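# Methods

## The index and its classification

The SCPI is a weighted sum of six non-exclusive checkbox endorsements. The
default weights (+2, +1, +2 for the positively worded options 1a/1b/1c;
−1, −2, −2 for the negatively worded 2a/2b/2c) make the positive weights sum
to +5 and the negative ones to −5, so every integer in [−5, +5] is
attainable (verified by exhaustive enumeration of the 64 patterns).
Classification uses fixed cut-points — low ≤ 0 < moderate ≤ 3 < high — not
data-driven tertiles; the three groups are therefore unequal in general.
Patterns endorsing nothing are valid (score 0, low) but flagged, as are rows
with missing answers, which keep their place in the output with a null score
and are excluded from all statistics (complete-case analysis). Contradictory
endorsements (e.g. 1c together with 2c) are deliberately permitted: the
option set is designed to let respondents express ambivalence.

## Generative model for synthetic cohorts

Item endorsements follow a latent threshold (probit) model: three standard
normal factors **F** with correlation matrix Φ (unit diagonal, all
off-diagonals 0.3 by default — a conventional moderate value; the analysis
stage estimates its own Φ̂, so this is a simulation input, not an estimate),
item loadings λ = (0.71, 0.89, 0.79, 0.96, 0.88, 0.90) with factor
membership {1b, 1c} → capability/activation, {2b, 2c} → depleted inner
resources, {1a, 2a} → health literacy / information need, and per-item signs
+1 for positively and −1 for negatively worded items. Item *i* is endorsed
when

    s_i λ_i F_f(i) + sqrt(1 − λ_i²) ε_i  >  τ_i ,   ε_i ~ N(0, 1) iid.

This is exactly the data-generating process under which tetrachoric and
polychoric correlations are defined, so the assumptions of the downstream
factor analysis hold by construction, and the latent correlation of two
same-factor items is the product of their signed loadings (used as a
closed-form check in the tests). The sign convention orients all three
factors towards good preparedness; within the literacy factor the two items
therefore load with opposite signs, which reproduces the observed pattern
that knowledge-rich respondents rarely also ask for more information.

### Threshold calibration

Published cohort summaries pin down the score distribution (level shares
27.0/39.2/33.8 %, mean 2.22, SD 2.31) but not the per-item endorsement
rates, so the six thresholds τ are free parameters fitted by simulation:
one set of latent draws (n = 100 000 by default) is held fixed — common
random numbers — while Nelder–Mead (restarted until no further improvement)
minimises the sum of squared discrepancies, each standardised by its
tolerance (±1.5 points on shares, ±0.05 on mean and SD). Two design points:

* A soft penalty keeps each τ inside ±1.645 (endorsement rates ≈ 5–95 %).
  The targets leave the rates heavily under-determined and the unpenalised
  optimiser parks one item at a ~99 % rate, which empties 2×2 cells and
  makes that item's tetrachoric correlations (hence the EFA) needlessly
  noisy. The penalty costs a small centred bias — the converged solution
  sits at shares ≈ 26.3/39.5/34.2 % and mean ≈ 2.20, inside every
  tolerance — which we accept as the price of keeping all six items
  informative.
* Calibration draws are larger (100 000) than the verification cohorts
  (50 000) because a derivative-free optimiser will exploit the noise of a
  fixed simulation draw; the larger draw suppresses that over-fitting, and
  every calibration claim in the tests is then checked *out of sample* on a
  fresh seed.

### Outcome links

Outcomes never see the score directly. A single latent propensity — the
score-weighted combination of the factors, standardised — enters a Gaussian
copula: for link coefficient β the outcome's normal score is
βη + sqrt(1 − β²)z, mapped through the outcome's marginal quantile function.
Because the map is monotone, β controls the Spearman correlation with the
SCPI, which is found by bisection (tolerance 0.005) against the target; the
correlation with the discrete six-item sum then *emerges* through the items,
preserving the attenuation a real cohort would show. Targets for the three
headline outcomes are the published correlations (0.31 HRQoL, −0.27 BDI,
0.24 PAM); the remaining outcomes get modest defaults matching the published
gradient directions (they have no printed correlations). Marginals: 15D ~
logit-normal moment-matched to mean 0.865, SD 0.097 (support (0, 1)); BDI ~
gamma (6.3, 5.2); PAM, BMI, waist, physical activity, LDL, education, age ~
clipped normals at the published pooled moments; binary self-ratings ~
thresholded copula normal at the published prevalences. An optional
`sex_effect` shifts the item propensities by sex (men up, women down, off by
default) for experiments that need the published sex difference in means.

### What the generator does and does not emulate

It reproduces: the score distribution summaries, the planted three-factor
binary item structure, the headline rank correlations, monotone per-level
outcome gradients, and outcome marginals of realistic shape and support. It
does **not** model: longitudinal change or intervention effects, missing
data (complete questionnaires only), item-level response styles,
sex-specific waist distributions, or the joint correlation structure among
the *outcomes* beyond what the shared propensity induces. Passing tests on
synthetic cohorts therefore validate the machinery and its statistical
calibration, not any clinical claim about real patients.

## Analysis stages

**Trend tests.** Binary outcomes: Cochran–Armitage z with ordinal group
scores (results invariant to affine score changes; default (−1, 0, +1)),
two-sided normal p. Continuous outcomes: one-way ANOVA linear contrast t
with pooled within-group MSE on N − k df. Degenerate inputs (all events, a
single non-empty level, zero variance everywhere) are flagged, not raised,
with p = 1. Both tests are verified against independent oracles (exact
conditional enumeration over the hypergeometric table distribution; an OLS
cell-means contrast test) and their null rejection rate is simulated at
10 000 replicates.

**Correlations.** Spearman's rho on mid-ranks (ties averaged), Fisher-z
interval with SE 1/√(n−3). The plain 95 % interval reproduces the published
headline intervals at n = 293; Sidak handling — adjusted p = 1 − (1−p)^m and
per-comparison CI level (1−α)^(1/m) — applies only when a family of m > 1
comparisons is declared in the configuration (as for a battery of HRQoL
dimensions), since the published headline intervals are consistent with
unadjusted 95 % computation. Two-sided p-values throughout.

**Polychoric EFA.** Binary items make the polychoric matrix tetrachoric:
thresholds from marginal probits, then ρ̂ maximising the 2×2
bivariate-normal likelihood (bounded scalar optimisation, |ρ̂| capped at
0.999). The bivariate normal CDF uses the arcsin-substitution integral
evaluated with fixed 64-point Gauss–Legendre quadrature — deterministic to
~1e−14, no randomised integration. Zero cells push the MLE to the boundary:
the estimate is reported at the signed cap and flagged; an optional
continuity correction (+0.5 per cell) is off by default. Extraction:
iterated principal factoring from squared-multiple-correlation starts,
convergence when communalities move < 1e−6 (max 1000 iterations), Heywood
communalities clipped at 1 with a warning. Retention: Kaiser's rule applied
to the eigenvalues of the polychoric matrix itself (strict > 1), with a
scree table for Cattell's visual check. Rotation: varimax (Kaiser row
normalisation, SVD algorithm) followed by promax with power 4, column signs
fixed so each factor's dominant loading is positive and columns ordered by
explained variance; the solution matches R's `stats::promax` within 1e−4 on
a frozen fixture. Variance explained is reported under three conventions
(Σh²/p, retained-eigenvalue share, structure-SS share) because no single
convention is canonical for a rotated polychoric solution.

## Numerical choices

* All randomness flows from `numpy.random.default_rng` seeds;
  (profile, n, seed) determines a cohort byte-for-byte, and the pipeline
  splits calibration and generation streams from one master seed via
  `SeedSequence`.
* Eigen-decompositions fix the sign of each eigenvector at its
  largest-magnitude element, so factor solutions are deterministic.
* Verification cohorts in tests and the acceptance script use n = 50 000 —
  large enough that Monte-Carlo noise (≈ 0.01 on a mean score, ≈ 0.005 on a
  Spearman r) is well inside every stated tolerance, small enough that the
  whole suite runs in a couple of minutes.

## Known limitations

* **Identifiability at the Ledermann bound.** Six items with three factors
  sit exactly at the Ledermann bound, where uniquenesses are not uniquely
  determined. Iterated principal factoring applied to the *exact*
  model-implied matrix converges to a different exact rank-3 solution that
  equalises the literacy factor's (0.71, 0.96) loading pair to ≈ (0.81,
  0.85); the other four loadings are recovered within ±0.03. Consequently,
  per-item loading recovery for the two literacy items is not achievable by
  this (or any) estimator from the correlation matrix alone, and the unique
  direction also carries high sampling variance at finite n. The robust,
  tested consequences are: three factors retained, tetrachoric consistency,
  within-factor loading *products*, and the four capability/resources
  loadings.
* Two-indicator factors also make Heywood cases common at study-sized n;
  they are clipped and warned about rather than treated as errors.
* The Fisher-z interval at n = 293 for r = 0.24 is (0.13, 0.35); an interval
  of (0.12, 0.34) arises from the same computation at the unrounded
  r ≈ 0.235. The package computes from whatever r it is given and does not
  attempt to reverse-engineer unrounded inputs.
* The exact conditional trend-test distribution is discrete; the normal
  reference approximates its mid-p, and the tests assert closeness in that
  sense at moderate table sizes rather than pointwise equality.
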