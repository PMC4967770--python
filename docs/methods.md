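# Methods

## Measurement model

All items are modelled with Samejima's graded response model under a
logistic link.  For item *j* with categories 0..C_j−1 and latent vector
θ ∈ R^K,

    P(Y_j ≥ c | θ) = σ(Σ_k a_jk θ_k − b_jc),   c = 1..C_j−1,
    P(Y_j = c | θ) = P(Y_j ≥ c | θ) − P(Y_j ≥ c+1 | θ),

with b_j strictly increasing.  Factors are standard normal and mutually
orthogonal during estimation (identification: factor means 0, variances 1,
slopes free).  A per-factor variance is carried in `GRMParameters` and
folded into *effective slopes* a·√σ², so the free-variance cross-validation
variant reuses the same standard-normal quadrature machinery.

Standardized loadings are reported on the correlation metric via the usual
logistic/normal-ogive bridge with D = 1.7:

    λ_jk = (a_jk/D) / sqrt(1 + Σ_k (a_jk/D)²).

This is an approximation to a probit-metric fit, adopted because the
quantities of interest downstream (salience at |λ| ≥ 0.40, omegas) are
conventionally read on the correlation scale.  Exact equality with a
probit-ML fit is not claimed; no probit estimation path is provided.

## Estimation

Marginal maximum likelihood by Bock–Aitkin EM:

- **E-step.** Person posteriors over a Gauss–Hermite grid; expected
  response counts r_j[c, node] accumulated per item ("artificial data").
  Persons with no observed responses contribute 0 (logged).
- **M-step.** Items are conditionally independent given θ, so each item's
  slopes and thresholds are updated separately by bounded L-BFGS-B with
  analytic gradients in an unconstrained parameterisation (first
  threshold + log-gaps, guaranteeing monotone thresholds).  The update
  starts from the current parameters and is rejected if it would lower the
  expected complete-data log-likelihood, making the scheme a generalised
  EM: the observed-data log-likelihood never decreases (asserted in tests
  to 1e-8 relative).
- **Start values.** Slopes 1.0 on all permitted loadings; thresholds from
  the inverse link of empirical cumulative category proportions.
  Deterministic, so fits are exactly reproducible.
- **Degenerate inputs.** Response categories never observed are merged
  into their lower neighbour with a logged mapping (parameter counts use
  the merged scale).  An item with a single observed category cannot be
  merged below two categories; its unidentified threshold drifts to the
  optimizer box constraint (|t1| ≤ 12, |a| ≤ 10) and the fit is flagged
  rather than aborted.
- **Sign convention.** After fitting, any factor whose slope column sums
  negative is reflected (the model is invariant under θ_k → −θ_k).

### Bifactor dimension reduction

In bifactor patterns (every item on the general factor plus at most two
group factors), conditional on the general factor g the item blocks
attached to disjoint group-factor sets are independent, so

    L_i = ∫ φ(g) Π_b [ ∫ φ(u_b) Π_{j∈b} P_j(y_ij | g, u_b) du_b ] dg.

Each inner integral is at most two-dimensional (a specific factor plus a
method factor for the GHQ and WEMWBS blocks), so the cost of the
six-factor model grows with the number of blocks, not exponentially in K.
The reduction is algebraically exact on the same tensor grid; a test
verifies equality with full three-dimensional dense quadrature to 1e-5.
Rows structurally missing an entire block (e.g. wave-2 persons in the
GHQ block) are skipped in that block's pass.

### Quadrature

Defaults: 21 nodes per dimension for integrals of effective dimension ≤ 2,
9 per dimension otherwise (the 3-d bifactor blocks).  These coarse grids
estimate parameters accurately (recovery tests below) but bias the
*absolute* log-likelihood by a few units at survey scale, because person
posteriors are much narrower than the prior-scaled grid.  All *reported*
log-likelihoods (in `FitResult` and cross-validation) are therefore
re-evaluated on ≥ 21 nodes per dimension, chunked over persons to bound
memory; at that density doubling the node count moves the LL by < 0.1 on a
study-shaped n = 2000 sample, so the information criteria are
quadrature-stable.  The `adaptive` flag in `QuadratureSpec` is reserved;
per-person adaptive placement is not implemented.

### Convergence controls

EM stops when the (estimation-grid) LL changes by less than `tol`
(default 1e-3) or after `max_iter` iterations (default 500);
non-convergence flags the result.  Study-scale pipeline runs use
`max_iter = 100, tol = 0.01`: at LL ≈ −3·10⁵ that is a relative change of
~3·10⁻⁸ per iteration, and loadings are stable to well under the sampling
error at that point.  These are the problem sizes used throughout the test
suite and the acceptance script.

## Exploratory model and geomin rotation

Model 2 fits a full item × m slope matrix with echelon identification
(m(m−1)/2 fixed zeros in the leading rows) and orthogonal factors, then
rotates the standardized loadings obliquely by minimising the geomin
criterion Q(Λ) = Σ_i (Π_k (λ_ik² + ε))^{1/m} with ε = 0.01 (the common
default for three or more factors).  Minimisation uses the gradient
projection algorithm over rotation matrices with unit-length columns; the
line search only accepts criterion decreases, so Q is non-increasing.
Geomin is multimodal: 30 seeded random starts plus the identity are run
and the best criterion kept; a test checks invariance of the solution (up
to column permutation and sign) under random pre-rotation of the input.
Factors are reported sorted by descending sum of squared loadings with
positive dominant sign.  Rotation leaves the criteria (LL, p, BIC)
untouched; it only re-expresses the loadings, preserving communalities and
the model-implied common covariance ΛΦΛᵀ.

## Model selection and cross-validation

BIC = −2LL + p·ln n; adjusted BIC = −2LL + p·ln((n+2)/24).  The *n* used
is the number of persons with at least one observed response, computed
from the analysed sample rather than the nominal design size.  Parameter
counts: Σ_j (C_j−1) thresholds plus one slope per permitted item–factor
pair (the echelon zeros of the exploratory model are already absent from
its pattern).  For the default 31-item battery this gives 133 / 192 / 164
/ 175 free parameters for models 1–4.

Cross-validation freezes the estimation-half loadings and thresholds and
evaluates the person-disjoint validation half either as-is (`all_fixed`,
p = 0, hence BIC = −2LL) or re-estimating one variance per factor
(`free_variances`, p = number of factors: 4 for model 3, 6 for model 4),
via L-BFGS-B on log-variances.  Freed variances near 1 indicate the latent
metric transfers to the holdout.

## Post-fit analytics

- **Salience.** |λ| ≥ 0.40 flags an interpretable loading; the boundary
  counts as salient.
- **Information.** Fisher information about the general factor per item,
  I_j(θ) = Σ_c (∂P_c/∂θ_g)²/P_c, with all other factors held at 0 (their
  population mean) — the standard conditional "partial information" for
  bifactor models; whether to marginalise over the group factors instead
  is an open choice and the conditional convention is documented here
  deliberately.  The θ axis is the standardized general dimension (0 =
  population mean, SD = 1); curves are tabulated on −4..4 in steps of
  0.05 and are additive over items, so the battery curve equals the sum of
  instrument partials.  Relative efficiency is the pointwise ratio of two
  partial curves.
- **Omega.** From standardized loadings of an orthogonal bifactor
  solution:  ω = [(Σλ_g)² + Σ_f (Σλ_f)²] / [(Σλ_g)² + Σ_f (Σλ_f)² +
  Σ(1−h²)], ω_h with only the general term in the numerator, and ω_s per
  instrument with the general term removed (sums restricted to the
  instrument's items).  Exploratory/rotated solutions are rejected —
  these formulas require orthogonal factors.

## Synthetic data generator

The generator emulates the pooled-survey design, not any real dataset:

- Three waves of 7255, 7246 and 4789 persons (19 290 pooled); the GHQ-12
  instrument is absent from wave 2, producing structural missingness for
  ~37% of persons on those 12 items.
- Households hold one or two selected respondents (a fresh household is
  two-person with probability 0.5, giving about two-thirds of persons a
  household partner).  The estimation/validation split sends one member of
  each pair to each half and assigns singletons by fair coin, so the halves
  are person-disjoint, household-disjoint within pairs, and slightly
  unbalanced in size, as in household-based designs.
- Incidental missingness: 1% completely at random on top of the design.
- Latent factors are independent standard normal (orthogonal bifactor
  truth); an optional factor covariance supports generating correlated-
  factor data for exploratory-model tests.
- Default truth (fixtures on the standardized-loading scale, with small
  deterministic per-item jitter): GHQ-like items λ_g ≈ 0.75 with a weak
  specific factor (0.20) and 0.30 on the wording method factor for the six
  negatively phrased items; WEMWBS-like items λ_g ≈ 0.60, specific 0.45,
  0.35 on the social/interest factor for five designated items; EQ-5D-like
  items: anxiety/depression 0.70 general / 0.40 specific, the other four
  0.20 general / 0.70 specific.  Threshold locations put most GHQ/WEMWBS
  measurement below the population mean (difficulties −1.9..1.1 in θ
  units), EQ-5D-like items above it.  These values are chosen so that the
  qualitative conclusions the pipeline should detect — a dominant general
  factor, near-zero GHQ-specific variance, a distinct EQ-5D factor, GHQ
  information concentrated below the mean — are true *by construction* of
  the generator, at effect sizes typical of well-being batteries.

What passing tests on these data do **not** show: anything about real
survey estimates.  The generator has no survey weights, no demographic
structure, no response styles, no differential item functioning, and its
truth values are fixtures, not estimates.  Tests against it validate the
*machinery* (estimation, selection, decomposition), and the qualitative
headline test validates that the pipeline detects a pattern it is known to
contain.

## Design choices and limitations

- The five WEMWBS social/interest items are a documented designation
  (`wb02, wb04, wb09, wb12, wb13`); the factor's size (5 items) is what
  matters for the parameter accounting.
- Codebook/config validation is implemented directly in the dataclass
  constructors; file IO is YAML/JSON for configs and plain CSV (empty cell
  = missing; 0- or 1-based category codes via a flag) for responses.
- No standard errors of item parameters, no survey weights, no
  weighted-least-squares estimation path, no limited-information fit
  indices (RMSEA/TLI/CFI), no DIF analyses, no EQ-5D health-state tariff
  scoring.
- Reported LLs from different models use a common dense reporting grid, so
  BIC comparisons are internally consistent; absolute LLs still carry the
  usual smooth-quadrature error, far below the criterion differences that
  drive selection.
- The free-variance holdout optimisation bounds log-variances to ±3 and
  reports non-convergence of the bounded optimiser in the result flag.
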