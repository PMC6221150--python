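# Methods

## Model and decision framework

All computations operate on the normal approximation to NMA evidence:
relative effects `y ~ N(δ, V)` with known block-diagonal `V` (one block per
study; a three-arm study contributes two correlated data points whose
sampling correlation comes from the shared baseline arm).  Treatment 1 is
the reference; the basic parameters `d = (d₂, …, d_K)` carry all contrasts
via consistency, `d_ab = d_b − d_a`.  Two likelihood structures are
supported:

- **Fixed effect (FE)**: `δ = Xd` with the signed-incidence design X.
- **Random effects (RE)**: `δ | d ~ N(Xd, Σ_τ²)`, where `Σ_τ² = A τ²` is
  block diagonal with 1 on the diagonal and 0.5 off diagonal within
  multi-arm blocks (exchangeable arm-level heterogeneity).  `τ²` is treated
  as known, fixed, and invariant to bias adjustment; this is the price of a
  closed-form joint posterior.  `tau2_sensitivity` sweeps a user-supplied
  list of values (e.g. the limits of a credible interval from the original
  fit) to probe the assumption.

Priors are multivariate normal `d ~ N(d₀, Σ_d)`.  The default "vague" prior
is `N(0, 10⁶ I)` — the conventional diffuse choice in Bayesian NMA
software; an improper flat prior (prior precision 0) is available and
reproduces generalised least squares exactly.  Extended models add
parameters μ (study baselines, covariates) with designs M (likelihood) and
L (linking δ to data), and class-effect models place `d | z ~ N(Zz,
Σ_class)` with exchangeable (Σ_class ≻ 0) or fixed (Σ_class = 0, handled by
reparametrising the design to XZ) class effects.

The decision rule is maximal expected efficacy, `k* = argmax_k E(d_k)`
(internally negated for `lower_better` outcomes), optionally demanding a
margin ρ (MCID) before an alternative counts as better.  Exact ties break
to the lowest treatment code and are flagged.

## Thresholds

Because every supported posterior is jointly normal, an additive data
perturbation β shifts the posterior mean of d by Hβ, where H depends only
on the model (see README for the catalogue).  The candidate adjustment
making alternative a tie with k* through datum m is a ratio of an expected
contrast to an influence difference; the thresholds are the extreme members
of that solution set, and the treatment attaining them is the new optimum
(its contrast with k* is the one whose posterior expectation changes sign
at the threshold — verified empirically against refits throughout the test
suite rather than re-derived).  Zero influence differences give ±∞
("NT": no adjustment in that direction can change the decision); a solution
of exactly 0 means a tie at no adjustment and is reported as a degenerate
threshold with a warning rather than an error.

Common biases shared by an index set M sum the influences, equivalently
combine the per-datum solutions harmonically (`1/∞ = 0`); we compute from
the summed influences for numerical robustness and test the harmonic
identity separately.  Simultaneous free adjustments in r data points give
hyperplanes `βᵀw = 1` with `w_i = 1/u_i` on the adjusted set; in 2-D the
invariant region is the intersection of the origin-side half-planes,
computed with shapely against a bounding box 10× the largest finite
threshold (a region touching the box is flagged open).  `β_min = w/‖w‖²`
gives the smallest simultaneous adjustment reaching each alternative.
Visual region output is limited to two dimensions; higher-r analyses report
hyperplane coefficients and β_min vectors only.

## Contrast-level reconstruction

Given only `(η, Σ)` for d, the study-level H is unrecoverable, so the
package refuses to guess and instead reconstructs a hypothetical
independent one-datum-per-edge FE likelihood: solve `XᵀWX = Σ⁻¹ − Σ_d⁻¹`
for diagonal `W ⩾ 0` by non-negative least squares on the half-vectorised
symmetric system (off-diagonals scaled by √2 so the NNLS objective equals
the Frobenius residual).  On a complete network the K(K−1)/2 rank-one terms
span the symmetric matrices and the solution is exact; otherwise the
residual and a Gaussian KL diagnostic quantify the approximation
(log-Bayes-factor reading: < 1 good, 1–3 fair, > 3 poor).  Weights below
10⁻¹² of the largest are truncated to zero (infinite variance — that
contrast's direct evidence carries no influence and its thresholds are NT
on both sides).  The KL is computed as KL(reconstructed ‖ true) with the
reconstructed mean set equal to the true mean — the reconstruction matches
covariances only, and the hypothetical data values are never needed for
thresholds; the reverse direction is also stored on the result for
inspection since the verbal convention is ambiguous.  Invariant intervals
at contrast level are anchored at the posterior contrast means.  A target
precision `Σ⁻¹ − Σ_d⁻¹` that is not positive semi-definite is rejected with
advice to supply a flatter prior.

## Numerical choices

- All SPD inversions go through Cholesky; condition numbers above 10¹⁰
  raise a warning, singular systems raise an error naming the approximate
  null-space direction.
- Thresholds are reported to 2 decimals with signed zero preserved
  ("−0.00" is meaningful: an infinitesimal negative change flips the
  decision).
- The bisection oracle brackets geometrically from 10⁻⁶ to 10⁶ and declares
  a side open beyond that; the predicate "optimum changed" is monotone in
  |β| because each pairwise comparison is linear in β.
- `fit_re_fixed_tau(τ² = 0)` falls back to the FE fit with `B* = Σ_n Xᵀ`,
  the continuity limit, so the RE influence path is defined at τ² = 0.

## Synthetic data and what green tests establish

The generator draws exactly from the stated hierarchy (connected random
networks with 2- and 3-arm studies, arm-variance-induced covariance blocks,
exchangeable 0.5 multi-arm correlation).  Defaults — K = 4, 8 studies, 25%
three-arm, arm variances U(0.05, 0.5), τ² = 0 — describe a modest evidence
base on a log-odds-ratio-like scale, chosen once as typical of the
published NMAs this method targets.  Because the data-generating process
matches the model assumptions, passing tests establish the *algebra*
(influence identities, threshold/oracle equivalence, reconstruction round
trips), not robustness to model misspecification: real extractions with
non-normal likelihoods, unknown τ², or missing covariance cells are only
approximated by this machinery.  Estimating τ², exact binomial likelihoods,
net-benefit decision rules and meta-regression bias models are out of
scope.

## Design decisions

- Treatment codes are 1-based throughout (column of treatment k is k−1 in
  1-based, k−2 in 0-based indexing), keeping the algebra legible against
  the field's standard notation.
- Sign convention: adjusted data are `y + β`; a positive threshold means
  the datum must move up.  `lower_better` is handled by negating outcomes
  (means and influence) before the threshold formulas, which leaves the
  reported adjustments in original data units.
- Multi-arm sampling covariance must be supplied (or induced from arm-level
  data by differencing against the baseline arm); it is never approximated.
  Missing covariance cells in CSV input default to 0 with a warning.
- Study-level analyses never refit: H is computed once per (model, data)
  pair and all thresholds are read from it.
- The class-effect between-treatment covariance is called `Sigma_class` to
  avoid colliding with the prior covariance `Σ_d`.
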