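# Methods

## Model and score

All fitting is ordinary least squares with an intercept that is always
included. The Gaussian −2 log-likelihood is profiled over the error
variance, so for an active set A with residual sum of squares `rss`

    −2ℓ_A = n·(log(2π·rss/n) + 1),      Q_A = −2ℓ_A + λ·|A|,

with the variance MLE `rss/n` plugged in. `|A|` counts active slopes only:
the intercept is forced into every model and never penalized (constant
offsets cancel in every Q difference, so counting it would only shift all
scores), and the variance parameter is likewise not counted. All additive
constants are kept so printed Q values are well defined; importance and
selection depend only on Q differences, which are invariant to affine
transformations of the predictors and to any additive constant in −2ℓ.

Penalties: AIC λ = 2, BIC λ = log n, HQIC λ = 2·log log n (the Hannan–Quinn
constant k fixed at 1; n ≥ 3 required so the penalty is positive), plus a
pass-through `custom` λ ≥ 0.

## Importance measures

For a variable set S, `VI(S) = min{Q_A : A ∩ S = ∅} − min{Q_A : S ⊆ A}` and
`mVI(S) = VI(S) + λ|S|`. Two bounds drive the test suite:

* `VI ≥ −λ|S|`: take the optimum A₁ among models excluding S and add all of
  S; nesting can only lower −2ℓ, so Q rises by at most λ|S|, and the model
  obtained competes in the including branch.
* `mVI ≥ 0`: immediate from the first bound.

Both hold for *exact* search engines. A heuristic engine may return a
local optimum in either branch, which can break the bounds; records
computed that way carry `exact=False` and the p-value routines refuse
negative statistics.

For |S| > 1 the including branch requires **every** member active. This is
the grouped-predictor reading (an indicator block enters or leaves
together); it is also what makes the nonnegativity argument work, since the
construction adds the entire set. Subsets containing only part of S belong
to neither branch. A consequence is that for multi-member sets the sign of
VI does not by itself determine whether the unconstrained optimum contains
the whole set (that optimum may keep part of S), so the `selected` flag for
such sets is computed from an explicit unconstrained search.

## Search engines

* A **Gram cache** holds the cross-product matrix of `[1, X, y]`. Any
  subset's normal equations are a slice of it, so a refit costs
  O(|A|³) independent of n, and replacing the response touches only the
  last row/column (the update used by the bootstrap, which redraws y with X
  fixed).
* **Exhaustive** enumeration scans subsets size-major, lexicographic
  (guarded at 25 free variables).
* **Branch and bound** fixes variables in or out along a depth-first tree,
  branching first on the variables with the largest single-variable Q drop
  measured at the root, with the greedy-forward solution as the initial
  incumbent. At a node with fixed-in F and free U the bound
  `−2ℓ(F ∪ U) + λ|F|` is a valid minorant of every descendant (free
  variables may be dropped, so only F's penalty is guaranteed); the subtree
  is pruned only when the bound exceeds the incumbent by more than the tie
  tolerance, so the engine reproduces exhaustive enumeration exactly,
  including ties.
* **Forward/backward** greedy passes provide cheap upper bounds and the
  appendix-style heuristic alternative; their results are locally optimal
  (no single move improves Q).

Tie-break everywhere: Q values within 1e-9 (absolute) are tied; prefer
fewer variables, then the lexicographically smallest index tuple. This
makes every reported active set deterministic.

* The **all-subsets scanner** pre-inverts each subset's normal-equations
  matrix once per design (2^p small inverses, embedded in a common frame)
  and then computes `rss[S, b] = y_b'y_b − c_b' P_S c_b` for a whole batch
  of responses with one einsum. Collapsing each membership branch to
  per-size minima of −2ℓ makes the penalized minimum for *any* λ a min over
  at most p+1 numbers, so one batch serves all criteria at once. Memory and
  setup grow as 2^p; the default cutoff is p ≤ 15, beyond which the
  bootstrap falls back to per-replicate branch-and-bound via the Gram
  y-refresh path. Both paths consume the random stream in the same order
  and agree draw for draw (tested).

## Inference

* Naive reference: upper tail of χ² with |S| degrees of freedom.
* Parametric bootstrap: fit the reduced model (all columns except S) by
  OLS; draw `y* = fitted + σ̂·ε` with X fixed; recompute mVI(S) on each
  draw. σ̂² defaults to the MLE `rss/n`, coherent with the profile
  likelihood used everywhere else; `variance="unbiased"` switches to
  `rss/(n−k−1)` (the two differ by O(p/n)).
* p estimator: `(1 + #{draws ≥ observed})/(B + 1)`. The add-one form is a
  valid p-value at any finite B and never returns 0. Default B = 100.
* Per-group randomness derives from `SeedSequence([seed, group_index])`, so
  tables are reproducible and independent of group evaluation order. In a
  p-value table the same substream serves all criteria for a group: the
  replicate responses are shared and only the penalty changes.
* Exact-engine draws are clamped to zero from below after a −1e-6 sanity
  check; anything more negative raises, since it signals a broken engine
  rather than roundoff.
* No multiplicity adjustment is applied; the table reports raw per-variable
  p-values, alongside full-model Wald p-values (t reference for singletons,
  χ²_{|S|} for sets, unbiased variance estimate) and post-selection Wald
  p-values inside each selected model, the latter shown for comparison
  only — they ignore the selection event.

## Simulation design

The generator produces the validation testbed: p = 6 covariates with base
coefficients (2, 3, 4, 5, 6, 7), of which `n_null = 3` uniformly chosen
entries are zeroed per replicate (so the ranking of the surviving effects
varies); rows `x ~ N₆(1, Σ)` with equicorrelation `Σ = ρJ + (1−ρ)I`; outcome
`y ~ N(x'β + 1, σ²)` with `σ² = β'Σβ / SNR` and default SNR = 3/7, i.e.
population R² = SNR/(1+SNR) = 0.3 — a noisy, adversarial regime. σ² is
computed from the post-zeroing β (the coefficients that actually generate
the data) so the realized SNR equals the target in every replicate; a flag
restores the pre-zeroing convention. Covariates are redrawn for every
replicate.

Experiments: (a) pool the null-variable mVI draws and compare with χ²₁;
(b) convert null p-values into empirical type-1 error rates at levels
{0.01, 0.05, 0.10}. Default problem sizes are 1,000 simulated models for
the chi-square/naive experiments and 500 models × 100 bootstrap replicates
for the bootstrap experiments, which gives binomial Monte-Carlo standard
errors of about 0.004 at the 5% level (3,000 null tests) while keeping any
experiment under a few minutes on one core; `--models` scales them up.
Expected behavior, verified by the acceptance tests: near-nominal rates for
all criteria at ρ = 0; marked naive inflation for BIC/HQIC at ρ = 0.9;
bootstrap rates within 0.03 of nominal even at ρ = 0.99.

What the generator does *not* emulate: non-Gaussian errors,
heteroscedasticity, non-equicorrelated designs, categorical predictors and
model sizes beyond six. Passing tests therefore certify the algebraic
properties in general (those are distribution-free) but calibration claims
only within this family.

## Numerical conventions

* Cholesky pivot below 1e-10 of the corresponding diagonal ⇒
  rank-deficiency error naming the first offending column; no pseudo-inverse
  fallback, so Q is never silently redefined on a singular subsystem.
* rss ≤ 1e-12·y'y ⇒ degenerate-fit error (the profile likelihood diverges).
* Standardization = center and scale by the sample SD (n−1 denominator),
  outcome untouched; original locations/scales are retained so raw
  coefficients are recoverable. Selection and importance are invariant to
  it. Intercepts, unlike slopes, are convention-dependent under
  standardization and are not treated as a comparable output.
* Reports print three decimals; all computation is double precision.

## Limitations

Gaussian linear models only (the constrained-search structure would carry
over to other GLM families, but fast refitting would need iterative
solvers). The scanner's 2^p memory limits batched bootstraps to p ≤ 15.
p-values are valid per variable but not adjusted for testing many
variables, and bootstrap p-values inherit Monte-Carlo noise of order
1/√B.
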