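# Methods

## Model and criterion

`dsalloc` targets parallel studies in which every subject's baseline
covariates are known before any intervention starts, so the whole allocation
can be chosen at once. The working model is the linear model
`y = X b + T g + e` with `X` (`N x p`) the covariate matrix and `T`
(`N x (t-1)`) the treatment-contrast matrix for `t` arms. Outcomes `y` do
not exist at allocation time and are never touched; the package manipulates
only the row assignment of `T`.

The optimality criterion is the determinant of the residual
sums-of-squares-and-products matrix of the contrasts after regressing them
on the covariates,

    Ds = | T'T - T'X (X'X)^- X'T |,

which is proportional to the inverse generalized variance of the
covariate-adjusted arm-effect estimator. Because arm sizes are fixed, `T'T`
is constant and maximizing `Ds` is the same as maximizing the determinant of
the full information matrix `|F'F|`, `F = [X T]` — the classical D-optimal
blocking objective with blocks reinterpreted as study arms.

The scale-free **D_s-efficiency** is `Ds^(1/(t-1)) / N`. It equals 1 exactly
when the contrasts are orthogonal to the covariate space and 0 exactly when
some contrast lies inside it. For any arm sizes it is bounded by 1:
`trace(T'T) = N(t-1)` for the scaled Helmert construction, so by AM-GM
`|T'T| <= N^(t-1)`, and projecting out the covariates can only shrink the
determinant. With unequal arm sizes `|T'T| < N^(t-1)` already, so the
attainable optimum is below 1 by the size imbalance alone.

## Contrast construction

The contrast family is not unique; `Ds` is invariant to any orthogonal
reparameterization. We use **scaled Helmert contrasts**: row `i` of `T` is
`sqrt(t)` times row `arm(i)` of the `t x (t-1)` orthonormal Helmert matrix
(columns unit-norm, mutually orthogonal, orthogonal to the ones vector).
This is deterministic, and for equal arm sizes gives `T'T = N I` exactly —
each contrast has length `sqrt(N)` — so `|T'T| = N^(t-1)` (e.g. `162^2 =
26244` for three arms of 54). For unequal arm sizes individual column norms
can exceed `N` (e.g. sizes 2/2/1), but the determinant bound above still
holds; efficiency is always reported with denominator `N`.

## Covariate encoding and rank deficiency

`encode_covariates` builds `X` as: intercept, one column per continuous
covariate (as supplied; centering/rescaling provably leaves `Ds` unchanged
and is therefore not forced), and a **full** 0/1 indicator set per
categorical covariate with no reference level dropped. Full-dummy coding
keeps the encoding aligned column-for-column with how balance tables are
read, at the cost of rank deficiency (each indicator set sums to the
intercept; the trial encoding has p = 23 columns and rank 21). The criterion
is therefore computed through an orthonormal basis `B` of col(`X`) (thin
SVD, rank threshold `sigma_1 * max(N, p) * eps`):

    Ds = | T'T - (B'T)'(B'T) |,

which depends only on the column space and is well defined for any encoding.
The textbook ratio form `|F'F| / |X'X|` requires full rank and is kept as an
independent cross-check (`ds_via_ratio`), verified against the projection
form on hundreds of random full-rank instances at 1e-8 relative tolerance.

Determinants of the small `(t-1) x (t-1)` residual matrix are evaluated via
`slogdet`; a determinant in `[-1e-10 * scale, 0]` is treated as a rounded
zero (complete aliasing), anything more negative raises as an internal
error. Missing covariate values are rejected, never imputed; a constant
continuous column is accepted with a warning (it is aliased with the
intercept and cannot affect the result).

## The exchange optimizer

Arm sizes are fixed, so the natural search neighborhood is the **pairwise
swap** of two subjects in different arms — it preserves arm counts by
construction (single-subject moves would not). Each restart draws a
uniformly random size-respecting allocation, then performs steepest-ascent
passes: every cross-arm pair is scored and the single best improving swap is
applied, until a full pass finds no swap improving `Ds` by more than 1e-10
relative (the threshold prevents cycling on floating-point noise). Ties
break toward the lexicographically smallest pair, making each restart fully
deterministic. The default of 50 restarts plays the role of the iteration
count in classical exchange-type blocking software; on the 162-subject
problem each restart converges in roughly 15 swaps and the whole run takes
well under a second.

Scoring a swap does not refit anything. Swapping subjects `i` and `j`
changes `T` by a rank-one row update, leaves `T'T` unchanged, and perturbs
the residual Gram `G = T'T - P'P` (`P = B'T`) by a symmetric rank-two term;
the matrix determinant lemma collapses the determinant ratio to a scalar
expression in `d'G^-1 d`, `d'G^-1 v`, `v'G^-1 v` and `||b_i - b_j||^2`.
All cross-arm pairs are scored as vectorized array operations per arm pair.
After an accepted swap the state (`P`, `G`, `det`) is recomputed exactly —
at `O(N r (t-1))` this costs nothing at these problem sizes and keeps the
bookkeeping bit-identical to a from-scratch evaluation, which the tests
assert.

Seeding: one master seed spawns per-restart generators through a fixed
counter scheme (`SeedSequence([seed, restart])`), so results are independent
of execution order.

`brute_force_optimize` enumerates every distinct size-respecting assignment
(guarded at 200,000) and serves as the exact oracle for instances up to
N ~ 10; the exchange search attains the enumerated optimum on all tested
instances.

## Randomization baselines and Monte Carlo

"Complete" randomization is interpreted as a uniform draw over allocations
with the prescribed arm sizes (54/54/54), not per-subject coin flips: the
efficiency normalization presupposes fixed `T'T`, which only holds at fixed
arm counts. "Stratified" randomization draws independently within each
stratum, achieving prescribed stratum-by-arm counts exactly;
`even_stratum_arm_counts` builds the canonical prescription (each stratum
split as evenly as possible, leftovers to the arms with the largest
remaining deficit, so column totals equal the arm sizes).

`monte_carlo` evaluates the D_s-efficiency of each of `n_draws` (default
10,000) random allocations against the fixed covariate matrix and reports
the empirical middle-95% interval — 2.5th/97.5th percentiles with linear
interpolation between order statistics (the quantile convention is a
package choice) — plus the extremes. The per-draw evaluation is batched
(einsum over blocks of 512 draws), so 10,000 draws take a few seconds.

## Synthetic data

No subject-level data from the motivating trial are deposited, so
`generate_trial_replica` emulates its published marginal structure, and all
replica-scale results in this package are computed on that synthetic stand-in:

* exact design facts in every replica: 162 subjects, 104 F / 58 M, 17
  first-visit groups of sizes (10, 10, 11, 7, 11, 10, 7, 11, 8, 9, 9, 11,
  10, 10, 12, 6, 10), gender randomly interleaved across groups;
* random continuous covariates: age ~ N(42.6, 12.3^2) years truncated to
  [18, 70], BMI ~ N(25.3, 3.6^2) kg/m^2 truncated to [18, 40], health score
  ~ N(1.476, 0.13^2). The truncation ranges are physiological-plausibility
  choices and shift the moments negligibly (< 0.3 years on the age mean).
  Pooled single-population parameters are used; near-equality of per-arm
  means is then an *output* of good allocation, not an input. No correlation
  among the continuous covariates is imposed by default; a correlation-matrix
  hook (Gaussian copula) exists for sensitivity studies.

What the replica does *not* emulate: the joint distribution of the real
covariates (only marginals), any gender-by-group or seasonal structure, and
the real data's particular realization. Consequences observed with the
default generator: the optimized efficiency on replicas is stably ~0.9915
(across generator seeds and from 50 up to 500 restarts), slightly below the
0.992 published for the original data — the documented -0.005 tolerance on
that benchmark is therefore in use — and the maximum efficiency among 10,000
completely random allocations is ~0.95 rather than the published 0.97, even
though the middle-95% intervals reproduce almost exactly ([82, 92]% complete,
[93.2, 98.4]% stratified). Extreme order statistics are simply more sensitive
to the particular covariate realization than the bulk of the distribution.
(The published complete-randomization interval is itself reported once as
[82.0, 92.0]% and once as [0.80, 0.90]; the percent-scale figures are the
ones used as reference points here.)

`generate_toy` produces tiny instances (standard-normal continuous columns,
round-robin categorical levels, arm sizes as equal as possible) whose
allocation spaces can be enumerated, for oracle testing.

## Problem sizes used in the shipped checks

Unit and property tests run on instances from N = 4 to N = 40 plus the
162-subject replica; Monte-Carlo checks use 1,000–2,000 draws where the
distributional endpoints are being compared (the acceptance script uses the
full 10,000) and 10,000 draws where the maximum is at stake. The full test
suite completes in well under a minute.

## Known limitations

* Sequential enrollment is out of scope: the method requires all covariates
  before the first assignment.
* Outcome-model fitting, power calculations and multiple-endpoint designs
  are out of scope.
* The steepest-ascent exchange search is a local optimizer; restarts make
  the best-found optimum reproducible but global optimality is only
  verified against enumeration at small N.
* With strongly unequal arm sizes the efficiency ceiling is below 1 by
  construction; reported efficiencies should be compared against that
  ceiling, not against 1.
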