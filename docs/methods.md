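# Methods

## Model and test

The test statistic averages m+n log-Bayes factors, one per pooled
observation. For observation `Z_i` in the X-group, the "different densities"
model estimates its density from `X` minus `Z_i`; the "equal densities" model
from the pooled sample minus `Z_i`. Each model's marginal likelihood
integrates a kernel estimate over a bandwidth prior; restricting priors to a
scale family `π(h) = π₀(h/b)/b` collapses both integrals to kernel estimates
with the prior-averaged kernel

    L(z) = ∫₀^∞ u⁻¹ π₀(u) K(z/u) du

and bandwidth `b`, so the statistic is computed exactly — no numerical
integration appears anywhere in the statistic path. The prior-averaged form
matters for a second reason: `L` always has heavier tails than `K`, and
likelihood cross-validation (which selects `b`) is only well-behaved for
heavy-tailed kernels. The package treats the scale-mixture identity
"`K = φ`, `h² ~ inverse-gamma(ν/2, ν/2)` ⟹ `L = t_ν`" as the canonical prior
family and keeps `induced_kernel` generic for arbitrary user priors
(quadrature on `u = e^t`, absolute tolerance 1e−8, since the integrand's mass
can sit near 0).

Assumptions: i.i.d. samples within each group, independence across groups,
and (for the permutation null to be exact) exchangeability of the pooled
sample under H₀. Duplicate observations are allowed — kernel-matrix entries
stay finite — and no jittering is applied, since permutation validity does
not require distinctness.

## Bandwidth selection

`CV(b) = Σ_i log f̂_L(Z_i | b, Z_{−i})` over the pooled sample is label-free,
so the maximizer `b̂` is shared by every permutation (computed once per data
set). The search — the criterion is smooth and in practice unimodal in
`log b` — uses a 41-point log-spaced grid on `[10⁻³·s, 10·s]`, `s` a robust
scale of the pooled data (MAD × 1.4826, falling back to IQR/1.349, then the
standard deviation), polished by bounded scalar maximization on `log b` to
tolerance 1e−4; if the grid optimum lands on an endpoint the window widens by
a decade and retries (up to four times). Bivariate fits initialize each
coordinate from its univariate fit and polish `(log b₁, log b₂)` with
Nelder–Mead (xatol = fatol = 1e−4), a cheap, derivative- and seed-free local
search. The fit records its full evaluation trace, and the returned criterion
never falls below the best traced value. At least 3 distinct pooled values
are required; otherwise the criterion has no interior maximizer and selection
raises.

## Permutation null, p-value, critical value

The kernel matrix of pairwise scaled kernel evaluations (diagonal excluded)
never sees labels, so each permuted ALB is an O((m+n)²) reduction over the
same matrix: per-row shifted exponentials turn every group leave-one-out
log-density into `shift + log(row·indicator) − log(group−1)`, and
permutations are processed in vectorized blocks of 2048. Rows whose shifted
own-group sums underflow into subnormals (possible when the shift comes from
a much closer pooled neighbor; threshold 1e−250) are recomputed by exact
log-sum-exp. Permutations are sampled uniformly with replacement from the
relabeling group, driven by one integer seed.

Conventions, chosen where the procedure itself leaves them open and echoed in
every report:

- `t_{m,n}` is the order statistic at position `ceil((1−α)·N)` of the `N`
  permuted values — simple and conservative.
- The p-value counts strict exceedances `#{ALB* > ALB}/N`; ties count as
  non-exceedances. An add-one variant `(#{ALB* ≥ ALB}+1)/(N+1)` is available
  for users needing guaranteed finite-sample validity, but is not the
  default.
- The critical value is `max(0, t_{m,n})`: under H₀ the statistic is
  eventually negative, and rejecting on a negative value of an evidence
  statistic would be senseless.

The conditional-level diagnostic quantifies the cost of estimating the
critical value from few permutations: the `1−α` quantile of `N₁` permuted
ALBs is scored against `N₂` further permutations; the returned share is the
actual level of the `N₁`-permutation test conditional on the data.

## Bivariate extension and boundary correction

Bivariate estimates use a product kernel with one bandwidth per coordinate.
For data on `[0,1]²`, each source point is reflected across both axes
(`(x,y) → (x,−y), (−x,−y), (−x,y)`); the estimate built from the 4k copies is
multiplied by 4, and each leave-one-out estimate leaves out the evaluation
point together with its three reflections, so the estimate remains
independent of the point where it is evaluated. In the kernel matrix this is
one entry per pair — the sum of the product kernel over the four reflections
of the source point — so the whole univariate machinery (LCV, ALB,
permutations) applies unchanged. The correction removes bias along `x = 0`
and `y = 0`; mass can still leak past the unreflected edges `x = 1`, `y = 1`,
which is acceptable for data concentrated near the origin (as in the sonar
demo) and is not corrected. No univariate boundary correction is offered.

## Synthetic benchmark densities

`draw_random_mixture` emulates a stress benchmark of random normal mixtures:
component count `M` on {2,…,20} with `P(M=m) ∝ 1/m`, weights
`Dirichlet(1/2,…,1/2)`, variances i.i.d. inverse-gamma with shape 1/2 and
**scale** 1/2 (density ∝ x^{−3/2} e^{−1/(2x)}; shape/scale is the convention
recorded in output), means `μ_j | σ_j ~ N(0, σ_j²)`. The heavy-tailed
variance prior yields everything from near-normal to sharply multimodal
shapes. What these simulations do *not* emulate: dependence within samples,
measurement error, discreteness or ties, and densities outside the normal-
mixture class — passing tests show correct calibration and power in the
simulated regimes, not performance guarantees on arbitrary real data.

The two standard experiments default to the design under which the method's
operating characteristics are usually reported: m = n = 50, kernel `L0`,
α = 0.05, 338 first-stage vs 3845 second-stage permutations for conditional
levels, 3845 permutations for p-values, 500 replicates, every replicate on an
independent child seed spawned from a master seed.

## Problem sizes in the test suite

The suite keeps everything desk-scale: conditional-level and power checks run
at 100 replicates (second stage 1000 permutations, power 999 permutations);
null p-value uniformity runs 400 replicates of m = n = 20–25 with 499
permutations each — 400 rather than 200 because the Monte-Carlo noise of the
Kolmogorov distance estimate alone would otherwise approach the 0.1
acceptance band (P(D > 0.1) ≈ 4% at 200 replicates under exact uniformity).
The full-size runs (500 replicates, 3845 permutations) live in
`scripts/acceptance.py` and complete in about a minute on one CPU.

A note on the Kolmogorov–Smirnov baseline: at m = n = 50 the KS statistic is
discrete, its null p-values sit on atoms with gaps up to ≈ 0.27, and no
correct implementation has two-sided-uniform p-values at that size; the suite
therefore checks the one-sided validity direction (the empirical CDF of null
p-values never rises more than 0.1 above the diagonal). The kernel-L2
baseline's bandwidth is the pooled normal-reference value
`σ̂ (4/(3(m+n)))^{1/5}`, with the L2 integral evaluated in closed form via
Gaussian convolution identities; published power figures for such tests
depend on these nuisance choices, so they are soft references rather than
exact reproduction targets.

## Known limitations

- Dimensions above 2, non-product bivariate kernels, compact-support kernels
  and adaptive bandwidths are out of scope.
- Per-group bandwidths are deliberately not offered: a single pooled
  bandwidth is what makes the permutation distribution exact and cheap.
- The sonar demo requires the UCI connectionist-bench file, which is read
  locally or downloaded only on explicit request; the variables are used as
  given (inherently in [0,1]), with no rescaling before reflection.
- ALB is not Bayes-consistent — its magnitude is bounded by ≈ log 2 — so it
  must be read through its permutation distribution (or its sign, for large
  samples), never on the Bayes-factor evidence scale.
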