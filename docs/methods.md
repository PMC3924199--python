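# Methods

## Model

A gene's read count in sample *j* of group *i* (i = 0 control, 1
treatment) is modeled as negative binomial with mean
μ<sub>ij</sub> = d<sub>ij</sub>γ<sub>i</sub> and variance μ(1 + μφ):
d<sub>ij</sub> is a per-sample normalization factor (sequencing depth and
composition), γ<sub>i</sub> the normalized expression level, and φ ≥ 0
the dispersion, with φ = 0 the Poisson limit. Within a group the counts
are treated as approximately identically distributed, so the group sum
Y<sub>i</sub> is NB(n<sub>i</sub>d<sub>i</sub>\*γ<sub>i</sub>, φ/n<sub>i</sub>),
where d<sub>i</sub>\* is the geometric mean of the group's normalization
factors. The package works directly on these group sums; it does not
implement quantile-adjusted pseudocounts, so the approximate identical
distribution of raw counts within a group is an explicit assumption
rather than something manufactured by a quantile adjustment.

## Exact test

Conditional on the total s = Y₁ + Y₀, the null distribution of Y₁ is

q<sub>a</sub> ∝ f(a; n₁wμ₀, φ/n₁) · f(s−a; n₀μ₀, φ/n₀),  a = 0…s,

computed in log space and normalized by log-sum-exp (the support is
finite, so no truncation enters here). The default two-sided p-value is
the *small-probabilities* rule: the sum of all q<sub>b</sub> ≤
q<sub>y₁</sub>(1 + τ), with a relative tie tolerance τ = 10⁻⁷ so that
analytically tied outcomes (the mirror split of a symmetric design) are
not dropped to floating-point noise. A doubled-smaller-tail variant
(`method="doubled"`: twice the smaller inclusive tail, capped at 1) is
provided for sensitivity analysis; the two rules coincide for symmetric
conditionals and differ at the ±1-sample level in solved designs.

**Null abundance.** In a real analysis the expression level is unknown
and the test plugs in the abundance implied by the conditioning total,
μ̂₀ = s/(n₀ + n₁w). The power engine therefore evaluates p-values at this
plug-in abundance by default (`null_abundance="estimated"`). When w = 1
and the design is balanced the conditional distribution is abundance-free
and the choice is irrelevant; for w ≠ 1 the plug-in null is what an
analysis of the resulting experiment would actually compute, and it is
the configuration under which the package reproduces published
application designs. `null_abundance="fixed"` evaluates the null at the
design μ₀ instead.

## Power and sample size

Power is the alternative-model mass of the rejection region
{p(y₁, y₀) < α} with alternative marginals Y₁ ~ NB(n₁wρμ₀, φ/n₁),
Y₀ ~ NB(n₀μ₀, φ/n₀). The double sum is truncated at per-group tail mass
ε/2 (ε = 10⁻¹⁰ by default); the indicator is bounded by 1, so the total
truncation error is at most ε. The engine iterates over totals s,
computing each conditional distribution and its full p-value table once
(O(S²) work overall instead of O(S³) per-pair testing), which keeps
designs with n in the hundreds at μ₀ ≈ 1 in the tens of seconds.

The sample-size solver treats power as empirically monotone in n but
discrete: doubling from n = 2 brackets the target, integer bisection
closes the bracket, and the returned n carries a certificate
power(n) ≥ target > power(n−1). The floor n = 2 reflects that designs
without replication cannot estimate dispersion. Strict inequality
p < α is used in the rejection indicator. Unbalanced designs are
supported through a ratio k with n₁ = k·n₀ (k·n must be whole).

With many genes, the FDR identity f = m₀α/(m₀α + r₁) (valid under
independence or weak dependence) converts an FDR level f and a target
number of true rejections r₁ into the marginal operating point
α\* = r₁f/(m₀(1−f)), β\* = 1 − r₁/m₁. Per-gene mode solves
Σ<sub>g</sub> ξ(n, ρ<sub>g</sub>, μ₀<sub>g</sub>, φ<sub>g</sub>, w, α\*) ≥ r₁
with a single common w; conservative mode replaces every prognostic gene
by the least-favourable triple (ρ\* = argmin |log₂ρ<sub>g</sub>|,
μ₀\* = min μ₀<sub>g</sub>, φ\* = max φ<sub>g</sub>), which upper-bounds
the required n. A tie on |log₂ρ| is broken toward the down-regulated
candidate, for determinism only. The target power is the exact r₁/m₁
(e.g. 107/133 = 0.8045), not its rounded value.

## Pilot estimation

Genes are filtered to those whose total count exceeds a threshold
(default 5) in *both* groups. Normalization uses TMM (trimmed mean of
M-values) with the standard defaults — 30% M-trim, 5% A-trim, precision
weighting, reference sample chosen by the upper-quartile rule — applied
to library sizes; effective factors d<sub>ij</sub> are rescaled to
geometric mean 1, and w is the ratio of the treatment over control
geometric means. The implementation was checked against an independent
run of the reference TMM implementation on a seeded fixture (agreement to
5×10⁻¹¹); a plain library-size mode exists mostly for testing. Because
the factors are constrained to geometric mean 1, rescaling one library
leaves fold changes invariant but shifts all absolute means by a common
factor; this is a property of the convention, not an estimation error.

Per-gene estimates: μ₀<sub>g</sub> is the mean normalized control count;
ρ<sub>g</sub> the ratio of normalized group means, with +0.5 added to
both means when either is zero (bounded, deterministic fold changes for
genes absent in one group); φ<sub>g</sub> the per-gene maximum-likelihood
dispersion with group means profiled out by the moment plug-in
γ̂<sub>i</sub> = Σy/Σd, floored at 0.

Two pooled common-dispersion estimators are provided. The *conditional*
estimator (default) maximizes the summed per-gene conditional
log-likelihoods given each group's total — free of the unknown means when
samples within a group are identically distributed, and close to unbiased
even at small n (it recovers φ = 0.1 to three digits at m = 10⁴, n = 20).
The *profile* estimator maximizes the unconditional likelihood with
moment plug-in means; it honours unequal normalization factors (so it is
the pilot-data choice) but is biased low at small group sizes, since the
plugged-in means absorb part of the variability.

The prognostic set is the ⌈proportion·m⌉ genes with smallest exact-test
p-values (computed on group sums with the pooled dispersion and w), ties
broken by larger |log₂ρ|, then lexicographic gene id. The ceiling is a
deterministic convention; published analyses have rounded such counts
either way (175 vs ⌈0.01·17306⌉ = 174).

## Validation harness

Each replicate draws m independent NB genes at the design's parameters
(first m₁ prognostic with treatment mean wρμ₀, the rest null) for n
samples per group, then analyses the matrix without knowledge of the
truth: normalization factors and ŵ from the simulated data (library-size
factors by default — adequate when the prognostic fraction is small;
TMM available and advisable when planted effects are large enough to
bias library totals), pooled conditional-ML dispersion, exact-test
p-values for every gene from its group sums (cached per total, since the
plug-in conditional depends on the data only through s), Storey q-values,
rejection at q ≤ f. Genes with zero total count get p = 1.

Storey q-values use a fixed λ = 0.5: π̂₀ = #{p > λ}/(m(1−λ)) capped at 1
and floored at 1/m (a zero estimate would force zero rejections by
fiat), and q<sub>i</sub> = min<sub>p<sub>j</sub>≥p<sub>i</sub></sub>
π̂₀·m·p<sub>j</sub>/rank(p<sub>j</sub>). No smoother is fitted; with the
discrete p-values of exact tests the fixed-λ estimate is the more stable
choice.

Replicates are seeded via `SeedSequence([seed, replicate_index])`, so the
result is bitwise reproducible and replicates are independent.

**What the harness does and does not emulate.** It reproduces the
design's stochastic model exactly (independent NB genes, shared
dispersion, a depth-imbalance factor w on treatment means) and an honest
estimation pipeline. It does not emulate correlated genes, per-gene
dispersion heterogeneity, or the quantile-adjustment and weighted
conditional-likelihood machinery of production differential-expression
packages; achieved true-rejection counts therefore agree with published
pipeline-based simulations only up to the small-sample behaviour of
those estimators (a few percent in per-gene power), while FDR control
and the power calculation itself are exact-model properties that the
harness verifies directly. The acceptance run uses 500 replicates of the
m = 10⁴ design — enough for a Monte-Carlo standard error of about 0.2
true rejections.

## Numerical choices

- All pmf evaluation in log space with log-gamma; for dispersions below
  10⁻⁴ (size parameter r > 10⁴) the rising factorial
  lgamma(y+r) − lgamma(r) is computed as a cumulative log-product, which
  avoids the catastrophic cancellation of subtracting two huge log-gamma
  values and keeps the Poisson limit accurate to < 10⁻⁷ in absolute pmf
  error.
- Tail truncation bounds come from the distribution's quantile function;
  `nb_tail_bound(spec, ε)` is the smallest B with P(Y > B) ≤ ε.
- Dispersion optimizations run on log φ over [10⁻⁸, 10²] with bounded
  Brent; estimates landing at the lower boundary are reported as 0
  (Poisson).
- Degenerate inputs: α ≤ 0 returns power 0 (p-values are strictly
  positive); a conditioning total of 0 has the single outcome (0,0) with
  p = 1; all-zero samples and empty post-filter matrices raise errors.

## Known limitations

- Two-group comparisons only; no multi-group designs.
- Independence across genes is assumed in both the FDR identity and the
  generator.
- The solved n is sensitive at the power boundary: design cells whose
  power at n−1 sits within a few 10⁻³ of the target can shift by ±1
  under a different two-sided rule, truncation level, or p-value
  implementation. The bracketing powers are reported precisely so such
  cells can be recognized.
- Very large fold changes with small μ₀ make the rejection region
  dominated by a handful of discrete outcomes; reported power then moves
  in visible steps with n.
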