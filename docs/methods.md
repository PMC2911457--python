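# Methods

This note records the statistical model, the estimation choices, the
defaults, and the limitations of `cnapower`, in the order the pipeline
runs.

## Preprocessing

**Normalization.** Each sample's log2 ratios are shifted so their median is
zero. Wave-pattern correction is exposed as a configuration flag but is a
no-op hook that logs a notice; wavy profiles should be corrected before
upload.

**Segmentation.** A clean-room circular binary segmentation: within each
segment the two-sample statistic is maximized over all circular arcs
(minimum width 2 probes), and a split is accepted when its permutation
p-value is below `alpha = 0.01` (up to 1000 permutations). Two shortcuts
keep the permutation test exact in effect but cheap: sampling stops early
once enough exceedances have accrued that the p-value can no longer fall
below alpha, or once a clean run is long enough (~3/alpha permutations)
that it is decisively below; and splits whose statistic exceeds a
Bonferroni bound over all ~n²/2 arcs (with a 10x safety margin) are
accepted without sampling. Segment levels are medians of member probes.
Segmentation is a means to delineate regions here; it is not intended to
reproduce any particular external segmenter probe-for-probe, and power-only
mode exists for users who preprocess elsewhere.

**Calling.** Fixed log2-ratio thresholds, inclusive on the aberrant side:
loss ≤ −0.15, gain ≥ +0.15, amplification ≥ +0.9. There is no double-loss
class. Calls only delineate regions; all test statistics use RWLRs, which
limits the impact of the threshold choice.

**Collapsing.** Scanning probes in genomic order, a region closes when the
call vector across samples differs from the *region's opening profile* in
more than ⌈τ·n⌉ samples (τ = 0.10), or at a chromosome boundary.
Comparing against the opening profile rather than only the adjacent probe
lets per-sample boundary jitter — which spreads call changes one sample at
a time over many probes — accumulate into a shared breakpoint; with
strictly adjacent comparison, jittered shared aberrations produce no
boundaries at all. The RWLR of a region in a sample is the median of its
normalized probe log ratios (midpoint convention for even counts).

## Region tests

Welch's t on the RWLRs with unbiased group variances; two-sided p-values
from the standard normal (a deliberate fixed choice of the method, not the
t distribution). Zero-variance regions are dropped with a warning before
any mixture fitting: their p-values of exactly 0 or 1 carry no information
and distort the mixture. Note that at small group sizes the normal
p-values are anticonservative in the tails (at n = 15 per group, roughly a
factor 2 at p ≈ 0.003 relative to the t reference); see Limitations.

## Mixture estimation

The p-values follow F(t) = γt + (1−γ)G(t). For each γ on the grid
{0.50, 0.505, …, 0.995}:

- the non-parametric estimator Ĝ_γ(t) = (F̂(t) − γt)/(1−γ) is evaluated on
  a 1000-point uniform grid on (0.001, 1], clipped to [0, 1] and
  monotonized by isotonic regression (pool-adjacent-violators);
- the parametric estimator fits, by maximum likelihood at fixed γ, the
  alternative t ~ 0.5·N(a, 1+b²) + 0.5·N(−a, 1+b²) (noncentralities
  θ ~ N(±a, b²)). The sign-balanced mixture is the default because copy
  number differences comprise both gains and losses; a single-normal
  variant (`alternative: signed`) is available. Both imply the same
  two-sided p-value distribution
  G(t) = 1 − Φ(c_t − a)/v) + Φ((−c_t − a)/v), c_t = Φ⁻¹(1 − t/2),
  v = √(1+b²). Optimization is Nelder–Mead, warm-started along the γ grid
  with moment-based and null starting points at the first γ.

γ̂ minimizes the sup-distance between the two curves (an L2 option exists;
it is markedly less stable in our experiments). Ties break toward the
smaller γ. Two guards apply:

- *Feasibility screen.* Because G ≤ 1, F(t) ≤ γt + (1−γ), hence
  γ ≤ (1−F(t))/(1−t) for every t. Candidate γ above the minimum of this
  bound over t ∈ [0.05, 0.95] (plus a 2/√m sampling allowance) are
  excluded. Without the screen, the clipping of Ĝ hides the more-than-unit
  alternative mass an infeasible γ implies, and the discrepancy can
  degenerate at the upper grid edge under strong signal.
- Warnings are attached when γ̂ > 0.95 (too close to 1 for reliable
  estimation) or when the sup-distance exceeds 0.10.

A fit where no optimization converges is an estimation failure and yields a
flat-line report rather than an exception.

## Effect-size deconvolution

The t statistics have density γφ(t) + (1−γ)(φ * λ)(t): a Gaussian
convolution of the unknown effect density λ. λ̂ is the nonparametric
maximum-likelihood mixing density on the grid θ ∈ [−10, 10] (step 0.05),
computed by expectation–maximization with γ fixed at γ̂ — the classical
NPMLE of a mixing distribution, which enforces non-negativity and unit mass
by construction. Observations are pooled into 2000 bins first, making the
iteration cost independent of m (up to 1000 iterations, relative tolerance
1e-9). Direct characteristic-function inversion with a hard frequency
cutoff was evaluated and rejected: the empirical-CF noise grows like
e^{s²/2}/√m, and after negative-clipping the recovered density was far too
diffuse to support the power extrapolation. If the NPMLE is degenerate
(≥99% of mass in one grid cell) the parametric density N(a, b²) from the
mixture fit is substituted and flagged.

## Power extrapolation

For a balanced candidate design of n per group, s(n) = √((n/2)/h₀) with
h₀ = (1/n_A + 1/n_B)⁻¹, and

G_n(t) = Σ_k w_k [1 − Φ(c_t − sθ_k) + Φ(−c_t − sθ_k)].

The adaptive BH threshold u*(n) is the largest u ∈ (0, 1] with
γ̂u/(γ̂u + (1−γ̂)G_n(u)) ≤ α, found on a 400-point log grid (1e-8..1) and
refined by bisection to relative tolerance 1e-6; Π(n) = G_n(u*(n)), or 0
when no threshold exists. Candidate sizes default to n = 2..100 and α to
0.10. Unbalanced extrapolation is supported through the effective-size
formula but is not the default. A curve on which no candidate size reaches
0.1% average power is flagged *flat line* — estimation noise can place tiny
density mass at extreme effect sizes, producing thresholds of ~1e-8 and
powers of ~1e-5 that are scientifically indistinguishable from zero.

Π(n) is non-decreasing in n by construction: scaling only moves
noncentrality mass outward, which raises G_n pointwise and relaxes the
threshold simultaneously.

## Diagnostics

- *Goodness of fit*: both G curves on the shared grid plus their
  sup-distance, graded satisfactory (≤ 0.10), mediocre (≤ 0.15) or failed
  (> 0.15, estimation failure, or a flat-line curve). The cutoffs are
  calibrated so that a well-specified strong-signal fit at around a
  thousand regions grades satisfactory despite the 1/(1−γ) noise
  amplification in Ĝ.
- *P-value density*: 20-bin histogram; the convex flag requires at least
  80% of the second differences of the 3-bin moving average to be above a
  noise-scaled tolerance (max of 0.05 and twice the binomial bin noise)
  and the density not to rise from the first to the last bin — a rising
  density (fewer small p-values than chance) is technically convex but
  signals failure. The low-p enrichment ratio is the mean density on
  [0, 0.1].
- *RWLR moments*: per region, each group is centered at its mean, residuals
  pooled, and g1 = m₃/m₂^{3/2}, g2 = m₄/m₂² − 3 compared to the
  0.5%–99.5% band of the same statistics on 1000×m standard-normal samples
  of equal size (seeded, reproducible). Whether the original method
  computed moments per region or per sample is not documented; per region
  across group-centered samples is used here.
- *Pilot-consistency study*: stratified subsets (10%–90%, group sizes
  rounded, minimum 2) are drawn without replacement, the full pipeline is
  re-run on each (10 repetitions per fraction), flat-line failures are
  excluded — and counted, never silently — and the surviving power curves
  are averaged.

## Simulator

The generator emulates tumour profiles in a two-group design: baseline
i.i.d. N(0, 0.15²) probe noise (optional AR(1) correlation, default off),
30 shared aberrations with Bernoulli(0.70) carriers over all samples, 5
aberrations private to each sample, and k per-group aberrations (0–10) with
Bernoulli(0.70) carriers within the group. Extents are one, three or six
consecutive cytobands, an arm, or a chromosome (10/30/30/20/10%), truncated
at the chromosome end; types are gain/loss with equal probability, with a
2% amplification chance for single-band events. Amplitudes (not documented
for the original simulations) default to gain +0.58 (= log2 3/2), loss
−1.0, amplification +2.0. Each carrier's boundaries are shifted
independently by integers uniform on −10..10, clamped to the chromosome;
inverted spans are redrawn. Zero-carrier Bernoulli outcomes are kept and
recorded. The default synthetic genome has 22 chromosomes of 300 probes
(100 kb each) with 6 cytobands per arm, which keeps the jitter-to-band
ratio comparable to a dense clinical array while remaining tractable for
permutation-based segmentation; simulations in the test suite use this
scale (roughly 200–300 regions after collapsing).

What the generator does not emulate: technical wave artifacts, correlated
probe noise along real genomic distance, resampled clinical baselines,
platform-specific probe layouts. Consequently, passing tests show the
estimation chain is internally correct under the stated model — not that
any particular clinical platform satisfies its assumptions.

## Known limitations

- γ̂ is biased downward; in repeated clean simulations (γ = 0.9, m = 1000)
  roughly three quarters to nine tenths of estimates fall within ±0.05 of
  the truth, with the misses essentially all below. The discrepancy
  profile is shallow below the truth because the normal alternative can
  partially absorb extra null mass.
- Normal (rather than t) p-values are anticonservative at pilot sizes of
  ~15 per group. In simulations with no group-specific signal, carrier
  imbalance plus this tail inflation yields weak pseudo-signal: the fitted
  power curve can lift a few percent off zero at large n instead of
  flat-lining.
- With a few hundred regions the ECDF noise in Ĝ is substantial; the
  goodness-of-fit grade is a coarse instrument at that scale and should be
  read together with the p-value density.
- The sup-distance minimization, the grade cutoffs, the flat-line epsilon
  and the convexity tolerances are operationalizations of qualitative
  descriptions; all are exposed in configuration.
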