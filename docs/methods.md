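# Methods

## Model

`gwarch` treats a complex trait as `L` mutational opportunities. Each site
draws a selection coefficient `s` from a density `f(s)`; conditionally on
`s`, the site carries a segregating variant with probability `seg(s)`, the
variant's minor allele frequency `p` follows the demography-dependent site
frequency spectrum `P(p | s)`, its effect on the standardized trait is
`β | s ~ N(0, c·s)`, and its GWAS z-score is
`z ~ N(β·sqrt(2p(1−p)·N), 1)`. The constant `c` is not free: it is pinned
by the heritability normalization

    h² = L · E_f(s),SFS[ seg(s) · 2p(1−p) · c · s ],

so that the per-site effect-variance scale is `c = h² / (L·I)` with
`I = E[seg·s·2p(1−p)]`. Because heterozygosity times selection is nearly
invariant in `s` at mutation–selection balance, `I` (hence `c`) depends
only weakly on the shape of `f(s)`; the per-trait constant
`k = 4μ/I` is exposed as `ModelGrid.trait_constant_k`. A variant is a GWAS
hit iff `p > 0.01` and `|z| > 5.45` (the two-sided 5×10⁻⁸ threshold).
Sites are independent; block labels exist only for resampling. The
one-dimensional (no-pleiotropy) variant replaces the Gaussian effect by a
deterministic magnitude, `z ~ N(sqrt(c·s·2p(1−p)·N), 1)`.

Binary traits enter on the liability scale: a case-control design
`(M, ω, K)` maps to the effective quantitative sample size
`N' = M·ω(1−ω)·φ(T)²/(K²(1−K)²)` with `T = Φ⁻¹(1−K)`, z-scores deflate as
`sqrt(N'/N)`, and log-odds effects convert by `K(1−K)/φ(T)` (the standard
small-effect liability-threshold factor). Binary-trait association in the
synthetic harness is a per-variant score test — the small-effect equivalent
of logistic regression — rather than an iterative fit, for speed.

## Wright–Fisher SFS engine

Underdominance is implemented literally as genotype fitnesses
`(1, 1−s, 1)`: the deterministic update is
`Δq = −s·q(1−q)(1−2q)/w̄`, `w̄ = 1−2s·q(1−q)`, followed by binomial drift
with `2N` draws. The exact fitness parameterization induced by a
multidimensional stabilizing-selection model is not uniquely determined by
the underdominant form; this choice is documented rather than asserted as
canonical.

`P(p | s)` is estimated by an injection (origination) sampler: each
replicate is one mutation arising at a generation drawn with probability
proportional to `2N_t` over burn-in plus epochs, started at `1/(2N_t)` and
tracked to the present. Survivor frequencies, folded to MAF, estimate the
segregating-conditional spectrum;
`seg_prob = μ·Σ_t 2N_t · P(segregating at present)` is the per-site
probability of carrying a segregating variant, exact in the θ→0 limit
where at most one mutation per site survives. A naive recurrent-mutation
scheme is equivalent in that limit but produces essentially no segregating
replicates at realistic μ; the injection sampler is the standard
importance-sampling reformulation. The neutral constant-size limit
reproduces the folded `1/i + 1/(2N−i)` spectrum; at 2N ≲ 1000 the discrete
chain deviates from this diffusion form by more than the Monte-Carlo error
of a ~10⁶-replicate run, so diffusion-limit checks use 2N = 2048.

Frequencies live on log-spaced bins over `(1/(4N_final), 0.5]` with a
**log-uniform law inside each bin**. This within-bin convention is used
consistently by the simulator (sampling), the likelihood (numerator
jacobian `1/(p·ln(b/a))`, denominator via per-bin Gauss–Legendre nodes in
`ln p`), and the residual p-values — which makes residual p-values exactly
probability-integral-transform uniform under the generating model and the
likelihood normalization exact to quadrature.

### Desk-scale demography

The default `toy_demography()` is a three-epoch caricature of a
European-style history: ancestral N = 2048 diploids (400 generations,
preceded by a 5·2N-generation burn-in — more than twice the neutral
fixation timescale), a bottleneck of N = 512 (100 generations), and growth
to N = 16384 (200 generations). The sizes were chosen so that, across the
default selection grid (`1e-4 … 0.25`, 12 log-spaced points plus neutral),
`2N·s` spans the drift barrier (≪1) to strong selection (≫100), and —
critically — so that strongly selected mutations cannot reach the 1% MAF
threshold: the product `4N·s·0.01` reaches ≫1 within the grid. That is the
regime in which GWAS ascertainment reshapes architectures. Because the
MAF threshold (1%) does not rescale with population size, a toy demography
cannot be an exact diffusion rescaling of the real one; the package keeps
the mutation rate at 1.25×10⁻⁸ per site per generation and treats the toy
model as its own well-defined study system.

### Study-condition f(s) densities

`f(s)` is a four-knot spline on `log10 s` (natural cubic in log-density,
linear extrapolation with the end slopes, clamped to the support,
normalized to integrate to 1; the four knot values therefore carry three
degrees of freedom). Two canonical desk-scale conditions ship with the
package:

- `SplineFS.toy_reference()` — a unimodal density peaking near
  `s ≈ 1.8×10⁻³` with a steep strong-selection tail; the "typical
  quantitative trait" condition. At `h²=0.5, L=10⁸, N=3×10⁵` it yields
  ~400–500 hits per simulation with median MAF ≈ 0.1.
- `SplineFS.toy_strong()` — the "brain-related" condition: most
  probability mass sits at selection strengths whose carriers essentially
  never become common (in linear `s`, a gently declining log-density still
  concentrates mass at large `s`), plus a weakly selected shoulder. Its
  GWAS-visible hits come from that shoulder: they are several-fold fewer,
  sit at higher MAF (median ≈ 0.14), and cluster near the significance
  threshold, while the pre-ascertainment frequency distribution is ~6×
  rarer than the reference. The ascertainment-driven reversal of the MAF
  ordering is the phenomenology of interest; reproducing it at desk scale
  requires exactly this structure (a strong bulk beyond the commonness
  cutoff feeding no hits), because a merely location-shifted unimodal
  density moves its hits into the rare-but-powerful borderline zone and
  lowers hit MAF instead.

## Likelihood and optimization

Each hit contributes
`log P(z, p | h², L, f(s)) − log P(hit | h², L, f(s))`, with the numerator
mixed over 20–64 Gauss–Legendre nodes in `ln s` (weights folded with
`f(s)`, SFS rows log-linearly interpolated between grid rows,
`seg_prob` interpolated geometrically) and the z-part of the denominator
in closed form, `2Φ̄(5.45/σ)` per `(p, s)`. Per-hit numerators are
evaluated by log-sum-exp; an underflowing denominator surfaces as `-inf`
rather than a silent zero.

The conditional hit likelihood depends on `(h², L)` only through
`c ∝ h²/L`. To separate the two — as the generative model does — the trait
objective adds the Poisson hit-count term `n·log(L·P(hit)) − L·P(hit)`
(config flag `use_hit_count`, default on) and subtracts the penalty
`0.05·(L/3×10⁸ + h²/1)`, which only matters when the likelihood is flat.
Per trait, nested bounded 1-D searches run over `log10 L ∈ [3, 9.5]`
(outer) and `h² ∈ [10⁻³, 0.99]` (inner); non-convergence sets a flag
rather than raising. Group fits share one `f(s)`: Nelder–Mead over the
four knot values (positions fixed; the additive gauge is removed by
centering) from eight scattered starts by default, best total penalized
log-likelihood wins, ties to the earliest start. Confidence envelopes come
from resampling genomic blocks with replacement and refitting from the
point estimate with a single start.

Identifiability at desk scale has a known limit: `f(s)` mass in the
commonness-dead zone produces no hits and is constrained only through the
count term jointly with `(h², L)`, so a strong-condition trait does not
pin down its own dead-zone mass. Recovery checks therefore target the
density mode (for the reference condition, whose support is fully
GWAS-visible) and `h²/L`, the scaling parameter that governs power.

Alternative models share the machinery with `p` drawn from the neutral SFS
row: the normal model (`β ~ N(0, σ²)`) and the α-model
(`Var(β|p) = σ²(2p(1−p))^α`, `α ∈ [−1, 0]`); α = 0 reduces exactly to the
normal model, and `L` is profiled in closed form through the count term.

## Diagnostics

Residual p-values `Pr(|Z| > |z_i| | |Z| > 5.45, p_i, model)` use the
posterior mixture `f(s | p) ∝ f(s)·seg(s)·P(p | s)`; they are two-sided in
`|z|`, matching the ascertainment rule (the one-sided alternative differs
only by the symmetric factor of two and was not adopted). Cross-validation
partitions blocks into 10 folds, refits the model family on the training
blocks and scores each hit exactly once. Uniformity is tested with
two-sided KS (scipy's exact small-sample distribution) and controlled
across trait-model pairs with Benjamini–Hochberg FDR at 0.05 (BY was not
used; the choice is a documented assumption).

## Classification, pruning, burden

ACAT combines dependent one-sided enrichment p-values via
`T = mean(tan((0.5−p)π))`, `p = 0.5 − arctan(T)/π`; inputs at 0 or 1 are
clamped to a configurable ε (default 10⁻¹⁵) with a warning; the statistic
is dominated by its smallest input. A trait is brain-related iff its
combined CNS p-value is strictly below `0.05/(10 × n_traits)`. Trait
pruning is greedy in order of enrichment strength (strongest first —
resolving an ambiguity between ordering descriptions in favor of the named
starting trait), keeping a trait iff `|r_g| ≤ 0.5` against everything
already kept; traits lacking estimates are skipped with a log entry.

Burden analysis forms `γ̂² − SE²` (unbiased for `γ²`;
`Var = 2SE⁴ + 4γ²SE²` under normality), bins genes into 15 shet quantiles
(stable tie-breaking by gene order), normalizes every value by the pooled
(both categories) grand mean of the tenth bin — pooling preserves the
between-category contrast the curves are meant to show — and summarizes
each category with a lowess smoother (tricube local linear regression,
span 0.75). The bootstrap resamples traits with replacement by default;
gene-within-trait resampling is available. Per-bin means weight gene-trait
pairs equally by default, with equal-trait weighting as a flag.

## Synthetic data

Generators are seed-deterministic and return ground truth. Cohorts draw
genotypes `Binomial(2, p)` with MAF uniform on (0.05, 0.5) by default, an
additive standardized phenotype with exact target heritability, and
standard-normal noise; no LD, relatedness, structure or covariates are
emulated — passing tests demonstrate internal consistency of the
statistical machinery, not robustness to those real-data complications.
Enrichment matrices are null-uniform with planted CNS signal (one-sided
normal p-values at a chosen mean shift). Burden tables couple
`E[γ² | shet]` as a power law with a steeper exponent for brain traits
(1.0 vs 0.4, scale 0.05 at shet = 10⁻²), shet log-uniform on
`[10⁻⁴, 1]` — producing the curve crossing without making either category
uniformly larger. Default sizes (5×10⁴ individuals, ≤10³ cohort variants,
10⁶-replicate SFS rows, ≤10⁸ simulated sites per trait) keep every stage
in seconds to a couple of minutes on one CPU.

## Numerical and testing choices

- Optimizer tolerances: outer `xatol` 0.02 on `log10 L`, inner 10⁻³ on
  `h²`, Nelder–Mead `xatol` 0.05 / `fatol` 10⁻³ on knot values.
- Frequency integrals use 4 Gauss–Legendre nodes per common bin in `ln p`.
- The likelihood-vs-simulation agreement check compares coarse `(z, p)`
  cell probabilities (six cells tiling the ascertained range) on pooled
  simulations of ≥1.5×10⁴ hits; agreement is required within 0.05 nats.
- The target-size sweep (`L ∈ {3, 10, 30}×10⁷` at the reference `f(s)`)
  must steepen the hit-|z| CDF while moving the hit-MAF CDF by less than
  0.15 per decade of `L` — and by less than the selection-strength effect
  (reference vs strong contrast ≈ 0.17). At desk scale the MAF
  distribution is only *largely*, not perfectly, insensitive to `L`: the
  narrow GWAS-visible selection window of the toy demography makes the
  hit composition more power-sensitive than in a full-scale model.
- Seeds: every simulation and fit takes an explicit seed; table caches are
  byte-identical under identical inputs.

## Known limitations

- No linkage disequilibrium anywhere; "blocks" are bookkeeping.
- The toy demography compresses the selection window; absolute values of
  `seg_prob`, hit counts and `c` are internally consistent but not
  transferable to real cohorts.
- Dead-zone `f(s)` mass is not identifiable from a single trait's hits
  (see above).
- The α-model lower bound (α ≥ −1) is occasionally active on
  strongly-coupled data; fits report the boundary value with the
  convergence flag.
- Burden analysis covers quantitative traits only; binary-trait burden
  testing is out of scope.
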