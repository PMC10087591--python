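# Methods

This note documents the models implemented in `conformity`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Learning rules

Two families map a demonstrator frequency q ∈ [0, 1] to an adoption
probability.

The three-demonstrator rule `p(q) = q + D·q·(1−q)·(2q−1)` models a
learner who samples three demonstrators and preferentially adopts the
majority among them; `D = 1` equals the majority-of-three binomial
probability `q³ + 3q²(1−q)` exactly, and `D = 0` is unbiased copying.
`D` is restricted to [0, 1].

The logistic rule `p(q) = q^β/(q^β + (1−q)^β)` is the two-variant case
of the discrete-choice form `p_i = q_i^β / Σ_j q_j^β`.  Its exponent β
is the single tunable conformity strength: β > 1 gives hyper-conformity
(disproportionate majority adoption, the sense in which "conformist
transmission" is used throughout), β = 1 unbiased copying, 0 < β < 1
weak conformity, β < 0 anti-conformity.  β = 0 is classified with
anti-conformity but flagged as the frequency-independent boundary
(uniform 1/K choice).  The rule is the choice distribution of an agent
maximizing ln(q_j) + ε_j with i.i.d. Gumbel (Extreme Value Type-I)
noise of scale 1/β; `sample_choice` draws from that utility model
directly and therefore serves as an independent Monte-Carlo oracle for
the closed form as well as the simulator's decision sampler.

Numerics: the two-variant rule is evaluated in logit form
`expit(β·logit(q))`, which is exact in the interior and immune to the
overflow of `q^β` at large |β|; the K-variant rule is evaluated as
normalized exponentials of `β·ln q_j` after subtracting the maximum.
Endpoints are defined by continuity for β > 0 (p(0) = 0, p(1) = 1) and
raise a degenerate-input error for β ≤ 0, where the two one-sided
limits disagree with the symmetric value and silently returning either
would be misleading.

The error mixture `p′(q) = α/2 + (1−α)·p(q)` lets a fraction α of
learners choose uniformly at random, producing the plateau
`p′(1) = 1 − α/2` observed in real learners facing unanimous
majorities.  With K variants the random component is generalized to
uniform over all K options (α/K), an extension documented here because
the two-variant form does not dictate it.

## Estimating β from choice-frequency data

Input is a grouped table: per (group, variant), the demonstrator
frequency, the number of observers and the number of adoptions.
Adoption counts may be fractional so exact proportions (the
infinite-observer limit) are representable.

Because `ln(p/(1−p)) = β·ln(q/(1−q))`, β is fitted as a through-origin
least-squares slope of empirical response log odds on demonstrator log
odds; the conformity test is one-sided for β > 1 against a t reference
with (points − 1) degrees of freedom.  Design choices:

* **Weighting.**  The default is inverse-variance ("binomial") weights
  `n·p̂(1−p̂)`, the reciprocal of the large-sample variance of an
  empirical log odds.  The unweighted option ("ols") is retained, but
  Monte-Carlo calibration at a 9-level × 200-observer design (1000
  replicates) showed it anti-conservative — type-I error ≈ 0.12 at the
  nominal 0.05 — because the extreme frequency levels carry both the
  largest leverage and the largest sampling variance, which
  homoskedastic standard errors understate.  The weighted test is
  calibrated (≈ 0.05) with power ≈ 1 at β = 5, so it is the default.
* **Unanimity handling.**  Observed proportions of 0 or 1 have infinite
  log odds.  The default applies the Haldane–Anscombe continuity
  correction (+0.5 to counts, +1 to totals) to the affected groups
  only; `unanimity="drop"` removes them instead.  Groups whose
  *demonstrator* frequency is 0 or 1 carry no slope information and are
  always dropped with a warning.  Which rows were touched is reported
  in the estimate's metadata.
* **Degenerate fits.**  Exact data yield a zero residual standard
  error; the test then degenerates to p = 0 if β̂ > 1 and p = 1
  otherwise rather than a 0/0 statistic.
* **Multi-variant pooling.**  With K variants every unordered
  within-group pair contributes one point
  `(ln(q_A/q_B), ln(p̂_A/p̂_B))` in a fixed sorted-label order — using
  both orderings would duplicate each point and fake precision.  A
  single pooled through-origin slope is fitted (unweighted; the
  pairwise log-ratios within a group share observers, so independent
  binomial weights would be mis-specified).  With K = 2 and adoption
  counts summing to the observer count this reduces exactly to the
  binary estimator in its unweighted form.
* **Error-mixture fit.**  (α, β) are estimated by maximizing the
  binomial likelihood over α ∈ [0, 1], |β| ≤ 50 (L-BFGS-B from several
  starts, Nelder-Mead polish); standard errors come from the observed
  information, and boundary optima are flagged rather than silently
  accepted since their Wald errors are unreliable.  At least three
  distinct frequency levels are required for the two free parameters;
  tables containing only unanimous demonstrator groups leave β
  unidentifiable and raise an error.

Slope invariance under relabelling of the two variants (both log odds
negate) is asserted by tests, as is agreement of the unweighted slope
and standard error with an independent general-purpose least-squares
implementation.

## The metapopulation simulator

Haploid, sexed, two-locus individuals; non-overlapping generations; a
constant 1:1 sex ratio by construction (each female leaves exactly one
son and one daughter, so population and subpopulation sizes are
conserved without any fitness normalization — selection acts purely
through male mating success).  Haploidy is the minimal reading of
"conformist or random-mating females": no dominance assumptions enter.

Parameters (defaults in parentheses): number of subpopulations (20),
subpopulation size (50), conformity strength β (2.8), dispersal
fraction d (0.02), recombination rate r (0.20), initial conformity
allele frequency q0 (0.20), choice error rate α (0), generations (500),
perception mode, seed.  β = 2.8, d = 0.02, q0 = r = 0.20 are the
canonical study conditions for the structured-versus-unstructured
contrast; group sizes are a package choice (see below).

* **Initialization.**  Display alleles A/B i.i.d. Bernoulli(1/2)
  metapopulation-wide; strategy allele C i.i.d. Bernoulli(q0),
  independent of the display, so the two loci start unassociated.
* **Perceived frequency.**  What q a conformist female observes is an
  open modelling question; two modes are implemented.  The default,
  "male-frequency", is the standing frequency of A among local adult
  males.  "mating-observation" feeds each female (in uniformly shuffled
  order) the fraction of A among matings already realized locally this
  generation, the first chooser falling back to the male frequency;
  this mode is sequential and correspondingly slower.  Neither is
  privileged by theory; the default is the simpler and faster one.
* **Mate choice.**  A c-female picks a uniform male.  A C-female
  targets display A with probability p(q; β, α) and then picks a
  uniform male of that display; if the targeted display is locally
  extinct she falls back to a uniform male.  Males mate without limit.
  At unanimity endpoints the simulator uses the continuity limit for
  every β so runs remain defined after local fixation (for β < 0 the
  limit targets the extinct minority, which resolves to the fallback).
* **Reproduction.**  Per offspring, independently: with probability
  1 − r both alleles come from one uniformly chosen parent, with
  probability r the display allele comes from one uniformly chosen
  parent and the strategy allele from the other.  r is thus exactly the
  probability of a recombinant two-locus transmission.
* **Dispersal.**  Each offspring is independently flagged a migrant
  with probability d; within each sex, migrants are randomly permuted
  across all vacated slots metapopulation-wide.  Sizes and sex ratios
  are conserved exactly.  A migrant can land back in its origin
  subpopulation with probability ≈ 1/n_subpops; excluding the origin
  would complicate the slot-permutation scheme for an O(1/n) effect.
* **Seeding.**  Sweeps derive one independent stream per (grid cell,
  replicate) from the base seed via `SeedSequence` counters, so every
  replicate is reproducible in isolation and results are bit-identical
  across reruns.

State is stored as small integer arrays and generations advance with
vectorized sampling; `choose_mate` and `reproduce` restate the same
rules one decision at a time as the readable, unit-tested reference.

**Group sizes are not canonical.**  The validation scale — 10
subpopulations of 20 for 300 generations, with a 1 × 200 unstructured
control — was chosen so that drift breaks the display symmetry within
subpopulations quickly and full contrasts run in seconds on a desktop.
The qualitative outcomes (structured: among-group display diversity
persists and C rises above q0; unstructured: display diversity lost, C
neutral; low dispersal beats high dispersal for C) are robust at this
scale, but absolute final frequencies depend on group size and horizon
and should not be read as universal values.

## What the synthetic data do and do not show

The choice-table generator draws binomial adoptions from the logistic
rule at fixed design frequencies — observers are independent,
identically ruled, and see the true q.  Real experiments violate all
three (observer heterogeneity, memory and sequential observation,
sampling error in q itself), so passing recovery and calibration tests
here certifies the estimator's correctness under its own model, not
robustness to those violations; the mixed-effects and
measurement-error extensions that would address them are out of scope.
Similarly, the simulator omits costs of conformity, overlapping
generations, more than two variants per locus and any explicit space
beyond the island model, and the transient runaway boost C receives in
*any* population before display fixation means small unstructured
controls hover only approximately at q0 — neutrality there is an
asymptotic, not exact, statement.

## Known limitations

* The error-mixture standard errors are Wald-type; near the α = 0
  boundary they are flagged unreliable rather than replaced by a
  profile-likelihood interval.
* The multi-variant estimator treats pooled pairs as independent
  points; its standard error is approximate when groups contribute
  several pairs.
* The mating-observation perception mode is a per-female Python loop
  and is noticeably slower than the vectorized default at large
  subpopulation sizes.
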