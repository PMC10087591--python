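# conformity

Tools for studying **conformist transmission** — positive
frequency-dependent social learning, in which individuals adopt the
majority variant *disproportionately* more often than random copying —
and for asking how such a learning rule can evolve in the first place
through **Fisher runaway sexual selection** in a spatially structured
population.

The package is aimed at behavioural ecologists and cultural-evolution
modellers who need (a) flexible learning-rule curves, (b) a statistical
test for conformity in choice-frequency data, and (c) a forward-time
simulator of conformist mate choice in a metapopulation.

## The models

**Learning rules.** With two variants and demonstrator frequency *q*,
the classical three-demonstrator conformist bias is

    p(q) = q + D·q·(1−q)·(2q−1),        D ∈ [0, 1]

and the logistic (discrete-choice) family is

    p(q) = q^β / (q^β + (1−q)^β)

whose single exponent spans hyper-conformity (β > 1), unbiased copying
(β = 1), weak conformity (0 < β < 1) and anti-conformity (β ≤ 0).  It
generalizes to any number of variants, p_i = q_i^β / Σ_j q_j^β, and has
a random-utility micro-foundation: an agent maximizing ln(q_j) plus
i.i.d. Gumbel noise of scale 1/β makes exactly these choices.  An error
rate α mixes in uniform random choice,
p′(q) = α/2 + (1−α)·p(q), producing the empirically ubiquitous
departures from unanimous majorities (p′(1) = 1 − α/2).

**The β > 1 test.**  Taking log odds linearizes the rule:

    ln(p/(1−p)) = β · ln(q/(1−q))

so β is a through-origin regression slope, and a one-sided test of
β > 1 is a test for conformist transmission.  The package fits this
slope (inverse-variance weighted by default), its K-variant pairwise
generalization ln(p_A/p_B) = β·ln(q_A/q_B), and the (α, β)
error-mixture by maximum binomial likelihood.

**The metapopulation model.**  Haploid individuals carry a male-only
display locus (A/B, fitness-neutral) and a female-only strategy locus:
C-females choose mates by the logistic conformist rule applied to the
local frequency of A males, c-females mate randomly.  Each female has
one son and one daughter (recombination rate r between the loci), and a
fraction d of offspring disperses among subpopulations each generation.
Conformist mate choice builds a statistical association between C and
the locally common display — Fisher's runaway — and with modest
dispersal the conformity allele spreads, while in an unstructured
population display diversity is quickly lost and C stays neutral.

## Worked example

```python
import numpy as np
from conformity import (LogisticRule, ChoiceDesign, classify_regime,
                        logistic_prob, simulate_choices, fit_beta_binary)

rule = LogisticRule(beta=2.8)
print("p(0.6) =", logistic_prob(0.6, rule))
print(classify_regime(2.8))

table = simulate_choices(rule, ChoiceDesign(np.linspace(0.1, 0.9, 9),
                                            observers=200), seed=42)
print(fit_beta_binary(table).report())
```

prints

```
p(0.6) = 0.7568160923896962
RegimeLabel(label='hyper-conformity', note=None)
Conformity estimate (binary log-odds regression (binomial, unanimity=haldane))
  beta_hat = 2.61933  (SE 0.104, 9 points)
  one-sided test of beta > 1: p = 1.483e-07  ** conformist transmission **
```

A learner at q = 0.6 under β = 2.8 adopts the majority variant 76% of
the time — well above the 60% of random copying — and the regression on
a simulated experiment (9 demonstrator frequencies, 200 observers each)
recovers a slope near the generating β = 2.8 and rejects β ≤ 1
decisively.

The same workflows are available from the shell:

```sh
conformity rules --rule logistic --beta 2.8 --grid 101   # response curve
conformity fit choices.csv --method binary               # estimate beta
conformity simulate --config examples/run.toml --out out/
conformity sweep    --config examples/run.toml --out out/
conformity power --betas 1.0,5.0 --replicates 500
```

`conformity simulate` with the example configuration (20 subpopulations
of 50, β = 2.8, d = 0.02, q0 = r = 0.2) ends, for seed 0, with the
conformity allele at frequency 0.52 — up from its initial 0.20 — and
five subpopulations still polymorphic for the display:

```
final C frequency: 0.5240  (mean A: 0.0680, polymorphic subpops: 5)
```

See `examples/run.toml` for a fully commented configuration and
`docs/methods.md` for the modelling details and their rationale.

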