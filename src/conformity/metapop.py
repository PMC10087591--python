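"""Forward-time metapopulation model of conformity evolving by Fisher
runaway sexual selection.

Individuals are haploid carriers of two unlinked diallelic loci.  A
display locus (alleles A/B) is expressed in males only and is neutral
for fitness; a learning-strategy locus (alleles C/c) is expressed in
females only: c-females mate with a uniformly random local male, while
C-females apply the logistic conformist learning rule to the perceived
local frequency of A males and then pick a random male of the targeted
phenotype.  Both loci are carried silently by the non-expressing sex.

Life cycle, non-overlapping generations: each female has exactly two
offspring, one son and one daughter, each inheriting a full haplotype
from one uniformly chosen parent with probability 1 - r, or the display
allele from one parent and the strategy allele from the other with
probability r (recombination).  Offspring then disperse: each is
independently flagged a migrant with probability d, and migrants are
randomly permuted across the vacated slots of their own sex
metapopulation-wide, so subpopulation sizes and the 1:1 sex ratio are
conserved exactly.

Within a subpopulation, drift breaks the A/B symmetry; conformist
females amplify the local majority, their sons carry the locally sexy
display, and the statistical association this assortment creates between
C and the local majority allele drives the runaway.  Spatial structure
with modest dispersal keeps different subpopulations fixed on different
display traditions, which is what keeps conformity selectively
advantageous; in an unstructured population display polymorphism is
quickly lost and C becomes neutral.

The simulation state is stored as small integer arrays (one row per
subpopulation) and generations are advanced with vectorized sampling;
the per-individual functions (:func:`choose_mate`, :func:`reproduce`)
implement the identical rules one decision at a time and serve as the
readable, unit-testable statement of the model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import DomainError
from .learning_rules import LogisticRule

__all__ = [
    "TRAIT_A", "TRAIT_B", "PREF_C", "PREF_c",
    "Individual", "Subpopulation", "SimParams", "Metapopulation",
    "SimResult", "SweepResult",
    "init_metapopulation", "perceived_frequency", "choose_mate",
    "reproduce", "disperse", "step_generation", "run_simulation",
    "run_sweep", "summarize",
]

log = logging.getLogger(__name__)

# allele codes; columns of the state arrays are [display, strategy]
TRAIT_A, TRAIT_B = 1, 0
PREF_C, PREF_c = 1, 0
LOCUS_TRAIT, LOCUS_PREF = 0, 1

PERCEPTION_MODES = ("male-frequency", "mating-observation")


@dataclass(frozen=True)
class Individual:
    """One sexed two-locus carrier.  ``trait`` is 1 for A, 0 for B;
    ``pref`` is 1 for C (conformist), 0 for c (random mater).  Both loci
    are populated regardless of sex."""

    sex: str
    trait: int
    pref: int

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.trait not in (0, 1) or self.pref not in (0, 1):
            raise DomainError("alleles must be coded 0/1")


@dataclass
class Subpopulation:
    """A view of one subpopulation: ``males`` and ``females`` are
    (k, 2) integer arrays with columns [display allele, strategy
    allele]."""

    males: np.ndarray
    females: np.ndarray
    id: int = 0

    @property
    def freq_A_males(self) -> float:
        return float(self.males[:, LOCUS_TRAIT].mean())

    @property
    def freq_C_females(self) -> float:
        return float(self.females[:, LOCUS_PREF].mean())


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters.

    ``beta`` and ``alpha`` parameterize the conformist rule used by
    C-females; ``d`` is the offspring dispersal fraction, ``r`` the
    recombination rate between the two loci, ``q0`` the initial fraction
    of the conformity allele C.  ``perception`` selects what demonstrator
    frequency a choosing female perceives: the standing frequency of A
    among local adult males ("male-frequency", default) or the fraction
    of A males among matings already realized locally this generation
    ("mating-observation", with a male-frequency fallback for the first
    chooser).
    """

    n_subpops: int = 20
    subpop_size: int = 50
    beta: float = 2.8
    d: float = 0.02
    r: float = 0.20
    q0: float = 0.20
    alpha: float = 0.0
    generations: int = 500
    perception: str = "male-frequency"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise DomainError(f"n_subpops must be >= 1, got {self.n_subpops}")
        if self.subpop_size < 4 or self.subpop_size % 2:
            raise DomainError(
                f"subpop_size must be an even count >= 4, got {self.subpop_size}"
            )
        for name, val, lo, hi in (
            ("d", self.d, 0.0, 1.0),
            ("r", self.r, 0.0, 0.5),
            ("q0", self.q0, 0.0, 1.0),
            ("alpha", self.alpha, 0.0, 1.0),
        ):
            if not (lo <= val <= hi):
                raise DomainError(f"{name} must lie in [{lo}, {hi}], got {val}")
        if not math.isfinite(self.beta):
            raise DomainError(f"beta must be finite, got {self.beta!r}")
        if self.generations < 1:
            raise DomainError(f"generations must be >= 1, got {self.generations}")
        if self.perception not in PERCEPTION_MODES:
            raise DomainError(
                f"perception must be one of {PERCEPTION_MODES}, got {self.perception!r}"
            )

    @property
    def total_size(self) -> int:
        return self.n_subpops * self.subpop_size

    def rule(self) -> LogisticRule:
        return LogisticRule(beta=self.beta, alpha=self.alpha)


@dataclass
class Metapopulation:
    """State of every subpopulation: ``males`` and ``females`` are
    (n_subpops, k, 2) integer arrays, k = subpop_size // 2."""

    males: np.ndarray
    females: np.ndarray
    generation: int = 0

    @property
    def n_subpops(self) -> int:
        return self.males.shape[0]

    def subpop(self, i: int) -> Subpopulation:
        return Subpopulation(males=self.males[i], females=self.females[i], id=i)

    def freq_A_males(self) -> np.ndarray:
        """Per-subpopulation frequency of display allele A among males."""
        return self.males[:, :, LOCUS_TRAIT].mean(axis=1)

    def freq_C_females(self) -> np.ndarray:
        """Per-subpopulation frequency of conformity allele C among females."""
        return self.females[:, :, LOCUS_PREF].mean(axis=1)

    def cov_trait_pref(self) -> np.ndarray:
        """Within-subpopulation covariance between carrying A and carrying
        C, pooled over both sexes — the statistical linkage the runaway
        builds despite free recombination."""
        both = np.concatenate([self.males, self.females], axis=1).astype(float)
        x = both[:, :, LOCUS_TRAIT]
        y = both[:, :, LOCUS_PREF]
        return (x * y).mean(axis=1) - x.mean(axis=1) * y.mean(axis=1)

    def check_invariants(self, params: SimParams) -> None:
        k = params.subpop_size // 2
        expected = (params.n_subpops, k, 2)
        if self.males.shape != expected or self.females.shape != expected:
            raise AssertionError(
                f"state shape {self.males.shape}/{self.females.shape}, expected {expected}"
            )


def init_metapopulation(params: SimParams, rng: Optional[np.random.Generator] = None) -> Metapopulation:
    """Found the metapopulation.

    Display alleles A/B are allocated uniformly at random (expected
    50:50) metapopulation-wide; the conformity allele C is allocated
    independently with probability ``q0``, so the two loci start
    statistically unassociated.  Each subpopulation holds exactly
    ``subpop_size/2`` males and as many females.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    k = params.subpop_size // 2
    shape = (params.n_subpops, k)
    males = np.empty(shape + (2,), dtype=np.int8)
    females = np.empty(shape + (2,), dtype=np.int8)
    for arr in (males, females):
        arr[:, :, LOCUS_TRAIT] = rng.random(shape) < 0.5
        arr[:, :, LOCUS_PREF] = rng.random(shape) < params.q0
    return Metapopulation(males=males, females=females, generation=0)


def _target_prob_A(q: float, beta: float, alpha: float) -> float:
    """Probability a conformist female targets an A male given perceived
    frequency q.  Interior points use the logistic rule in logit form;
    unanimity endpoints take the continuous limit for every beta so the
    simulator stays defined after a subpopulation fixes (for beta < 0 the
    limit targets the extinct minority, which then falls back to a
    uniform male)."""
    if q == 0.0:
        core = 0.0 if beta > 0 else (0.5 if beta == 0 else 1.0)
    elif q == 1.0:
        core = 1.0 if beta > 0 else (0.5 if beta == 0 else 0.0)
    else:
        core = float(expit(beta * logit(q)))
    return alpha / 2.0 + (1.0 - alpha) * core


def perceived_frequency(
    subpop: Subpopulation,
    mode: str = "male-frequency",
    matings: Optional[Sequence[int]] = None,
) -> float:
    """Demonstrator frequency of A as seen by a choosing female.

    "male-frequency": proportion of A among the subpopulation's adult
    males.  "mating-observation": proportion of A among the display
    alleles of males already mated this generation (``matings``), falling
    back to the male frequency when no mating has happened yet.
    """
    if subpop.males.shape[0] < 1:
        raise DomainError("subpopulation has no males")
    if mode == "male-frequency":
        return subpop.freq_A_males
    if mode == "mating-observation":
        if matings is None or len(matings) == 0:
            return subpop.freq_A_males
        return float(np.mean(np.asarray(matings) == TRAIT_A))
    raise DomainError(f"unknown perception mode {mode!r}")


def choose_mate(
    female: Individual,
    subpop: Subpopulation,
    q: float,
    rule: LogisticRule,
    rng: np.random.Generator,
) -> int:
    """Return the index of the male this female mates with.

    c-females pick uniformly at random.  C-females target display A with
    probability given by the logistic rule at perceived frequency ``q``
    and then pick uniformly among local males of the targeted display;
    if none exists locally they fall back to a uniform male.  Males may
    mate any number of times.
    """
    n_males = subpop.males.shape[0]
    if n_males < 1:
        raise DomainError("subpopulation has no males")
    if female.sex != "female":
        raise DomainError(f"chooser must be female, got {female.sex!r}")
    if female.pref == PREF_c:
        return int(rng.integers(n_males))
    p_a = _target_prob_A(q, rule.beta, rule.alpha)
    target = TRAIT_A if rng.random() < p_a else TRAIT_B
    candidates = np.flatnonzero(subpop.males[:, LOCUS_TRAIT] == target)
    if candidates.size == 0:
        log.debug(
            "subpop %s: no male of targeted display %d; uniform fallback",
            subpop.id, target,
        )
        return int(rng.integers(n_males))
    return int(candidates[rng.integers(candidates.size)])


def reproduce(
    mother: Individual,
    father: Individual,
    r: float,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Produce exactly one son and one daughter.

    Each offspring independently inherits, with probability 1 - r, both
    alleles from one uniformly chosen parent (a parental haplotype); with
    probability r, the display allele from one uniformly chosen parent
    and the strategy allele from the other (a recombinant).
    """
    if mother.sex != "female" or father.sex != "male":
        raise DomainError(
            f"parents must be (female, male), got ({mother.sex!r}, {father.sex!r})"
        )
    out = []
    for sex in ("male", "female"):
        from_father = rng.random() < 0.5
        recomb = rng.random() < r
        trait = father.trait if from_father else mother.trait
        pref_from_father = from_father != recomb
        pref = father.pref if pref_from_father else mother.pref
        out.append(Individual(sex=sex, trait=trait, pref=pref))
    return out[0], out[1]


def disperse(pool: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Island-model dispersal for one sex's offspring pool.

    ``pool`` has shape (n_subpops, k, 2).  Each offspring is
    independently flagged a migrant with probability ``d``; migrants are
    then randomly permuted across all vacated slots of that sex
    metapopulation-wide.  Subpopulation sizes are conserved by
    construction.  A migrant may land back in its origin subpopulation
    with probability ~1/n_subpops.
    """
    if not (0.0 <= d <= 1.0):
        raise DomainError(f"dispersal fraction d must lie in [0, 1], got {d}")
    out = pool.copy()
    flat = out.reshape(-1, pool.shape[-1])
    migrants = np.flatnonzero(rng.random(flat.shape[0]) < d)
    if migrants.size:
        flat[migrants] = flat[rng.permutation(migrants)]
    return out


def _mate_vectorized(
    males: np.ndarray,
    females: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Father index for every female of one subpopulation, perceiving the
    standing male frequency of A."""
    n_m = males.shape[0]
    n_f = females.shape[0]
    father = rng.integers(n_m, size=n_f)
    conformist = np.flatnonzero(females[:, LOCUS_PREF] == PREF_C)
    if conformist.size == 0:
        return father
    q = float(males[:, LOCUS_TRAIT].mean())
    p_a = _target_prob_A(q, params.beta, params.alpha)
    wants_a = rng.random(conformist.size) < p_a
    idx_a = np.flatnonzero(males[:, LOCUS_TRAIT] == TRAIT_A)
    idx_b = np.flatnonzero(males[:, LOCUS_TRAIT] == TRAIT_B)
    for wants, idx in ((wants_a, idx_a), (~wants_a, idx_b)):
        who = conformist[wants]
        if who.size == 0:
            continue
        if idx.size:
            father[who] = idx[rng.integers(idx.size, size=who.size)]
        else:
            father[who] = rng.integers(n_m, size=who.size)  # fallback: display extinct
    return father


def _mate_sequential(
    males: np.ndarray,
    females: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Father index for every female, chosen one at a time in uniformly
    shuffled order, each conformist perceiving the frequency of A among
    matings already realized this generation."""
    n_m = males.shape[0]
    n_f = females.shape[0]
    father = np.empty(n_f, dtype=np.int64)
    standing = float(males[:, LOCUS_TRAIT].mean())
    idx_by_trait = {
        TRAIT_A: np.flatnonzero(males[:, LOCUS_TRAIT] == TRAIT_A),
        TRAIT_B: np.flatnonzero(males[:, LOCUS_TRAIT] == TRAIT_B),
    }
    a_matings = 0
    n_matings = 0
    for i in rng.permutation(n_f):
        if females[i, LOCUS_PREF] == PREF_c:
            j = int(rng.integers(n_m))
        else:
            q = a_matings / n_matings if n_matings else standing
            p_a = _target_prob_A(q, params.beta, params.alpha)
            target = TRAIT_A if rng.random() < p_a else TRAIT_B
            cand = idx_by_trait[target]
            j = int(cand[rng.integers(cand.size)]) if cand.size else int(rng.integers(n_m))
        father[i] = j
        a_matings += int(males[j, LOCUS_TRAIT] == TRAIT_A)
        n_matings += 1
    return father


def _offspring(
    mother_alleles: np.ndarray,
    father_alleles: np.ndarray,
    r: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized transmission: one offspring per mating pair."""
    n = mother_alleles.shape[0]
    from_father = rng.random(n) < 0.5
    recomb = rng.random(n) < r
    trait = np.where(from_father, father_alleles[:, LOCUS_TRAIT], mother_alleles[:, LOCUS_TRAIT])
    pref_from_father = from_father != recomb
    pref = np.where(pref_from_father, father_alleles[:, LOCUS_PREF], mother_alleles[:, LOCUS_PREF])
    return np.stack([trait, pref], axis=1).astype(np.int8)


def step_generation(
    metapop: Metapopulation,
    params: SimParams,
    rng: np.random.Generator,
) -> Metapopulation:
    """Advance one non-overlapping generation: mate choice and
    reproduction within each subpopulation, then dispersal of the
    offspring, which fully replace the parents."""
    n_subpops = metapop.n_subpops
    k = metapop.males.shape[1]
    sons = np.empty_like(metapop.males)
    daughters = np.empty_like(metapop.females)
    mate = _mate_vectorized if params.perception == "male-frequency" else _mate_sequential
    for s in range(n_subpops):
        males = metapop.males[s]
        females = metapop.females[s]
        father_idx = mate(males, females, params, rng)
        fathers = males[father_idx]
        sons[s] = _offspring(females, fathers, params.r, rng)
        daughters[s] = _offspring(females, fathers, params.r, rng)
    if params.d > 0.0 and n_subpops > 1:
        sons = disperse(sons, params.d, rng)
        daughters = disperse(daughters, params.d, rng)
    new = Metapopulation(males=sons, females=daughters, generation=metapop.generation + 1)
    assert new.males.shape == (n_subpops, k, 2) and new.females.shape == (n_subpops, k, 2)
    return new


@dataclass
class SimResult:
    """Per-generation, per-subpopulation trajectory of one run.

    ``records`` columns: run_id, generation (1..generations), subpop,
    freq_A_males, freq_C_females, plus the diagnostic cov_trait_pref
    (within-subpopulation trait-preference covariance, both sexes
    pooled).
    """

    params: SimParams
    seed: int
    records: pd.DataFrame
    run_id: int = 0

    TIMESERIES_COLUMNS = ["run_id", "generation", "subpop", "freq_A_males", "freq_C_females"]

    def to_timeseries_csv(self, path) -> None:
        self.records[self.TIMESERIES_COLUMNS].to_csv(path, index=False)

    def final_state(self) -> pd.DataFrame:
        last = self.records["generation"].max()
        return self.records[self.records["generation"] == last]


def run_simulation(params: SimParams, run_id: int = 0) -> SimResult:
    """Initialize and iterate the life cycle for ``params.generations``
    generations; fully reproducible from (params, seed)."""
    rng = np.random.default_rng(params.seed)
    metapop = init_metapopulation(params, rng)
    n_rows = params.generations * params.n_subpops
    out = np.empty((n_rows, 5))
    subpop_ids = np.arange(params.n_subpops)
    row = 0
    for gen in range(1, params.generations + 1):
        metapop = step_generation(metapop, params, rng)
        sl = slice(row, row + params.n_subpops)
        out[sl, 0] = gen
        out[sl, 1] = subpop_ids
        out[sl, 2] = metapop.freq_A_males()
        out[sl, 3] = metapop.freq_C_females()
        out[sl, 4] = metapop.cov_trait_pref()
        row += params.n_subpops
    records = pd.DataFrame(
        out,
        columns=["generation", "subpop", "freq_A_males", "freq_C_females", "cov_trait_pref"],
    )
    records.insert(0, "run_id", run_id)
    records["generation"] = records["generation"].astype(int)
    records["subpop"] = records["subpop"].astype(int)
    return SimResult(params=params, seed=params.seed, records=records, run_id=run_id)


def summarize(result: SimResult) -> dict:
    """End-state summary of one run: final metapopulation C frequency
    (among females), final per-subpopulation A frequencies with their
    among-subpopulation variance (population variance, equal sizes), and
    the number of subpopulations still polymorphic for the display."""
    if len(result.records) == 0:
        raise DomainError("cannot summarize an empty simulation result")
    final = result.final_state()
    freq_a = final["freq_A_males"].to_numpy()
    return {
        "final_freq_C": float(final["freq_C_females"].mean()),
        "final_freq_A_by_subpop": freq_a.tolist(),
        "mean_final_freq_A": float(freq_a.mean()),
        "var_among_subpop_freq_A": float(freq_a.var()),
        "n_polymorphic_subpops": int(np.sum((freq_a > 0.0) & (freq_a < 1.0))),
    }


@dataclass
class SweepResult:
    """Per-(beta, d, replicate) end-state summaries of a parameter sweep.

    ``table`` columns: beta, d, replicate, seed, final_freq_C,
    mean_final_freq_A, var_among_subpop_freq_A, n_polymorphic_subpops.
    """

    table: pd.DataFrame
    base_params: SimParams
    base_seed: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def cell_means(self) -> pd.DataFrame:
        """Mean and median final C frequency per (beta, d) cell."""
        return (
            self.table.groupby(["beta", "d"])["final_freq_C"]
            .agg(["mean", "median"])
            .reset_index()
        )


def _replicate_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Counter-based derivation of an independent, reproducible stream
    seed for one replicate of one sweep cell (kept below 2**31)."""
    ss = np.random.SeedSequence(entropy=[int(base_seed), int(cell_index), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_sweep(
    betas: Sequence[float],
    ds: Sequence[float],
    replicates: int,
    base_params: SimParams,
    base_seed: int,
) -> SweepResult:
    """Run ``replicates`` independent simulations for every (beta, d)
    grid cell and summarize each end state."""
    if len(betas) == 0 or len(ds) == 0:
        raise DomainError("beta and d grids must be non-empty")
    if replicates < 1:
        raise DomainError(f"replicates must be >= 1, got {replicates}")
    rows = []
    for ci, (beta, d) in enumerate((b, dd) for b in betas for dd in ds):
        for rep in range(replicates):
            seed = _replicate_seed(base_seed, ci, rep)
            params = replace(base_params, beta=float(beta), d=float(d), seed=seed)
            summary = summarize(run_simulation(params, run_id=rep))
            rows.append({
                "beta": float(beta),
                "d": float(d),
                "replicate": rep,
                "seed": seed,
                "final_freq_C": summary["final_freq_C"],
                "mean_final_freq_A": summary["mean_final_freq_A"],
                "var_among_subpop_freq_A": summary["var_among_subpop_freq_A"],
                "n_polymorphic_subpops": summary["n_polymorphic_subpops"],
            })
    return SweepResult(table=pd.DataFrame(rows), base_params=base_params, base_seed=base_seed)
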