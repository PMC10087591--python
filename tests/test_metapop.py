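"""Tests for the two-locus metapopulation simulator."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from conformity import (
    DomainError,
    Individual,
    LogisticRule,
    SimParams,
    choose_mate,
    disperse,
    init_metapopulation,
    perceived_frequency,
    reproduce,
    run_simulation,
    run_sweep,
    step_generation,
    summarize,
)
from conformity.metapop import (
    LOCUS_PREF,
    LOCUS_TRAIT,
    PREF_C,
    PREF_c,
    TRAIT_A,
    TRAIT_B,
    SimResult,
    Subpopulation,
)

SMALL = SimParams(n_subpops=4, subpop_size=10, beta=2.8, d=0.1, q0=0.2,
                  generations=10, seed=1)


def make_subpop(male_traits, male_prefs=None):
    males = np.zeros((len(male_traits), 2), dtype=np.int8)
    males[:, LOCUS_TRAIT] = male_traits
    if male_prefs is not None:
        males[:, LOCUS_PREF] = male_prefs
    females = np.zeros((len(male_traits), 2), dtype=np.int8)
    return Subpopulation(males=males, females=females, id=0)


class TestParamsAndInit:
    def test_param_validation(self):
        with pytest.raises(DomainError):
            SimParams(subpop_size=7)  # odd
        with pytest.raises(DomainError):
            SimParams(d=1.5)
        with pytest.raises(DomainError):
            SimParams(r=0.7)
        with pytest.raises(DomainError):
            SimParams(perception="telepathy")

    def test_construction_contract(self):
        meta = init_metapopulation(SMALL)
        assert meta.males.shape == (4, 5, 2)
        assert meta.females.shape == (4, 5, 2)

    def test_q0_zero_means_no_conformists(self):
        meta = init_metapopulation(replace(SMALL, q0=0.0))
        assert meta.males[:, :, LOCUS_PREF].sum() == 0
        assert meta.females[:, :, LOCUS_PREF].sum() == 0

    def test_display_allocated_at_half(self):
        """Display alleles are i.i.d. Bernoulli(1/2) metapopulation-wide:
        the mean frequency over many independent foundings sits within
        binomial tolerance of 0.5."""
        params = replace(SMALL, n_subpops=2, subpop_size=10)
        freqs = []
        for seed in range(300):
            meta = init_metapopulation(replace(params, seed=seed))
            both = np.concatenate([meta.males, meta.females], axis=1)
            freqs.append(both[:, :, LOCUS_TRAIT].mean())
        n_draws = 300 * 20
        assert abs(np.mean(freqs) - 0.5) < 4 * np.sqrt(0.25 / n_draws)


class TestPerceivedFrequency:
    def test_male_frequency_counting(self):
        sp = make_subpop([1, 1, 1, 0, 0])
        assert perceived_frequency(sp, "male-frequency") == pytest.approx(0.6)
        assert perceived_frequency(make_subpop([1, 1]), "male-frequency") == 1.0

    def test_mating_observation_counting(self):
        sp = make_subpop([1, 1, 1, 0, 0])
        assert perceived_frequency(sp, "mating-observation",
                                   matings=[TRAIT_A, TRAIT_A, TRAIT_B]) == pytest.approx(2 / 3)
        # first chooser falls back to the standing male frequency
        assert perceived_frequency(sp, "mating-observation", matings=[]) == pytest.approx(0.6)

    def test_no_males_rejected(self):
        empty = Subpopulation(males=np.zeros((0, 2), np.int8),
                              females=np.zeros((3, 2), np.int8))
        with pytest.raises(DomainError):
            perceived_frequency(empty)


class TestChooseMate:
    def test_random_mater_is_uniform(self, rng):
        sp = make_subpop([1, 1, 0, 0, 0])
        female = Individual("female", TRAIT_A, PREF_c)
        n = 20_000
        counts = np.bincount(
            [choose_mate(female, sp, 0.4, LogisticRule(2.8), rng) for _ in range(n)],
            minlength=5,
        )
        assert np.all(np.abs(counts / n - 0.2) < 4 * np.sqrt(0.2 * 0.8 / n))

    def test_conformist_targets_majority_disproportionately(self, rng):
        """A conformist at q=0.6 under beta=2.8 ends up with an A male
        with probability ~0.7568 (the logistic rule value)."""
        sp = make_subpop([1, 1, 1, 0, 0])
        female = Individual("female", TRAIT_B, PREF_C)
        n = 100_000
        chosen_a = [
            sp.males[choose_mate(female, sp, 0.6, LogisticRule(2.8), rng), LOCUS_TRAIT]
            for _ in range(n)
        ]
        assert np.mean(chosen_a) == pytest.approx(0.7568, abs=0.006)

    def test_symmetry_point(self, rng):
        sp = make_subpop([1, 1, 0, 0])
        female = Individual("female", TRAIT_A, PREF_C)
        n = 20_000
        chosen_a = [
            sp.males[choose_mate(female, sp, 0.5, LogisticRule(5.0), rng), LOCUS_TRAIT]
            for _ in range(n)
        ]
        assert np.mean(chosen_a) == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / n))

    def test_fallback_when_target_absent(self, rng):
        sp = make_subpop([0, 0, 0])  # no A male
        female = Individual("female", TRAIT_A, PREF_C)
        idx = choose_mate(female, sp, 0.99, LogisticRule(10.0), rng)
        assert 0 <= idx < 3


class TestReproduce:
    def test_identical_parents_breed_true(self, rng):
        mother = Individual("female", TRAIT_A, PREF_C)
        father = Individual("male", TRAIT_A, PREF_C)
        for _ in range(50):
            son, daughter = reproduce(mother, father, r=0.5, rng=rng)
            assert (son.trait, son.pref) == (TRAIT_A, PREF_C)
            assert (daughter.trait, daughter.pref) == (TRAIT_A, PREF_C)
            assert (son.sex, daughter.sex) == ("male", "female")

    def test_no_recombination_preserves_haplotypes(self, rng):
        mother = Individual("female", TRAIT_B, PREF_C)
        father = Individual("male", TRAIT_A, PREF_c)
        for _ in range(200):
            son, _ = reproduce(mother, father, r=0.0, rng=rng)
            assert (son.trait, son.pref) in [(TRAIT_B, PREF_C), (TRAIT_A, PREF_c)]

    def test_transmission_distribution(self, rng):
        """Mother (B, C) x father (A, c) at r=0.2: parental haplotypes
        appear with probability 0.4 each, recombinants 0.1 each."""
        mother = Individual("female", TRAIT_B, PREF_C)
        father = Individual("male", TRAIT_A, PREF_c)
        n = 50_000
        counts = {(TRAIT_B, PREF_C): 0, (TRAIT_A, PREF_c): 0,
                  (TRAIT_B, PREF_c): 0, (TRAIT_A, PREF_C): 0}
        for _ in range(n):
            son, _ = reproduce(mother, father, r=0.2, rng=rng)
            counts[(son.trait, son.pref)] += 1
        for hap, p in [((TRAIT_B, PREF_C), 0.4), ((TRAIT_A, PREF_c), 0.4),
                       ((TRAIT_B, PREF_c), 0.1), ((TRAIT_A, PREF_C), 0.1)]:
            assert counts[hap] / n == pytest.approx(p, abs=4 * np.sqrt(p * (1 - p) / n))

    def test_sex_mismatch_rejected(self, rng):
        male = Individual("male", TRAIT_A, PREF_c)
        with pytest.raises(DomainError):
            reproduce(male, male, r=0.2, rng=rng)


class TestDisperse:
    def test_no_dispersal_is_identity(self, rng):
        pool = rng.integers(0, 2, size=(3, 4, 2)).astype(np.int8)
        out = disperse(pool, 0.0, rng)
        assert np.array_equal(out, pool)

    def test_full_dispersal_conserves_alleles(self, rng):
        pool = rng.integers(0, 2, size=(2, 6, 2)).astype(np.int8)
        out = disperse(pool, 1.0, rng)
        assert out.shape == pool.shape
        # the multiset of haplotypes is conserved exactly
        a = sorted(map(tuple, pool.reshape(-1, 2)))
        b = sorted(map(tuple, out.reshape(-1, 2)))
        assert a == b

    def test_migrant_count_is_binomial(self, rng):
        """With d=0.02 in a 20x50 metapopulation (one sex = 500 slots),
        the expected number of flagged migrants is 10 per pool."""
        pool = np.arange(20 * 25 * 2, dtype=np.int32).reshape(20, 25, 2)
        moved = []
        for _ in range(300):
            out = disperse(pool, 0.02, rng)
            moved.append(np.sum(np.any(out != pool, axis=2)))
        # moved counts slightly undershoot flagged counts (a migrant can
        # return to its own slot), so allow a generous band around 10
        assert 8.0 < np.mean(moved) < 11.0


class TestLifeCycle:
    def test_population_size_and_sex_ratio_conserved(self, rng):
        meta = init_metapopulation(SMALL)
        for _ in range(10):
            meta = step_generation(meta, SMALL, rng)
            meta.check_invariants(SMALL)

    def test_absorbing_states(self, rng):
        """Allele frequencies of 0 or 1 metapopulation-wide are closed
        under the life cycle."""
        params = replace(SMALL, q0=0.0, generations=20)
        result = run_simulation(params)
        assert (result.records["freq_C_females"] == 0.0).all()

        meta = init_metapopulation(SMALL)
        meta.males[:, :, LOCUS_TRAIT] = TRAIT_A
        meta.females[:, :, LOCUS_TRAIT] = TRAIT_A
        for _ in range(10):
            meta = step_generation(meta, SMALL, rng)
        assert (meta.freq_A_males() == 1.0).all()

    def test_determinism(self):
        r1 = run_simulation(SMALL)
        r2 = run_simulation(SMALL)
        pd.testing.assert_frame_equal(r1.records, r2.records)

    def test_mating_observation_mode_runs_and_conserves(self):
        params = replace(SMALL, perception="mating-observation", generations=5)
        result = run_simulation(params)
        assert len(result.records) == 5 * params.n_subpops
        assert result.records["freq_A_males"].between(0, 1).all()

    def test_record_shape(self):
        result = run_simulation(SMALL)
        assert len(result.records) == SMALL.generations * SMALL.n_subpops
        assert result.records["generation"].max() == SMALL.generations


class TestSummarize:
    @staticmethod
    def result_from_final(freq_a_list, freq_c_list):
        rows = [
            {"run_id": 0, "generation": 1, "subpop": i, "freq_A_males": fa,
             "freq_C_females": fc, "cov_trait_pref": 0.0}
            for i, (fa, fc) in enumerate(zip(freq_a_list, freq_c_list))
        ]
        return SimResult(params=SMALL, seed=0, records=pd.DataFrame(rows))

    def test_single_fixed_subpop(self):
        s = summarize(self.result_from_final([1.0], [0.3]))
        assert s["var_among_subpop_freq_A"] == 0.0
        assert s["n_polymorphic_subpops"] == 0

    def test_two_opposite_fixations(self):
        s = summarize(self.result_from_final([0.0, 1.0], [0.2, 0.4]))
        assert s["var_among_subpop_freq_A"] == pytest.approx(0.25)
        assert s["n_polymorphic_subpops"] == 0
        assert s["final_freq_C"] == pytest.approx(0.3)

    def test_empty_result_rejected(self):
        empty = SimResult(params=SMALL, seed=0, records=pd.DataFrame(
            columns=["run_id", "generation", "subpop", "freq_A_males",
                     "freq_C_females", "cov_trait_pref"]))
        with pytest.raises(DomainError):
            summarize(empty)


class TestRunawayDynamics:
    def test_statistical_linkage_with_local_majority(self):
        """Assortative mating by conformist females builds a positive
        within-subpopulation covariance between the conformity allele
        and the *locally common* display allele before fixation, despite
        the loci being physically unlinked (r = 0.2)."""
        base = replace(SMALL, n_subpops=10, subpop_size=20, d=0.02, generations=25)
        pooled = []
        for rep in range(100):
            rec = run_simulation(replace(base, seed=5000 + rep)).records
            m = rec[
                rec["generation"].between(2, 25)
                & rec["freq_A_males"].between(0, 1, inclusive="neither")
                & (rec["freq_A_males"] != 0.5)
                & rec["freq_C_females"].between(0, 1, inclusive="neither")
            ]
            aligned = m["cov_trait_pref"] * np.sign(m["freq_A_males"] - 0.5)
            pooled.extend(aligned.tolist())
        pooled = np.array(pooled)
        se = pooled.std() / np.sqrt(len(pooled))
        assert pooled.mean() > 2 * se

    def test_conformity_neutral_after_display_fixation(self):
        """Once one display allele is globally fixed there is nothing
        left to conform to: the subsequent change in C frequency has
        mean zero within Monte-Carlo tolerance."""
        deltas = []
        for rep in range(60):
            params = SimParams(n_subpops=1, subpop_size=100, beta=2.8, d=0.0,
                               q0=0.3, r=0.2, generations=100, seed=6000 + rep)
            rec = run_simulation(params).records
            fixed = rec[rec["freq_A_males"].isin([0.0, 1.0])]
            if fixed.empty:
                continue
            g = fixed["generation"].iloc[0]
            c_at_fix = rec.loc[rec["generation"] == g, "freq_C_females"].iloc[0]
            c_final = rec.loc[rec["generation"] == rec["generation"].max(),
                              "freq_C_females"].iloc[0]
            deltas.append(c_final - c_at_fix)
        deltas = np.array(deltas)
        assert len(deltas) >= 30
        se = deltas.std() / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 4 * se


class TestSweep:
    def test_bookkeeping_and_reproducibility(self):
        base = replace(SMALL, generations=5)
        s1 = run_sweep([2.8], [0.1], replicates=3, base_params=base, base_seed=42)
        s2 = run_sweep([2.8], [0.1], replicates=3, base_params=base, base_seed=42)
        assert len(s1.table) == 3
        assert s1.table["seed"].nunique() == 3
        assert (s1.table["seed"] < 2**31).all()
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_empty_grid_rejected(self):
        with pytest.raises(DomainError):
            run_sweep([], [0.1], 1, SMALL, 0)
        with pytest.raises(DomainError):
            run_sweep([2.8], [0.1], 0, SMALL, 0)
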