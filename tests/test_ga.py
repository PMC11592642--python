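import numpy as np
import pytest

from icroc.classify import evaluate_classifier
from icroc.ga import (
    Chromosome,
    GAConfig,
    _DYNAMIC_CYCLE,
    crossover,
    fitness,
    ga1_config,
    ga2_config,
    init_population,
    intersect_masks,
    mutate,
    run_ga,
    select_parents,
)


class TestConfig:
    def test_stock_variants(self):
        g1, g2 = ga1_config(), ga2_config()
        assert (g1.crossover_prob, g1.mutation_prob, g1.scheme) == (0.8, 0.3, "fixed")
        assert (g2.crossover_prob, g2.mutation_prob, g2.scheme) == (0.6, 0.001, "dynamic")
        assert g1.generations == g2.generations == 50
        assert g1.pop_size == g2.pop_size == 100

    def test_invalid_probability_raises(self):
        with pytest.raises(ValueError):
            GAConfig(mutation_prob=1.5)


class TestInitPopulation:
    def test_reproducible_and_repaired(self):
        cfg = GAConfig(pop_size=50, seed=4)
        a = init_population(10, cfg)
        b = init_population(10, cfg)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.mask, cb.mask)
        assert all(c.mask.any() for c in a)

    def test_bit_frequency_near_half(self):
        cfg = GAConfig(pop_size=400, seed=0)
        pop = init_population(20, cfg)
        freq = np.mean([c.mask for c in pop])
        assert abs(freq - 0.5) < 0.03  # ~4 sigma for 8000 Bernoulli(0.5) bits


class TestFitness:
    def test_full_mask_matches_direct_evaluation(self, small_planted_table):
        cfg = GAConfig(seed=0)  # default objective: negated CV AUC
        chrom = Chromosome(np.ones(small_planted_table.d, bool))
        direct = evaluate_classifier(small_planted_table, cfg.classifier, seed=0)
        assert fitness(chrom, small_planted_table, cfg) == pytest.approx(-direct.auc)

    def test_deterministic(self, small_planted_table):
        cfg = GAConfig(seed=1)
        chrom = Chromosome(np.array([True] * 4 + [False] * 8))
        assert fitness(chrom, small_planted_table, cfg) == fitness(
            chrom, small_planted_table, cfg
        )

    def test_informative_mask_beats_noise_mask(self):
        from icroc.synth import SyntheticTableSpec, make_feature_table

        cfg = GAConfig(seed=0)
        wins = 0
        for s in range(10):
            table = make_feature_table(
                SyntheticTableSpec(n_instances=250, n_features=10, n_informative=3, seed=500 + s)
            )
            info = Chromosome(np.array([True] * 3 + [False] * 7))
            noise = Chromosome(np.array([False] * 3 + [True] * 7))
            wins += fitness(info, table, cfg) < fitness(noise, table, cfg)
        assert wins >= 9

    def test_empty_mask_rejected(self, small_planted_table):
        with pytest.raises(ValueError):
            fitness(Chromosome(np.zeros(12, bool)), small_planted_table, GAConfig())


class TestSelection:
    @staticmethod
    def _pop(fitnesses):
        pop = [Chromosome(np.ones(3, bool)) for _ in fitnesses]
        for c, f in zip(pop, fitnesses):
            c.fitness = f
        return pop

    def test_uniform_fitness_gives_uniform_selection(self):
        pop = self._pop([1.0] * 4)
        rng = np.random.default_rng(0)
        picks = np.zeros(4)
        pairs = select_parents(pop, rng, 5000)
        for a, b in pairs:
            picks[pop.index(a)] += 1
            picks[pop.index(b)] += 1
        freq = picks / picks.sum()
        assert np.all(np.abs(freq - 0.25) < 0.02)

    def test_best_has_highest_selection_frequency(self):
        pop = self._pop([5.0, -2.0, 1.0, 9.0])  # index 1 is best (minimization)
        rng = np.random.default_rng(1)
        picks = np.zeros(4)
        for a, b in select_parents(pop, rng, 5000):
            picks[pop.index(a)] += 1
            picks[pop.index(b)] += 1
        assert picks.argmax() == 1

    def test_frequencies_match_rank_weights(self):
        pop = self._pop([3.0, 1.0, 2.0])  # ranks: best=idx1, then idx2, idx0
        rng = np.random.default_rng(2)
        picks = np.zeros(3)
        n_pairs = 20000
        for a, b in select_parents(pop, rng, n_pairs):
            picks[pop.index(a)] += 1
            picks[pop.index(b)] += 1
        expected = np.array([1, 3, 2]) / 6
        freq = picks / (2 * n_pairs)
        assert np.all(np.abs(freq - expected) < 3 * np.sqrt(expected * (1 - expected) / (2 * n_pairs)) + 0.01)

    def test_unevaluated_population_raises(self):
        pop = [Chromosome(np.ones(3, bool))]
        with pytest.raises(ValueError):
            select_parents(pop, np.random.default_rng(0), 1)


class TestVariation:
    def test_zero_crossover_prob_copies_parents(self):
        cfg = GAConfig(crossover_prob=0.0)
        a = Chromosome(np.array([True, True, False, False]))
        b = Chromosome(np.array([False, True, True, True]))
        c, d = crossover((a, b), cfg, 0, np.random.default_rng(0))
        np.testing.assert_array_equal(c.mask, a.mask)
        np.testing.assert_array_equal(d.mask, b.mask)

    def test_single_point_structure(self):
        cfg = GAConfig(crossover_prob=1.0, scheme="fixed")
        ones = Chromosome(np.ones(8, bool))
        zeros = Chromosome(np.zeros(8, bool))
        c, d = crossover((ones, zeros), cfg, 0, np.random.default_rng(3))
        # offspring are 1...10...0 and its complement
        flips_c = np.flatnonzero(np.diff(c.mask.astype(int)))
        assert flips_c.size == 1 and c.mask[0] and not c.mask[-1]
        np.testing.assert_array_equal(c.mask, ~d.mask)

    def test_dynamic_cycle_uses_three_operators(self):
        assert len({op.__name__ for op in _DYNAMIC_CYCLE}) == 3
        cfg = GAConfig(crossover_prob=1.0, scheme="dynamic")
        ones = Chromosome(np.ones(12, bool))
        zeros = Chromosome(np.zeros(12, bool))
        # generation 1 -> two-point: contiguous swapped window inside ones
        c, _ = crossover((ones, zeros), cfg, 1, np.random.default_rng(0))
        runs = np.flatnonzero(np.diff(c.mask.astype(int)))
        assert runs.size <= 2
        # generation 2 -> uniform: complementary offspring again
        c, d = crossover((ones, zeros), cfg, 2, np.random.default_rng(0))
        np.testing.assert_array_equal(c.mask, ~d.mask)

    def test_mutation_extremes(self):
        chrom = Chromosome(np.array([True, False, True, False]))
        rng = np.random.default_rng(0)
        same = mutate(chrom, GAConfig(mutation_prob=0.0), rng)
        np.testing.assert_array_equal(same.mask, chrom.mask)
        flipped = mutate(chrom, GAConfig(mutation_prob=1.0), rng)
        np.testing.assert_array_equal(flipped.mask, ~chrom.mask)

    def test_mutation_flip_rate(self):
        rng = np.random.default_rng(5)
        cfg = GAConfig(mutation_prob=0.3)
        base = Chromosome(np.zeros(50, bool))
        flips = [mutate(base, cfg, rng).mask.sum() for _ in range(200)]
        assert np.mean(flips) == pytest.approx(15.0, abs=1.0)

    def test_all_zero_mutation_repaired(self):
        chrom = Chromosome(np.array([True, False]))
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert mutate(chrom, GAConfig(mutation_prob=1.0), rng).mask.any()


class TestRunGA:
    def test_single_generation_and_monotone_trace(self, small_planted_table):
        cfg = ga1_config(generations=1, pop_size=8, seed=0)
        result = run_ga(small_planted_table, cfg)
        assert result.best_fitness_trace.size == 2
        cfg = ga1_config(generations=5, pop_size=10, seed=1)
        result = run_ga(small_planted_table, cfg)
        assert np.all(np.diff(result.best_fitness_trace) <= 0)
        assert result.best_mask.any()

    def test_reproducible(self, small_planted_table):
        cfg = ga2_config(generations=3, pop_size=8, seed=9)
        a = run_ga(small_planted_table, cfg)
        b = run_ga(small_planted_table, cfg)
        np.testing.assert_array_equal(a.best_mask, b.best_mask)
        np.testing.assert_array_equal(a.best_fitness_trace, b.best_fitness_trace)


class TestIntersection:
    def test_bitwise_and(self):
        m1 = Chromosome(np.array([True, True, False, False]))
        m2 = Chromosome(np.array([True, False, True, False]))
        both, empty = intersect_masks(m1, m2)
        np.testing.assert_array_equal(both.mask, [True, False, False, False])
        assert not empty

    def test_idempotent(self):
        m = Chromosome(np.array([True, False, True]))
        both, _ = intersect_masks(m, m)
        np.testing.assert_array_equal(both.mask, m.mask)

    def test_disjoint_masks_flagged_empty(self):
        m1 = Chromosome(np.array([True, False]))
        m2 = Chromosome(np.array([False, True]))
        both, empty = intersect_masks(m1, m2)
        assert empty and not both.mask.any()

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            intersect_masks(Chromosome(np.ones(2, bool)), Chromosome(np.ones(3, bool)))
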