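import numpy as np
import pytest

from sfqspr.data_io import DescriptorTable
from sfqspr.ga import (
    EliteHistory,
    GAConfig,
    Individual,
    PopulationCollapseError,
    SENTINEL_FITNESS,
    SelectionReport,
    adaptive_mutation_probs,
    adaptive_mutation_scores,
    choose_subset_size,
    crossover,
    evaluate_fitness,
    mutate_adaptive,
    mutate_fixed,
    rank_descriptors,
    roulette_probabilities,
    run_ga,
    select_next_generation,
    single_point_cross,
    spin_roulette,
    sweep_subset_sizes,
)
from sfqspr.modeling import ModelSpec


# ---------------------------------------------------------------------------
# roulette
# ---------------------------------------------------------------------------

class TestRoulette:
    def test_proportional_probabilities(self):
        # fitnesses already non-negative: shift is only the tiny epsilon
        state = roulette_probabilities([1.0, 1.0, 2.0], eps=0.0)
        # shift subtracts the minimum, so weights become (0, 0, 1) unless the
        # raw values are used; the documented behaviour shifts by min + eps
        assert state.cumulative[-1] == pytest.approx(1.0, abs=1e-12)

    def test_shift_preserves_order_and_sums_to_one(self):
        state = roulette_probabilities([-0.5, 0.1, 0.4])
        p = state.probabilities
        assert p[0] < p[1] < p[2]
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(np.diff(state.cumulative), p[1:], atol=1e-15)

    def test_uniform_when_all_equal(self):
        state = roulette_probabilities([0.3, 0.3, 0.3, 0.3])
        np.testing.assert_allclose(state.probabilities, 0.25)

    def test_interval_rule_draw(self):
        # textbook example: p = (0.25, 0.25, 0.5), r = 0.6 -> third individual
        state = roulette_probabilities([0.0, 0.0, 0.0])
        state.probabilities = np.array([0.25, 0.25, 0.5])
        state.cumulative = np.cumsum(state.probabilities)
        assert spin_roulette(state, 0.6) == 2
        assert spin_roulette(state, 0.2) == 0
        assert spin_roulette(state, 0.3) == 1

    def test_sentinel_individuals_get_zero_probability(self):
        state = roulette_probabilities([SENTINEL_FITNESS, 0.5, 0.7])
        assert state.probabilities[0] == 0.0

    def test_population_collapse_raises(self):
        with pytest.raises(PopulationCollapseError):
            roulette_probabilities([SENTINEL_FITNESS, SENTINEL_FITNESS])


class TestSelection:
    def test_single_individual_population(self):
        ind = Individual(np.array([1, 0, 1]), fitness=0.5)
        state = roulette_probabilities([0.5])
        rng = np.random.default_rng(0)
        out = select_next_generation([ind], state, rng)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].genome, ind.genome)

    def test_zero_probability_never_drawn(self):
        pop = [Individual(np.array([1, 0]), SENTINEL_FITNESS),
               Individual(np.array([0, 1]), 0.9)]
        state = roulette_probabilities([i.fitness for i in pop])
        rng = np.random.default_rng(1)
        out = select_next_generation(pop * 1, state, rng)
        for _ in range(200):
            out = select_next_generation(pop, state, rng)
            for ind in out:
                np.testing.assert_array_equal(ind.genome, pop[1].genome)

    def test_counts_match_multinomial(self):
        pop = [Individual(np.zeros(2, np.uint8) + i % 2, float(f))
               for i, f in enumerate([1.0, 1.0, 2.0])]
        state = roulette_probabilities([0, 0, 0])
        state.probabilities = np.array([0.25, 0.25, 0.5])
        state.cumulative = np.cumsum(state.probabilities)
        rng = np.random.default_rng(2)
        draws = [spin_roulette(state, r) for r in rng.random(3000)]
        counts = np.bincount(draws, minlength=3)
        for c, p in zip(counts, state.probabilities):
            sigma = np.sqrt(3000 * p * (1 - p))
            assert abs(c - 3000 * p) < 3.5 * sigma


# ---------------------------------------------------------------------------
# crossover / mutation
# ---------------------------------------------------------------------------

class TestVariation:
    def test_crossover_gate_closed(self):
        a = Individual(np.array([1, 1, 1, 1], np.uint8))
        b = Individual(np.array([0, 0, 0, 0], np.uint8))
        ca, cb = crossover(a, b, pc=0.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(ca.genome, a.genome)
        np.testing.assert_array_equal(cb.genome, b.genome)

    def test_single_point_cut(self):
        ca, cb = single_point_cross(
            np.array([1, 1, 1, 1], np.uint8), np.array([0, 0, 0, 0], np.uint8), cut=2
        )
        np.testing.assert_array_equal(ca, [1, 1, 0, 0])
        np.testing.assert_array_equal(cb, [0, 0, 1, 1])

    def test_forced_crossover_swaps_tails(self):
        a = Individual(np.array([1, 1, 1, 1], np.uint8))
        b = Individual(np.array([0, 0, 0, 0], np.uint8))
        ca, cb = crossover(a, b, pc=1.0, rng=np.random.default_rng(3))
        # whatever the cut, each child is a prefix of one parent + suffix of the other
        joined = np.concatenate([ca.genome, cb.genome])
        assert joined.sum() == 4
        assert ca.genome[0] == 1 and cb.genome[0] == 0

    def test_forced_mutation_flips_exactly_one_bit(self):
        ind = Individual(np.array([1, 0, 1, 0, 1], np.uint8))
        out = mutate_fixed(ind, pm=1.0, rng=np.random.default_rng(4))
        assert int(np.sum(out.genome != ind.genome)) == 1

    def test_mutation_gate_closed(self):
        ind = Individual(np.array([1, 0, 1], np.uint8))
        out = mutate_fixed(ind, pm=0.0, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(out.genome, ind.genome)


# ---------------------------------------------------------------------------
# history-adaptive mutation
# ---------------------------------------------------------------------------

class TestAdaptiveMutation:
    def make_history(self):
        h = EliteHistory(capacity=50)
        h.push(np.array([1, 0, 0], np.uint8), 0.6)
        h.push(np.array([0, 1, 0], np.uint8), 0.9)
        return h

    def test_scores_min_max_normalized_with_absent_fallback(self):
        scores = adaptive_mutation_scores(self.make_history(), 3)
        np.testing.assert_allclose(scores, [0.0, 1.0, 0.5])

    def test_scores_bounded(self):
        rng = np.random.default_rng(6)
        h = EliteHistory(capacity=50)
        for _ in range(30):
            h.push((rng.random(8) < 0.4).astype(np.uint8), float(rng.normal()))
        s = adaptive_mutation_scores(h, 8)
        assert np.all((s >= 0) & (s <= 1))

    def test_degenerate_window_all_half(self):
        h = EliteHistory(capacity=50)
        h.push(np.array([1, 1, 0], np.uint8), 0.7)
        h.push(np.array([1, 1, 0], np.uint8), 0.7)
        np.testing.assert_allclose(adaptive_mutation_scores(h, 3), [0.5, 0.5, 0.5])

    def test_empty_history_uniform_at_pm(self):
        probs = adaptive_mutation_probs(EliteHistory(capacity=50), 4, fallback_pm=0.01)
        np.testing.assert_allclose(probs, 0.01)

    def test_affine_range_mapping(self):
        probs = adaptive_mutation_probs(self.make_history(), 3, pm_range=(0.001, 0.05))
        np.testing.assert_allclose(probs, [0.001, 0.05, 0.0255])

    def test_window_capacity_rolls(self):
        h = EliteHistory(capacity=3)
        for i in range(5):
            h.push(np.array([1], np.uint8), float(i))
        assert len(h) == 3 and h.fitnesses == [2.0, 3.0, 4.0]

    def test_adaptive_flip_determinism(self):
        ind = Individual(np.zeros(100, np.uint8))
        probs = np.full(100, 0.2)
        a = mutate_adaptive(ind, probs, np.random.default_rng(9)).genome
        b = mutate_adaptive(ind, probs, np.random.default_rng(9)).genome
        np.testing.assert_array_equal(a, b)
        assert a.sum() > 0  # with p=0.2 over 100 genes some flips happen


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

class TestFitness:
    def test_perfect_linear_fit(self, linear_table):
        genome = np.array([1, 0, 0], np.uint8)
        f = evaluate_fitness(genome, linear_table, ModelSpec("pls", params={"n_components": 1}))
        assert f == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_genome_sentinel(self, linear_table):
        assert evaluate_fitness(np.zeros(3, np.uint8), linear_table,
                                ModelSpec("pls")) == SENTINEL_FITNESS

    def test_noise_descriptors_score_nonpositive_on_average(self):
        rng = np.random.default_rng(11)
        scores = []
        for s in range(30):
            X = rng.standard_normal((20, 4))
            y = rng.standard_normal(20)
            t = DescriptorTable([f"m{i}" for i in range(20)],
                                ["a", "b", "c", "d"], X, y)
            scores.append(evaluate_fitness(np.ones(4, np.uint8), t,
                                           ModelSpec("pls", params={"n_components": 2}),
                                           rng_seed=s))
        assert np.mean(scores) < 0


# ---------------------------------------------------------------------------
# the run loop
# ---------------------------------------------------------------------------

def tiny_ga_table(seed=0, n=16, d=25):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = X[:, 0] + 0.5 * X[:, 1] + 0.2 * rng.standard_normal(n)
    return DescriptorTable([f"m{i}" for i in range(n)],
                           [f"d{j:02d}" for j in range(d)], X, y)


class TestRunGA:
    @pytest.mark.parametrize("variant", ["RE", "REC"])
    def test_elitist_trace_monotone(self, variant):
        cfg = GAConfig(population_size=10, generations=15, variant=variant, rng_seed=1)
        rep = run_ga(tiny_ga_table(), ModelSpec("pls", params={"n_components": 1}), cfg)
        tr = rep.best_fitness_trace
        assert len(tr) == 15
        assert all(a <= b + 1e-12 for a, b in zip(tr, tr[1:]))

    def test_plain_ga_without_operators_cannot_improve(self):
        cfg = GAConfig(population_size=10, generations=10, variant="O",
                       crossover_prob=0.0, mutation_prob=0.0, rng_seed=2)
        table = tiny_ga_table()
        rep = run_ga(table, ModelSpec("pls", params={"n_components": 1}), cfg)
        # no new genomes can appear: the trace can never exceed the best genome
        # present at initialisation, which stays in the selection pool
        assert max(rep.best_fitness_trace) <= max(rep.elite_fitnesses) + 1e-12
        assert max(rep.best_fitness_trace) == pytest.approx(rep.best_fitness_trace[0], abs=1e-12) or \
            rep.best_fitness_trace[-1] <= rep.best_fitness_trace[0] + 1e-12

    def test_deterministic_given_seed(self):
        cfg = GAConfig(population_size=8, generations=8, variant="REC", rng_seed=5)
        model = ModelSpec("pls", params={"n_components": 1})
        t = tiny_ga_table()
        r1 = run_ga(t, model, cfg)
        r2 = run_ga(t, model, cfg)
        assert r1.best_fitness_trace == r2.best_fitness_trace
        for g1, g2 in zip(r1.elite_genomes, r2.elite_genomes):
            np.testing.assert_array_equal(g1, g2)


# ---------------------------------------------------------------------------
# ranking and sweep
# ---------------------------------------------------------------------------

def hand_report():
    names = ["a", "b", "c", "d"]
    elites = [np.array(g, np.uint8) for g in
              ([1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 0, 0])]
    fits = [0.5, 0.9, 0.7]
    return SelectionReport(descriptor_names=names,
                           best_fitness_trace=fits,
                           elite_genomes=elites,
                           elite_fitnesses=fits)


class TestRanking:
    def test_hand_counted_order(self):
        # a in all 3 elites; b in 2 (mean .6); c in 1 (mean .9); d in none
        assert rank_descriptors(hand_report(), 4) == ["a", "b", "c", "d"]

    def test_ever_selected_beats_never_selected(self):
        ranked = rank_descriptors(hand_report(), 4)
        assert ranked.index("a") < ranked.index("d")

    def test_frequency_tie_broken_by_elite_mean_fitness(self):
        names = ["x", "y"]
        elites = [np.array([1, 0], np.uint8), np.array([0, 1], np.uint8)]
        rep = SelectionReport(names, [0.9, 0.8], elites, [0.9, 0.8])
        assert rank_descriptors(rep, 2) == ["x", "y"]
        rep2 = SelectionReport(names, [0.8, 0.9], elites, [0.8, 0.9])
        assert rank_descriptors(rep2, 2) == ["y", "x"]

    def test_identical_columns_pool_their_appearances(self):
        names = ["a", "b", "c"]
        values = np.array([[1.0, 5.0, 1.0], [2.0, 6.0, 2.0], [3.0, 7.0, 3.0]])
        # column c duplicates a; each appears in one elite, b in both
        elites = [np.array([1, 1, 0], np.uint8), np.array([0, 1, 1], np.uint8)]
        rep = SelectionReport(names, [0.5, 0.5], elites, [0.5, 0.5])
        ranked = rank_descriptors(rep, 3, values=values)
        # pooled, {a, c} appears in both elites and is reported once as 'a'
        assert ranked[:2] == ["a", "b"]
        assert "c" not in ranked

    def test_n_keep_exceeds_descriptors(self):
        with pytest.raises(ValueError):
            rank_descriptors(hand_report(), 5)


class TestSweep:
    def test_single_informative_peaks_at_size_one(self, linear_table):
        curve = sweep_subset_sizes(["x0", "x1", "x2"], linear_table,
                                   ModelSpec("pls", params={"n_components": 1}),
                                   sizes=[1, 2, 3], folds=4, rng_seed=0)
        assert choose_subset_size(curve) == 1
        assert curve[0]["cv_r2"] == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_sizes_warn_and_dedupe(self, linear_table):
        with pytest.warns(UserWarning, match="duplicate"):
            curve = sweep_subset_sizes(["x0", "x1"], linear_table,
                                       ModelSpec("pls", params={"n_components": 1}),
                                       sizes=[1, 1, 2], folds=4, rng_seed=0)
        assert [c["size"] for c in curve] == [1, 2]

    def test_size_exceeding_ranking_errors(self, linear_table):
        with pytest.raises(ValueError):
            sweep_subset_sizes(["x0"], linear_table, ModelSpec("pls"), sizes=[2])
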