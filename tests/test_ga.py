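"""Sparsity-constrained GA operators, fitness, and the scan driver."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lyapnet as ln
from lyapnet.ga import (
    CandidateSolution,
    GAConfig,
    PriorMask,
    create_individual,
    crossover,
    default_lambda_grid,
    evaluate_fitness,
    lambda_scan,
    mutate,
    run_ga,
)


def sparsity(bits):
    return 1.0 - bits.sum() / bits.size


class TestCreateIndividual:
    def test_min_sparsity_by_construction(self):
        cfg = GAConfig(min_sparsity=0.5)
        rng = np.random.default_rng(0)
        for _ in range(200):
            bits = create_individual(4, cfg, rng=rng)
            assert bits.sum() <= 8  # at most half of the 16 positions
            assert bits.sum() >= 1

    def test_zero_min_sparsity_admits_all_ones(self):
        cfg = GAConfig(min_sparsity=0.0)
        rng = np.random.default_rng(1)
        counts = {int(create_individual(2, cfg, rng=rng).sum()) for _ in range(500)}
        assert 4 in counts  # the complete digraph is reachable

    def test_mask_positions_respected(self):
        cfg = GAConfig(min_sparsity=0.5)
        mask = PriorMask(known_zero=frozenset({3}), known_nonzero=frozenset({0}))
        rng = np.random.default_rng(2)
        for _ in range(1000):
            bits = create_individual(3, cfg, mask, rng)
            assert not bits[3]
            assert bits[0]

    def test_infeasible_mask_rejected(self):
        cfg = GAConfig(min_sparsity=0.5)
        mask = PriorMask(known_nonzero=frozenset(range(9)))  # 9 forced > 8 allowed
        with pytest.raises(ValueError):
            create_individual(4, cfg, mask, np.random.default_rng(0))

    @given(st.integers(0, 10_000))
    def test_popcount_within_feasible_range(self, seed):
        cfg = GAConfig(min_sparsity=0.5)
        bits = create_individual(5, cfg, rng=np.random.default_rng(seed))
        assert 1 <= bits.sum() <= 12


class TestCrossoverAndMutate:
    cfg = GAConfig(min_sparsity=0.5)

    def test_identical_parents_identical_children(self):
        rng = np.random.default_rng(0)
        p = create_individual(4, self.cfg, rng=rng)
        ca, cb = crossover(p, p, self.cfg, rng=rng)
        np.testing.assert_array_equal(ca, p)
        np.testing.assert_array_equal(cb, p)

    def test_children_repaired_to_min_sparsity(self):
        """Parents at exactly the sparsity boundary, 1,000 random pairs:
        no child ever violates the constraint."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            pa = np.zeros(16, bool)
            pa[rng.choice(16, 8, replace=False)] = True
            pb = np.zeros(16, bool)
            pb[rng.choice(16, 8, replace=False)] = True
            ca, cb = crossover(pa, pb, self.cfg, rng=rng)
            assert sparsity(ca) >= 0.5 and sparsity(cb) >= 0.5

    def test_child_bits_from_parents_when_no_repair(self):
        cfg = GAConfig(min_sparsity=0.0)
        rng = np.random.default_rng(2)
        pa = rng.random(25) < 0.4
        pb = rng.random(25) < 0.4
        ca, cb = crossover(pa, pb, cfg, rng=rng)
        agree = (ca == pa) | (ca == pb)
        assert agree.all()
        agree_b = (cb == pa) | (cb == pb)
        assert agree_b.all()

    def test_masked_zero_stays_zero_in_children(self):
        mask = PriorMask(known_zero=frozenset({5, 6}))
        rng = np.random.default_rng(3)
        for _ in range(200):
            pa = create_individual(4, self.cfg, mask, rng)
            pb = create_individual(4, self.cfg, mask, rng)
            ca, cb = crossover(pa, pb, self.cfg, mask, rng)
            assert not ca[5] and not ca[6] and not cb[5] and not cb[6]

    def test_zero_mutation_rate_is_identity(self):
        cfg = GAConfig(mutation_rate=0.0)
        rng = np.random.default_rng(4)
        p = create_individual(4, cfg, rng=rng)
        np.testing.assert_array_equal(mutate(p, cfg, rng=rng), p)

    def test_mean_flip_fraction_matches_rate(self):
        """Monte-Carlo estimate of the realized flip rate on a half-dense
        individual stays within 0.05 ± 0.005."""
        cfg = GAConfig(min_sparsity=0.5, mutation_rate=0.05)
        rng = np.random.default_rng(5)
        L = 400
        base = np.zeros(L, bool)
        base[rng.choice(L, 200, replace=False)] = True
        flips = 0
        trials = 10_000
        for _ in range(trials):
            out = mutate(base, cfg, rng=rng)
            flips += int((out != base).sum())
        assert abs(flips / (trials * L) - 0.05) < 0.005

    def test_mutation_never_violates_constraint(self):
        cfg = GAConfig(min_sparsity=0.5, mutation_rate=0.2)
        rng = np.random.default_rng(6)
        base = np.zeros(36, bool)
        base[rng.choice(36, 18, replace=False)] = True
        current = base
        for _ in range(10_000):
            current = mutate(current, cfg, rng=rng)
            assert sparsity(current) >= 0.5


class TestFitness:
    def test_dual_objective_arithmetic(self, exact_system5):
        sys, J, _ = exact_system5
        # zero_count=100, lambda=0.05, residual=1e-6 -> f = 5 + 6 = 11
        sol = CandidateSolution(
            structure=np.zeros(1, bool), zero_count=100, j_values=np.empty(0),
            residual=1e-6, fitness=100 * 0.05 - np.log10(1e-6),
        )
        assert sol.fitness == pytest.approx(11.0)
        # and the evaluator reproduces the same formula on a real structure
        s = (J.reshape(-1, order="F") != 0)
        got = evaluate_fitness(s, sys, 0.05)
        assert got.fitness == pytest.approx(
            got.zero_count * 0.05 - np.log10(got.residual)
        )

    def test_true_structure_dominated_by_residual_term(self, exact_system5):
        sys, J, _ = exact_system5
        s = J.reshape(-1, order="F") != 0
        sol = evaluate_fitness(s, sys, 0.05)
        assert sol.residual < 1e-10
        assert sol.fitness > sol.zero_count * 0.05 + 5

    def test_lambda_zero_ranks_by_residual_only(self, exact_system5):
        sys, J, _ = exact_system5
        truth = J.reshape(-1, order="F") != 0
        worse = truth.copy()
        worse[np.flatnonzero(truth)[0]] = False
        worse[np.flatnonzero(~truth)[0]] = True
        f_true = evaluate_fitness(truth, sys, 0.0)
        f_worse = evaluate_fitness(worse, sys, 0.0)
        assert f_true.fitness == pytest.approx(-np.log10(f_true.residual))
        assert f_true.fitness > f_worse.fitness

    def test_all_zero_structure_gets_worst_fitness(self, exact_system5):
        sys, _, _ = exact_system5
        sol = evaluate_fitness(np.zeros(25, bool), sys, 0.05)
        assert sol.fitness == -np.inf


class TestRunGA:
    def test_deterministic_given_seed(self, exact_system5, small_cfg):
        sys, _, _ = exact_system5
        a = run_ga(sys, 0.05, small_cfg, rng=np.random.default_rng(7))
        b = run_ga(sys, 0.05, small_cfg, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a.structure, b.structure)
        assert a.fitness == b.fitness

    def test_population_of_one_no_mutation_returns_initial(self, exact_system5):
        sys, _, _ = exact_system5
        cfg = GAConfig(
            population_size=1, max_generations=5, mutation_rate=0.0,
            lambda_grid=(0.05,), repeats_per_lambda=1,
        )
        rng = np.random.default_rng(8)
        initial = create_individual(5, cfg, rng=np.random.default_rng(8))
        best = run_ga(sys, 0.05, cfg, rng=np.random.default_rng(8))
        np.testing.assert_array_equal(best.structure, initial)

    def test_best_fitness_monotone_nondecreasing(self, exact_system5, small_cfg):
        sys, _, _ = exact_system5
        history = []
        run_ga(sys, 0.05, small_cfg, rng=np.random.default_rng(9), history=history)
        fits = [h[1] for h in history]
        assert all(b >= a for a, b in zip(fits, fits[1:]))

    def test_every_individual_satisfies_constraints(self, exact_system5):
        """Instrument fitness evaluation: every structure the GA ever scores
        satisfies min-sparsity and the prior mask."""
        sys, _, _ = exact_system5
        mask = PriorMask(known_zero=frozenset({7}), known_nonzero=frozenset({0}))
        cfg = GAConfig(
            population_size=20, max_generations=15, lambda_grid=(0.05,),
            repeats_per_lambda=1, min_sparsity=0.5,
        )
        seen = []
        import lyapnet.ga as ga_mod
        orig = ga_mod.evaluate_fitness

        def spy(structure, s, lam):
            seen.append(np.asarray(structure, dtype=bool).copy())
            return orig(structure, s, lam)

        ga_mod.evaluate_fitness = spy
        try:
            run_ga(sys, 0.05, cfg, mask, rng=np.random.default_rng(10))
        finally:
            ga_mod.evaluate_fitness = orig
        assert len(seen) > 200
        for bits in seen:
            assert sparsity(bits) >= 0.5
            assert not bits[7]
            assert bits[0]

    def test_recovers_true_structure_at_calibrated_lambda(self, exact_system5):
        """Structure recovery from the exact covariance of the seeded 5-node
        system: at a calibrated sparsity weight most seeded runs return
        exactly the true support."""
        sys, J, _ = exact_system5
        truth = J.reshape(-1, order="F") != 0
        cfg = GAConfig(
            population_size=200, max_generations=200, lambda_grid=(0.12,),
            repeats_per_lambda=1,
        )
        hits = sum(
            np.array_equal(
                run_ga(sys, 0.12, cfg, rng=np.random.default_rng(s)).structure,
                truth,
            )
            for s in range(10)
        )
        assert hits >= 7


class TestLambdaScan:
    def test_default_grid_accounting(self):
        grid = default_lambda_grid()
        assert len(grid) == 19
        assert grid[0] == pytest.approx(0.01)
        assert grid[-1] == pytest.approx(0.10)
        assert np.allclose(np.diff(grid), 0.005)
        cfg = GAConfig()
        assert len(cfg.lambda_grid) * cfg.repeats_per_lambda == 190

    def test_single_cell_scan_equals_run_ga(self, exact_system5):
        sys, _, _ = exact_system5
        cfg = GAConfig(
            population_size=20, max_generations=10, lambda_grid=(0.05,),
            repeats_per_lambda=1, rng_seed=3,
        )
        scan = lambda_scan(sys, cfg)
        assert len(scan) == 1
        direct = run_ga(sys, 0.05, cfg, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(scan[0].structure, direct.structure)

    def test_candidates_ordered_by_lambda_then_repeat(self, exact_system5):
        sys, _, _ = exact_system5
        cfg = GAConfig(
            population_size=10, max_generations=3, lambda_grid=(0.02, 0.05),
            repeats_per_lambda=2, rng_seed=0,
        )
        scan = lambda_scan(sys, cfg)
        assert [c.lam for c in scan] == [0.02, 0.02, 0.05, 0.05]
        assert [c.run_index for c in scan] == [0, 1, 2, 3]
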