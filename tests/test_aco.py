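import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from octaco.aco import (
    ACOConfig,
    PheromoneState,
    construct_subset,
    fisher_visibility,
    global_update,
    init_state,
    local_update,
    prune_redundant,
    run_aco,
    subset_fitness,
    transition_probabilities,
)
from octaco.features import FeatureTable
from octaco.fixtures import PlantedTableSpec, make_planted_table

from conftest import sign_fixture


def state_of(pheromone, visibility):
    return PheromoneState(np.asarray(pheromone, float), np.asarray(visibility, float))


class TestConfig:
    @pytest.mark.parametrize("kw", [
        {"mu_local_rate": 0.0}, {"mu_local_rate": 1.0},
        {"theta_global_rate": 0.0}, {"theta_global_rate": 1.5},
        {"delta0_init": 0.0}, {"n_iterations": 0},
        {"prune_fraction": 0.5}, {"prune_fraction": 0.1},
        {"heuristic_mode": "entropy"},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            ACOConfig(**kw)

    def test_prune_override(self):
        cfg = ACOConfig(prune_fraction=0.5, allow_prune_override=True)
        assert cfg.prune_fraction == 0.5

    def test_default_subset_size_half_d(self):
        assert ACOConfig().resolved_subset_size(100) == 50
        assert ACOConfig().resolved_subset_size(2000) == 512  # cap


class TestInitState:
    def test_literal_colony_rule(self):
        """Kn = V x d under the literal colony-sizing rule."""
        rng = np.random.default_rng(0)
        table = FeatureTable(rng.standard_normal((10, 5)),
                             np.arange(10) % 2)
        _, colony = init_state(table, ACOConfig(n_ants="literal"))
        assert (colony.n_samples, colony.n_features, colony.n_ants) == (10, 5, 50)

    def test_auto_colony_capped(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(rng.standard_normal((100, 20)), np.arange(100) % 2)
        _, colony = init_state(table, ACOConfig(n_ants="auto"))
        assert colony.n_ants == 32

    def test_uniform_pheromone_init(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(rng.standard_normal((6, 4)), np.arange(6) % 2)
        state, _ = init_state(table, ACOConfig(delta0_init=1.0))
        np.testing.assert_array_equal(state.pheromone, np.ones(4))

    def test_paper_literal_visibility_equals_pheromone(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(rng.standard_normal((6, 4)), np.arange(6) % 2)
        state, _ = init_state(table, ACOConfig(heuristic_mode="paper_literal",
                                               delta0_init=2.0))
        np.testing.assert_array_equal(state.visibility, state.pheromone)

    def test_single_feature_rejected(self):
        table = FeatureTable(np.zeros((4, 1)), np.arange(4) % 2)
        with pytest.raises(ValueError, match="2 features"):
            init_state(table, ACOConfig())

    def test_nonfinite_rejected(self):
        X = np.zeros((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            init_state(FeatureTable(X, np.arange(4) % 2), ACOConfig())


class TestFisherVisibility:
    def test_hand_computed_ratio(self):
        """Two classes with means 0 and 1, within-class variance 0.25 each:
        Fisher ratio 1.0."""
        X = np.array([[-0.5], [0.5], [0.5], [1.5]])
        table = FeatureTable(X, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(fisher_visibility(table), [1.0])

    def test_constant_feature_zero(self):
        X = np.column_stack([np.full(6, 3.0), np.random.default_rng(0).standard_normal(6)])
        table = FeatureTable(X, np.arange(6) % 2)
        assert fisher_visibility(table)[0] == 0.0

    def test_perfect_separator_gets_max_visibility(self):
        """A zero-within-variance separating feature dominates noisy ones
        (hand-checkable 6-sample fixture)."""
        rng = np.random.default_rng(1)
        X = np.column_stack([
            np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]),  # perfect, zero within-var
            np.array([-0.6, 0.1, 0.5, 0.4, 1.1, 1.6]),  # separating, noisy
            rng.standard_normal(6),                      # noise
        ])
        vis = fisher_visibility(FeatureTable(X, np.array([0, 0, 0, 1, 1, 1])))
        assert np.argmax(vis) == 0
        assert vis[0] == pytest.approx(2.0 * max(vis[1], vis[2]))

    def test_sample_order_invariance(self, tiny_planted):
        table, _ = tiny_planted
        perm = np.random.default_rng(0).permutation(table.n_samples)
        shuffled = FeatureTable(table.matrix[perm], table.labels[perm])
        np.testing.assert_allclose(fisher_visibility(shuffled),
                                   fisher_visibility(table))

    def test_single_class_rejected(self):
        table = FeatureTable(np.zeros((4, 3)), np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="2 classes"):
            fisher_visibility(table)


class TestTransitionProbabilities:
    def test_uniform_when_beta_zero(self):
        state = state_of([1, 1, 1, 1], [9, 1, 5, 3])
        cfg = ACOConfig(beta_visibility_exponent=0.0)
        p = transition_probabilities(state, cfg, excluded=set())
        np.testing.assert_allclose(p, 0.25)

    def test_two_feature_ratio(self):
        state = state_of([2, 1], [1, 1])
        p = transition_probabilities(state, ACOConfig(), excluded=set())
        np.testing.assert_allclose(p, [2 / 3, 1 / 3])

    def test_matches_bruteforce_products(self):
        delta = np.array([1.0, 2, 3, 4, 5])
        vis = np.array([5.0, 4, 3, 2, 1])
        p = transition_probabilities(state_of(delta, vis), ACOConfig(), set())
        products = delta * vis
        np.testing.assert_allclose(p, products / products.sum())

    def test_excluded_zero_and_normalized(self):
        state = state_of([1, 2, 3, 4], [1, 1, 1, 1])
        p = transition_probabilities(state, ACOConfig(), excluded={1, 3})
        assert p[1] == 0.0 and p[3] == 0.0
        assert abs(p.sum() - 1.0) < 1e-12

    def test_all_excluded_rejected(self):
        state = state_of([1, 1], [1, 1])
        with pytest.raises(ValueError, match="excluded"):
            transition_probabilities(state, ACOConfig(), {0, 1})

    @settings(max_examples=50, derandomize=True)
    @given(
        delta=arrays(np.float64, 8, elements=st.floats(1e-3, 1e3)),
        vis=arrays(np.float64, 8, elements=st.floats(0.0, 1e3)),
        excluded=st.sets(st.integers(0, 7), max_size=7),
    )
    def test_normalization_property(self, delta, vis, excluded):
        """For any positive pheromone, nonnegative visibility and proper
        exclusion set: probabilities sum to 1 and vanish exactly on the
        excluded indices."""
        p = transition_probabilities(state_of(delta, vis), ACOConfig(), excluded)
        assert abs(p.sum() - 1.0) <= 1e-12
        assert all(p[i] == 0.0 for i in excluded)
        assert np.all(p >= 0)


class TestConstructSubset:
    def test_pure_exploitation_picks_top_products(self):
        state = state_of([5, 1, 4, 2, 3], [1, 1, 1, 1, 1])
        cfg = ACOConfig(exploit_prob_q0=1.0)
        s = construct_subset(state, cfg, np.random.default_rng(0), subset_size=3)
        assert s.tolist() == [0, 2, 4]

    def test_exhaustive_when_subset_is_everything(self):
        state = state_of([1, 2, 3], [3, 2, 1])
        cfg = ACOConfig(exploit_prob_q0=0.0)
        s = construct_subset(state, cfg, np.random.default_rng(1), subset_size=3)
        assert s.tolist() == [0, 1, 2]

    def test_oversized_subset_rejected(self):
        state = state_of([1, 2], [1, 1])
        with pytest.raises(ValueError, match="exceeds"):
            construct_subset(state, ACOConfig(), np.random.default_rng(0),
                             subset_size=3)

    def test_first_pick_frequency_binomial(self):
        """With q0=0, beta=0 and pheromone (2,1), feature 0 opens the subset
        with probability 2/3 (binomial check over 10,000 draws)."""
        state = state_of([2.0, 1.0], [1.0, 1.0])
        cfg = ACOConfig(exploit_prob_q0=0.0, beta_visibility_exponent=0.0)
        rng = np.random.default_rng(123)
        n = 10_000
        hits = sum(
            construct_subset(state, cfg, rng, subset_size=1)[0] == 0
            for _ in range(n)
        )
        p = 2 / 3
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * sigma

    def test_deterministic_under_seed(self):
        state = state_of(np.arange(1, 9), np.ones(8))
        cfg = ACOConfig(seed=0)
        a = construct_subset(state, cfg, np.random.default_rng(9), subset_size=4)
        b = construct_subset(state, cfg, np.random.default_rng(9), subset_size=4)
        np.testing.assert_array_equal(a, b)


class TestSubsetFitness:
    def test_perfect_feature_scores_one(self):
        table = sign_fixture()
        assert subset_fitness(table, [0], ACOConfig(seed=0)) == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((400, 4))
        y = np.arange(400) % 2
        table = FeatureTable(X, rng.permutation(y))
        f = subset_fitness(table, [0, 1, 2, 3], ACOConfig(seed=1))
        n_test = 100  # 25% holdout of 400
        sigma = np.sqrt(0.25 / n_test)
        assert abs(f - 0.5) < 3 * sigma

    def test_all_features_no_better_than_oracle_subset(self):
        table = sign_fixture()
        f_best = subset_fitness(table, [0], ACOConfig(seed=0))
        f_all = subset_fitness(table, range(4), ACOConfig(seed=0))
        assert f_all <= f_best + 0.1

    def test_out_of_range_rejected(self):
        table = sign_fixture()
        with pytest.raises(ValueError, match="out-of-range"):
            subset_fitness(table, [99], ACOConfig())

    def test_agrees_with_sklearn_knn(self):
        """Independent oracle: scikit-learn's 1-NN on the same standardized
        split reproduces the internal fitness."""
        from sklearn.neighbors import KNeighborsClassifier

        from octaco.aco import _FitnessEvaluator

        table, _ = make_planted_table(
            PlantedTableSpec(n_per_class=40, n_classes=3, n_informative=2,
                             n_noise=4, seed=2)
        )
        cfg = ACOConfig(seed=4)
        ev = _FitnessEvaluator(table, cfg)
        subset = np.array([0, 2, 5])
        knn = KNeighborsClassifier(n_neighbors=1)
        knn.fit(ev.Ztr[:, subset], ev.ytr)
        expected = knn.score(ev.Zte[:, subset], ev.yte)
        assert ev(subset) == pytest.approx(expected)


class TestPheromoneUpdates:
    def test_local_update_arithmetic(self):
        state = state_of([1.0, 1.0], [1, 1])
        local_update(state, [0], best_fitness=0.8,
                     cfg=ACOConfig(mu_local_rate=0.5))
        assert state.pheromone[0] == pytest.approx(0.9)
        assert state.pheromone[1] == 1.0  # locality: untouched bit-identical

    def test_global_update_arithmetic_and_fixed_point(self):
        cfg = ACOConfig(theta_global_rate=0.1, delta0_init=1.0)
        state = state_of([2.0, 1.0], [1, 1])
        global_update(state, cfg)
        assert state.pheromone[0] == pytest.approx(1.9)
        assert state.pheromone[1] == pytest.approx(1.0)  # delta0 is a fixed point

    def test_geometric_contraction(self):
        """sup-norm distance to delta0 shrinks by (1-theta) per step."""
        cfg = ACOConfig(theta_global_rate=0.3, delta0_init=1.0)
        state = state_of([5.0, 0.5, 1.0], [1, 1, 1])
        for k in range(1, 6):
            prev = np.abs(state.pheromone - 1.0).max()
            global_update(state, cfg)
            now = np.abs(state.pheromone - 1.0).max()
            assert now == pytest.approx(prev * 0.7)

    def test_positivity_preserved_under_any_update_sequence(self):
        rng = np.random.default_rng(8)
        cfg = ACOConfig(mu_local_rate=0.9, theta_global_rate=0.9,
                        delta0_init=0.01)
        state = state_of(np.full(6, 0.01), np.ones(6))
        for _ in range(200):
            subset = rng.choice(6, size=3, replace=False)
            local_update(state, subset, float(rng.random()), cfg)
            global_update(state, cfg)
            assert np.all(state.pheromone > 0)


class TestPrune:
    def _orthogonal_table(self):
        # eight exactly-uncorrelated columns from a scaled Hadamard basis
        from scipy.linalg import hadamard

        H = hadamard(8).astype(float)
        y = (H[:, 1] > 0).astype(int)
        return FeatureTable(H, y)

    def test_floor_arithmetic(self, planted):
        table, _ = planted
        kept, pruned = prune_redundant(table, range(20), 0.20)
        assert len(pruned) == 4 and len(kept) == 16

    def test_duplicate_column_pruned_first(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        X[:, 3] = X[:, 0]  # exact duplicate
        table = FeatureTable(X, np.arange(30) % 2)
        kept, pruned = prune_redundant(table, range(5), 0.20, allow_override=True)
        assert pruned.tolist() in ([0], [3])  # floor(0.2*5) = 1 removed

    def test_orthogonal_prunes_lowest_visibility(self):
        table = self._orthogonal_table()
        vis = np.array([5.0, 7, 1, 6, 3, 8, 4, 2])
        kept, pruned = prune_redundant(table, range(8), 0.20, visibility=vis)
        # floor(0.2*8)=1: the single pruned feature is the least visible
        assert pruned.tolist() == [2]

    def test_singleton_subset_unchanged(self, planted):
        table, _ = planted
        kept, pruned = prune_redundant(table, [7], 0.20)
        assert kept.tolist() == [7] and pruned.size == 0

    def test_range_enforced_without_override(self, planted):
        table, _ = planted
        with pytest.raises(ValueError, match="0.15"):
            prune_redundant(table, range(10), 0.5)


class TestRunACO:
    def test_degenerate_schedule_deterministic(self, tiny_planted):
        """One iteration, one ant, q0=1: the kept set is the pruned
        top-product subset, exactly reproducible."""
        table, _ = tiny_planted
        cfg = ACOConfig(n_iterations=1, n_ants=1, exploit_prob_q0=1.0,
                        subset_size=4, seed=0)
        res = run_aco(table, cfg)
        vis = fisher_visibility(table)
        top4 = np.sort(np.argsort(-vis, kind="stable")[:4])
        np.testing.assert_array_equal(res.best_subset, top4)
        assert len(res.kept_indices) == 4  # floor(0.2*4)=0 pruned
        np.testing.assert_array_equal(res.kept_indices, top4)

    def test_same_seed_identical_result(self, tiny_planted):
        table, _ = tiny_planted
        cfg = ACOConfig(n_iterations=10, subset_size=3, seed=21)
        a, b = run_aco(table, cfg), run_aco(table, cfg)
        np.testing.assert_array_equal(a.kept_indices, b.kept_indices)
        np.testing.assert_array_equal(a.final_pheromone, b.final_pheromone)
        np.testing.assert_array_equal(a.best_fitness_per_iteration,
                                      b.best_fitness_per_iteration)

    def test_elitist_trace_monotone_and_kept_disjoint_from_pruned(self, planted):
        table, _ = planted
        cfg = ACOConfig(n_iterations=15, subset_size=12, seed=2)
        res = run_aco(table, cfg)
        assert np.all(np.diff(res.best_fitness_per_iteration) >= 0)
        assert set(res.kept_indices) & set(res.pruned_indices) == set()
        assert set(res.kept_indices) | set(res.pruned_indices) == set(res.best_subset)
        assert np.all(res.final_pheromone > 0)

    def test_matches_exhaustive_search_on_small_instance(self):
        """Generous-budget run attains the exhaustive optimum over all
        C(8,3)=56 subsets on a planted instance."""
        table, _ = make_planted_table(
            PlantedTableSpec(n_per_class=30, n_classes=3, n_informative=3,
                             n_noise=5, class_sep=1.0, seed=12)
        )
        cfg = ACOConfig(n_iterations=50, n_ants=20, subset_size=3, seed=12)
        best = max(
            subset_fitness(table, s, cfg)
            for s in itertools.combinations(range(8), 3)
        )
        res = run_aco(table, cfg)
        assert res.best_fitness == pytest.approx(best)

    def test_result_roundtrip(self, tmp_path, tiny_planted):
        table, _ = tiny_planted
        res = run_aco(table, ACOConfig(n_iterations=3, subset_size=3, seed=0))
        p = tmp_path / "sel.json"
        res.save(p)
        loaded = type(res).load(p)
        np.testing.assert_array_equal(loaded.kept_indices, res.kept_indices)
        np.testing.assert_array_equal(loaded.best_fitness_per_iteration,
                                      res.best_fitness_per_iteration)
        assert loaded.config == res.config
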