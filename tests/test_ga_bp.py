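"""Network, genetic operators, and the hybrid training procedure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptsdpipe.ga_bp import (
    Chromosome,
    GAConfig,
    NetworkConfig,
    NetworkParams,
    Normalizer,
    coding_length,
    crossover,
    decode,
    encode,
    fitness,
    forward,
    grid_search,
    init_params,
    load_model,
    loss_and_gradients,
    mutate,
    normalize,
    run_ga,
    save_model,
    select_roulette,
    train_bp,
    train_ga_bp,
)

layer_sizes = st.integers(1, 8)


class TestNormalizer:
    def test_unit_interval_formula(self):
        norm = Normalizer(0.0, 10.0, (0.0, 1.0))
        assert np.allclose(normalize(np.array([0.0, 5.0, 10.0]), norm), [0, 0.5, 1])

    def test_default_target_is_symmetric(self):
        norm = Normalizer(0.0, 10.0)
        assert np.allclose(normalize(np.array([0.0, 5.0, 10.0]), norm), [-1, 0, 1])

    def test_hand_value(self):
        norm = Normalizer(2.0, 7.0, (0.0, 1.0))
        assert np.allclose(normalize(np.array([2.0, 3.0, 7.0]), norm), [0, 0.2, 1])

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            Normalizer(3.0, 3.0)

    @given(
        st.lists(st.integers(-100, 100), min_size=2, max_size=20, unique=True),
        st.floats(-5, 0),
        st.floats(0.5, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_affine_order_preserving_onto_endpoints(self, xs, lo, hi):
        x = np.asarray(xs, dtype=float)
        norm = Normalizer.fit(x, (lo, hi))
        y = norm.transform(x)
        assert np.argmin(y) == np.argmin(x) and np.argmax(y) == np.argmax(x)
        assert y.min() == pytest.approx(lo, abs=1e-9)
        assert y.max() == pytest.approx(hi, abs=1e-9)
        assert np.allclose(norm.inverse(y), x, atol=1e-8)


class TestForward:
    def test_zero_params_logistic(self):
        cfg = NetworkConfig(2, 3, 2)
        params = NetworkParams(np.zeros((2, 3)), np.zeros(3), np.zeros((3, 2)), np.zeros(2))
        out, hidden = forward(params, cfg, np.zeros(2))
        assert np.allclose(hidden, 0.5)
        assert np.allclose(out, 0.0)

    def test_hand_evaluation_1_1_1(self):
        cfg = NetworkConfig(1, 1, 1)
        params = NetworkParams(
            np.array([[1.0]]), np.array([0.0]), np.array([[2.0]]), np.array([1.0])
        )
        out, _ = forward(params, cfg, np.array([0.0]))
        assert out[0] == pytest.approx(2 * 0.5 + 1)

    def test_tanh_at_zero_passes_bias(self):
        cfg = NetworkConfig(2, 4, 1, hidden_activation="tanh")
        params = NetworkParams(
            np.ones((2, 4)), np.zeros(4), np.ones((4, 1)), np.array([3.0])
        )
        out, hidden = forward(params, cfg, np.zeros(2))
        assert np.allclose(hidden, 0.0)
        assert out[0] == pytest.approx(3.0)

    def test_shape_mismatch_rejected(self):
        cfg = NetworkConfig(2, 3, 1)
        params = init_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="features"):
            forward(params, cfg, np.zeros(4))


class TestGradients:
    @pytest.mark.parametrize("activation", ["logistic", "tanh"])
    def test_backprop_matches_finite_differences(self, activation):
        """Analytic gradients against central differences on a 3-4-2 net."""
        rng = np.random.default_rng(12)
        cfg = NetworkConfig(3, 4, 2, hidden_activation=activation)
        params = init_params(cfg, rng)
        x = rng.standard_normal((5, 3))
        y = rng.standard_normal((5, 2))
        _, grads = loss_and_gradients(params, cfg, x, y)
        eps = 1e-6
        for attr in ("w_in_hidden", "b_hidden", "w_hidden_out", "b_out"):
            analytic = getattr(grads, attr)
            for idx in np.ndindex(analytic.shape):
                p_hi = params.copy()
                getattr(p_hi, attr)[idx] += eps
                p_lo = params.copy()
                getattr(p_lo, attr)[idx] -= eps
                m_hi, _ = loss_and_gradients(p_hi, cfg, x, y)
                m_lo, _ = loss_and_gradients(p_lo, cfg, x, y)
                numeric = (m_hi - m_lo) / (2 * eps)
                denom = max(abs(numeric), 1e-8)
                assert abs(analytic[idx] - numeric) / denom < 1e-5

    def test_stationary_point_leaves_params_unchanged(self):
        cfg = NetworkConfig(1, 2, 1, max_epochs=10)
        params = init_params(cfg, np.random.default_rng(1))
        x = np.array([[0.3], [0.7], [-0.2]])
        y, _ = forward(params, cfg, x)  # targets equal current output
        trained, trace = train_bp(params, cfg, x, y)
        assert np.allclose(trained.w_in_hidden, params.w_in_hidden)
        assert trace[0] == pytest.approx(0.0, abs=1e-30)


class TestTraining:
    def test_converges_on_linear_function(self):
        cfg = NetworkConfig(1, 2, 1, learning_rate=0.05, max_epochs=2000)
        x = np.linspace(-1, 1, 50)[:, None]
        y = 0.5 * x
        params0 = init_params(cfg, np.random.default_rng(3))
        _, trace = train_bp(params0, cfg, x, y)
        assert trace[-1] < 1e-3

    def test_error_goal_stops_early(self):
        cfg = NetworkConfig(1, 2, 1, learning_rate=0.05, max_epochs=5000, error_goal=0.01)
        x = np.linspace(-1, 1, 30)[:, None]
        y = 0.5 * x
        _, trace = train_bp(init_params(cfg, np.random.default_rng(3)), cfg, x, y)
        assert len(trace) < 5001
        assert trace[-1] <= 0.01

    def test_empty_data_rejected(self):
        cfg = NetworkConfig(1, 2, 1)
        with pytest.raises(ValueError, match="nonempty"):
            train_bp(init_params(cfg, np.random.default_rng(0)), cfg,
                     np.empty((0, 1)), np.empty((0, 1)))


class TestCoding:
    @pytest.mark.parametrize("ikj, expected", [((1, 1, 1), 4), ((3, 12, 1), 61)])
    def test_known_lengths(self, ikj, expected):
        assert coding_length(*ikj) == expected

    @given(layer_sizes, layer_sizes, layer_sizes)
    @settings(max_examples=100, derandomize=True)
    def test_length_equals_parameter_count(self, i, k, j):
        cfg = NetworkConfig(i, k, j)
        params = init_params(cfg, np.random.default_rng(0))
        chrom = encode(params)
        assert coding_length(i, k, j) == chrom.genes.size == params.n_parameters

    def test_round_trip_identity(self):
        cfg = NetworkConfig(4, 6, 2)
        params = init_params(cfg, np.random.default_rng(5))
        back = decode(encode(params), cfg)
        for attr in ("w_in_hidden", "b_hidden", "w_hidden_out", "b_out"):
            assert np.array_equal(getattr(back, attr), getattr(params, attr))

    def test_documented_gene_order(self):
        params = NetworkParams(
            np.array([[2.0]]), np.array([3.0]), np.array([[4.0]]), np.array([5.0])
        )
        assert encode(params).genes.tolist() == [2.0, 3.0, 4.0, 5.0]

    def test_length_mismatch_rejected(self):
        cfg = NetworkConfig(3, 12, 1)  # needs 61 genes
        with pytest.raises(ValueError, match="61"):
            decode(Chromosome(np.zeros(60)), cfg)


class TestFitness:
    def test_perfect_prediction_is_zero(self):
        cfg = NetworkConfig(1, 1, 1)
        params = init_params(cfg, np.random.default_rng(2))
        x = np.array([[0.1], [0.9]])
        y, _ = forward(params, cfg, x)
        assert fitness(encode(params), cfg, x, y) == 0.0

    def test_single_sample_absolute_error(self):
        cfg = NetworkConfig(1, 1, 1)
        # zero weights, output bias 0.25 -> constant prediction 0.25
        params = NetworkParams(
            np.zeros((1, 1)), np.zeros(1), np.zeros((1, 1)), np.array([0.25])
        )
        f = fitness(encode(params), cfg, np.array([[0.0]]), np.array([[1.0]]))
        assert f == pytest.approx(0.75)

    def test_linear_in_coefficient(self):
        cfg = NetworkConfig(1, 1, 1)
        params = init_params(cfg, np.random.default_rng(4))
        x = np.array([[0.2], [0.4]])
        y = np.array([[1.0], [1.0]])
        chrom = encode(params)
        assert fitness(chrom, cfg, x, y, k_f=2.0) == pytest.approx(
            2 * fitness(chrom, cfg, x, y, k_f=1.0)
        )


class TestSelection:
    @staticmethod
    def _pop(fits):
        pop = []
        for f in fits:
            c = Chromosome(np.zeros(2))
            c.fitness = f
            pop.append(c)
        return pop

    def test_two_individual_law(self):
        """F=(1,3) with inverse-fitness scores gives probabilities (3/4, 1/4)."""
        rng = np.random.default_rng(0)
        pop = self._pop([1.0, 3.0])
        pop[0].genes[:] = 0.0
        pop[1].genes[:] = 1.0
        draws = select_roulette(pop, rng, n=100_000)
        freq0 = np.mean([c.genes[0] == 0.0 for c in draws])
        assert freq0 == pytest.approx(0.75, abs=0.01)

    def test_equal_fitness_uniform(self):
        rng = np.random.default_rng(1)
        pop = self._pop([2.0, 2.0, 2.0, 2.0])
        for i, c in enumerate(pop):
            c.genes[:] = i
        draws = select_roulette(pop, rng, n=40_000)
        freqs = np.bincount([int(c.genes[0]) for c in draws], minlength=4) / 40_000
        assert np.allclose(freqs, 0.25, atol=0.02)

    def test_best_has_highest_probability(self):
        rng = np.random.default_rng(2)
        pop = self._pop([0.1, 1.0, 5.0])
        for i, c in enumerate(pop):
            c.genes[:] = i
        draws = select_roulette(pop, rng, n=20_000)
        counts = np.bincount([int(c.genes[0]) for c in draws], minlength=3)
        assert counts[0] > counts[1] > counts[2]

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_roulette([], np.random.default_rng(0))


class TestCrossover:
    def test_blend_zero_copies_parents(self, rng):
        a = Chromosome(np.array([2.0, 6.0]))
        b = Chromosome(np.array([6.0, 2.0]))
        ca, cb = crossover(a, b, 1.0, rng, blend=0.0, positions=np.array([True, True]))
        assert np.array_equal(ca.genes, a.genes)
        assert np.array_equal(cb.genes, b.genes)

    def test_blend_one_swaps(self, rng):
        a = Chromosome(np.array([2.0, 6.0]))
        b = Chromosome(np.array([6.0, 2.0]))
        ca, cb = crossover(a, b, 1.0, rng, blend=1.0, positions=np.array([True, True]))
        assert np.array_equal(ca.genes, b.genes)
        assert np.array_equal(cb.genes, a.genes)

    def test_quarter_blend_hand_values(self, rng):
        a = Chromosome(np.array([2.0]), bounds=(0.0, 10.0))
        b = Chromosome(np.array([6.0]), bounds=(0.0, 10.0))
        ca, cb = crossover(a, b, 1.0, rng, blend=0.25, positions=np.array([True]))
        assert ca.genes[0] == pytest.approx(3.0)  # 2*0.75 + 6*0.25
        assert cb.genes[0] == pytest.approx(5.0)  # 6*0.75 + 2*0.25

    def test_zero_probability_copies(self, rng):
        a = Chromosome(np.array([1.0, -1.0]))
        b = Chromosome(np.array([-1.0, 1.0]))
        ca, cb = crossover(a, b, 0.0, rng)
        assert np.array_equal(ca.genes, a.genes) and np.array_equal(cb.genes, b.genes)

    @given(st.integers(0, 1000))
    @settings(max_examples=50, derandomize=True)
    def test_children_stay_in_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = Chromosome(rng.uniform(-1, 1, 8))
        b = Chromosome(rng.uniform(-1, 1, 8))
        ca, cb = crossover(a, b, 0.8, rng)
        for c in (ca, cb):
            assert (c.genes >= -1).all() and (c.genes <= 1).all()

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            crossover(Chromosome(np.zeros(2)), Chromosome(np.zeros(3)), 1.0, rng)


class TestMutation:
    def test_zero_probability_is_identity(self, rng):
        c = Chromosome(np.array([0.3, -0.7]))
        out = mutate(c, 0.0, 5, 50, rng)
        assert np.array_equal(out.genes, c.genes)

    def test_final_generation_annealed_to_zero(self, rng):
        c = Chromosome(np.array([0.3, -0.7]))
        out = mutate(c, 1.0, 50, 50, rng)
        assert np.allclose(out.genes, c.genes)

    def test_generation_beyond_max_rejected(self, rng):
        with pytest.raises(ValueError, match="max_generations"):
            mutate(Chromosome(np.zeros(2)), 0.1, 51, 50, rng)

    @given(st.integers(0, 500), st.integers(0, 49))
    @settings(max_examples=100, derandomize=True)
    def test_mutants_stay_in_bounds(self, seed, g):
        rng = np.random.default_rng(seed)
        c = Chromosome(rng.uniform(-1, 1, 6))
        out = mutate(c, 0.5, g, 50, rng)
        assert (out.genes >= -1).all() and (out.genes <= 1).all()

    def test_printed_convention_clipped(self):
        # force mutation of every gene; the printed upper branch moves away
        # from the upper bound but must stay clipped within bounds
        rng = np.random.default_rng(3)
        c = Chromosome(np.array([0.9] * 20))
        out = mutate(c, 1.0, 1, 50, rng, printed_convention=True)
        assert (out.genes >= -1).all() and (out.genes <= 1).all()


class TestGA:
    def test_trace_non_increasing(self):
        for seed in range(5):
            cfg = GAConfig(seed=seed, max_generations=30)
            _, trace = run_ga(cfg, lambda g: float(np.sum(g**2)), 4)
            assert all(trace[i + 1] <= trace[i] for i in range(len(trace) - 1))

    def test_elitism_floor_at_zero(self):
        # fitness is zero on a whole region; once hit, the best stays zero
        def f(genes):
            return float(max(0.0, np.abs(genes).sum() - 1.5))

        cfg = GAConfig(seed=1, max_generations=20)
        best, trace = run_ga(cfg, f, 2)
        assert best.fitness == 0.0
        assert trace[-1] == 0.0

    def test_toy_quadratic_near_optimum(self):
        cfg = GAConfig(seed=7)
        best, _ = run_ga(cfg, lambda g: (g[0] - 0.3) ** 2 + (g[1] + 0.2) ** 2, 2)
        assert best.fitness < 0.05

    def test_runs_exactly_max_generations(self):
        cfg = GAConfig(seed=0, max_generations=13)
        _, trace = run_ga(cfg, lambda g: float(np.sum(g**2)), 3)
        assert len(trace) == 13

    def test_seed_determinism(self):
        cfg = GAConfig(seed=21)
        b1, t1 = run_ga(cfg, lambda g: float(np.sum(g**2)), 4)
        b2, t2 = run_ga(cfg, lambda g: float(np.sum(g**2)), 4)
        assert np.array_equal(b1.genes, b2.genes) and t1 == t2


class TestGABP:
    @staticmethod
    def _task():
        x = np.linspace(-1, 1, 30)[:, None]
        return x, 0.4 * np.sin(np.pi * x) + 0.1

    def test_degenerate_ga_equals_bp_from_best_of_population(self):
        x, y = self._task()
        cfg = NetworkConfig(1, 3, 1, learning_rate=0.1, max_epochs=50)
        ga = GAConfig(seed=8, max_generations=0)
        params, ga_trace, bp_trace = train_ga_bp(ga, cfg, x, y)
        assert ga_trace == []
        assert len(bp_trace) == 51

    def test_seed_determinism(self):
        x, y = self._task()
        cfg = NetworkConfig(1, 3, 1, learning_rate=0.1, max_epochs=100)
        ga = GAConfig(seed=5, max_generations=10)
        p1, _, t1 = train_ga_bp(ga, cfg, x, y)
        p2, _, t2 = train_ga_bp(ga, cfg, x, y)
        assert np.array_equal(p1.w_in_hidden, p2.w_in_hidden)
        assert t1 == t2

    def test_model_json_round_trip(self, tmp_path):
        x, y = self._task()
        cfg = NetworkConfig(1, 3, 1, learning_rate=0.1, max_epochs=20)
        params, ga_trace, bp_trace = train_ga_bp(GAConfig(seed=2, max_generations=5), cfg, x, y)
        path = tmp_path / "model.json"
        save_model(str(path), params, cfg, ga_trace, bp_trace)
        loaded, loaded_cfg, payload = load_model(str(path))
        assert loaded_cfg == cfg
        assert np.allclose(loaded.w_in_hidden, params.w_in_hidden)
        out1, _ = forward(params, cfg, x)
        out2, _ = forward(loaded, loaded_cfg, x)
        assert np.allclose(out1, out2)


class TestGridSearch:
    @staticmethod
    def _task():
        x = np.linspace(-1, 1, 40)[:, None]
        return x, 0.5 * x**2

    def test_single_value_is_argmin(self):
        x, y = self._task()
        cfg = NetworkConfig(1, 4, 1, learning_rate=0.1, max_epochs=30)
        table, best = grid_search(cfg, x, y, "hidden_nodes", [6], seed=0)
        assert best == 6 and len(table) == 1

    def test_more_steps_no_worse(self):
        """Longer training cannot increase the final error on this task."""
        x, y = self._task()
        cfg = NetworkConfig(1, 4, 1, learning_rate=0.1)
        table, _ = grid_search(cfg, x, y, "step_size", [20, 200], seed=1)
        err = dict(table)
        assert err[200] <= err[20]

    def test_full_hidden_grid_shape(self):
        x, y = self._task()
        cfg = NetworkConfig(1, 4, 1, learning_rate=0.1, max_epochs=30)
        table, best = grid_search(cfg, x, y, "hidden_nodes", list(range(4, 15)), seed=2)
        assert len(table) == 11
        assert best in set(v for v, _ in table)
        assert best == min(table, key=lambda t: t[1])[0]

    def test_empty_grid_rejected(self):
        x, y = self._task()
        with pytest.raises(ValueError, match="empty"):
            grid_search(NetworkConfig(1, 4, 1), x, y, "hidden_nodes", [])

    def test_unknown_axis_rejected(self):
        x, y = self._task()
        with pytest.raises(ValueError, match="axis"):
            grid_search(NetworkConfig(1, 4, 1), x, y, "momentum", [0.1])
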