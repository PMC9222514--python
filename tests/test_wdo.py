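"""Wind Driven Optimization: updates, ranking, convergence, tuning."""

import numpy as np
import pytest

from osteosae.wdo import (
    AirParcel,
    Dimension,
    SearchSpace,
    WDOConfig,
    fitness,
    optimize,
    rank_parcels,
    update_position,
    update_velocity,
)


class TestFitness:
    def test_no_misclassification(self):
        assert fitness(["a"] * 50, ["a"] * 50) == 0.0

    def test_direct_count(self):
        preds = ["a"] * 95 + ["b"] * 5
        labels = ["a"] * 100
        assert fitness(preds, labels) == 5.0

    def test_permutation_invariant(self, rng):
        labels = list(rng.choice(["x", "y"], size=40))
        preds = list(rng.choice(["x", "y"], size=40))
        perm = rng.permutation(40)
        assert fitness(preds, labels) == fitness([preds[i] for i in perm], [labels[i] for i in perm])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fitness([], [])


def _parcels(pressures):
    return [AirParcel(x=np.zeros(2), u=np.zeros(2), pressure=p, index=i)
            for i, p in enumerate(pressures)]


class TestRanking:
    def test_sorting(self):
        pop = rank_parcels(_parcels([3.0, 1.0, 2.0]))
        assert [p.k for p in pop] == [3, 1, 2]

    def test_ties_break_by_index(self):
        pop = rank_parcels(_parcels([1.0, 1.0, 1.0]))
        assert [p.k for p in pop] == [1, 2, 3]

    def test_ranks_are_a_bijection(self, rng):
        pop = rank_parcels(_parcels(list(rng.uniform(size=15))))
        assert sorted(p.k for p in pop) == list(range(1, 16))

    def test_nonfinite_pressure_ranked_worst(self):
        pop = rank_parcels(_parcels([2.0, float("nan"), 1.0]))
        assert pop[1].k == 3


class TestVelocityUpdate:
    def test_rank_one_pressure_term_vanishes(self):
        cfg = WDOConfig(g=0.2, alpha=0.4, RT=3.0, c=0.4, max_velocity=10.0, seed=0)
        p = AirParcel(x=np.array([0.5]), u=np.array([0.1]), k=1)
        u = update_velocity(p, np.array([-0.2]), cfg, np.random.default_rng(0))
        # 1-D: d' = d, so u_new = -g x + (1-alpha) u - c u / k
        assert u[0] == pytest.approx(-0.2 * 0.5 + 0.6 * 0.1 - 0.4 * 0.1, abs=1e-12)

    def test_hand_evaluated_one_dimensional_case(self):
        cfg = WDOConfig(g=0.2, alpha=0.4, RT=3.0, c=0.4, max_velocity=0.3, seed=0)
        p = AirParcel(x=np.array([0.5]), u=np.array([0.1]), k=2)
        u = update_velocity(p, np.array([-0.2]), cfg, np.random.default_rng(0))
        # unclamped: -0.1 + 0.06 + 0.5*3*(-0.7) - 0.4*0.1/2 = -1.11 -> clamp -0.3
        assert u[0] == -0.3
        cfg_wide = WDOConfig(g=0.2, alpha=0.4, RT=3.0, c=0.4, max_velocity=10.0, seed=0)
        u2 = update_velocity(p, np.array([-0.2]), cfg_wide, np.random.default_rng(0))
        assert u2[0] == pytest.approx(-1.11, abs=1e-12)

    def test_limit_pure_pressure_gradient(self):
        # g=c=0, alpha=0, large k: parcels head straight for x_max scaled by RT
        cfg = WDOConfig(g=0.0, alpha=0.0, RT=3.0, c=0.0, max_velocity=100.0, seed=0)
        p = AirParcel(x=np.array([0.2, -0.4]), u=np.zeros(2), k=10**9)
        u = update_velocity(p, np.array([0.8, 0.8]), cfg, np.random.default_rng(0))
        np.testing.assert_allclose(u, 3.0 * (np.array([0.8, 0.8]) - p.x), atol=1e-6)

    def test_unranked_parcel_rejected(self):
        cfg = WDOConfig(seed=0)
        p = AirParcel(x=np.zeros(2), u=np.zeros(2), k=0)
        with pytest.raises(RuntimeError):
            update_velocity(p, np.zeros(2), cfg, np.random.default_rng(0))


class TestPositionUpdate:
    def test_zero_velocity_keeps_position(self):
        cfg = WDOConfig(seed=0)
        p = AirParcel(x=np.array([0.3, -0.1]), u=np.zeros(2))
        x, _ = update_position(p, cfg)
        np.testing.assert_array_equal(x, p.x)

    def test_boundary_clip_zeroes_velocity(self):
        cfg = WDOConfig(max_velocity=0.5, seed=0)
        p = AirParcel(x=np.array([0.9]), u=np.array([0.5]))
        x, u = update_position(p, cfg)
        assert x[0] == 1.0 and u[0] == 0.0

    def test_positions_stay_in_box_under_random_updates(self, rng):
        cfg = WDOConfig(seed=0)
        p = AirParcel(x=rng.uniform(-1, 1, 3), u=rng.uniform(-0.3, 0.3, 3), k=2)
        for _ in range(100):
            p.u = update_velocity(p, rng.uniform(-1, 1, 3), cfg, rng)
            p.x, p.u = update_position(p, cfg)
            assert (np.abs(p.x) <= 1.0).all()
            assert (np.abs(p.u) <= cfg.max_velocity).all()


class TestSearchSpace:
    def test_grid_encode_decode_roundtrip(self):
        d = Dimension("bs", "grid", grid=(8, 16, 32, 64))
        for v in d.grid:
            assert d.decode(d.encode(v)) == v

    def test_log_dimension_bounds(self):
        d = Dimension("lr", "log", lower=1e-4, upper=1e-1)
        assert d.decode(-1.0) == pytest.approx(1e-4)
        assert d.decode(1.0) == pytest.approx(1e-1)
        assert d.decode(d.encode(1e-2)) == pytest.approx(1e-2)

    def test_invalid_dimension_rejected(self):
        with pytest.raises(ValueError):
            Dimension("x", "log", lower=-1.0, upper=1.0)


class TestOptimize:
    def test_constant_objective_found_after_first_iteration(self):
        sp = SearchSpace([Dimension("a", "linear", -1, 1)])
        res = optimize(lambda p: 42.0, sp, WDOConfig(population_size=4, iterations=3, seed=0))
        assert res.best_fitness == 42.0
        assert res.history["best_fitness"].iloc[0] == 42.0

    def test_best_fitness_monotone_nonincreasing(self):
        sp = SearchSpace([Dimension(f"x{i}", "linear", -1, 1) for i in range(3)])
        res = optimize(lambda p: sum(v * v for v in p.values()), sp,
                       WDOConfig(population_size=8, iterations=30, seed=1))
        best = res.history["best_fitness"].to_numpy()
        assert (np.diff(best) <= 1e-15).all()

    def test_sphere_convergence_beats_random_search(self):
        """5-D sphere: best < 1e-2 and better than equal-budget random search
        in median over 10 seeds."""
        sp = SearchSpace([Dimension(f"x{i}", "linear", -1, 1) for i in range(5)])
        wdo_best, rnd_best = [], []
        for seed in range(10):
            res = optimize(lambda p: sum(v * v for v in p.values()), sp,
                           WDOConfig(population_size=20, iterations=200, seed=seed))
            wdo_best.append(res.best_fitness)
            xs = np.random.default_rng(1000 + seed).uniform(-1, 1, size=(res.n_evaluations, 5))
            rnd_best.append(float((xs**2).sum(axis=1).min()))
        assert np.median(wdo_best) < 1e-2
        assert max(wdo_best) < 1e-2
        assert np.median(wdo_best) < np.median(rnd_best)

    @pytest.mark.parametrize("shape", [(5,), (4, 3)])
    def test_discrete_grid_matches_exhaustive_search(self, shape):
        """WDO finds the exhaustive-search optimum on enumerable grids
        (10-seed median, budget >= 3x grid size)."""
        values = np.random.default_rng(42).uniform(0, 10, size=shape)
        dims = [Dimension(f"d{i}", "grid", grid=tuple(range(n))) for i, n in enumerate(shape)]
        sp = SearchSpace(dims)
        exact = values.min()
        budget = 3 * values.size
        found = []
        for seed in range(10):
            pop = 6 if len(shape) > 1 else 5
            res = optimize(lambda p: float(values[tuple(int(p[f"d{i}"]) for i in range(len(shape)))]),
                           sp, WDOConfig(population_size=pop, iterations=max(2, budget // pop),
                                         max_velocity=0.6, seed=seed))
            found.append(res.best_fitness)
        assert np.median(found) == pytest.approx(exact, abs=1e-12)

    def test_pressure_gradient_ablation_degrades_convergence(self):
        """Zeroing RT (no pull toward the best parcel) hurts the sphere median.

        The sphere is shifted off the origin so the gravitation term (which
        always pulls toward the box centre) cannot solve it by itself.
        """
        sp = SearchSpace([Dimension(f"x{i}", "linear", -1, 1) for i in range(5)])

        def obj(p):
            return sum((v - 0.4) ** 2 for v in p.values())

        full, ablated = [], []
        for seed in range(6):
            kw = dict(population_size=10, iterations=60, seed=seed)
            full.append(optimize(obj, sp, WDOConfig(**kw)).best_fitness)
            ablated.append(optimize(obj, sp, WDOConfig(RT=0.0, **kw)).best_fitness)
        assert np.median(full) < np.median(ablated)

    def test_objective_error_scored_worst(self):
        sp = SearchSpace([Dimension("a", "linear", -1, 1)])

        def bad(p):
            raise RuntimeError("boom")

        res = optimize(bad, sp, WDOConfig(population_size=3, iterations=2, seed=0))
        assert res.best_fitness == 100.0

    def test_identical_seed_identical_trajectory(self):
        sp = SearchSpace([Dimension(f"x{i}", "linear", -1, 1) for i in range(3)])
        a = optimize(lambda p: sum(v * v for v in p.values()), sp,
                     WDOConfig(population_size=6, iterations=20, seed=7))
        b = optimize(lambda p: sum(v * v for v in p.values()), sp,
                     WDOConfig(population_size=6, iterations=20, seed=7))
        assert a.best_fitness == b.best_fitness
        assert np.array_equal(a.best_x, b.best_x)
        assert a.history.equals(b.history)


class TestTuneDSSAE:
    def test_missing_mandatory_dimension_rejected(self, separable_blobs):
        from osteosae.wdo import tune_dssae

        X, y = separable_blobs
        sp = SearchSpace([Dimension("epochs", "grid", grid=(10, 20))])
        with pytest.raises(ValueError, match="mandatory"):
            tune_dssae(X, y, space=sp)

    def test_degenerate_budget_returns_valid_model(self, separable_blobs):
        from osteosae.dssae import TrainConfig, predict
        from osteosae.wdo import tune_dssae

        X, y = separable_blobs
        cfg = WDOConfig(population_size=2, iterations=1, seed=0)
        best, model, res = tune_dssae(X, y, config=cfg, hidden_dims=(8, 4, 3, 2),
                                      base_train=TrainConfig(epochs=10, seed=0))
        preds, P = predict(model, X)
        assert len(preds) == len(y)
        assert set(best) >= {"epochs", "batch_size", "learning_rate"}

    def test_identical_seed_identical_best(self, separable_blobs):
        from osteosae.dssae import TrainConfig
        from osteosae.wdo import tune_dssae

        X, y = separable_blobs
        cfg = WDOConfig(population_size=3, iterations=2, seed=5)
        base = TrainConfig(epochs=10, seed=5)
        b1, _, _ = tune_dssae(X, y, config=cfg, hidden_dims=(8, 4, 3, 2), base_train=base)
        b2, _, _ = tune_dssae(X, y, config=cfg, hidden_dims=(8, 4, 3, 2), base_train=base)
        assert b1 == b2
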