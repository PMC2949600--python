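"""Unit and property tests for the gravitation-field engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gravfield.evaluation import get_benchmark
from gravfield.gfa_core import (
    Dust,
    GFAConfig,
    Group,
    MassFunction,
    _initial_state,
    absorb,
    assign_to_groups,
    divide_average,
    divide_power_weight,
    evaluate_mass,
    factorize_near_equal,
    initialize_dusts,
    move_dust,
    multi_minima,
    optimize,
    pseudo_peak_probability,
    run_epoch,
    update_centre,
)


# ---------------------------------------------------------------------------
# mass evaluation


class TestEvaluateMass:
    def test_minimize_sphere_at_origin_is_zero(self):
        f = get_benchmark("sphere").mass_function(50, (-2, 2))
        assert evaluate_mass(f, np.zeros(50)) == 0.0

    @pytest.mark.parametrize(
        "sense,expected", [("minimize", -4.0), ("maximize", 4.0)]
    )
    def test_sense_negation(self, sense, expected):
        f = MassFunction(lambda X: X[:, 0] ** 2, np.array([[-5.0, 5.0]]), sense=sense)
        assert evaluate_mass(f, [2.0]) == expected

    def test_out_of_box_positions_clipped(self):
        f = MassFunction(lambda X: X[:, 0], np.array([[0.0, 1.0]]), sense="maximize")
        assert evaluate_mass(f, [7.0]) == 1.0

    def test_non_finite_value_is_worst_mass(self):
        f = MassFunction(
            lambda X: np.where(X[:, 0] > 0, np.nan, X[:, 0]),
            np.array([[-1.0, 1.0]]),
            sense="maximize",
        )
        assert evaluate_mass(f, [0.5]) == -np.inf

    def test_wrong_dimension_raises(self):
        f = MassFunction(lambda X: X[:, 0], np.array([[0.0, 1.0]]), sense="maximize")
        with pytest.raises(ValueError):
            evaluate_mass(f, [0.1, 0.2])


# ---------------------------------------------------------------------------
# initialization


class TestInitialize:
    def test_dusts_inside_box_with_masses(self, sphere_2d, rng):
        config = GFAConfig(n=10, m=5, seed=0)
        dusts = initialize_dusts(sphere_2d, config, rng)
        assert len(dusts) == 50
        X = np.stack([d.position for d in dusts])
        assert np.all(X >= -2) and np.all(X <= 2)
        for d in dusts:
            assert d.mass == evaluate_mass(sphere_2d, d.position)
            assert not d.is_centre

    def test_uniform_mean_matches_clt(self, rng):
        # 10,000 uniform dusts on [0, 1]: mean within 3 standard errors of 0.5
        f = MassFunction(lambda X: X[:, 0], np.array([[0.0, 1.0]]), sense="maximize")
        dusts = initialize_dusts(f, GFAConfig(n=100, m=100, seed=1), rng)
        mean = np.mean([d.position[0] for d in dusts])
        se = (1 / np.sqrt(12.0)) / np.sqrt(10_000)
        assert abs(mean - 0.5) < 3 * se

    def test_prior_density_used(self, sphere_2d, rng):
        prior = lambda r, size: np.full((size, 2), 0.25)
        dusts = initialize_dusts(sphere_2d, GFAConfig(n=2, m=2, seed=0), rng, prior)
        assert all(np.allclose(d.position, 0.25) for d in dusts)


# ---------------------------------------------------------------------------
# division


class TestDivideAverage:
    def test_12_groups_is_4x3_grid_of_unit_cells(self):
        # brute force over all factor pairs of 12 confirms (4, 3) is closest
        pairs = [(a, 12 // a) for a in range(1, 13) if 12 % a == 0]
        best = min(pairs, key=lambda p: abs(p[0] - p[1]))
        assert sorted(best, reverse=True) == [4, 3]
        regions = divide_average(np.array([[0.0, 4.0], [0.0, 3.0]]), 12, 2)
        assert len(regions) == 12
        areas = [np.prod(regions.bounds(g)[:, 1] - regions.bounds(g)[:, 0]) for g in range(12)]
        assert np.allclose(areas, 1.0)

    def test_200_groups_factor_pair(self):
        pairs = [(a, 200 // a) for a in range(1, 201) if 200 % a == 0]
        best = min(pairs, key=lambda p: abs(p[0] - p[1]))
        assert sorted(factorize_near_equal(200, 2), reverse=True) == sorted(
            best, reverse=True
        ) == [20, 10]

    def test_single_group_is_whole_domain(self):
        domain = np.array([[-1.0, 1.0], [0.0, 5.0]])
        regions = divide_average(domain, 1, 2)
        assert len(regions) == 1
        assert np.allclose(regions.bounds(0), domain)

    def test_prime_m_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="prime"):
            regions = divide_average(np.array([[0.0, 1.0], [0.0, 1.0]]), 7, 2)
        assert len(regions) == 7

    def test_grid_partitions_points_exactly_once(self, rng):
        domain = np.array([[0.0, 4.0], [0.0, 3.0]])
        regions = divide_average(domain, 12, 2)
        X = rng.uniform([0, 0], [4, 3], size=(500, 2))
        gid = regions.assign(X)
        assert np.all((gid >= 0) & (gid < 12))
        for i in range(0, 50):
            b = regions.bounds(int(gid[i]))
            assert np.all(X[i] >= b[:, 0]) and np.all(X[i] <= b[:, 1])

    def test_boundary_point_in_exactly_one_cell(self):
        regions = divide_average(np.array([[0.0, 4.0], [0.0, 4.0]]), 4, 2)
        gid = regions.assign(np.array([[2.0, 2.0], [4.0, 4.0]]))
        assert gid.shape == (2,)  # shared corner and top corner both resolve
        assert 0 <= gid[0] < 4 and gid[1] == 3


class TestDividePowerWeight:
    def test_proportional_split_1d(self):
        # two centres with masses 3 and 1 on [0, 4]: boundary at the 3:1 split
        dusts = [Dust(np.array([1.0]), 3.0), Dust(np.array([3.5]), 1.0)]
        regions = divide_power_weight(dusts, 2, domain=np.array([[0.0, 4.0]]))
        assert np.allclose(regions.edges, [0.0, 3.0, 4.0])

    def test_equal_masses_give_equal_regions(self):
        dusts = [Dust(np.array([1.0]), 2.0), Dust(np.array([3.0]), 2.0)]
        regions = divide_power_weight(dusts, 2, domain=np.array([[0.0, 4.0]]))
        assert np.allclose(regions.edges, [0.0, 2.0, 4.0])

    def test_single_centre_owns_whole_domain(self):
        dusts = [Dust(np.array([2.0]), 5.0)]
        regions = divide_power_weight(dusts, 3, domain=np.array([[0.0, 4.0]]))
        assert len(regions) == 1
        assert np.allclose(regions.edges, [0.0, 4.0])

    def test_min_sep_limits_centre_count(self):
        X = np.array([[0.0, 0.0], [0.01, 0.0], [1.0, 1.0]])
        masses = np.array([3.0, 2.9, 1.0])
        regions = divide_power_weight(
            X, 3, domain=np.array([[0.0, 1.0], [0.0, 1.0]]), masses=masses, min_sep=0.1
        )
        assert len(regions) == 2  # the near-duplicate dust is not a centre


class TestAssign:
    def test_max_mass_dust_becomes_centre(self):
        dusts = [
            Dust(np.array([0.1]), 1.0),
            Dust(np.array([0.2]), 5.0),
            Dust(np.array([0.3]), 2.0),
        ]
        regions = divide_average(np.array([[0.0, 1.0]]), 1, 1)
        groups = assign_to_groups(dusts, regions)
        assert len(groups) == 1
        assert groups[0].centre.mass == 5.0
        assert groups[0].centre.is_centre
        assert len(groups[0].surrounding) == 2

    def test_mass_tie_goes_to_lowest_index(self):
        dusts = [Dust(np.array([0.1]), 5.0), Dust(np.array([0.9]), 5.0)]
        regions = divide_average(np.array([[0.0, 1.0]]), 1, 1)
        groups = assign_to_groups(dusts, regions)
        assert groups[0].centre is dusts[0]

    def test_group_sizes_sum_to_dust_count(self, rng):
        dusts = [
            Dust(p, float(m))
            for p, m in zip(rng.uniform(0, 1, (100, 2)), rng.normal(size=100))
        ]
        regions = divide_average(np.array([[0.0, 1.0], [0.0, 1.0]]), 4, 2)
        groups = assign_to_groups(dusts, regions)
        assert sum(g.dust_count for g in groups) == 100
        for g in groups:
            assert all(d.mass <= g.centre.mass for d in g.surrounding)


# ---------------------------------------------------------------------------
# motion and re-election


class TestMoveDust:
    def test_pace_is_m_times_distance(self, quadratic_1d):
        # dis = 10 with the golden-section weight: pace = 0.618
        f = MassFunction(lambda X: X[:, 0], np.array([[-20.0, 20.0]]), sense="maximize")
        dust = Dust(np.array([0.0]), evaluate_mass(f, [0.0]))
        centre = Dust(np.array([10.0]), evaluate_mass(f, [10.0]), is_centre=True)
        moved = move_dust(dust, centre, 0.0618, f)
        assert moved.position[0] == pytest.approx(0.618)

    def test_straight_segment_2d(self):
        f = MassFunction(
            lambda X: np.zeros(X.shape[0]),
            np.array([[-2.0, 2.0], [-2.0, 2.0]]),
            sense="maximize",
        )
        dust = Dust(np.array([0.0, 0.0]), 0.0)
        centre = Dust(np.array([1.0, 0.0]), 0.0, is_centre=True)
        moved = move_dust(dust, centre, 0.0618, f)
        assert np.allclose(moved.position, [0.0618, 0.0])

    @given(
        st.integers(min_value=1, max_value=30),
        st.floats(min_value=0.01, max_value=0.9),
    )
    @settings(deadline=None, max_examples=30)
    def test_s_moves_contract_by_power(self, s, M):
        f = MassFunction(
            lambda X: np.zeros(X.shape[0]),
            np.array([[-100.0, 100.0], [-100.0, 100.0]]),
            sense="maximize",
        )
        centre = Dust(np.array([3.0, -4.0]), 0.0, is_centre=True)
        dust = Dust(np.array([-5.0, 8.0]), 0.0)
        d0 = np.linalg.norm(dust.position - centre.position)
        for _ in range(s):
            dust = move_dust(dust, centre, M, f)
        d = np.linalg.norm(dust.position - centre.position)
        assert d == pytest.approx(d0 * (1 - M) ** s, rel=1e-12)

    def test_zero_distance_no_move(self, quadratic_1d):
        centre = Dust(np.array([0.5]), 0.0, is_centre=True)
        dust = Dust(np.array([0.5]), 0.0)
        assert move_dust(dust, centre, 0.0618, quadratic_1d) is dust

    def test_centre_refuses_to_move(self, quadratic_1d):
        centre = Dust(np.array([0.5]), 0.0, is_centre=True)
        with pytest.raises(ValueError):
            move_dust(centre, centre, 0.0618, quadratic_1d)


class TestUpdateCentre:
    def test_stronger_surrounding_dust_takes_over(self):
        c = Dust(np.array([0.0]), 5.0, is_centre=True)
        s1, s2 = Dust(np.array([1.0]), 3.0), Dust(np.array([2.0]), 7.0)
        g = update_centre(Group(np.array([[0.0, 3.0]]), c, [s1, s2]))
        assert g.centre is s2 and g.centre.is_centre
        assert c in g.surrounding and not c.is_centre

    def test_tie_keeps_incumbent(self):
        c = Dust(np.array([0.0]), 5.0, is_centre=True)
        g = update_centre(
            Group(np.array([[0.0, 3.0]]), c, [Dust(np.array([1.0]), 3.0), Dust(np.array([2.0]), 5.0)])
        )
        assert g.centre is c

    def test_repeated_move_update_climbs_bell(self, quadratic_1d):
        # dense grid-search oracle for the bell maximum
        grid = np.linspace(0, 1, 20001)[:, None]
        oracle_x = grid[np.argmax(quadratic_1d.mass(grid)), 0]
        dusts = [
            Dust(np.array([x]), evaluate_mass(quadratic_1d, [x])) for x in (0.05, 0.5, 0.9)
        ]
        regions = divide_average(np.array([[0.0, 1.0]]), 1, 1)
        groups = assign_to_groups(dusts, regions)
        g = groups[0]
        for _ in range(400):
            g.surrounding = [
                move_dust(d, g.centre, 0.0618, quadratic_1d) for d in g.surrounding
            ]
            g = update_centre(g)
        assert abs(g.centre.position[0] - oracle_x) < 1e-3


class TestAbsorb:
    def _group(self, positions, masses, centre_idx=0):
        dusts = [Dust(np.array([p]), m) for p, m in zip(positions, masses)]
        dusts[centre_idx].is_centre = True
        sur = [d for i, d in enumerate(dusts) if i != centre_idx]
        return Group(np.array([[0.0, 1.0]]), dusts[centre_idx], sur)

    def test_contracted_group_collapses_to_centre(self):
        g = self._group([0.5, 0.5001, 0.4999], [5.0, 1.0, 2.0])
        survivor = absorb(g, GFAConfig(n=2, m=1), eps=1e-2)
        assert survivor is not None and not survivor.is_centre
        assert g.surrounding == []

    def test_spread_group_survives(self):
        g = self._group([0.5, 0.9, 0.1], [5.0, 1.0, 2.0])
        assert absorb(g, GFAConfig(n=2, m=1), eps=1e-3) is None

    def test_crowded_group_absorbs_immediately(self):
        n = 70
        g = self._group(np.linspace(0, 1, n), np.linspace(1, 2, n), centre_idx=n - 1)
        survivor = absorb(g, GFAConfig(n=2, m=1, crowd_threshold=50), eps=0.0)
        assert survivor is not None

    def test_survivor_count_equals_group_count(self):
        groups = [
            self._group([0.1 * k, 0.1 * k + 1e-6], [2.0, 1.0]) for k in range(1, 6)
        ]
        survivors = [absorb(g, GFAConfig(n=2, m=1), eps=1e-3) for g in groups]
        assert sum(s is not None for s in survivors) == 5


# ---------------------------------------------------------------------------
# epochs and full runs


class TestRunEpoch:
    def test_epoch_best_mass_never_decreases(self, sphere_2d):
        config = GFAConfig(n=10, m=6, s=4, max_epochs=30, seed=7)
        rng = np.random.default_rng(config.seed)
        state = _initial_state(sphere_2d, config, rng)
        prev = state.best_mass
        for _ in range(30):
            state = run_epoch(state, sphere_2d, config, rng)
            assert state.best_mass >= prev
            prev = state.best_mass
        assert state.history == sorted(state.history)

    def test_survivors_equal_group_count_without_replenish(self, sphere_2d):
        config = GFAConfig(n=10, m=4, s=3, replenish=False, division="average", seed=3)
        rng = np.random.default_rng(3)
        state = _initial_state(sphere_2d, config, rng)
        regions = divide_average(sphere_2d.domain, 4, 2)
        n_nonempty = len(np.unique(regions.assign(state.X)))
        state = run_epoch(state, sphere_2d, config, rng)
        assert state.X.shape[0] == n_nonempty

    def test_single_group_converges_to_sampled_argmax(self, quadratic_1d):
        # with one group and a huge absorption eps, one epoch keeps exactly
        # the best sampled dust
        config = GFAConfig(
            n=40, m=1, s=1, seed=5, absorb_distance_eps=10.0, jitter_rate=0.0,
            replenish=False, division="average",
        )
        rng = np.random.default_rng(5)
        state = _initial_state(quadratic_1d, config, rng)
        all_masses = state.mass.copy()
        state = run_epoch(state, quadratic_1d, config, rng)
        assert state.best_mass >= all_masses.max()


class TestOptimize:
    def test_sphere_2d_reaches_global_minimum(self, sphere_2d):
        res = optimize(sphere_2d, GFAConfig(n=20, m=10, s=5, max_epochs=100, seed=11))
        assert res.best_value < 1e-3
        # history is monotone non-increasing for minimization
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_constant_function_converges_immediately(self):
        f = MassFunction(
            lambda X: np.full(X.shape[0], 3.25), np.array([[0.0, 1.0]]), sense="minimize"
        )
        res = optimize(f, GFAConfig(n=5, m=1, s=2, max_epochs=50, stall_epochs=1, seed=0))
        assert res.best_value == 3.25
        assert res.converged and res.epochs_used == 1

    def test_same_seed_reproduces_different_seeds_vary(self, sphere_2d):
        cfg = dict(n=10, m=5, s=3, max_epochs=20)
        a = optimize(sphere_2d, GFAConfig(**cfg, seed=1))
        b = optimize(sphere_2d, GFAConfig(**cfg, seed=1))
        c = optimize(sphere_2d, GFAConfig(**cfg, seed=2))
        assert a.best_value == b.best_value
        assert np.allclose(a.best_position, b.best_position)
        assert a.best_value != c.best_value

    def test_matches_exhaustive_lattice_oracle_1d(self):
        # bumpy 1-D objective: GFA's best must match dense lattice search
        fn = lambda X: np.sin(5 * X[:, 0]) + 0.5 * np.cos(13 * X[:, 0])
        f = MassFunction(fn, np.array([[0.0, 3.0]]), sense="minimize")
        lattice = np.linspace(0, 3, 300001)[:, None]
        oracle = float(fn(lattice).min())
        res = optimize(f, GFAConfig(n=20, m=10, s=5, max_epochs=60, seed=4))
        assert res.best_value == pytest.approx(oracle, abs=1e-5)


class TestMultiMinima:
    def test_three_cosine_minima_found(self):
        f = MassFunction(
            lambda X: np.cos(2 * np.pi * X[:, 0]), np.array([[0.0, 2.5]]), sense="minimize"
        )
        res = multi_minima(
            f, GFAConfig(n=20, m=10, s=5, max_epochs=80, stall_epochs=20, seed=0), 3
        )
        assert res.complete and len(res.minima) == 3
        xs = sorted(float(p[0]) for p, _ in res.minima)
        assert np.allclose(xs, [0.5, 1.5, 2.5], atol=0.01)
        assert all(v == pytest.approx(-1.0, abs=1e-3) for _, v in res.minima)

    def test_unimodal_function_flagged_incomplete(self, sphere_2d):
        res = multi_minima(
            sphere_2d, GFAConfig(n=25, m=10, s=5, max_epochs=60, stall_epochs=20, seed=1), 5
        )
        assert not res.complete
        assert len(res.minima) < 5
        assert res.minima[0][1] < 1e-3

    def test_k1_equals_single_optimum_search(self, sphere_2d):
        cfg = GFAConfig(n=20, m=10, s=5, max_epochs=60, seed=9)
        single = optimize(sphere_2d, cfg)
        multi = multi_minima(sphere_2d, cfg, 1)
        assert multi.minima[0][1] == pytest.approx(single.best_value, rel=1e-12)

    def test_k_must_be_positive(self, sphere_2d):
        with pytest.raises(ValueError):
            multi_minima(sphere_2d, GFAConfig(n=5, m=2), 0)


# ---------------------------------------------------------------------------
# pseudo-peak probability


class TestPseudoPeakProbability:
    def test_direct_arithmetic(self):
        assert pseudo_peak_probability(0.5, 1.0, 11) == pytest.approx(0.5**10)
        assert pseudo_peak_probability(0.5, 1.0, 11) == pytest.approx(9.765625e-4)

    def test_zero_lmax_gives_zero(self):
        assert pseudo_peak_probability(0.0, 1.0, 5) == 0.0

    @given(st.floats(min_value=0.01, max_value=0.99), st.integers(2, 60))
    @settings(deadline=None, max_examples=50)
    def test_decreases_with_group_size(self, ratio, n):
        p1 = pseudo_peak_probability(ratio, 1.0, n)
        p2 = pseudo_peak_probability(ratio, 1.0, n + 1)
        assert 0 <= p2 <= p1 <= 1

    def test_vanishes_for_large_groups(self):
        assert pseudo_peak_probability(0.9, 1.0, 500) < 1e-20

    @pytest.mark.parametrize("lmax,ltot,n", [(1.0, 1.0, 3), (2.0, 1.0, 3), (0.5, 1.0, 1)])
    def test_invalid_inputs_raise(self, lmax, ltot, n):
        with pytest.raises(ValueError):
            pseudo_peak_probability(lmax, ltot, n)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(M=0.0),
            dict(M=1.0),
            dict(n=1),
            dict(m=0),
            dict(s=0),
            dict(jitter_rate=1.5),
            dict(division="voronoi"),
        ],
    )
    def test_bad_config_rejected(self, kw):
        with pytest.raises(ValueError):
            GFAConfig(**kw)
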