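"""Metaheuristic search: update formulas, run contract, box/elitism invariants."""

import math

import numpy as np
import pytest
from scipy import special

import nirselect as ns
from nirselect.exceptions import ParameterError
from nirselect.objective import CostSpec, make_split, CostEvaluator
from nirselect.optimizers import (
    ALGORITHMS,
    BaParams,
    CsoParams,
    FaParams,
    FpoParams,
    GwoParams,
    PsoParams,
    RunResult,
    SearchConfig,
    WoaParams,
    _DRIVERS,
    _Tracker,
    bat_frequency,
    control_schedule,
    derive_seed,
    firefly_move,
    fpo_global_move,
    fpo_local_move,
    gwo_candidate,
    gwo_position,
    levy_sample,
    mantegna_sigma,
    pso_velocity,
    run,
    woa_spiral_move,
)


class TestLevy:
    def test_sigma_matches_independent_gamma_evaluation(self):
        lam = 1.5
        num = special.gamma(1 + lam) * math.sin(math.pi * lam / 2)
        den = special.gamma((1 + lam) / 2) * lam * 2 ** ((lam - 1) / 2)
        assert mantegna_sigma(lam) == pytest.approx((num / den) ** (1 / lam),
                                                    abs=1e-14)

    def test_seeded_determinism(self):
        s1 = levy_sample(1.5, 100, np.random.default_rng(3))
        s2 = levy_sample(1.5, 100, np.random.default_rng(3))
        np.testing.assert_array_equal(s1, s2)

    def test_heavy_tail(self):
        s = levy_sample(1.5, 100_000, np.random.default_rng(7))
        assert np.abs(s).max() > 50 * np.median(np.abs(s))

    @pytest.mark.parametrize("lam", [0.9, 1.0, 2.5])
    def test_exponent_range(self, lam):
        with pytest.raises(ParameterError):
            mantegna_sigma(lam)


class TestSingleStepUpdates:
    """1-D hand-derived cases for each update equation."""

    def test_pso_velocity_hand_case(self):
        v = pso_velocity(v=0.0, x=0.5, pbest=0.5, gbest=0.9,
                         inertia=2.0, a1=1.0, a2=2.0, b1=0.5, b2=0.5)
        assert v == pytest.approx(0.4, abs=1e-12)
        assert 0.5 + v == pytest.approx(0.9, abs=1e-12)

    def test_pso_fixed_point_at_consensus(self):
        v = pso_velocity(0.0, 0.7, 0.7, 0.7, 2.0, 1.0, 2.0, 0.3, 0.8)
        assert v == 0.0

    def test_firefly_hand_case(self):
        # dimmer firefly at 0.8 attracted toward the brighter one at 0.2:
        # x' = 0.8 + exp(-1 * 0.6^2) * (0.2 - 0.8)
        new = firefly_move(xi=0.8, xj=0.2, beta0=1.0, gamma=1.0,
                           alpha_rand=0.0, eps=0.0)
        assert new == pytest.approx(0.8 - 0.6 * math.exp(-0.36), abs=1e-12)

    def test_firefly_attraction_limits(self):
        # zero distance: attraction term has unit weight (beta = beta0)
        assert firefly_move(0.5, 0.5, 1.0, 1.0, 0.0, 0.0) == 0.5
        # infinite absorption: pure random walk
        new = firefly_move(0.2, 0.8, 1.0, 1e12, 1.0, 0.1)
        assert new == pytest.approx(0.3, abs=1e-9)

    def test_bat_frequency_endpoints(self):
        assert bat_frequency(1.0, 0.0, 2.0) == 2.0
        assert bat_frequency(0.0, 0.0, 2.0) == 0.0

    def test_fpo_global_hand_case(self):
        assert fpo_global_move(0.4, 0.8, 1.0, 0.5) == pytest.approx(0.6, abs=1e-12)

    def test_fpo_fixed_points(self):
        assert fpo_global_move(0.8, 0.8, 1.0, 123.0) == pytest.approx(0.8)
        assert fpo_local_move(0.4, 0.6, 0.6, 0.9) == pytest.approx(0.4)

    def test_woa_spiral_hand_case(self):
        # D' = 0.4, l = 0: x' = 0.4 * e^0 * cos(0) + 0.6 = 1.0
        assert woa_spiral_move(0.2, 0.6, b=1.0, l=0.0) == pytest.approx(1.0,
                                                                        abs=1e-12)

    def test_woa_spiral_fixed_point_at_best(self):
        assert woa_spiral_move(0.6, 0.6, 1.0, 0.25) == pytest.approx(0.6)

    def test_control_schedule_endpoints(self):
        assert control_schedule(0, 100) == 2.0
        assert control_schedule(100, 100) == 0.0

    def test_gwo_hand_case(self):
        # A = 0, C = 1 at t=0 with r1 = r2 = 0.5: candidates are the leaders
        a = control_schedule(0, 100)
        a_coef = 2 * a * 0.5 - a
        c_coef = 2 * 0.5
        new = gwo_position(0.2, leaders=[0.9, 0.8, 0.7],
                           a_coefs=[a_coef] * 3, c_coefs=[c_coef] * 3)
        assert a_coef == 0.0
        assert new == pytest.approx(0.8, abs=1e-12)

    def test_gwo_fixed_point_when_leaders_coincide(self):
        new = gwo_position(0.35, leaders=[0.35, 0.35, 0.35],
                           a_coefs=[0.0] * 3, c_coefs=[1.0] * 3)
        assert new == pytest.approx(0.35, abs=1e-15)

    def test_gwo_candidate_uses_absolute_distance(self):
        # D = |C x_L - x| keeps the distance term non-negative
        assert gwo_candidate(0.9, 0.5, 1.0, 1.0) == pytest.approx(0.5 - 0.4)


class _ConstantEvaluator:
    """Flat cost landscape; also records every queried position."""

    def __init__(self, j=0.5):
        self.j = j
        self.positions = []

    def cost_of_position(self, position):
        self.positions.append(np.array(position, copy=True))
        from nirselect.objective import FeatureMask
        return self.j, 0.0, 1, FeatureMask(bits=(1,))


@pytest.mark.parametrize("algorithm", ALGORITHMS)
class TestRunContract:
    def test_curve_monotone_and_consistent(self, algorithm, separable_table):
        res = run(separable_table,
                  SearchConfig(algorithm=algorithm, t_max=20, seed=5))
        assert len(res.curve) == 20
        assert all(a >= b - 1e-15 for a, b in zip(res.curve, res.curve[1:]))
        assert res.best_cost == res.curve[-1]

    def test_best_cost_reproduces_mask_evaluation(self, algorithm,
                                                  separable_table):
        spec = CostSpec()
        res = run(separable_table,
                  SearchConfig(algorithm=algorithm, t_max=15, seed=2), spec)
        split = make_split(separable_table, spec, seed=derive_seed(2, 0))
        j, acc, n_sel = CostEvaluator(separable_table, split,
                                      spec).cost(res.best_mask)
        assert j == res.best_cost
        assert acc == res.best_accuracy
        assert n_sel == res.n_selected

    def test_seeded_determinism(self, algorithm, separable_table):
        cfg = SearchConfig(algorithm=algorithm, t_max=10, seed=4)
        r1 = run(separable_table, cfg)
        r2 = run(separable_table, cfg)
        assert r1.best_mask == r2.best_mask
        assert r1.curve == r2.curve
        assert r1.best_cost == r2.best_cost

    def test_box_invariance_of_every_evaluated_position(self, algorithm):
        ev = _ConstantEvaluator()
        tracker = _Tracker()
        evaluate = tracker.make_eval(ev)
        rng = np.random.default_rng(0)
        params = SearchConfig(algorithm=algorithm).resolved_params()
        _DRIVERS[algorithm](evaluate, params, 6, 5, 12, rng, tracker)
        pos = np.array(ev.positions)
        assert np.all(pos >= 0.0) and np.all(pos <= 1.0)

    def test_constant_landscape_no_spurious_improvement(self, algorithm):
        ev = _ConstantEvaluator(j=0.5)
        tracker = _Tracker()
        evaluate = tracker.make_eval(ev)
        rng = np.random.default_rng(1)
        params = SearchConfig(algorithm=algorithm).resolved_params()
        curve = _DRIVERS[algorithm](evaluate, params, 5, 4, 10, rng, tracker)
        assert curve == [0.5] * 10

    def test_run_result_json_round_trip(self, algorithm, separable_table):
        res = run(separable_table,
                  SearchConfig(algorithm=algorithm, t_max=5, seed=1))
        back = RunResult.from_json(res.to_json())
        assert back.best_mask == res.best_mask
        assert back.curve == res.curve
        assert back.best_cost == res.best_cost


class TestAlgorithmSpecifics:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ParameterError):
            SearchConfig(algorithm="simulated_annealing")

    @pytest.mark.parametrize("algorithm,n", [("gwo", 2), ("fpo", 2), ("pso", 1)])
    def test_population_floor(self, algorithm, n):
        with pytest.raises(ParameterError):
            SearchConfig(algorithm=algorithm, pop_size=n)

    def test_cso_zero_step_zero_abandonment_is_static(self):
        # alpha_step = 0 and Pa = 0: every candidate equals an existing nest,
        # equal costs never replace (strict inequality), nothing moves
        ev = _ConstantEvaluator(j=0.3)
        tracker = _Tracker()
        evaluate = tracker.make_eval(ev)
        rng = np.random.default_rng(2)
        params = CsoParams(alpha_step=0.0, pa=0.0)
        _DRIVERS["cso"](evaluate, params, 5, 3, 8, rng, tracker)
        initial = {tuple(p) for p in ev.positions[:5]}
        assert all(tuple(p) in initial for p in ev.positions)

    def test_cso_abandonment_floor_count(self):
        # Pa=0.25, N=10: floor(2.5)=2 nests re-seeded per generation, so each
        # generation costs N + 2 evaluations on top of the N initial ones
        ev = _ConstantEvaluator()
        tracker = _Tracker()
        rng = np.random.default_rng(3)
        _DRIVERS["cso"](tracker.make_eval(ev), CsoParams(), 10, 3, 7, rng, tracker)
        assert tracker.evaluations == 10 + 7 * (10 + 2)

    def test_pso_literal_preset_matches_reported_parameters(self):
        lit = PsoParams.literal()
        assert (lit.inertia, lit.a1, lit.a2) == (2.0, 1.0, 2.0)

    def test_different_seeds_explore_differently(self, separable_table):
        r1 = run(separable_table, SearchConfig(algorithm="gwo", t_max=10, seed=1))
        r2 = run(separable_table, SearchConfig(algorithm="gwo", t_max=10, seed=2))
        assert r1.curve != r2.curve or r1.best_mask != r2.best_mask
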