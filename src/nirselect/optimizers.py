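"""Continuous population metaheuristics for wrapper feature selection.

Seven algorithms search the box [0, 1]^D to minimize the wrapper cost
(accuracy + subset-size penalty): particle swarm optimization (PSO), cuckoo
search (CSO), the firefly algorithm (FA), the bat algorithm (BA), flower
pollination optimization (FPO), the whale optimization algorithm (WOA) and
grey wolf optimization (GWO). Positions leaving the box are clamped to it;
a position is scored by thresholding it into a feature subset at 0.5.

All algorithms share one run contract: a seeded uniform initialization of
N positions, one evaluation pass, then exactly T step-evaluate cycles with
an elitist best-so-far record, yielding a non-increasing length-T
convergence curve and a fully deterministic result for a given seed. The
study settings are T = 100 iterations and N = 10 individuals.

The single-step update formulas (``pso_velocity``, ``firefly_move``,
``woa_spiral_move``, ``gwo_candidate``...) are exposed as pure functions so
they can be checked against hand-derived values independently of the
stochastic drivers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .exceptions import ParameterError
from .features import FeatureTable
from .objective import CostEvaluator, CostSpec, FeatureMask, make_split

__all__ = [
    "ALGORITHMS",
    "SearchConfig",
    "PsoParams",
    "CsoParams",
    "FaParams",
    "BaParams",
    "FpoParams",
    "WoaParams",
    "GwoParams",
    "RunResult",
    "levy_sample",
    "mantegna_sigma",
    "control_schedule",
    "pso_velocity",
    "firefly_move",
    "bat_frequency",
    "fpo_global_move",
    "fpo_local_move",
    "woa_spiral_move",
    "woa_encircle_move",
    "gwo_candidate",
    "gwo_position",
    "run",
]

ALGORITHMS = ("pso", "cso", "fa", "ba", "fpo", "woa", "gwo")


# -- parameter records (defaults follow the study's configuration table) -----

@dataclass(frozen=True)
class PsoParams:
    """Damped particle swarm: inertia decreasing linearly 0.9 -> 0.4 over
    the run, acceleration coefficients c1 = c2 = 2 and velocity clamped to
    ±vmax. A constant inertia above 1 doubles the velocity every iteration
    and freezes the clamped swarm at box corners, so the ``literal()``
    parameter set (inertia 2, c1 = 1, c2 = 2) is kept only as a preset."""

    inertia: float = 0.9
    inertia_end: float | None = 0.4  # None -> constant inertia
    a1: float = 2.0
    a2: float = 2.0
    vmax: float = 0.5

    @classmethod
    def literal(cls) -> "PsoParams":
        return cls(inertia=2.0, inertia_end=None, a1=1.0, a2=2.0, vmax=0.9)


@dataclass(frozen=True)
class CsoParams:
    alpha_step: float = 1.0
    levy_lambda: float = 1.5
    pa: float = 0.25  # abandoned fraction of worst nests


@dataclass(frozen=True)
class FaParams:
    beta0: float = 1.0
    gamma: float = 1.0
    alpha_rand: float = 1.0


@dataclass(frozen=True)
class BaParams:
    fmin: float = 0.0
    fmax: float = 2.0
    loudness0: float = 2.0
    loudness_decay: float = 0.9
    pulse_growth: float = 0.9
    pulse0: float = 0.5


@dataclass(frozen=True)
class FpoParams:
    p_switch: float = 0.8
    levy_lambda: float = 1.5
    step_scale: float = 1.0


@dataclass(frozen=True)
class WoaParams:
    b: float = 1.0  # logarithmic spiral constant


@dataclass(frozen=True)
class GwoParams:
    pass  # GWO is parameter-free beyond T and N


_PARAM_TYPES = {
    "pso": PsoParams,
    "cso": CsoParams,
    "fa": FaParams,
    "ba": BaParams,
    "fpo": FpoParams,
    "woa": WoaParams,
    "gwo": GwoParams,
}


@dataclass(frozen=True)
class SearchConfig:
    """One optimizer run: algorithm, iteration/population budget and seed."""

    algorithm: str = "gwo"
    t_max: int = 100
    pop_size: int = 10
    seed: int = 0
    params: object | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.t_max < 1:
            raise ParameterError("t_max must be >= 1")
        min_n = 3 if self.algorithm in ("gwo", "fpo") else 2
        if self.pop_size < min_n:
            raise ParameterError(
                f"pop_size must be >= {min_n} for {self.algorithm}"
            )
        if self.params is not None and not isinstance(
            self.params, _PARAM_TYPES[self.algorithm]
        ):
            raise ParameterError(
                f"params must be {_PARAM_TYPES[self.algorithm].__name__}"
            )

    def resolved_params(self):
        return self.params if self.params is not None else _PARAM_TYPES[self.algorithm]()


@dataclass
class RunResult:
    """Outcome of one seeded optimizer run."""

    algorithm: str
    best_mask: FeatureMask
    best_cost: float
    best_accuracy: float
    n_selected: int
    curve: list[float]
    evaluations: int
    seed: int

    def to_json(self) -> str:
        return json.dumps({
            "algorithm": self.algorithm,
            "best_mask": self.best_mask.to_string(),
            "best_cost": self.best_cost,
            "best_accuracy": self.best_accuracy,
            "n_selected": self.n_selected,
            "curve": self.curve,
            "evaluations": self.evaluations,
            "seed": self.seed,
        })

    @classmethod
    def from_json(cls, s: str | Path) -> "RunResult":
        obj = json.loads(s if isinstance(s, str) else s.read_text())
        return cls(
            algorithm=obj["algorithm"],
            best_mask=FeatureMask.from_string(obj["best_mask"]),
            best_cost=obj["best_cost"],
            best_accuracy=obj["best_accuracy"],
            n_selected=obj["n_selected"],
            curve=list(obj["curve"]),
            evaluations=obj["evaluations"],
            seed=obj["seed"],
        )


# -- Lévy flights -------------------------------------------------------------

def mantegna_sigma(lam: float) -> float:
    """Closed-form scale of the Mantegna Lévy-step numerator,

    sigma_u = [ Gamma(1+lam) sin(pi lam / 2)
                / (Gamma((1+lam)/2) lam 2^((lam-1)/2)) ]^(1/lam).
    """
    if not (1.0 < lam <= 2.0):
        raise ParameterError("levy exponent must satisfy 1 < lambda <= 2")
    num = math.gamma(1.0 + lam) * math.sin(math.pi * lam / 2.0)
    den = math.gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0)
    return (num / den) ** (1.0 / lam)


def levy_sample(lam: float, size, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed Lévy steps via the Mantegna scheme: u / |v|^(1/lam)."""
    sigma = mantegna_sigma(lam)
    u = rng.normal(0.0, sigma, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / lam)


# -- pure single-step update formulas -----------------------------------------

def control_schedule(t: int, t_max: int) -> float:
    """Linearly decreasing exploration control a = 2 (1 - t / t_max)."""
    return 2.0 * (1.0 - t / t_max)


def pso_velocity(v, x, pbest, gbest, inertia, a1, a2, b1, b2):
    """v' = inertia*v + a1*b1*(pbest - x) + a2*b2*(gbest - x)."""
    v, x = np.asarray(v, float), np.asarray(x, float)
    return (inertia * v
            + a1 * np.asarray(b1, float) * (np.asarray(pbest, float) - x)
            + a2 * np.asarray(b2, float) * (np.asarray(gbest, float) - x))


def firefly_move(xi, xj, beta0, gamma, alpha_rand, eps):
    """Move the dimmer firefly i toward the brighter j:
    x_i' = x_i + beta0 exp(-gamma r_ij^2)(x_j - x_i) + alpha_rand * eps."""
    xi, xj = np.asarray(xi, float), np.asarray(xj, float)
    r2 = float(np.sum((xj - xi) ** 2))
    return xi + beta0 * np.exp(-gamma * r2) * (xj - xi) + alpha_rand * np.asarray(eps, float)


def bat_frequency(beta: float, fmin: float, fmax: float) -> float:
    """f = fmin + (fmax - fmin) * beta with beta ~ U(0, 1)."""
    return fmin + (fmax - fmin) * beta


def fpo_global_move(x, gbest, step_scale, levy_step):
    """Global pollination: x' = x + step_scale * L * (g* - x)."""
    x = np.asarray(x, float)
    return x + step_scale * np.asarray(levy_step, float) * (np.asarray(gbest, float) - x)


def fpo_local_move(x, xj, xk, eps: float):
    """Local pollination: x' = x + eps * (x_j - x_k)."""
    return np.asarray(x, float) + eps * (np.asarray(xj, float) - np.asarray(xk, float))


def woa_spiral_move(x, xbest, b: float, l: float):
    """Bubble-net spiral: x' = |x* - x| e^{b l} cos(2 pi l) + x*."""
    x, xbest = np.asarray(x, float), np.asarray(xbest, float)
    d_prime = np.abs(xbest - x)
    return d_prime * np.exp(b * l) * np.cos(2.0 * np.pi * l) + xbest


def woa_encircle_move(x, target, a_coef: float, c_coef: float):
    """Encircling/search move: x' = target - A |C target - x|."""
    x, target = np.asarray(x, float), np.asarray(target, float)
    return target - a_coef * np.abs(c_coef * target - x)


def gwo_candidate(x, leader, a_coef, c_coef):
    """Leader-guided candidate: x_l = x_L - A * |C x_L - x|."""
    x, leader = np.asarray(x, float), np.asarray(leader, float)
    return leader - np.asarray(a_coef, float) * np.abs(
        np.asarray(c_coef, float) * leader - x
    )


def gwo_position(x, leaders, a_coefs, c_coefs):
    """Average of the three leader-guided candidates (alpha, beta, delta)."""
    cands = [gwo_candidate(x, L, a, c)
             for L, a, c in zip(leaders, a_coefs, c_coefs)]
    return sum(cands) / 3.0


# -- run machinery ------------------------------------------------------------

def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


class _Tracker:
    """Elitist best-so-far record over every evaluated position."""

    def __init__(self) -> None:
        self.best_j = math.inf
        self.best_acc = 0.0
        self.best_n_sel = 0
        self.best_mask: FeatureMask | None = None
        self.evaluations = 0

    def make_eval(self, evaluator: CostEvaluator) -> Callable[[np.ndarray], float]:
        def evaluate(position: np.ndarray) -> float:
            j, acc, n_sel, mask = evaluator.cost_of_position(position)
            self.evaluations += 1
            if j < self.best_j:
                self.best_j, self.best_acc = j, acc
                self.best_n_sel, self.best_mask = n_sel, mask
            return j
        return evaluate


def _init_population(evaluate, rng, n, d) -> tuple[np.ndarray, np.ndarray]:
    x = rng.uniform(0.0, 1.0, size=(n, d))
    costs = np.array([evaluate(x[i]) for i in range(n)])
    return x, costs


def _run_pso(evaluate, params: PsoParams, n, d, t_max, rng, tracker) -> list[float]:
    x, costs = _init_population(evaluate, rng, n, d)
    v = np.zeros((n, d))
    pbest = x.copy()
    pbest_cost = costs.copy()
    gbest = x[int(np.argmin(costs))].copy()
    gbest_cost = float(np.min(costs))
    curve = []
    for t in range(t_max):
        if params.inertia_end is None:
            w = params.inertia
        else:
            w = params.inertia - (params.inertia - params.inertia_end) * t / t_max
        b1 = rng.uniform(size=(n, d))
        b2 = rng.uniform(size=(n, d))
        v = pso_velocity(v, x, pbest, gbest, w, params.a1, params.a2, b1, b2)
        v = np.clip(v, -params.vmax, params.vmax)
        x = _clamp(x + v)
        for i in range(n):
            costs[i] = evaluate(x[i])
            if costs[i] < pbest_cost[i]:
                pbest_cost[i] = costs[i]
                pbest[i] = x[i].copy()
                if costs[i] < gbest_cost:
                    gbest_cost = costs[i]
                    gbest = x[i].copy()
        curve.append(tracker.best_j)
    return curve


def _run_cso(evaluate, params: CsoParams, n, d, t_max, rng, tracker) -> list[float]:
    x, costs = _init_population(evaluate, rng, n, d)
    n_abandon = int(math.floor(params.pa * n))
    curve = []
    for _ in range(t_max):
        for _ in range(n):  # one Lévy cuckoo per nest per generation
            i = int(rng.integers(n))
            cand = _clamp(x[i] + params.alpha_step
                          * levy_sample(params.levy_lambda, d, rng))
            jc = evaluate(cand)
            j = int(rng.integers(n))
            if jc < costs[j]:  # strict greedy replacement of a random nest
                x[j], costs[j] = cand, jc
        if n_abandon:
            order = np.argsort(costs, kind="stable")
            worst = order[n - n_abandon:]
            survivors = order[: n - n_abandon]
            for w in worst:
                src = x[int(survivors[int(rng.integers(len(survivors)))])]
                cand = _clamp(src + params.alpha_step
                              * levy_sample(params.levy_lambda, d, rng))
                x[w], costs[w] = cand, evaluate(cand)
        curve.append(tracker.best_j)
    return curve


def _run_fa(evaluate, params: FaParams, n, d, t_max, rng, tracker) -> list[float]:
    x, costs = _init_population(evaluate, rng, n, d)
    curve = []
    for _ in range(t_max):
        intensity = costs.copy()  # lower cost = brighter
        for i in range(n):
            attracted = False
            for j in range(n):
                if intensity[j] < intensity[i]:
                    eps = rng.uniform(-0.5, 0.5, size=d)
                    x[i] = _clamp(firefly_move(
                        x[i], x[j], params.beta0, params.gamma,
                        params.alpha_rand, eps))
                    attracted = True
            if not attracted:  # the brightest walks randomly
                eps = rng.uniform(-0.5, 0.5, size=d)
                x[i] = _clamp(x[i] + params.alpha_rand * eps)
        for i in range(n):
            costs[i] = evaluate(x[i])
        curve.append(tracker.best_j)
    return curve


def _run_ba(evaluate, params: BaParams, n, d, t_max, rng, tracker) -> list[float]:
    x, costs = _init_population(evaluate, rng, n, d)
    v = np.zeros((n, d))
    loudness = np.full(n, params.loudness0)
    pulse = np.full(n, params.pulse0)
    best_cost = float(np.min(costs))
    xbest = x[int(np.argmin(costs))].copy()
    curve = []
    for t in range(t_max):
        for i in range(n):
            beta = float(rng.uniform())
            f = bat_frequency(beta, params.fmin, params.fmax)
            v[i] = v[i] + (x[i] - xbest) * f
            x[i] = _clamp(x[i] + v[i])
            costs[i] = evaluate(x[i])
            if rng.uniform() < pulse[i]:
                eps = rng.uniform(-1.0, 1.0, size=d)
                cand = _clamp(xbest + eps * float(loudness.max()))
                prev_best = tracker.best_j  # best known before this candidate
                jc = evaluate(cand)
                # acceptance: audible AND strictly better than the best known
                if rng.uniform() < loudness[i] and jc < prev_best:
                    x[i], costs[i] = cand, jc
                    loudness[i] *= params.loudness_decay
                    pulse[i] = params.pulse0 * (
                        1.0 - math.exp(-params.pulse_growth * (t + 1))
                    )
            if costs[i] < best_cost:
                best_cost = float(costs[i])
                xbest = x[i].copy()
        curve.append(tracker.best_j)
    return curve


def _run_fpo(evaluate, params: FpoParams, n, d, t_max, rng, tracker) -> list[float]:
    x, costs = _init_population(evaluate, rng, n, d)
    gbest = x[int(np.argmin(costs))].copy()
    gbest_cost = float(np.min(costs))
    curve = []
    for _ in range(t_max):
        for i in range(n):
            if rng.uniform() < params.p_switch:
                step = levy_sample(params.levy_lambda, d, rng)
                cand = fpo_global_move(x[i], gbest, params.step_scale, step)
            else:
                eps = float(rng.uniform())
                j, k = rng.choice(n, size=2, replace=False)
                cand = fpo_local_move(x[i], x[j], x[k], eps)
            cand = _clamp(cand)
            jc = evaluate(cand)
            if jc < costs[i]:  # greedy acceptance
                x[i], costs[i] = cand, jc
                if jc < gbest_cost:
                    gbest_cost, gbest = jc, cand.copy()
        curve.append(tracker.best_j)
    return curve


def _run_woa(evaluate, params: WoaParams, n, d, t_max, rng, tracker) -> list[float]:
    x, costs = _init_population(evaluate, rng, n, d)
    xbest = x[int(np.argmin(costs))].copy()
    best_cost = float(np.min(costs))
    curve = []
    for t in range(t_max):
        a = control_schedule(t, t_max)
        for i in range(n):
            p = float(rng.uniform())
            # A and C are per-dimension coefficient vectors, as in the
            # original whale-optimization reference implementation
            a_coef = 2.0 * a * rng.uniform(size=d) - a
            c_coef = 2.0 * rng.uniform(size=d)
            if p < 0.5:
                rand_whale = x[int(rng.integers(n))].copy()
                encircling = np.abs(a_coef) < 1.0
                target = np.where(encircling, xbest, rand_whale)
                x[i] = _clamp(target - a_coef * np.abs(c_coef * target - x[i]))
            else:
                l = float(rng.uniform(-1.0, 1.0))
                x[i] = _clamp(woa_spiral_move(x[i], xbest, params.b, l))
        for i in range(n):
            costs[i] = evaluate(x[i])
            if costs[i] < best_cost:
                best_cost = float(costs[i])
                xbest = x[i].copy()
        curve.append(tracker.best_j)
    return curve


def _run_gwo(evaluate, params: GwoParams, n, d, t_max, rng, tracker) -> list[float]:
    x, costs = _init_population(evaluate, rng, n, d)
    order = np.argsort(costs, kind="stable")[:3]
    leaders = [x[int(i)].copy() for i in order]
    leader_costs = [float(costs[int(i)]) for i in order]
    curve = []
    for t in range(t_max):
        a = 2.0 - 2.0 * t / t_max
        for i in range(n):
            a_coefs = [2.0 * a * rng.uniform(size=d) - a for _ in range(3)]
            c_coefs = [2.0 * rng.uniform(size=d) for _ in range(3)]
            x[i] = _clamp(gwo_position(x[i], leaders, a_coefs, c_coefs))
        for i in range(n):
            costs[i] = evaluate(x[i])
            # elitist leader update: keep the three best solutions ever seen
            for rank in range(3):
                if costs[i] < leader_costs[rank]:
                    leaders.insert(rank, x[i].copy())
                    leader_costs.insert(rank, float(costs[i]))
                    del leaders[3], leader_costs[3]
                    break
        curve.append(tracker.best_j)
    return curve


_DRIVERS = {
    "pso": _run_pso,
    "cso": _run_cso,
    "fa": _run_fa,
    "ba": _run_ba,
    "fpo": _run_fpo,
    "woa": _run_woa,
    "gwo": _run_gwo,
}


def derive_seed(seed: int, stream: int) -> int:
    """Counter-based sub-seed derivation; stable across algorithm additions."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    return int(ss.generate_state(1)[0] % (2**31))


def run(table: FeatureTable, config: SearchConfig,
        cost_spec: CostSpec = CostSpec()) -> RunResult:
    """Execute one seeded metaheuristic run against the wrapper cost.

    The holdout split is derived from ``config.seed`` (stream 0) and fixed
    for the whole run; the search randomness uses an independent stream
    (stream 1). Identical inputs yield a bit-identical :class:`RunResult`.
    """
    params = config.resolved_params()
    split = make_split(table, cost_spec, seed=derive_seed(config.seed, 0))
    evaluator = CostEvaluator(table, split, cost_spec)
    tracker = _Tracker()
    evaluate = tracker.make_eval(evaluator)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    curve = _DRIVERS[config.algorithm](
        evaluate, params, config.pop_size, table.n_features,
        config.t_max, rng, tracker,
    )
    assert tracker.best_mask is not None
    return RunResult(
        algorithm=config.algorithm,
        best_mask=tracker.best_mask,
        best_cost=tracker.best_j,
        best_accuracy=tracker.best_acc,
        n_selected=tracker.best_n_sel,
        curve=curve,
        evaluations=tracker.evaluations,
        seed=config.seed,
    )
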