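"""Derivative-free optimizers for the tuning vector phi = (lambda, eps, tau).

All algorithms maximize a black-box objective over the box
lambda in [0,1], eps in [0, 25] (the grid's restriction of the unbounded
shape-exponent axis; beyond roughly eps = 25 the studied layouts are past the
extreme borrowing boundary anyway), tau in [0,1].  Every objective call goes
through a shared counting wrapper, so budgets are enforced uniformly —
including out-of-bounds proposals of the unbounded simulated annealing
variant, which consume budget but are never accepted.

Eight study configurations are provided: bounded simulated annealing at start
temperatures 100/10/1 (reflection at the box walls), unbounded simulated
annealing at start temperature 10 ("invalid outside the box"), differential
evolution (rand/1/bin, pop 40, F = 0.8, CR = 0.5), the grey wolf optimizer
(pop 40, linear 2 -> 0 exploration decay), a COBYLA adapter, and the
deterministic 10 x 10 x 10 grid search.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from .design import TuningParams

__all__ = [
    "SearchSpace",
    "OptProblem",
    "OptResult",
    "reflect",
    "sa_bounded",
    "sa_unbounded",
    "de",
    "gwo",
    "cobyla",
    "grid_search",
    "default_grid",
    "ALGORITHMS",
    "run_algorithm",
]

Objective = Callable[[TuningParams], float]


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds of the three tuning parameters."""

    lambda_bounds: tuple[float, float] = (0.0, 1.0)
    epsilon_bounds: tuple[float, float] = (0.0, 25.0)
    tau_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in self.as_pairs():
            if not hi > lo:
                raise ValueError("upper bound must exceed lower bound")

    def as_pairs(self) -> tuple[tuple[float, float], ...]:
        return (self.lambda_bounds, self.epsilon_bounds, self.tau_bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([p[0] for p in self.as_pairs()])

    @property
    def upper(self) -> np.ndarray:
        return np.array([p[1] for p in self.as_pairs()])

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass
class OptProblem:
    """A maximization problem: objective, box, evaluation budget, seed."""

    objective: Objective
    space: SearchSpace = field(default_factory=SearchSpace)
    budget: int = 1000
    seed: int = 0
    start: TuningParams | None = None

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass
class OptResult:
    """Best point found, evaluation accounting and the full trajectory."""

    best_phi: TuningParams
    best_value: float
    n_evals: int
    trajectory: list[tuple[int, TuningParams, float]]
    elapsed: float
    algorithm: str = ""
    converged: bool = True

    def trajectory_array(self) -> np.ndarray:
        """(n_evals, 5) array: eval index, lambda, eps, tau, value."""
        return np.array(
            [[k, p.lambda_, p.epsilon, p.tau, v] for k, p, v in self.trajectory]
        )


class _BudgetExhausted(Exception):
    pass


class _Recorder:
    """Counts evaluations, records the trajectory and tracks the best point.

    Invalid (out-of-bounds) evaluations are recorded with value -inf and
    still consume budget.
    """

    def __init__(self, problem: OptProblem):
        self.problem = problem
        self.n_evals = 0
        self.trajectory: list[tuple[int, TuningParams, float]] = []
        self.best_phi: TuningParams | None = None
        self.best_value = -np.inf

    def __call__(self, x: np.ndarray, valid: bool = True) -> float:
        if self.n_evals >= self.problem.budget:
            raise _BudgetExhausted
        self.n_evals += 1
        phi = TuningParams.from_array(np.asarray(x, dtype=float))
        value = self.problem.objective(phi) if valid else -np.inf
        self.trajectory.append((self.n_evals, phi, value))
        if value > self.best_value or self.best_phi is None:
            self.best_phi, self.best_value = phi, value
        return value

    def invalid(self, x: np.ndarray) -> float:
        """Record an out-of-bounds proposal without evaluating the objective."""
        if self.n_evals >= self.problem.budget:
            raise _BudgetExhausted
        self.n_evals += 1
        # clip only for recording a representable phi; the value is -inf
        lo, hi = self.problem.space.lower, self.problem.space.upper
        phi = TuningParams.from_array(np.clip(np.asarray(x, float), lo, hi))
        self.trajectory.append((self.n_evals, phi, -np.inf))
        return -np.inf

    def result(self, algorithm: str, t0: float, converged: bool = True) -> OptResult:
        if self.best_phi is None:
            raise RuntimeError("no evaluation was performed")
        return OptResult(
            best_phi=self.best_phi,
            best_value=self.best_value,
            n_evals=self.n_evals,
            trajectory=self.trajectory,
            elapsed=time.perf_counter() - t0,
            algorithm=algorithm,
            converged=converged,
        )


def reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real into [lo, hi] by repeated reflection at the walls.

    Equivalent to the affine-plus-remainder construction: the map has period
    2(hi - lo) and is the identity on [lo, hi].
    """
    if not hi > lo:
        raise ValueError("hi must exceed lo")
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    return lo + (width - abs(y - width))


def _initial_point(problem: OptProblem, rng: np.random.Generator) -> np.ndarray:
    if problem.start is not None:
        x0 = problem.start.as_array()
        if not problem.space.contains(x0):
            raise ValueError("start point lies outside the search space")
        return x0
    lo, hi = problem.space.lower, problem.space.upper
    return rng.uniform(lo, hi)


def _sa(
    problem: OptProblem,
    t_start: float,
    bounded: bool,
    t_final: float = 1e-8,
    step_frac: float = 0.1,
    step_frac_final: float = 0.05,
) -> OptResult:
    """Simulated annealing core.

    Geometric cooling from ``t_start`` to ``t_final`` over the budget, one
    objective evaluation per temperature step, Metropolis acceptance of
    worsening moves with probability exp(delta/T).  Proposals are independent
    Gaussian steps per dimension whose width decays geometrically from 10% of
    each axis range to ``step_frac_final`` of that width — coarse exploration
    early, fine localization late.  The cold final temperature keeps the
    late-phase thermal jitter (radius ~ sqrt(T)) far below the proposal
    width, so the walk settles onto the optimum instead of rattling around
    it.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(problem.seed)
    rec = _Recorder(problem)
    lo, hi = problem.space.lower, problem.space.upper
    base_scale = step_frac * (hi - lo)
    cool = (
        (t_final / t_start) ** (1.0 / max(problem.budget - 1, 1))
        if problem.budget > 1
        else 1.0
    )
    try:
        x = _initial_point(problem, rng)
        u = rec(x)
        temp = t_start
        while True:
            scale = base_scale * step_frac_final ** (
                rec.n_evals / problem.budget
            )
            prop = x + rng.normal(0.0, scale)
            if bounded:
                prop = np.array(
                    [reflect(v, l, h) for v, l, h in zip(prop, lo, hi)]
                )
                u_prop = rec(prop)
            elif problem.space.contains(prop):
                u_prop = rec(prop)
            else:
                u_prop = rec.invalid(prop)
            delta = u_prop - u
            if delta >= 0 or (
                np.isfinite(delta)
                and temp > 0
                and rng.random() < np.exp(delta / temp)
            ):
                x, u = prop, u_prop
            temp *= cool
    except _BudgetExhausted:
        pass
    name = f"sa_bounded_t{t_start:g}" if bounded else f"sa_unbounded_t{t_start:g}"
    return rec.result(name, t0)


def sa_bounded(problem: OptProblem, t_start: float = 1.0) -> OptResult:
    """Bounded simulated annealing: proposals reflected into the box."""
    return _sa(problem, t_start, bounded=True)


def sa_unbounded(problem: OptProblem, t_start: float = 10.0) -> OptResult:
    """Unbounded simulated annealing: out-of-bounds proposals are counted as
    invalid evaluations (value -inf) and never accepted."""
    return _sa(problem, t_start, bounded=False)


def de(
    problem: OptProblem,
    pop_size: int = 40,
    scale: float = 0.8,
    crossover: float = 0.5,
) -> OptResult:
    """Differential evolution, rand/1/bin with greedy selection.

    Donors are ``x_a + scale * (x_b - x_c)`` over distinct population members,
    clipped into the box; binomial crossover keeps at least one donor
    component; offspring replace parents when at least as good.
    """
    if problem.budget < pop_size:
        raise ValueError("budget must cover one full population")
    t0 = time.perf_counter()
    rng = np.random.default_rng(problem.seed)
    rec = _Recorder(problem)
    lo, hi = problem.space.lower, problem.space.upper
    d = len(lo)
    pop = rng.uniform(lo, hi, size=(pop_size, d))
    try:
        fitness = np.array([rec(x) for x in pop])
        while True:
            for i in range(pop_size):
                a, b, c = rng.choice(
                    [k for k in range(pop_size) if k != i], size=3, replace=False
                )
                donor = np.clip(pop[a] + scale * (pop[b] - pop[c]), lo, hi)
                mask = rng.random(d) < crossover
                mask[rng.integers(d)] = True
                trial = np.where(mask, donor, pop[i])
                u = rec(trial)
                if u >= fitness[i]:
                    pop[i], fitness[i] = trial, u
    except _BudgetExhausted:
        pass
    return rec.result("de", t0)


def gwo(problem: OptProblem, pop_size: int = 40) -> OptResult:
    """Grey wolf optimizer, canonical linear-decay variant.

    Candidates move to the mean of three leader-guided points (alpha, beta,
    delta wolves); the exploration coefficient decays linearly from 2 to 0
    over the generation budget; positions are clipped into the box.
    """
    if problem.budget < pop_size:
        raise ValueError("budget must cover one full population")
    t0 = time.perf_counter()
    rng = np.random.default_rng(problem.seed)
    rec = _Recorder(problem)
    lo, hi = problem.space.lower, problem.space.upper
    d = len(lo)
    pop = rng.uniform(lo, hi, size=(pop_size, d))
    n_gens = max(problem.budget // pop_size - 1, 1)
    try:
        fitness = np.array([rec(x) for x in pop])
        gen = 0
        while True:
            order = np.argsort(fitness)[::-1]
            leaders = pop[order[:3]]
            a = 2.0 * max(1.0 - gen / n_gens, 0.0)
            new_pop = np.empty_like(pop)
            for i in range(pop_size):
                guided = np.empty((3, d))
                for l, lead in enumerate(leaders):
                    A = a * (2.0 * rng.random(d) - 1.0)
                    C = 2.0 * rng.random(d)
                    guided[l] = lead - A * np.abs(C * lead - pop[i])
                new_pop[i] = np.clip(guided.mean(axis=0), lo, hi)
            new_fitness = np.array([rec(x) for x in new_pop])
            pop, fitness = new_pop, new_fitness
            gen += 1
    except _BudgetExhausted:
        pass
    return rec.result("gwo", t0)


def cobyla(
    problem: OptProblem, xtol: float = 1e-6, ftol: float = 0.0
) -> OptResult:
    """COBYLA adapter: linear-approximation trust-region search.

    Box bounds are imposed as linear inequality constraints; the wrapper
    additionally folds every iterate into the box before evaluation, so all
    recorded evaluations are feasible.  Non-convergence is reported via
    ``converged``, never raised.
    """
    t0 = time.perf_counter()
    rng = np.random.default_rng(problem.seed)
    rec = _Recorder(problem)
    lo, hi = problem.space.lower, problem.space.upper
    x0 = _initial_point(problem, rng)

    def neg_obj(x: np.ndarray) -> float:
        return -rec(np.clip(x, lo, hi))

    constraints = []
    for k in range(len(lo)):
        constraints.append(
            {"type": "ineq", "fun": lambda x, k=k: x[k] - lo[k]}
        )
        constraints.append(
            {"type": "ineq", "fun": lambda x, k=k: hi[k] - x[k]}
        )
    converged = True
    try:
        res = optimize.minimize(
            neg_obj,
            x0,
            method="COBYLA",
            constraints=constraints,
            tol=xtol,
            options={"maxiter": problem.budget, "rhobeg": 0.2},
        )
        converged = bool(res.success)
    except _BudgetExhausted:
        converged = False
    return rec.result("cobyla", t0, converged=converged)


def default_grid() -> dict[str, list[float]]:
    """The study's 10 x 10 x 10 search grid (1000 combinations)."""
    return {
        "lambda_": [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99, 0.999],
        "epsilon": [0.0, 0.5, 1.0, 1.5, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0],
        "tau": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0],
    }


def grid_search(
    problem: OptProblem, grid: dict[str, list[float]] | None = None
) -> OptResult:
    """Exhaustive, deterministic search over the parameter grid.

    Combinations are visited in row-major (lambda, eps, tau) order and ties
    are broken by first occurrence.
    """
    t0 = time.perf_counter()
    grid = grid or default_grid()
    rec = _Recorder(problem)
    try:
        for lam in grid["lambda_"]:
            for eps in grid["epsilon"]:
                for tau in grid["tau"]:
                    rec(np.array([lam, eps, tau]))
    except _BudgetExhausted:
        pass
    return rec.result("grid_search", t0)


# The eight study configurations of the algorithm-comparison part.
ALGORITHMS: dict[str, dict] = {
    "sa_bounded_t100": {"fn": sa_bounded, "kwargs": {"t_start": 100.0},
                        "stochastic": True},
    "sa_bounded_t10": {"fn": sa_bounded, "kwargs": {"t_start": 10.0},
                       "stochastic": True},
    "sa_bounded_t1": {"fn": sa_bounded, "kwargs": {"t_start": 1.0},
                      "stochastic": True},
    "sa_unbounded_t10": {"fn": sa_unbounded, "kwargs": {"t_start": 10.0},
                         "stochastic": True},
    "de": {"fn": de, "kwargs": {}, "stochastic": True},
    "gwo": {"fn": gwo, "kwargs": {}, "stochastic": True},
    "cobyla": {"fn": cobyla, "kwargs": {}, "stochastic": False},
    "grid_search": {"fn": grid_search, "kwargs": {}, "stochastic": False},
}


def run_algorithm(name: str, problem: OptProblem) -> OptResult:
    """Run one of the eight named study configurations on a problem."""
    spec = ALGORITHMS[name]
    return spec["fn"](problem, **spec["kwargs"])
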