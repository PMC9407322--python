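"""Metaheuristic minimizers: RSA, MRSA (Tent init + Gaussian random walk), GA, PSO.

The reptile search algorithm (RSA) mimics crocodile group hunting.  A
population of N box-bounded candidates is rewritten every iteration by one
of four position rules, scheduled by iteration quarter:

  t <= T/4        high walking       x' = Best*(-eta)*beta - R*rand
  T/4 < t <= T/2  belly walking      x' = Best*x_r1*ES(t)*rand
  T/2 < t <= 3T/4 hunting coord.     x' = Best*P*rand
  t > 3T/4        hunting coop.      x' = Best - eta*eps - R*rand

with the reduce function R = (Best - x_r2)/(Best + eps), the evolutionary
sense ES(t) = 2*r3*(1 - t/T) (r3 ~ U[-1,1]), the hunting operator
eta = Best*P, and the percentage difference
P = alpha + (x - M(x))/(Best*(ub - lb) + eps) where M(x) is the mean of a
candidate over its dimensions.  Positions are clipped to the box; the best
solution found so far is tracked greedily.

MRSA replaces the uniform initial population with a Tent chaotic sequence
and, after every iteration, perturbs each candidate by a Gaussian random
walk around the current best with greedy acceptance.

The printed form of the evolutionary sense, ES = 2*r3*(1 - 1/T) (constant
over iterations), and an integer-valued r3 are available behind flags; the
defaults follow the described behaviour of a randomly decreasing schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SearchSpace:
    """Box constraints: lower/upper bound per dimension."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower and upper must have the same shape")
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dims(self) -> int:
        return self.lower.size

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.lower, self.upper)


@dataclass
class RsaParams:
    """RSA/MRSA settings; alpha and beta are the sensitivity constants (0.1)."""

    n_candidates: int = 20
    max_iters: int = 50
    alpha: float = 0.1
    beta: float = 0.1
    epsilon: float = 1e-10
    seed: int | None = None
    es_printed: bool = False     # literal ES = 2*r3*(1 - 1/T)
    es_integer_r3: bool = False  # literal r3 in {-1, 0, 1}

    def __post_init__(self) -> None:
        if self.n_candidates < 2:
            raise ValueError("n_candidates must be >= 2")
        if self.max_iters < 4:
            raise ValueError("max_iters must be >= 4 (phase schedule needs 4 quarters)")
        if self.alpha <= 0 or self.beta <= 0 or self.epsilon <= 0:
            raise ValueError("alpha, beta and epsilon must be positive")


@dataclass
class Population:
    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float


@dataclass
class OptimizerResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    evaluations: int


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    values = np.array([float(objective(x)) for x in X])
    bad = ~np.isfinite(values)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-finite objective value(s) treated as +inf",
            UserWarning,
        )
        values[bad] = np.inf
    return values


# -- Tent chaotic map ------------------------------------------------------

_ABSORBING = (0.0, 0.5, 1.0)


def _tent_step(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.where(z <= 0.5, 2.0 * z, 2.0 * (1.0 - z))
    # {0, 0.5, 1} collapse the orbit (0.5 -> 1 -> 0 -> 0); re-seed those entries
    stuck = np.isin(out, _ABSORBING)
    if stuck.any():
        out = np.where(stuck, rng.random(out.shape), out)
    return out


def tent_sequence(length: int, dims: int, seed=None) -> np.ndarray:
    """Chaotic sequence in [0,1]: uniform first row, Tent map thereafter."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = np.empty((length, dims))
    z = rng.random(dims)
    while np.isin(z, _ABSORBING).any():
        z = np.where(np.isin(z, _ABSORBING), rng.random(dims), z)
    Z[0] = z
    for i in range(1, length):
        z = _tent_step(z, rng)
        Z[i] = z
    return Z


def tent_initialize(space: SearchSpace, n: int, seed=None) -> Population:
    """Population whose positions are Tent values mapped affinely into the box."""
    Z = tent_sequence(n, space.dims, seed)
    positions = space.lower + Z * (space.upper - space.lower)
    return Population(
        positions=positions,
        fitness=np.full(n, np.nan),
        best_position=positions[0].copy(),
        best_fitness=np.inf,
    )


# -- Gaussian random walk --------------------------------------------------

def gaussian_walk_step(
    pop: Population, objective, iteration: int, rng=None,
    space: SearchSpace | None = None,
) -> tuple[Population, int]:
    """Perturb every candidate around the best with greedy acceptance.

    Step scale tau = (log G / G) * (x_i - Best) per dimension (G is the
    iteration number); the candidate is drawn from Gaussian(Best, |tau|)
    plus g1*Best - g2*x_i with g1, g2 ~ U[0,1), clipped to the box when a
    space is given.  A candidate replaces its parent only if strictly
    better, so the population best never worsens.  Returns the updated
    population and the number of objective evaluations spent.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = pop.positions
    n = X.shape[0]
    scale = np.log(iteration) / iteration if iteration > 0 else 0.0
    tau = np.abs(scale * (X - pop.best_position))
    g1 = rng.random((n, 1))
    g2 = rng.random((n, 1))
    candidates = (
        rng.normal(loc=pop.best_position, scale=tau)
        + g1 * pop.best_position
        - g2 * X
    )
    if space is not None:
        candidates = space.clip(candidates)
    cand_fit = _evaluate(objective, candidates)
    better = cand_fit < pop.fitness
    new_X = np.where(better[:, None], candidates, X)
    new_fit = np.where(better, cand_fit, pop.fitness)
    best_i = int(np.argmin(new_fit))
    best_pos, best_fit = pop.best_position, pop.best_fitness
    if new_fit[best_i] < best_fit:
        best_fit = float(new_fit[best_i])
        best_pos = new_X[best_i].copy()
    return Population(new_X, new_fit, best_pos, best_fit), n


# -- RSA / MRSA engine -----------------------------------------------------

def _rsa_engine(
    objective,
    space: SearchSpace,
    params: RsaParams,
    *,
    use_tent: bool,
    use_grw: bool,
) -> OptimizerResult:
    rng = np.random.default_rng(params.seed)
    N, T, D = params.n_candidates, params.max_iters, space.dims
    lb, ub = space.lower, space.upper
    eps = params.epsilon

    if use_tent:
        X = lb + tent_sequence(N, D, rng) * (ub - lb)
    else:
        X = rng.random((N, D)) * (ub - lb) + lb
    fitness = _evaluate(objective, X)
    evaluations = N
    best_i = int(np.argmin(fitness))
    best = X[best_i].copy()
    best_f = float(fitness[best_i])

    cols = np.arange(D)[None, :]
    trace = np.empty(T)
    for t in range(1, T + 1):
        if params.es_integer_r3:
            r3 = float(rng.integers(-1, 2))
        else:
            r3 = float(rng.uniform(-1.0, 1.0))
        es = 2.0 * r3 * ((1.0 - 1.0 / T) if params.es_printed else (1.0 - t / T))

        M = X.mean(axis=1)
        P = params.alpha + (X - M[:, None]) / (best[None, :] * (ub - lb)[None, :] + eps)
        eta = best[None, :] * P
        r1 = rng.integers(0, N, size=(N, D))
        r2 = rng.integers(0, N, size=(N, D))
        R = (best[None, :] - X[r2, cols]) / (best[None, :] + eps)
        rand = rng.random((N, D))

        if t <= T / 4:                      # high walking
            X_new = best[None, :] * (-eta) * params.beta - R * rand
        elif t <= T / 2:                    # belly walking
            X_new = best[None, :] * X[r1, cols] * es * rand
        elif t <= 3 * T / 4:                # hunting coordination
            X_new = best[None, :] * P * rand
        else:                               # hunting cooperation
            X_new = best[None, :] - eta * eps - R * rand

        X = space.clip(X_new)
        fitness = _evaluate(objective, X)
        evaluations += N
        best_i = int(np.argmin(fitness))
        if fitness[best_i] < best_f:
            best_f = float(fitness[best_i])
            best = X[best_i].copy()

        if use_grw:
            pop = Population(X, fitness, best, best_f)
            walked, n_eval = gaussian_walk_step(pop, objective, t, rng, space=space)
            X, fitness = walked.positions, walked.fitness
            evaluations += n_eval
            if walked.best_fitness < best_f:
                best_f = walked.best_fitness
                best = walked.best_position.copy()

        trace[t - 1] = best_f

    return OptimizerResult(best, best_f, trace, evaluations)


def rsa_minimize(objective, space: SearchSpace, params: RsaParams) -> OptimizerResult:
    """Canonical reptile search algorithm (uniform init, no random walk)."""
    return _rsa_engine(objective, space, params, use_tent=False, use_grw=False)


def mrsa_minimize(
    objective,
    space: SearchSpace,
    params: RsaParams,
    *,
    use_tent: bool = True,
    use_grw: bool = True,
) -> OptimizerResult:
    """Modified RSA: Tent chaotic initialization + per-iteration Gaussian walk.

    With both switches off this reduces exactly to :func:`rsa_minimize`
    (identical trace for identical seeds).
    """
    return _rsa_engine(objective, space, params, use_tent=use_tent, use_grw=use_grw)


# -- baselines -------------------------------------------------------------

def _ga_minimize(objective, space, n, iters, seed):
    rng = np.random.default_rng(seed)
    D = space.dims
    span = space.upper - space.lower
    X = rng.random((n, D)) * span + space.lower
    fit = _evaluate(objective, X)
    evaluations = n
    order = np.argsort(fit)
    best, best_f = X[order[0]].copy(), float(fit[order[0]])
    trace = np.empty(iters)
    for g in range(iters):
        children = np.empty_like(X)
        children[0] = best  # elitism
        for i in range(1, n):
            # tournament selection (size 3)
            a = X[min(rng.integers(0, n, 3), key=lambda j: fit[j])]
            b = X[min(rng.integers(0, n, 3), key=lambda j: fit[j])]
            if rng.random() < 0.9:  # BLX-0.5 blend crossover
                lo = np.minimum(a, b)
                hi = np.maximum(a, b)
                d = hi - lo
                child = rng.uniform(lo - 0.5 * d, hi + 0.5 * d)
            else:
                child = a.copy()
            mutate = rng.random(D) < 1.0 / D
            child = np.where(mutate, child + rng.normal(0.0, 0.1 * span), child)
            children[i] = child
        X = space.clip(children)
        fit = _evaluate(objective, X)
        evaluations += n
        i_best = int(np.argmin(fit))
        if fit[i_best] < best_f:
            best_f = float(fit[i_best])
            best = X[i_best].copy()
        trace[g] = best_f
    return OptimizerResult(best, best_f, trace, evaluations)


def _pso_minimize(objective, space, n, iters, seed):
    rng = np.random.default_rng(seed)
    D = space.dims
    span = space.upper - space.lower
    X = rng.random((n, D)) * span + space.lower
    V = np.zeros((n, D))
    vmax = 0.5 * span
    fit = _evaluate(objective, X)
    evaluations = n
    pbest, pbest_f = X.copy(), fit.copy()
    g_i = int(np.argmin(fit))
    gbest, gbest_f = X[g_i].copy(), float(fit[g_i])
    trace = np.empty(iters)
    for t in range(iters):
        w = 0.9 - 0.5 * (t / max(1, iters - 1))
        r1, r2 = rng.random((n, D)), rng.random((n, D))
        V = w * V + 2.0 * r1 * (pbest - X) + 2.0 * r2 * (gbest - X)
        V = np.clip(V, -vmax, vmax)
        X = space.clip(X + V)
        fit = _evaluate(objective, X)
        evaluations += n
        improved = fit < pbest_f
        pbest[improved] = X[improved]
        pbest_f[improved] = fit[improved]
        g_i = int(np.argmin(pbest_f))
        if pbest_f[g_i] < gbest_f:
            gbest_f = float(pbest_f[g_i])
            gbest = pbest[g_i].copy()
        trace[t] = gbest_f
    return OptimizerResult(gbest, gbest_f, trace, evaluations)


def baseline_minimize(
    method: str,
    objective,
    space: SearchSpace,
    n: int = 20,
    iters: int = 50,
    seed: int | None = None,
) -> OptimizerResult:
    """Real-coded GA (tournament/blend/elitism) or global-best PSO baseline."""
    if method == "ga":
        return _ga_minimize(objective, space, n, iters, seed)
    if method == "pso":
        return _pso_minimize(objective, space, n, iters, seed)
    raise ValueError(f"unknown baseline method {method!r}; expected 'ga' or 'pso'")


def minimize(method: str, objective, space: SearchSpace, params: RsaParams) -> OptimizerResult:
    """Dispatch by optimizer name ('mrsa', 'rsa', 'ga', 'pso')."""
    if method == "mrsa":
        return mrsa_minimize(objective, space, params)
    if method == "rsa":
        return rsa_minimize(objective, space, params)
    if method in ("ga", "pso"):
        return baseline_minimize(
            method, objective, space,
            n=params.n_candidates, iters=params.max_iters, seed=params.seed,
        )
    raise ValueError(f"unknown optimizer {method!r}")
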