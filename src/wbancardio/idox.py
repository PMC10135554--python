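"""Improved Dingo Optimizer (IDOX): a population metaheuristic for box-bounded
minimization with continuous, binary and integer decodings.

The dingo optimizer mimics three hunting behaviours — group attack, persecution
and scavenging — chosen stochastically per agent, plus a survival "rescue"
update that pulls the weakest agents toward the incumbent best. The improved
variant replaces the classic uniform step draws (beta1 in [-2, 2], beta2 in
[-1, 1]) with a fitness-adaptive factor built from the population's best,
worst and mean fitness, clipped back into the classic range; populations with
no fitness spread fall back to the classic uniform draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

BETA_RANGES = {1: (-2.0, 2.0), 2: (-1.0, 1.0)}


class OptimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded search domain with a decoding convention."""

    dim: int
    lower: float | Sequence[float]
    upper: float | Sequence[float]
    encoding: str = "continuous"  # continuous | binary | integer

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        lo, hi = self.bounds()
        if not np.all(lo < hi):
            raise ValueError("lower must be elementwise below upper")
        if self.encoding not in ("continuous", "binary", "integer"):
            raise ValueError(f"unknown encoding {self.encoding!r}")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.broadcast_to(np.asarray(self.lower, float), (self.dim,)).copy()
        hi = np.broadcast_to(np.asarray(self.upper, float), (self.dim,)).copy()
        return lo, hi


@dataclass(frozen=True)
class IDOXConfig:
    """Optimizer parameters.

    ``hunting_rate`` (P) selects hunting over scavenging; ``group_attack_rate``
    (Q) selects group attack over persecution within hunting. ``na_range``
    bounds the number of attackers drawn per group attack. ``beta_mode``
    toggles the adaptive step ('improved') against the classic uniform draws
    ('classic'). ``beta1_const``/``beta2_const`` record the published constant
    pairs for the two step factors; they are documentation only and play no
    part in the computation.
    """

    population_size: int = 10
    max_iterations: int = 25
    hunting_rate: float = 0.5
    group_attack_rate: float = 0.7
    na_range: tuple[int, int] = (2, 50)
    survival_threshold: float = 0.3
    beta_mode: str = "improved"
    seed: int = 0
    beta1_const: tuple[float, float] = (-2.0, 4.094535)
    beta2_const: tuple[float, float] = (-1.0, 2.95045)

    def __post_init__(self) -> None:
        if not (0.0 <= self.hunting_rate <= 1.0 and 0.0 <= self.group_attack_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size < 3:
            raise ValueError("population_size must be >= 3")
        if self.na_range[0] < 2:
            raise ValueError("na_range lower bound must be >= 2")
        if self.beta_mode not in ("classic", "improved"):
            raise ValueError(f"unknown beta_mode {self.beta_mode!r}")
        if not 0.0 <= self.survival_threshold <= 1.0:
            raise ValueError("survival_threshold must lie in [0, 1]")


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    fitness_history: list[float] = field(default_factory=list)
    evaluations: int = 0


def adaptive_beta(
    fitness: np.ndarray, beta_index: int, rng: np.random.Generator, mode: str = "improved"
) -> float:
    """One step factor draw.

    Improved mode: alpha = best - worst fitness; X = (mean - worst)/(mean - best);
    the factor is alpha * c * X with c ~ U(0, 1), clipped into the classic range
    for the requested index. Degenerate populations (no spread, or mean equal to
    the best) and classic mode use the uniform draw on the classic range.
    """
    fitness = np.asarray(fitness, float)
    if fitness.size == 0:
        raise OptimizationError("empty population")
    lo, hi = BETA_RANGES[beta_index]
    best, worst, mean = fitness.min(), fitness.max(), fitness.mean()
    if mode == "classic" or best == worst or mean == best:
        return float(rng.uniform(lo, hi))
    alpha = best - worst
    x = (mean - worst) / (mean - best)
    c = rng.uniform(0.0, 1.0)
    return float(np.clip(alpha * c * x, lo, hi))


def group_attack(
    agent: np.ndarray, attackers: np.ndarray, best: np.ndarray, beta1: float
) -> np.ndarray:
    """Group attack: beta1 * mean(attackers - agent) - best (pre-clip)."""
    attackers = np.atleast_2d(attackers)
    return beta1 * (attackers - agent).mean(axis=0) - best


def persecution(
    agent: np.ndarray, best: np.ndarray, peer: np.ndarray, beta1: float, beta2: float
) -> np.ndarray:
    """Persecution: best + beta1 * e^{beta2} * (peer - agent) (pre-clip)."""
    return best + beta1 * np.exp(beta2) * (peer - agent)


def scavenger(agent: np.ndarray, peer: np.ndarray, beta2: float, sigma: int) -> np.ndarray:
    """Scavenging: 0.5 * (e^{beta2} * peer - (-1)^sigma * agent) (pre-clip)."""
    return 0.5 * (np.exp(beta2) * peer - ((-1.0) ** sigma) * agent)


def survival_rate(fitness: np.ndarray) -> np.ndarray:
    """Per-agent survival in [0, 1]: best agent -> 1, worst -> 0.

    All-equal populations get survival 1 everywhere (nothing to rescue).
    """
    fitness = np.asarray(fitness, float)
    best, worst = fitness.min(), fitness.max()
    if best == worst:
        return np.ones_like(fitness)
    return (worst - fitness) / (worst - best)


def low_survival_update(
    best: np.ndarray, peer1: np.ndarray, peer2: np.ndarray, sigma: int
) -> np.ndarray:
    """Rescue move for weak agents: best + 0.5*(peer1 - (-1)^sigma * peer2)."""
    return best + 0.5 * (peer1 - ((-1.0) ** sigma) * peer2)


def decode_integer(position: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Round-and-clip decoding of a real vector onto the integer box [lo, hi]."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    return np.clip(np.rint(np.asarray(position, float)), lo, hi).astype(int)


def decode_binary(position: np.ndarray) -> np.ndarray:
    """Sigmoid-threshold decoding to a bit mask, with all-zero repair.

    A dimension is selected when sigmoid(x) > 0.5 (strictly). If no dimension
    is selected, the dimension with the largest sigmoid value is forced on.
    """
    position = np.asarray(position, float)
    sig = 1.0 / (1.0 + np.exp(-position))
    mask = (sig > 0.5).astype(int)
    if mask.sum() == 0:
        mask[int(np.argmax(sig))] = 1
    return mask


class IDOX:
    """The optimizer: construct with a space and config, call :meth:`optimize`."""

    def __init__(self, space: SearchSpace, config: IDOXConfig | None = None):
        self.space = space
        self.config = config or IDOXConfig()

    def _initialize(self, objective, rng):
        lo, hi = self.space.bounds()
        pop = rng.uniform(lo, hi, size=(self.config.population_size, self.space.dim))
        fit = np.array([objective(p) for p in pop], float)
        if not np.isfinite(fit).all():
            i = int(np.argmax(~np.isfinite(fit)))
            raise OptimizationError(
                f"objective returned a non-finite value at initial point {pop[i]}"
            )
        return pop, fit

    def optimize(self, objective: Callable[[np.ndarray], float]) -> OptimizationResult:
        cfg = self.config
        if cfg.max_iterations < 1:
            raise OptimizationError("max_iterations must be >= 1")
        rng = np.random.default_rng(cfg.seed)
        lo, hi = self.space.bounds()
        pop, fit = self._initialize(objective, rng)
        evals = cfg.population_size
        # best ties break toward the earlier-indexed agent (np.argmin convention)
        best_i = int(np.argmin(fit))
        best_pos, best_fit = pop[best_i].copy(), float(fit[best_i])
        na_lo = max(2, cfg.na_range[0])
        na_hi = min(cfg.na_range[1], cfg.population_size - 1)
        na_hi = max(na_hi, na_lo)
        history: list[float] = []

        for _ in range(cfg.max_iterations):
            for i in range(cfg.population_size):
                b1 = adaptive_beta(fit, 1, rng, cfg.beta_mode)
                b2 = adaptive_beta(fit, 2, rng, cfg.beta_mode)
                others = np.delete(np.arange(cfg.population_size), i)
                if rng.uniform() < cfg.hunting_rate:
                    if rng.uniform() < cfg.group_attack_rate:
                        na = int(rng.integers(na_lo, na_hi + 1))
                        na = min(na, len(others))
                        idx = rng.choice(others, size=na, replace=False)
                        cand = group_attack(pop[i], pop[idx], best_pos, b1)
                    else:
                        peer = pop[int(rng.choice(others))]
                        cand = persecution(pop[i], best_pos, peer, b1, b2)
                else:
                    peer = pop[int(rng.choice(others))]
                    cand = scavenger(pop[i], peer, b2, int(rng.integers(0, 2)))
                cand = np.clip(cand, lo, hi)
                f = float(objective(cand))
                evals += 1
                if f < fit[i]:  # greedy acceptance keeps elitism intact
                    pop[i], fit[i] = cand, f

            sur = survival_rate(fit)
            for i in np.flatnonzero(sur < cfg.survival_threshold):
                peers = rng.choice(cfg.population_size, size=2, replace=False)
                cand = low_survival_update(
                    best_pos, pop[peers[0]], pop[peers[1]], int(rng.integers(0, 2))
                )
                cand = np.clip(cand, lo, hi)
                f = float(objective(cand))
                evals += 1
                if f < fit[i]:
                    pop[i], fit[i] = cand, f

            it_best = int(np.argmin(fit))
            if fit[it_best] < best_fit:
                best_pos, best_fit = pop[it_best].copy(), float(fit[it_best])
            history.append(best_fit)

        return OptimizationResult(best_pos, best_fit, history, evals)


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: IDOXConfig | None = None,
) -> OptimizationResult:
    """Functional entry point; see :class:`IDOX`."""
    return IDOX(space, config).optimize(objective)
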