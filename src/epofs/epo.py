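"""Continuous Eagle Prey Optimization (EPO).

EPO is a population-based metaheuristic modelled on the hunting behaviour of
eagles: a bird first selects a promising search region, then scans it in
widening and narrowing spirals (exploration), and finally swoops on the prey
(exploitation).  Each candidate solution is a real-valued position vector in a
bounded box; five update rules move candidates relative to the best-so-far
position ``pos_best`` and the current population mean ``pos_mean``:

* search-space selection — a one-off refinement of the initial population
  toward the best region,
* expanded exploration — a contraction of the best position blended with the
  population mean,
* narrowed exploration — a Lévy-flight-scaled jump around a random peer,
  shaped by spiral coefficients,
* exploitation — a small step toward the best position,
* narrowed exploitation — a quality-function-weighted swoop with a
  Lévy-flight escape term.

The optimizer maximizes an arbitrary objective ``f(position) -> float`` under
greedy (elitist) replacement: a candidate's move is kept only if it improves
its own fitness, so the best fitness history is monotone non-decreasing.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from :attr:`EpoConfig.seed`; per update the draw order is fixed (branch coin,
then the rule's own draws), so runs are bit-for-bit reproducible.  Every rule
accepts keyword overrides for its stochastic draws, which makes single-step
hand traces testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np

__all__ = [
    "EpoConfig",
    "Population",
    "OptState",
    "init_population",
    "select_search_space",
    "expanded_exploration",
    "narrowed_exploration",
    "exploitation",
    "narrowed_exploitation",
    "levy_flight",
    "levy_scale",
    "spiral_coefficients",
    "exploration_factor",
    "run_epo",
]


@dataclass
class EpoConfig:
    """Hyperparameters of the continuous EPO optimizer.

    Parameters
    ----------
    n_pop : int
        Population size (number of candidate positions), >= 2.
    n_iter : int
        Number of iterations of the main loop. ``0`` is allowed and returns
        the best member of the initial population untouched.
    alpha : float
        Exploding learning factor in (0, 1) scaling the search-space
        selection step.
    gamma : float
        Exploration parameter in (0, 1); contracts the best position during
        expanded exploration and scales the Lévy term of the narrowed
        exploitation rule.
    b : float
        Lévy exponent (> 1); 1.5 is the conventional value.
    search_cycle : float
        Spiral search-cycle parameter SC in (0, 5).
    rotation_a : float
        Spiral rotation parameter a in (2, 10).
    w_max, w_min : float
        Endpoints of the linearly decaying exploration factor schedule.
    phase_split : float
        Fraction of iterations spent in the exploration phase; the remainder
        uses the exploitation rules.
    seed : int
        Seed of the single shared random generator.
    """

    n_pop: int = 30
    n_iter: int = 100
    alpha: float = 0.5
    gamma: float = 0.5
    b: float = 1.5
    search_cycle: float = 2.5
    rotation_a: float = 5.0
    w_max: float = 0.9
    w_min: float = 0.4
    phase_split: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < 2:
            raise ValueError(f"n_pop must be >= 2, got {self.n_pop}")
        if self.n_iter < 0:
            raise ValueError(f"n_iter must be >= 0, got {self.n_iter}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma}")
        if self.b <= 1.0:
            raise ValueError(f"b must be > 1, got {self.b}")
        if not 0.0 < self.search_cycle < 5.0:
            raise ValueError(f"search_cycle must lie in (0, 5), got {self.search_cycle}")
        if not 2.0 < self.rotation_a < 10.0:
            raise ValueError(f"rotation_a must lie in (2, 10), got {self.rotation_a}")
        if not 0.0 < self.w_min <= self.w_max:
            raise ValueError("require 0 < w_min <= w_max")
        if not 0.0 < self.phase_split < 1.0:
            raise ValueError(f"phase_split must lie in (0, 1), got {self.phase_split}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EpoConfig":
        return cls(**d)


@dataclass
class Population:
    """Candidate positions plus the box bounds they are confined to."""

    positions: np.ndarray  # (n_pop, m)
    lower: np.ndarray  # (m,)
    upper: np.ndarray  # (m,)

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def m(self) -> int:
        return self.positions.shape[1]


@dataclass
class OptState:
    """Result of an optimization run."""

    t: int
    best_position: np.ndarray
    best_fitness: float
    mean_position: np.ndarray
    history: list = field(default_factory=list)


def _as_bounds(bounds, m: int) -> tuple[np.ndarray, np.ndarray]:
    lower, upper = bounds
    lower = np.broadcast_to(np.asarray(lower, dtype=float), (m,)).copy()
    upper = np.broadcast_to(np.asarray(upper, dtype=float), (m,)).copy()
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
        raise ValueError("bounds must be finite")
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    return lower, upper


def _clamp(x: np.ndarray, bounds) -> np.ndarray:
    if bounds is None:
        return x
    lower, upper = bounds
    return np.clip(x, lower, upper)


def init_population(cfg: EpoConfig, m: int, bounds) -> Population:
    """Sample ``cfg.n_pop`` positions uniformly inside the bounding box."""
    if m < 1:
        raise ValueError(f"dimension m must be >= 1, got {m}")
    lower, upper = _as_bounds(bounds, m)
    rng = np.random.default_rng(cfg.seed)
    positions = rng.uniform(size=(cfg.n_pop, m)) * (upper - lower) + lower
    return Population(positions=positions, lower=lower, upper=upper)


def select_search_space(
    pos_best: np.ndarray,
    pos_mean: np.ndarray,
    pos_i: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
    *,
    beta: Optional[float] = None,
    bounds=None,
) -> np.ndarray:
    """Search-space selection step: ``pos_best + alpha*beta*(pos_mean - pos_i)``."""
    if beta is None:
        beta = rng.uniform()
    out = pos_best + alpha * beta * (pos_mean - pos_i)
    return _clamp(out, bounds)


def expanded_exploration(
    pos_best: np.ndarray,
    pos_mean: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
    *,
    beta: Optional[float] = None,
    bounds=None,
) -> np.ndarray:
    """High-altitude spiral scan: ``pos_best*gamma + (pos_mean - pos_best)*beta``."""
    if beta is None:
        beta = rng.uniform()
    out = pos_best * gamma + (pos_mean - pos_best) * beta
    return _clamp(out, bounds)


def levy_scale(b: float) -> float:
    """Scale parameter of the Mantegna Lévy-flight sampler for exponent ``b``.

    ``omega = [Gamma(1+b) sin(pi b / 2) / (Gamma((1+b)/2) b 2^((b-1)/2))]^(1/b)``
    """
    if b <= 1.0:
        raise ValueError(f"Levy exponent b must be > 1, got {b}")
    num = math.gamma(1.0 + b) * math.sin(math.pi * b / 2.0)
    den = math.gamma((1.0 + b) / 2.0) * b * 2.0 ** ((b - 1.0) / 2.0)
    return (num / den) ** (1.0 / b)


def levy_flight(
    m: int,
    b: float,
    rng: np.random.Generator,
    *,
    u: Optional[np.ndarray] = None,
    v: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Heavy-tailed Lévy-flight step ``0.01 * u * omega / |v|^(1/b)`` per dimension.

    ``u`` and ``v`` are standard-normal draws (Mantegna sampler); ``u*omega``
    is then Normal(0, omega^2).  Any ``v`` drawn exactly 0 is redrawn to guard
    the division.
    """
    omega = levy_scale(b)
    if u is None:
        u = rng.standard_normal(m)
    else:
        u = np.broadcast_to(np.asarray(u, dtype=float), (m,))
    if v is None:
        v = rng.standard_normal(m)
        while np.any(v == 0.0):  # pragma: no cover - probability zero
            v = np.where(v == 0.0, rng.standard_normal(m), v)
    else:
        v = np.broadcast_to(np.asarray(v, dtype=float), (m,))
        if np.any(v == 0.0):
            raise ValueError("pinned v must be nonzero")
    return 0.01 * u * omega / np.abs(v) ** (1.0 / b)


def spiral_coefficients(
    m: int,
    rotation_a: float,
    search_cycle: float,
    rng: np.random.Generator,
    *,
    beta: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Spiral-shape coefficients X, Y, each normalized to unit maximum magnitude.

    Per dimension i: ``theta_i = a*pi*beta_i``, ``r_i = theta_i + SC*beta_i``;
    ``x_i = r_i sin(theta_i)``, ``y_i = r_i cos(theta_i)``; X and Y divide x
    and y by their respective maximum absolute entries.
    """
    pinned = beta is not None
    for _ in range(100):
        if beta is None:
            beta = rng.uniform(size=m)
        else:
            beta = np.broadcast_to(np.asarray(beta, dtype=float), (m,))
        theta = rotation_a * math.pi * beta
        r = theta + search_cycle * beta
        x = r * np.sin(theta)
        y = r * np.cos(theta)
        # degenerate (numerically) all-zero axis, e.g. every angle a multiple
        # of pi: redraw rather than normalize by round-off noise
        tol = 1e-9 * max(float(np.max(np.abs(r))), 1.0)
        if np.max(np.abs(x)) > tol and np.max(np.abs(y)) > tol:
            return x / np.max(np.abs(x)), y / np.max(np.abs(y))
        if pinned:
            raise ValueError("pinned beta yields a degenerate all-zero spiral axis")
        beta = None
    raise RuntimeError("spiral coefficient redraw guard exhausted")  # pragma: no cover


def narrowed_exploration(
    pos_best: np.ndarray,
    pos_rand: np.ndarray,
    cfg: EpoConfig,
    rng: np.random.Generator,
    *,
    levy: Optional[np.ndarray] = None,
    coeffs: Optional[tuple[np.ndarray, np.ndarray]] = None,
    beta: Optional[float] = None,
    bounds=None,
) -> np.ndarray:
    """Narrowing spiral around a random peer:
    ``pos_best*F(D) + pos_rand + (Y - X)*beta``.
    """
    m = pos_best.shape[0]
    if levy is None:
        levy = levy_flight(m, cfg.b, rng)
    if coeffs is None:
        coeffs = spiral_coefficients(m, cfg.rotation_a, cfg.search_cycle, rng)
    x, y = coeffs
    if beta is None:
        beta = rng.uniform()
    out = pos_best * levy + pos_rand + (y - x) * beta
    return _clamp(out, bounds)


def exploitation(
    pos_best: np.ndarray,
    pos_mean: np.ndarray,
    pos_i: np.ndarray,
    rng: np.random.Generator,
    *,
    beta: Optional[float] = None,
    bounds=None,
) -> np.ndarray:
    """Slow swoop:
    ``0.1*(pos_best - pos_mean) - 0.2*beta*(pos_mean - pos_i) + pos_i``.

    The constants 0.1 and 0.2 are fixed adjustment parameters of the phase.
    """
    if beta is None:
        beta = rng.uniform()
    out = 0.1 * (pos_best - pos_mean) - 0.2 * beta * (pos_mean - pos_i) + pos_i
    return _clamp(out, bounds)


def narrowed_exploitation(
    pos_best: np.ndarray,
    pos_i: np.ndarray,
    t: int,
    cfg: EpoConfig,
    rng: np.random.Generator,
    *,
    beta: Optional[float] = None,
    levy: Optional[np.ndarray] = None,
    bounds=None,
) -> np.ndarray:
    """Forced ground swoop:
    ``QF(t)*pos_best - 2*beta*pos_i - 2*gamma*F(D) + 2*beta`` with the quality
    function ``QF(t) = t^((2*beta - 1) / (1 - n_iter)^2)``.
    """
    if t < 1:
        raise ValueError(f"narrowed exploitation requires t >= 1, got {t}")
    if beta is None:
        beta = rng.uniform()
    m = pos_best.shape[0]
    if levy is None:
        levy = levy_flight(m, cfg.b, rng)
    if cfg.n_iter == 1:
        qf = 1.0  # degenerate single-iteration schedule
    else:
        qf = float(t) ** ((2.0 * beta - 1.0) / (1.0 - cfg.n_iter) ** 2)
    out = qf * pos_best - 2.0 * beta * pos_i - 2.0 * cfg.gamma * levy + 2.0 * beta
    return _clamp(out, bounds)


def exploration_factor(t: int, n_iter: int, w_max: float = 0.9, w_min: float = 0.4) -> float:
    """Linearly decaying exploration factor ``w_max - (w_max - w_min)*t/n_iter``.

    Evaluated in interpolation form so both endpoints are exact in floating
    point: ``w_max`` at ``t=0`` and ``w_min`` at ``t=n_iter``.
    """
    if n_iter <= 0:
        raise ValueError("n_iter must be positive")
    f = t / n_iter
    return w_max * (1.0 - f) + w_min * f


def run_epo(
    objective: Callable[[np.ndarray], float],
    cfg: EpoConfig,
    bounds,
    m: int,
    mutator: Optional[Callable[[np.ndarray, int, np.random.Generator], np.ndarray]] = None,
) -> OptState:
    """Maximize ``objective`` over the bounding box with the EPO update rules.

    The loop keeps one shared generator; each iteration recomputes the
    population mean, then updates every candidate with one rule (exploration
    rules while ``t <= phase_split*n_iter``, exploitation rules after, chosen
    with a fair coin) under greedy replacement.  Before the first iteration
    the whole population takes one search-space selection step.

    Parameters
    ----------
    objective : callable
        Position -> finite float, to be maximized.
    mutator : callable, optional
        ``mutator(position, t, rng) -> position`` applied to every candidate
        once per iteration, after its update; the mutated position replaces
        it only on improvement (elitism is preserved).

    Returns
    -------
    OptState
        Best position/fitness, final population mean, and the per-iteration
        best-fitness history (entry 0 is the initialized population's best).
    """
    pop = init_population(cfg, m, bounds)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    box = (pop.lower, pop.upper)

    def evaluate(x: np.ndarray) -> float:
        val = float(objective(x))
        if not math.isfinite(val):
            raise ValueError(f"objective returned a non-finite value {val!r}")
        return val

    fit = np.array([evaluate(x) for x in pop.positions])
    best_idx = int(np.argmax(fit))
    best_pos = pop.positions[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = [best_fit]
    mean = pop.positions.mean(axis=0)

    if cfg.n_iter == 0:
        return OptState(t=0, best_position=best_pos, best_fitness=best_fit,
                        mean_position=mean, history=history)

    def try_accept(i: int, cand: np.ndarray) -> None:
        nonlocal best_pos, best_fit
        f = evaluate(cand)
        if f > fit[i]:
            pop.positions[i] = cand
            fit[i] = f
            if f > best_fit:
                best_fit = f
                best_pos = cand.copy()

    # one-off refinement of the initial population toward the best region
    for i in range(pop.n):
        cand = select_search_space(best_pos, mean, pop.positions[i], cfg.alpha,
                                   rng, bounds=box)
        try_accept(i, cand)

    n_explore = cfg.phase_split * cfg.n_iter
    for t in range(1, cfg.n_iter + 1):
        mean = pop.positions.mean(axis=0)
        exploring = t <= n_explore
        for i in range(pop.n):
            coin = rng.uniform()
            if exploring:
                if coin < 0.5:
                    cand = expanded_exploration(best_pos, mean, cfg.gamma, rng,
                                                bounds=box)
                else:
                    j = int(rng.integers(pop.n))
                    cand = narrowed_exploration(best_pos, pop.positions[j], cfg,
                                                rng, bounds=box)
            else:
                if coin < 0.5:
                    cand = exploitation(best_pos, mean, pop.positions[i], rng,
                                        bounds=box)
                else:
                    cand = narrowed_exploitation(best_pos, pop.positions[i], t,
                                                 cfg, rng, bounds=box)
            try_accept(i, cand)
            if mutator is not None:
                mutated = _clamp(mutator(pop.positions[i], t, rng), box)
                try_accept(i, mutated)
        history.append(best_fit)

    return OptState(t=cfg.n_iter, best_position=best_pos, best_fitness=best_fit,
                    mean_position=pop.positions.mean(axis=0), history=history)
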