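"""Refracted Sand Cat Swarm Optimization (RL-SCSO).

A population metaheuristic modelled on the sand cat's low-frequency
hearing.  A sensitivity range V_S = gamma - gamma*I/Imax decays linearly
over iterations and controls the exploration/exploitation balance through
the phase factor U ~ Uniform[-V_S, V_S]: cats with |U| <= 1 exploit (move
toward the global best along a roulette-wheel angle), the rest explore
(move relative to an optimal candidate position with a personal range
V_range ~ Uniform[0, V_S]).  After every sweep, a refracted
opposition-based counterpart of the global best —

    T' = (LB+UB)/2 + (LB+UB)/(2*k*mu) - T/(k*mu)

— is evaluated and the better of the pair is kept, which helps escape
local optima.  All positions are clipped to [LB, UB] after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SwarmConfig",
    "CandidateSolution",
    "OptimizationResult",
    "sensitivity_range",
    "phase_factor",
    "personal_range",
    "explore_step",
    "exploit_step",
    "select_angle",
    "refract",
    "run_rl_scso",
]


@dataclass(frozen=True)
class SwarmConfig:
    pop_size: int = 100
    max_iter: int = 100
    gamma: float = 2.0
    lower_bound: np.ndarray | float = -4.0
    upper_bound: np.ndarray | float = 4.0
    seed: int = 0
    refraction_scale: float = 1.0    # k
    refraction_index: float = 1.0    # mu
    ocp_mode: str = "better_half"    # or "global_best"
    angle_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.pop_size < 1 or self.max_iter < 1:
            raise ValueError("pop_size and max_iter must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.refraction_scale <= 0 or self.refraction_index <= 0:
            raise ValueError("refraction scale and index must be positive")
        if self.ocp_mode not in ("better_half", "global_best"):
            raise ValueError("ocp_mode must be 'better_half' or 'global_best'")

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        lb = np.broadcast_to(np.asarray(self.lower_bound, dtype=float), (dim,)).copy()
        ub = np.broadcast_to(np.asarray(self.upper_bound, dtype=float), (dim,)).copy()
        if not (lb < ub).all():
            raise ValueError("lower bounds must be strictly below upper bounds")
        return lb, ub


@dataclass
class CandidateSolution:
    position: np.ndarray
    fitness: float


@dataclass
class OptimizationResult:
    best: CandidateSolution
    trace: list[float] = field(default_factory=list)
    vs_trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def sensitivity_range(iteration: int, max_iter: int, gamma: float = 2.0) -> float:
    """V_S = gamma - gamma * I / Imax, decaying linearly to 0."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not 0 <= iteration <= max_iter:
        raise ValueError("iteration must lie in [0, max_iter]")
    return gamma - gamma * (iteration / max_iter)


def phase_factor(v_s: float, rng: np.random.Generator) -> float:
    """U = 2*rand*V_S - V_S, uniform on [-V_S, V_S]."""
    if v_s < 0:
        raise ValueError("V_S must be non-negative")
    return 2.0 * rng.random() * v_s - v_s


def personal_range(v_s: float, rng: np.random.Generator) -> float:
    """V_range = rand * V_S, uniform on [0, V_S]."""
    if v_s < 0:
        raise ValueError("V_S must be non-negative")
    return rng.random() * v_s


def _clip(pos: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    return np.clip(pos, lb, ub)


def explore_step(q_ocp, q_cur, v_range: float, rng: np.random.Generator,
                 lb, ub) -> np.ndarray:
    """Exploration move Q(t+1) = V_range * (Q_ocp - rand*Q_cur), with an
    independent uniform draw per dimension, clipped to bounds."""
    q_ocp = np.asarray(q_ocp, dtype=float)
    q_cur = np.asarray(q_cur, dtype=float)
    if q_ocp.shape != q_cur.shape:
        raise ValueError("position dimension mismatch")
    r = rng.random(q_cur.shape)
    new = v_range * (q_ocp - q_cur * r)
    return _clip(new, lb, ub)


def exploit_step(q_best, q_cur, v_range: float, beta_deg: float,
                 rng: np.random.Generator, lb, ub) -> np.ndarray:
    """Exploitation move toward the prey:

    Q_sc_pr = |rand*Q_best - Q_cur| (per-dimension draws),
    Q(t+1)  = Q_best - Q_sc_pr * V_range * cos(beta), clipped to bounds.
    """
    if not 0.0 <= beta_deg <= 360.0:
        raise ValueError("angle must lie in [0, 360] degrees")
    q_best = np.asarray(q_best, dtype=float)
    q_cur = np.asarray(q_cur, dtype=float)
    r = rng.random(q_cur.shape)
    dist = np.abs(q_best * r - q_cur)
    new = q_best - dist * v_range * np.cos(np.deg2rad(beta_deg))
    return _clip(new, lb, ub)


_ANGLE_GRID = np.arange(0.0, 361.0)  # 1-degree grid over [0, 360]


def select_angle(rng: np.random.Generator, weights=None) -> float:
    """Roulette-wheel draw of a movement angle from a 1-degree grid of
    [0, 360].  Uniform weights by default (a uniform wheel reduces to a
    uniform angle choice); custom non-negative weights supported."""
    if weights is None:
        return float(rng.choice(_ANGLE_GRID))
    w = np.asarray(weights, dtype=float)
    if w.shape != _ANGLE_GRID.shape:
        raise ValueError(f"weights must have shape {_ANGLE_GRID.shape}")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    # roulette wheel: cumulative-probability inversion of a single spin
    cum = np.cumsum(w) / w.sum()
    return float(_ANGLE_GRID[np.searchsorted(cum, rng.random(), side="right")])


def refract(position, lb, ub, k: float = 1.0, mu: float = 1.0) -> np.ndarray:
    """Refracted opposite point, per dimension:

    T' = (LB+UB)/2 + (LB+UB)/(2*k*mu) - T/(k*mu), clipped to [LB, UB].

    With k = mu = 1 this is the opposite point reflected through the
    interval midpoint (T' = LB + UB - T).
    """
    if k * mu == 0:
        raise ValueError("k * mu must be nonzero")
    t = np.asarray(position, dtype=float)
    lb = np.broadcast_to(np.asarray(lb, dtype=float), t.shape)
    ub = np.broadcast_to(np.asarray(ub, dtype=float), t.shape)
    mid = (lb + ub) / 2.0
    new = mid + (lb + ub) / (2.0 * k * mu) - t / (k * mu)
    return _clip(new, lb, ub)


def run_rl_scso(objective, dim: int, config: SwarmConfig) -> OptimizationResult:
    """Minimize ``objective`` over [LB, UB]^dim with refracted SCSO.

    Population initializes uniformly in the bounds; each iteration I in
    1..Imax computes V_S (0 exactly at the final iteration), moves each cat
    by the exploit rule when |U| <= 1 and the explore rule otherwise, then
    refracts the global best and keeps the better of the pair.  The
    returned best is the minimum over every evaluation and the
    best-so-far trace is non-increasing.  Fully reproducible under the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    lb, ub = config.bounds(dim)
    k, mu = config.refraction_scale, config.refraction_index

    def evaluate(pos: np.ndarray) -> float:
        val = float(objective(pos))
        if not np.isfinite(val):
            raise ValueError(f"non-finite objective value {val} at position {pos!r}")
        return val

    pop = rng.uniform(lb, ub, size=(config.pop_size, dim))
    fits = np.array([evaluate(p) for p in pop])
    n_evals = config.pop_size
    b = int(np.argmin(fits))
    best = CandidateSolution(pop[b].copy(), float(fits[b]))

    trace: list[float] = []
    vs_trace: list[float] = []
    for it in range(1, config.max_iter + 1):
        v_s = sensitivity_range(it, config.max_iter, config.gamma)
        vs_trace.append(v_s)
        order = np.argsort(fits)
        half = order[: max(1, config.pop_size // 2)]
        for i in range(config.pop_size):
            u = phase_factor(v_s, rng)
            v_range = personal_range(v_s, rng)
            if abs(u) <= 1.0:
                beta = select_angle(rng, config.angle_weights)
                pop[i] = exploit_step(best.position, pop[i], v_range, beta, rng, lb, ub)
            else:
                if config.ocp_mode == "global_best":
                    q_ocp = best.position
                else:
                    q_ocp = pop[int(rng.choice(half))]
                pop[i] = explore_step(q_ocp, pop[i], v_range, rng, lb, ub)
            fits[i] = evaluate(pop[i])
            n_evals += 1
            if fits[i] < best.fitness:
                best = CandidateSolution(pop[i].copy(), float(fits[i]))
        refracted = refract(best.position, lb, ub, k, mu)
        f_ref = evaluate(refracted)
        n_evals += 1
        if f_ref < best.fitness:
            best = CandidateSolution(refracted.copy(), float(f_ref))
        trace.append(best.fitness)

    return OptimizationResult(best=best, trace=trace, vs_trace=vs_trace,
                              n_evaluations=n_evals)
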