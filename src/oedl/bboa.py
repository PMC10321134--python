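"""Big-bang swarm optimizer: a PSO-style integer-vector metaheuristic.

A population of "galaxies" expands through an integer box.  Initial
positions come from a sinusoidal chaotic map (m' = a * m^2 * sin(pi*m))
seeded from random integers, which disperses the initial swarm more than
uniform draws.  Each iteration every galaxy's velocity mixes an
adaptively annealed inertia term, attraction to its own best position
ever seen, and attraction to the swarm's best; the inertia weight decays
linearly from w_s to w_e over the run.  Personal and global bests are
kept greedily (replaced only on strict improvement), so the best-so-far
fitness history is monotone non-decreasing.

The optimizer is generic over any fitness function on integer vectors;
:func:`search_architecture` binds it to depth/width search for the deep
base learners (position = [n_layers, neurons_1, ..., neurons_Lmax]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import learners, metrics
from .containers import int_to_labels
from .learners import LearnerSpec


@dataclass
class BBOAConfig:
    dims: int
    lower: np.ndarray  # D_x per dim
    upper: np.ndarray  # U_x per dim
    pop_size: int = 20
    chaos_a: float = 2.3
    ef1: float = 2.0  # attraction to the galaxy's own best
    ef2: float = 2.0  # attraction to the swarm best
    w_s: float = 0.9
    w_e: float = 0.4
    n_iter: int = 100
    velocity_clamp_frac: float = 0.2
    integer: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.size != self.dims or self.upper.size != self.dims:
            raise ValueError("bounds must have one entry per dimension")
        if (self.lower >= self.upper).any():
            raise ValueError("each lower bound must be below its upper bound")
        if not (0 < self.w_e <= self.w_s):
            raise ValueError("need 0 < w_e <= w_s")
        if self.n_iter < 1 or self.pop_size < 2:
            raise ValueError("need n_iter >= 1 and pop_size >= 2")


@dataclass
class SwarmState:
    positions: np.ndarray
    velocities: np.ndarray
    chaos: np.ndarray
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    gbest_pos: np.ndarray
    gbest_fit: float
    t: int = 0
    history: list[float] = field(default_factory=list)


def chaotic_sequence(m0: float, a: float, length: int) -> np.ndarray:
    """Iterate the sinusoidal map m' = a * m^2 * sin(pi * m)."""
    out = np.empty(length)
    m = float(m0)
    for i in range(length):
        m = a * m * m * np.sin(np.pi * m)
        out[i] = m
    return out


def inertia_weight(t: int, cfg: BBOAConfig) -> float:
    """Linearly annealed inertia: w_s at t=0 down to w_e at t=n_iter."""
    return cfg.w_s - (cfg.w_s - cfg.w_e) * t / cfg.n_iter


def _snap(cfg: BBOAConfig, x: np.ndarray) -> np.ndarray:
    x = np.clip(x, cfg.lower, cfg.upper)
    return np.round(x) if cfg.integer else x


def _evaluate(fitness_fn, positions: np.ndarray) -> np.ndarray:
    fits = np.empty(len(positions))
    for i, pos in enumerate(positions):
        f = float(fitness_fn(pos))
        if not np.isfinite(f):
            raise ValueError(f"fitness function returned non-finite value for galaxy {i}")
        fits[i] = f
    return fits


def init_population(cfg: BBOAConfig, fitness_fn=None, incumbent=None) -> SwarmState:
    """Chaotically dispersed initial swarm with zero velocities.

    Per galaxy and dimension the chaotic state starts from a random
    integer in [0, 100] mapped into [0, 1], then advances one map step;
    the state is carried into [lower, upper] by the affine transform
    lower + m * (upper - lower), rounded for integer search spaces.
    An optional ``incumbent`` position (e.g. the current architecture)
    replaces the first galaxy, so the search never loses to its start.
    """
    rng = np.random.default_rng(cfg.seed)
    m0 = rng.integers(0, 101, size=(cfg.pop_size, cfg.dims)) / 100.0
    chaos = cfg.chaos_a * m0**2 * np.sin(np.pi * m0)
    positions = _snap(cfg, cfg.lower + chaos * (cfg.upper - cfg.lower))
    if incumbent is not None:
        positions[0] = _snap(cfg, np.asarray(incumbent, dtype=float))
    velocities = np.zeros_like(positions)
    state = SwarmState(
        positions=positions,
        velocities=velocities,
        chaos=chaos,
        pbest_pos=positions.copy(),
        pbest_fit=np.full(cfg.pop_size, -np.inf),
        gbest_pos=positions[0].copy(),
        gbest_fit=-np.inf,
    )
    if fitness_fn is not None:
        fits = _evaluate(fitness_fn, positions)
        state.pbest_fit = fits.copy()
        best = int(np.argmax(fits))
        state.gbest_pos = positions[best].copy()
        state.gbest_fit = float(fits[best])
        state.history.append(state.gbest_fit)
    return state


def step(state: SwarmState, cfg: BBOAConfig, fitness_fn, rng: np.random.Generator) -> SwarmState:
    """One swarm iteration: velocity/position update + greedy best retention."""
    if state.t >= cfg.n_iter:
        raise ValueError("swarm already ran its configured iteration budget")
    state.t += 1
    w_w = inertia_weight(state.t, cfg)
    r1 = rng.random(state.positions.shape)
    r2 = rng.random(state.positions.shape)
    vmax = cfg.velocity_clamp_frac * (cfg.upper - cfg.lower)
    v = (
        w_w * state.velocities
        + cfg.ef1 * r1 * (state.pbest_pos - state.positions)
        + cfg.ef2 * r2 * (state.gbest_pos - state.positions)
    )
    state.velocities = np.clip(v, -vmax, vmax)
    state.positions = _snap(cfg, state.positions + state.velocities)
    fits = _evaluate(fitness_fn, state.positions)
    improved = fits > state.pbest_fit  # greedy: strict improvement only
    state.pbest_pos[improved] = state.positions[improved]
    state.pbest_fit[improved] = fits[improved]
    best = int(np.argmax(state.pbest_fit))
    if state.pbest_fit[best] > state.gbest_fit:
        state.gbest_fit = float(state.pbest_fit[best])
        state.gbest_pos = state.pbest_pos[best].copy()
    state.history.append(state.gbest_fit)
    return state


class MemoizedFitness:
    """Caches fitness per position so repeat visits cost nothing."""

    def __init__(self, fn):
        self.fn = fn
        self.cache: dict[tuple, float] = {}
        self.n_evaluations = 0

    def __call__(self, pos: np.ndarray) -> float:
        key = tuple(np.asarray(pos).tolist())
        if key not in self.cache:
            self.n_evaluations += 1
            self.cache[key] = float(self.fn(pos))
        return self.cache[key]


def optimize(cfg: BBOAConfig, fitness_fn, incumbent=None) -> tuple[np.ndarray, float, list[float]]:
    """Run the full swarm; returns (best position, best fitness, history)."""
    memo = MemoizedFitness(fitness_fn)
    state = init_population(cfg, memo, incumbent=incumbent)
    rng = np.random.default_rng(cfg.seed + 1)
    for _ in range(cfg.n_iter):
        step(state, cfg, memo, rng)
    return state.gbest_pos.copy(), state.gbest_fit, list(state.history)


# ----------------------------------------------------------------------
# architecture search binding
# ----------------------------------------------------------------------


def decode_position(pos: np.ndarray, family: str, base_spec: LearnerSpec) -> LearnerSpec:
    """[n_layers, neurons_1..neurons_Lmax] -> LearnerSpec (unused slots dropped)."""
    n_layers = int(pos[0])
    neurons = tuple(int(v) for v in pos[1:1 + n_layers])
    return LearnerSpec(
        family=family, n_hidden_layers=n_layers, neurons=neurons,
        lr=base_spec.lr, batch_size=base_spec.batch_size,
        momentum_beta=base_spec.momentum_beta, epochs=base_spec.epochs,
    )


def search_architecture(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    families: tuple[str, ...] = learners.FAMILIES,
    l_max: int = 3,
    fit_epochs: int = 100,
    objective: str = "macro_f1",
    cfg: BBOAConfig | None = None,
    seed: int = 0,
    lr: float = 1e-4,
    batch_size: int = 20,
) -> tuple[dict[str, LearnerSpec], dict[str, list[float]]]:
    """Optimize hidden-layer count and widths per family, independently.

    Fitness is the validation macro-F1 (or accuracy) of the learner
    trained at a reduced epoch budget; the winning spec per family is
    returned for a full-budget refit by the caller.
    """
    if len(y_val) == 0:
        raise ValueError("empty validation split")
    if objective not in ("macro_f1", "acc"):
        raise ValueError("objective must be macro_f1 or acc")
    y_val_letters = int_to_labels(y_val)
    specs: dict[str, LearnerSpec] = {}
    histories: dict[str, list[float]] = {}
    for fi, family in enumerate(families):
        base = LearnerSpec(family=family, n_hidden_layers=1, neurons=(10,),
                           epochs=fit_epochs, lr=lr, batch_size=batch_size)
        fam_cfg = cfg or BBOAConfig(
            dims=1 + l_max,
            lower=np.ones(1 + l_max),
            upper=np.array([l_max] + [learners.MAX_NEURONS] * l_max, dtype=float),
            seed=seed + fi,
        )

        def fitness(pos, _family=family, _base=base):
            spec = decode_position(pos, _family, _base)
            model = learners.fit(spec, X_train, y_train, seed=seed)
            pred = int_to_labels(model.predict(X_val))
            report = metrics.macro_metrics(metrics.confusion(y_val_letters, pred))
            return report.macro_f1 if objective == "macro_f1" else report.acc

        # start from the pre-optimization incumbent: two hidden layers of 10
        incumbent = np.array([2.0] + [10.0] * l_max)
        best_pos, _, history = optimize(fam_cfg, fitness, incumbent=incumbent)
        specs[family] = decode_position(best_pos, family, base)
        histories[family] = history
    return specs, histories
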