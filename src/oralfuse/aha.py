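"""Artificial Hummingbird Algorithm (AHA): a bounded continuous maximizer.

AHA is a population metaheuristic modelled on hummingbird foraging.  Each
bird holds a position (a candidate solution, a "food source") inside a box
``[L, U]`` and a fitness (the source's nectar-refilling rate).  A visit
table ``VT[i, j]`` counts how long since bird ``i`` visited source ``j``;
sources unvisited for longer take priority as guided-foraging targets.
Three moves drive the search:

* guided foraging — move toward the most-overdue target, perturbed along a
  flight direction mask: ``V = X_tar + a * D * (X_i - X_tar)``, a ~ N(0,1);
* territorial foraging — local multiplicative exploration around the
  bird's own source: ``V = X_i + b * D * X_i``, b ~ N(0,1);
* migration — the worst source is abandoned and re-seeded uniformly in the
  box once every ``migration_period`` iterations.

Flight direction masks ``D`` are binary: axial (one active coordinate),
diagonal (a random subset of 2..d-1 coordinates) or omnidirectional (all
coordinates).  Candidate moves are clamped to the box (with a vanishing random inset at
the boundary, so coordinates never pile up in exact rank ties) and
accepted greedily whenever they do not worsen the bird's fitness: a
strictly worse candidate is always rejected, while equal-fitness
candidates are accepted so the swarm can drift across the plateaus of
piecewise-constant objectives (such as rank-based feature-selection
fitness) instead of freezing on them.  The best-so-far fitness trace is
therefore monotone non-decreasing.

Scheduling choices that the foraging model leaves open (documented in the
methods note): flight mode drawn uniformly from the three patterns; guided
vs territorial chosen with probability 1/2 per bird per iteration;
``migration_period`` defaults to ``2 * n_birds`` iterations; in a migration
iteration the worst bird's move *is* the migration, so the evaluation
budget is exactly ``(max_iter + 1) * n_birds``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AHAConfig",
    "SwarmState",
    "DirectionVector",
    "OptimizationResult",
    "EvaluationError",
    "initialize_swarm",
    "sample_direction",
    "guided_forage",
    "territorial_forage",
    "migration_forage",
    "run_aha",
]


class EvaluationError(RuntimeError):
    """Raised when the objective returns a non-finite value."""


@dataclass(frozen=True)
class AHAConfig:
    """Swarm conditions.  Defaults follow the published configuration for
    the feature-selection use (25 birds, 2500 iterations)."""

    dimension: int
    lower: float | np.ndarray = 0.0
    upper: float | np.ndarray = 1.0
    n_birds: int = 25
    max_iter: int = 2500
    migration_period: int | None = None  # default 2 * n_birds
    #: probabilities of axial / diagonal / omnidirectional flight masks
    flight_probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    #: probability a bird forages guided (else territorial) each iteration
    p_guided: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.n_birds < 2:
            raise ValueError("n_birds must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        L, U = self.bounds()
        if not (np.all(np.isfinite(L)) and np.all(np.isfinite(U))):
            raise ValueError("bounds must be finite")
        if not np.all(L < U):
            raise ValueError("lower bounds must be strictly below upper bounds")
        if self.migration_period is not None and self.migration_period < 1:
            raise ValueError("migration_period must be >= 1")
        fp = self.flight_probabilities
        if len(fp) != 3 or min(fp) < 0 or abs(sum(fp) - 1.0) > 1e-9:
            raise ValueError("flight_probabilities must be 3 non-negatives summing to 1")
        if not 0 <= self.p_guided <= 1:
            raise ValueError("p_guided must be in [0, 1]")

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        L = np.broadcast_to(np.asarray(self.lower, float), (self.dimension,)).copy()
        U = np.broadcast_to(np.asarray(self.upper, float), (self.dimension,)).copy()
        return L, U

    @property
    def effective_migration_period(self) -> int:
        return self.migration_period or 2 * self.n_birds


@dataclass
class SwarmState:
    positions: np.ndarray  # (n_birds, d), always within [L, U]
    fitness: np.ndarray  # (n_birds,)
    visit_table: np.ndarray  # (n_birds, n_birds), diagonal never read
    best_position: np.ndarray
    best_fitness: float
    iteration: int = 0
    evaluations: int = 0


@dataclass(frozen=True)
class DirectionVector:
    """Binary flight-direction mask."""

    D: np.ndarray
    mode: str  # axial | diagonal | omnidirectional


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness, length max_iter + 1
    evaluations: int


def _evaluate(objective, x: np.ndarray, bird: int) -> float:
    f = float(objective(x))
    if not np.isfinite(f):
        raise EvaluationError(
            f"objective returned non-finite value {f!r} for bird {bird}"
        )
    return f


def _clamp(v: np.ndarray, L: np.ndarray, U: np.ndarray, rng) -> np.ndarray:
    """Clamp to the box with a vanishing random inset (<= 1e-6 of the box
    span) at the boundary.  Rank-based objectives are piecewise constant in
    the positions; a hard clamp would pile coordinates onto exactly the
    boundary value, creating rank ties that freeze the search."""
    span = U - L
    low = v < L
    high = v > U
    if low.any():
        v[low] = L[low] + rng.random(int(low.sum())) * 1e-6 * span[low]
    if high.any():
        v[high] = U[high] - rng.random(int(high.sum())) * 1e-6 * span[high]
    return v


def initialize_swarm(cfg: AHAConfig, objective, rng=None) -> SwarmState:
    """Uniform positions in the box, zeroed visit table, one evaluation
    per bird."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    L, U = cfg.bounds()
    X = L + rng.random((cfg.n_birds, cfg.dimension)) * (U - L)
    fit = np.array([_evaluate(objective, X[i], i) for i in range(cfg.n_birds)])
    best = int(np.argmax(fit))
    return SwarmState(
        positions=X,
        fitness=fit,
        visit_table=np.zeros((cfg.n_birds, cfg.n_birds)),
        best_position=X[best].copy(),
        best_fitness=float(fit[best]),
        evaluations=cfg.n_birds,
    )


def sample_direction(
    d: int,
    rng,
    mode: str | None = None,
    probabilities: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> DirectionVector:
    """Draw a flight-direction mask.

    When ``mode`` is None the pattern is drawn with the given
    axial/diagonal/omnidirectional probabilities (uniform by default);
    for d < 3 the diagonal pattern is unavailable (it needs 2..d-1 active
    coordinates) and collapses to omnidirectional.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    if mode is None:
        r = rng.random()
        p_ax, p_diag, _ = probabilities
        mode = (
            "axial"
            if r < p_ax
            else ("diagonal" if r < p_ax + p_diag else "omnidirectional")
        )
    if mode == "diagonal" and d < 3:
        mode = "omnidirectional"
    D = np.zeros(d)
    if mode == "axial":
        D[rng.integers(d)] = 1.0
    elif mode == "diagonal":
        k = min(d - 1, max(2, 1 + int(np.ceil(rng.random() * (d - 2)))))
        D[rng.permutation(d)[:k]] = 1.0
    elif mode == "omnidirectional":
        D[:] = 1.0
    else:
        raise ValueError(f"unknown flight mode {mode!r}")
    return DirectionVector(D=D, mode=mode)


def _choose_target(state: SwarmState, i: int) -> int:
    """Guided-foraging target: maximal visit counter, ties broken by
    higher fitness, then lower index.  The diagonal is never consulted."""
    n = len(state.fitness)
    vt = state.visit_table[i]
    candidates = [j for j in range(n) if j != i]
    vmax = max(vt[j] for j in candidates)
    tied = [j for j in candidates if vt[j] == vmax]
    fmax = max(state.fitness[j] for j in tied)
    return min(j for j in tied if state.fitness[j] == fmax)


def _after_forage_visits(state: SwarmState, i: int, target: int | None) -> None:
    n = len(state.fitness)
    others = np.arange(n) != i
    state.visit_table[i, others] += 1
    if target is not None:
        state.visit_table[i, target] = 0


def guided_forage(
    state: SwarmState, i: int, rng, objective, cfg: AHAConfig
) -> SwarmState:
    """Move bird ``i`` toward its visit-table target; greedy acceptance."""
    L, U = cfg.bounds()
    tar = _choose_target(state, i)
    direction = sample_direction(cfg.dimension, rng, probabilities=cfg.flight_probabilities)
    a = rng.standard_normal()
    v = state.positions[tar] + a * direction.D * (state.positions[i] - state.positions[tar])
    _clamp(v, L, U, rng)
    fv = _evaluate(objective, v, i)
    state.evaluations += 1
    if fv >= state.fitness[i]:
        state.positions[i] = v
        state.fitness[i] = fv
        if fv > state.best_fitness:
            state.best_fitness = fv
            state.best_position = v.copy()
    _after_forage_visits(state, i, tar)
    return state


def territorial_forage(
    state: SwarmState, i: int, rng, objective, cfg: AHAConfig
) -> SwarmState:
    """Local multiplicative exploration around bird ``i``'s own source."""
    L, U = cfg.bounds()
    direction = sample_direction(cfg.dimension, rng, probabilities=cfg.flight_probabilities)
    b = rng.standard_normal()
    v = state.positions[i] + b * direction.D * state.positions[i]
    _clamp(v, L, U, rng)
    fv = _evaluate(objective, v, i)
    state.evaluations += 1
    if fv >= state.fitness[i]:
        state.positions[i] = v
        state.fitness[i] = fv
        if fv > state.best_fitness:
            state.best_fitness = fv
            state.best_position = v.copy()
    _after_forage_visits(state, i, None)
    return state


def migration_forage(state: SwarmState, rng, objective, cfg: AHAConfig) -> SwarmState:
    """Re-seed the worst bird uniformly in the box; reset its visit
    counters (row and column)."""
    L, U = cfg.bounds()
    worst = int(np.argmin(state.fitness))
    x = L + rng.random(cfg.dimension) * (U - L)
    state.positions[worst] = x
    state.fitness[worst] = _evaluate(objective, x, worst)
    state.evaluations += 1
    state.visit_table[worst, :] = 0
    state.visit_table[:, worst] = 0
    if state.fitness[worst] > state.best_fitness:
        state.best_fitness = float(state.fitness[worst])
        state.best_position = x.copy()
    return state


def run_aha(objective, cfg: AHAConfig) -> OptimizationResult:
    """Maximize ``objective`` over the box; returns the elitist best and
    the per-iteration best-so-far trace (length ``max_iter + 1``)."""
    rng = np.random.default_rng(cfg.seed)
    state = initialize_swarm(cfg, objective, rng)
    trace = [state.best_fitness]
    period = cfg.effective_migration_period
    for t in range(1, cfg.max_iter + 1):
        state.iteration = t
        migrate = t % period == 0
        migrant = int(np.argmin(state.fitness)) if migrate else -1
        for i in range(cfg.n_birds):
            if i == migrant:
                migration_forage(state, rng, objective, cfg)
            elif rng.random() < cfg.p_guided:
                guided_forage(state, i, rng, objective, cfg)
            else:
                territorial_forage(state, i, rng, objective, cfg)
        trace.append(state.best_fitness)
    return OptimizationResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        trace=np.array(trace),
        evaluations=state.evaluations,
    )
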