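"""Inverse fitting of (Q_l, Q_r, P_s) to a recorded trajectory pair.

The fitting pipeline runs three derivative-free optimizers — Nelder–Mead
(NM), particle swarm (PSO), and an artificial/simulated bee colony (SBC) —
against each of the three cost functions Γ₁, Γ₂, Γ₃, yielding nine
candidate parameter sets per subject.  Since the costs live on different
scales, the winner is the candidate with the smallest selection metric Γ
(normalized squared trajectory distance).

A coarse grid search over the bounded parameter box seeds NM (best point)
and PSO (top-k points injected as initial particles); the stochastic bee
colony starts from uniform random food sources.  Every simulation inside
the objective is cached on the rounded parameter triple, so the nine runs
and the grid share work.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .costs import COST_FUNCTIONS, gamma_final
from .errors import (
    DomainError,
    FitFailureError,
    GlottifitError,
    IntegrationBlowupError,
    SearchFailureError,
)
from .evaluate import SuccessReport, assess_success, symmetry_quotient
from .model import simulate
from .parameters import FitVariables, StandardParameters
from .signals import TrajectoryPair, fundamental_frequency

__all__ = [
    "SearchSpace",
    "FitConfig",
    "OptimizerResult",
    "RunRecord",
    "FitResult",
    "initial_grid_search",
    "nelder_mead",
    "particle_swarm",
    "bee_colony",
    "fit_subject",
]

#: finite penalty returned when a simulation blows up, so stochastic
#: searches can continue past pathological parameter combinations
BLOWUP_PENALTY = 1e6


@dataclass(frozen=True)
class SearchSpace:
    """Bounded box for (Q_l, Q_r, P_s) with the initial-search grid steps.

    The default bounds generously cover the parameter ranges observed when
    fitting healthy adult phonation (Q ≈ 0.8–4.9, P_s ≈ 10–46 cmH₂O).
    """

    ql_bounds: tuple[float, float] = (0.5, 6.0)
    qr_bounds: tuple[float, float] = (0.5, 6.0)
    ps_bounds: tuple[float, float] = (5.0, 50.0)
    q_step: float = 0.5
    ps_step: float = 5.0

    def __post_init__(self) -> None:
        for lo, hi in (self.ql_bounds, self.qr_bounds, self.ps_bounds):
            if not lo < hi:
                raise DomainError("search bounds must satisfy lower < upper")
        if self.q_step <= 0 or self.ps_step <= 0:
            raise DomainError("grid steps must be positive")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.ql_bounds[0], self.qr_bounds[0], self.ps_bounds[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.ql_bounds[1], self.qr_bounds[1], self.ps_bounds[1]])

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower) & np.all(x <= self.upper))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(x, dtype=float), self.lower, self.upper)

    def grid_axes(self):
        ql = np.arange(self.ql_bounds[0], self.ql_bounds[1] + 1e-9, self.q_step)
        qr = np.arange(self.qr_bounds[0], self.qr_bounds[1] + 1e-9, self.q_step)
        ps = np.arange(self.ps_bounds[0], self.ps_bounds[1] + 1e-9, self.ps_step)
        return ql, qr, ps


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the fitting pipeline (all optimizer defaults here).

    The initial-value search has two parts: the regular coarse grid, and a
    frequency-guided refinement that exploits the model's monotone
    frequency–stiffness relation (f₀ grows with Q) to place starting points
    inside the narrow basin where model and recording oscillate in step —
    without it, every local search strands on the decorrelation plateau.
    """

    budget: int = 2000              # objective evaluations per optimizer run
    n_particles: int = 30
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    n_sources: int = 30             # bee-colony food sources
    abandonment_limit: int = 20
    top_k_pso: int = 5              # grid points injected into the swarm
    xatol: float = 1e-4
    fatol: float = 1e-8
    nm_initial_step: tuple = (0.02, 0.02, 0.5)  # basin-sized simplex
    refine: bool = True             # frequency-guided start refinement
    algorithms: tuple = ("nm", "pso", "sbc")
    costs: tuple = ("gamma1", "gamma2", "gamma3")
    total_ms: float = 500.0
    transient_ms: float = 400.0
    cache_decimals: int = 6
    smooth: float = 0.0

    @classmethod
    def fast(cls) -> "FitConfig":
        """Reduced-budget profile for quick exploratory fits."""
        return cls(budget=300)

    def to_dict(self) -> dict:
        return {
            "budget": self.budget,
            "n_particles": self.n_particles,
            "inertia": self.inertia,
            "cognitive": self.cognitive,
            "social": self.social,
            "n_sources": self.n_sources,
            "abandonment_limit": self.abandonment_limit,
            "top_k_pso": self.top_k_pso,
            "algorithms": list(self.algorithms),
            "costs": list(self.costs),
            "total_ms": self.total_ms,
            "transient_ms": self.transient_ms,
        }


@dataclass(frozen=True)
class OptimizerResult:
    """Best point and value of one optimizer run."""

    x: np.ndarray
    value: float
    n_evaluations: int
    converged: bool
    n_scouts: int = 0


@dataclass(frozen=True)
class RunRecord:
    """One optimizer × cost run within a subject fit."""

    algorithm: str
    cost: str
    start: list | None
    params: FitVariables
    cost_value: float
    gamma: float
    n_evaluations: int
    seed: int | None
    converged: bool

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "cost": self.cost,
            "start": self.start,
            "Ql": self.params.Ql,
            "Qr": self.params.Qr,
            "Ps_cmH2O": self.params.Ps,
            "cost_value": self.cost_value,
            "gamma": self.gamma,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunRecord":
        return cls(
            algorithm=d["algorithm"],
            cost=d["cost"],
            start=d.get("start"),
            params=FitVariables(d["Ql"], d["Qr"], d["Ps_cmH2O"]),
            cost_value=d["cost_value"],
            gamma=d["gamma"],
            n_evaluations=d["n_evaluations"],
            seed=d.get("seed"),
            converged=d["converged"],
        )


@dataclass(frozen=True)
class FitResult:
    """Complete per-subject fit: nine run records plus the Γ-selected best."""

    subject_id: str
    records: list
    best: RunRecord
    qlr: float
    f_el: float
    f_er: float
    f_ml: float
    f_mr: float
    success: SuccessReport
    config: dict = field(compare=False, default_factory=dict)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def initial_grid_search(objective, space: SearchSpace):
    """Evaluate the objective on the regular grid; points sorted ascending.

    Deterministic; raises ``SearchFailureError`` if no grid evaluation is
    finite.
    """
    points, values = [], []
    for ql, qr, ps in itertools.product(*space.grid_axes()):
        x = np.array([ql, qr, ps])
        points.append(x)
        values.append(float(objective(x)))
    values = np.asarray(values)
    if not np.any(np.isfinite(values)):
        raise SearchFailureError("no finite objective value on the initial grid")
    order = np.argsort(values, kind="stable")
    return [(points[i], values[i]) for i in order]


def _penalized(objective, space: SearchSpace, counter: list):
    """Wrap an objective with bound projection + quadratic penalty."""

    def wrapped(x):
        counter[0] += 1
        xp = space.clip(x)
        pen = 1e3 * float(np.sum((np.asarray(x) - xp) ** 2))
        return float(objective(xp)) + pen

    return wrapped


def nelder_mead(
    objective,
    start,
    space: SearchSpace,
    budget: int = 2000,
    xatol: float = 1e-4,
    fatol: float = 1e-8,
    initial_step=None,
) -> OptimizerResult:
    """Nelder–Mead simplex search (reflection 1, expansion 2, contraction
    0.5, shrink 0.5) with out-of-bounds points projected and penalized.

    ``initial_step`` sets the per-dimension edge lengths of the starting
    simplex; the default lets the backend choose.  Deterministic given the
    start point.
    """
    start = np.asarray(start, dtype=float)
    if not space.contains(start):
        raise DomainError("start point outside the search space")
    counter = [0]
    options = {"maxfev": budget, "xatol": xatol, "fatol": fatol, "adaptive": False}
    if initial_step is not None:
        simplex = np.tile(start, (4, 1))
        for d in range(3):
            simplex[d + 1, d] += initial_step[d]
        options["initial_simplex"] = simplex
    res = minimize(
        _penalized(objective, space, counter),
        start,
        method="Nelder-Mead",
        options=options,
    )
    x = space.clip(res.x)
    return OptimizerResult(
        x=x, value=float(objective(x)), n_evaluations=counter[0],
        converged=bool(res.success),
    )


def particle_swarm(
    objective,
    space: SearchSpace,
    seed: int,
    budget: int = 2000,
    n_particles: int = 30,
    inertia: float = 0.72,
    cognitive: float = 1.49,
    social: float = 1.49,
    init_points=None,
) -> OptimizerResult:
    """Global-best particle swarm with reflecting bounds.

    Velocities are clamped to half the range per dimension; ``init_points``
    (e.g. the best grid-search points) replace the first particles.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = space.lower, space.upper
    vmax = 0.5 * (hi - lo)
    pos = rng.uniform(lo, hi, size=(n_particles, 3))
    if init_points is not None:
        for i, p in enumerate(list(init_points)[:n_particles]):
            pos[i] = space.clip(p)
    vel = rng.uniform(-vmax, vmax, size=(n_particles, 3)) * 0.1

    n_evals = 0
    values = np.array([float(objective(p)) for p in pos])
    n_evals += n_particles
    pbest, pbest_val = pos.copy(), values.copy()
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    while n_evals + n_particles <= budget:
        r1 = rng.uniform(size=(n_particles, 3))
        r2 = rng.uniform(size=(n_particles, 3))
        vel = (
            inertia * vel
            + cognitive * r1 * (pbest - pos)
            + social * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = pos + vel
        # reflect at the bounds
        for _ in range(2):
            below = pos < lo
            pos = np.where(below, 2 * lo - pos, pos)
            vel = np.where(below, -vel, vel)
            above = pos > hi
            pos = np.where(above, 2 * hi - pos, pos)
            vel = np.where(above, -vel, vel)
        pos = np.clip(pos, lo, hi)
        values = np.array([float(objective(p)) for p in pos])
        n_evals += n_particles
        improved = values < pbest_val
        pbest[improved] = pos[improved]
        pbest_val[improved] = values[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])

    return OptimizerResult(x=gbest, value=gbest_val, n_evaluations=n_evals,
                           converged=True)


def bee_colony(
    objective,
    space: SearchSpace,
    seed: int,
    budget: int = 2000,
    n_sources: int = 30,
    limit: int = 20,
) -> OptimizerResult:
    """Artificial bee colony with employed/onlooker/scout phases.

    Food sources start uniformly at random within the bounds (no grid
    seeding); a source unimproved for ``limit`` trials is abandoned and
    re-scouted.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = space.lower, space.upper
    pos = rng.uniform(lo, hi, size=(n_sources, 3))
    values = np.array([float(objective(p)) for p in pos])
    n_evals = n_sources
    trials = np.zeros(n_sources, dtype=int)
    n_scouts = 0
    b = int(np.argmin(values))
    best, best_val = pos[b].copy(), float(values[b])

    def fitness(v):
        return 1.0 / (1.0 + v) if v >= 0 else 1.0 + abs(v)

    def neighbor(i):
        k = rng.integers(n_sources - 1)
        if k >= i:
            k += 1
        d = rng.integers(3)
        phi = rng.uniform(-1.0, 1.0)
        cand = pos[i].copy()
        cand[d] += phi * (pos[i][d] - pos[k][d])
        return np.clip(cand, lo, hi)

    def greedy(i, cand):
        nonlocal best, best_val, n_evals
        v = float(objective(cand))
        n_evals += 1
        if v < values[i]:
            pos[i], values[i], trials[i] = cand, v, 0
        else:
            trials[i] += 1
        if v < best_val:
            best, best_val = cand.copy(), v

    while n_evals + 2 * n_sources + 1 <= budget:
        for i in range(n_sources):            # employed phase
            greedy(i, neighbor(i))
        fits = np.array([fitness(v) for v in values])
        probs = fits / fits.sum()
        for i in rng.choice(n_sources, size=n_sources, p=probs):  # onlookers
            greedy(int(i), neighbor(int(i)))
        worst = int(np.argmax(trials))        # scout phase (one per cycle)
        if trials[worst] > limit:
            pos[worst] = rng.uniform(lo, hi)
            values[worst] = float(objective(pos[worst]))
            n_evals += 1
            trials[worst] = 0
            n_scouts += 1
            if values[worst] < best_val:
                best, best_val = pos[worst].copy(), float(values[worst])

    return OptimizerResult(x=best, value=best_val, n_evaluations=n_evals,
                           converged=True, n_scouts=n_scouts)


# ---------------------------------------------------------------------------
# frequency-guided start refinement
# ---------------------------------------------------------------------------

def _model_f0(cache: "_SimulationCache", x) -> float | None:
    pair = cache.trajectories(x)
    if pair is None:
        return None
    try:
        return fundamental_frequency(pair.left, pair.sample_rate)
    except GlottifitError:
        return None


def _evaluate_pool(objective, points) -> list:
    seen = set()
    pool = []
    for x in points:
        key = tuple(np.round(np.asarray(x, float), 6))
        if key in seen:
            continue
        seen.add(key)
        pool.append((np.asarray(x, float), float(objective(x))))
    pool.sort(key=lambda pv: pv[1])
    return pool


def refine_start_points(
    objective,
    cache: "_SimulationCache",
    space: SearchSpace,
    f_target: float,
    coarse,
) -> list:
    """Frequency-guided refinement of the initial-value search.

    The time- and frequency-domain costs only leave the decorrelation
    plateau once the model's fundamental frequency matches the recording to
    within about one DFT bin, so the useful basin around the optimum is far
    narrower than any affordable regular grid.  This stage (1) scans
    symmetric Q at a few pressures for the Q whose simulated f₀ best
    matches the recorded f₀ (monotone frequency–stiffness relation), then
    (2) lays a local left/right-asymmetry grid around the matched point and
    (3) a micro-grid around its best point.  Returns candidate starts
    sorted by objective value, pooled with the coarse grid results.
    """
    lo, hi = space.lower, space.upper

    # (1) symmetric-Q frequency matching at a few pressures
    centers = []
    for ps in np.linspace(max(lo[2], 10.0), min(hi[2], 40.0), 4):
        qs = np.arange(lo[0], hi[0] + 1e-9, 0.25)
        errs = []
        for q in qs:
            f0 = _model_f0(cache, [q, q, ps])
            errs.append(abs(f0 - f_target) if f0 is not None else np.inf)
        if not np.any(np.isfinite(errs)):
            continue
        q_best = qs[int(np.argmin(errs))]
        fine = np.arange(max(lo[0], q_best - 0.25), min(hi[0], q_best + 0.25) + 1e-9, 0.02)
        errs = []
        for q in fine:
            f0 = _model_f0(cache, [q, q, ps])
            errs.append(abs(f0 - f_target) if f0 is not None else np.inf)
        if np.any(np.isfinite(errs)):
            centers.append(np.array([fine[int(np.argmin(errs))]] * 2 + [ps]))

    pool = _evaluate_pool(objective, centers) if centers else []
    if not pool:
        return coarse

    # (2) local asymmetry grid around the best frequency-matched center
    cq = pool[0][0]
    dq = np.arange(-0.24, 0.24 + 1e-9, 0.04)
    dps = np.array([-2.5, 0.0, 2.5])
    points = [
        space.clip([cq[0] + a, cq[1] + b, cq[2] + c])
        for a in dq for b in dq for c in dps
    ]
    pool = _evaluate_pool(objective, [p for p, _ in pool] + points)

    # (3) micro-grid around the asymmetry-grid winner
    cq = pool[0][0]
    dq = np.arange(-0.03, 0.03 + 1e-9, 0.0075)
    dps = np.arange(-1.5, 1.5 + 1e-9, 0.75)
    points = [
        space.clip([cq[0] + a, cq[1] + b, cq[2] + c])
        for a in dq for b in dq for c in dps
    ]
    pool = _evaluate_pool(objective, [p for p, _ in pool] + points)

    merged = pool + [(p, v) for p, v in coarse]
    merged.sort(key=lambda pv: pv[1])
    return merged


# ---------------------------------------------------------------------------
# subject fitting
# ---------------------------------------------------------------------------

class _SimulationCache:
    """Memoized model trajectories keyed on the rounded parameter triple."""

    def __init__(self, t_e: TrajectoryPair, std: StandardParameters, config: FitConfig):
        self.t_e = t_e
        self.std = std
        self.config = config
        self._cache: dict = {}
        # simulate exactly the experimental window length
        n = t_e.n_samples
        self.total_ms = config.transient_ms + n * 1000.0 / t_e.sample_rate

    def trajectories(self, x) -> TrajectoryPair | None:
        key = tuple(np.round(np.asarray(x, dtype=float), self.config.cache_decimals))
        if key in self._cache:
            return self._cache[key]
        try:
            fit = FitVariables(*key)
            sim = simulate(
                fit,
                self.std,
                total_ms=self.total_ms,
                output_rate=self.t_e.sample_rate,
                transient_ms=self.config.transient_ms,
                smooth=self.config.smooth,
            )
            pair = TrajectoryPair(
                left=sim.t_ml, right=sim.t_mr,
                sample_rate=self.t_e.sample_rate, unit=self.t_e.unit,
            )
        except (IntegrationBlowupError, DomainError):
            pair = None
        self._cache[key] = pair
        return pair

    def objective(self, cost_name: str):
        cost_fn = COST_FUNCTIONS[cost_name]

        def fun(x):
            pair = self.trajectories(x)
            if pair is None:
                return BLOWUP_PENALTY
            try:
                value = float(cost_fn(self.t_e, pair))
            except GlottifitError:
                return BLOWUP_PENALTY
            return value if np.isfinite(value) else BLOWUP_PENALTY

        return fun


def fit_subject(
    t_e: TrajectoryPair,
    std: StandardParameters | None = None,
    space: SearchSpace | None = None,
    config: FitConfig | None = None,
    seed: int = 0,
    subject_id: str = "subject",
) -> FitResult:
    """Fit (Q_l, Q_r, P_s) to a preprocessed experimental trajectory pair.

    ``t_e`` must be metric and ``std`` must already carry the subject's
    rest geometry (see :func:`glottifit.signals.subject_parameters`).  Runs
    every configured optimizer against every configured cost function,
    simulates each winner, and selects the parameter set with the smallest
    Γ.  Deterministic for a fixed seed.
    """
    if std is None:
        std = StandardParameters()
    if space is None:
        space = SearchSpace()
    if config is None:
        config = FitConfig()

    cache = _SimulationCache(t_e, std, config)
    seeds = np.random.SeedSequence(seed).generate_state(
        len(config.algorithms) * len(config.costs)
    )

    try:
        f_target = 0.5 * (
            fundamental_frequency(t_e.left, t_e.sample_rate)
            + fundamental_frequency(t_e.right, t_e.sample_rate)
        )
    except GlottifitError:
        f_target = None

    records: list[RunRecord] = []
    run_idx = 0
    needs_starts = "nm" in config.algorithms or "pso" in config.algorithms
    refined_pool = None  # refinement points shared across costs (sims cached)
    if needs_starts and config.refine and f_target is not None:
        # the time-domain cost discriminates best near the optimum; use it
        # (when configured) to lay out the shared candidate pool
        pathfinder = "gamma2" if "gamma2" in config.costs else config.costs[0]
        objective = cache.objective(pathfinder)
        coarse = initial_grid_search(objective, space)
        refined = refine_start_points(objective, cache, space, f_target, coarse)
        refined_pool = [p for p, _ in refined]
    for cost_name in config.costs:
        objective = cache.objective(cost_name)
        grid = None
        if needs_starts:
            if refined_pool is not None:
                # the pool already merges the coarse grid; re-rank it under
                # this cost (simulations are cached, so this is cheap)
                grid = _evaluate_pool(objective, refined_pool)
            else:
                grid = initial_grid_search(objective, space)
        for algo in config.algorithms:
            run_seed = int(seeds[run_idx] % (2**31))
            run_idx += 1
            start = None
            if algo == "nm":
                start = grid[0][0]
                opt = nelder_mead(
                    objective, start, space,
                    budget=config.budget, xatol=config.xatol, fatol=config.fatol,
                    initial_step=config.nm_initial_step,
                )
            elif algo == "pso":
                init_points = [p for p, _ in grid[: config.top_k_pso]]
                start = init_points
                opt = particle_swarm(
                    objective, space, seed=run_seed, budget=config.budget,
                    n_particles=config.n_particles, inertia=config.inertia,
                    cognitive=config.cognitive, social=config.social,
                    init_points=init_points,
                )
            elif algo == "sbc":
                opt = bee_colony(
                    objective, space, seed=run_seed, budget=config.budget,
                    n_sources=config.n_sources, limit=config.abandonment_limit,
                )
            else:
                raise DomainError(f"unknown algorithm {algo!r}")

            pair = cache.trajectories(opt.x)
            if pair is None:
                gamma = float("inf")
            else:
                try:
                    gamma = gamma_final(t_e, pair)
                except GlottifitError:
                    gamma = float("inf")
            records.append(
                RunRecord(
                    algorithm=algo,
                    cost=cost_name,
                    start=np.asarray(start).tolist() if start is not None else None,
                    params=FitVariables.from_array(opt.x),
                    cost_value=opt.value,
                    gamma=gamma,
                    n_evaluations=opt.n_evaluations,
                    seed=run_seed if algo in ("pso", "sbc") else None,
                    converged=opt.converged,
                )
            )

    gammas = np.array([r.gamma for r in records])
    if not np.any(np.isfinite(gammas)):
        raise FitFailureError("no optimizer run produced a finite selection metric")
    best = records[int(np.argmin(gammas))]

    best_pair = cache.trajectories(best.params.as_array())
    f_el = fundamental_frequency(t_e.left, t_e.sample_rate)
    f_er = fundamental_frequency(t_e.right, t_e.sample_rate)
    try:
        f_ml = fundamental_frequency(best_pair.left, best_pair.sample_rate)
        f_mr = fundamental_frequency(best_pair.right, best_pair.sample_rate)
    except GlottifitError:
        f_ml = f_mr = float("nan")
    try:
        success = assess_success(t_e, best_pair)
    except GlottifitError:
        # degenerate best model (e.g. barely oscillating): rate as failed
        success = SuccessReport(
            frequency_ok=False, closure_ok=False, amplitude_ok=False,
            freq_deviation_l=float("nan"), freq_deviation_r=float("nan"),
            exp_amplitude_range_l=(float("nan"), float("nan")),
            exp_amplitude_range_r=(float("nan"), float("nan")),
            model_amplitude_l=float("nan"), model_amplitude_r=float("nan"),
        )
    return FitResult(
        subject_id=subject_id,
        records=records,
        best=best,
        qlr=symmetry_quotient(best.params.Ql, best.params.Qr),
        f_el=f_el, f_er=f_er, f_ml=f_ml, f_mr=f_mr,
        success=success,
        config=config.to_dict(),
    )
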