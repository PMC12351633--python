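"""Hybrid montage optimization: SLSQP currents inside a genetic subset search.

The fitness (NERNI, or its group mean) is a concave quadratic in the
electrode currents, so for a fixed electrode subset the optimal currents are
found by constrained sequential least squares (the inner problem). An outer
genetic algorithm searches over electrode subsets of bounded cardinality.

Safety constraints: at most ``max_current_per_electrode`` (mA) at any
electrode including the implicit reference, total injected (anodal) current
at most ``max_total_injected`` (mA), zero net current by construction, and at
most ``max_electrodes`` active electrodes.

The inner problem is reformulated with split positive/negative currents
(I = p - m, and an explicit split reference current) so that every constraint
is linear and SLSQP sees a smooth concave program whose feasible polytope
maps exactly onto the true constraint set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .model import Montage, SubjectModel
from .objective import mean_en, nerni

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizationConfig",
    "CurrentSolution",
    "OptimizationResult",
    "LooResult",
    "solve_currents",
    "ga_optimize",
    "optimize_group_loo",
    "check_constraints",
]


@dataclass
class OptimizationConfig:
    """Constraint bounds and genetic-algorithm settings."""

    max_current_per_electrode: float = 2.0  # mA
    max_total_injected: float = 4.0  # mA, anodal sum including the reference
    max_electrodes: int = 8
    ga_population: int = 3000
    ga_stall_tolerance: float = 1e-6
    ga_stall_generations: int = 5
    ga_max_generations: int = 100
    tournament_size: int = 3
    crossover_prob: float = 0.5
    mutation_rate: float | None = None  # default 2 / n_candidates per gene
    elitism: int = 1
    seed: int = 0
    current_tolerance: float = 1e-6  # mA
    count_reference_in_budget: bool = False

    def __post_init__(self) -> None:
        if min(self.max_current_per_electrode, self.max_total_injected) <= 0:
            raise ValueError("current bounds must be positive")
        if self.max_electrodes < 2:
            raise ValueError("max_electrodes must be >= 2")
        if self.ga_population < 2:
            raise ValueError("ga_population must be >= 2")


@dataclass
class CurrentSolution:
    """Optimal currents for a fixed electrode subset."""

    montage: Montage
    objective: float
    currents: dict[str, float]

    @property
    def reference_current(self) -> float:
        return self.montage.reference_current


@dataclass
class OptimizationResult:
    """Outcome of a (possibly degenerate) genetic montage optimization."""

    montage: Montage
    objective: float
    generations_run: int
    history: list[float]
    active_electrodes: tuple[str, ...]
    seed: int


@dataclass
class LooResult:
    """Leave-one-out group optimization outcome for one held-out subject."""

    result: OptimizationResult
    held_out_nerni: float
    held_out_mean_en: float


class _GroupQuadratic:
    """Group-averaged quadratic form of NERNI over candidate electrodes.

    NERNI_g(I) = 2 b.I - I.Q.I with Q and b averaged over subjects, so group
    inner solves cost the same as single-subject ones regardless of group
    size or mesh resolution.
    """

    def __init__(self, subjects: Sequence[SubjectModel], candidates: Sequence[str]):
        if len(subjects) == 0:
            raise ValueError("empty subject list")
        self.candidates = tuple(candidates)
        refs = {s.leadfield.reference_label for s in subjects}
        if len(refs) != 1:
            raise ValueError(f"subjects disagree on the reference electrode: {refs}")
        self.reference_label = refs.pop()
        n = len(self.candidates)
        Q = np.zeros((n, n))
        b = np.zeros(n)
        for s in subjects:
            idx = [s.leadfield.column_index(lab) for lab in self.candidates]
            K = s.leadfield.matrix[:, idx]
            w = s.target.weights
            wt = w * s.target.en_trg
            denom = float(wt @ wt)
            if denom == 0.0:
                raise ValueError(f"subject {s.subject_id!r}: weighted target is zero")
            M = w[:, None] * K
            Q += (M.T @ M) / denom
            b += (M.T @ wt) / denom
        self.Q = Q / len(subjects)
        self.b = b / len(subjects)

    def objective(self, I: np.ndarray, idx: np.ndarray) -> float:
        Qs = self.Q[np.ix_(idx, idx)]
        bs = self.b[idx]
        return float(2.0 * bs @ I - I @ Qs @ I)


def _solve_qp(
    Q: np.ndarray, b: np.ndarray, config: OptimizationConfig, force_zero_reference: bool = False
) -> tuple[np.ndarray, float]:
    """Maximise 2 b.I - I.Q.I over the safety polytope. Returns (I, value)."""
    k = len(b)
    imax = config.max_current_per_electrode
    itot = config.max_total_injected

    def value(I: np.ndarray) -> float:
        return float(2.0 * b @ I - I @ Q @ I)

    def feasible(I: np.ndarray, tol: float = 1e-7) -> bool:
        ref = -I.sum()
        if force_zero_reference and abs(ref) > tol:
            return False
        anodal = I[I > 0].sum() + max(ref, 0.0)
        return (
            np.abs(I).max(initial=0.0) <= imax + tol
            and abs(ref) <= imax + tol
            and anodal <= itot + tol
        )

    # unconstrained stationary point: done if already feasible
    I_u, *_ = np.linalg.lstsq(Q, b, rcond=None)
    if feasible(I_u, tol=0.0) and not force_zero_reference:
        return I_u, value(I_u)

    # split formulation: z = [p, m, p_ref, m_ref], I = p - m
    def split(z):
        return z[:k] - z[k : 2 * k]

    def neg_f(z):
        return -value(split(z))

    def neg_grad(z):
        g = 2.0 * (b - Q @ split(z))
        return np.concatenate([-g, g, [0.0, 0.0]])

    bounds = [(0.0, imax)] * (2 * k) + [(0.0, 0.0), (0.0, 0.0)] if force_zero_reference else [
        (0.0, imax)
    ] * (2 * k + 2)
    A_eq = np.concatenate([np.ones(k), -np.ones(k), [1.0, -1.0]])
    constraints = [
        {"type": "eq", "fun": lambda z: A_eq @ z, "jac": lambda z: A_eq},
        {
            "type": "ineq",
            "fun": lambda z: itot - (z[:k].sum() + z[2 * k]),
            "jac": lambda z: -np.concatenate([np.ones(k), np.zeros(k), [1.0, 0.0]]),
        },
    ]

    def z_from(I: np.ndarray) -> np.ndarray:
        ref = -I.sum()
        return np.concatenate(
            [np.maximum(I, 0.0), np.maximum(-I, 0.0), [max(ref, 0.0), max(-ref, 0.0)]]
        )

    # warm start: scale the unconstrained optimum into the polytope
    ref_u = -I_u.sum()
    anodal_u = I_u[I_u > 0].sum() + max(ref_u, 0.0)
    scale = min(
        1.0,
        imax / max(np.abs(I_u).max(initial=0.0), 1e-30),
        imax / max(abs(ref_u), 1e-30),
        itot / max(anodal_u, 1e-30),
    )
    starts = [z_from(I_u * scale), np.zeros(2 * k + 2)]

    best_I, best_val = np.zeros(k), 0.0
    for z0 in starts:
        res = minimize(
            neg_f,
            z0,
            jac=neg_grad,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"ftol": 1e-12, "maxiter": 500},
        )
        I = split(res.x)
        if feasible(I) and value(I) > best_val:
            best_I, best_val = I, value(I)
    if best_val == 0.0 and not feasible(best_I):
        raise RuntimeError("SLSQP failed to produce a feasible current solution")
    return best_I, best_val


def solve_currents(
    electrodes: Sequence[str],
    subjects: SubjectModel | Sequence[SubjectModel],
    config: OptimizationConfig | None = None,
    _quad: _GroupQuadratic | None = None,
) -> CurrentSolution:
    """Optimal currents on a fixed electrode subset (group objective if several
    subjects are given). The implicit reference obeys the per-electrode bound;
    currents are balanced by construction."""
    if isinstance(subjects, SubjectModel):
        subjects = [subjects]
    config = config or OptimizationConfig()
    electrodes = list(electrodes)
    if not electrodes:
        raise ValueError("empty electrode subset")
    quad = _quad or _GroupQuadratic(subjects, electrodes)
    idx = np.array([quad.candidates.index(lab) for lab in electrodes])
    Qs = quad.Q[np.ix_(idx, idx)]
    bs = quad.b[idx]
    force_zero_ref = config.count_reference_in_budget and len(electrodes) >= config.max_electrodes
    I, val = _solve_qp(Qs, bs, config, force_zero_reference=force_zero_ref)
    currents = {
        lab: float(c) for lab, c in zip(electrodes, I) if abs(c) > 1e-12
    }
    montage = Montage(currents, reference_label=quad.reference_label)
    return CurrentSolution(montage=montage, objective=val, currents=currents)


def _repair(mask: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    active = np.flatnonzero(mask)
    if len(active) > k:
        drop = rng.choice(active, size=len(active) - k, replace=False)
        mask[drop] = False
    elif len(active) < k:
        inactive = np.flatnonzero(~mask)
        add = rng.choice(inactive, size=k - len(active), replace=False)
        mask[add] = True
    return mask


def ga_optimize(
    subjects: SubjectModel | Sequence[SubjectModel],
    candidates: Sequence[str] | None = None,
    config: OptimizationConfig | None = None,
) -> OptimizationResult:
    """Genetic search over electrode subsets with SLSQP inner current solves.

    Populations of binary electrode masks (exactly ``max_electrodes`` active
    genes, repaired after crossover/mutation) evolve by tournament selection,
    uniform crossover and per-gene mutation with elitism; the run stops when
    the best objective improves by less than ``ga_stall_tolerance`` for
    ``ga_stall_generations`` consecutive generations. Deterministic for a
    fixed seed; equal-objective subsets tie-break to the lexicographically
    smallest label set.
    """
    if isinstance(subjects, SubjectModel):
        subjects = [subjects]
    config = config or OptimizationConfig()
    if candidates is None:
        candidates = subjects[0].leadfield.electrode_labels
    candidates = tuple(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate electrodes")
    quad = _GroupQuadratic(subjects, candidates)
    n = len(candidates)
    k = min(config.max_electrodes, n)

    def subset_labels(idx_tuple: tuple[int, ...]) -> tuple[str, ...]:
        return tuple(candidates[i] for i in idx_tuple)

    cache: dict[tuple[int, ...], float] = {}

    def fitness(idx_tuple: tuple[int, ...]) -> float:
        if idx_tuple not in cache:
            Qs = quad.Q[np.ix_(idx_tuple, idx_tuple)]
            bs = quad.b[np.asarray(idx_tuple)]
            force = config.count_reference_in_budget and len(idx_tuple) >= config.max_electrodes
            _, val = _solve_qp(Qs, bs, config, force_zero_reference=force)
            cache[idx_tuple] = val
        return cache[idx_tuple]

    if n <= config.max_electrodes:
        # degenerate: extra electrodes never hurt a concave objective
        sol = solve_currents(list(candidates), subjects, config, _quad=quad)
        return OptimizationResult(
            montage=sol.montage,
            objective=sol.objective,
            generations_run=0,
            history=[sol.objective],
            active_electrodes=sol.montage.active_electrodes(config.current_tolerance),
            seed=config.seed,
        )

    rng = np.random.default_rng(config.seed)
    p_mut = config.mutation_rate if config.mutation_rate is not None else 2.0 / n
    pop_size = config.ga_population

    population = []
    for _ in range(pop_size):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        population.append(mask)

    best_idx: tuple[int, ...] | None = None
    best_val = -np.inf
    history: list[float] = []
    stall = 0
    generations = 0

    for gen in range(config.ga_max_generations):
        generations = gen + 1
        fits = np.empty(pop_size)
        for i, mask in enumerate(population):
            idx_tuple = tuple(np.flatnonzero(mask))
            fits[i] = fitness(idx_tuple)
            labels = subset_labels(idx_tuple)
            if fits[i] > best_val or (
                fits[i] == best_val
                and best_idx is not None
                and labels < subset_labels(best_idx)
            ):
                best_val, best_idx = fits[i], idx_tuple
        prev = history[-1] if history else -np.inf
        history.append(best_val)
        improvement = best_val - prev
        stall = stall + 1 if improvement < config.ga_stall_tolerance else 0
        logger.info(
            "generation=%d best=%.8f stall=%d unique=%d", gen, best_val, stall, len(cache)
        )
        if stall >= config.ga_stall_generations:
            break

        order = np.argsort(fits)[::-1]
        next_pop = [population[order[e]].copy() for e in range(config.elitism)]
        while len(next_pop) < pop_size:
            contenders = rng.integers(0, pop_size, size=config.tournament_size)
            pa = population[contenders[np.argmax(fits[contenders])]]
            contenders = rng.integers(0, pop_size, size=config.tournament_size)
            pb = population[contenders[np.argmax(fits[contenders])]]
            cross = rng.random(n) < config.crossover_prob
            child = np.where(cross, pa, pb)
            child = child ^ (rng.random(n) < p_mut)
            next_pop.append(_repair(child.copy(), k, rng))
        population = next_pop

    assert best_idx is not None
    sol = solve_currents(list(subset_labels(best_idx)), subjects, config, _quad=quad)
    return OptimizationResult(
        montage=sol.montage,
        objective=sol.objective,
        generations_run=generations,
        history=history,
        active_electrodes=sol.montage.active_electrodes(config.current_tolerance),
        seed=config.seed,
    )


def optimize_group_loo(
    cohort: Sequence[SubjectModel],
    config: OptimizationConfig | None = None,
    candidates: Sequence[str] | None = None,
) -> dict[str, LooResult]:
    """Leave-one-out group optimization.

    For every subject, the group objective is optimized over the remaining
    subjects and the resulting montage is evaluated on the held-out subject.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    config = config or OptimizationConfig()
    out: dict[str, LooResult] = {}
    for held in cohort:
        rest = [s for s in cohort if s is not held]
        logger.info("group LOO optimization, held-out subject=%s", held.subject_id)
        result = ga_optimize(rest, candidates=candidates, config=config)
        out[held.subject_id] = LooResult(
            result=result,
            held_out_nerni=nerni(result.montage, held),
            held_out_mean_en=mean_en(result.montage, held),
        )
    return out


def check_constraints(
    montage: Montage, config: OptimizationConfig | None = None, tol: float = 1e-6
) -> None:
    """Raise if a montage violates the safety constraint suite."""
    config = config or OptimizationConfig()
    currents = np.array(list(montage.currents.values()))
    ref = montage.reference_current
    max_cur = max(np.abs(currents).max(initial=0.0), abs(ref))
    if max_cur > config.max_current_per_electrode + tol:
        raise ValueError(f"per-electrode current {max_cur:.6f} mA exceeds the bound")
    anodal = currents[currents > 0].sum() + max(ref, 0.0)
    if anodal > config.max_total_injected + tol:
        raise ValueError(f"total injected current {anodal:.6f} mA exceeds the bound")
    if abs(currents.sum() + ref) > 1e-9:
        raise ValueError("montage is not current-balanced")
    n_active = len(montage.active_electrodes(config.current_tolerance))
    if n_active > config.max_electrodes:
        raise ValueError(f"{n_active} active electrodes exceed the cap")
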