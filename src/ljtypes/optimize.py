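"""Local optimization of LJ parameters in the dimensionless mathematical space,
multi-start replicates, the superspace consistency check, and greedy
type-splitting.

The default method is damped Gauss-Newton on the square-rooted per-compound
terms with central finite-difference Jacobians; plain gradient descent is
available for fidelity experiments. Termination: k-step norm < step
tolerance, objective change below the objective tolerance, or the iteration
cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chem import TypingModel, build_model, parse_model_name
from .core import LJParameterSet, from_math, to_math
from .objective import ObjectiveBreakdown

ObjectiveFn = Callable[[LJParameterSet], ObjectiveBreakdown]


@dataclass
class OptConfig:
    step_tol: float = 0.01  # Euclidean norm of the k-step
    objective_tol: float = 1.0  # unitless objective change between iterations
    max_iter: int = 100
    fd_step: float = 1e-3  # central-difference step in k
    seed: int = 0
    method: str = "gauss-newton"  # or "gradient-descent"

    def __post_init__(self):
        if self.step_tol <= 0 or self.objective_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.method not in ("gauss-newton", "gradient-descent"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class OptResult:
    params: LJParameterSet
    breakdown: ObjectiveBreakdown
    trace: list[tuple[np.ndarray, float]]  # accepted (k, L) per iteration
    termination: str  # step-tol | objective-tol | max-iter
    seed: int

    @property
    def objective(self) -> float:
        return self.breakdown.total


class _CachedObjective:
    """Caches breakdowns by (rounded) k so FD probes are not recomputed."""

    def __init__(self, fn: ObjectiveFn, ref: LJParameterSet):
        self.fn = fn
        self.ref = ref
        self.cache: dict[tuple, ObjectiveBreakdown] = {}
        self.n_evals = 0

    def __call__(self, k: np.ndarray) -> ObjectiveBreakdown:
        key = tuple(np.round(k, 12))
        if key not in self.cache:
            self.n_evals += 1
            bd = self.fn(from_math(k, self.ref, clamp=True))
            if not math.isfinite(bd.total):
                raise FloatingPointError(f"non-finite objective at k={k}")
            self.cache[key] = bd
        return self.cache[key]

    def residuals(self, k: np.ndarray) -> np.ndarray:
        """Data residual rows plus sqrt(w_reg) * k restraint rows.

        Objectives exposing ``residual_vector(params)`` (per-property signed
        residuals over denominators) get exact Gauss-Newton structure; others
        fall back to sqrt of the per-compound terms, which is non-smooth only
        at exactly zero residual.
        """
        bd = self(k)
        if hasattr(self.fn, "residual_vector"):
            key = ("res",) + tuple(np.round(k, 12))
            if key not in self.cache:
                self.cache[key] = self.fn.residual_vector(from_math(k, self.ref, clamp=True))
            data = self.cache[key]
        elif bd.terms:
            data = np.sqrt(np.maximum(list(bd.terms.values()), 0.0))
        else:
            data = np.zeros(0)
        reg = math.sqrt(bd.w_reg) * k
        return np.concatenate([data, reg])


def _fd_jacobian(cached: _CachedObjective, k: np.ndarray, h: float) -> np.ndarray:
    r0 = cached.residuals(k)
    jac = np.empty((r0.size, k.size))
    for j in range(k.size):
        kp, km = k.copy(), k.copy()
        kp[j] += h
        km[j] -= h
        jac[:, j] = (cached.residuals(kp) - cached.residuals(km)) / (2 * h)
    return jac


def optimize(
    model: TypingModel,
    start: LJParameterSet,
    objective_fn: ObjectiveFn,
    cfg: OptConfig | None = None,
) -> OptResult:
    """Locally minimize the objective in k-space from ``start``.

    ``start``'s reference point defines the restraint center; the trace of
    accepted (k, L) pairs is recorded.
    """
    cfg = cfg or OptConfig()
    cached = _CachedObjective(objective_fn, start)
    k = to_math(start)
    current = cached(k)
    trace: list[tuple[np.ndarray, float]] = [(k.copy(), current.total)]
    termination = "max-iter"
    lam = None  # Levenberg-Marquardt damping, initialized from JtJ scale
    nu = 2.0

    for _ in range(cfg.max_iter):
        if cfg.method == "gauss-newton":
            r = cached.residuals(k)
            jac = _fd_jacobian(cached, k, cfg.fd_step)
            jtj = jac.T @ jac
            g = jac.T @ r
            if lam is None:
                lam = 1e-3 * max(np.max(np.diag(jtj)), 1e-12)
            step = None
            for _try in range(40):
                try:
                    cand = np.linalg.solve(jtj + lam * np.eye(k.size), -g)
                except np.linalg.LinAlgError:
                    lam *= nu
                    nu *= 2
                    continue
                actual = current.total - cached(k + cand).total
                predicted = float(cand @ (lam * cand - g))  # model decrease
                if actual > 0:
                    step = cand
                    # gain-ratio schedule (Madsen-Nielsen)
                    rho = actual / max(predicted, 1e-300)
                    lam *= max(1.0 / 3.0, 1.0 - (2.0 * rho - 1.0) ** 3)
                    nu = 2.0
                    break
                lam *= nu
                nu *= 2
            if step is None:
                termination = "step-tol"  # no descent step found: converged
                break
        else:  # gradient descent with backtracking
            grad = np.empty(k.size)
            for j in range(k.size):
                kp, km = k.copy(), k.copy()
                kp[j] += cfg.fd_step
                km[j] -= cfg.fd_step
                grad[j] = (cached(kp).total - cached(km).total) / (2 * cfg.fd_step)
            gnorm = np.linalg.norm(grad)
            if gnorm == 0:
                termination = "step-tol"
                break
            alpha, step = 1.0 / max(gnorm, 1.0), None
            for _try in range(40):
                cand = -alpha * grad
                if cached(k + cand).total < current.total:
                    step = cand
                    break
                alpha /= 2
            if step is None:
                termination = "step-tol"
                break

        new = cached(k + step)
        delta_l = current.total - new.total
        k = k + step
        current = new
        trace.append((k.copy(), current.total))
        if np.linalg.norm(step) < cfg.step_tol:
            termination = "step-tol"
            break
        if delta_l < cfg.objective_tol:
            termination = "objective-tol"
            break

    return OptResult(
        params=from_math(k, start, clamp=True),
        breakdown=current,
        trace=trace,
        termination=termination,
        seed=cfg.seed,
    )


@dataclass
class MultiStartResult:
    replicates: list[OptResult]
    best_index: int

    @property
    def best(self) -> OptResult:
        return self.replicates[self.best_index]

    @property
    def objective_range(self) -> tuple[float, float]:
        objs = [r.objective for r in self.replicates]
        return min(objs), max(objs)


def multi_start(
    model: TypingModel,
    start: LJParameterSet,
    objective_fn: ObjectiveFn,
    cfg: OptConfig | None = None,
    n_replicates: int = 3,
    seeds: Sequence[int] | None = None,
    start_perturbation: float = 0.0,
) -> MultiStartResult:
    """Triplicate (by default) optimizations; the replicate with the lowest
    final training objective is flagged as best, all replicates retained.

    ``start_perturbation`` > 0 jitters the starting k-vector per replicate
    (Gaussian, seeded); with 0 and a deterministic objective the replicates
    are identical.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    cfg = cfg or OptConfig()
    seeds = list(seeds) if seeds is not None else [cfg.seed + i for i in range(n_replicates)]
    results = []
    for seed in seeds:
        rep_cfg = OptConfig(**{**cfg.__dict__, "seed": seed})
        rep_start = start
        if start_perturbation > 0:
            rng = np.random.default_rng(seed)
            k0 = to_math(start) + rng.normal(0, start_perturbation, start.n_params)
            rep_start = from_math(k0, start, clamp=True)
        results.append(optimize(model, rep_start, objective_fn, rep_cfg))
    best = min(range(len(results)), key=lambda i: results[i].objective)
    return MultiStartResult(replicates=results, best_index=best)


def embed_coarse_optimum(
    coarse_params: LJParameterSet,
    fine_ref: LJParameterSet,
    mapping: dict[str, str],
) -> LJParameterSet:
    """Copy each fine type's parameters from its coarse image; a restart point
    in the fine model's superspace."""
    values = {}
    for tid in fine_ref.type_order:
        coarse_tid = mapping[tid]
        src = coarse_params.get(coarse_tid)
        values[tid] = (src.epsilon, src.rmin_half)
    return fine_ref.with_values(values)


@dataclass
class ConsistencyVerdict:
    verdict: str  # "under-optimized" | "pass"
    fine_objective: float
    coarse_objective: float
    restart_point: LJParameterSet


def consistency_check(
    fine: OptResult,
    coarse: OptResult,
    mapping: dict[str, str] | None,
    fine_ref: LJParameterSet | None = None,
) -> ConsistencyVerdict:
    """Superspace reality check: a fully optimized refinement can never score
    worse on the training set than the model it refines.

    ``mapping`` is the fine-type -> coarse-type surjection from
    :func:`ljtypes.chem.refinement_relation`; the returned restart point
    embeds the coarse optimum into the fine model.
    """
    if mapping is None:
        raise ValueError("models are not in a refinement relation")
    ref = fine_ref if fine_ref is not None else fine.params
    restart = embed_coarse_optimum(coarse.params, ref, mapping)
    verdict = "under-optimized" if fine.objective > coarse.objective else "pass"
    return ConsistencyVerdict(
        verdict=verdict,
        fine_objective=fine.objective,
        coarse_objective=coarse.objective,
        restart_point=restart,
    )


@dataclass
class GreedySearchResult:
    accepted: list[str]  # accepted split labels, in order
    final_model: TypingModel
    final_result: OptResult | None
    history: list[dict]  # per-round candidate scores


def greedy_split_search(
    base: TypingModel,
    candidate_splits: dict[str, int],
    fit_fn: Callable[[TypingModel], OptResult],
    score_fn: Callable[[TypingModel, OptResult], float],
    margin: float = 0.0,
) -> GreedySearchResult:
    """Iteratively accept the type split that most improves the score.

    ``candidate_splits`` maps an element letter to the split type count (e.g.
    ``{"H": 2, "O": 3}``); each round re-fits every candidate refinement of
    the current model, accepts the best score improvement beyond ``margin``
    (lower score is better), and stops when none qualifies.
    """
    current_counts = parse_model_name(base.name)
    current = base
    current_fit = fit_fn(current)
    current_score = score_fn(current, current_fit)
    remaining = dict(candidate_splits)
    accepted: list[str] = []
    history: list[dict] = []

    while remaining:
        round_scores: dict[str, float] = {}
        fits: dict[str, tuple[TypingModel, OptResult]] = {}
        for elem, count in remaining.items():
            counts = dict(current_counts)
            counts[elem] = count
            name = "".join(
                f"{e}{c if c > 1 else ''}" for e, c in counts.items()
            )
            candidate = build_model(name)
            fit = fit_fn(candidate)
            round_scores[elem] = score_fn(candidate, fit)
            fits[elem] = (candidate, fit)
        history.append({"current": current.name, "scores": dict(round_scores)})
        best_elem = min(round_scores, key=round_scores.get)
        if current_score - round_scores[best_elem] <= margin:
            break
        accepted.append(f"{best_elem}->{best_elem}{remaining[best_elem]}")
        current_counts[best_elem] = remaining.pop(best_elem)
        current, current_fit = fits[best_elem]
        current_score = round_scores[best_elem]

    return GreedySearchResult(
        accepted=accepted,
        final_model=current,
        final_result=current_fit,
        history=history,
    )


def exhaustive_pair_search(
    base: TypingModel,
    candidate_splits: dict[str, int],
    fit_fn: Callable[[TypingModel], OptResult],
    score_fn: Callable[[TypingModel, OptResult], float],
) -> tuple[TypingModel, float]:
    """Score every pair of splits jointly; complements the greedy search when
    two splits only help in combination."""
    import itertools

    base_counts = parse_model_name(base.name)
    best_model, best_score = base, score_fn(base, fit_fn(base))
    for pair in itertools.combinations(candidate_splits, 2):
        counts = dict(base_counts)
        for elem in pair:
            counts[elem] = candidate_splits[elem]
        name = "".join(f"{e}{c if c > 1 else ''}" for e, c in counts.items())
        candidate = build_model(name)
        score = score_fn(candidate, fit_fn(candidate))
        if score < best_score:
            best_model, best_score = candidate, score
    return best_model, best_score
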