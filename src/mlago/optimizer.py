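"""Constrained global optimization of kinetic parameters with a real-coded GA.

Two estimation modes are provided over the same search engine:

* conventional — minimize the badness-of-fit BOF(p) subject only to box
  bounds; prone to unrealistic, non-unique estimates.
* constrained (machine-learning-aided) — minimize the log10-scale RMSE
  between the searched K_m's and reference values (typically
  machine-learning predictions) subject to BOF(p) <= AE, the allowable
  error (default 0.02), plus the box bounds.

The engine is a real-coded genetic algorithm of the REXstar/JGG family:
each generation a random parent subset is replaced by the best children
of an ensemble crossover centered on the parents' centroid and steered
toward the better parents. Constraints are handled by stochastic ranking
of (objective, violation) pairs. Because K_m spans ~8 orders of
magnitude, the search runs in log10-transformed coordinates; the default
bounds 1e-5..1e3 mM become the uniform box [-5, 3].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from mlago.kinetics import BOF_SENTINEL, ExperimentalDataset, KineticModel, evaluate_bof
from mlago.predictor import rmse

logger = logging.getLogger(__name__)

DEFAULT_AE = 0.02
DEFAULT_LOWER_MM = 1e-5
DEFAULT_UPPER_MM = 1e3


@dataclass
class SearchSpace:
    """Box bounds in model units (mM for K_m's); search runs in log10 coordinates."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if np.any(self.lower <= 0):
            raise ValueError("lower bounds must be positive (log10 search coordinates)")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be below upper bounds")

    @classmethod
    def default(cls, n_dim: int, lower: float = DEFAULT_LOWER_MM, upper: float = DEFAULT_UPPER_MM):
        return cls(np.full(n_dim, lower), np.full(n_dim, upper))

    @property
    def n_dim(self) -> int:
        return len(self.lower)

    @property
    def log_lower(self) -> np.ndarray:
        return np.log10(self.lower)

    @property
    def log_upper(self) -> np.ndarray:
        return np.log10(self.upper)


@dataclass
class RcgaSettings:
    """REXstar/JGG hyperparameters (all overridable).

    Defaults follow common usage of this algorithm family: population
    max(50, 10 d), parents per generation d+1, children 5 (d+1), step
    upper bound t = 6 for the steering term, stochastic-ranking
    comparison probability Pf = 0.45. ``feasibility_first=True`` switches
    to a strict feasible-before-infeasible ranking.
    """

    population_size: int | None = None
    n_parents: int | None = None
    n_children: int | None = None
    t_step: float = 6.0
    pf: float = 0.45
    feasibility_first: bool = False
    stagnation_generations: int = 300
    stagnation_tol: float = 1e-6

    def resolved(self, n_dim: int) -> "RcgaSettings":
        pop = self.population_size or max(50, 10 * n_dim)
        npar = self.n_parents or (n_dim + 1)
        nchi = self.n_children or 5 * (n_dim + 1)
        return RcgaSettings(pop, npar, nchi, self.t_step, self.pf,
                            self.feasibility_first, self.stagnation_generations, self.stagnation_tol)


@dataclass
class MlagoProblem:
    """A constrained K_m estimation problem.

    ``reference`` is the log10-scale reference vector over the searched
    parameters included in the RMSE (``rmse_mask``). Co-searched
    k_cat/V_max parameters carry ``rmse_mask=False``: they are optimized
    but excluded from the objective.
    """

    model: KineticModel
    data: ExperimentalDataset
    searched_names: list[str]
    reference: np.ndarray  # log10, length = rmse_mask.sum()
    p_fixed: np.ndarray  # full parameter vector; searched entries overwritten
    rmse_mask: np.ndarray | None = None
    ae: float = DEFAULT_AE
    space: SearchSpace | None = None
    budget: int = 100_000
    seed: int = 0
    settings: RcgaSettings = field(default_factory=RcgaSettings)

    def __post_init__(self):
        n = len(self.searched_names)
        if self.rmse_mask is None:
            self.rmse_mask = np.ones(n, dtype=bool)
        self.rmse_mask = np.asarray(self.rmse_mask, dtype=bool)
        self.reference = np.asarray(self.reference, dtype=float)
        if not self.rmse_mask.any():
            raise ValueError("rmse_mask needs at least one True entry")
        if len(self.reference) != int(self.rmse_mask.sum()):
            raise ValueError("reference length must match rmse_mask True count")
        if not np.isfinite(self.reference).all():
            raise ValueError("reference must be finite")
        if self.ae <= 0:
            raise ValueError("allowable error must be positive")
        if self.space is None:
            self.space = SearchSpace.default(n)


@dataclass
class EstimationResult:
    best_p: np.ndarray  # model units
    best_objective: float
    best_bof: float
    best_rmse_to_reference: float | None
    feasible: bool
    trace: list[tuple[int, float, float]]  # (evaluations, best feasible objective, best violation)
    n_evaluations: int
    seed: int
    settings: dict


# ---------------------------------------------------------------------------
# ranking


def stochastic_ranking(obj: np.ndarray, viol: np.ndarray, pf: float, rng: np.random.Generator) -> np.ndarray:
    """Order indices best-first by stochastic ranking of (objective, violation).

    A bubble-sort sweep compares adjacent individuals by objective with
    probability ``pf`` (or when both are feasible), otherwise by
    violation; sweeps stop when no swap occurs.
    """
    n = len(obj)
    idx = np.arange(n)
    for _ in range(n):
        swapped = False
        u = rng.random(n - 1)
        for i in range(n - 1):
            a, b = idx[i], idx[i + 1]
            both_feasible = viol[a] <= 0 and viol[b] <= 0
            if both_feasible or u[i] < pf:
                worse = obj[a] > obj[b]
            else:
                worse = viol[a] > viol[b]
            if worse:
                idx[i], idx[i + 1] = b, a
                swapped = True
        if not swapped:
            break
    return idx


def feasibility_first_ranking(obj: np.ndarray, viol: np.ndarray) -> np.ndarray:
    """Deb-style ranking: feasible by objective first, then infeasible by violation."""
    keys = np.where(viol <= 0, obj, np.inf)
    return np.lexsort((obj, viol > 0, np.where(viol > 0, viol, 0.0), keys))


# ---------------------------------------------------------------------------
# core engine


def rcga_run(
    objective: Callable[[np.ndarray], float],
    constraint_violation: Callable[[np.ndarray], float] | None,
    space: SearchSpace,
    budget: int,
    seed: int,
    settings: RcgaSettings | None = None,
) -> EstimationResult:
    """REXstar/JGG search in log10 coordinates.

    ``objective`` and ``constraint_violation`` receive the parameter
    vector in model units (after 10**q back-transform). With no
    constraint the run is a plain bound-constrained minimization. Among
    all evaluated points, the returned best is the feasible point of
    minimal objective, or the minimal-violation point if none was
    feasible; the trace's best objective is non-increasing among feasible
    iterates by construction. Identical seeds give identical runs.
    """
    st = (settings or RcgaSettings()).resolved(space.n_dim)
    d = space.n_dim
    lo, hi = space.log_lower, space.log_upper
    if budget < st.population_size:
        raise ValueError(
            f"budget {budget} smaller than one generation (population {st.population_size})"
        )
    rng = np.random.default_rng(seed)
    violation = constraint_violation or (lambda p: 0.0)

    def evaluate(q: np.ndarray) -> tuple[float, float]:
        p = 10.0**q
        return float(objective(p)), float(violation(p))

    pop = rng.uniform(lo, hi, size=(st.population_size, d))
    obj = np.empty(st.population_size)
    viol = np.empty(st.population_size)
    for i in range(st.population_size):
        obj[i], viol[i] = evaluate(pop[i])
    n_eval = st.population_size

    best_feas_q, best_feas_obj = None, np.inf
    best_viol_q, best_viol = None, np.inf
    best_viol_obj = np.inf

    def update_best(q, o, v):
        nonlocal best_feas_q, best_feas_obj, best_viol_q, best_viol, best_viol_obj
        if v <= 0 and o < best_feas_obj:
            best_feas_q, best_feas_obj = q.copy(), o
        if v < best_viol or (v == best_viol and o < best_viol_obj):
            best_viol_q, best_viol, best_viol_obj = q.copy(), v, o

    for i in range(st.population_size):
        update_best(pop[i], obj[i], viol[i])

    trace: list[tuple[int, float, float]] = [(n_eval, best_feas_obj, best_viol)]
    stagnant = 0
    last_improvement_obj = best_feas_obj
    last_improvement_viol = best_viol

    m = min(st.n_parents, st.population_size)
    while n_eval < budget:
        parents_idx = rng.choice(st.population_size, size=m, replace=False)
        parents = pop[parents_idx]
        centroid = parents.mean(axis=0)
        # steering target: centroid of the better half of the parents
        if st.feasibility_first:
            order = feasibility_first_ranking(obj[parents_idx], viol[parents_idx])
        else:
            order = stochastic_ranking(obj[parents_idx], viol[parents_idx], st.pf, rng)
        n_best = max(1, m // 2)
        centroid_best = parents[order[:n_best]].mean(axis=0)

        n_children = min(st.n_children, budget - n_eval)
        if n_children < 1:
            break
        xi_t = rng.uniform(0.0, st.t_step, size=(n_children, 1))
        u = rng.normal(0.0, np.sqrt(1.0 / m), size=(n_children, m))
        children = centroid + xi_t * (centroid_best - centroid) + u @ (parents - centroid)
        np.clip(children, lo, hi, out=children)

        c_obj = np.empty(n_children)
        c_viol = np.empty(n_children)
        for i in range(n_children):
            c_obj[i], c_viol[i] = evaluate(children[i])
            update_best(children[i], c_obj[i], c_viol[i])
        n_eval += n_children

        # JGG replacement: best m children take the parents' slots
        if st.feasibility_first:
            c_order = feasibility_first_ranking(c_obj, c_viol)
        else:
            c_order = stochastic_ranking(c_obj, c_viol, st.pf, rng)
        take = c_order[: min(m, n_children)]
        slots = parents_idx[: len(take)]
        pop[slots] = children[take]
        obj[slots] = c_obj[take]
        viol[slots] = c_viol[take]

        trace.append((n_eval, best_feas_obj, best_viol))
        improved = best_feas_obj < last_improvement_obj - st.stagnation_tol or \
            best_viol < last_improvement_viol - st.stagnation_tol
        if improved:
            last_improvement_obj = best_feas_obj
            last_improvement_viol = best_viol
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= st.stagnation_generations:
                logger.debug("rcga_run: stagnation stop after %d evaluations", n_eval)
                break

    feasible = best_feas_q is not None
    q_best = best_feas_q if feasible else best_viol_q
    o_best = best_feas_obj if feasible else best_viol_obj
    return EstimationResult(
        best_p=10.0**q_best,
        best_objective=float(o_best),
        best_bof=np.nan,  # filled by the callers that know the BOF semantics
        best_rmse_to_reference=None,
        feasible=feasible,
        trace=trace,
        n_evaluations=n_eval,
        seed=seed,
        settings={
            "population_size": st.population_size, "n_parents": st.n_parents,
            "n_children": st.n_children, "t_step": st.t_step, "pf": st.pf,
            "feasibility_first": st.feasibility_first,
            "stagnation_generations": st.stagnation_generations,
            "stagnation_tol": st.stagnation_tol, "budget": budget,
        },
    )


# ---------------------------------------------------------------------------
# estimation modes


def _substitute(p_fixed: np.ndarray, idx: np.ndarray, p_sub: np.ndarray) -> np.ndarray:
    p = p_fixed.copy()
    p[idx] = p_sub
    return p


def conventional_estimate(
    model: KineticModel,
    data: ExperimentalDataset,
    searched_names: Sequence[str],
    p_fixed: np.ndarray,
    space: SearchSpace | None = None,
    budget: int = 100_000,
    seed: int = 0,
    settings: RcgaSettings | None = None,
    reference: np.ndarray | None = None,
    ae: float | None = None,
) -> EstimationResult:
    """Unconstrained fit: minimize BOF over the searched parameters.

    ``p_fixed`` supplies values for the parameters that are not searched.
    ``reference`` (log10, optional) is used only to report the diagnostic
    RMSE of the result; ``ae`` (optional) only to report the feasibility
    flag on the same footing as the constrained mode.
    """
    searched_names = list(searched_names)
    idx = model.parameter_index(searched_names)
    space = space or SearchSpace.default(len(idx))

    def objective(p_sub):
        return evaluate_bof(model, _substitute(p_fixed, idx, p_sub), data)

    res = rcga_run(objective, None, space, budget, seed, settings)
    res.best_bof = res.best_objective
    if reference is not None:
        res.best_rmse_to_reference = rmse(np.log10(res.best_p), np.asarray(reference, dtype=float))
    res.feasible = bool(res.best_bof <= ae) if ae is not None else res.feasible
    res.settings.update({"mode": "conventional", "searched": searched_names})
    return res


def mlago_estimate(problem: MlagoProblem) -> EstimationResult:
    """Constrained fit: minimize RMSE to the reference subject to BOF <= AE.

    The objective is the log10-scale RMSE over the ``rmse_mask`` subset of
    the searched parameters; the constraint violation is
    max(0, BOF − AE). The result is the feasible point of minimal
    objective if any was visited, else the minimal-violation point with
    ``feasible=False``.
    """
    model, data = problem.model, problem.data
    idx = model.parameter_index(problem.searched_names)
    mask = problem.rmse_mask
    ref = problem.reference
    _bof_cache: dict[bytes, float] = {}

    def bof_of(p_sub: np.ndarray) -> float:
        key = p_sub.tobytes()
        val = _bof_cache.get(key)
        if val is None:
            val = evaluate_bof(model, _substitute(problem.p_fixed, idx, p_sub), data)
            if len(_bof_cache) > 4096:
                _bof_cache.clear()
            _bof_cache[key] = val
        return val

    def objective(p_sub):
        return rmse(np.log10(p_sub[mask]), ref)

    def violation(p_sub):
        b = bof_of(p_sub)
        return max(0.0, min(b, BOF_SENTINEL) - problem.ae)

    res = rcga_run(objective, violation, problem.space, problem.budget, problem.seed, problem.settings)
    res.best_bof = bof_of(res.best_p)
    res.best_rmse_to_reference = res.best_objective
    res.feasible = bool(res.best_bof <= problem.ae)
    res.settings.update({"mode": "mlago", "ae": problem.ae, "searched": list(problem.searched_names)})
    return res


# ---------------------------------------------------------------------------
# repeated trials


@dataclass
class TrialSummary:
    results: list[EstimationResult]
    feasibility_rate: float
    rmse_mean: float | None
    rmse_sd: float | None
    per_parameter_sd: np.ndarray  # SD of log10 estimates across trials
    bof_mean: float
    bof_sd: float


def repeated_trials(
    estimate: Callable[[int], EstimationResult],
    n_trials: int = 10,
    base_seed: int = 0,
) -> TrialSummary:
    """Run ``estimate(seed)`` for seeds base_seed..base_seed+n_trials−1.

    The dispersion summary mirrors a repeated-estimation experiment:
    feasibility rate, mean ± SD of the RMSE to the reference, and the
    per-parameter standard deviation of the log10 estimates across
    trials (small SD = unique estimation).
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials for a dispersion summary")
    results = [estimate(base_seed + t) for t in range(n_trials)]
    q = np.array([np.log10(r.best_p) for r in results])
    rmses = [r.best_rmse_to_reference for r in results]
    have_rmse = all(r is not None for r in rmses)
    bofs = np.array([r.best_bof for r in results])
    return TrialSummary(
        results=results,
        feasibility_rate=float(np.mean([r.feasible for r in results])),
        rmse_mean=float(np.mean(rmses)) if have_rmse else None,
        rmse_sd=float(np.std(rmses, ddof=1)) if have_rmse else None,
        per_parameter_sd=q.std(axis=0, ddof=1),
        bof_mean=float(bofs.mean()),
        bof_sd=float(bofs.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# result persistence


def save_result(result: EstimationResult, directory: str | Path, name: str = "estimation") -> None:
    """Write a JSON manifest plus a delimited trace table for convergence curves."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "best_p": [float(v) for v in result.best_p],
        "best_objective": result.best_objective,
        "best_bof": result.best_bof,
        "best_rmse_to_reference": result.best_rmse_to_reference,
        "feasible": result.feasible,
        "n_evaluations": result.n_evaluations,
        "seed": result.seed,
        "settings": result.settings,
    }
    (d / f"{name}.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    lines = ["evaluations\tbest_feasible_objective\tbest_violation"]
    for ev, ob, vi in result.trace:
        lines.append(f"{ev}\t{ob}\t{vi}")
    (d / f"{name}_trace.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
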