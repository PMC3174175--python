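"""Reverse engineering of transition matrices from growth objectives.

The latent variables of the model are the transition probabilities on the
ETG edges.  Each objective ties the Perron eigenvalue of one elementary
cost matrix (a protein's per-transition growth factor, possibly on a
condition-filtered phase of the graph) to an observed value or interval.
The score of a candidate matrix is the Euclidean distance between the
achieved eigenvalues and the objectives; eigenvalues have no closed form
in the probabilities, so the minimization is an ad-hoc seeded local search
on the row simplices.

Interval objectives define a *solution set* of valid matrices, explored as
in the polyhedral picture: a source point near the middle of every
interval, boundary points found by bisection along random directions, a
Monte-Carlo volume estimate, and interior samples by convex combination.
Per-transition sensitivities (percent score change under a 1% probability
perturbation) rank the biological interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EtmcError, MinimalityError
from .etg import (
    EventTransitionGraph,
    TransitionMatrix,
    apply_condition,
    restrict_renormalize,
    uniform_chain,
)
from .impact import CostMatrix, ImpactMatrix
from .accumulation import dominant_eigen
from .timeseries import GrowthObjective

__all__ = [
    "Objective",
    "ObjectiveSet",
    "SolutionPoint",
    "SolutionSet",
    "SensitivityReport",
    "score",
    "achieved_lambdas",
    "achieved_values",
    "local_search",
    "source_point",
    "boundary_point",
    "sample_solution_set",
    "estimate_volume",
    "sensitivity",
    "predict_distribution",
]


@dataclass
class Objective:
    """One growth objective paired with its impact matrix and phase.

    ``a_target`` optionally constrains the initial-condition constant of
    the accumulation law (the intercept of the fitted exponential, equal
    to the constant ``a`` of the asymptotic mean ``a * lambda**n`` under a
    uniform initial event distribution).  When set, the exact-search score
    fits it alongside the growth rate; interval feasibility always applies
    to the growth rate only.
    """

    growth: GrowthObjective
    impact: ImpactMatrix
    condition: str | None = None
    a_target: float | None = None

    @property
    def target(self) -> float:
        return self.growth.lambda_obj

    @property
    def interval(self) -> tuple[float, float]:
        if self.growth.interval is not None:
            return self.growth.interval
        return (self.growth.lambda_obj, self.growth.lambda_obj)


@dataclass
class ObjectiveSet:
    """Objectives sharing one ETG (phases are condition filters on it)."""

    etg: EventTransitionGraph
    objectives: list[Objective]

    def __post_init__(self) -> None:
        if not self.objectives:
            raise EtmcError("objective set is empty")
        for obj in self.objectives:
            if obj.impact.etg.event_names != self.etg.event_names:
                raise EtmcError("impact matrix indexes different events than the set's ETG")

    @property
    def targets(self) -> np.ndarray:
        """Growth-rate targets followed by any initial-constant targets."""
        lams = [o.target for o in self.objectives]
        consts = [o.a_target for o in self.objectives if o.a_target is not None]
        return np.array(lams + consts)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return [o.interval for o in self.objectives]

    @property
    def has_a_targets(self) -> bool:
        return any(o.a_target is not None for o in self.objectives)


@dataclass
class SolutionPoint:
    """A transition matrix with its achieved eigenvalues and score."""

    matrix: TransitionMatrix
    lambdas: np.ndarray
    score: float
    converged: bool = True
    evaluations: int = 0

    @property
    def params(self) -> np.ndarray:
        return _pack(self.matrix)


@dataclass
class SolutionSet:
    """Source + boundary approximation of the feasible polytope."""

    etg: EventTransitionGraph
    objectives: ObjectiveSet
    source: SolutionPoint
    boundary: list[SolutionPoint] = field(default_factory=list)
    directions: list[np.ndarray] = field(default_factory=list)
    volume: float | None = None
    volume_se: float | None = None

    @property
    def points(self) -> list[SolutionPoint]:
        return [self.source, *self.boundary]


@dataclass
class SensitivityReport:
    """Per-edge sensitivity of the score to a 1% probability change."""

    edges: list[tuple[str, str]]
    sensitivities: np.ndarray
    normalized: bool  # False when ranked by raw |dF| at a near-zero optimum

    def ranking(self) -> list[tuple[tuple[str, str], float]]:
        order = np.argsort(-self.sensitivities, kind="stable")
        return [(self.edges[k], float(self.sensitivities[k])) for k in order]


# ---------------------------------------------------------------------------
# parameter packing: one free parameter per supported edge, rows renormalized


def _edge_list(etg: EventTransitionGraph) -> list[tuple[int, int]]:
    return list(etg.edges)


def _pack(P: TransitionMatrix) -> np.ndarray:
    return np.array([P.values[i, j] for (i, j) in P.etg.edges])


def _unpack(etg: EventTransitionGraph, params: np.ndarray) -> TransitionMatrix:
    n = etg.n_events
    V = np.zeros((n, n))
    for k, (i, j) in enumerate(etg.edges):
        V[i, j] = params[k]
    rows = V.sum(axis=1)
    if np.any(rows <= 0):
        raise EtmcError("row without mass in parameter vector")
    V /= rows[:, None]
    return TransitionMatrix(etg, V)


def _row_groups(etg: EventTransitionGraph) -> list[np.ndarray]:
    groups: dict[int, list[int]] = {}
    for k, (i, _) in enumerate(etg.edges):
        groups.setdefault(i, []).append(k)
    return [np.array(v) for _, v in sorted(groups.items())]


def _project_row_sum_zero(etg: EventTransitionGraph, direction: np.ndarray) -> np.ndarray:
    """Project a direction onto the tangent space of the row simplices."""
    d = direction.astype(float).copy()
    for g in _row_groups(etg):
        d[g] -= d[g].mean()
    return d


# ---------------------------------------------------------------------------
# scoring


def achieved_lambdas(P: TransitionMatrix, objectives: ObjectiveSet) -> np.ndarray:
    """Dominant eigenvalue of each objective's elementary cost matrix.

    A phase objective evaluates on its condition-filtered subgraph, with
    the probabilities of the full matrix restricted and renormalized there
    (the same chain drives every phase; dropped edges are neglected).
    """
    return _achieved(P, objectives, with_constants=False)


def achieved_values(P: TransitionMatrix, objectives: ObjectiveSet) -> np.ndarray:
    """Achieved growth rates, followed by achieved initial constants for
    every objective carrying an ``a_target`` (uniform initial events)."""
    return _achieved(P, objectives, with_constants=True)


def _achieved(
    P: TransitionMatrix, objectives: ObjectiveSet, with_constants: bool
) -> np.ndarray:
    lams = np.empty(len(objectives.objectives))
    consts: list[float] = []
    cache: dict[str | None, TransitionMatrix] = {}
    for k, obj in enumerate(objectives.objectives):
        cond = obj.condition
        if cond not in cache:
            if cond is None:
                cache[cond] = P
            else:
                sub = apply_condition(objectives.etg, cond)
                cache[cond] = restrict_renormalize(P, sub)
        Pc = cache[cond]
        C = CostMatrix(etg=Pc.etg, values=Pc.values * obj.impact.values, protein=obj.impact.protein)
        lam, left, right = dominant_eigen(C)
        lams[k] = lam
        if with_constants and obj.a_target is not None:
            n = Pc.values.shape[0]
            v0 = np.full(n, 1.0 / n)
            consts.append(float((v0 @ right) * (left @ np.ones(n))))
    if with_constants and consts:
        return np.concatenate([lams, consts])
    return lams


def score(P: TransitionMatrix, objectives: ObjectiveSet) -> float:
    """Euclidean distance between achieved and objective values
    (growth rates, plus initial constants where targeted)."""
    vals = achieved_values(P, objectives)
    return float(np.linalg.norm(vals - objectives.targets))


def _score_params(
    etg: EventTransitionGraph, params: np.ndarray, objectives: ObjectiveSet,
    targets: np.ndarray,
) -> tuple[float, np.ndarray, TransitionMatrix]:
    P = _unpack(etg, params)
    vals = achieved_values(P, objectives)
    return float(np.linalg.norm(vals - targets)), vals, P


# ---------------------------------------------------------------------------
# local search


@dataclass
class SearchOptions:
    tolerance: float = 1e-6
    budget: int = 20_000
    n_starts: int = 8
    initial_step: float = 0.5
    min_step: float = 1e-10
    fail_streak: int = 30  # halve the step after this many rejected moves


def local_search(
    etg: EventTransitionGraph,
    objectives: ObjectiveSet,
    seed: int = 0,
    options: SearchOptions | None = None,
    targets: np.ndarray | None = None,
) -> SolutionPoint:
    """Seeded multi-start stochastic descent on the row simplices.

    Each move multiplies one random edge probability by ``exp(+/- step)``
    and renormalizes its row; improving moves are kept, the step adapts
    (grows on success, halves after a failure streak).  The first start is
    the uniform chain, further starts draw Dirichlet rows.  Returns the
    best point found, flagged ``converged`` when the score beats the
    tolerance; infeasibility is a flag, never an exception.
    """
    opts = options or SearchOptions()
    rng = np.random.default_rng(seed)
    if targets is None:
        targets = objectives.targets
    n_edges = len(etg.edges)
    groups = _row_groups(etg)
    best: tuple[float, np.ndarray] | None = None
    evals = 0

    def evaluate(params: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        s, _, _ = _score_params(etg, params, objectives, targets)
        return s

    def descend(params: np.ndarray, cur: float, budget: int) -> tuple[np.ndarray, float]:
        step = opts.initial_step
        fails = 0
        used = 0
        while used < budget and cur > opts.tolerance:
            if step <= opts.min_step:
                step = opts.initial_step  # re-kick out of a flat region
            k = int(rng.integers(n_edges))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            cand = params.copy()
            cand[k] *= float(np.exp(sign * step))
            try:
                s = evaluate(cand)
            except (MinimalityError, EtmcError):
                s = np.inf
            used += 1
            if s < cur:
                params, cur = cand, s
                fails = 0
                step = min(step * 1.3, 2.0)
            else:
                fails += 1
                if fails >= opts.fail_streak:
                    step *= 0.5
                    fails = 0
        return params, cur

    # exploration: multi-start over half the budget ...
    start_budget = opts.budget // (2 * opts.n_starts)
    for start in range(opts.n_starts):
        if start == 0:
            params = _pack(uniform_chain(etg))
        else:
            params = np.empty(n_edges)
            for g in groups:
                params[g] = rng.dirichlet(np.ones(len(g)))
        try:
            cur = evaluate(params)
        except MinimalityError:
            continue
        params, cur = descend(params, cur, start_budget)
        if best is None or cur < best[0]:
            best = (cur, params.copy())
        if best[0] <= opts.tolerance:
            break
    if best is None:
        raise MinimalityError("no start produced an evaluable chain")
    # ... then polish the best point with the remainder: a derivative-free
    # direction-set (Powell) refinement in log-parameter space, which
    # handles the narrow curved valleys of the implicit eigenvalue score
    # far better than single-coordinate moves
    if best[0] > opts.tolerance and evals < opts.budget:
        best, polish_evals = _powell_polish(
            etg, objectives, targets, best, opts, opts.budget - evals
        )
        evals += polish_evals
    s, params = best
    P = _unpack(etg, params)
    lams = achieved_lambdas(P, objectives)
    return SolutionPoint(
        matrix=P, lambdas=lams, score=s, converged=bool(s <= opts.tolerance),
        evaluations=evals,
    )


class _Converged(Exception):
    pass


def _powell_polish(
    etg: EventTransitionGraph,
    objectives: ObjectiveSet,
    targets: np.ndarray,
    best: tuple[float, np.ndarray],
    opts: SearchOptions,
    budget: int,
) -> tuple[tuple[float, np.ndarray], int]:
    from scipy import optimize

    tracker = {"score": best[0], "x": np.log(np.maximum(best[1], 1e-12)), "nfev": 0}

    def f(x: np.ndarray) -> float:
        tracker["nfev"] += 1
        try:
            s, _, _ = _score_params(etg, np.exp(x), objectives, targets)
        except (MinimalityError, EtmcError):
            return 1e6
        if s < tracker["score"]:
            tracker["score"], tracker["x"] = s, x.copy()
        if s <= opts.tolerance:
            raise _Converged
        return s

    try:
        optimize.minimize(
            f, tracker["x"].copy(), method="Powell",
            options={"maxfev": budget, "xtol": 1e-12, "ftol": 1e-14},
        )
    except _Converged:
        pass
    params = np.exp(tracker["x"])
    return (float(tracker["score"]), params), int(tracker["nfev"])


def source_point(
    etg: EventTransitionGraph,
    objectives: ObjectiveSet,
    seed: int = 0,
    options: SearchOptions | None = None,
) -> SolutionPoint:
    """Local search towards the midpoint of every objective interval.

    The returned point is flagged converged only when it lies strictly
    inside all intervals.
    """
    mids = [(lo + hi) / 2 for lo, hi in objectives.intervals]
    consts = [o.a_target for o in objectives.objectives if o.a_target is not None]
    pt = local_search(etg, objectives, seed=seed, options=options,
                      targets=np.array(mids + consts))
    inside = _feasible(pt.lambdas, objectives.intervals, slack=0.0)
    pt.converged = bool(pt.converged and inside)
    return pt


# ---------------------------------------------------------------------------
# solution-set geometry


def _feasible(
    lams: np.ndarray, intervals: list[tuple[float, float]], slack: float = 1e-9
) -> bool:
    return all(lo - slack <= lam <= hi + slack for lam, (lo, hi) in zip(lams, intervals))


def _point_feasible(
    etg: EventTransitionGraph, params: np.ndarray, objectives: ObjectiveSet,
    slack: float = 1e-9,
) -> tuple[bool, np.ndarray | None]:
    if np.any(params < 0):
        return False, None
    for g in _row_groups(etg):
        if params[g].sum() <= 0:
            return False, None
    try:
        P = _unpack(etg, params)
        lams = achieved_lambdas(P, objectives)
    except (MinimalityError, EtmcError):
        return False, None
    return _feasible(lams, objectives.intervals, slack=slack), lams


def boundary_point(
    source: SolutionPoint,
    direction: np.ndarray,
    objectives: ObjectiveSet,
    tolerance: float = 1e-6,
) -> SolutionPoint:
    """Bisect along a ray from the source until a constraint goes active.

    The direction is projected onto the row-sum-zero tangent space (so the
    ray stays on the simplex affine hull); feasibility means probabilities
    >= 0 and every achieved eigenvalue inside its interval.  The returned
    point is the last feasible one, within ``tolerance`` of the boundary.
    """
    etg = source.matrix.etg
    d = _project_row_sum_zero(etg, np.asarray(direction, dtype=float))
    norm = float(np.linalg.norm(d))
    if norm < 1e-14:
        raise EtmcError("direction is numerically zero after projection")
    d /= norm
    p0 = source.params
    # bracket: grow t until infeasible (any probability < 0 caps t anyway)
    t_lo, t_hi = 0.0, 0.25
    ok, lams_lo = _point_feasible(etg, p0, objectives)
    if not ok:
        raise EtmcError("source point is not feasible")
    for _ in range(60):
        ok, _ = _point_feasible(etg, p0 + t_hi * d, objectives)
        if not ok:
            break
        t_lo = t_hi
        t_hi *= 2.0
    else:
        raise EtmcError("could not bracket the boundary (unbounded direction?)")
    while t_hi - t_lo > tolerance:
        mid = 0.5 * (t_lo + t_hi)
        ok, lams = _point_feasible(etg, p0 + mid * d, objectives)
        if ok:
            t_lo, lams_lo = mid, lams
        else:
            t_hi = mid
    params = p0 + t_lo * d
    params = np.clip(params, 0.0, None)
    P = _unpack(etg, params)
    lams = achieved_lambdas(P, objectives)
    return SolutionPoint(matrix=P, lambdas=lams, score=score(P, objectives), converged=True)


def sample_solution_set(
    etg: EventTransitionGraph,
    objectives: ObjectiveSet,
    n_directions: int = 16,
    seed: int = 0,
    options: SearchOptions | None = None,
    source: SolutionPoint | None = None,
) -> SolutionSet:
    """Source point plus boundary points along random unit directions."""
    if n_directions < 1:
        raise EtmcError("n_directions must be >= 1")
    rng = np.random.default_rng(seed)
    src = source if source is not None else source_point(etg, objectives, seed=seed, options=options)
    sol = SolutionSet(etg=etg, objectives=objectives, source=src)
    n_edges = len(etg.edges)
    widths = np.array([hi - lo for lo, hi in objectives.intervals])
    for _ in range(n_directions):
        direction = rng.standard_normal(n_edges)
        if np.all(widths == 0):
            # degenerate intervals: the set is (generically) the single source point
            sol.boundary.append(src)
            sol.directions.append(direction)
            continue
        try:
            bp = boundary_point(src, direction, objectives)
        except EtmcError:
            continue
        sol.boundary.append(bp)
        sol.directions.append(direction)
    return sol


def _free_coords(etg: EventTransitionGraph, params: np.ndarray) -> np.ndarray:
    """Drop each row's last edge (determined by the row-sum constraint)."""
    keep = []
    for g in _row_groups(etg):
        keep.extend(g[:-1].tolist())
    return params[np.array(keep, dtype=int)] if keep else np.empty(0)


def _from_free_coords(etg: EventTransitionGraph, free: np.ndarray) -> np.ndarray | None:
    params = np.empty(len(etg.edges))
    pos = 0
    for g in _row_groups(etg):
        k = len(g) - 1
        vals = free[pos : pos + k]
        pos += k
        last = 1.0 - vals.sum()
        if np.any(vals < 0) or last < 0:
            return None
        params[g[:-1]] = vals
        params[g[-1]] = last
    return params


def estimate_volume(
    solset: SolutionSet, mc_samples: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo volume of the feasible set in free-parameter coordinates.

    Samples uniformly in the bounding box of the stored points' free
    coordinates; feasibility is re-checked by direct eigenvalue
    evaluation.  Returns ``(volume, standard_error)``.
    """
    etg = solset.etg
    pts = np.array([_free_coords(etg, p.params) for p in solset.points])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    extent = hi - lo
    active = extent > 1e-12
    if not np.any(active):
        return 0.0, 0.0
    box_vol = float(np.prod(extent[active]))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(mc_samples):
        free = lo.copy()
        free[active] = lo[active] + extent[active] * rng.random(int(active.sum()))
        params = _from_free_coords(etg, free)
        if params is None:
            continue
        ok, _ = _point_feasible(etg, params, solset.objectives)
        if ok:
            hits += 1
    p = hits / mc_samples
    vol = box_vol * p
    se = box_vol * float(np.sqrt(p * (1 - p) / mc_samples))
    return vol, se


# ---------------------------------------------------------------------------
# sensitivity and prediction


SENS_FLOOR = 1e-9


def sensitivity(point: SolutionPoint, objectives: ObjectiveSet) -> SensitivityReport:
    """Percent score change when each edge probability is raised by 1%.

    Each supported edge's probability is multiplied by 1.01, its row
    renormalized, and the score recomputed; sensitivity is
    ``100 * |F_new - F_ref| / F_ref``.  At a (near-)exact optimum the
    reference score vanishes, so raw ``|dF|`` values are ranked instead
    (flagged by ``normalized=False``).
    """
    etg = point.matrix.etg
    f_ref = point.score
    normalized = f_ref > SENS_FLOOR
    sens = np.zeros(len(etg.edges))
    for k in range(len(etg.edges)):
        params = point.params
        if params[k] == 0.0:
            continue  # a zero edge is unchanged by a multiplicative nudge
        cand = params.copy()
        cand[k] *= 1.01
        try:
            s, _, _ = _score_params(etg, cand, objectives, objectives.targets)
        except (MinimalityError, EtmcError):
            continue
        df = abs(s - f_ref)
        sens[k] = 100.0 * df / f_ref if normalized else df
    names = [(etg.events[i].name, etg.events[j].name) for (i, j) in etg.edges]
    return SensitivityReport(edges=names, sensitivities=sens, normalized=normalized)


def predict_distribution(
    solset: SolutionSet,
    impact: ImpactMatrix,
    n_samples: int = 1000,
    seed: int = 0,
    condition: str | None = None,
) -> tuple[np.ndarray, float]:
    """Growth-rate distribution of a protein over the solution set.

    Interior candidates are convex combinations (Dirichlet weights) of the
    source and boundary points, re-checked for feasibility; for each kept
    matrix the protein's dominant eigenvalue is computed.  Returns the
    sample array and its mean.
    """
    if not solset.points:
        raise EtmcError("empty solution set")
    rng = np.random.default_rng(seed)
    pts = np.array([p.params for p in solset.points])
    etg = solset.etg
    samples: list[float] = []
    sub = apply_condition(etg, condition) if condition is not None else None
    for _ in range(n_samples):
        w = rng.dirichlet(np.ones(len(pts)))
        params = w @ pts
        # slack matches the boundary tolerance: stored vertices are feasible
        # only up to the search/bisection precision
        ok, _ = _point_feasible(etg, params, solset.objectives, slack=1e-6)
        if not ok:
            continue
        P = _unpack(etg, params)
        Pc = restrict_renormalize(P, sub) if sub is not None else P
        C = CostMatrix(etg=Pc.etg, values=Pc.values * impact.values, protein=impact.protein)
        lam, _, _ = dominant_eigen(C)
        samples.append(lam)
    if not samples:
        raise EtmcError("no feasible samples drawn from the solution set")
    arr = np.array(samples)
    return arr, float(arr.mean())
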