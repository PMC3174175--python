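"""Fixture generators and the end-to-end case-study pipeline.

Two reference systems ship with the package:

* the **two-gene tutorial**: a four-event graph (x+/x-, y+/y-) whose
  transition matrix carries two unknown probabilities, small enough to
  follow every step of the method by hand;
* the **carbon-starvation reconstruction**: an 11-event, 22-edge graph for
  the E. coli carbon-starvation response (genes fis, crp, cya, gyrAB,
  topA plus an auxiliary starvation-signal node), with two edges present
  only outside starvation.  The published graph is a figure, so the edge
  list here is a documented reconstruction (see the data file header).

Also provided: synthetic piecewise-exponential series, random minimal
ETGs for property testing, and :func:`run_case_study`, the pipeline that
strings fixtures -> impacts -> objectives -> inference -> prediction ->
sensitivity into one JSON-serializable report.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from .errors import EtmcError
from .etg import (
    EventTransitionGraph,
    TransitionMatrix,
    apply_condition,
    check_minimality,
    uniform_chain,
)
from .impact import ImpactConfig, build_impact_matrix, elementary_cost
from .accumulation import convergence_error, dominant_eigen, exact_mean
from .inference import (
    Objective,
    ObjectiveSet,
    SearchOptions,
    local_search,
    predict_distribution,
    sample_solution_set,
    sensitivity,
)
from .timeseries import (
    GrowthObjective,
    ProteinSeries,
    fit_piecewise_exponential,
    growth_objective,
    reconstruct_series,
)

__all__ = [
    "two_gene_fixture",
    "two_gene_matrix",
    "carbon_starvation_fixture",
    "CARBON_STARVATION_DELTA_MIN",
    "fis_series_fixture",
    "SyntheticSeriesSpec",
    "synthetic_series",
    "random_etg",
    "run_case_study",
]

# one Markov iteration corresponds to 0.35 min of real time in the E. coli
# case (20 iterations per 7 minutes)
CARBON_STARVATION_DELTA_MIN = 7.0 / 20.0


def two_gene_fixture(rho: float = 0.95) -> tuple[EventTransitionGraph, dict[str, ImpactConfig]]:
    """Two-gene tutorial graph: 4 events, 8 edges, two free parameters.

    The published tutorial matrix is graphical; this reconstruction is
    symmetric under the swap (x <-> y combined with + <-> -), each event
    has out-degree 2, and the uniform chain is irreducible and aperiodic
    with a uniform stationary law.  The two-unknown parameterization of
    the tutorial is exposed by :func:`two_gene_matrix`.
    """
    edges = [
        ("x:+", "x:-"), ("x:+", "y:+"),
        ("x:-", "y:+"), ("x:-", "y:-"),
        ("y:+", "y:-"), ("y:+", "x:+"),
        ("y:-", "x:+"), ("y:-", "x:-"),
    ]
    etg = EventTransitionGraph.from_named_edges(edges)
    configs = {
        "x": ImpactConfig(protein="x", passive_rate=rho),
        "y": ImpactConfig(protein="y", passive_rate=rho),
    }
    return etg, configs


def two_gene_matrix(etg: EventTransitionGraph, p: float, q: float) -> TransitionMatrix:
    """The tutorial's two-unknown transition matrix.

    ``p`` governs the x-event rows, ``q`` the y-event rows:
    ``P(x+ -> x-) = p``, ``P(x- -> y+) = p``, ``P(y+ -> y-) = q``,
    ``P(y- -> x+) = q`` (the complementary edge of each row takes the
    rest).  ``p = q = 0.5`` recovers the uniform chain.
    """
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise EtmcError("p and q must lie in [0, 1]")
    n = etg.n_events
    V = np.zeros((n, n))
    rows = {
        ("x:+", "x:-"): p, ("x:+", "y:+"): 1 - p,
        ("x:-", "y:+"): p, ("x:-", "y:-"): 1 - p,
        ("y:+", "y:-"): q, ("y:+", "x:+"): 1 - q,
        ("y:-", "x:+"): q, ("y:-", "x:-"): 1 - q,
    }
    for (src, dst), val in rows.items():
        V[etg.index(src), etg.index(dst)] = val
    return TransitionMatrix(etg, V)


def carbon_starvation_fixture(
    rho: float = 0.95,
) -> tuple[EventTransitionGraph, dict[str, ImpactConfig]]:
    """Reconstructed E. coli carbon-starvation ETG with self-checks.

    Asserts the printed structural facts at build time: 11 events, 22
    edges, exactly 2 edges conditional on ``"no-starvation"``, and a
    minimal uniform chain under both conditions.
    """
    ref = importlib.resources.files("etmc.data").joinpath("carbon_starvation_etg.tsv")
    with importlib.resources.as_file(ref) as path:
        etg = _io.read_etg(path, auxiliaries=["signal"])
    etg.known_conditions = {"starvation", "no-starvation"}
    if etg.n_events != 11:
        raise EtmcError(f"fixture self-check: expected 11 events, got {etg.n_events}")
    if len(etg.edges) != 22:
        raise EtmcError(f"fixture self-check: expected 22 edges, got {len(etg.edges)}")
    n_cond = sum(1 for c in etg.edge_conditions if c == "no-starvation")
    if n_cond != 2:
        raise EtmcError(f"fixture self-check: expected 2 no-starvation edges, got {n_cond}")
    for cond in ("starvation", "no-starvation"):
        sub = apply_condition(etg, cond)
        rep = check_minimality(uniform_chain(sub))
        if not rep.minimal:
            raise EtmcError(f"fixture self-check: uniform chain not minimal under {cond!r}")
    configs = {
        gene: ImpactConfig(protein=gene, passive_rate=rho)
        for gene in ("fis", "crp", "cya", "gyrAB", "topA")
    }
    return etg, configs


def fis_series_fixture() -> tuple[ProteinSeries, list[float]]:
    """Fis concentration curve: x10 over the first 80 min, then decline.

    Only the 10-fold/80-min stationary-phase rise and the subsequent
    exponential-phase decrease are published; the sampling grid, the
    initial level (1 a.u.) and the decay factor of the second segment are
    synthetic.  Returns the series and its cutpoints [0, 80, 140].
    """
    cutpoints = [0.0, 80.0, 140.0]
    t1 = np.linspace(0.0, 80.0, 9)
    rise = 10.0 ** (t1 / 80.0)  # exactly x10 at t = 80
    decay_factor = 0.985  # per-minute, synthetic
    t2 = np.linspace(87.5, 140.0, 7)
    fall = rise[-1] * decay_factor ** (t2 - 80.0)
    times = np.concatenate([t1, t2])
    conc = np.concatenate([rise, fall])
    return ProteinSeries(protein="fis", times=times, concentrations=conc), cutpoints


@dataclass
class SyntheticSeriesSpec:
    """Recipe for a synthetic exponential series with log-normal noise."""

    lam: float  # per-transition growth factor
    delta: float  # minutes per transition
    K0: float
    times: np.ndarray
    sigma: float = 0.0  # sd of additive noise on log-concentration
    seed: int = 0
    protein: str = "synthetic"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.sigma < 0:
            raise EtmcError("sigma must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise EtmcError("times must be strictly increasing")


def synthetic_series(spec: SyntheticSeriesSpec) -> ProteinSeries:
    """``c(t) = K0 * lam**(t/delta) * exp(noise)``, seeded."""
    rng = np.random.default_rng(spec.seed)
    logc = np.log(spec.K0) + (spec.times / spec.delta) * np.log(spec.lam)
    if spec.sigma > 0:
        logc = logc + rng.normal(0.0, spec.sigma, size=spec.times.size)
    return ProteinSeries(
        protein=spec.protein, times=spec.times, concentrations=np.exp(logc)
    )


def random_etg(
    seed: int,
    n_products: int = 3,
    extra_edges: int = 4,
    max_tries: int = 500,
    well_posed: bool = True,
) -> EventTransitionGraph:
    """Random minimal ETG over ``n_products`` genes (2 events each).

    Builds a random Hamiltonian cycle through all events plus random extra
    edges, retrying until the uniform chain is irreducible and aperiodic
    and (when ``well_posed``) the equilibrium rule has a solution for every
    gene.  The screen mirrors regulatory networks, where each gene's rise
    and fall are reachable through independent routes: on graphs where
    every cycle through ``g:+`` also crosses ``g:-`` the active production
    and degradation cancel exactly and no impact scale can hold the
    expected concentration constant.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    names = [f"g{k}:{s}" for k in range(n_products) for s in "+-"]
    products = [f"g{k}" for k in range(n_products)]
    n = len(names)
    for _ in range(max_tries):
        order = rng.permutation(n)
        edges = {(int(order[i]), int(order[(i + 1) % n])) for i in range(n)}
        while len(edges) < n + extra_edges:
            i, j = int(rng.integers(n)), int(rng.integers(n))
            edges.add((i, j))
        named = [(names[i], names[j]) for (i, j) in sorted(edges)]
        etg = EventTransitionGraph.from_named_edges(named)
        rep = check_minimality(uniform_chain(etg))
        if not rep.minimal:
            continue
        if well_posed:
            from .errors import EquilibriumError
            from .impact import build_impact_matrix

            try:
                for prod in products:
                    build_impact_matrix(etg, ImpactConfig(protein=prod))
            except EquilibriumError:
                continue
        return etg
    raise EtmcError("failed to draw a minimal random ETG")


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_case_study(config: dict, seed: int = 0) -> dict:
    """Execute the full pipeline for a named fixture and return a report.

    ``config`` keys:

    * ``fixture``: ``"two-gene"`` or ``"carbon-starvation"``;
    * ``rho``: passive rate (default 0.95);
    * ``horizon``: iterations for the tutorial fold-change (default 100);
    * ``budget`` / ``tolerance``: local-search options.

    The report carries the inferred matrix, achieved eigenvalues, the
    predicted series per protein, the sensitivity ranking and all seeds.
    Deterministic given the seed.
    """
    name = config.get("fixture", "two-gene")
    rho = float(config.get("rho", 0.95))
    opts = SearchOptions(
        tolerance=float(config.get("tolerance", 1e-9)),
        budget=int(config.get("budget", 20_000)),
    )
    report: dict = {"fixture": name, "rho": rho, "seed": seed}

    if name == "two-gene":
        etg, configs = two_gene_fixture(rho)
        horizon = int(config.get("horizon", 100))
        fold = float(config.get("fold", 100.0))
        lam_obj = fold ** (1.0 / horizon)
        impact_x = build_impact_matrix(etg, configs["x"])
        growth = GrowthObjective(protein="x", segment=0, lambda_obj=lam_obj, delta=1.0)
        # the tutorial's two measured points fix both the exponential slope
        # (lambda) and its intercept: with c(0) normalized, a = 1
        objset = ObjectiveSet(
            etg=etg, objectives=[Objective(growth=growth, impact=impact_x, a_target=1.0)]
        )
        point = local_search(etg, objset, seed=seed, options=opts)
        v0 = np.full(etg.n_events, 1.0 / etg.n_events)
        mean_fold = exact_mean(point.matrix, impact_x, v0, horizon)
        report.update(
            {
                "objective_lambda": lam_obj,
                "achieved_lambda": float(point.lambdas[0]),
                "score": point.score,
                "converged": point.converged,
                "horizon": horizon,
                "x_fold_change": mean_fold,
                "matrix": point.matrix.values.tolist(),
                "events": etg.event_names,
            }
        )
        rep = sensitivity(point, objset)
        report["sensitivity"] = [
            {"source": s, "target": t, "value": v} for (s, t), v in rep.ranking()
        ]
        return report

    if name == "carbon-starvation":
        etg, configs = carbon_starvation_fixture(rho)
        sub = apply_condition(etg, "starvation")
        delta = CARBON_STARVATION_DELTA_MIN
        series, cutpoints = fis_series_fixture()
        fit = fit_piecewise_exponential(series, cutpoints)
        growth = growth_objective(fit, segment=0, delta=delta)
        impacts = {
            gene: build_impact_matrix(sub, ImpactConfig(protein=gene, passive_rate=rho))
            for gene in configs
        }
        objset = ObjectiveSet(
            etg=sub, objectives=[Objective(growth=growth, impact=impacts["fis"])]
        )
        point = local_search(sub, objset, seed=seed, options=opts)
        lam_hat = float(point.lambdas[0])
        times = np.linspace(0.0, 80.0, 17)
        fis_pred = reconstruct_series([lam_hat], delta, series.concentrations[0], times)
        v0 = np.full(sub.n_events, 1.0 / sub.n_events)
        # unobserved proteins: predict the mean growth rate over the set of
        # matrices consistent with an interval around the Fis objective
        interval_set = ObjectiveSet(
            etg=sub,
            objectives=[Objective(growth=growth.with_interval(0.005), impact=impacts["fis"])],
        )
        solset = sample_solution_set(
            sub, interval_set, n_directions=int(config.get("directions", 12)),
            seed=seed, options=opts, source=point,
        )
        predictions = {}
        for gene, imp in impacts.items():
            _, lam_mean = predict_distribution(solset, imp, n_samples=400, seed=seed + 1)
            curve = reconstruct_series([lam_mean], delta, 1.0, times, protein=gene)
            predictions[gene] = {
                "lambda": lam_mean,
                "times": times.tolist(),
                "concentrations": curve.concentrations.tolist(),
            }
        rep = sensitivity(point, objset)
        report.update(
            {
                "delta_min": delta,
                "objective_lambda": growth.lambda_obj,
                "achieved_lambda": lam_hat,
                "score": point.score,
                "converged": point.converged,
                "fis_fold_change_80min": float(
                    fis_pred.concentrations[-1] / fis_pred.concentrations[0]
                ),
                "convergence_error_pct_n20": convergence_error(
                    point.matrix, impacts["fis"], v0, 20
                ),
                "matrix": point.matrix.values.tolist(),
                "events": sub.event_names,
                "predictions": predictions,
                "sensitivity": [
                    {"source": s, "target": t, "value": v} for (s, t), v in rep.ranking()
                ],
            }
        )
        return report

    raise EtmcError(f"unknown fixture {name!r}")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
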