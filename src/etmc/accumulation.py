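"""Asymptotics of multiplicative accumulation rules.

A trajectory of the event chain multiplies a protein's concentration by
the impact of each transition it crosses.  The mean accumulated cost after
``n`` steps is exactly ``v0 @ C^n @ 1`` where ``C`` is the elementary cost
matrix (probabilities times impacts) and ``v0`` the initial event
distribution.  For a minimal (irreducible, aperiodic) chain the accumulated
cost is asymptotically log-normal with

    mean(n)     ~  a * lambda1**n
    variance(n) ~  b * lambda2**n  -  a**2 * lambda1**(2n)

where ``lambda1``/``lambda2`` are the Perron eigenvalues of the generating
matrices ``C(1) = C`` and ``C(2)`` (entries ``p_ij * iota_ij**2``), and
``a``, ``b`` come from the dominant left/right eigenvectors and ``v0``.
The relative error of the asymptotic mean decays like ``epsilon**n`` with
``epsilon`` the spectral-gap ratio of ``C(1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EtmcError, MinimalityError
from .etg import TransitionMatrix, check_minimality
from .impact import CostMatrix, ImpactMatrix

__all__ = [
    "AccumulationStats",
    "SimulationResult",
    "dominant_eigen",
    "generating_matrix",
    "exact_mean",
    "asymptotic_stats",
    "simulate",
    "convergence_error",
]

_EIG_TOL = 1e-10
_DENSE_LIMIT = 64


def _support_digraph_minimal(M: np.ndarray) -> None:
    import networkx as nx

    g = nx.DiGraph()
    n = M.shape[0]
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(M)
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    if not nx.is_strongly_connected(g):
        raise MinimalityError("cost matrix support is reducible")


def dominant_eigen(C: "CostMatrix | np.ndarray") -> tuple[float, np.ndarray, np.ndarray]:
    """Perron root with positive left/right eigenvectors.

    Normalization: ``sum(right) = 1`` and ``left @ right = 1``.  Raises
    :class:`MinimalityError` when the support is reducible or the dominant
    eigenvalue is not simple and real (periodic chain).
    """
    M = C.values if isinstance(C, CostMatrix) else np.asarray(C, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise EtmcError("dominant_eigen expects a square matrix")
    if np.any(M < 0):
        raise EtmcError("cost matrix must be nonnegative")
    _support_digraph_minimal(M)
    n = M.shape[0]
    if n <= _DENSE_LIMIT:
        w, vr = np.linalg.eig(M)
        wl, vl = np.linalg.eig(M.T)
        k = int(np.argmax(np.abs(w)))
        lam = w[k]
        mods = np.sort(np.abs(w))[::-1]
        if len(mods) > 1 and mods[1] > np.abs(lam) - _EIG_TOL * max(1.0, np.abs(lam)):
            raise MinimalityError(
                "dominant eigenvalue is not simple (periodic chain?); "
                f"top moduli {mods[:2]}"
            )
        if abs(lam.imag) > _EIG_TOL * max(1.0, abs(lam)):
            raise MinimalityError("dominant eigenvalue is complex; chain not aperiodic")
        lam = float(lam.real)
        right = np.real(vr[:, k])
        kl = int(np.argmin(np.abs(wl - lam)))
        left = np.real(vl[:, kl])
    else:  # power iteration for large supports
        rng = np.random.default_rng(0)
        right = np.abs(rng.standard_normal(n)) + 1.0
        left = np.abs(rng.standard_normal(n)) + 1.0
        lam = 1.0
        for _ in range(10_000):
            r2 = M @ right
            l2 = M.T @ left
            lam2 = float(np.linalg.norm(r2))
            r2 /= lam2
            l2 /= np.linalg.norm(l2)
            if np.max(np.abs(r2 - right)) < _EIG_TOL and np.max(np.abs(l2 - left)) < _EIG_TOL:
                right, left, lam = r2, l2, lam2
                break
            right, left, lam = r2, l2, lam2
        lam = float(right @ (M @ right) / (right @ right))
    if lam <= 0:
        raise MinimalityError(f"Perron root must be positive, got {lam}")
    # Perron vectors of an irreducible nonnegative matrix are signed uniformly
    if np.sum(right) < 0:
        right = -right
    if np.sum(left) < 0:
        left = -left
    if np.any(right < -1e-8) or np.any(left < -1e-8):
        raise MinimalityError("dominant eigenvectors not positive; chain not minimal")
    right = np.clip(right, 0.0, None)
    left = np.clip(left, 0.0, None)
    right = right / right.sum()
    left = left / float(left @ right)
    return lam, left, right


def generating_matrix(P: TransitionMatrix, I: ImpactMatrix, s: float) -> CostMatrix:
    """Entries ``p_ij * iota_ij**s``; s=0 recovers P, s=1 the cost matrix."""
    if np.any(I.values < 0):
        raise EtmcError("impacts must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        pow_ = np.where(I.values > 0, I.values, 1.0) ** s
    return CostMatrix(etg=P.etg, values=P.values * pow_, protein=I.protein)


def _as_cost(P: "TransitionMatrix", I: "ImpactMatrix", s: float = 1.0) -> np.ndarray:
    return generating_matrix(P, I, s).values


def exact_mean(
    P: TransitionMatrix, I: ImpactMatrix, v0: np.ndarray, n: int, s: float = 1.0
) -> float:
    """Exact mean accumulated cost ``v0 @ C(s)^n @ 1`` (n = 0 gives 1)."""
    v0 = np.asarray(v0, dtype=float)
    if abs(v0.sum() - 1.0) > 1e-9:
        raise EtmcError("initial distribution must sum to 1")
    if n < 0:
        raise EtmcError("n must be >= 0")
    C = _as_cost(P, I, s)
    vec = v0.copy()
    for _ in range(n):
        vec = vec @ C
    return float(vec.sum())


@dataclass
class AccumulationStats:
    """Spectral summary of an accumulation rule (Perron data of C(1), C(2))."""

    lambda1: float
    lambda2: float
    a: float
    b: float
    epsilon: float
    n: int
    mean: np.ndarray = field(repr=False)  # mean(k), k = 0..n
    variance: np.ndarray = field(repr=False)  # variance(k), NaN where closed form < 0

    def to_dict(self) -> dict:
        return {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "a": self.a,
            "b": self.b,
            "epsilon": self.epsilon,
            "mean": self.mean.tolist(),
            "variance": self.variance.tolist(),
        }


def _spectral_gap(M: np.ndarray, lam: float) -> float:
    w = np.linalg.eigvals(M)
    mods = np.sort(np.abs(w))[::-1]
    return float(mods[1] / lam) if len(mods) > 1 else 0.0


def asymptotic_stats(
    P: TransitionMatrix, I: ImpactMatrix, v0: np.ndarray, n: int
) -> AccumulationStats:
    """Asymptotic mean/variance of the accumulated cost after 1..n steps.

    ``a = (v0 @ r1)(l1 @ 1)`` with ``l1 @ r1 = 1`` (and analogously ``b``
    from C(2)), so ``mean(k) = a * lambda1**k`` up to an ``epsilon**k``
    relative error.  The closed-form variance is reported where
    nonnegative; smaller k fall back to the exact second moment via C(2).
    """
    if n < 1:
        raise EtmcError("n must be >= 1")
    v0 = np.asarray(v0, dtype=float)
    C1 = _as_cost(P, I, 1.0)
    C2 = _as_cost(P, I, 2.0)
    lam1, l1, r1 = dominant_eigen(C1)
    lam2, l2, r2 = dominant_eigen(C2)
    ones = np.ones(len(v0))
    a = float((v0 @ r1) * (l1 @ ones))
    b = float((v0 @ r2) * (l2 @ ones))
    eps = _spectral_gap(C1, lam1)
    ks = np.arange(n + 1)
    mean = a * lam1 ** ks
    var = b * lam2 ** ks - a**2 * lam1 ** (2 * ks)
    # closed form can dip negative for small k; recompute exactly there
    for k in range(n + 1):
        if var[k] < 0:
            m1 = exact_mean(P, I, v0, k, s=1.0)
            m2 = exact_mean(P, I, v0, k, s=2.0)
            var[k] = m2 - m1**2
    return AccumulationStats(
        lambda1=lam1, lambda2=lam2, a=a, b=b, epsilon=eps, n=n,
        mean=mean, variance=var,
    )


@dataclass
class SimulationResult:
    """Monte-Carlo trajectories of the accumulation rule."""

    costs: np.ndarray
    mean: float
    variance: float
    reps: int
    n: int
    seed: int
    ks_statistic: float  # KS distance of standardized log-costs to N(0,1)

    def standard_error(self) -> float:
        return float(np.sqrt(self.variance / self.reps))


def simulate(
    P: TransitionMatrix,
    I: ImpactMatrix,
    v0: np.ndarray,
    n: int,
    reps: int,
    seed: int,
) -> SimulationResult:
    """Sample ``reps`` trajectories of length ``n`` and accumulate impacts.

    The initial event is drawn from ``v0`` and each step from the matching
    row of ``P``, via inverse-CDF lookup so results are bit-reproducible
    across platforms for a fixed seed.  Products are accumulated in log
    space.
    """
    if reps < 1:
        raise EtmcError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    v0 = np.asarray(v0, dtype=float)
    nev = P.n
    cum_rows = np.cumsum(P.values, axis=1)
    cum_rows[:, -1] = 1.0
    cum_v0 = np.cumsum(v0)
    cum_v0[-1] = 1.0
    with np.errstate(divide="ignore"):
        logI = np.where(I.values > 0, np.log(np.where(I.values > 0, I.values, 1.0)), 0.0)
    state = np.searchsorted(cum_v0, rng.random(reps), side="right")
    state = np.minimum(state, nev - 1)
    logcost = np.zeros(reps)
    for _ in range(n):
        u = rng.random(reps)
        nxt = np.empty(reps, dtype=np.int64)
        for i in range(nev):  # vectorized per current state
            mask = state == i
            if np.any(mask):
                nxt[mask] = np.searchsorted(cum_rows[i], u[mask], side="right")
        nxt = np.minimum(nxt, nev - 1)
        logcost += logI[state, nxt]
        state = nxt
    costs = np.exp(logcost)
    mean = float(costs.mean())
    var = float(costs.var(ddof=1)) if reps > 1 else 0.0
    sd = float(np.std(logcost, ddof=1)) if reps > 1 else 0.0
    if sd > 0:
        from scipy import stats

        z = (logcost - logcost.mean()) / sd
        ks = float(stats.kstest(z, "norm").statistic)
    else:
        ks = 0.0
    return SimulationResult(
        costs=costs, mean=mean, variance=var, reps=reps, n=n, seed=seed, ks_statistic=ks
    )


def convergence_error(
    P: TransitionMatrix, I: ImpactMatrix, v0: np.ndarray, n: int
) -> float:
    """Relative error (percent) between the exact mean and ``a*lambda1**n``."""
    v0 = np.asarray(v0, dtype=float)
    C1 = _as_cost(P, I, 1.0)
    lam1, l1, r1 = dominant_eigen(C1)
    a = float((v0 @ r1) * (l1 @ np.ones(len(v0))))
    exact = exact_mean(P, I, v0, n)
    return 100.0 * abs(exact - a * lam1**n) / exact
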