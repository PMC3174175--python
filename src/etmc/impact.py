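"""Per-protein multiplicative impact matrices and elementary cost matrices.

Each transition of the event chain multiplies a protein's concentration by
one of three factors:

* ``s`` — active production, on every edge that *reaches* the event
  ``protein:+`` (the gene switches to increasing activity);
* ``d`` — active degradation, on every edge reaching ``protein:-``;
* ``rho`` — passive (natural) degradation, on every other edge.

``rho`` is a free parameter, 5% natural degradation (``rho = 0.95``) by
default.  ``d`` is fixed by an equilibrium rule: under the uniform chain
the expected one-step multiplicative factor must be 1 (expected protein
concentration constant in the absence of any information), and
``s = 1/d``.  Substituting ``s = 1/d`` turns the stability condition

    m_plus * s  +  m_minus * d  +  (1 - m_plus - m_minus) * rho  =  1

into a degree-two equation in ``d`` with a unique root in (0, 1); here
``m_plus`` / ``m_minus`` are the stationary probabilities (under the
uniform chain) of the events ``protein:+`` / ``protein:-``, i.e. the mass
flowing into the production / degradation events each step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    EquilibriumError,
    LookupError_,
    MalformedGraphError,
    MinimalityError,
)
from .etg import (
    EventTransitionGraph,
    TransitionMatrix,
    check_minimality,
    stationary_distribution,
    uniform_chain,
)

__all__ = [
    "ImpactConfig",
    "EquilibriumSolution",
    "ImpactMatrix",
    "CostMatrix",
    "active_event_sets",
    "equilibrium_degradation",
    "build_impact_matrix",
    "elementary_cost",
]

DEFAULT_PASSIVE_RATE = 0.95


@dataclass
class ImpactConfig:
    """Configuration for one protein's impact matrix.

    ``passive_rate`` is the multiplicative factor applied by every
    transition that does not target the protein's own events (dimensionless,
    0 < rho <= 1).  ``half_life_min`` is the shortest amino-acid half-life
    of the protein (minutes), used by the N-end-rule transition duration.
    Explicit ``overrides`` (keys ``"s"`` and/or ``"d"``) bypass the
    equilibrium solver, e.g. a flat 20% production boost ``s = 1.2``.
    """

    protein: str
    passive_rate: float = DEFAULT_PASSIVE_RATE
    half_life_min: float | None = None
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.passive_rate <= 1.0):
            raise EquilibriumError(f"passive rate must be in (0,1], got {self.passive_rate}")


@dataclass
class EquilibriumSolution:
    """Active degradation coefficient d and production coefficient s = 1/d."""

    d: float
    s: float
    degenerate: bool = False  # d == 1 exactly (rho = 1 symmetric case)

    def __post_init__(self) -> None:
        if abs(self.s * self.d - 1.0) > 1e-12:
            raise EquilibriumError("s must be the inverse of d")


@dataclass
class ImpactMatrix:
    """Multiplicative per-transition effects on one protein's concentration.

    Supported entries take exactly the values {s, d, rho} (absent
    overrides); entries outside the chain support are zero.
    """

    etg: EventTransitionGraph
    protein: str
    values: np.ndarray
    solution: EquilibriumSolution | None = None
    passive_rate: float = DEFAULT_PASSIVE_RATE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        S = self.etg.support_matrix()
        if np.any(self.values[~S] != 0.0):
            raise MalformedGraphError("impact outside ETG support")
        if np.any(self.values[S] <= 0.0):
            raise MalformedGraphError("impacts must be positive on the support")


@dataclass
class CostMatrix:
    """Elementary cost: entrywise product of probabilities and impacts."""

    etg: EventTransitionGraph
    values: np.ndarray
    protein: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise MalformedGraphError("cost matrix must be nonnegative")


def active_event_sets(
    etg: EventTransitionGraph, protein: str, allow_missing: bool = False
) -> tuple[set[int], set[int]]:
    """Indices of the active production (``protein:+``) and active
    degradation (``protein:-``) events present in the graph."""
    plus = {i for i, e in enumerate(etg.events) if e.product == protein and e.sign == "+"}
    minus = {i for i, e in enumerate(etg.events) if e.product == protein and e.sign == "-"}
    if not plus and not minus and not allow_missing:
        raise LookupError_(f"product {protein!r} has no events in the graph")
    return plus, minus


def equilibrium_degradation(
    pi: np.ndarray, mass_plus: float, mass_minus: float, rho: float
) -> EquilibriumSolution:
    """Unique root d in (0, 1] of the stability equation.

    With ``rest = 1 - mass_plus - mass_minus``, stability of the expected
    one-step factor reads ``mass_plus/d + mass_minus*d + rest*rho = 1``,
    i.e. ``mass_minus*d^2 + (rest*rho - 1)*d + mass_plus = 0``.

    The product of the two roots is ``mass_plus/mass_minus > 0`` and their
    sum is ``(1 - rest*rho)/mass_minus > 0``, and the polynomial evaluated
    at d=1 is ``rest*(rho - 1) <= 0`` while it is positive at d=0; hence
    exactly one root lies in (0, 1] — equal to 1 only when ``rho = 1`` and
    ``mass_plus = mass_minus`` (flagged degenerate, impacts all trivial).
    """
    if mass_plus <= 0 or mass_minus <= 0:
        raise EquilibriumError(
            f"need positive stationary mass on both active events "
            f"(got +:{mass_plus:.3g}, -:{mass_minus:.3g})"
        )
    rest = 1.0 - mass_plus - mass_minus
    a, b, c = mass_minus, rest * rho - 1.0, mass_plus
    disc = b * b - 4 * a * c
    if disc < 0:
        raise EquilibriumError(f"stability equation has no real root (discriminant {disc:.3g})")
    d = (-b - math.sqrt(disc)) / (2 * a)  # smaller root (b < 0, both roots positive)
    if not (0.0 < d <= 1.0 + 1e-12):
        raise EquilibriumError(f"no admissible root in (0,1]; got {d:.6g}")
    degenerate = abs(d - 1.0) <= 1e-12
    d = min(d, 1.0)
    return EquilibriumSolution(d=d, s=1.0 / d, degenerate=degenerate)


def _fill_impacts(
    etg: EventTransitionGraph, plus: set[int], minus: set[int], s: float, d: float, rho: float
) -> np.ndarray:
    S = etg.support_matrix()
    V = np.where(S, rho, 0.0)
    for (i, j) in etg.edges:
        if j in plus:
            V[i, j] = s
        elif j in minus:
            V[i, j] = d
    return V


def _perron_root(M: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def build_impact_matrix(
    etg: EventTransitionGraph,
    config: ImpactConfig,
    calibration: str = "spectral",
) -> ImpactMatrix:
    """Impact matrix by the equilibrium rule.

    Every edge targeting ``protein:+`` gets s, every edge targeting
    ``protein:-`` gets d, every other supported edge gets rho.  ``d`` is
    fixed so that the uniform chain leaves the expected concentration
    constant; two calibrations of that statement are available:

    * ``"spectral"`` (default): the Perron eigenvalue of the uniform
      chain's elementary cost matrix equals 1 exactly — the mean
      accumulated concentration is asymptotically constant.  Solved by
      bracketed root-finding in d; the stationary quadratic supplies the
      starting bracket.
    * ``"stationary"``: the degree-two stationary equation of
      :func:`equilibrium_degradation` alone.  This sets the *one-step*
      expected factor under the stationary law to 1; the resulting Perron
      eigenvalue is close to, but slightly below, 1 (a multiplicative
      Jensen gap), so the mean concentration decays slowly.

    ``config.overrides`` (explicit ``s`` and/or ``d``) bypass both.
    """
    rho = config.passive_rate
    plus, minus = active_event_sets(etg, config.protein)
    if "s" in config.overrides or "d" in config.overrides:
        if "d" in config.overrides:
            d = float(config.overrides["d"])
            s = float(config.overrides.get("s", 1.0 / d))
        else:
            s = float(config.overrides["s"])
            d = float(config.overrides.get("d", 1.0 / s))
        sol = None if abs(s * d - 1.0) > 1e-12 else EquilibriumSolution(d=d, s=s)
        V = _fill_impacts(etg, plus, minus, s, d, rho)
        return ImpactMatrix(etg=etg, protein=config.protein, values=V, solution=sol,
                            passive_rate=rho)
    if calibration not in ("spectral", "stationary"):
        raise ConfigError(f"unknown calibration {calibration!r}")
    P = uniform_chain(etg)
    rep = check_minimality(P)
    if not rep.irreducible:
        raise MinimalityError("uniform chain reducible; equilibrium rule undefined")
    pi = stationary_distribution(P)
    mass_plus = float(sum(pi[i] for i in plus))
    mass_minus = float(sum(pi[i] for i in minus))
    sol = equilibrium_degradation(pi, mass_plus, mass_minus, rho)
    if calibration == "spectral" and not sol.degenerate:
        from scipy.optimize import brentq

        def gap(d: float) -> float:
            C = P.values * _fill_impacts(etg, plus, minus, 1.0 / d, d, rho)
            return _perron_root(C) - 1.0

        # lambda is monotone decreasing in d; bracket around the quadratic root
        d_hi = 1.0 - 1e-12
        d_lo = sol.d
        while gap(d_lo) <= 0.0:
            d_lo *= 0.5
            if d_lo < 1e-12:
                raise EquilibriumError("could not bracket the spectral equilibrium")
        if gap(d_hi) >= 0.0:
            raise EquilibriumError("spectral equilibrium root at the d=1 boundary")
        d = float(brentq(gap, d_lo, d_hi, xtol=1e-14, rtol=8.9e-16))
        sol = EquilibriumSolution(d=d, s=1.0 / d, degenerate=False)
    V = _fill_impacts(etg, plus, minus, sol.s, sol.d, rho)
    return ImpactMatrix(etg=etg, protein=config.protein, values=V, solution=sol,
                        passive_rate=rho)


def elementary_cost(P: TransitionMatrix, I: ImpactMatrix) -> CostMatrix:
    """Entrywise product ``c_ij = p_ij * iota_ij``."""
    if P.etg.event_names != I.etg.event_names:
        raise MalformedGraphError("transition and impact matrices index different events")
    if P.values.shape != I.values.shape:
        raise MalformedGraphError("shape mismatch between P and impact matrix")
    return CostMatrix(etg=P.etg, values=P.values * I.values, protein=I.protein)
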