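"""Events, event transition graphs and row-stochastic transition matrices.

The state space of the model is not the set of qualitative states of a
regulatory network but the set of *events*: constant slope directions
(``+`` increase, ``-`` decrease) of one product's activity over one time
unit.  The event transition graph (ETG) records which event may succeed
which, and a transition matrix supported on the ETG edges turns the graph
into a Markov chain whose stationary law describes the permanent regime of
a cell population.

Events are written ``product:sign`` in all file formats (e.g. ``fis:+``).
Auxiliary nodes (environmental signals, complexes) are single events with
kind ``"auxiliary"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import (
    ConfigError,
    DeadEndError,
    LookupError_,
    MalformedGraphError,
    MinimalityError,
)

ROW_SUM_TOL = 1e-9
STATIONARY_TOL = 1e-10

__all__ = [
    "Event",
    "EventTransitionGraph",
    "StateTransitionGraph",
    "TransitionMatrix",
    "MinimalityReport",
    "etg_from_state_graph",
    "uniform_chain",
    "stationary_distribution",
    "check_minimality",
    "apply_condition",
    "restrict_renormalize",
]


@dataclass(frozen=True, order=True)
class Event:
    """A slope-change event: one product varying in one direction.

    Parameters
    ----------
    product:
        Identifier of the gene product or auxiliary compound.
    sign:
        ``"+"`` (increase) or ``"-"`` (decrease).
    kind:
        ``"transcriptional"`` for gene products, ``"auxiliary"`` for
        signal/complex style nodes.
    """

    product: str
    sign: str
    kind: str = "transcriptional"

    def __post_init__(self) -> None:
        if not self.product:
            raise MalformedGraphError("event product must be nonempty")
        if self.sign not in ("+", "-"):
            raise MalformedGraphError(f"event sign must be '+' or '-', got {self.sign!r}")
        if self.kind not in ("transcriptional", "auxiliary"):
            raise MalformedGraphError(f"unknown event kind {self.kind!r}")

    @property
    def name(self) -> str:
        return f"{self.product}:{self.sign}"

    @classmethod
    def parse(cls, text: str, auxiliaries: Iterable[str] = ()) -> "Event":
        """Parse ``product:sign``; minus may be ASCII ``-`` or Unicode ``−``."""
        if ":" not in text:
            raise MalformedGraphError(f"event {text!r} is not of the form product:sign")
        product, sign = text.rsplit(":", 1)
        sign = sign.replace("−", "-")
        kind = "auxiliary" if product in set(auxiliaries) else "transcriptional"
        return cls(product=product, sign=sign, kind=kind)


def _canonical_order(events: Iterable[Event]) -> list[Event]:
    # transcriptional first (sorted by product then sign), auxiliaries last
    return sorted(events, key=lambda e: (e.kind == "auxiliary", e.product, e.sign))


@dataclass
class EventTransitionGraph:
    """Directed graph over events encoding the possible event successions.

    ``edges`` are pairs of indices into ``events``.  An edge may carry a
    condition label (free string) naming the environmental condition under
    which it exists; an unlabeled edge exists under every condition.
    """

    events: list[Event]
    edges: list[tuple[int, int]]
    edge_conditions: list[str | None] = field(default_factory=list)
    known_conditions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.edge_conditions:
            self.edge_conditions = [None] * len(self.edges)
        if len(self.edge_conditions) != len(self.edges):
            raise MalformedGraphError("edge_conditions length must match edges")
        n = len(self.events)
        if len({(e.product, e.sign) for e in self.events}) != n:
            raise MalformedGraphError("duplicate events in graph")
        seen: set[tuple[int, int]] = set()
        for (i, j) in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise MalformedGraphError(f"edge ({i},{j}) references unknown event index")
            if (i, j) in seen:
                raise MalformedGraphError(f"duplicate edge {self.events[i].name}->{self.events[j].name}")
            seen.add((i, j))

    # -- convenience ---------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def event_names(self) -> list[str]:
        return [e.name for e in self.events]

    def index(self, name_or_event: "str | Event") -> int:
        name = name_or_event.name if isinstance(name_or_event, Event) else name_or_event
        for i, e in enumerate(self.events):
            if e.name == name:
                return i
        raise LookupError_(f"event {name!r} not in graph")

    def support_matrix(self) -> np.ndarray:
        """Boolean adjacency matrix of the (condition-unfiltered) edge set."""
        S = np.zeros((self.n_events, self.n_events), dtype=bool)
        for (i, j) in self.edges:
            S[i, j] = True
        return S

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_events))
        g.add_edges_from(self.edges)
        return g

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_events, dtype=int)
        for (i, _) in self.edges:
            deg[i] += 1
        return deg

    def conditions(self) -> set[str]:
        """Labels appearing on edges plus any declared condition names."""
        return {c for c in self.edge_conditions if c is not None} | self.known_conditions

    def validate_connected(self) -> None:
        """Reject isolated events (events on no edge)."""
        used = {i for e in self.edges for i in e}
        for i in range(self.n_events):
            if i not in used:
                raise MalformedGraphError(f"event {self.events[i].name} is isolated")

    @classmethod
    def from_named_edges(
        cls,
        edges: Sequence[tuple[str, str] | tuple[str, str, str | None]],
        auxiliaries: Iterable[str] = (),
    ) -> "EventTransitionGraph":
        """Build a graph from ``(source, target[, condition])`` name triples.

        Events are collected from the edge list and canonically ordered
        (products alphabetically, auxiliaries last) so matrices are
        reproducible across runs.
        """
        aux = set(auxiliaries)
        parsed = []
        for edge in edges:
            src, dst = edge[0], edge[1]
            cond = edge[2] if len(edge) > 2 else None
            parsed.append((Event.parse(src, aux), Event.parse(dst, aux), cond or None))
        events = _canonical_order({e for s, d, _ in parsed for e in (s, d)})
        idx = {e.name: i for i, e in enumerate(events)}
        pairs = [(idx[s.name], idx[d.name]) for s, d, _ in parsed]
        conds = [c for _, _, c in parsed]
        return cls(events=events, edges=pairs, edge_conditions=conds)


@dataclass
class StateTransitionGraph:
    """Asynchronous qualitative dynamics: discrete states and single-variable moves.

    Each transition is ``(source state index, target state index, changed
    variable, direction)``; by the asynchronous convention exactly one
    variable changes per transition.
    """

    variables: list[str]
    states: list[tuple[int, ...]]
    transitions: list[tuple[int, int, str, str]]

    def validate(self) -> None:
        nvar = len(self.variables)
        var_idx = {v: k for k, v in enumerate(self.variables)}
        for s in self.states:
            if len(s) != nvar:
                raise MalformedGraphError("state vector length mismatch")
        for (a, b, var, direction) in self.transitions:
            if var not in var_idx:
                raise MalformedGraphError(f"unknown variable {var!r}")
            if direction not in ("+", "-"):
                raise MalformedGraphError(f"bad direction {direction!r}")
            sa, sb = self.states[a], self.states[b]
            diff = [k for k in range(nvar) if sa[k] != sb[k]]
            if len(diff) != 1 or self.variables[diff[0]] != var:
                raise MalformedGraphError(
                    f"transition {a}->{b} must change exactly the declared variable"
                )
            if (sb[diff[0]] > sa[diff[0]]) != (direction == "+"):
                raise MalformedGraphError(f"transition {a}->{b} direction inconsistent")


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix supported on the edges of an ETG."""

    etg: EventTransitionGraph
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.etg.n_events
        if self.values.shape != (n, n):
            raise MalformedGraphError(f"matrix shape {self.values.shape} != ({n},{n})")
        self.validate()

    def validate(self) -> None:
        S = self.etg.support_matrix()
        if np.any(self.values[~S] != 0.0):
            raise MalformedGraphError("nonzero probability outside ETG support")
        if np.any(self.values < 0):
            raise MalformedGraphError("negative transition probability")
        rows = self.values.sum(axis=1)
        bad = np.abs(rows - 1.0) > ROW_SUM_TOL
        if np.any(bad):
            i = int(np.argmax(bad))
            raise MalformedGraphError(
                f"row for event {self.etg.events[i].name} sums to {rows[i]:.12g}, not 1"
            )

    @property
    def n(self) -> int:
        return self.etg.n_events

    def copy(self) -> "TransitionMatrix":
        return TransitionMatrix(self.etg, self.values.copy())


@dataclass
class MinimalityReport:
    """Irreducibility / aperiodicity verdict for a chain's support graph."""

    irreducible: bool
    aperiodic: bool
    period: int

    @property
    def minimal(self) -> bool:
        return self.irreducible and self.aperiodic


# ---------------------------------------------------------------------------
# operations


def etg_from_state_graph(stg: StateTransitionGraph) -> EventTransitionGraph:
    """Derive the event transition graph from asynchronous qualitative dynamics.

    For every length-2 path ``s1 -> s2 -> s3`` in the state graph, the event
    of the first transition (its changed variable and direction) gains an
    edge to the event of the second.  Duplicate edges collapse; the returned
    events are exactly those appearing on some transition.
    """
    stg.validate()
    succ: dict[int, list[tuple[int, str, str]]] = {}
    for (a, b, var, direction) in stg.transitions:
        succ.setdefault(a, []).append((b, var, direction))
    named: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for (a, b, var1, d1) in stg.transitions:
        for (_, var2, d2) in succ.get(b, ()):
            pair = (f"{var1}:{d1}", f"{var2}:{d2}")
            if pair not in seen:
                seen.add(pair)
                named.append(pair)
    if not named:
        raise MalformedGraphError("state graph has no length-2 path; ETG would be empty")
    return EventTransitionGraph.from_named_edges(named)


def uniform_chain(etg: EventTransitionGraph, condition: str | None = None) -> TransitionMatrix:
    """Equal-split transition matrix: each row distributes mass uniformly
    over its out-edges.  Dead-end events are a hard error because every
    downstream spectral statement assumes a bona fide Markov chain.
    """
    g = apply_condition(etg, condition) if condition is not None else etg
    n = g.n_events
    P = np.zeros((n, n))
    deg = g.out_degrees()
    for i in range(n):
        if deg[i] == 0:
            raise DeadEndError(f"event {g.events[i].name} has no outgoing transition")
    for (i, j) in g.edges:
        P[i, j] = 1.0 / deg[i]
    return TransitionMatrix(g, P)


def stationary_distribution(P: TransitionMatrix) -> np.ndarray:
    """Solve pi @ P = pi, pi >= 0, sum(pi) = 1 for an irreducible chain."""
    rep = check_minimality(P)
    if not rep.irreducible:
        raise MinimalityError("chain is reducible; stationary law not unique")
    n = P.n
    A = P.values.T - np.eye(n)
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.where(np.abs(pi) < STATIONARY_TOL, 0.0, pi)
    if np.any(pi < -STATIONARY_TOL):
        raise MinimalityError("stationary solve produced negative mass")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    resid = float(np.max(np.abs(pi @ P.values - pi)))
    if resid > 1e-8:
        raise MinimalityError(f"stationary residual {resid:.3g} too large")
    return pi


def _support_period(g: nx.DiGraph) -> int:
    """gcd of cycle lengths of a strongly connected digraph (BFS levels)."""
    start = next(iter(g.nodes))
    level = {start: 0}
    order = [start]
    gcd = 0
    for u in order:
        for v in g.successors(u):
            if v not in level:
                level[v] = level[u] + 1
                order.append(v)
            else:
                gcd = math.gcd(gcd, level[u] + 1 - level[v])
    return abs(gcd) if gcd else 0


def check_minimality(P: "TransitionMatrix | EventTransitionGraph") -> MinimalityReport:
    """Irreducibility via strong connectivity of the support graph;
    aperiodicity via the gcd of cycle lengths."""
    if isinstance(P, TransitionMatrix):
        g = nx.DiGraph()
        g.add_nodes_from(range(P.n))
        ii, jj = np.nonzero(P.values)
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    else:
        g = P.to_networkx()
    irreducible = g.number_of_nodes() > 0 and nx.is_strongly_connected(g)
    if not irreducible:
        return MinimalityReport(irreducible=False, aperiodic=False, period=0)
    period = _support_period(g)
    return MinimalityReport(irreducible=True, aperiodic=period == 1, period=period)


def apply_condition(etg: EventTransitionGraph, condition: str | None) -> EventTransitionGraph:
    """Subgraph of edges that are unconditional or tagged with ``condition``."""
    known = etg.conditions()
    if condition is not None and known and condition not in known:
        # an unknown label on a graph with no conditional edges is a no-op,
        # but on a conditional graph it is almost surely a typo
        raise ConfigError(f"unknown condition {condition!r}; graph knows {sorted(known)}")
    keep = [
        k
        for k, c in enumerate(etg.edge_conditions)
        if c is None or c == condition
    ]
    return EventTransitionGraph(
        events=list(etg.events),
        edges=[etg.edges[k] for k in keep],
        edge_conditions=[etg.edge_conditions[k] for k in keep],
        known_conditions=set(etg.known_conditions),
    )


def restrict_renormalize(P: TransitionMatrix, etg2: EventTransitionGraph) -> TransitionMatrix:
    """Carry an inferred matrix onto a different edge set (condition switch).

    Probabilities on removed edges are dropped and each affected row is
    renormalized.  Newly added edges get probability 0 when the row retains
    positive mass; a row left without mass falls back to an equal split
    over its new out-edges.  A row with no out-edges at all is a dead end.
    """
    if etg2.event_names != P.etg.event_names:
        raise MalformedGraphError("restrict_renormalize requires identical event sets")
    n = etg2.n_events
    S2 = etg2.support_matrix()
    V = np.where(S2, P.values, 0.0)
    deg2 = S2.sum(axis=1)
    for i in range(n):
        s = V[i].sum()
        if s > 0:
            V[i] /= s
        elif deg2[i] > 0:
            V[i, S2[i]] = 1.0 / deg2[i]
        else:
            raise DeadEndError(f"event {etg2.events[i].name} has no outgoing transition")
    return TransitionMatrix(etg2, V)
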