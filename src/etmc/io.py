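"""Plain-text exchange formats.

* ETG: TSV with header ``source<TAB>target<TAB>condition``; events are
  ``product:sign``; empty condition means the edge exists unconditionally;
  ``#`` starts a comment line.
* State transition graph: TSV
  ``state_id<TAB>levels<TAB>successor_id<TAB>changed_var<TAB>direction``
  with comma-separated integer levels.
* Matrices (transition / impact / cost): dense CSV with event-name header
  row and column.
* Protein series: CSV ``time_min,concentration``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import MalformedGraphError
from .etg import Event, EventTransitionGraph, StateTransitionGraph, TransitionMatrix


def write_etg(etg: EventTransitionGraph, path: str | Path) -> None:
    lines = []
    aux = sorted({e.product for e in etg.events if e.kind == "auxiliary"})
    if aux:
        lines.append("# auxiliaries: " + " ".join(aux))
    if etg.known_conditions:
        lines.append("# conditions: " + " ".join(sorted(etg.known_conditions)))
    lines.append("source\ttarget\tcondition")
    for (i, j), cond in zip(etg.edges, etg.edge_conditions):
        lines.append(f"{etg.events[i].name}\t{etg.events[j].name}\t{cond or ''}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_etg(path: str | Path, auxiliaries: Iterable[str] = ()) -> EventTransitionGraph:
    rows = []
    aux = set(auxiliaries)
    known: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            # header pragmas: "# auxiliaries: a b", "# conditions: c1 c2"
            body = line.lstrip("#").strip()
            for key, sink in (("auxiliaries:", aux), ("conditions:", known)):
                if body.startswith(key):
                    sink.update(body[len(key):].split())
            continue
        parts = line.split("\t")
        if parts[0] == "source":
            continue
        if len(parts) < 2:
            raise MalformedGraphError(f"bad ETG line: {raw!r}")
        cond = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
        rows.append((parts[0], parts[1], cond))
    etg = EventTransitionGraph.from_named_edges(rows, auxiliaries=aux)
    etg.known_conditions = known
    return etg


def read_state_graph(path: str | Path) -> StateTransitionGraph:
    states: dict[str, tuple[int, ...]] = {}
    raw_transitions: list[tuple[str, str, str, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("state_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise MalformedGraphError(f"bad state-graph line: {raw!r}")
        sid, levels, succ, var, direction = parts
        states.setdefault(sid, tuple(int(x) for x in levels.split(",")))
        raw_transitions.append((sid, succ, var, direction))
    ids = sorted(states)
    index = {sid: k for k, sid in enumerate(ids)}
    nvar = len(next(iter(states.values())))
    transitions = []
    for (sid, succ, var, direction) in raw_transitions:
        if succ not in index:
            raise MalformedGraphError(f"successor state {succ!r} has no level vector")
        transitions.append((index[sid], index[succ], var, direction))
    # infer variable order: map changed_var names onto positions by diffing states
    name_by_pos: dict[int, str] = {}
    for (a, b, var, _) in transitions:
        sa, sb = states[ids[a]], states[ids[b]]
        diff = [k for k in range(nvar) if sa[k] != sb[k]]
        if len(diff) == 1:
            name_by_pos[diff[0]] = var
    variables = [name_by_pos.get(k, f"v{k}") for k in range(nvar)]
    stg = StateTransitionGraph(
        variables=variables,
        states=[states[sid] for sid in ids],
        transitions=transitions,
    )
    stg.validate()
    return stg


def matrix_to_frame(values: np.ndarray, names: list[str]) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(values, dtype=float), index=names, columns=names)


def write_matrix(values: np.ndarray, names: list[str], path: str | Path) -> None:
    matrix_to_frame(values, names).to_csv(path, index_label="event")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_transition_matrix(path: str | Path, etg: EventTransitionGraph) -> TransitionMatrix:
    df = read_matrix(path)
    order = etg.event_names
    try:
        df = df.loc[order, order]
    except KeyError as exc:
        raise MalformedGraphError(f"matrix events do not match graph: {exc}") from exc
    return TransitionMatrix(etg, df.to_numpy())


def write_series(times: np.ndarray, concentrations: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_min": times, "concentration": concentrations}).to_csv(path, index=False)


def read_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"time_min", "concentration"} <= set(df.columns):
        raise MalformedGraphError("series CSV must have columns time_min, concentration")
    return df


def etg_to_string(etg: EventTransitionGraph) -> str:
    buf = _io.StringIO()
    buf.write("source\ttarget\tcondition\n")
    for (i, j), cond in zip(etg.edges, etg.edge_conditions):
        buf.write(f"{etg.events[i].name}\t{etg.events[j].name}\t{cond or ''}\n")
    return buf.getvalue()
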