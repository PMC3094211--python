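"""State-transition flux analysis of reprogramming path ensembles.

For a recipe, many random initial states are evolved under the target
condition; every state traversed by a path that ends in the target fate
carries a flux count. The normalized flux of a state is the number of
reprogramming paths through it divided by the number of states in the
graph. Transition states are states crossed by many paths at high
normalized flux across the whole recipe ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .dynamics import Condition, evolve, random_initial_states
from .landscape import StateTransitionGraph
from .network import RegulatoryNetwork
from .phenotype import ClassificationScheme
from .reprogramming import Recipe, _recipe_kwargs


@dataclass
class FluxRecords:
    """Per-state reprogramming-path traversal counts for one graph."""

    counts: dict[int, int]  # state key -> paths through
    n_states: int
    n_paths: int  # successfully reprogramming paths
    n_failed: int  # sampled paths not reaching the target class

    def normalized(self) -> dict[int, float]:
        return {k: c / self.n_states for k, c in self.counts.items()}


def reprogramming_graph(
    net: RegulatoryNetwork,
    recipe: Recipe | None,
    target_class: str,
    condition: Condition,
    scheme: ClassificationScheme,
    n_init: int = 10_000,
    seed: int = 0,
    max_steps: int = 1000,
) -> tuple[StateTransitionGraph, FluxRecords]:
    """Build the state-transition graph of a recipe and tally per-state
    path counts. All trajectories contribute states and edges; only
    trajectories ending in ``target_class`` count as reprogramming paths.
    A path crossing a state several times (cycles) counts once."""
    rng = np.random.default_rng(seed)
    S = random_initial_states(net, n_init, condition, rng)
    overrides = _recipe_kwargs(recipe).get("overrides") if recipe else None
    clamps = _recipe_kwargs(recipe).get("clamps") if recipe else None
    g = StateTransitionGraph(net=net, condition=condition)
    counts: dict[int, int] = {}
    n_paths = 0
    n_failed = 0
    cls_cache: dict[tuple, str] = {}
    for i in range(n_init):
        traj = evolve(
            net, S[i], condition, overrides=overrides, clamps=clamps,
            max_steps=max_steps,
        )
        keys = [s.key for s in traj.states]
        for st in traj.states:
            g.add_state(st.key, st.array())
        for a, b in zip(keys[:-1], keys[1:]):
            g.add_transition(a, b)
        cyc = [s.key for s in traj.attractor.states]
        g.attractor_keys.update(cyc)
        g.add_transition(keys[-1], cyc[(cyc.index(keys[-1]) + 1) % len(cyc)])
        g.roots.append(keys[0])
        ck = traj.attractor.canonical_key
        if ck not in cls_cache:
            cls_cache[ck] = scheme.classify(traj.attractor)
        if cls_cache[ck] == target_class:
            n_paths += 1
            for k in set(keys):
                counts[k] = counts.get(k, 0) + 1
        else:
            n_failed += 1
    return g, FluxRecords(
        counts=counts, n_states=g.n_states, n_paths=n_paths, n_failed=n_failed
    )


@dataclass
class TransitionStateReport:
    candidates: pd.DataFrame  # state key, total paths, mean normalized flux
    accepted: list[int]
    min_paths: int
    min_mean_flux: float
    node_values: pd.DataFrame | None = None  # per accepted state


def find_transition_states(
    records: Sequence[FluxRecords],
    min_paths: int = 9000,
    min_mean_flux: float = 0.05,
    per_graph: bool = False,
    net: RegulatoryNetwork | None = None,
    state_bits: Mapping[int, np.ndarray] | None = None,
) -> TransitionStateReport:
    """Transition states shared across a recipe ensemble.

    A state is accepted when the number of reprogramming paths through it
    (summed across graphs; with ``per_graph=True``, required within every
    graph where it appears) reaches ``min_paths`` and its normalized flux
    averaged over all graphs exceeds ``min_mean_flux``.
    """
    if not records:
        raise ValueError("empty record list")
    n_graphs = len(records)
    totals: dict[int, int] = {}
    flux_sum: dict[int, float] = {}
    present: dict[int, int] = {}
    for rec in records:
        norm = rec.normalized()
        for k, c in rec.counts.items():
            totals[k] = totals.get(k, 0) + c
            flux_sum[k] = flux_sum.get(k, 0.0) + norm[k]
            present[k] = present.get(k, 0) + 1
    rows = []
    for k in totals:
        mean_flux = flux_sum[k] / n_graphs
        if per_graph:
            path_ok = all(
                rec.counts.get(k, 0) >= min_paths for rec in records
                if k in rec.counts
            )
        else:
            path_ok = totals[k] >= min_paths
        rows.append(
            {
                "state": k,
                "paths": totals[k],
                "graphs": present[k],
                "mean_normalized_flux": mean_flux,
                "accepted": bool(path_ok and mean_flux > min_mean_flux),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["accepted", "paths"], ascending=[False, False], ignore_index=True
    ) if rows else pd.DataFrame(
        columns=["state", "paths", "graphs", "mean_normalized_flux", "accepted"]
    )
    accepted = [int(r.state) for r in df.itertuples() if r.accepted]
    node_values = None
    if net is not None and accepted:
        bits = {}
        comp = net.compiled()
        for k in accepted:
            if state_bits is not None and k in state_bits:
                bits[k] = state_bits[k]
            else:
                bits[k] = comp.decode(k)
        node_values = pd.DataFrame(
            {k: b for k, b in bits.items()}, index=net.node_ids()
        ).T
    return TransitionStateReport(
        candidates=df,
        accepted=accepted,
        min_paths=min_paths,
        min_mean_flux=min_mean_flux,
        node_values=node_values,
    )


# ---------------------------------------------------------------------------
# graph export / import
# ---------------------------------------------------------------------------

def to_networkx(
    graph: StateTransitionGraph, flux: FluxRecords | None = None
) -> nx.DiGraph:
    G = nx.DiGraph()
    norm = flux.normalized() if flux is not None else {}
    for k in graph.order:
        G.add_node(
            str(k),
            attractor=k in graph.attractor_keys,
            root=k in set(graph.roots),
            normalized_flux=norm.get(k, 0.0),
        )
    total = sum(graph.transitions.values())
    for (a, b), c in graph.transitions.items():
        G.add_edge(str(a), str(b), flux=c, probability=c / total)
    return G


def export_graph(
    graph: StateTransitionGraph,
    path: str | Path,
    format: str = "graphml",
    flux: FluxRecords | None = None,
) -> Path:
    """Lossless export of states, edges, flux counts and attractor flags
    to GraphML, TSV edge list, or DOT."""
    if graph.n_states == 0:
        raise ValueError("cannot export an empty graph")
    path = Path(path)
    G = to_networkx(graph, flux)
    if format == "graphml":
        nx.write_graphml(G, path)
        return path
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source_key\ttarget_key\tflux\tprobability\n")
            total = sum(graph.transitions.values())
            for (a, b), c in sorted(graph.transitions.items()):
                fh.write(f"{a}\t{b}\t{c}\t{c / total}\n")
        return path
    if format == "dot":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("digraph state_transitions {\n")
            for k in graph.order:
                shape = "doublecircle" if k in graph.attractor_keys else "circle"
                fh.write(f'  "{k}" [shape={shape}];\n')
            for (a, b), c in sorted(graph.transitions.items()):
                fh.write(f'  "{a}" -> "{b}" [penwidth={max(1, c)}];\n')
            fh.write("}\n")
        return path
    raise ValueError(f"unknown export format {format!r}")


def import_graph_tsv(
    path: str | Path, net: RegulatoryNetwork, condition: Condition
) -> StateTransitionGraph:
    """Rebuild a graph from the TSV edge-list export (states decoded from
    their integer keys)."""
    g = StateTransitionGraph(net=net, condition=condition)
    comp = net.compiled()
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples():
        for k in (int(row.source_key), int(row.target_key)):
            g.add_state(k, comp.decode(k))
        g.add_transition(int(row.source_key), int(row.target_key), int(row.flux))
    return g
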