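"""Regulatory-network model: node/edge types, validation, I/O, randomization.

A network is a signed directed graph over typed nodes. Most nodes follow a
weighted-majority Boolean rule; ``logic_and`` and ``phenotype`` nodes are pure
conjunctions of their (all-activating) inputs; ``signal`` nodes are inputs set
by the environmental condition and have no regulators.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NODE_KINDS = frozenset(
    {"protein", "logic_and", "gene_group", "pathway", "phenotype", "signal"}
)
SELF_MODES = frozenset({"degradation", "sustaining", "activation"})

#: node kinds whose next state is the conjunction of their inputs
CONJUNCTION_KINDS = frozenset({"logic_and", "phenotype"})


class NetworkValidationError(ValueError):
    """Raised when a network (or a serialized network file) is malformed."""


@dataclass(frozen=True)
class NodeSpec:
    id: str
    label: str = ""
    kind: str = "protein"
    self_mode: str = "sustaining"
    perturbable: bool | None = None

    def is_perturbable(self) -> bool:
        if self.perturbable is not None:
            return self.perturbable
        return self.kind == "protein"


@dataclass(frozen=True)
class EdgeSpec:
    source: str
    target: str
    sign: int  # +1 activation, -1 repression
    provenance: str = ""


class RegulatoryNetwork:
    """Static regulatory network. Node declaration order fixes the
    state-vector index used everywhere in the dynamics."""

    def __init__(
        self,
        nodes: Sequence[NodeSpec],
        edges: Sequence[EdgeSpec],
        condition_signals: Mapping[str, str] | None = None,
        cell_size_signal: str | None = None,
        spor_node: str | None = None,
        validate: bool = True,
    ):
        self.nodes: list[NodeSpec] = list(nodes)
        self.edges: list[EdgeSpec] = list(edges)
        self.condition_signals: dict[str, str] = dict(condition_signals or {})
        self.cell_size_signal = cell_size_signal
        self.spor_node = spor_node
        self.index: dict[str, int] = {n.id: i for i, n in enumerate(self.nodes)}
        if validate:
            self.validate()
        self._compiled: _CompiledNetwork | None = None

    # -- basic introspection -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node(self, node_id: str) -> NodeSpec:
        return self.nodes[self.index[node_id]]

    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def perturbable_nodes(self) -> list[str]:
        return [n.id for n in self.nodes if n.is_perturbable()]

    def signal_ids(self) -> list[str]:
        return [n.id for n in self.nodes if n.kind == "signal"]

    def regulators(self, node_id: str) -> list[EdgeSpec]:
        return [e for e in self.edges if e.target == node_id]

    def state_values(self, bits: np.ndarray) -> dict[str, int]:
        """Map a state vector to {node id: 0/1}."""
        return {n.id: int(bits[i]) for i, n in enumerate(self.nodes)}

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for n in self.nodes:
            if n.id in seen:
                raise NetworkValidationError(f"duplicate node id {n.id!r}")
            seen.add(n.id)
            if n.kind not in NODE_KINDS:
                raise NetworkValidationError(
                    f"node {n.id!r}: unknown kind {n.kind!r}"
                )
            if n.self_mode not in SELF_MODES:
                raise NetworkValidationError(
                    f"node {n.id!r}: unknown self_mode {n.self_mode!r}"
                )
        pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.index:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target} references undeclared "
                        f"node {endpoint!r}"
                    )
            if e.sign not in (1, -1):
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target}: sign must be +1/-1, "
                    f"got {e.sign!r}"
                )
            if (e.source, e.target) in pairs:
                raise NetworkValidationError(
                    f"duplicate edge {e.source}->{e.target}"
                )
            pairs.add((e.source, e.target))
            tgt = self.node(e.target)
            if tgt.kind == "signal":
                raise NetworkValidationError(
                    f"signal node {e.target!r} may not have incoming edges"
                )
            if tgt.kind in CONJUNCTION_KINDS and e.sign != 1:
                raise NetworkValidationError(
                    f"conjunction node {e.target!r} takes only activating "
                    f"inputs (edge from {e.source!r} has sign {e.sign})"
                )
        for role, node_id in self.condition_signals.items():
            if node_id not in self.index:
                raise NetworkValidationError(
                    f"condition signal {role!r} names unknown node {node_id!r}"
                )
        g = self.condition_signals.get("growth")
        s = self.condition_signals.get("sporulation")
        if g is not None and g == s:
            raise NetworkValidationError(
                "growth and sporulation signals must be distinct nodes"
            )
        if self.cell_size_signal is not None and self.cell_size_signal not in self.index:
            raise NetworkValidationError(
                f"cell_size_signal names unknown node {self.cell_size_signal!r}"
            )
        if self.spor_node is not None and self.spor_node not in self.index:
            raise NetworkValidationError(
                f"spor_node names unknown node {self.spor_node!r}"
            )
        for n in self.nodes:
            if n.kind in CONJUNCTION_KINDS and not any(
                e.target == n.id for e in self.edges
            ):
                raise NetworkValidationError(
                    f"conjunction node {n.id!r} has no inputs"
                )

    # -- compiled arrays for the dynamics engine -----------------------------
    def compiled(self) -> "_CompiledNetwork":
        if self._compiled is None:
            self._compiled = _CompiledNetwork(self)
        return self._compiled

    # -- equality (used by round-trip tests) ---------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and sorted(self.edges, key=lambda e: (e.source, e.target))
            == sorted(other.edges, key=lambda e: (e.source, e.target))
            and self.condition_signals == other.condition_signals
            and self.cell_size_signal == other.cell_size_signal
            and self.spor_node == other.spor_node
        )

    def __repr__(self) -> str:
        return (
            f"RegulatoryNetwork({self.n_nodes} nodes, {len(self.edges)} edges)"
        )


class _CompiledNetwork:
    """Dense array view of a network for vectorized synchronous updates."""

    def __init__(self, net: RegulatoryNetwork):
        self.net = net
        n = net.n_nodes
        self.n = n
        # weight matrix: A[i, j] = contribution of parent j to target i
        A = np.zeros((n, n), dtype=np.float32)
        conj_parents: dict[int, list[int]] = {}
        for e in net.edges:
            i = net.index[e.target]
            j = net.index[e.source]
            if net.nodes[i].kind in CONJUNCTION_KINDS:
                conj_parents.setdefault(i, []).append(j)
            else:
                A[i, j] = e.sign
        self.A = A
        self.conj_items = sorted(conj_parents.items())
        modes = np.array(
            [
                {"degradation": 0, "activation": 1, "sustaining": 2}[n_.self_mode]
                for n_ in net.nodes
            ],
            dtype=np.int8,
        )
        self.tie_keep = modes == 2
        self.tie_const = (modes == 1).astype(np.uint8)  # 1 for activation, 0 deg
        self.powers = (np.uint64(1) << np.arange(n, dtype=np.uint64))

    def encode(self, bits: np.ndarray) -> np.ndarray:
        """Pack (m, n) bit arrays into uint64 keys (n <= 63)."""
        return (bits.astype(np.uint64) @ self.powers).astype(np.uint64)

    def decode(self, key: int) -> np.ndarray:
        return ((np.uint64(key) >> np.arange(self.n, dtype=np.uint64)) & np.uint64(1)).astype(
            np.uint8
        )

    def step_batch(
        self,
        states: np.ndarray,
        clamp_idx: np.ndarray | None = None,
        clamp_val: np.ndarray | None = None,
    ) -> np.ndarray:
        """One synchronous update of (m, n) states."""
        F = states.astype(np.float32) @ self.A.T
        nxt = np.where(
            F > 0,
            np.uint8(1),
            np.where(
                F < 0,
                np.uint8(0),
                np.where(self.tie_keep, states, self.tie_const),
            ),
        ).astype(np.uint8)
        for i, parents in self.conj_items:
            nxt[:, i] = states[:, parents].min(axis=1)
        if clamp_idx is not None and len(clamp_idx):
            nxt[:, clamp_idx] = clamp_val
        return nxt


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _net_to_dict(net: RegulatoryNetwork) -> dict:
    nodes = []
    for n in net.nodes:
        d: dict = {"id": n.id, "label": n.label, "kind": n.kind, "self_mode": n.self_mode}
        if n.perturbable is not None:
            d["perturbable"] = n.perturbable
        nodes.append(d)
    edges = []
    for e in net.edges:
        d = {"source": e.source, "target": e.target, "sign": e.sign}
        if e.provenance:
            d["provenance"] = e.provenance
        edges.append(d)
    signals = dict(net.condition_signals)
    if net.cell_size_signal is not None:
        signals["cell_size"] = net.cell_size_signal
    out = {"nodes": nodes, "edges": edges, "signals": signals}
    if net.spor_node is not None:
        out["spor_node"] = net.spor_node
    return out


def _net_from_dict(doc: Mapping) -> RegulatoryNetwork:
    try:
        nodes = [
            NodeSpec(
                id=d["id"],
                label=d.get("label", ""),
                kind=d.get("kind", "protein"),
                self_mode=d.get("self_mode", "sustaining"),
                perturbable=d.get("perturbable"),
            )
            for d in doc["nodes"]
        ]
        edges = [
            EdgeSpec(
                source=d["source"],
                target=d["target"],
                sign=int(d["sign"]),
                provenance=d.get("provenance", ""),
            )
            for d in doc.get("edges", [])
        ]
    except KeyError as exc:  # pragma: no cover - defensive
        raise NetworkValidationError(f"missing required field {exc}") from exc
    signals = dict(doc.get("signals", {}))
    cell_size = signals.pop("cell_size", None)
    return RegulatoryNetwork(
        nodes,
        edges,
        condition_signals=signals,
        cell_size_signal=cell_size,
        spor_node=doc.get("spor_node"),
    )


def load_network(path: str | Path, format: str | None = None) -> RegulatoryNetwork:
    """Read a network from JSON (canonical), two-file TSV, or SIF.

    For the TSV dialect ``path`` is a directory containing ``nodes.tsv``
    and ``edges.tsv``. SIF files carry only edges; node kinds default to
    protein with sustaining self-mode.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "tsv"
        elif path.suffix == ".sif":
            format = "sif"
        else:
            format = "json"
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            return _net_from_dict(json.load(fh))
    if format == "tsv":
        return _load_tsv(path)
    if format == "sif":
        return _load_sif(path)
    raise ValueError(f"unknown network format {format!r}")


_ROLE_FIELDS = ("growth", "sporulation", "cell_size", "spor_node")


def _load_tsv(dirpath: Path) -> RegulatoryNetwork:
    nodes: list[NodeSpec] = []
    roles: dict[str, str] = {}
    with open(dirpath / "nodes.tsv", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            pert = rec.get("perturbable", "")
            nodes.append(
                NodeSpec(
                    id=rec["id"],
                    label=rec.get("label", ""),
                    kind=rec.get("kind", "protein"),
                    self_mode=rec.get("self_mode", "sustaining"),
                    perturbable=None if pert in ("", "none") else pert == "true",
                )
            )
            role = rec.get("role", "")
            if role:
                if role not in _ROLE_FIELDS:
                    raise NetworkValidationError(
                        f"node {rec['id']!r}: unknown role {role!r}"
                    )
                roles[role] = rec["id"]
    edges: list[EdgeSpec] = []
    with open(dirpath / "edges.tsv", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            edges.append(
                EdgeSpec(
                    source=rec["source"],
                    target=rec["target"],
                    sign=int(rec["sign"]),
                    provenance=rec.get("provenance", ""),
                )
            )
    signals = {k: roles[k] for k in ("growth", "sporulation") if k in roles}
    return RegulatoryNetwork(
        nodes,
        edges,
        condition_signals=signals,
        cell_size_signal=roles.get("cell_size"),
        spor_node=roles.get("spor_node"),
    )


def _load_sif(path: Path) -> RegulatoryNetwork:
    edges: list[EdgeSpec] = []
    ids: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise NetworkValidationError(
                    f"{path}:{lineno}: expected 'source sign target'"
                )
            src, rel, tgt = parts
            if rel not in ("+1", "-1", "1"):
                raise NetworkValidationError(
                    f"{path}:{lineno}: unknown relation {rel!r}"
                )
            ids.setdefault(src)
            ids.setdefault(tgt)
            edges.append(EdgeSpec(src, tgt, 1 if rel in ("+1", "1") else -1))
    nodes = [NodeSpec(id=i) for i in ids]
    return RegulatoryNetwork(nodes, edges)


def write_network(
    net: RegulatoryNetwork, path: str | Path, format: str = "json"
) -> Path:
    """Serialize a network; ``load_network`` of the output reproduces it."""
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_net_to_dict(net), fh, indent=1, ensure_ascii=False)
            fh.write("\n")
        return path
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        roles = {v: k for k, v in net.condition_signals.items()}
        if net.cell_size_signal is not None:
            roles[net.cell_size_signal] = "cell_size"
        if net.spor_node is not None:
            roles[net.spor_node] = "spor_node"
        with open(path / "nodes.tsv", "w", encoding="utf-8") as fh:
            fh.write("id\tlabel\tkind\tself_mode\trole\tperturbable\n")
            for n in net.nodes:
                pert = "" if n.perturbable is None else str(n.perturbable).lower()
                fh.write(
                    f"{n.id}\t{n.label}\t{n.kind}\t{n.self_mode}\t"
                    f"{roles.get(n.id, '')}\t{pert}\n"
                )
        with open(path / "edges.tsv", "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tsign\tprovenance\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.sign}\t{e.provenance}\n")
        return path
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for e in net.edges:
                fh.write(f"{e.source}\t{'+1' if e.sign > 0 else '-1'}\t{e.target}\n")
        return path
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# randomization / synthesis
# ---------------------------------------------------------------------------

def randomize_network(
    net: RegulatoryNetwork, seed: int, n_swaps: int | None = None
) -> RegulatoryNetwork:
    """Degree-preserving, sign-stratified rewiring.

    Repeatedly swaps the *targets* of two same-sign edges, which preserves
    every node's out-degree and, per sign, in-degree. Edges terminating at
    conjunction (logic AND / phenotype) nodes are never touched, no
    duplicate edges or self-loops are created, and rewired edges may not
    point at signal nodes (signals have no regulators by construction).
    """
    rng = np.random.default_rng(seed)
    if n_swaps is None:
        n_swaps = 10 * len(net.edges)
    protected = {
        i
        for i, e in enumerate(net.edges)
        if net.node(e.target).kind in CONJUNCTION_KINDS
    }
    edges = list(net.edges)
    swappable = [i for i in range(len(edges)) if i not in protected]
    if len(swappable) < 2 or n_swaps == 0:
        if n_swaps > 0:
            warnings.warn(
                "randomize_network: no valid swap exists; returning input",
                stacklevel=2,
            )
        return RegulatoryNetwork(
            net.nodes,
            edges,
            net.condition_signals,
            net.cell_size_signal,
            net.spor_node,
        )
    existing = {(e.source, e.target) for e in edges}
    done = 0
    attempts = 0
    max_attempts = 100 * n_swaps
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        i, j = rng.choice(len(swappable), size=2, replace=False)
        ei, ej = edges[swappable[i]], edges[swappable[j]]
        if ei.sign != ej.sign:
            continue
        new_i = (ei.source, ej.target)
        new_j = (ej.source, ei.target)
        if new_i[0] == new_i[1] or new_j[0] == new_j[1]:
            continue
        if new_i in existing or new_j in existing:
            continue
        existing.discard((ei.source, ei.target))
        existing.discard((ej.source, ej.target))
        existing.add(new_i)
        existing.add(new_j)
        edges[swappable[i]] = EdgeSpec(ei.source, ej.target, ei.sign, ei.provenance)
        edges[swappable[j]] = EdgeSpec(ej.source, ei.target, ej.sign, ej.provenance)
        done += 1
    if done < n_swaps:
        logger.warning(
            "randomize_network: only %d/%d swaps possible", done, n_swaps
        )
        if done == 0:
            warnings.warn(
                "randomize_network: no valid swap exists; returning input",
                stacklevel=2,
            )
    return RegulatoryNetwork(
        net.nodes, edges, net.condition_signals, net.cell_size_signal, net.spor_node
    )


def signed_degree_table(net: RegulatoryNetwork) -> dict[str, tuple[int, int, int, int]]:
    """Per-node (in-degree, out-degree, #activators-in, #repressors-in)."""
    table = {n.id: [0, 0, 0, 0] for n in net.nodes}
    for e in net.edges:
        table[e.target][0] += 1
        table[e.source][1] += 1
        if e.sign > 0:
            table[e.target][2] += 1
        else:
            table[e.target][3] += 1
    return {k: tuple(v) for k, v in table.items()}


DEFAULT_SELF_MODE_MIX = {"degradation": 1 / 3, "sustaining": 1 / 3, "activation": 1 / 3}


def generate_synthetic_network(
    n_nodes: int,
    edge_density: float,
    activator_fraction: float = 0.5,
    self_mode_mix: Mapping[str, float] | None = None,
    seed: int = 0,
) -> RegulatoryNetwork:
    """Random signed network of protein nodes for testing and null studies.

    The edge count is ``round(n*(n-1)*edge_density)`` ordered pairs drawn
    without replacement; edge signs are i.i.d. activating with probability
    ``activator_fraction``; self-modes are i.i.d. from ``self_mode_mix``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not (0 < edge_density <= 1):
        raise ValueError("edge_density must be in (0, 1]")
    mix = dict(self_mode_mix or DEFAULT_SELF_MODE_MIX)
    modes = sorted(mix)
    probs = np.array([mix[m] for m in modes], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    ids = [f"n{i:02d}" for i in range(n_nodes)]
    node_modes = rng.choice(len(modes), size=n_nodes, p=probs)
    nodes = [
        NodeSpec(id=ids[i], label=ids[i], kind="protein", self_mode=modes[node_modes[i]])
        for i in range(n_nodes)
    ]
    pairs = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    n_edges = int(round(len(pairs) * edge_density))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    signs = np.where(rng.random(n_edges) < activator_fraction, 1, -1)
    edges = [
        EdgeSpec(ids[pairs[c][0]], ids[pairs[c][1]], int(s))
        for c, s in zip(chosen, signs)
    ]
    return RegulatoryNetwork(nodes, edges)
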