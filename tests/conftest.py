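"""Shared fixtures: packaged networks, derived schemes, hand-built toys,
and an independent pure-Python update oracle."""

from __future__ import annotations

import numpy as np
import pytest

from refate.network import EdgeSpec, NodeSpec, RegulatoryNetwork
from refate.datasets import yeast_network, cell_cycle_toy, yeast_phase_weights
from refate.phenotype import ClassificationScheme

# ---------------------------------------------------------------------------
# independent oracle: re-implements the update semantics from the raw
# node/edge tables, with no shared code with the vectorized engine
# ---------------------------------------------------------------------------

def oracle_step(net: RegulatoryNetwork, state: dict, clamps: dict | None = None) -> dict:
    clamps = clamps or {}
    nxt = {}
    for node in net.nodes:
        ins = [e for e in net.edges if e.target == node.id]
        if node.kind in ("logic_and", "phenotype"):
            val = 1 if ins and all(state[e.source] == 1 for e in ins) else 0
        else:
            f = sum(e.sign * state[e.source] for e in ins)
            if f > 0:
                val = 1
            elif f < 0:
                val = 0
            else:
                val = {
                    "degradation": 0,
                    "activation": 1,
                    "sustaining": state[node.id],
                }[node.self_mode]
        nxt[node.id] = val
    for k, v in clamps.items():
        nxt[k] = v
    return nxt


def oracle_trajectory(net, state: dict, clamps: dict | None = None, max_steps: int = 500):
    """(states, cycle_start_index); states as tuples in node order."""
    order = [n.id for n in net.nodes]
    seen = {}
    states = []
    cur = dict(state)
    for _ in range(max_steps + 1):
        key = tuple(cur[i] for i in order)
        if key in seen:
            return states, seen[key]
        seen[key] = len(states)
        states.append(key)
        cur = oracle_step(net, cur, clamps)
    raise RuntimeError("oracle did not converge")


# ---------------------------------------------------------------------------
# packaged fixtures (session-scoped: derivation samples 50k states once)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def yeast():
    return yeast_network()


@pytest.fixture(scope="session")
def toy11():
    return cell_cycle_toy()


@pytest.fixture(scope="session")
def yeast_scheme_fx(yeast):
    return ClassificationScheme.derive(yeast, n_init=50_000, seed=0)


@pytest.fixture(scope="session")
def weights_fx():
    return yeast_phase_weights()


# ---------------------------------------------------------------------------
# hand-built toys
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_mutual():
    """2-node mutual activation, both sustaining: fixed points 00 and 11,
    basins of exactly 2 states each."""
    return RegulatoryNetwork(
        [NodeSpec("a", self_mode="sustaining"), NodeSpec("b", self_mode="sustaining")],
        [EdgeSpec("a", "b", 1), EdgeSpec("b", "a", 1)],
    )


@pytest.fixture
def toy_cycle():
    """Mutual repression with self-activation: synchronous NOT-gates, so
    00 <-> 11 is a period-2 limit cycle and 10/01 are fixed points."""
    return RegulatoryNetwork(
        [NodeSpec("a", self_mode="activation"), NodeSpec("b", self_mode="activation")],
        [EdgeSpec("a", "b", -1), EdgeSpec("b", "a", -1)],
    )


@pytest.fixture
def toy_spor():
    """8-node fate-decision toy with signals, a conjunction phenotype node
    and a self-sustaining meiotic module; small enough for exhaustive
    enumeration (6 free nodes)."""
    nodes = [
        NodeSpec("SG", kind="signal"),
        NodeSpec("SS", kind="signal"),
        NodeSpec("X1", self_mode="degradation"),
        NodeSpec("A", self_mode="degradation"),
        NodeSpec("B", self_mode="sustaining"),
        NodeSpec("E", kind="gene_group", self_mode="sustaining"),
        NodeSpec("M", kind="gene_group", self_mode="degradation"),
        NodeSpec("SP", kind="phenotype"),
    ]
    edges = [
        EdgeSpec("SG", "X1", 1),
        EdgeSpec("SS", "A", 1),
        EdgeSpec("A", "E", 1),
        EdgeSpec("B", "E", -1),
        EdgeSpec("E", "M", 1),
        EdgeSpec("E", "SP", 1),
        EdgeSpec("M", "SP", 1),
    ]
    return RegulatoryNetwork(
        nodes,
        edges,
        condition_signals={"growth": "SG", "sporulation": "SS"},
        spor_node="SP",
    )


@pytest.fixture
def toy_spor_scheme(toy_spor):
    return ClassificationScheme(
        spor_node="SP",
        marker_nodes=["X1"],
        marker_reference={"X1": 1},
        node_index=dict(toy_spor.index),
    )


def random_small_net(seed: int, n_lo: int = 4, n_hi: int = 10):
    """Random synthetic network for oracle-equivalence sweeps."""
    from refate.network import generate_synthetic_network

    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    density = float(rng.uniform(0.1, 0.4))
    return generate_synthetic_network(
        n, density, activator_fraction=float(rng.uniform(0.3, 0.8)), seed=seed
    )
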