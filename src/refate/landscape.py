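"""Potential-landscape estimation over sampled state-transition graphs.

The deterministic dynamics is softened into a noisy Markov chain: each
node assumes its deterministic next value with probability

    q = (1 - c) / (1 + exp(-mu * |F|)) + c/2      (F != 0)
    q = (1 - c) + c/2                              (F == 0, mode-resolved)

and the complementary probability of flipping; the chain's transition
probability between two states is the product over nodes. A pseudo-state
absorbs the mass leaving the sampled graph and returns uniformly. The
steady state of the chain gives the potential U = -ln p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import Condition, evolve, prepare_initial, random_initial_states, _clamp_arrays
from .network import RegulatoryNetwork
from .reprogramming import Recipe, _recipe_kwargs


@dataclass
class StateTransitionGraph:
    """Sampled deterministic transition graph with traversal counts."""

    net: RegulatoryNetwork
    condition: Condition
    states: dict[int, np.ndarray] = field(default_factory=dict)  # key -> bits
    transitions: dict[tuple[int, int], int] = field(default_factory=dict)
    roots: list[int] = field(default_factory=list)
    attractor_keys: set = field(default_factory=set)
    order: list[int] = field(default_factory=list)  # insertion order of keys

    def add_state(self, key: int, bits: np.ndarray) -> None:
        if key not in self.states:
            self.states[key] = bits
            self.order.append(key)

    def add_transition(self, src: int, dst: int, count: int = 1) -> None:
        self.transitions[(src, dst)] = self.transitions.get((src, dst), 0) + count

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_matrix(self) -> np.ndarray:
        return np.stack([self.states[k] for k in self.order])


def build_state_graph(
    net: RegulatoryNetwork,
    seed_states: np.ndarray,
    condition: Condition,
    recipe: Recipe | None = None,
    pad_to: int = 10_000,
    seed: int = 0,
    max_steps: int = 1000,
    max_pad_trajectories: int = 100_000,
) -> StateTransitionGraph:
    """State-transition graph from the seeds' evolving paths, padded with
    random-trajectory states up to ``pad_to`` states (or until the random
    trajectory budget is spent). Attractor cycle/self edges are included;
    transition counts tally traversals."""
    g = StateTransitionGraph(net=net, condition=condition)
    seeds = np.atleast_2d(np.asarray(seed_states, dtype=np.uint8))

    def ingest(initial: np.ndarray, overrides=None) -> None:
        traj = evolve(net, initial, condition, overrides=overrides, max_steps=max_steps)
        keys = [s.key for s in traj.states]
        for st in traj.states:
            g.add_state(st.key, st.array())
        for a, b in zip(keys[:-1], keys[1:]):
            g.add_transition(a, b)
        # close the attractor (self-loop for fixed points, cycle edge otherwise)
        cyc = [s.key for s in traj.attractor.states]
        g.attractor_keys.update(cyc)
        g.add_transition(keys[-1], cyc[(cyc.index(keys[-1]) + 1) % len(cyc)])

    overrides = _recipe_kwargs(recipe).get("overrides") if recipe else None
    for i in range(seeds.shape[0]):
        ingest(seeds[i], overrides=overrides)
        g.roots.append(
            int(net.compiled().encode(
                prepare_initial(net, seeds[i], condition, overrides).reshape(1, -1)
            )[0])
        )
    rng = np.random.default_rng(seed)
    tries = 0
    while g.n_states < pad_to and tries < max_pad_trajectories:
        S = random_initial_states(net, 1, condition, rng)
        ingest(S[0])
        tries += 1
    return g


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix over graph states plus a trailing pseudo-state."""

    T: np.ndarray  # (n+1, n+1) dense
    state_keys: list[int]
    mu: float
    c: float

    @property
    def n(self) -> int:
        return len(self.state_keys)


def _per_node_probs(
    net: RegulatoryNetwork,
    states: np.ndarray,
    condition: Condition,
    mu: float,
    c: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic successors and per-node probability of taking the
    deterministic value. Clamped nodes never flip (q = 1)."""
    comp = net.compiled()
    cidx, cval = _clamp_arrays(net, condition.clamps)
    F = states.astype(np.float64) @ comp.A.T.astype(np.float64)
    det = comp.step_batch(states, cidx, cval)
    q = np.where(
        F != 0,
        (1 - c) / (1 + np.exp(-mu * np.abs(F))) + c / 2,
        (1 - c) + c / 2,
    )
    if len(cidx):
        q[:, cidx] = 1.0
    return det, q


def transition_matrix(
    graph: StateTransitionGraph,
    net: RegulatoryNetwork | None = None,
    condition: Condition | None = None,
    mu: float = 5.0,
    c: float = 0.001,
    radius: int = 2,
) -> TransitionMatrix:
    """Noisy transition matrix over the graph's states plus a pseudo-state.

    Explicit mass is assigned to in-graph states within Hamming distance
    ``radius`` of each state's deterministic successor; the remaining mass
    (including all out-of-graph states) goes to the pseudo-state, which
    returns uniformly to the in-graph states.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if not (0 <= c < 1):
        raise ValueError("c must lie in [0, 1)")
    net = net or graph.net
    condition = condition or graph.condition
    states = graph.state_matrix()
    keys = list(graph.order)
    n, nn = states.shape
    det, q = _per_node_probs(net, states, condition, mu, c)
    T = np.zeros((n + 1, n + 1))
    # base probability of landing exactly on the deterministic successor
    logq = np.log(np.maximum(q, 1e-300))
    base = np.exp(logq.sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(q < 1, (1 - q) / np.maximum(q, 1e-300), 0.0)
    chunk = max(1, int(2e7) // max(n, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        # mism[i, j, b] = det_i bit b differs from state_j bit b
        mism = det[lo:hi, None, :] != states[None, :, :]
        h = mism.sum(axis=2)
        within = h <= radius
        for i in range(lo, hi):
            js = np.nonzero(within[i - lo])[0]
            for j in js:
                m = mism[i - lo, j]
                prob = base[i] * np.prod(ratio[i, m]) if m.any() else base[i]
                T[i, j] = prob
    T[:n, n] = np.maximum(0.0, 1.0 - T[:n, :n].sum(axis=1))
    T[n, :n] = 1.0 / n
    # guard against tiny negative / rounding drift
    T = np.maximum(T, 0.0)
    T /= T.sum(axis=1, keepdims=True)
    return TransitionMatrix(T=T, state_keys=keys, mu=mu, c=c)


@dataclass
class SteadyStateResult:
    p: np.ndarray
    converged: bool
    residual: float
    iterations: int


def steady_state(
    T: TransitionMatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1_000_000,
) -> SteadyStateResult:
    """Stationary distribution of a row-stochastic matrix by power
    iteration (p <- pT) from the uniform start, converged in L1."""
    M = T.T if isinstance(T, TransitionMatrix) else np.asarray(T, float)
    n = M.shape[0]
    p = np.full(n, 1.0 / n)
    residual = np.inf
    for it in range(1, max_iter + 1):
        nxt = p @ M
        nxt /= nxt.sum()
        residual = float(np.abs(nxt - p).sum())
        p = nxt
        if residual < tol:
            return SteadyStateResult(p, True, residual, it)
    return SteadyStateResult(p, False, residual, max_iter)


@dataclass
class PotentialMap:
    """Per-state steady probabilities per condition, their mean, and the
    potential U = -ln(mean p)."""

    table: pd.DataFrame  # index: state key (+ 'pseudo'), columns p_<cond>, p_mean, U


def potential(
    per_condition: Mapping[str, tuple[Sequence[int], np.ndarray]]
) -> PotentialMap:
    """Combine steady-state solutions across conditions.

    ``per_condition`` maps a condition name to (state keys, probability
    vector over keys + trailing pseudo-state). States absent under a
    condition contribute probability 0 to the mean; U is +inf where the
    mean probability is 0.
    """
    all_keys: list = []
    for keys, p in per_condition.values():
        if len(p) != len(keys) + 1:
            raise ValueError("probability vector must include the pseudo-state")
        for k in keys:
            if k not in all_keys:
                all_keys.append(k)
    cols = {}
    for cond, (keys, p) in per_condition.items():
        lookup = {k: p[i] for i, k in enumerate(keys)}
        cols[f"p_{cond}"] = [lookup.get(k, 0.0) for k in all_keys] + [p[-1]]
    df = pd.DataFrame(cols, index=pd.Index(list(all_keys) + ["pseudo"], name="state"))
    df["p_mean"] = df.mean(axis=1)
    with np.errstate(divide="ignore"):
        df["U"] = -np.log(df["p_mean"].to_numpy())
    return PotentialMap(table=df)
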