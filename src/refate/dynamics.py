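"""Synchronous Boolean dynamics: stepping, trajectories, attractors, basins.

Update rule for a non-conjunction node i with parents j and weights a_ij
(+1 activation, -1 repression):

    F_i = sum_j a_ij * S_j(t)
    S_i(t+1) = 1 if F_i > 0, 0 if F_i < 0, and for F_i = 0 the node's
    self-mode decides: degradation -> 0, sustaining -> S_i(t),
    activation -> 1.

Conjunction (logic AND / phenotype) nodes take the product of their
parents' previous states. Condition clamps override the rule at every
step; transient overrides set bits only in the initial state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .network import RegulatoryNetwork

EXHAUSTIVE_LIMIT = 22


class NonConvergenceError(RuntimeError):
    """A trajectory failed to revisit any state within max_steps."""


@dataclass(frozen=True)
class NetworkState:
    bits: tuple
    key: int

    @classmethod
    def from_bits(cls, bits: np.ndarray) -> "NetworkState":
        b = np.asarray(bits, dtype=np.uint8)
        key = int((b.astype(np.uint64) * (np.uint64(1) << np.arange(b.size, dtype=np.uint64))).sum())
        return cls(bits=tuple(int(x) for x in b), key=key)

    def array(self) -> np.ndarray:
        return np.array(self.bits, dtype=np.uint8)


@dataclass(frozen=True)
class Condition:
    """Environmental condition: signal clamps plus the cell-size protocol.

    ``clamps`` are applied at every update; ``cell_size_protocol`` is
    either "off" (cell-size signal clamped to 0) or "pulse_at_t0"
    (set to 1 in the initial state, clamped to 0 afterwards).
    """

    name: str
    clamps: Mapping[str, int] = field(default_factory=dict)
    cell_size_protocol: str = "off"

    @classmethod
    def for_network(
        cls,
        net: RegulatoryNetwork,
        name: str,
        cell_size_protocol: str = "off",
    ) -> "Condition":
        if name not in ("growth", "sporulation", "none"):
            raise ValueError(f"unknown condition {name!r}")
        clamps: dict[str, int] = {}
        g = net.condition_signals.get("growth")
        s = net.condition_signals.get("sporulation")
        if g is not None:
            clamps[g] = 1 if name == "growth" else 0
        if s is not None:
            clamps[s] = 1 if name == "sporulation" else 0
        if net.cell_size_signal is not None:
            clamps[net.cell_size_signal] = 0
        return cls(name=name, clamps=clamps, cell_size_protocol=cell_size_protocol)

    def validate_against(self, net: RegulatoryNetwork) -> None:
        for nid in self.clamps:
            if nid not in net.index:
                raise KeyError(f"clamp on nonexistent node {nid!r}")
        g = net.condition_signals.get("growth")
        s = net.condition_signals.get("sporulation")
        if g in self.clamps and s in self.clamps:
            if self.clamps[g] == 1 and self.clamps[s] == 1:
                raise ValueError("growth and sporulation signals both clamped on")


@dataclass
class Attractor:
    states: list[NetworkState]
    period: int
    basin_count: int = 0

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    @property
    def canonical_key(self) -> tuple:
        keys = [s.key for s in self.states]
        k = keys.index(min(keys))
        return tuple(keys[k:] + keys[:k])


@dataclass
class Trajectory:
    states: list[NetworkState]
    attractor: Attractor
    steps_to_attractor: int


@dataclass
class SamplingResult:
    attractors: list[Attractor]
    labels: list[str]
    fractions: dict[str, float]
    n_sampled: int
    seed: int | None
    converged: bool

    def attractor_fractions(self) -> dict[tuple, float]:
        return {
            a.canonical_key: a.basin_count / self.n_sampled for a in self.attractors
        }


# ---------------------------------------------------------------------------
# clamp plumbing
# ---------------------------------------------------------------------------

def _clamp_arrays(
    net: RegulatoryNetwork, *clamp_maps: Mapping[str, int] | None
) -> tuple[np.ndarray, np.ndarray]:
    merged: dict[str, int] = {}
    for m in clamp_maps:
        if m:
            merged.update(m)
    for nid in merged:
        if nid not in net.index:
            raise KeyError(f"clamp on nonexistent node {nid!r}")
    idx = np.array([net.index[k] for k in merged], dtype=np.intp)
    val = np.array([int(v) for v in merged.values()], dtype=np.uint8)
    return idx, val


def step(
    net: RegulatoryNetwork,
    state: np.ndarray | NetworkState,
    clamps: Mapping[str, int] | None = None,
    overrides: Mapping[str, int] | None = None,
) -> np.ndarray:
    """One synchronous update of a single state.

    ``overrides`` are applied to the *input* state before updating
    (transient-perturbation semantics); ``clamps`` pin output bits.
    """
    if isinstance(state, NetworkState):
        state = state.array()
    s = np.asarray(state, dtype=np.uint8).reshape(1, -1)
    if s.shape[1] != net.n_nodes:
        raise ValueError("state length does not match network")
    if overrides:
        oidx, oval = _clamp_arrays(net, overrides)
        s = s.copy()
        s[:, oidx] = oval
    cidx, cval = _clamp_arrays(net, clamps)
    return net.compiled().step_batch(s, cidx, cval)[0]


def prepare_initial(
    net: RegulatoryNetwork,
    bits: np.ndarray,
    condition: Condition,
    overrides: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Apply condition clamps, cell-size pulse and transient overrides to
    an initial state (2-D batches accepted)."""
    bits = np.asarray(bits, dtype=np.uint8)
    s = np.atleast_2d(bits).copy()
    cidx, cval = _clamp_arrays(net, condition.clamps)
    if len(cidx):
        s[:, cidx] = cval
    if condition.cell_size_protocol == "pulse_at_t0" and net.cell_size_signal:
        s[:, net.index[net.cell_size_signal]] = 1
    if overrides:
        oidx, oval = _clamp_arrays(net, overrides)
        s[:, oidx] = oval
    return s if bits.ndim == 2 else s[0]


def evolve(
    net: RegulatoryNetwork,
    initial: np.ndarray | NetworkState,
    condition: Condition,
    overrides: Mapping[str, int] | None = None,
    clamps: Mapping[str, int] | None = None,
    max_steps: int = 1000,
) -> Trajectory:
    """Iterate the synchronous update until a state repeats.

    ``overrides`` act only on the initial state (transient perturbation);
    ``clamps`` (e.g. deletion mutants) are merged with the condition's
    signal clamps and applied at every step. Raises
    :class:`NonConvergenceError` if no state revisit occurs in
    ``max_steps`` updates.
    """
    condition.validate_against(net)
    if isinstance(initial, NetworkState):
        initial = initial.array()
    comp = net.compiled()
    s = prepare_initial(net, np.asarray(initial, dtype=np.uint8), condition, overrides)
    if clamps:
        midx, mval = _clamp_arrays(net, clamps)
        s = s.copy()
        s[midx] = mval
    cidx, cval = _clamp_arrays(net, condition.clamps, clamps)
    states = [s]
    seen = {int(comp.encode(s.reshape(1, -1))[0]): 0}
    cur = s
    for _ in range(max_steps):
        cur = comp.step_batch(cur.reshape(1, -1), cidx, cval)[0]
        key = int(comp.encode(cur.reshape(1, -1))[0])
        if key in seen:
            k = seen[key]
            cycle = [NetworkState.from_bits(b) for b in states[k:]]
            attr = Attractor(states=cycle, period=len(cycle))
            return Trajectory(
                states=[NetworkState.from_bits(b) for b in states],
                attractor=attr,
                steps_to_attractor=k,
            )
        seen[key] = len(states)
        states.append(cur)
    raise NonConvergenceError(
        f"no revisited state within {max_steps} steps (trajectory truncated)"
    )


# ---------------------------------------------------------------------------
# batch evolution
# ---------------------------------------------------------------------------

class AttractorRegistry:
    """De-duplicated attractor store keyed by canonical cycle key."""

    def __init__(self) -> None:
        self.attractors: dict[tuple, Attractor] = {}
        self._order: list[tuple] = []

    def add(self, attr: Attractor, count: int = 1) -> Attractor:
        ck = attr.canonical_key
        if ck not in self.attractors:
            self.attractors[ck] = Attractor(attr.states, attr.period, 0)
            self._order.append(ck)
        self.attractors[ck].basin_count += count
        return self.attractors[ck]

    def list(self) -> list[Attractor]:
        return [self.attractors[k] for k in self._order]


def evolve_batch(
    net: RegulatoryNetwork,
    initials: np.ndarray,
    condition: Condition,
    overrides: Mapping[str, int] | None = None,
    clamps: Mapping[str, int] | None = None,
    max_steps: int = 1000,
    registry: AttractorRegistry | None = None,
    fp_rounds: int = 200,
) -> tuple[list[Attractor], np.ndarray, AttractorRegistry]:
    """Evolve (m, n) initial states; return per-row attractor and step count.

    Fixed points are detected vectorized; rows still changing after
    ``fp_rounds`` updates (candidate limit cycles) fall back to the scalar
    walker with full hashing. ``steps[i]`` is the number of updates from
    the (override-applied) initial state to the first attractor state.
    """
    condition.validate_against(net)
    comp = net.compiled()
    reg = registry if registry is not None else AttractorRegistry()
    S0 = prepare_initial(net, np.asarray(initials, dtype=np.uint8), condition, overrides)
    if clamps:
        midx, mval = _clamp_arrays(net, clamps)
        S0[:, midx] = mval
    cidx, cval = _clamp_arrays(net, condition.clamps, clamps)
    m = S0.shape[0]
    steps = np.zeros(m, dtype=np.int64)
    row_attr: list[Attractor | None] = [None] * m
    cur = S0
    active = np.arange(m)
    for t in range(min(fp_rounds, max_steps)):
        nxt = comp.step_batch(cur, cidx, cval)
        fixed = (nxt == cur).all(axis=1)
        if fixed.any():
            fixed_rows = active[fixed]
            fixed_states = cur[fixed]
            keys = comp.encode(fixed_states)
            uniq, inv, counts = np.unique(keys, return_inverse=True, return_counts=True)
            first = {}
            for pos, u in enumerate(keys):
                if u not in first:
                    first[u] = pos
            for ui, u in enumerate(uniq):
                attr = reg.add(
                    Attractor(
                        [NetworkState.from_bits(fixed_states[first[u]])], period=1
                    ),
                    count=int(counts[ui]),
                )
                for r in fixed_rows[inv == ui]:
                    row_attr[r] = attr
            steps[fixed_rows] = t
            keep = ~fixed
            active = active[keep]
            cur = nxt[keep]
        else:
            cur = nxt
        if active.size == 0:
            break
    # leftover rows: scalar walk with hashing (limit cycles or slow paths)
    for pos, r in enumerate(active):
        traj = _walk(comp, cur[pos], cidx, cval, max_steps)
        k, cycle_states = traj
        attr = reg.add(
            Attractor([NetworkState.from_bits(b) for b in cycle_states],
                      period=len(cycle_states)),
            count=1,
        )
        row_attr[r] = attr
        # steps already taken in batch phase + remaining to attractor
        already = min(fp_rounds, max_steps)
        steps[r] = already + k
    return row_attr, steps, reg  # type: ignore[return-value]


def _walk(comp, s0, cidx, cval, max_steps) -> tuple[int, list[np.ndarray]]:
    states = [s0]
    seen = {int(comp.encode(s0.reshape(1, -1))[0]): 0}
    cur = s0
    for _ in range(max_steps):
        cur = comp.step_batch(cur.reshape(1, -1), cidx, cval)[0]
        key = int(comp.encode(cur.reshape(1, -1))[0])
        if key in seen:
            k = seen[key]
            return k, states[k:]
        seen[key] = len(states)
        states.append(cur)
    raise NonConvergenceError(f"no revisited state within {max_steps} steps")


def random_initial_states(
    net: RegulatoryNetwork,
    n: int,
    condition: Condition,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform random states over free nodes; signal bits set by condition."""
    S = rng.integers(0, 2, size=(n, net.n_nodes), dtype=np.uint8)
    return prepare_initial(net, S, condition)


DefaultClassifier = Callable[[Attractor], str]


def _self_label(attr: Attractor) -> str:
    return f"attr:{attr.canonical_key[0]}"


def sample_attractors(
    net: RegulatoryNetwork,
    condition: Condition,
    seed: int,
    batch: int = 5000,
    tol: float = 0.01,
    cap: int = 1_000_000,
    classifier: DefaultClassifier | None = None,
    max_steps: int = 1000,
) -> SamplingResult:
    """Convergent basin sampling.

    Draws uniform random initial states in batches, evolves each to its
    attractor, and stops when the cumulative per-class fractions change by
    less than ``tol`` between consecutive batches (or at ``cap`` with
    ``converged=False``). With no classifier each attractor is its own
    class.
    """
    if batch < 1 or cap < batch:
        raise ValueError("need batch >= 1 and cap >= batch")
    rng = np.random.default_rng(seed)
    label_of = classifier or _self_label
    reg = AttractorRegistry()
    n_total = 0
    prev: dict[str, float] | None = None
    converged = False
    label_cache: dict[tuple, str] = {}
    while n_total < cap:
        n_draw = min(batch, cap - n_total)
        S = random_initial_states(net, n_draw, condition, rng)
        evolve_batch(net, S, condition, max_steps=max_steps, registry=reg)
        n_total += n_draw
        frac: dict[str, float] = {}
        for a in reg.list():
            ck = a.canonical_key
            if ck not in label_cache:
                label_cache[ck] = label_of(a)
            lab = label_cache[ck]
            frac[lab] = frac.get(lab, 0.0) + a.basin_count / n_total
        if prev is not None:
            keys = set(prev) | set(frac)
            if all(abs(frac.get(k, 0) - prev.get(k, 0)) < tol for k in keys):
                converged = True
                break
        prev = frac
    attractors = reg.list()
    labels = [label_cache[a.canonical_key] for a in attractors]
    fractions: dict[str, float] = {}
    for a, lab in zip(attractors, labels):
        fractions[lab] = fractions.get(lab, 0.0) + a.basin_count / n_total
    return SamplingResult(
        attractors=attractors,
        labels=labels,
        fractions=fractions,
        n_sampled=n_total,
        seed=seed,
        converged=converged,
    )


def all_states(n_free: int, free_idx: np.ndarray, n_nodes: int) -> np.ndarray:
    grid = (
        (np.arange(2**n_free, dtype=np.uint64)[:, None] >> np.arange(n_free, dtype=np.uint64))
        & np.uint64(1)
    ).astype(np.uint8)
    S = np.zeros((2**n_free, n_nodes), dtype=np.uint8)
    S[:, free_idx] = grid
    return S


def enumerate_attractors(
    net: RegulatoryNetwork,
    condition: Condition,
    classifier: DefaultClassifier | None = None,
    limit: int = EXHAUSTIVE_LIMIT,
    max_steps: int = 10000,
    chunk: int = 1 << 14,
) -> SamplingResult:
    """Exact basins over all 2^(free nodes) initial states.

    The oracle counterpart of :func:`sample_attractors`; refuses networks
    with more than ``limit`` free (unclamped, non-signal-fixed) nodes.
    """
    cidx, _ = _clamp_arrays(net, condition.clamps)
    free_idx = np.array(
        [i for i in range(net.n_nodes) if i not in set(int(c) for c in cidx)],
        dtype=np.intp,
    )
    n_free = len(free_idx)
    if n_free > limit:
        raise ValueError(
            f"{n_free} free nodes exceeds the exhaustive limit of {limit}"
        )
    S = all_states(n_free, free_idx, net.n_nodes)
    reg = AttractorRegistry()
    for lo in range(0, S.shape[0], chunk):
        evolve_batch(net, S[lo : lo + chunk], condition, max_steps=max_steps, registry=reg)
    label_of = classifier or _self_label
    attractors = reg.list()
    labels = [label_of(a) for a in attractors]
    n_total = S.shape[0]
    fractions: dict[str, float] = {}
    for a, lab in zip(attractors, labels):
        fractions[lab] = fractions.get(lab, 0.0) + a.basin_count / n_total
    return SamplingResult(
        attractors=attractors,
        labels=labels,
        fractions=fractions,
        n_sampled=n_total,
        seed=None,
        converged=True,
    )


def largest_attractor(result: SamplingResult) -> Attractor:
    return max(result.attractors, key=lambda a: a.basin_count)


def excited_trajectory(
    net: RegulatoryNetwork,
    attractor: Attractor,
    condition: Condition | None = None,
    clamps: Mapping[str, int] | None = None,
    max_steps: int = 1000,
) -> Trajectory:
    """The canonical START trajectory: pulse the cell-size signal in the
    given attractor state and evolve back to an attractor. The returned
    trajectory begins at the first post-pulse state (the excited G1 /
    START state, with the size-checkpoint cyclin freshly activated); the
    transient pulse state itself is not part of it."""
    cond = condition or Condition.for_network(net, "growth")
    cond = Condition(cond.name, dict(cond.clamps), "pulse_at_t0")
    traj = evolve(
        net, attractor.states[0].array(), cond, clamps=clamps, max_steps=max_steps
    )
    if len(traj.states) > 1:
        return Trajectory(
            states=traj.states[1:],
            attractor=traj.attractor,
            steps_to_attractor=max(traj.steps_to_attractor - 1, 0),
        )
    return traj


def identify_cyclic_markers(
    net: RegulatoryNetwork,
    condition: Condition | None = None,
    n_init: int = 100_000,
    seed: int = 0,
    marker_kinds: Sequence[str] = ("protein",),
    result: SamplingResult | None = None,
) -> tuple[list[str], dict[str, int], Attractor, Trajectory]:
    """Marker nodes for the proliferative fate.

    Finds the largest-basin attractor (by sampling ``n_init`` states under
    the condition), pulses the cell-size signal to launch the excited
    trajectory, and returns the protein/complex nodes whose state changes
    at least once along that trajectory, together with their values in the
    largest attractor.
    """
    cond = condition or Condition.for_network(net, "growth")
    if result is None:
        result = sample_attractors(
            net, cond, seed=seed, batch=min(5000, n_init), cap=n_init, tol=0.0
        )
    big = largest_attractor(result)
    traj = excited_trajectory(net, big, cond)
    arr = np.stack([s.array() for s in traj.states])
    changing = (arr != arr[0]).any(axis=0)
    markers = [
        n.id
        for i, n in enumerate(net.nodes)
        if changing[i] and n.kind in marker_kinds
    ]
    ref_bits = big.states[0].array()
    reference = {m: int(ref_bits[net.index[m]]) for m in markers}
    return markers, reference, big, traj
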