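"""Null-model significance via degree-preserving random networks and
structural perturbations."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .network import (
    CONJUNCTION_KINDS,
    EdgeSpec,
    RegulatoryNetwork,
    randomize_network,
)

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    metric: str
    values: np.ndarray
    observed: float
    mean: float
    sd: float
    p_parametric: float  # normal tail on the z-score
    p_empirical: float  # +1-smoothed empirical tail
    n_requested: int
    n_failed: int
    seed: int
    tail: str = "two-sided"


def null_distribution(
    net: RegulatoryNetwork,
    metric: Callable[[RegulatoryNetwork], float],
    observed: float | None = None,
    n_random: int = 10_000,
    seed: int = 0,
    n_swaps: int | None = None,
    metric_name: str = "metric",
    tail: str = "two-sided",
) -> NullDistribution:
    """Evaluate a network metric over an ensemble of degree-preserving
    randomizations. Draw i uses the counter-based seed ``seed + i`` so the
    ensemble is extensible without replaying. Metric failures are logged
    and excluded (counted in ``n_failed``).
    """
    if observed is None:
        observed = float(metric(net))
    values = []
    n_failed = 0
    for i in range(n_random):
        rnd = randomize_network(net, seed=seed + i, n_swaps=n_swaps)
        try:
            values.append(float(metric(rnd)))
        except Exception as exc:  # metric may be undefined on a draw
            logger.warning("metric failed on draw %d: %s", i, exc)
            n_failed += 1
    vals = np.array(values, dtype=float)
    mean = float(vals.mean()) if len(vals) else float("nan")
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    if sd > 0:
        z = (observed - mean) / sd
        if tail == "two-sided":
            p_par = float(2 * stats.norm.sf(abs(z)))
        elif tail == "greater":
            p_par = float(stats.norm.sf(z))
        else:
            p_par = float(stats.norm.cdf(z))
    else:
        p_par = 1.0 if observed == mean else 0.0
    if tail == "two-sided":
        extreme = np.abs(vals - mean) >= abs(observed - mean)
    elif tail == "greater":
        extreme = vals >= observed
    else:
        extreme = vals <= observed
    p_emp = (int(extreme.sum()) + 1) / (len(vals) + 1)
    return NullDistribution(
        metric=metric_name,
        values=vals,
        observed=observed,
        mean=mean,
        sd=sd,
        p_parametric=p_par,
        p_empirical=p_emp,
        n_requested=n_random,
        n_failed=n_failed,
        seed=seed,
        tail=tail,
    )


def structural_perturbation(
    net: RegulatoryNetwork,
    op: str,
    k: int = 1,
    seed: int = 0,
    max_retries: int = 1000,
) -> RegulatoryNetwork:
    """Apply k random structural edits: ``add_edge`` (random new signed
    edge), ``delete_edge``, or ``flip_direction`` (reverse an edge,
    keeping its sign). Edges into conjunction nodes and signal nodes are
    protected. Infeasible edits after bounded retries reduce k with a
    logged warning."""
    if op not in ("add_edge", "delete_edge", "flip_direction"):
        raise ValueError(f"unknown structural operation {op!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    edges = list(net.edges)
    ids = net.node_ids()
    protected_targets = {
        n.id for n in net.nodes if n.kind in CONJUNCTION_KINDS or n.kind == "signal"
    }
    done = 0
    for _ in range(max_retries * k):
        if done >= k:
            break
        existing = {(e.source, e.target) for e in edges}
        if op == "add_edge":
            src = ids[rng.integers(len(ids))]
            tgt = ids[rng.integers(len(ids))]
            if src == tgt or tgt in protected_targets or (src, tgt) in existing:
                continue
            sign = 1 if rng.random() < 0.5 else -1
            edges.append(EdgeSpec(src, tgt, sign, provenance="perturbed"))
            done += 1
        elif op == "delete_edge":
            candidates = [
                i for i, e in enumerate(edges) if e.target not in protected_targets
            ]
            if not candidates:
                break
            edges.pop(candidates[int(rng.integers(len(candidates)))])
            done += 1
        else:  # flip_direction
            candidates = [
                i
                for i, e in enumerate(edges)
                if e.target not in protected_targets
                and e.source not in protected_targets
                and net.node(e.source).kind != "signal"
                and (e.target, e.source) not in existing
            ]
            if not candidates:
                break
            i = candidates[int(rng.integers(len(candidates)))]
            e = edges[i]
            edges[i] = EdgeSpec(e.target, e.source, e.sign, e.provenance)
            done += 1
    if done < k:
        logger.warning(
            "structural_perturbation: applied %d of %d %s edits", done, k, op
        )
    return RegulatoryNetwork(
        net.nodes, edges, net.condition_signals, net.cell_size_signal, net.spor_node
    )
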