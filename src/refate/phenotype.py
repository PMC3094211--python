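"""Phenotype prediction: attractor classes, sporulation efficiency,
cell-cycle phase assignment, viability calls, and evaluation statistics.

An attractor is *sporulation* if the sporulation phenotype node is on (in
every cycle state), *cell cycle* if a fixed set of marker proteins matches
their values in the largest growth-condition attractor (again in every
cycle state), and *other* otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import (
    Attractor,
    Condition,
    NetworkState,
    SamplingResult,
    Trajectory,
    evolve_batch,
    excited_trajectory,
    identify_cyclic_markers,
    random_initial_states,
)
from .network import RegulatoryNetwork

PHASES = ("START", "G1", "S", "G2", "M", "stationary_G1")

SPORULATION = "sporulation"
CELL_CYCLE = "cell_cycle"
OTHER = "other"


@dataclass
class ClassificationScheme:
    """Marker-based three-way attractor classifier for one network."""

    spor_node: str | None
    marker_nodes: list[str]
    marker_reference: dict[str, int]
    node_index: dict[str, int]
    start_state: np.ndarray | None = None  # largest growth attractor bits

    @classmethod
    def derive(
        cls,
        net: RegulatoryNetwork,
        condition: Condition | None = None,
        n_init: int = 100_000,
        seed: int = 0,
        result: SamplingResult | None = None,
    ) -> "ClassificationScheme":
        markers, reference, big, _traj = identify_cyclic_markers(
            net, condition, n_init=n_init, seed=seed, result=result
        )
        return cls(
            spor_node=net.spor_node,
            marker_nodes=markers,
            marker_reference=reference,
            node_index=dict(net.index),
            start_state=big.states[0].array(),
        )

    def classify(self, attr: Attractor) -> str:
        return classify_attractor(attr, self)


def classify_attractor(attr: Attractor, scheme: ClassificationScheme) -> str:
    """Three-way partition; sporulation takes precedence over cell cycle.

    For limit cycles the label must hold in every cycle state.
    """
    arrs = [s.array() for s in attr.states]
    if scheme.spor_node is not None:
        si = scheme.node_index[scheme.spor_node]
        if all(a[si] == 1 for a in arrs):
            return SPORULATION
    if scheme.marker_nodes:
        ok = all(
            all(
                a[scheme.node_index[m]] == scheme.marker_reference[m]
                for m in scheme.marker_nodes
            )
            for a in arrs
        )
        if ok:
            return CELL_CYCLE
    return OTHER


def class_fractions(
    net: RegulatoryNetwork,
    condition: Condition,
    scheme: ClassificationScheme,
    n: int = 10_000,
    seed: int = 0,
    clamps: Mapping[str, int] | None = None,
    overrides: Mapping[str, int] | None = None,
    max_steps: int = 1000,
) -> dict[str, float]:
    """Fractions of random initial states per attractor class, with
    optional permanent clamps (mutants) and t=0 overrides (recipes)."""
    rng = np.random.default_rng(seed)
    S = random_initial_states(net, n, condition, rng)
    row_attr, _steps, _reg = evolve_batch(
        net, S, condition, overrides=overrides, clamps=clamps, max_steps=max_steps
    )
    counts = {SPORULATION: 0, CELL_CYCLE: 0, OTHER: 0}
    cache: dict[tuple, str] = {}
    for a in row_attr:
        ck = a.canonical_key
        if ck not in cache:
            cache[ck] = scheme.classify(a)
        counts[cache[ck]] += 1
    return {k: v / n for k, v in counts.items()}


def sporulation_fraction(
    net: RegulatoryNetwork,
    mutation: Mapping[str, int] | None,
    condition: Condition,
    n: int = 10_000,
    seed: int = 0,
    scheme: ClassificationScheme | None = None,
    max_steps: int = 1000,
) -> float:
    """Fraction of random initial states converging to sporulation
    attractors with the mutation clamped at every step."""
    sch = scheme or ClassificationScheme(
        spor_node=net.spor_node,
        marker_nodes=[],
        marker_reference={},
        node_index=dict(net.index),
    )
    frac = class_fractions(
        net, condition, sch, n=n, seed=seed, clamps=mutation, max_steps=max_steps
    )
    return frac[SPORULATION]


def predicted_prespo_spore_ratio(f_wt: float, f_mut: float) -> float:
    """Predicted Prespo/Spore ratio: wild-type over mutant sporulation
    fraction. A mutant fraction of 0 yields +inf (rank statistics cope)."""
    if f_wt <= 0:
        raise ValueError("wild-type sporulation fraction must be > 0")
    if f_mut == 0:
        return math.inf
    return f_wt / f_mut


# ---------------------------------------------------------------------------
# cell-cycle phases
# ---------------------------------------------------------------------------

@dataclass
class PhaseWeightMatrix:
    """Per-(marker node, phase) weights in [0, 1] used by the g(j) score."""

    w: pd.DataFrame  # index: node ids, columns: PHASES
    phases: tuple = PHASES

    def __post_init__(self) -> None:
        vals = self.w.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("phase weights must lie in [0, 1]")
        missing = [p for p in self.phases if p not in self.w.columns]
        if missing:
            raise ValueError(f"weight table lacks phases {missing}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PhaseWeightMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(w=df, phases=tuple(df.columns))

    def write_tsv(self, path: str | Path) -> None:
        self.w.to_csv(path, sep="\t", index_label="node_id")


@dataclass
class PhaseCall:
    phase: str | None
    scores: dict[str, float]
    tie: bool = False
    unassignable: bool = False


def assign_phase(
    values: Mapping[str, int], weights: PhaseWeightMatrix
) -> PhaseCall:
    """Score a state against each cell-cycle phase.

    The raw score of phase j is the product over marker nodes i of w_ij
    when the node is on and (1 - w_ij) when it is off; scores are
    normalized to sum to 1 and the phase is the argmax (earliest phase in
    canonical order on ties, flagged).
    """
    missing = [n for n in weights.w.index if n not in values]
    if missing:
        raise KeyError(f"state lacks marker nodes {missing}")
    s = np.array([int(values[n]) for n in weights.w.index], dtype=float)
    W = weights.w.to_numpy(dtype=float)
    contrib = np.where(s[:, None] == 1, W, 1.0 - W)
    raw = contrib.prod(axis=0)
    total = raw.sum()
    if total == 0:
        return PhaseCall(
            phase=None,
            scores={p: 0.0 for p in weights.phases},
            unassignable=True,
        )
    g = raw / total
    best = float(g.max())
    winners = [p for p, v in zip(weights.phases, g) if v == best]
    return PhaseCall(
        phase=winners[0],
        scores={p: float(v) for p, v in zip(weights.phases, g)},
        tie=len(winners) > 1,
    )


def phase_sequence(
    traj: Trajectory, weights: PhaseWeightMatrix, net: RegulatoryNetwork
) -> list[str]:
    """Phase label per trajectory state with consecutive repeats collapsed
    (phase duration is not proportional to state count)."""
    seq: list[str] = []
    for st in traj.states:
        call = assign_phase(net.state_values(st.array()), weights)
        lab = call.phase or "unassignable"
        if not seq or seq[-1] != lab:
            seq.append(lab)
    return seq


_VIABLE_ORDERS = (
    ["START", "G1", "S", "G2", "M", "stationary_G1"],
    ["START", "G1", "S", "G2", "M", "G1", "stationary_G1"],
)


@dataclass
class ViabilityCall:
    viable: bool
    phase_sequence: list[str]
    reason: str = ""


def check_viability(
    net: RegulatoryNetwork,
    mutation: Mapping[str, int] | None,
    scheme: ClassificationScheme,
    weights: PhaseWeightMatrix,
    max_steps: int = 1000,
) -> ViabilityCall:
    """Viable iff, starting from the START state (largest growth attractor
    with the cell-size pulse) with the mutation clamped, the trajectory
    (i) converges to a cell-cycle attractor and (ii) passes the phases in
    order START-G1-S-G2-M-(G1)-stationary G1 (the G1 before stationary G1
    is optional)."""
    if scheme.start_state is None:
        raise ValueError("scheme lacks the largest-attractor start state")
    start = Attractor([NetworkState.from_bits(scheme.start_state)], period=1)
    try:
        traj = excited_trajectory(net, start, clamps=mutation, max_steps=max_steps)
    except Exception:
        return ViabilityCall(False, [], reason="no attractor")
    if scheme.classify(traj.attractor) != CELL_CYCLE:
        return ViabilityCall(
            False,
            phase_sequence(traj, weights, net),
            reason="did not converge to a cell-cycle attractor",
        )
    seq = phase_sequence(traj, weights, net)
    if seq in [list(o) for o in _VIABLE_ORDERS]:
        return ViabilityCall(True, seq)
    return ViabilityCall(False, seq, reason="improper phase order")


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    num = c.tp * c.tn - c.fp * c.fn
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def evaluate_against_table(
    predictions: Mapping[str, float | str],
    table: pd.DataFrame | str | Path,
    value_column: str = "value",
    positive_label: str = "viable",
) -> dict[str, float]:
    """Compare per-mutant predictions with an experimental table.

    Numeric tables yield Pearson r (with its t-test p-value on n-2 df) and
    Spearman rho; categorical tables (e.g. viable/inviable) yield accuracy
    and MCC. Requires at least 3 shared mutant identifiers.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype={0: str}).set_index(
            "mutant_id"
        )
    shared = [m for m in table.index if m in predictions]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared mutants (need >= 3)")
    exp = table.loc[shared, value_column]
    pred = pd.Series({m: predictions[m] for m in shared})
    out: dict[str, float] = {"n": float(len(shared))}
    if pd.api.types.is_numeric_dtype(exp) and pd.api.types.is_numeric_dtype(pred):
        x = pred.to_numpy(dtype=float)
        y = exp.to_numpy(dtype=float)
        finite = np.isfinite(x) & np.isfinite(y)
        if finite.sum() >= 3:
            r, p = stats.pearsonr(x[finite], y[finite])
            out["pearson_r"] = float(r)
            out["pearson_p"] = float(p)
        rho, rho_p = stats.spearmanr(x, y)
        out["spearman_rho"] = float(rho)
        out["spearman_p"] = float(rho_p)
    else:
        yhat = pred.astype(str) == positive_label
        y = exp.astype(str) == positive_label
        c = ConfusionCounts(
            tp=int((yhat & y).sum()),
            tn=int((~yhat & ~y).sum()),
            fp=int((yhat & ~y).sum()),
            fn=int((~yhat & y).sum()),
        )
        out["accuracy"] = c.accuracy
        out["mcc"] = mcc(c)
    return out


# ---------------------------------------------------------------------------
# phase-weight derivation (the shipped weight table is generated this way)
# ---------------------------------------------------------------------------

def segment_trajectory_phases(
    net: RegulatoryNetwork,
    traj: Trajectory,
    start_node: str,
    clb_s: str,
    clb_m: str,
    exit_node: str,
) -> list[str]:
    """Label each excited-trajectory state with its cell-cycle phase from
    the canonical cyclin milestones: START while the size-checkpoint
    cyclin (``start_node``, Cln3) is on (and in the pulse state itself),
    G1 until the S-phase cyclin (``clb_s``) fires, S until the mitotic
    cyclin (``clb_m``) fires, G2 until the anaphase trigger
    (``exit_node``, Cdc20) fires, M until both are degraded, then G1
    again, and stationary G1 once the attractor is reached."""
    idx = net.index
    labels: list[str] = []
    phase = "START"
    for t, st in enumerate(traj.states):
        b = st.array()
        if phase == "START" and t > 0 and b[idx[start_node]] == 0:
            phase = "G1"
        if phase == "G1" and b[idx[clb_s]] == 1:
            phase = "S"
        if phase == "S" and b[idx[clb_m]] == 1:
            phase = "G2"
        if phase == "G2" and b[idx[exit_node]] == 1:
            phase = "M"
        if phase == "M" and b[idx[clb_m]] == 0 and b[idx[exit_node]] == 0:
            phase = "G1"
        if t >= traj.steps_to_attractor:
            phase = "stationary_G1"
        labels.append(phase)
    return labels


def derive_phase_weights(
    net: RegulatoryNetwork,
    marker_nodes: Sequence[str],
    traj: Trajectory,
    phase_labels: Sequence[str],
    high: float = 0.9,
    low: float = 0.1,
) -> PhaseWeightMatrix:
    """Initialize weights from the biological trajectory: w_ij interpolates
    between ``low`` and ``high`` with the fraction of phase-j states in
    which marker i is on (soft version of the 1/0 seeding with manual
    softening)."""
    arr = np.stack([s.array() for s in traj.states])
    rows = {}
    for m in marker_nodes:
        col = arr[:, net.index[m]]
        rows[m] = {
            p: low
            + (high - low)
            * (
                float(np.mean([col[t] for t, lab in enumerate(phase_labels) if lab == p]))
                if any(lab == p for lab in phase_labels)
                else 0.0
            )
            for p in PHASES
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[list(PHASES)]
    return PhaseWeightMatrix(w=df)
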