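"""Packaged network fixtures and derived marker/weight tables.

``yeast_network`` is a *synthetic reconstruction* of the 56-node budding
yeast cell-cycle/sporulation network (44 proteins/complexes, 5 logical
AND nodes, the EMG/MMG gene groups, the cAMP/PKA pathway, the SPOR
phenotype and three signal nodes). Every interaction named in the source
narrative carries provenance ``main_text``; the remaining wiring needed
for a functioning model is tagged ``reconstructed``. It is a stand-in for
the originally curated network, whose full edge table was published only
as supplementary material; absolute basin sizes therefore differ from the
original study while the modelling machinery is unchanged.

``cell_cycle_toy`` is the classical 11-node synchronous Boolean model of
the yeast cell cycle (Cln3..Mcm1/SFF) whose dominant stationary-G1 fixed
point (basin 1764 of 2048) is a standard benchmark.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .dynamics import Condition
from .network import RegulatoryNetwork, load_network
from .phenotype import (
    ClassificationScheme,
    PhaseWeightMatrix,
    derive_phase_weights,
    segment_trajectory_phases,
)

_DATA = resources.files("refate") / "data"

# milestone nodes used to segment the excited trajectory into phases
YEAST_MILESTONES = dict(
    start_node="CLN3", clb_s="CLB5", clb_m="CLB2", exit_node="CDC20"
)
TOY_MILESTONES = dict(
    start_node="Cln3", clb_s="Clb56", clb_m="Clb12", exit_node="Cdc20"
)


def _load(name: str) -> RegulatoryNetwork:
    with resources.as_file(_DATA / name) as p:
        return load_network(p)


def yeast_network() -> RegulatoryNetwork:
    """The packaged 56-node cell-cycle/sporulation network (synthetic
    reconstruction; see module docstring)."""
    return _load("yeast56_synthetic.json")


def cell_cycle_toy() -> RegulatoryNetwork:
    """The 11-node yeast cell-cycle benchmark network."""
    return _load("cellcycle11.json")


def yeast_scheme(
    net: RegulatoryNetwork | None = None,
    n_init: int = 100_000,
    seed: int = 0,
) -> ClassificationScheme:
    """Marker scheme for the packaged yeast network (derived by sampling
    the growth-condition landscape)."""
    net = net or yeast_network()
    return ClassificationScheme.derive(net, n_init=n_init, seed=seed)


def yeast_phase_weights() -> PhaseWeightMatrix:
    """The packaged phase-weight table (generated from the excited
    cell-cycle trajectory of the synthetic network)."""
    with resources.as_file(_DATA / "phase_weights_synthetic.tsv") as p:
        return PhaseWeightMatrix.read_tsv(p)


def build_phase_weights(
    net: RegulatoryNetwork,
    scheme: ClassificationScheme,
    milestones: dict | None = None,
) -> PhaseWeightMatrix:
    """Re-derive the phase-weight table from the excited trajectory of
    the largest growth-condition attractor."""
    from .dynamics import Attractor, NetworkState, excited_trajectory

    milestones = milestones or YEAST_MILESTONES
    big = Attractor([NetworkState.from_bits(scheme.start_state)], period=1)
    traj = excited_trajectory(net, big)
    labels = segment_trajectory_phases(net, traj, **milestones)
    return derive_phase_weights(net, scheme.marker_nodes, traj, labels)
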