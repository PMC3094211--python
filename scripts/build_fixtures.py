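"""Regenerate the packaged network fixtures (maintenance tool).

The 56-node network is a synthetic reconstruction of the budding-yeast
cell-cycle/sporulation regulatory network assembled from the study
narrative; the 11-node toy is the classical synchronous cell-cycle
benchmark. Run from the repository root:

    python scripts/build_fixtures.py
"""
from pathlib import Path

from refate.network import NodeSpec, EdgeSpec, RegulatoryNetwork, write_network

# ---------------------------------------------------------------- 11-node toy
CC11_NODES = [
    ("Cln3", "degradation"),
    ("MBF", "sustaining"),
    ("SBF", "sustaining"),
    ("Cln12", "degradation"),
    ("Cdh1", "sustaining"),
    ("Swi5", "degradation"),
    ("Cdc20", "degradation"),
    ("Clb56", "sustaining"),
    ("Sic1", "sustaining"),
    ("Clb12", "sustaining"),
    ("Mcm1", "degradation"),
]
CC11_EDGES = [
    ("Cln3", "MBF", 1), ("Cln3", "SBF", 1),
    ("MBF", "Clb56", 1),
    ("SBF", "Cln12", 1),
    ("Cln12", "Sic1", -1), ("Cln12", "Cdh1", -1),
    ("Clb56", "Mcm1", 1), ("Clb56", "Clb12", 1),
    ("Clb56", "Sic1", -1), ("Clb56", "Cdh1", -1),
    ("Clb12", "Mcm1", 1), ("Clb12", "Cdc20", 1),
    ("Clb12", "Sic1", -1), ("Clb12", "Cdh1", -1),
    ("Clb12", "MBF", -1), ("Clb12", "SBF", -1), ("Clb12", "Swi5", -1),
    ("Mcm1", "Clb12", 1), ("Mcm1", "Cdc20", 1), ("Mcm1", "Swi5", 1),
    ("Cdc20", "Swi5", 1), ("Cdc20", "Cdh1", 1), ("Cdc20", "Sic1", 1),
    ("Cdc20", "Clb56", -1), ("Cdc20", "Clb12", -1),
    ("Swi5", "Sic1", 1),
    ("Sic1", "Clb56", -1), ("Sic1", "Clb12", -1),
    ("Cdh1", "Clb12", -1),
]

def build_cc11():
    nodes = [NodeSpec(id=i, label=i, kind="protein", self_mode=m) for i, m in CC11_NODES]
    edges = [EdgeSpec(s, t, g) for s, t, g in CC11_EDGES]
    return RegulatoryNetwork(nodes, edges)

# ------------------------------------------------------------ 56-node network
# P = protein, with (id, self_mode, perturbable)
Y_PROTEINS = [
    # cell cycle (20)
    ("CLN3", "degradation", True), ("CLN1", "degradation", True),
    ("CLN2", "degradation", True), ("MBF", "sustaining", False),
    ("SBF", "sustaining", False), ("CLB5", "degradation", True),
    ("CLB2", "degradation", True), ("MCM1_SFF", "degradation", True),
    ("CDH1", "sustaining", True), ("SIC1", "sustaining", True),
    ("CDC20", "degradation", True), ("CDC14", "degradation", True),
    ("SWI5", "degradation", True), ("ESP1", "activation", True),
    ("PDS1", "activation", True), ("SPO12", "degradation", True),
    ("CDC5", "degradation", True), ("SCF", "sustaining", True),
    ("GRR1", "sustaining", True), ("CDC28", "sustaining", True),
    # sporulation / signalling (24)
    ("IME1", "degradation", True), ("UME6", "activation", True),
    ("RIM11", "activation", True), ("IME2", "degradation", True),
    ("NDT80", "degradation", True), ("SUM1", "sustaining", True),
    ("HST1", "sustaining", True), ("RIM15", "degradation", True),
    ("MSN2", "sustaining", True), ("MSN4", "degradation", True),
    ("TUP1", "sustaining", True), ("MIG1", "sustaining", True),
    ("RPD3", "sustaining", True), ("GCN5", "sustaining", True),
    ("RIM4", "degradation", True), ("RME1", "degradation", True),
    ("SNF1", "degradation", True), ("SOK2", "degradation", True),
    ("RAS2", "degradation", True), ("SPS1", "degradation", True),
    ("SMK1", "degradation", True), ("AMA1", "degradation", True),
    ("SWE1", "degradation", True), ("MCK1", "degradation", True),
]

Y_SPECIAL = [
    NodeSpec("AND_FEAR", "FEAR network (Esp1*Spo12*Cdc5)", "logic_and", "sustaining", False),
    NodeSpec("AND_MIG1_TUP1", "Mig1-Tup1 corepressor complex", "logic_and", "sustaining", False),
    NodeSpec("AND_IME1_UME6_RIM11", "Ime1-Ume6-Rim11 complex", "logic_and", "sustaining", False),
    NodeSpec("AND_SUM1_HST1", "Sum1-Hst1 repressor complex", "logic_and", "sustaining", False),
    NodeSpec("AND_RIM15_MSN2", "Rim15-Msn2 starvation module", "logic_and", "sustaining", False),
    NodeSpec("EMG", "early meiotic genes", "gene_group", "degradation", False),
    NodeSpec("MMG", "middle meiotic genes", "gene_group", "degradation", False),
    NodeSpec("cAMP_PKA", "cAMP/PKA pathway", "pathway", "degradation", False),
    NodeSpec("SPOR", "sporulation phenotype", "phenotype", "sustaining", False),
    NodeSpec("CELL_SIZE", "cell size checkpoint signal", "signal", "sustaining", False),
    NodeSpec("GROWTH", "growth condition signal", "signal", "sustaining", False),
    NodeSpec("SPORULATION", "sporulation condition signal", "signal", "sustaining", False),
]

# (source, target, sign, provenance) -- "main_text" = named in the narrative
M, R = "main_text", "reconstructed"
Y_EDGES = [
    # cell-cycle backbone
    ("CELL_SIZE", "CLN3", 1, M),
    ("CLN3", "MBF", 1, M), ("CLN3", "SBF", 1, M),
    ("MBF", "CLB5", 1, M), ("SBF", "CLN1", 1, R), ("SBF", "CLN2", 1, R),
    ("CLN1", "SIC1", -1, R), ("CLN1", "CDH1", -1, R),
    ("CLN2", "SIC1", -1, R), ("CLN2", "CDH1", -1, R),
    ("CLB5", "MCM1_SFF", 1, M), ("CLB5", "CLB2", 1, R),
    ("CLB5", "SIC1", -1, R), ("CLB5", "CDH1", -1, R),
    ("CLB2", "MCM1_SFF", 1, R), ("CLB2", "CDC20", 1, R),
    ("CLB2", "SIC1", -1, R), ("CLB2", "CDH1", -1, R),
    ("CLB2", "MBF", -1, R), ("CLB2", "SBF", -1, R), ("CLB2", "SWI5", -1, R),
    ("MCM1_SFF", "CLB2", 1, M), ("MCM1_SFF", "CDC20", 1, R),
    ("MCM1_SFF", "SWI5", 1, R), ("MCM1_SFF", "SPO12", 1, R),
    ("MCM1_SFF", "CDC5", 1, R),
    ("CDC20", "CLB2", -1, R), ("CDC20", "CLB5", -1, R),
    ("CDC20", "PDS1", -1, R),
    ("PDS1", "ESP1", -1, R),
    ("ESP1", "AND_FEAR", 1, M), ("SPO12", "AND_FEAR", 1, M),
    ("CDC5", "AND_FEAR", 1, M),
    ("AND_FEAR", "CDC14", 1, M),
    ("CDC14", "CDH1", 1, R), ("CDC14", "SIC1", 1, R), ("CDC14", "SWI5", 1, R),
    ("SWI5", "SIC1", 1, R),
    ("SIC1", "CLB5", -1, R), ("SIC1", "CLB2", -1, M),
    ("CDH1", "CLB2", -1, M),
    ("GRR1", "SCF", 1, M),
    ("SWE1", "CLB2", -1, R),
    # growth signalling
    ("GROWTH", "cAMP_PKA", 1, R), ("GROWTH", "RAS2", 1, R),
    ("RAS2", "cAMP_PKA", 1, R),
    ("cAMP_PKA", "RIM15", -1, M), ("cAMP_PKA", "MSN2", -1, M),
    ("cAMP_PKA", "MSN4", -1, R), ("cAMP_PKA", "SOK2", 1, R),
    ("GROWTH", "MIG1", 1, M), ("SNF1", "MIG1", -1, R),
    ("SPORULATION", "SNF1", 1, R),
    ("GROWTH", "RME1", 1, R),
    ("RME1", "IME1", -1, M),
    ("SOK2", "IME1", -1, R),
    ("GROWTH", "IME1", -1, M),
    # sporulation cascade
    ("SPORULATION", "IME1", 1, R), ("SPORULATION", "RIM15", 1, R),
    ("SPORULATION", "MSN4", 1, R), ("SPORULATION", "MCK1", 1, R),
    ("RIM15", "AND_RIM15_MSN2", 1, R), ("MSN2", "AND_RIM15_MSN2", 1, R),
    ("AND_RIM15_MSN2", "IME1", 1, M),
    ("MSN4", "IME1", 1, M), ("MCK1", "IME1", 1, R),
    ("IME1", "AND_IME1_UME6_RIM11", 1, M),
    ("UME6", "AND_IME1_UME6_RIM11", 1, M),
    ("RIM11", "AND_IME1_UME6_RIM11", 1, M),
    ("AND_IME1_UME6_RIM11", "EMG", 1, M),
    ("cAMP_PKA", "RIM11", -1, R),
    ("GCN5", "EMG", 1, R), ("RPD3", "EMG", -1, M),
    ("EMG", "NDT80", 1, M), ("EMG", "IME2", 1, M), ("EMG", "RIM4", 1, R),
    ("SUM1", "NDT80", -1, M), ("SUM1", "MMG", -1, M),
    ("IME2", "SUM1", -1, M),
    ("NDT80", "MMG", 1, M), ("NDT80", "IME1", 1, M), ("NDT80", "IME2", 1, M),
    ("MMG", "NDT80", 1, R),
    ("RIM4", "MMG", 1, R),
    ("SUM1", "AND_SUM1_HST1", 1, R), ("HST1", "AND_SUM1_HST1", 1, R),
    ("AND_SUM1_HST1", "MMG", -1, R),
    ("MIG1", "AND_MIG1_TUP1", 1, M), ("TUP1", "AND_MIG1_TUP1", 1, M),
    ("AND_MIG1_TUP1", "RPD3", 1, M),
    ("MMG", "SPS1", 1, R), ("MMG", "SMK1", 1, R), ("MMG", "AMA1", 1, R),
    ("EMG", "SPOR", 1, M), ("MMG", "SPOR", 1, M),
]

def build_yeast():
    nodes = [
        NodeSpec(id=i, label=i, kind="protein", self_mode=m, perturbable=p)
        for i, m, p in Y_PROTEINS
    ] + Y_SPECIAL
    edges = [EdgeSpec(s, t, g, prov) for s, t, g, prov in Y_EDGES]
    return RegulatoryNetwork(
        nodes, edges,
        condition_signals={"growth": "GROWTH", "sporulation": "SPORULATION"},
        cell_size_signal="CELL_SIZE",
        spor_node="SPOR",
    )

if __name__ == "__main__":
    cc11 = build_cc11()
    print("cc11 ok:", cc11)
    y = build_yeast()
    print("yeast ok:", y, "proteins:",
          sum(1 for n in y.nodes if n.kind == "protein"),
          "perturbable:", len(y.perturbable_nodes()))
    data = Path(__file__).resolve().parent.parent / "src" / "refate" / "data"
    write_network(cc11, data / "cellcycle11.json")
    write_network(y, data / "yeast56_synthetic.json")
    # regenerate the phase-weight table from the excited trajectory
    from refate.phenotype import ClassificationScheme
    from refate.datasets import build_phase_weights

    scheme = ClassificationScheme.derive(y, n_init=100_000, seed=0)
    w = build_phase_weights(y, scheme)
    w.write_tsv(data / "phase_weights_synthetic.tsv")
    print("written")
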