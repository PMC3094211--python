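"""Attractor classification, phase scoring, viability, sporulation
efficiency and evaluation statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refate.dynamics import Attractor, Condition, NetworkState
from refate.phenotype import (
    CELL_CYCLE,
    OTHER,
    PHASES,
    SPORULATION,
    ClassificationScheme,
    ConfusionCounts,
    PhaseWeightMatrix,
    assign_phase,
    check_viability,
    class_fractions,
    classify_attractor,
    evaluate_against_table,
    mcc,
    predicted_prespo_spore_ratio,
    sporulation_fraction,
)


def _attr(bits):
    return Attractor([NetworkState.from_bits(np.array(bits, dtype=np.uint8))], 1)


# ------------------------------------------------------------- classification

def test_classify_sporulation_takes_precedence(toy_spor, toy_spor_scheme):
    # SP on (last bit) wins even if the marker matches the reference
    bits = [0, 0, 1, 0, 0, 1, 1, 1]  # X1=1 matches ref, SP=1
    assert classify_attractor(_attr(bits), toy_spor_scheme) == SPORULATION


def test_classify_marker_match_ignores_non_marker_nodes(toy_spor_scheme):
    a = [0, 0, 1, 0, 0, 0, 0, 0]
    b = [0, 0, 1, 1, 1, 0, 0, 0]  # differs only at non-marker nodes
    assert classify_attractor(_attr(a), toy_spor_scheme) == CELL_CYCLE
    assert classify_attractor(_attr(b), toy_spor_scheme) == CELL_CYCLE


def test_classify_marker_mismatch_is_other(toy_spor_scheme):
    assert classify_attractor(_attr([0] * 8), toy_spor_scheme) == OTHER


def test_classify_is_a_partition(toy_spor, toy_spor_scheme):
    from refate.dynamics import enumerate_attractors

    for name in ("growth", "sporulation", "none"):
        cond = Condition.for_network(toy_spor, name)
        res = enumerate_attractors(toy_spor, cond)
        for a in res.attractors:
            label = classify_attractor(a, toy_spor_scheme)
            assert label in (SPORULATION, CELL_CYCLE, OTHER)


def test_classify_cycle_requires_label_in_all_states(toy_spor_scheme):
    on = NetworkState.from_bits(np.array([0, 0, 1, 0, 0, 1, 1, 1], dtype=np.uint8))
    off = NetworkState.from_bits(np.array([0, 0, 1, 0, 0, 0, 0, 0], dtype=np.uint8))
    cyc = Attractor([on, off], period=2)
    assert classify_attractor(cyc, toy_spor_scheme) != SPORULATION


# --------------------------------------------------------- sporulation fraction

def test_sporulation_fraction_matches_enumeration(toy_spor, toy_spor_scheme):
    from refate.dynamics import enumerate_attractors

    cond = Condition.for_network(toy_spor, "sporulation")
    res = enumerate_attractors(toy_spor, cond)
    exact = sum(
        a.basin_count
        for a in res.attractors
        if classify_attractor(a, toy_spor_scheme) == SPORULATION
    ) / res.n_sampled
    n = 4000
    frac = sporulation_fraction(toy_spor, None, cond, n=n, seed=3,
                                scheme=toy_spor_scheme)
    se = math.sqrt(exact * (1 - exact) / n)
    assert abs(frac - exact) <= 3 * se + 1e-12


def test_sporulation_fraction_zero_when_spor_clamped_off(toy_spor, toy_spor_scheme):
    cond = Condition.for_network(toy_spor, "sporulation")
    for seed in (0, 1):
        assert sporulation_fraction(
            toy_spor, {"SP": 0}, cond, n=500, seed=seed, scheme=toy_spor_scheme
        ) == 0.0


def test_sporulation_fraction_one_when_spor_clamped_on(toy_spor, toy_spor_scheme):
    cond = Condition.for_network(toy_spor, "growth")
    assert sporulation_fraction(
        toy_spor, {"SP": 1}, cond, n=500, seed=0, scheme=toy_spor_scheme
    ) == 1.0


def test_prespo_spore_ratio():
    assert predicted_prespo_spore_ratio(0.16, 0.16) == 1.0
    assert predicted_prespo_spore_ratio(0.5, 0.25) == 2.0
    assert predicted_prespo_spore_ratio(0.5, 0.0) == math.inf
    with pytest.raises(ValueError):
        predicted_prespo_spore_ratio(0.0, 0.5)


# ------------------------------------------------------------------- phases

def _uniform_weights(nodes=("m1", "m2"), value=0.5):
    return PhaseWeightMatrix(
        w=pd.DataFrame({p: [value] * len(nodes) for p in PHASES}, index=list(nodes))
    )


def test_assign_phase_uniform_weights_tie():
    call = assign_phase({"m1": 1, "m2": 0}, _uniform_weights())
    assert call.tie
    assert call.phase == PHASES[0]
    assert all(abs(v - 1 / 6) < 1e-12 for v in call.scores.values())


def test_assign_phase_delta_weight():
    w = pd.DataFrame({p: [1.0 if p == "S" else 0.0] for p in PHASES}, index=["m"])
    call = assign_phase({"m": 1}, PhaseWeightMatrix(w=w))
    assert call.phase == "S" and call.scores["S"] == 1.0 and not call.tie


def test_assign_phase_unassignable_when_all_scores_zero():
    w = pd.DataFrame({p: [1.0] for p in PHASES}, index=["m"])
    call = assign_phase({"m": 0}, PhaseWeightMatrix(w=w))
    assert call.unassignable and call.phase is None


def test_assign_phase_scores_normalized_and_monotone():
    w = pd.DataFrame(
        {p: [0.6, 0.3] for p in PHASES}, index=["m1", "m2"]
    )
    state = {"m1": 1, "m2": 1}
    base = assign_phase(state, PhaseWeightMatrix(w=w.copy()))
    assert abs(sum(base.scores.values()) - 1.0) < 1e-12
    # raising w for a phase consistent with the state raises its score
    w2 = w.copy()
    w2.loc["m1", "G2"] = 0.9
    bumped = assign_phase(state, PhaseWeightMatrix(w=w2))
    assert bumped.scores["G2"] > base.scores["G2"]


def test_weight_matrix_rejects_out_of_range():
    w = pd.DataFrame({p: [1.2] for p in PHASES}, index=["m"])
    with pytest.raises(ValueError):
        PhaseWeightMatrix(w=w)


def test_weight_tsv_round_trip(tmp_path, weights_fx):
    p = tmp_path / "w.tsv"
    weights_fx.write_tsv(p)
    back = PhaseWeightMatrix.read_tsv(p)
    pd.testing.assert_frame_equal(back.w, weights_fx.w)


# ----------------------------------------------------------------- viability

def test_wild_type_is_viable_with_canonical_phase_order(
    yeast, yeast_scheme_fx, weights_fx
):
    call = check_viability(yeast, None, yeast_scheme_fx, weights_fx)
    assert call.viable
    assert call.phase_sequence in (
        ["START", "G1", "S", "G2", "M", "stationary_G1"],
        ["START", "G1", "S", "G2", "M", "G1", "stationary_G1"],
    )


@pytest.mark.parametrize("mutant", [{"CLB2": 0}, {"CLB5": 0}, {"CDC20": 0}])
def test_cell_cycle_mutants_are_inviable(yeast, yeast_scheme_fx, weights_fx, mutant):
    assert not check_viability(yeast, mutant, yeast_scheme_fx, weights_fx).viable


@pytest.mark.parametrize("mutant", [{"IME1": 0}, {"NDT80": 0}, {"TUP1": 0}])
def test_sporulation_mutants_stay_viable(yeast, yeast_scheme_fx, weights_fx, mutant):
    assert check_viability(yeast, mutant, yeast_scheme_fx, weights_fx).viable


def test_mutation_identical_to_wild_type_gets_same_call(
    yeast, yeast_scheme_fx, weights_fx
):
    # clamping a signal to its condition value changes nothing
    wt = check_viability(yeast, None, yeast_scheme_fx, weights_fx)
    same = check_viability(yeast, {"GROWTH": 1}, yeast_scheme_fx, weights_fx)
    assert wt.viable == same.viable
    assert wt.phase_sequence == same.phase_sequence


# ----------------------------------------------------------------- statistics

def test_mcc_perfect_zero_and_balanced():
    assert mcc(ConfusionCounts(36, 40, 0, 0)) == 1.0
    c = ConfusionCounts(0, 40, 0, 36)
    assert mcc(c) == 0.0
    assert abs(c.accuracy - 40 / 76) < 1e-12
    assert mcc(ConfusionCounts(1, 1, 1, 1)) == 0.0


@given(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_mcc_symmetries(tp, tn, fp, fn):
    if tp + tn + fp + fn == 0:
        return
    v = mcc(ConfusionCounts(tp, tn, fp, fn))
    assert -1.0 <= v <= 1.0
    assert mcc(ConfusionCounts(tn, tp, fn, fp)) == pytest.approx(v)
    # flipping every prediction negates the score
    assert mcc(ConfusionCounts(fp, fn, tp, tn)) == pytest.approx(-v)


def test_mcc_rejects_negative_counts():
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 0)


def test_evaluate_identity_and_anti_identity():
    pred = {f"m{i}": float(i) for i in range(8)}
    table = pd.DataFrame(
        {"value": [float(i) for i in range(8)]},
        index=pd.Index([f"m{i}" for i in range(8)], name="mutant_id"),
    )
    res = evaluate_against_table(pred, table)
    assert res["pearson_r"] == pytest.approx(1.0)
    assert res["spearman_rho"] == pytest.approx(1.0)
    neg = table.assign(value=-table["value"])
    res2 = evaluate_against_table(pred, neg)
    assert res2["pearson_r"] == pytest.approx(-1.0)


def test_evaluate_recovers_planted_monotone_correlation():
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 2, 400)
    noise = rng.normal(0, 0.15, 400)
    y = np.exp(x) + noise  # monotone transform + noise
    target_rho = 0.98  # frozen from this generator's construction
    pred = {f"m{i}": float(v) for i, v in enumerate(x)}
    table = pd.DataFrame(
        {"value": y}, index=pd.Index([f"m{i}" for i in range(400)], name="mutant_id")
    )
    res = evaluate_against_table(pred, table)
    from scipy.stats import spearmanr

    direct_rho = spearmanr(x, y).statistic
    assert res["spearman_rho"] == pytest.approx(direct_rho)
    assert abs(res["spearman_rho"] - target_rho) < 0.05


def test_evaluate_categorical_table_gives_accuracy_and_mcc():
    pred = {"a": "viable", "b": "viable", "c": "inviable", "d": "inviable"}
    table = pd.DataFrame(
        {"value": ["viable", "inviable", "inviable", "inviable"]},
        index=pd.Index(list("abcd"), name="mutant_id"),
    )
    res = evaluate_against_table(pred, table)
    assert res["accuracy"] == 0.75
    assert res["mcc"] == pytest.approx(mcc(ConfusionCounts(1, 2, 1, 0)))


def test_evaluate_requires_three_shared_mutants():
    table = pd.DataFrame(
        {"value": [1.0, 2.0]}, index=pd.Index(["a", "b"], name="mutant_id")
    )
    with pytest.raises(ValueError, match="shared"):
        evaluate_against_table({"a": 1.0, "b": 2.0}, table)
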