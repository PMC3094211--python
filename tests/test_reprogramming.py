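"""Recipe enumeration, potency/efficiency, commitment, heterogeneity and
Pareto filtering, with exhaustive-enumeration oracles on small networks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refate.dynamics import Condition, enumerate_attractors, evolve, evolve_batch, all_states
from refate.phenotype import CELL_CYCLE, SPORULATION, classify_attractor
from refate.reprogramming import (
    CommitmentSet,
    HeterogeneityProfile,
    Recipe,
    RecipeScore,
    commitment_analysis,
    efficiency,
    enumerate_recipes,
    evolving_distance,
    heterogeneity_deviation,
    heterogeneity_profile,
    pareto_front,
    perturbation_frequencies,
    potency,
    recipe_count,
    wild_type_cell_cycle_attractors,
)


# ------------------------------------------------------------------ recipes

def test_recipe_validation_and_parsing():
    r = Recipe.parse("GCN5:OE+RPD3:KD")
    assert r.perturbations == (("GCN5", "OE"), ("RPD3", "KD"))
    assert r.values() == {"GCN5": 1, "RPD3": 0}
    assert str(r) == "GCN5:OE+RPD3:KD"
    with pytest.raises(ValueError, match="once"):
        Recipe((("A", "OE"), ("A", "KD")))
    with pytest.raises(ValueError):
        Recipe((("A", "UP"),))


def test_enumerate_recipes_counts():
    it, n = enumerate_recipes(["a", "b"], max_size=1)
    assert n == 4 and len(list(it)) == 4
    it, n = enumerate_recipes(["a", "b", "c"], max_size=2)
    mat = list(it)
    assert n == 18 and len(mat) == 18  # 3*2 + 3*4
    assert len(set(map(str, mat))) == 18  # no duplicates


@pytest.mark.parametrize("n_nodes", range(1, 9))
@pytest.mark.parametrize("max_size", range(1, 5))
def test_enumeration_count_identity(n_nodes, max_size):
    nodes = [f"p{i}" for i in range(n_nodes)]
    it, count = enumerate_recipes(nodes, max_size=max_size)
    mat = {str(r) for r in it}
    assert len(mat) == count == sum(
        math.comb(n_nodes, k) * 2**k for k in range(1, max_size + 1)
    )


def test_enumerate_recipes_rejects_empty_set():
    with pytest.raises(ValueError):
        enumerate_recipes([], max_size=2)


# ------------------------------------------------------------------- potency

def _exact_class_fractions(net, condition, scheme, overrides=None, clamps=None):
    """Oracle: evolve every free-node state and tally classes exactly."""
    from refate.dynamics import _clamp_arrays

    cidx, _ = _clamp_arrays(net, condition.clamps)
    free = np.array(
        [i for i in range(net.n_nodes) if i not in set(int(c) for c in cidx)]
    )
    S = all_states(len(free), free, net.n_nodes)
    rows, _s, _ = evolve_batch(net, S, condition, overrides=overrides, clamps=clamps)
    out = {}
    for a in rows:
        lab = classify_attractor(a, scheme)
        out[lab] = out.get(lab, 0) + 1
    return {k: v / S.shape[0] for k, v in out.items()}


def test_potency_noop_recipe_equals_baseline_fractions(toy_spor, toy_spor_scheme):
    cond = Condition.for_network(toy_spor, "growth")
    base = potency(toy_spor, None, cond, SPORULATION, toy_spor_scheme,
                   n=2000, seed=4)
    from refate.phenotype import class_fractions

    frac = class_fractions(toy_spor, cond, toy_spor_scheme, n=2000, seed=4)
    assert base.class_fractions == frac


def test_potency_matches_enumeration_for_clamped_recipe(toy_spor, toy_spor_scheme):
    cond = Condition.for_network(toy_spor, "growth")
    recipe = Recipe((("B", "KD"), ("A", "OE")), mode="clamped")
    exact = _exact_class_fractions(
        toy_spor, cond, toy_spor_scheme, clamps=recipe.values()
    ).get(SPORULATION, 0.0)
    n = 4000
    score = potency(toy_spor, recipe, cond, SPORULATION, toy_spor_scheme,
                    n=n, seed=0)
    se = math.sqrt(max(exact * (1 - exact), 1e-9) / n)
    assert abs(score.potency - exact) <= 3 * se + 1e-12


def test_potency_zero_when_clamps_forbid_target(toy_spor, toy_spor_scheme):
    # clamping the meiotic module off makes the sporulation class impossible
    cond = Condition.for_network(toy_spor, "sporulation")
    recipe = Recipe((("A", "KD"), ("E", "KD")), mode="clamped")
    score = potency(toy_spor, recipe, cond, SPORULATION, toy_spor_scheme,
                    n=1000, seed=1)
    assert score.potency == 0.0


def test_reprogramming_flag_reversal_criterion(toy_spor, toy_spor_scheme):
    cond = Condition.for_network(toy_spor, "growth")
    # transient meiosis induction: E on, B off
    recipe = Recipe((("E", "OE"), ("B", "KD")))
    score = potency(toy_spor, recipe, cond, SPORULATION, toy_spor_scheme,
                    n=2000, seed=2)
    assert score.reprogramming_flag == (
        score.class_fractions[SPORULATION] > score.class_fractions[CELL_CYCLE]
    )


# --------------------------------------------------------- evolving distance

def test_evolving_distance_trivial_cases(toy_spor):
    cond = Condition.for_network(toy_spor, "growth")
    attr_state = evolve(
        toy_spor, np.zeros(8, dtype=np.uint8), cond
    ).attractor.states[0]
    d, _ = evolving_distance(toy_spor, attr_state.array(), cond)
    assert d == 0


def test_evolving_distance_matches_exhaustive_bfs():
    """All 64 states of a 6-node net: step count to the attractor equals
    the depth found by walking the full deterministic transition table."""
    from conftest import random_small_net, oracle_trajectory

    net = random_small_net(123, n_lo=6, n_hi=6)
    cond = Condition(name="none")
    ids = net.node_ids()
    for key in range(64):
        bits = np.array([(key >> i) & 1 for i in range(6)], dtype=np.uint8)
        d, _ = evolving_distance(net, bits, cond)
        _states, cyc = oracle_trajectory(net, dict(zip(ids, map(int, bits))))
        assert d == cyc


# ----------------------------------------------------- commitment & efficiency

def test_commitment_curves_match_exhaustive_recomputation(toy_spor, toy_spor_scheme):
    cset, curve = commitment_analysis(
        toy_spor, toy_spor_scheme, n_basins=2000, seed=0
    )
    # recompute per-bin reprogrammed fraction directly from the stored states
    growth = Condition.for_network(toy_spor, "growth")
    for row in curve.itertuples():
        mask = cset.distances == row.d
        states = cset.states[mask]
        rows, _s, _ = evolve_batch(toy_spor, states, growth)
        frac = np.mean([
            classify_attractor(a, toy_spor_scheme) == CELL_CYCLE for a in rows
        ])
        assert frac == pytest.approx(row.fraction_reprogrammed)
    # committed = close to the attractor and not switch-reprogrammable
    assert np.array_equal(
        cset.committed, (cset.distances <= 4) & ~cset.switch_reprogrammed
    )


def test_sporulation_attractor_state_is_committed_when_stable(toy_spor, toy_spor_scheme):
    cset, _ = commitment_analysis(toy_spor, toy_spor_scheme, n_basins=500, seed=1)
    d0 = cset.distances == 0
    assert d0.any()
    # d=0 states are sporulation attractor states; committed iff the
    # condition switch alone fails
    assert np.array_equal(cset.committed[d0], ~cset.switch_reprogrammed[d0])


def test_efficiency_exact_on_enumerated_committed_set(toy_spor, toy_spor_scheme):
    cset, _ = commitment_analysis(toy_spor, toy_spor_scheme, n_basins=3000, seed=2)
    pool = cset.committed_states()
    assert pool.shape[0] > 0
    recipe = Recipe((("B", "OE"),))  # repress the meiotic module
    growth = Condition.for_network(toy_spor, "growth")
    rows, _s, _ = evolve_batch(
        toy_spor, pool, growth, overrides=recipe.values()
    )
    exact = np.mean([
        classify_attractor(a, toy_spor_scheme) == CELL_CYCLE for a in rows
    ])
    n = 3000
    est = efficiency(toy_spor, recipe, cset, toy_spor_scheme, n=n, seed=3)
    se = math.sqrt(max(exact * (1 - exact), 1e-9) / n)
    assert abs(est - exact) <= 3 * se + 1e-12
    assert 0.0 <= est <= 1.0


def test_efficiency_rejects_empty_committed_set(toy_spor, toy_spor_scheme):
    empty = CommitmentSet(
        states=np.zeros((0, 8), dtype=np.uint8),
        distances=np.zeros(0, dtype=int),
        switch_reprogrammed=np.zeros(0, dtype=bool),
        committed=np.zeros(0, dtype=bool),
    )
    with pytest.raises(ValueError):
        efficiency(toy_spor, Recipe((("B", "OE"),)), empty, toy_spor_scheme)


# ------------------------------------------------------------- heterogeneity

def test_heterogeneity_profile_deterministic_and_exact(toy_spor, toy_spor_scheme):
    refs = wild_type_cell_cycle_attractors(
        toy_spor, toy_spor_scheme, n=2000, seed=0
    )
    assert refs  # growth condition has cell-cycle attractors
    p1 = heterogeneity_profile(toy_spor, None, refs, toy_spor_scheme, n=1000, seed=5)
    p2 = heterogeneity_profile(toy_spor, None, refs, toy_spor_scheme, n=1000, seed=5)
    assert np.array_equal(p1.fractions, p2.fractions)
    # exact check against enumeration
    cond = Condition.for_network(toy_spor, "growth")
    res = enumerate_attractors(toy_spor, cond)
    exact = {a.canonical_key: a.basin_count / res.n_sampled for a in res.attractors}
    big = heterogeneity_profile(toy_spor, None, refs, toy_spor_scheme, n=20000, seed=6)
    for k, f in zip(big.attractor_keys, big.fractions):
        se = math.sqrt(max(exact.get(k, 0) * (1 - exact.get(k, 0)), 1e-9) / 20000)
        assert abs(f - exact.get(k, 0.0)) <= 4 * se + 1e-12


def test_heterogeneity_deviation_examples():
    assert heterogeneity_deviation(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 0.0
    assert heterogeneity_deviation(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0
    assert heterogeneity_deviation(
        np.array([0.5, 0.5]), np.array([0.75, 0.25])
    ) == pytest.approx(0.25)
    # renormalization: scaling a profile changes nothing
    assert heterogeneity_deviation(
        np.array([0.2, 0.2]), np.array([0.5, 0.5])
    ) == 0.0


@given(
    st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
    st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
    st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_heterogeneity_deviation_is_a_metric(a, b, c):
    a, b, c = (np.array(v) for v in (a, b, c))
    if a.sum() == 0 or b.sum() == 0 or c.sum() == 0:
        return
    dab = heterogeneity_deviation(a, b)
    assert 0.0 <= dab <= 1.0
    assert dab == heterogeneity_deviation(b, a)
    if dab == 0.0:
        assert np.allclose(a / a.sum(), b / b.sum())
    assert dab <= heterogeneity_deviation(a, c) + heterogeneity_deviation(c, b) + 1e-12


def test_heterogeneity_deviation_mismatched_lengths():
    with pytest.raises(ValueError):
        heterogeneity_deviation(np.array([1.0]), np.array([0.5, 0.5]))


# -------------------------------------------------------------------- pareto

def _score(eff, dev):
    return RecipeScore(
        recipe=Recipe((("A", "OE"),)), efficiency=eff, heterogeneity_deviation=dev
    )


def test_pareto_trivial_cases():
    s = _score(0.5, 0.3)
    assert pareto_front([s]) == [s]
    dominant, dominated = _score(0.9, 0.1), _score(0.2, 0.8)
    assert pareto_front([dominant, dominated]) == [dominant]
    assert pareto_front([]) == []


def test_pareto_equals_quadratic_brute_force():
    rng = np.random.default_rng(0)
    scores = [_score(float(e), float(d))
              for e, d in rng.uniform(0, 1, size=(50, 2))]
    front = pareto_front(scores)
    brute = [
        s for s in scores
        if not any(
            o.efficiency >= s.efficiency
            and o.heterogeneity_deviation <= s.heterogeneity_deviation
            and (o.efficiency, o.heterogeneity_deviation)
            != (s.efficiency, s.heterogeneity_deviation)
            for o in scores
        )
    ]
    assert {(s.efficiency, s.heterogeneity_deviation) for s in front} == {
        (s.efficiency, s.heterogeneity_deviation) for s in brute
    }


# --------------------------------------------------------------- frequencies

def test_perturbation_frequencies_planted():
    recipes = [
        Recipe((("TUP1", "KD"), ("A", "OE"), ("B", "OE"), ("C", "OE")))
        for _ in range(100)
    ]
    df = perturbation_frequencies(recipes)
    freq = {(r.node, r.direction): r.frequency for r in df.itertuples()}
    assert freq[("TUP1", "KD")] == pytest.approx(0.25)
    assert df["frequency"].sum() == pytest.approx(1.0)


def test_perturbation_frequencies_recover_mixture():
    recipes = (
        [Recipe((("X", "OE"),))] * 3 + [Recipe((("Y", "KD"), ("X", "OE")))] * 2
    )
    df = perturbation_frequencies(recipes)
    freq = {(r.node, r.direction): r.frequency for r in df.itertuples()}
    assert freq[("X", "OE")] == pytest.approx(5 / 7)
    assert freq[("Y", "KD")] == pytest.approx(2 / 7)
    with pytest.raises(ValueError):
        perturbation_frequencies([])
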