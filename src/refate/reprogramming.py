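"""Reprogramming-recipe search and scoring.

A recipe is a set of 1-4 protein perturbations, each overexpression (OE,
node initialized/clamped to 1) or knockdown (KD, to 0). Transient recipes
set the bits only at t=0 (iPS-style induction); clamped recipes pin them
at every step (stable mutants). Potency is measured over all random
initial states, efficiency over states already committed to the source
fate, and heterogeneity deviation compares the distribution of
reprogrammed cells over the wild type's attractors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    Attractor,
    Condition,
    evolve,
    evolve_batch,
    random_initial_states,
)
from .network import RegulatoryNetwork
from .phenotype import CELL_CYCLE, OTHER, SPORULATION, ClassificationScheme

DIRECTIONS = ("OE", "KD")


@dataclass(frozen=True)
class Recipe:
    perturbations: tuple[tuple[str, str], ...]
    mode: str = "transient"

    def __post_init__(self) -> None:
        nodes = [n for n, _ in self.perturbations]
        if len(set(nodes)) != len(nodes):
            raise ValueError("a node may appear only once in a recipe")
        for n, d in self.perturbations:
            if d not in DIRECTIONS:
                raise ValueError(f"direction must be OE or KD, got {d!r}")
        if self.mode not in ("transient", "clamped"):
            raise ValueError(f"unknown recipe mode {self.mode!r}")

    @classmethod
    def parse(cls, text: str, mode: str = "transient") -> "Recipe":
        """Parse 'GCN5:OE+RPD3:KD+...' recipe strings."""
        perts = []
        for tok in text.split("+"):
            node, _, direction = tok.strip().partition(":")
            perts.append((node, direction))
        return cls(tuple(perts), mode=mode)

    def __str__(self) -> str:
        return "+".join(f"{n}:{d}" for n, d in self.perturbations)

    def values(self) -> dict[str, int]:
        return {n: 1 if d == "OE" else 0 for n, d in self.perturbations}

    def size(self) -> int:
        return len(self.perturbations)


@dataclass
class RecipeScore:
    recipe: Recipe
    potency: float = math.nan
    efficiency: float = math.nan
    heterogeneity_deviation: float = math.nan
    restored_attractors: int = 0
    reprogramming_flag: bool = False
    class_fractions: dict = field(default_factory=dict)


def recipe_count(n_perturbable: int, max_size: int = 4) -> int:
    """Closed form: sum over k=1..max_size of C(n, k) * 2**k."""
    return sum(
        math.comb(n_perturbable, k) * 2**k for k in range(1, max_size + 1)
    )


def enumerate_recipes(
    perturbable: Sequence[str], max_size: int = 4, mode: str = "transient"
) -> tuple[Iterator[Recipe], int]:
    """All perturbation combinations of 1..max_size nodes crossed with all
    OE/KD assignments, each exactly once, in deterministic order."""
    if not perturbable:
        raise ValueError("perturbable set is empty")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    nodes = list(perturbable)

    def gen() -> Iterator[Recipe]:
        for k in range(1, max_size + 1):
            for combo in itertools.combinations(nodes, k):
                for dirs in itertools.product(DIRECTIONS, repeat=k):
                    yield Recipe(tuple(zip(combo, dirs)), mode=mode)

    return gen(), recipe_count(len(nodes), max_size)


def _recipe_kwargs(recipe: Recipe | None) -> dict:
    if recipe is None:
        return {}
    if recipe.mode == "transient":
        return {"overrides": recipe.values()}
    return {"clamps": recipe.values()}


def _classify_rows(row_attr, scheme: ClassificationScheme) -> list[str]:
    cache: dict[tuple, str] = {}
    out = []
    for a in row_attr:
        ck = a.canonical_key
        if ck not in cache:
            cache[ck] = scheme.classify(a)
        out.append(cache[ck])
    return out


_PREFERRED = {"growth": CELL_CYCLE, "sporulation": SPORULATION}


def potency(
    net: RegulatoryNetwork,
    recipe: Recipe | None,
    condition: Condition,
    target_class: str,
    scheme: ClassificationScheme,
    n: int = 10_000,
    seed: int = 0,
    max_steps: int = 1000,
) -> RecipeScore:
    """Fraction of random initial states driven into the target class.

    The reprogramming flag is set when, under the perturbation, the target
    class outweighs the class the wild type prefers under this condition
    (for the no-signal condition: the non-target of cell cycle vs
    sporulation).
    """
    if target_class not in (CELL_CYCLE, SPORULATION):
        raise ValueError("target_class must be cell_cycle or sporulation")
    rng = np.random.default_rng(seed)
    S = random_initial_states(net, n, condition, rng)
    row_attr, _steps, _ = evolve_batch(
        net, S, condition, max_steps=max_steps, **_recipe_kwargs(recipe)
    )
    labels = _classify_rows(row_attr, scheme)
    frac = {
        c: labels.count(c) / n for c in (SPORULATION, CELL_CYCLE, OTHER)
    }
    preferred = _PREFERRED.get(
        condition.name,
        CELL_CYCLE if target_class == SPORULATION else SPORULATION,
    )
    flag = frac[target_class] > frac[preferred] if preferred != target_class else True
    return RecipeScore(
        recipe=recipe if recipe is not None else Recipe(()),
        potency=frac[target_class],
        reprogramming_flag=flag,
        class_fractions=frac,
    )


def evolving_distance(
    net: RegulatoryNetwork,
    state: np.ndarray,
    condition: Condition,
    max_steps: int = 1000,
) -> tuple[int, Attractor]:
    """Number of synchronous steps from the state to the first attractor
    state under the condition."""
    traj = evolve(net, state, condition, max_steps=max_steps)
    return traj.steps_to_attractor, traj.attractor


@dataclass
class CommitmentSet:
    """Sporulation-basin states with their evolving distance to the
    attractor and commitment flags (d <= depth and not reprogrammable by
    the condition switch alone)."""

    states: np.ndarray  # (m, n) unique basin states
    distances: np.ndarray  # (m,) steps to the sporulation attractor
    switch_reprogrammed: np.ndarray  # (m,) bool, condition switch alone works
    committed: np.ndarray  # (m,) bool
    depth: int = 4

    def committed_states(self) -> np.ndarray:
        return self.states[self.committed]


def harvest_sporulation_basin(
    net: RegulatoryNetwork,
    scheme: ClassificationScheme,
    n_basins: int,
    seed: int = 0,
    condition: Condition | None = None,
    max_steps: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Evolve ``n_basins`` random initial states under the sporulation
    condition and record every state (initial + on-path, de-duplicated)
    of trajectories that converge to sporulation attractors, together
    with its evolving distance to the attractor."""
    cond = condition or Condition.for_network(net, "sporulation")
    rng = np.random.default_rng(seed)
    S = random_initial_states(net, n_basins, cond, rng)
    comp = net.compiled()
    seen: dict[int, int] = {}
    states: list[np.ndarray] = []
    for i in range(S.shape[0]):
        traj = evolve(net, S[i], cond, max_steps=max_steps)
        if scheme.classify(traj.attractor) != SPORULATION:
            continue
        k = traj.steps_to_attractor
        for pos, st in enumerate(traj.states):
            d = max(k - pos, 0)
            if st.key not in seen:
                seen[st.key] = d
                states.append(st.array())
    if not states:
        return np.zeros((0, net.n_nodes), dtype=np.uint8), np.zeros(0, dtype=int)
    return np.stack(states), np.array(
        [seen[int(comp.encode(s.reshape(1, -1))[0])] for s in states], dtype=int
    )


def commitment_analysis(
    net: RegulatoryNetwork,
    scheme: ClassificationScheme,
    n_basins: int = 10_000,
    seed: int = 0,
    recipe: Recipe | None = None,
    depth: int = 4,
    max_steps: int = 1000,
) -> tuple[CommitmentSet, pd.DataFrame]:
    """Commitment to sporulation and reprogrammed fraction by distance.

    Harvests sporulation-basin states, bins them by evolving distance d,
    re-evolves each under the growth condition (optionally with a recipe)
    and reports the per-bin fraction that reaches cell-cycle attractors.
    The commitment flags always refer to the wild-type condition switch.
    """
    states, dists = harvest_sporulation_basin(net, scheme, n_basins, seed=seed,
                                              max_steps=max_steps)
    growth = Condition.for_network(net, "growth")
    if states.shape[0] == 0:
        empty = CommitmentSet(states, dists, np.zeros(0, bool), np.zeros(0, bool), depth)
        return empty, pd.DataFrame(columns=["d", "n", "fraction_reprogrammed"])
    row_attr, _s, _ = evolve_batch(net, states, growth, max_steps=max_steps)
    switch_ok = np.array(
        [lab == CELL_CYCLE for lab in _classify_rows(row_attr, scheme)]
    )
    if recipe is None:
        reprog = switch_ok
    else:
        row_attr_r, _s, _ = evolve_batch(
            net, states, growth, max_steps=max_steps, **_recipe_kwargs(recipe)
        )
        reprog = np.array(
            [lab == CELL_CYCLE for lab in _classify_rows(row_attr_r, scheme)]
        )
    committed = (dists <= depth) & ~switch_ok
    cset = CommitmentSet(states, dists, switch_ok, committed, depth)
    rows = []
    for d in sorted(set(dists.tolist())):
        mask = dists == d
        rows.append(
            {
                "d": d,
                "n": int(mask.sum()),
                "fraction_reprogrammed": float(reprog[mask].mean()),
            }
        )
    return cset, pd.DataFrame(rows)


def efficiency(
    net: RegulatoryNetwork,
    recipe: Recipe,
    committed: CommitmentSet,
    scheme: ClassificationScheme,
    n: int = 10_000,
    seed: int = 0,
    max_steps: int = 1000,
) -> float:
    """Fraction of sampled committed states the recipe reprograms to the
    cell-cycle fate under the growth condition. Samples with replacement
    (flag-free) when fewer than n committed states exist."""
    pool = committed.committed_states()
    if pool.shape[0] == 0:
        raise ValueError("committed set is empty")
    rng = np.random.default_rng(seed)
    replace = pool.shape[0] < n
    idx = rng.choice(pool.shape[0], size=n, replace=replace)
    S = pool[idx]
    growth = Condition.for_network(net, "growth")
    row_attr, _s, _ = evolve_batch(
        net, S, growth, max_steps=max_steps, **_recipe_kwargs(recipe)
    )
    labels = _classify_rows(row_attr, scheme)
    return labels.count(CELL_CYCLE) / n


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityProfile:
    attractor_keys: list[tuple]
    fractions: np.ndarray  # mass on the listed attractors
    unmatched: float = 0.0  # cell-cycle mass on attractors outside the list

    def restored_attractors(self, tol: float = 0.0) -> int:
        return int((self.fractions > tol).sum())


def wild_type_cell_cycle_attractors(
    net: RegulatoryNetwork,
    scheme: ClassificationScheme,
    n: int = 100_000,
    seed: int = 0,
    condition: Condition | None = None,
    max_steps: int = 1000,
) -> list[tuple]:
    """Canonical keys of the wild type's cell-cycle attractors under
    growth, ordered by decreasing basin count."""
    cond = condition or Condition.for_network(net, "growth")
    rng = np.random.default_rng(seed)
    S = random_initial_states(net, n, cond, rng)
    _rows, _steps, reg = evolve_batch(net, S, cond, max_steps=max_steps)
    ccs = [
        a for a in reg.list() if scheme.classify(a) == CELL_CYCLE
    ]
    ccs.sort(key=lambda a: (-a.basin_count, a.canonical_key))
    return [a.canonical_key for a in ccs]


def heterogeneity_profile(
    net: RegulatoryNetwork,
    recipe: Recipe | None,
    reference_attractors: Sequence[tuple],
    scheme: ClassificationScheme,
    condition: Condition | None = None,
    n: int = 10_000,
    seed: int = 0,
    max_steps: int = 1000,
) -> HeterogeneityProfile:
    """Distribution of (reprogrammed) cells over the wild type's
    cell-cycle attractors; cell-cycle mass on other attractors is tallied
    separately as ``unmatched``."""
    cond = condition or Condition.for_network(net, "growth")
    rng = np.random.default_rng(seed)
    S = random_initial_states(net, n, cond, rng)
    row_attr, _steps, _ = evolve_batch(
        net, S, cond, max_steps=max_steps, **_recipe_kwargs(recipe)
    )
    ref_index = {k: i for i, k in enumerate(reference_attractors)}
    counts = np.zeros(len(reference_attractors), dtype=np.int64)
    unmatched = 0
    cache: dict[tuple, str] = {}
    for a in row_attr:
        ck = a.canonical_key
        if ck in ref_index:
            counts[ref_index[ck]] += 1
        else:
            if ck not in cache:
                cache[ck] = scheme.classify(a)
            if cache[ck] == CELL_CYCLE:
                unmatched += 1
    return HeterogeneityProfile(
        list(reference_attractors), counts / n, unmatched / n
    )


def heterogeneity_deviation(
    w: HeterogeneityProfile | np.ndarray, x: HeterogeneityProfile | np.ndarray
) -> float:
    """Total-variation distance between renormalized profiles:
    0.5 * sum |w_i - x_i|. Zero iff the renormalized profiles coincide;
    1 for disjoint support."""
    wv = w.fractions if isinstance(w, HeterogeneityProfile) else np.asarray(w, float)
    xv = x.fractions if isinstance(x, HeterogeneityProfile) else np.asarray(x, float)
    if isinstance(w, HeterogeneityProfile) and isinstance(x, HeterogeneityProfile):
        if w.attractor_keys != x.attractor_keys:
            raise ValueError("profiles are over different attractor lists")
    if wv.shape != xv.shape:
        raise ValueError("profiles have different lengths")
    sw, sx = wv.sum(), xv.sum()
    if sw == 0 or sx == 0:
        raise ValueError("cannot renormalize a zero-mass profile")
    return 0.5 * float(np.abs(wv / sw - xv / sx).sum())


def pareto_front(scores: Iterable[RecipeScore]) -> list[RecipeScore]:
    """Non-dominated recipes maximizing efficiency and minimizing
    heterogeneity deviation; output sorted by decreasing efficiency."""
    items = list(scores)
    front = []
    for s in items:
        dominated = any(
            (o.efficiency >= s.efficiency and o.heterogeneity_deviation <= s.heterogeneity_deviation)
            and (o.efficiency > s.efficiency or o.heterogeneity_deviation < s.heterogeneity_deviation)
            for o in items
        )
        if not dominated:
            front.append(s)
    front.sort(key=lambda s: (-s.efficiency, s.heterogeneity_deviation, str(s.recipe)))
    return front


def perturbation_frequencies(recipes: Sequence[Recipe]) -> pd.DataFrame:
    """Frequency of each (node, direction) among all perturbation slots."""
    if not recipes:
        raise ValueError("empty recipe list")
    counts: dict[tuple[str, str], int] = {}
    total = 0
    for r in recipes:
        for p in r.perturbations:
            counts[p] = counts.get(p, 0) + 1
            total += 1
    rows = [
        {"node": n, "direction": d, "frequency": c / total}
        for (n, d), c in counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["frequency", "node"], ascending=[False, True], ignore_index=True
    )
    return df
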