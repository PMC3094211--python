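# refate

In-silico cell-fate reprogramming for the budding-yeast
cell-cycle/sporulation decision, built on synchronous Boolean network
dynamics.

Yeast cells proliferate through the mitotic cell cycle in rich medium and
sporulate when starved. `refate` models the regulatory network behind this
decision as a signed Boolean network, treats the stable states (attractors)
of the dynamics as cell fates, and asks the reprogramming question: which
small sets of protein perturbations (overexpression/knockdown, transient or
clamped) push a cell committed to one fate into the other — and how well do
the reprogrammed cells restore the heterogeneity of natural cells?

It is aimed at systems biologists who want to screen perturbation recipes
on logical models, quantify commitment and reprogramming efficiency, and
visualize the underlying epigenetic-landscape picture.

## The model

Each node carries a binary state. A non-conjunction node *i* with parents
*j* updates synchronously by the weighted-majority rule

```
F_i = Σ_j a_ij S_j(t),   a_ij ∈ {+1, −1}
S_i(t+1) = 1 if F_i > 0;  0 if F_i < 0;
           tie (F_i = 0) resolved by the node's self-mode:
           degradation → 0, sustaining → S_i(t), activation → 1
```

Logical-AND and phenotype nodes are pure conjunctions of their inputs;
signal nodes (growth condition, sporulation condition, cell size) are
clamped by the environment. On top of this engine the package provides:

- **Attractors and basins** — convergent random sampling (batches of 5,000
  until all class fractions move < 1%) with an exhaustive enumerator as
  the small-network oracle.
- **Phenotypes** — marker-based attractor classification (sporulation /
  cell cycle / other), sporulation-efficiency prediction for mutants
  (clamped nodes), Prespo/Spore ratios, cell-cycle phase assignment by the
  product score `g(j) = Π_i [w_ij if s_i=1 else 1−w_ij]` (normalized over
  phases), viability calls from the phase order
  START–G1–S–G2–M–(G1)–stationary G1, and MCC/correlation evaluation.
- **Reprogramming** — exhaustive recipe enumeration (all OE/KD
  combinations of 1–4 proteins), potency, commitment (states within 4
  evolving steps of a sporulation attractor that a condition switch alone
  cannot rescue), efficiency on committed states, heterogeneity profiles
  over the wild type's cell-cycle attractors with a total-variation
  deviation, and Pareto filtering.
- **Landscape and flux** — sampled state-transition graphs, a noisy
  transition matrix (sharpness μ = 5, noise floor c = 0.001, plus a
  pseudo-state absorbing out-of-graph mass), steady states by power
  iteration, potentials U = −ln p̄, per-state reprogramming-path fluxes
  and transition-state detection.
- **Significance** — degree-preserving (sign-stratified double-edge-swap)
  network randomization and null distributions for any network metric.

Two networks ship with the package: an 11-node cell-cycle benchmark whose
dominant stationary-G1 fixed point (basin 1764 of 2048 states) is
reproduced exactly, and a 56-node cell-cycle + sporulation network. The
56-node file is a **synthetic reconstruction** assembled from the
published narrative of the original study (the complete curated edge
table was never deposited); every edge is tagged `main_text` or
`reconstructed` accordingly. See `docs/methods.md` for what this does and
does not allow you to conclude.

## Worked example

```python
from refate import datasets, Condition, Recipe
from refate.phenotype import ClassificationScheme, class_fractions
from refate.reprogramming import potency

net = datasets.yeast_network()
scheme = ClassificationScheme.derive(net, n_init=50_000, seed=0)
growth = Condition.for_network(net, "growth")

fractions = class_fractions(net, growth, scheme, n=20_000, seed=1)
print({k: round(v, 3) for k, v in fractions.items()})

recipe = Recipe.parse("GCN5:OE+RPD3:KD+SUM1:KD+TUP1:KD")
score = potency(net, recipe, growth, "sporulation", scheme, n=10_000, seed=2)
print(f"potency={score.potency:.3f} reprogramming={score.reprogramming_flag}")
```

prints

```
{'sporulation': 0.063, 'cell_cycle': 0.715, 'other': 0.222}
potency=0.503 reprogramming=True
```

Under the growth condition 71.5% of random initial states converge to
cell-cycle attractors and 6.3% to sporulation. Transiently overexpressing
the histone acetyltransferase Gcn5 while knocking down the repressors
Rpd3, Sum1 and Tup1 inverts the preference: half of all initial states
now sporulate despite the growth signal, so the recipe reprograms the
proliferative fate (the flag reports that sporulation now outweighs the
wild type's preferred class).

A CLI mirrors the library (`refate net validate|randomize|synth`,
`refate dyn evolve|sample`, `refate pheno sporeff|viability`,
`refate recipes screen|pareto`, `refate landscape`, `refate flux`,
`refate null`); run `refate --help`.

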