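# Methods

## Update semantics

The dynamics is a synchronous Boolean network over typed nodes. For a
non-conjunction node *i* the input field is `F_i = Σ_j a_ij S_j(t)` with
unit weights `a_ij = ±1`. `F > 0` switches the node on, `F < 0` off, and a
tie (`F = 0`) is resolved by the node's self-mode: *degradation* (the
protein decays when unsupported), *sustaining* (the level persists), or
*activation* (unmodelled mechanisms keep it on). Logical-AND nodes and the
sporulation phenotype node are evaluated as pure conjunctions of their
previous-step inputs rather than through the threshold rule; a conjunction
over ±1 weights with the tie conventions above cannot express "on only if
all inputs are on" for arbitrary fan-in, which is why these kinds bypass
the weighted sum. Signal nodes have no regulators and are clamped by the
`Condition`.

Two perturbation mechanisms are distinct by design: **clamps** pin a node
at every step and model stable mutants (deletion = clamp 0,
overexpression mutant = clamp 1); **transient overrides** set bits only in
the initial state and model induced, decaying perturbations — the
reprogramming recipes. The cell-size signal is off during free basin
sampling (the stationary-G1 state requires it off) and is pulsed at t = 0
to launch the excited START trajectory; the returned trajectory starts at
the first post-pulse state, where the size-checkpoint cyclin Cln3 has just
fired, because the pulse state itself is marker-identical to stationary
G1.

Limit cycles are detected (first revisited state) and classified by
requiring the class label to hold in every cycle state; the fixtures'
biology is dominated by fixed points, but nothing assumes it.

## Attractors, basins, classes

Basins are estimated by uniform sampling of the free (non-signal) nodes in
batches of 5,000, stopping when every class fraction changes by less than
1 percentage point between consecutive cumulative tallies (cap
configurable). Networks with ≤ 22 free nodes can instead be enumerated
exactly; the enumerator is the oracle for every sampling test.

An attractor is *sporulation* when the SPOR phenotype node is on,
*cell cycle* when a marker set matches its values in the largest
growth-condition attractor (all other nodes free), else *other*. The
marker set is derived, not hard-coded: the protein/complex nodes that
change state at least once along the excited trajectory from the largest
attractor. "Changes along the excited trajectory" is one reading of a
genuinely ambiguous criterion (the alternative — changing anywhere in the
basin — would sweep in essentially every free node and destroy the
marker idea), and it reproduces the canonical cell-cycle machinery on
both packaged networks.

## Phases, weights, viability

A state's phase score is `g(j) ∝ Π_i (w_ij if s_i = 1 else 1 − w_ij)`
over the marker nodes, normalized to sum to 1 across the six phases
(START, G1, S, G2, M, stationary G1); the phase is the argmax, earliest
phase on ties (flagged). The packaged weight table is *derived* from the
excited trajectory: each trajectory state is labelled by cyclin
milestones (START while Cln3 is on; S at the Clb5 burst; G2 at Clb2; M at
Cdc20; G1 when both mitotic regulators are off; stationary G1 at the
attractor) and `w_ij = 0.1 + 0.8 · (fraction of phase-j states with node
i on)` — a softened version of 1/0 seeding. The original study's manually
tuned weight table was published only as supplementary material and is
not available, so the shipped `phase_weights_synthetic.tsv` is this
derivation applied to the packaged network.

A mutant is viable when, starting from the START state with the mutation
clamped, the trajectory converges to a cell-cycle attractor through the
collapsed phase sequence START–G1–S–G2–M–(G1)–stationary G1; runs are
collapsed because phase duration is not proportional to state count, and
the G1 between M and stationary G1 is optional.

## Reprogramming quantities

- **Potency**: fraction of random initial states the recipe drives into
  the target class; "reprogramming achieved" means the target class
  strictly outweighs the class the wild type prefers under the condition.
- **Commitment**: sporulation-basin states (initial + on-path,
  de-duplicated by state key) within 4 evolving steps of a sporulation
  attractor that a switch to the growth condition alone cannot bring to a
  cell-cycle attractor.
- **Efficiency**: fraction of sampled committed states the recipe (with
  the condition switched to growth) converts to cell cycle. Efficiency is
  deliberately *not* bounded by potency and no such invariant is
  asserted.
- **Heterogeneity deviation**: profiles are renormalized over the wild
  type's cell-cycle attractors and compared by total-variation distance
  ½ Σ|w_i − x_i| (0 iff identical, 1 for disjoint support). The original
  formula was printed as an unextractable image; total variation is this
  package's choice, isolated in one function so a Euclidean alternative
  can be swapped in.

## Landscape

The deterministic map is softened per node: the probability of taking the
deterministic next value is `(1−c)·σ(μ|F|) + c/2` for `F ≠ 0` and
`(1−c) + c/2` toward the mode-resolved value at a tie, with defaults
μ = 5 and c = 0.001; `T_ij` is the product over nodes, restricted to
in-graph states within Hamming distance 2 of the deterministic successor
(configurable radius). The remaining mass, including everything outside
the sampled graph, flows to a pseudo-state, which returns uniformly —
the simplest probability-conserving closure for a state that
"collectively represents" the unsampled space. The referenced noisy-map
construction was likewise not restated in the source, so the per-node
form above is this package's documented substitute; its zero-noise limit
(μ → ∞, c → 0 recovers the deterministic map exactly) pins the contract,
and power-iteration steady states are verified against direct linear
solves. Potentials average the steady probabilities over the three
conditions (growth, sporulation, none) and report U = −ln p̄, +∞ where
p̄ = 0.

## Flux analysis

For a recipe, trajectories from random initial states build a
state-transition graph; only paths ending in the target class count as
reprogramming paths, each crossing a state at most once. Normalized flux
is paths-through divided by graph size. Transition states must be crossed
by ≥ 9,000 reprogramming paths *summed across the recipe ensemble* (a
per-graph variant is a flag) with mean normalized flux > 0.05; per-graph
counts could never reach 9,000 for states shared across 100 graphs of
10,000 paths, which is why the aggregate reading is the default.

## Null models

Randomization uses sign-stratified double-edge target swaps: both edges
keep their sign and sources, preserving every node's out-degree and
per-sign in-degree; edges into conjunction/phenotype nodes are never
touched, and no duplicates or self-loops are created. Default 10·|E|
swaps. Null distributions report both a normal-tail parametric p and a
+1-smoothed empirical p, with counter-based seeding (draw *i* uses
seed + i) so ensembles extend without replaying.

## The packaged networks, and what passing tests show

`cellcycle11.json` transcribes the classical 11-node synchronous yeast
cell-cycle model; the enumerated fixed-point structure (basins
1764/151/109/9/7/7/1, dominant stationary G1 with Cdh1 and Sic1 on)
matches the published benchmark exactly, which validates the update
engine end to end.

`yeast56_synthetic.json` is a **synthetic reconstruction**, not the
original curated 56-node network, whose full edge table existed only as
supplementary material that was never deposited in a public archive. The
node census matches the published description (44 proteins/complexes, 5
AND nodes, EMG/MMG gene groups, the cAMP/PKA pathway, SPOR, three
signals; 42 perturbable proteins — the MBF and SBF complexes are marked
non-perturbable). Every interaction named in the study's narrative is
included (`provenance="main_text"`); the remaining wiring required for a
functioning model (`provenance="reconstructed"`) was chosen on standard
yeast biology, with three documented judgment calls: cyclin degradation
by SCF/Grr1 is represented by self-degradation modes rather than explicit
edges (as the original describes); Rme1's activation of CLN2 is omitted
because under unit weights it makes Cln2 constitutive in growth and
abolishes the stationary-G1 state; Ume6 and Rim11 are self-activating
(constitutively present), the same device used for Esp1/Pds1.

The reconstruction reproduces the *qualitative* biology: a dominant
stationary-G1 fate under growth with the canonical excited trajectory and
viable/inviable mutant calls (clb2Δ, clb5Δ, cdc20Δ arrest; meiotic
mutants stay viable), a dominant sporulation fate under starvation, a
growth-condition sporulation basin reachable through the Gcn5/Rpd3/Sum1
chromatin switch, and mixed OE+KD recipes that invert the fate
preference. Its *quantitative* values (exact basin percentages, 27
markers, 12 cell-cycle attractors, 97%/85%/48.7% named-recipe potencies,
the printed phase-score example) are properties of the original curated
edge table and are not expected to match; the acceptance test that
asserts them documents the deviation rather than certifying agreement.
Passing tests therefore validate the machinery (engine, classifiers,
estimators, all checked against independent oracles), not the biological
fidelity of the reconstructed edge list.

## Problem sizes and numerical choices

The acceptance script samples 50,000 initial states per condition for
basins and marker/attractor discovery, 10,000 states per recipe potency,
4,000 basins for commitment harvesting, 4,000 committed samples for
efficiency, 10,000 states per heterogeneity profile, and a 5-recipe ×
1,000-path ensemble for transition states (thresholds scaled to the same
90%-of-paths / 0.05-flux proportions). These sizes put Monte-Carlo error
well below the effects of interest (binomial SE ≤ 0.5 percentage points
at n = 10,000) while keeping a full run in the low minutes on one core.
Oracle-equivalence tests run 200 random networks of 4–10 nodes against
exhaustive enumeration and a pure-Python walker.

Other numerics: state keys are 64-bit packed bit-vectors (networks up to
63 nodes); batch evolution detects fixed points vectorized and falls back
to a hashing walker for limit cycles; power iteration converges in L1 to
1e-10 by default; phase ties break to the earliest phase with an explicit
flag; a zero denominator in MCC returns 0 by convention; a zero mutant
sporulation fraction yields an infinite Prespo/Spore ratio handled by
rank statistics.

## Known limitations

Synchronous updating only (no asynchronous schemes); no SBML-qual I/O; no
ODE layer; the landscape is estimated only on sampled reprogramming
paths, never over the full 2^56 state space; heterogeneity deviation and
the noisy transition form are documented substitutes for formulas
unavailable from the source; and all quantitative claims about the
56-node system refer to the synthetic reconstruction, not the original
curated network.
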