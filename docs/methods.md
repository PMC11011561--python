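# Methods

## The model

`netmoa` builds in-silico mechanism-of-action (MoA) models of a drug over
a disease on a signed, directed protein–protein interaction network. The
model is a perceptron-like network laid over the interactome: each
protein (node) n holds an activity o_n ∈ [−1, 1] (−1 completely
inhibited, +1 completely activated), each interaction (edge) m → n
carries a fixed sign s_mn ∈ {−1, +1} (activating / inhibiting) and a
trainable weight ω_mn ∈ [0, 1], and a node's activity is the hyperbolic
tangent of its signed, weighted input sum:

    o_n = tanh( Σ_m o_m · s_mn · ω_mn ).

A *stimulus* (a drug acting on its targets) hard-clamps the target nodes
at ±1; the signal then traverses the network to the *response* nodes —
effector proteins of the disease's pathophysiological processes, each
annotated with a pathological direction w_i ∈ {−1, +1} (hyper- /
hypoactivated in disease). The effect of a stimulus on a process with n
effectors is summarized by

    fSignal = (1/n) Σ_i w_i · o_i ∈ [−1, 1],

where −1 means complete reversal of the pathological pattern
(therapeutic effect) and +1 complete reproduction of it.

### Cycles and the fixed point

Real interactomes are cyclic, so the forward pass is defined as the fixed
point of the damped synchronous update

    o ← (1 − α) o + α tanh(A o),      α = 0.5 by default,

from the all-zero state, with clamps re-imposed every sweep. On an
acyclic graph this converges to exactly the layer-by-layer forward
evaluation (asserted against a topological-order oracle in the tests);
on cyclic graphs it defines deterministic semantics. Convergence is
declared when the largest per-node change falls below `tolerance`
(default 1e−6) within `max_iterations` (default 200); non-convergence
returns a flagged profile with a warning rather than an exception, since
the caller may still want the truncated state. Nodes unreachable from any
clamped node remain exactly 0.

Clamps are hard: a clamped target ignores incoming signal. The
alternative (additive signal injection) would let network feedback
override a pharmacological inhibition, which is not the intended
semantics of a target-level stimulus.

## Training

Edge weights are fitted to a training set of *restrictions*. Each
restriction pairs a stimulus with a response effector set and a relation:
**therapeutic** (the stimulus must reverse the set's pathological
pattern, fSignal < 0) or **inductive** (it must reproduce it,
fSignal > 0). A restriction is satisfied when fSignal has the required
sign and |fSignal| ≥ τ (default τ = 0.1, the package-wide threshold for a
meaningful activity difference); fSignal = 0 satisfies neither relation.
Accuracy is the satisfied fraction; an empty training set scores 1.0 with
a warning.

Weights are optimized by simulated annealing on the energy

    E(w) = (1 − accuracy) + λ · mean_r |relation_r − fSignal_r| / 2,

with λ = 0.5/|T| so the continuous term orders weight vectors within an
accuracy plateau but can never trade away a satisfied restriction. Moves
perturb one uniformly chosen weight by a Gaussian step (σ = 0.3) clipped
to [0, 1]; acceptance is Metropolis with geometric cooling (T: 0.05 →
5e−5, factor 0.85, 150 steps per temperature). Two further choices matter
in practice and are defaults:

* **Weak-signal initialization.** Initial weights are drawn from
  U(0, 0.5) rather than U(0, 1): dense strong weights saturate the tanh
  responses and flatten the energy landscape, while a weak start lets
  structure grow edge by edge.
* **Reheat cycles.** The cooling schedule is run 3 times (reheating from
  the current state) to escape accuracy plateaus; the search stops early
  once every restriction is satisfied.

The best-seen state is returned, never the final one, so the result is
never worse than the initial assignment. Annealing moves are scored at a
relaxed fixed-point tolerance (1e−4, warm-started from the incumbent
state); the accuracy stored with a solution is always recomputed from a
cold start at strict tolerance, so it is exactly what an independent
re-evaluation yields. Everything is driven by one integer seed —
identical inputs and seed give bitwise-identical solutions.

Because the weight space is heavily underdetermined (edges ≫
restrictions), many distinct weight assignments satisfy the data. The
unit of analysis is therefore an **ensemble** of solutions annealed from
consecutive seeds (the reference case uses 250; the bundled synthetic
studies use 10–25 to keep runtimes in seconds-to-minutes on one CPU).
All downstream statistics treat the ensemble, not any single solution, as
the model.

## Scenario analysis

Scenarios are clamp patterns on target nodes. For the bundled
VEGF-receptor case study: IAI (all six targets inhibited), VEGFR1−
(FLT1/PGF/VEGFB inhibited), VEGFR2− (KDR/VEGFA/LGALS1 inhibited), and
VEGFR2−(DME) (VEGFR2 pathway inhibited while the VEGFR1 pathway is held
activated). Per scenario the package computes per-solution activity
profiles, their mean, and per-process fSignal distributions (one value
per solution). Because fSignal is linear in the activities, the mean of
per-solution fSignals equals the fSignal of the mean profile; the code
exploits this and the tests assert it.

Scenario differences against a reference are tested per process with a
two-sided Mann–Whitney U (exact null below 20 solutions, tie-corrected
normal approximation otherwise) and Benjamini–Hochberg correction over
the whole (process × non-reference scenario) batch — the batch choice is
this package's convention. Flags follow the q < 0.005 rule, split at a
mean fSignal difference of 0.1 ("**" at ≥ 0.1, "*" below).

The effector-by-scenario heatmap matrix keeps rows whose largest
absolute mean activity is at least 0.1 (boundary kept) and orders them by
agglomerative hierarchical clustering (Euclidean distance, complete
linkage — the defaults of the usual heatmap tooling).

## Enrichment and Hausdorff clustering

The enrichment foreground is the set of proteins with |activity|
strictly above 0.8 under the reference scenario; the background is the
complete model protein list. Each GMT set is tested with an upper-tail
hypergeometric test; sets with fewer than 10 or more than 200 members
(within the background; the ceiling is configurable to 300) are dropped
*before* testing so they do not enter the BH family. Significance is
q ≤ 0.001. The q-direction and the size window are deliberately exposed
as parameters: significance cutoffs of this kind are sometimes printed
ambiguously, and a greater-than FDR rule is not a meaningful significance
criterion, so the package defaults to the standard reading.

Enriched sets are related geometrically with the Hausdorff distance
d_H(X, Y) = max(sup_x inf_y d, sup_y inf_x d) where d is the unweighted
hop distance on the interactome's undirected skeleton (an optional
`mean_min` mode averages nearest-member distances instead). Pairs with
d_H ≤ 1.2 become edges of the enrichment network. Note the cutoff is only
meaningful relative to the configured point metric: under the integer hop
metric, 1.2 admits pairs at distance ≤ 1. Disconnected required pairs
make d_H infinite and the pair un-linked.

## Mechanism-of-action paths

To isolate one pathway's contribution within a multi-target drug, an
effector is selected when (a) the single-pathway scenario reverses its
pathological direction (nonzero activity of sign −w_i), (b) the two
single-pathway scenarios differ by at least 0.1 in its predicted
activity, and (c) the full drug scenario also reverses it. Simple
directed paths from the pathway's clamped target to each selected
effector (up to 6 edges by default) are then scored across the ensemble:
a path is *active in a solution* when every edge weight is at least
δ = 0.01 and the terminal effector's activity sign in that solution
equals the source clamp sign times the product of edge signs. Paths
active in at least 75% of solutions are retained. The δ-support +
terminal-sign-consistency rule is this package's operational definition
of path activity, chosen so path frequency degrades gracefully as
annealed weights shrink; δ, the length cap, and the frequency cutoff are
configurable. Retained paths are exported as TSV and GraphViz DOT (green
activation / red inhibition node coloring, tee arrowheads on inhibiting
edges).

## Synthetic worlds

The generator builds self-contained study worlds so every stage is
testable without proprietary data. Defaults (150 nodes, attachment
parameter m = 2, 30% inhibitory edges, 6 processes × 5 effectors, 12
drugs × 2 targets, planted weights U(0.2, 1.0), no label noise) define
the reference study conditions for the recovery analyses.

* **Topology.** A Barabási–Albert graph whose edges are oriented from
  the newer toward the older endpoint with probability 0.7, giving
  heavy-tailed in-degree (hubs collect signal) while late-added nodes act
  as sources. Drug targets are drawn from the late half of the node
  order, so stimuli feed signal toward the hub core the way receptor
  perturbations feed the signaling backbone.
* **Ground truth.** Effector sets are drawn from proteins that actually
  receive signal (|activity| > 0.1 under at least one drug with planted
  weights). Restriction labels are the signs of the planted-model
  fSignals; (drug, process) pairs with |fSignal| below the truth margin
  (0.1 = τ) are excluded from both the training set and the truth map,
  because a sign label on a near-zero quantity is a coin flip. Planted
  weights are bounded away from 0 (≥ 0.2) for the same reason. With zero
  label noise the world is exactly self-consistent: the planted weights
  satisfy every restriction (asserted in the tests).
* **Recovery score.** The fraction of truth pairs whose ensemble-mean
  fSignal sign matches the planted sign; zero fSignal matches nothing, so
  an untrained all-zero model scores 0.
* **GMT fixture.** Random protein sets plus one "spiked" set collecting
  proteins strongly modulated by one drug's planted model, giving the
  enrichment stage a known positive control.
* **Dual-cone world.** A separate deterministic construction: two
  receptors, each feeding its own cone of intermediates, converging on
  shared effectors, with one uniform edge weight and all-activating
  edges. By symmetry, joint inhibition of both receptors reverses the
  shared effectors at least as strongly as either single inhibition, and
  inhibiting one receptor while activating the other cancels to the
  weakest reversal. This makes the qualitative scenario ordering of a
  dual-pathway drug a provable property of the planted model — no
  training involved — and it is asserted as such.

What the generator does **not** emulate: the scale of the real human
interactome (thousands of nodes; scale is a config knob), correlated
biological noise, literature-derived effector curation, or identifier
ambiguity. Passing recovery tests therefore demonstrates that the
training and analysis machinery works as specified on well-posed inputs,
not that any particular biological conclusion transfers to real data. At
the default synthetic scale some downstream counts (significant enriched
sets, retained MoA paths) can legitimately be zero for a given seed:
ensemble averaging shrinks activity magnitudes, and the 0.8 foreground /
75% frequency rules are calibrated for the full-scale setting.

## Problem sizes and numerical choices

The bundled analyses use deliberately compact sizes chosen as a desk-scale
stand-in for the reference setting: a 150-node world with a 25-solution
ensemble for recovery scoring (about two minutes end to end), an 80-node
world with a 10-solution ensemble for the demo pipeline. Other choices:

* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; ensembles use consecutive seeds from a base seed.
* Node and edge orderings are sorted everywhere, and all file exports use
  fixed float formatting, so a pipeline run is byte-reproducible
  (asserted in the tests); weight archives store full-precision `repr`
  floats so a cached ensemble reloads bit-exactly.
* Ties in Mann–Whitney fall back from the exact to the tie-corrected
  asymptotic method.
* Heatmap clustering of a single row skips linkage; an all-filtered
  matrix is returned empty with a warning.

## Known limitations

* The update rule has no self-loops and no time semantics; it is a
  steady-state abstraction, not kinetics.
* Hard clamping means feedback onto drug targets is invisible.
* On cyclic graphs the fixed point is defined by the damped iteration;
  other update schemes (asynchronous, ODE) could select different
  attractors.
* The annealer's schedule is tuned for the bundled problem scale;
  substantially larger networks will need longer schedules and benefit
  from the ensemble's embarrassingly parallel structure.
* Path extraction enumerates simple paths and is exponential in the
  length cap; the default cap of 6 keeps it tractable on hub-dominated
  networks.
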