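# Methods

## The strong-inhibition Boolean model

A gene regulatory network on N nodes is a signed digraph stored as an
integer matrix `a` with `a[i][j] ∈ {−1, 0, +1}` the effect of node *j*
on node *i* (source = column, target = row). Node states are Boolean,
S_i ∈ {0, 1}, updated synchronously. The general threshold rule is

    S_i(t+1) = 1    if Σ_j w_ij S_j(t) > 0
             = 0    if Σ_j w_ij S_j(t) < 0
             = S_i(t) otherwise,

with weights w_ij = +1 for activation, −γ for off-diagonal inhibition
and −1 for an inhibitory self-edge, γ ≥ 1. Inhibition dominates in many
transcriptional systems; in the dominant-inhibition limit γ → ∞ the
rule becomes purely logical. Writing the sign matrix as the disjoint
indicator pair g (activation) and r (inhibition), a = g − r, the update
is

    S_i(t+1) = ( OR_{j≠i} S_j g_ij  OR  S_i ∧ ¬r_ii  OR  ¬S_i ∧ g_ii )
               AND NOT ( OR_{j≠i} S_j r_ij ).

A single active inhibitor therefore switches its target off regardless
of the activators — the defining property of the strong-inhibition
model, and the reason `SignedNetwork` stores signs only.

Each node's rule is a chain function (a nested canalyzing function):
inhibitors are canalyzing with value 0, then the activators follow.

**Self-edges.** The logical rule gives a self-activated node (g_ii = 1)
the value 1 whenever no inhibitor is active, even from S_i = 0 with all
activators off, whereas the finite-γ threshold rule would hold such a
node at 0. The logical form is taken as the model definition; the
threshold/logical equivalence (exhaustive over all 2^N states, γ ≥ N)
is therefore guaranteed — and asserted in the tests — only for networks
without self-edges.

## Fixed-point enumeration

A singleton attractor is a state with S(t+1) = S(t). Substituting into
the update gives a per-node fixed-point condition whose local
consequences are seven propagation rules (an active node forces its
inhibitory neighbourhood off; a node with no possible active inhibitor
and a determined active activator must be on; a self-inhibited node
with no active activator must be off; and so on — the exact list is in
`attractor_search`'s module docstring).

Rules are applied to *partial* states (entries 0, 1 or unknown) with
entailment semantics: a premise of the form "Σ_j S_j x_ij = 0" counts
as satisfied only when every contributing node is determined and equal
to 0 (vacuously when there is no contributor), and an existential
premise needs a determined witness. Rules never fire on undetermined
premises, so every determination is entailed: it holds in *all*
fixed-point completions of the partial state. Propagation sweeps all
rules over all nodes until a full pass fires nothing. All rules are
monotone entailments, so the fixpoint is unique and independent of
sweep order; a conclusion clashing with an already determined value is
a contradiction, which proves the branch contains no fixed point.

Enumeration is depth-first branch-and-propagate: propagate on the fully
unknown state, then repeatedly pick an undecided node, assign 1 (then
0), propagate, prune contradictions, and emit a leaf when no unknowns
remain. The two branch values partition the completions, so no state
can be found twice. Each leaf is re-verified against the fixed-point
condition before emission — cheap (O(edges)) insurance against rule
transcription slips; with the present rule set the check never fails.

**Branching heuristic.** The branch node is the undecided node with the
most putative inhibitory connections, counted as inhibitory in-degree
plus out-degree over r (self-inhibition contributes to both sums), ties
broken by the smallest node index. Setting such a node to 1 immediately
determines its whole inhibitory neighbourhood, so contradictions
surface early. The heuristic affects search effort only; the result set
is invariant under any branching order. On the bundled budding-yeast
network the first two branch nodes are Clb1/2 (node 10, degree 8) and
Sic1 (node 9, degree 5).

## Pre-images and basins

A pre-image of a target T is any state S with one-step image T. Fixing
T turns the update into a constraint system on S, analysed per target
bit: five rules for T_i = 1 (all inhibitors of i must be off; the
activation part must be achievable, else contradiction) and five for
T_i = 0 (with no active inhibitor the activation part must be 0; if the
activation part is forced to 1 — a self-activation loop or a determined
active activator — the sole remaining candidate inhibitor must be on).
The listed rules include a pair where one subsumes the other (2.3 is
the self-activation special case of 2.4); both are kept for
traceability. The same DFS skeleton and heuristic are reused; leaves
are verified by one forward step. The rule set is not
propagation-complete — it need not be, since branching restores
completeness — and a target with no pre-image (a Garden-of-Eden state)
yields an empty set, detected either by an up-front contradiction or by
exhausting the branches.

The basin of attraction of a fixed point is reconstructed backwards:
layer 0 is the attractor, layer d+1 the not-yet-collected pre-images of
layer d, until a layer is empty. Because each state has exactly one
successor, the layer index equals the exact synchronous hitting time,
and the layers are pairwise disjoint. The tests validate basins against
an independent forward simulation from every state of the state space.

## Exhaustive oracles

Both enumerations have brute-force counterparts that scan all 2^N
states with a vectorised batch update (chunked matrix products), used
as independent oracles in the tests. They refuse networks above a
configurable ceiling (default N = 24) because the scan is exponential;
the ceiling exists to fail fast, not to be raised in production.

## Random ensembles

Random networks follow an Erdős–Rényi-style construction: every ordered
pair (i, j), the diagonal included, independently carries an edge with
probability p = ⟨k⟩/N, and each edge is inhibitory with probability r,
activating otherwise. The diagonal is deliberately not special-cased:
self-edges draw from the same two-point sign distribution. Defaults in
the experiments follow typical biological connectivity, ⟨k⟩ = 3 and
r = 0.4 (average degree 2–4, inhibition rarer than activation).

The ensemble harness enumerates the fixed points of M samples and
records per sample the attractor count NS, the number of branch
expansions, wall-clock seconds and a cap flag. Branch expansions are
the primary cost measure — across an ensemble they correlate with NS at
Pearson > 0.95 in our runs — because wall-clock time is
hardware-dependent; seconds are logged but never asserted. Sparse
networks can have astronomically many fixed points (an edgeless network
has 2^N), so a per-sample cap (default 10^6) stops enumeration
gracefully and flags the sample rather than dropping it.

Reproducibility: sample m of an ensemble uses the seed sequence
(root seed, m), so results are independent of iteration order and
identical across runs and machines.

## Problem sizes in tests and the acceptance script

Oracle-equivalence checks use 200 random networks with N ∈ [4, 12],
⟨k⟩ ∈ {1, 2, 3, 5}, r ∈ {0.2, 0.4, 0.8} — small enough for the 2^N
oracles, varied enough to exercise every rule. Threshold/logical
consistency is exhaustive up to N = 10; basin validation simulates all
2^N states up to N = 10. The parameter-trend experiments run M = 200
samples per condition at N = 14 (⟨k⟩ and r sweeps) and N = 20 (effort
correlation); the qualitative conclusions (avS falls steeply with ⟨k⟩,
rises with r, effort ∝ NS) are stable in N and M, and these sizes keep
the whole suite in the tens of seconds.

## The bundled fixture

The budding-yeast cell-cycle network (11 nodes, 34 edges; Li, Long, Lu,
Ouyang & Tang 2004, PNAS 101:4781) ships as a labelled matrix file with
the five self-degradation loops encoded as inhibitory self-edges. Under
the strong-inhibition update it has exactly seven fixed points,
including the biological G1 state (Cdh1 and Sic1 on) whose basin covers
1875 of the 2048 states; the seven basins partition the entire state
space (no cyclic attractor is reachable). These counts are enforced in
the tests against both the rule-based search and the exhaustive oracle.

## Known limitations

- Fixed points only: cyclic attractors are detected incidentally by
  `trajectory` but not enumerated; the propagation rules are derived
  from the fixed-point condition and say nothing about cycles.
- The rules are specific to the strong-inhibition update; they are
  unsound for finite γ (where inhibitors and activators trade off).
- Worst-case cost is exponential; in practice effort scales with the
  number of fixed points, so dense networks with few inhibitory edges
  are easy and near-edgeless networks are the hard case (use the cap).
- Basin reconstruction enumerates every member state; it is not a
  counting method and is impractical for basins of astronomical size.
- The synthetic ensembles are homogeneous ER digraphs; real regulatory
  networks have broad degree distributions, motif structure and signed
  correlations the generator does not emulate, so ensemble trends
  transfer qualitatively, not numerically.
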