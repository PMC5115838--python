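"""Enumeration of all pre-images of a target state, and basins of attraction.

A pre-image (predecessor) of a target state T is any state S with
strong_inhibition_step(S) = T.  Fixing the target turns the one-step
update into a constraint system over S; analysing it per target bit
gives two rule families (notation as in :mod:`sibnet.attractor_search`,
all conclusions about the *input* state S).

For target bit T_i = 1 (node i must be on next step):

  rule 1.1  r_ij = 1                                            =>  S_j = 0
  rule 1.2  r_ii = 1, g_ij0 = 1, sum_{j!=i} S_j r_ij = 0,
            sum_{j!=j0} S_j g_ij = 0                            => S_j0 = 1
  rule 1.3  g_ii = r_ii = 0, sum r = 0, sum g = 0               =>  S_i = 1
  rule 1.4  g_ii = 0, g_ij0 = 1, sum r = 0,
            sum_{j!=j0} S_j g_ij = 0, S_i = 0                   => S_j0 = 1
  rule 1.5  r_ii = 1 and sum_{j!=i} S_j g_ij = 0                =>  contradiction

For target bit T_i = 0 (node i must be off next step):

  rule 2.1  sum_{j!=i} S_j r_ij = 0 and g_ij0 = 1               => S_j0 = 0
  rule 2.2  g_ii = r_ii = 0 and sum_{j!=i} S_j r_ij = 0         =>  S_i = 0
  rule 2.3  g_ii = 1, r_ij0 = 1, sum_{j!=j0} S_j r_ij = 0       => S_j0 = 1
  rule 2.4  r_ij0 = 1, sum_{j!=i,j!=j0} S_j r_ij = 0, and
            (g_ii = 1 or some determined S_j0' g_ij0' = 1)      => S_j0 = 1
  rule 2.5  g_ii = 1 and sum_{j!=i} S_j r_ij = 0                =>  contradiction

Rule 2.4's premise groups as: the activation part of the update is
forced to 1 (either by a self-activation loop or by a determined active
activator), so with all other inhibitors off the sole remaining
candidate inhibitor must be active — the only parse under which the
rule is sound.  Rule 2.3 is the g_ii = 1 special case of 2.4 and is kept
for traceability.  As in the attractor search, premises use entailment
semantics, the rule set need not be propagation-complete (branching
restores completeness), and every leaf is verified by one forward step.

Iterating pre-images backwards from a fixed point reconstructs its basin
of attraction layer by layer: layer d holds the states whose forward
trajectory first reaches the attractor after exactly d steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._search import (
    Adjacency,
    PropagationOutcome,
    ResourceLimitError,
    RuleEngine,
    SearchStats,
    branch_and_propagate,
    entailed_zero,
    sole_candidates,
    states_chunk,
)
from .network_model import (
    RegulatoryDecomposition,
    SignedNetwork,
    as_state,
    decompose,
    format_state,
    is_singleton_attractor,
    parse_partial,
    step_batch,
    strong_inhibition_step,
)

__all__ = [
    "BasinLayers",
    "propagate_preimage",
    "enumerate_preimages",
    "brute_force_preimages",
    "compute_basin",
]


def _preimage_rules_for(target: np.ndarray):
    """Build the per-node rule function for a fixed, fully determined target."""

    def rules(eng: RuleEngine, i: int) -> None:
        adj = eng.adj
        vals = eng.vals
        activators = adj.activators[i]
        inhibitors = adj.inhibitors[i]
        if target[i] == 1:
            for j in inhibitors:  # rule 1.1: no inhibitor of i may be on
                eng.assign(j, 0, "1.1")
            if adj.r_diag[i]:
                if entailed_zero(activators, vals):  # rule 1.5
                    eng.contradiction("1.5", i)
                if entailed_zero(inhibitors, vals):  # rule 1.2
                    for j0 in sole_candidates(activators, vals):
                        eng.assign(j0, 1, "1.2")
            if not adj.g_diag[i] and not adj.r_diag[i]:
                if entailed_zero(inhibitors, vals) and entailed_zero(activators, vals):
                    eng.assign(i, 1, "1.3")  # rule 1.3
            if not adj.g_diag[i] and vals[i] == 0 and entailed_zero(inhibitors, vals):
                for j0 in sole_candidates(activators, vals):  # rule 1.4
                    eng.assign(j0, 1, "1.4")
        else:
            if adj.g_diag[i] and entailed_zero(inhibitors, vals):  # rule 2.5
                eng.contradiction("2.5", i)
            if entailed_zero(inhibitors, vals):
                for j0 in activators:  # rule 2.1: no activator of i may be on
                    eng.assign(j0, 0, "2.1")
                if not adj.g_diag[i] and not adj.r_diag[i]:
                    eng.assign(i, 0, "2.2")  # rule 2.2
            if adj.g_diag[i]:  # rule 2.3: sole candidate inhibitor must be on
                for j0 in sole_candidates(inhibitors, vals):
                    eng.assign(j0, 1, "2.3")
            # rule 2.4: activation part forced to 1 -> same conclusion
            if adj.g_diag[i] or any(vals[jp] == 1 for jp in activators):
                for j0 in sole_candidates(inhibitors, vals):
                    eng.assign(j0, 1, "2.4")

    return rules


def propagate_preimage(
    dec: RegulatoryDecomposition,
    target,
    partial,
    trace: bool = False,
) -> PropagationOutcome:
    """Run rules 1.1-1.5 / 2.1-2.5 to fixpoint on a partial input state."""
    tgt = as_state(target, dec.n_nodes)
    vals = parse_partial(partial)
    if vals.shape[0] != dec.n_nodes:
        raise ValueError("partial state length does not match network size")
    engine = RuleEngine(Adjacency(dec), _preimage_rules_for(tgt))
    return engine.run(vals, trace=trace)


def enumerate_preimages(
    net: SignedNetwork, target, max_results: int | None = None
) -> tuple[set[str], SearchStats]:
    """All states that map to ``target`` in one synchronous step, as bitstrings.

    Same branch-and-propagate skeleton as the attractor enumeration
    (inhibitory-degree branching heuristic, DFS, value 1 before 0), with
    the pre-image rule set and a one-forward-step leaf check.  An empty
    set is a legal outcome: ``target`` is then a Garden-of-Eden state.
    """
    dec = decompose(net)
    tgt = as_state(target, net.n_nodes)
    adj = Adjacency(dec)
    engine = RuleEngine(adj, _preimage_rules_for(tgt))

    def verify(state: np.ndarray) -> bool:
        return bool(np.array_equal(strong_inhibition_step(dec, state), tgt))

    return branch_and_propagate(adj, engine, verify, net.n_nodes, max_results)


def brute_force_preimages(net: SignedNetwork, target, ceiling: int = 24) -> set[str]:
    """Exhaustive predecessor scan over all 2^N inputs (testing oracle)."""
    n = net.n_nodes
    if n > ceiling:
        raise ResourceLimitError(
            f"brute force over 2^{n} states exceeds the ceiling of 2^{ceiling}; "
            "raise `ceiling` explicitly if you really want this"
        )
    dec = decompose(net)
    tgt = as_state(target, n)
    found: set[str] = set()
    total = 1 << n
    chunk = 1 << 18
    for start in range(0, total, chunk):
        ints = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        states = states_chunk(ints, n)
        hits = np.all(step_batch(dec, states) == tgt[None, :], axis=1)
        for row in states[hits]:
            found.add(format_state(row))
    return found


class NotAFixedPointError(ValueError):
    """Raised when basin reconstruction is asked for a non-fixed-point state."""


@dataclass(frozen=True)
class BasinLayers:
    """Basin of a singleton attractor, layered by first-hitting time.

    ``layers[0]`` is the attractor itself; ``layers[d]`` holds the states
    whose shortest forward path to the attractor has length exactly d.
    Layers are pairwise disjoint and every state in layer d steps into
    layer d-1.
    """

    attractor: str
    layers: tuple[frozenset[str], ...]

    @property
    def size(self) -> int:
        return sum(len(layer) for layer in self.layers)

    @property
    def depth(self) -> int:
        """Largest hitting time occurring in the basin."""
        return len(self.layers) - 1

    def states(self) -> set[str]:
        out: set[str] = set()
        for layer in self.layers:
            out |= layer
        return out


def compute_basin(
    net: SignedNetwork, attractor, max_layers: int | None = None
) -> BasinLayers:
    """Reconstruct the basin of a singleton attractor by iterated pre-imaging.

    Starting from the attractor, repeatedly collect the pre-images of the
    current layer that have not been seen before; the loop ends when a
    layer comes back empty (or at ``max_layers``).  Because the attractor
    is the unique successor of each of its pre-images, the layer index of
    a state equals its exact synchronous hitting time.
    """
    dec = decompose(net)
    s = as_state(attractor, net.n_nodes)
    if not is_singleton_attractor(dec, s):
        raise NotAFixedPointError(
            f"state {format_state(s)} is not a fixed point of this network"
        )
    root = format_state(s)
    layers: list[frozenset[str]] = [frozenset({root})]
    collected: set[str] = {root}
    while max_layers is None or len(layers) <= max_layers:
        frontier: set[str] = set()
        for state in layers[-1]:
            pres, _ = enumerate_preimages(net, state)
            frontier |= pres
        frontier -= collected
        if not frontier:
            break
        layers.append(frozenset(frontier))
        collected |= frontier
    return BasinLayers(attractor=root, layers=tuple(layers))
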