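"""Enumeration of all singleton attractors (fixed points) of a strong-inhibition network.

A singleton attractor is a state S with S(t+1) = S(t).  Under the
strong-inhibition update the fixed-point condition

    S_i = (OR_{j != i} S_j g_ij  OR  S_i & ~r_ii  OR  ~S_i & g_ii)
          AND NOT (OR_{j != i} S_j r_ij)

entails seven local consistency rules.  With S_i, g and r as above
(g_ij / r_ij = putative stimulatory / inhibitory edge from j to i):

  rule 1  S_i = 1 and r_ji = 1                                  =>  S_j = 0
  rule 2  S_i = 1 and r_ij = 1                                  =>  S_j = 0
  rule 3  S_i = 1, r_ii = 1, g_ij0 = 1, sum_{j!=j0} S_j g_ij = 0 => S_j0 = 1
  rule 4  S_i = 0, sum_{j!=i} S_j r_ij = 0, g_ij0 = 1,
          sum_{j!=j0} S_j g_ij = 0                              => S_j0 = 0
  rule 5  r_ii = 1 and sum_{j!=i} S_j g_ij = 0                  =>  S_i = 0
  rule 6  g_ii = 1 and sum_{j!=i} S_j r_ij = 0                  =>  S_i = 1
  rule 7  sum_{j!=i} S_j r_ij = 0 and some S_j0 g_ij0 = 1       =>  S_i = 1

Premises are read with entailment semantics on partial states: a sum
condition holds only when every contributing node is determined and 0
(vacuously when there are no contributors), and existential premises
need a determined witness.  The rules are therefore sound: they only
ever determine values shared by all fixed-point completions of the
partial state.  Completeness of the *enumeration* does not rest on the
rules — branching over the remaining unknowns guarantees it, and each
leaf is re-verified against the fixed-point condition.
"""

from __future__ import annotations

from functools import partial

import numpy as np

from ._search import (
    Adjacency,
    PropagationOutcome,
    ResourceLimitError,
    RuleEngine,
    SearchStats,
    branch_and_propagate,
    entailed_zero,
    select_from_order,
    sole_candidates,
    states_chunk,
)
from .network_model import (
    UNKNOWN,
    RegulatoryDecomposition,
    SignedNetwork,
    decompose,
    format_state,
    is_singleton_attractor,
    parse_partial,
    step_batch,
)

__all__ = [
    "SearchStats",
    "PropagationOutcome",
    "ResourceLimitError",
    "inhibitory_degree",
    "select_branch_node",
    "propagate",
    "enumerate_singleton_attractors",
    "brute_force_singleton_attractors",
]


def inhibitory_degree(dec: RegulatoryDecomposition, i: int) -> int:
    """Putative inhibitory connections of node ``i`` (1-based): in-degree + out-degree.

    Self-inhibition contributes to both sums.  This is the branching
    heuristic of the search: an active node with many inhibitory
    connections pins many neighbours at once (rules 1 and 2), so such
    nodes are branched on first.  The heuristic affects speed only,
    never the result set.
    """
    if not 1 <= i <= dec.n_nodes:
        raise IndexError(f"node index {i} out of range 1..{dec.n_nodes}")
    return int(dec.r[i - 1, :].sum() + dec.r[:, i - 1].sum())


def select_branch_node(dec: RegulatoryDecomposition, partial) -> int:
    """Undetermined node with maximal inhibitory degree, ties by smallest index (1-based)."""
    vals = parse_partial(partial)
    if vals.shape[0] != dec.n_nodes:
        raise ValueError("partial state length does not match network size")
    adj = Adjacency(dec)
    return select_from_order(adj, vals) + 1


def _attractor_rules(eng: RuleEngine, i: int) -> None:
    """Apply rules 1-7 at node i against the engine's current partial state."""
    adj = eng.adj
    vals = eng.vals
    v = vals[i]
    if v == 1:
        for j in adj.inh_targets[i]:  # rule 1: i inhibits j
            eng.assign(j, 0, "1")
        for j in adj.inhibitors[i]:  # rule 2: j inhibits i
            eng.assign(j, 0, "2")
        if adj.r_diag[i]:  # rule 3: sole remaining activator must be on
            for j0 in sole_candidates(adj.activators[i], vals):
                eng.assign(j0, 1, "3")
    elif v == 0:
        # rule 4: i off with no active inhibitor possible -> activators off
        if entailed_zero(adj.inhibitors[i], vals):
            for j0 in sole_candidates(adj.activators[i], vals):
                eng.assign(j0, 0, "4")
    # rules 5-7 determine S_i itself and fire regardless of its current value
    if adj.r_diag[i] and entailed_zero(adj.activators[i], vals):
        eng.assign(i, 0, "5")
    if adj.g_diag[i] and entailed_zero(adj.inhibitors[i], vals):
        eng.assign(i, 1, "6")
    if entailed_zero(adj.inhibitors[i], vals) and any(
        vals[j0] == 1 for j0 in adj.activators[i]
    ):
        eng.assign(i, 1, "7")


def propagate(dec: RegulatoryDecomposition, partial, trace: bool = False) -> PropagationOutcome:
    """Run rules 1-7 to fixpoint on a partial state.

    Rules are swept over all nodes repeatedly until a full pass fires
    nothing; the fixpoint is order-independent because every rule is a
    monotone entailment.  A conclusion clashing with an already
    determined value yields a contradiction outcome (a normal result,
    not an error: it prunes the branch).
    """
    vals = parse_partial(partial)
    if vals.shape[0] != dec.n_nodes:
        raise ValueError("partial state length does not match network size")
    engine = RuleEngine(Adjacency(dec), _attractor_rules)
    return engine.run(vals, trace=trace)


def enumerate_singleton_attractors(
    net: SignedNetwork, max_attractors: int | None = None
) -> tuple[set[str], SearchStats]:
    """All fixed points of the strong-inhibition dynamics, as bitstrings.

    Branch-and-propagate search: propagate on the fully unknown state,
    then depth-first branching on the undecided node with the most
    putative inhibitory connections, value 1 before value 0, pruning on
    contradiction.  Leaves are verified against the fixed-point
    condition before being emitted.  ``max_attractors`` caps the result
    count (the ``capped`` flag in the returned stats marks a truncated
    enumeration).
    """
    dec = decompose(net)
    adj = Adjacency(dec)
    engine = RuleEngine(adj, _attractor_rules)
    verify = partial(is_singleton_attractor, dec)
    return branch_and_propagate(adj, engine, verify, net.n_nodes, max_attractors)


def brute_force_singleton_attractors(
    net: SignedNetwork, ceiling: int = 24, chunk: int = 1 << 18
) -> set[str]:
    """Exhaustive fixed-point scan over all 2^N states (testing oracle).

    Refuses networks above ``ceiling`` nodes: the scan is exponential
    and meant for validating the rule-based search, not for production.
    """
    n = net.n_nodes
    if n > ceiling:
        raise ResourceLimitError(
            f"brute force over 2^{n} states exceeds the ceiling of 2^{ceiling}; "
            "raise `ceiling` explicitly if you really want this"
        )
    dec = decompose(net)
    found: set[str] = set()
    total = 1 << n
    for start in range(0, total, chunk):
        ints = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        states = states_chunk(ints, n)
        fixed = np.all(step_batch(dec, states) == states, axis=1)
        for row in states[fixed]:
            found.add(format_state(row))
    return found
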