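"""Shared branch-and-propagate machinery for attractor and pre-image enumeration.

Both enumerations explore partial states (vectors over {0, 1, unknown})
by depth-first search: pick an undecided node, try value 1 then value 0,
run constraint propagation after each assignment, prune branches whose
propagation hits a contradiction, and emit fully determined leaves after
an independent verification step.  Only the propagation rule set differs
between the two problems, so it is injected as a callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .network_model import UNKNOWN, RegulatoryDecomposition, format_state

CONSISTENT = "consistent"
CONTRADICTION = "contradiction"


class ResourceLimitError(RuntimeError):
    """Raised when an exhaustive scan would exceed its configured ceiling."""


@dataclass
class SearchStats:
    """Hardware-independent search-effort counters.

    ``nodes_expanded`` counts branch-node expansions (each expansion
    spawns the two children S_i0 = 1 and S_i0 = 0); it is the
    machine-free stand-in for CPU time.  ``propagation_passes`` counts
    full rule sweeps, ``contradictions`` counts pruned branches, and
    ``attractors_found`` the number of emitted results.  ``capped`` is
    set when enumeration stopped early at a configured result cap.
    """

    nodes_expanded: int = 0
    propagation_passes: int = 0
    contradictions: int = 0
    attractors_found: int = 0
    capped: bool = False

    def as_dict(self) -> dict:
        return {
            "nodes_expanded": self.nodes_expanded,
            "propagation_passes": self.propagation_passes,
            "contradictions": self.contradictions,
            "attractors_found": self.attractors_found,
            "capped": self.capped,
        }


@dataclass(frozen=True)
class PropagationOutcome:
    """Result of running a rule set to fixpoint on a partial state.

    When ``status`` is ``"consistent"``, ``state`` extends the input
    (determined entries are a superset and never flip); on
    ``"contradiction"`` the partial state admits no completion and
    ``state`` is None.  ``fired_rules`` traces the determinations as
    (rule id, 1-based node index) pairs, the last entry being the
    conflicting one on contradiction.
    """

    status: str
    state: np.ndarray | None
    fired_rules: tuple[tuple[str, int], ...] = ()

    @property
    def is_contradiction(self) -> bool:
        return self.status == CONTRADICTION


class Adjacency:
    """Per-node neighbour lists derived from a regulatory decomposition."""

    def __init__(self, dec: RegulatoryDecomposition) -> None:
        g, r = dec.g, dec.r
        n = dec.n_nodes
        self.n = n
        self.g_diag = dec.g_diag
        self.r_diag = dec.r_diag
        # activators[i] / inhibitors[i]: sources j != i acting on target i
        self.activators = [
            [int(j) for j in np.flatnonzero(g[i]) if j != i] for i in range(n)
        ]
        self.inhibitors = [
            [int(j) for j in np.flatnonzero(r[i]) if j != i] for i in range(n)
        ]
        # inh_targets[j]: targets i != j inhibited by j
        self.inh_targets = [
            [int(i) for i in np.flatnonzero(r[:, j]) if i != j] for j in range(n)
        ]
        # branching heuristic: putative inhibitory in-degree + out-degree
        self.inhibitory_degree = (r.sum(axis=1) + r.sum(axis=0)).astype(int)
        # static branching order: degree descending, index ascending
        self.branch_order = sorted(
            range(n), key=lambda i: (-self.inhibitory_degree[i], i)
        )


def entailed_zero(members: Sequence[int], vals: np.ndarray) -> bool:
    """True iff every listed node is determined and equal to 0 (vacuously true)."""
    return all(vals[j] == 0 for j in members)


def sole_candidates(members: Sequence[int], vals: np.ndarray) -> list[int]:
    """Nodes j0 in ``members`` with every *other* member determined 0.

    This is the entailment reading of premises of the form
    "sum over j != j0 of S_j x_ij = 0": the conclusion about j0 may fire
    only once all competing terms are pinned to zero.  When all members
    are determined 0, every member qualifies (useful: the conclusion then
    clashes with the determined value and surfaces as a contradiction).
    """
    unknown = [j for j in members if vals[j] == UNKNOWN]
    ones = [j for j in members if vals[j] == 1]
    if len(ones) >= 2:
        return []
    if len(ones) == 1:
        return [] if unknown else ones
    if len(unknown) == 1:
        return unknown
    if not unknown:
        return list(members)
    return []


class _Contradiction(Exception):
    pass


class RuleEngine:
    """Runs a per-node rule function to fixpoint over a partial state."""

    def __init__(
        self,
        adj: Adjacency,
        node_rules: Callable[["RuleEngine", int], None],
    ) -> None:
        self.adj = adj
        self._node_rules = node_rules
        self.vals: np.ndarray = np.empty(0, dtype=np.int8)
        self.changed = False
        self.trace: list[tuple[str, int]] | None = None

    def assign(self, j: int, value: int, rule: str) -> None:
        v = self.vals[j]
        if v == UNKNOWN:
            self.vals[j] = value
            self.changed = True
            if self.trace is not None:
                self.trace.append((rule, j + 1))
        elif v != value:
            if self.trace is not None:
                self.trace.append((rule, j + 1))
            raise _Contradiction

    def contradiction(self, rule: str, i: int) -> None:
        if self.trace is not None:
            self.trace.append((rule, i + 1))
        raise _Contradiction

    def run(
        self,
        partial: np.ndarray,
        stats: SearchStats | None = None,
        trace: bool = False,
    ) -> PropagationOutcome:
        self.vals = np.array(partial, dtype=np.int8)
        self.trace = [] if trace else None
        fired: tuple[tuple[str, int], ...] = ()
        try:
            self.changed = True
            while self.changed:
                self.changed = False
                if stats is not None:
                    stats.propagation_passes += 1
                for i in range(self.adj.n):
                    self._node_rules(self, i)
        except _Contradiction:
            if self.trace is not None:
                fired = tuple(self.trace)
            return PropagationOutcome(CONTRADICTION, None, fired)
        if self.trace is not None:
            fired = tuple(self.trace)
        return PropagationOutcome(CONSISTENT, self.vals.copy(), fired)


def select_from_order(adj: Adjacency, vals: np.ndarray) -> int:
    """First undecided node in the static branching order (0-based)."""
    for i in adj.branch_order:
        if vals[i] == UNKNOWN:
            return i
    raise ValueError("partial state has no undetermined node")


def branch_and_propagate(
    adj: Adjacency,
    engine: RuleEngine,
    verify: Callable[[np.ndarray], bool],
    n: int,
    max_results: int | None = None,
) -> tuple[set[str], SearchStats]:
    """Depth-first enumeration of all completions consistent with the rules.

    Branch value 1 is explored before value 0.  Every fully determined
    leaf is re-checked with ``verify`` before being emitted; with a sound
    and terminating rule set the check never fails, it is defence in
    depth against rule transcription slips.
    """
    stats = SearchStats()
    results: set[str] = set()
    root = np.full(n, UNKNOWN, dtype=np.int8)
    out = engine.run(root, stats)
    if out.is_contradiction:
        stats.contradictions += 1
        return results, stats
    stack: list[np.ndarray] = [out.state]
    while stack:
        vals = stack.pop()
        if not np.any(vals == UNKNOWN):
            if verify(vals):
                results.add(format_state(vals))
                stats.attractors_found = len(results)
                if max_results is not None and len(results) >= max_results:
                    if stack:
                        stats.capped = True
                    break
            continue
        i0 = select_from_order(adj, vals)
        stats.nodes_expanded += 1
        for value in (0, 1):  # LIFO stack: value 1 is explored first
            child = vals.copy()
            child[i0] = value
            out = engine.run(child, stats)
            if out.is_contradiction:
                stats.contradictions += 1
            else:
                stack.append(out.state)
    stats.attractors_found = len(results)
    return results, stats


def states_chunk(ints: np.ndarray, n: int) -> np.ndarray:
    """Decode integers into (B, N) bit arrays, node 1 = most significant bit."""
    shifts = (n - 1 - np.arange(n)).astype(np.uint64)
    return ((ints[:, None] >> shifts) & 1).astype(np.int8)
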