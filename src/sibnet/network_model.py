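"""Core model: signed networks, the threshold update and its strong-inhibition limit.

A gene regulatory network is represented by a signed adjacency matrix
``a``, where ``a[i][j]`` is the effect of node *j* on node *i* (source =
column, target = row): ``+1`` activation, ``-1`` inhibition, ``0`` no
edge.  The synchronous threshold dynamics weighs off-diagonal inhibitory
edges by a factor gamma >= 1; in the dominant-inhibition limit
(gamma = infinity) the update collapses to a purely logical rule in which
a single active inhibitor switches its target off regardless of how many
activators are on.  That logical rule is the strong-inhibition model
implemented here, and only the *signs* of the edges matter for it, which
is why :class:`SignedNetwork` stores signs only.

States are length-N vectors over {0, 1}; partial states additionally
allow the sentinel :data:`UNKNOWN` (-1) for nodes whose value has not
been decided yet.  Externally states are written as bitstrings with node
1 leftmost (``"00001000100"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UNKNOWN",
    "SignedNetwork",
    "RegulatoryDecomposition",
    "Trajectory",
    "decompose",
    "parse_state",
    "format_state",
    "parse_partial",
    "format_partial",
    "as_state",
    "threshold_step",
    "strong_inhibition_step",
    "step_batch",
    "is_singleton_attractor",
    "trajectory",
]

#: Sentinel for an undecided node in a partial state.
UNKNOWN = -1


class NetworkValidationError(ValueError):
    """Raised when a signed adjacency matrix violates the model's contract."""


@dataclass(frozen=True)
class SignedNetwork:
    """A signed regulatory network.

    Parameters
    ----------
    a
        N x N integer matrix with entries in {-1, 0, +1}; ``a[i][j]`` is
        the sign of the edge from node ``j+1`` to node ``i+1`` (1-based
        node numbering is used in all external interfaces).
    node_labels
        Optional node names, length N.
    """

    a: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.int8)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkValidationError(
                f"adjacency matrix must be square, got shape {a.shape}"
            )
        if a.shape[0] < 1:
            raise NetworkValidationError("network needs at least one node")
        bad = np.argwhere((a < -1) | (a > 1))
        if bad.size:
            i, j = bad[0]
            raise NetworkValidationError(
                f"entry a[{i + 1}][{j + 1}] = {self.a[i][j]} not in {{-1, 0, 1}}"
            )
        object.__setattr__(self, "a", a)
        if self.node_labels is not None:
            labels = tuple(str(x) for x in self.node_labels)
            if len(labels) != a.shape[0]:
                raise NetworkValidationError(
                    f"{len(labels)} labels for {a.shape[0]} nodes"
                )
            object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of edges = nonzero matrix entries (self-edges included)."""
        return int(np.count_nonzero(self.a))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return np.array_equal(self.a, other.a)

    def __hash__(self) -> int:
        return hash(self.a.tobytes())


@dataclass(frozen=True)
class RegulatoryDecomposition:
    """Binary split of a sign matrix into putative stimulatory (g) and inhibitory (r) edges.

    ``g[i][j] = 1`` iff node j activates node i; ``r[i][j] = 1`` iff node j
    inhibits node i.  An edge is never both.  Derived arrays used by the
    vectorised update are cached here (off-diagonal copies and diagonals).
    """

    g: np.ndarray
    r: np.ndarray
    # caches, derived in __post_init__
    g_off: np.ndarray = field(init=False, repr=False, compare=False)
    r_off: np.ndarray = field(init=False, repr=False, compare=False)
    g_diag: np.ndarray = field(init=False, repr=False, compare=False)
    r_diag: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=np.int8)
        r = np.asarray(self.r, dtype=np.int8)
        if g.shape != r.shape or g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise NetworkValidationError("g and r must be equal-shape square matrices")
        if np.any((g < 0) | (g > 1)) or np.any((r < 0) | (r > 1)):
            raise NetworkValidationError("g and r must be binary")
        if np.any(g * r):
            raise NetworkValidationError("g[i][j] and r[i][j] cannot both be 1")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "r", r)
        off = ~np.eye(g.shape[0], dtype=bool)
        object.__setattr__(self, "g_off", (g * off).astype(np.int8))
        object.__setattr__(self, "r_off", (r * off).astype(np.int8))
        object.__setattr__(self, "g_diag", np.diag(g).copy())
        object.__setattr__(self, "r_diag", np.diag(r).copy())

    @property
    def n_nodes(self) -> int:
        return self.g.shape[0]

    def sign_matrix(self) -> np.ndarray:
        """Recover the signed adjacency matrix (inverse of :func:`decompose`)."""
        return (self.g.astype(np.int8) - self.r.astype(np.int8)).astype(np.int8)


def decompose(net: SignedNetwork) -> RegulatoryDecomposition:
    """Split a signed network into putative stimulatory / inhibitory indicator matrices.

    ``a[i][j] = +1`` maps to ``g[i][j] = 1``; ``a[i][j] = -1`` maps to
    ``r[i][j] = 1``; absent edges map to zero in both.
    """
    a = net.a
    return RegulatoryDecomposition(g=(a == 1).astype(np.int8), r=(a == -1).astype(np.int8))


# ---------------------------------------------------------------------------
# state helpers


def parse_state(bits: str | Sequence[int]) -> np.ndarray:
    """Turn a bitstring (node 1 leftmost) or 0/1 sequence into a state array."""
    if isinstance(bits, str):
        try:
            arr = np.array([int(c) for c in bits.strip()], dtype=np.int8)
        except ValueError as exc:
            raise ValueError(f"invalid state bitstring {bits!r}") from exc
    else:
        arr = np.asarray(bits, dtype=np.int8)
    if arr.ndim != 1 or np.any((arr != 0) & (arr != 1)):
        raise ValueError(f"state entries must be 0 or 1, got {bits!r}")
    return arr


def format_state(state: Sequence[int]) -> str:
    """Bitstring form of a fully determined state, node 1 leftmost."""
    return "".join(str(int(x)) for x in state)


def parse_partial(text: str | Sequence[int]) -> np.ndarray:
    """Parse a partial state; '?', '*' or -1 mark undecided nodes."""
    if isinstance(text, str):
        mapping = {"0": 0, "1": 1, "?": UNKNOWN, "*": UNKNOWN}
        try:
            arr = np.array([mapping[c] for c in text.strip()], dtype=np.int8)
        except KeyError as exc:
            raise ValueError(f"invalid partial-state character in {text!r}") from exc
    else:
        arr = np.asarray(text, dtype=np.int8)
        if np.any((arr != 0) & (arr != 1) & (arr != UNKNOWN)):
            raise ValueError("partial-state entries must be 0, 1 or UNKNOWN (-1)")
    return arr


def format_partial(partial: Sequence[int]) -> str:
    return "".join("?" if int(x) == UNKNOWN else str(int(x)) for x in partial)


def n_unknown(partial: np.ndarray) -> int:
    """l0: number of undecided nodes in a partial state."""
    return int(np.count_nonzero(np.asarray(partial) == UNKNOWN))


def as_state(state: str | Sequence[int], n: int) -> np.ndarray:
    """Coerce to a length-``n`` state array, validating the length."""
    arr = parse_state(state)
    if arr.shape[0] != n:
        raise ValueError(f"state has {arr.shape[0]} entries for a {n}-node network")
    return arr


# ---------------------------------------------------------------------------
# dynamics


def threshold_step(
    net: SignedNetwork, state: str | Sequence[int], gamma: float = np.inf
) -> np.ndarray:
    """One synchronous step of the weighted threshold dynamics.

    Each node computes the weighted sum of its inputs, where an
    off-diagonal ``-1`` entry counts as weight ``-gamma`` and a diagonal
    ``-1`` as weight ``-1``; positive sum switches the node on, negative
    switches it off, zero leaves it unchanged.

    ``gamma`` must be >= 1 (inhibition at least as strong as activation);
    ``numpy.inf`` gives the dominant-inhibition limit, in which case a
    node with any active inhibitor is forced off.
    """
    if gamma < 1:
        raise ValueError(f"gamma must be >= 1, got {gamma}")
    s = as_state(state, net.n_nodes)
    a = net.a
    if np.isinf(gamma):
        # avoid inf*0: any active off-diagonal inhibitor makes the sum -inf,
        # otherwise the finite part (activators plus the +/-1 self-weight) decides
        dec = decompose(net)
        diag = np.diag(a).astype(np.int64)
        finite = (dec.g_off @ s).astype(np.int64) + diag * s
        inh_active = (dec.r_off @ s) > 0
        sign = np.where(inh_active, -1, np.sign(finite))
        return np.where(sign > 0, 1, np.where(sign < 0, 0, s)).astype(np.int8)
    w = a.astype(np.float64)
    off = ~np.eye(net.n_nodes, dtype=bool)
    w[off & (a == -1)] = -float(gamma)
    total = w @ s
    return np.where(total > 0, 1, np.where(total < 0, 0, s)).astype(np.int8)


def strong_inhibition_step(
    dec: RegulatoryDecomposition, state: str | Sequence[int]
) -> np.ndarray:
    """One synchronous step of the strong-inhibition (dominant inhibition) rule.

    S_i(t+1) = (OR_{j != i} S_j g_ij  OR  S_i & ~r_ii  OR  ~S_i & g_ii)
               AND NOT (OR_{j != i} S_j r_ij)
    """
    s = as_state(state, dec.n_nodes)
    act = (dec.g_off @ s) > 0
    inh = (dec.r_off @ s) > 0
    keep = (s == 1) & (dec.r_diag == 0)
    self_on = (s == 0) & (dec.g_diag == 1)
    return ((act | keep | self_on) & ~inh).astype(np.int8)


def step_batch(dec: RegulatoryDecomposition, states: np.ndarray) -> np.ndarray:
    """Vectorised strong-inhibition step for a (B, N) batch of states."""
    s = np.asarray(states, dtype=np.int8)
    act = (s @ dec.g_off.T) > 0
    inh = (s @ dec.r_off.T) > 0
    keep = (s == 1) & (dec.r_diag == 0)
    self_on = (s == 0) & (dec.g_diag == 1)
    return ((act | keep | self_on) & ~inh).astype(np.int8)


def is_singleton_attractor(
    dec: RegulatoryDecomposition, state: str | Sequence[int]
) -> bool:
    """True iff the state is a fixed point of the strong-inhibition update."""
    s = as_state(state, dec.n_nodes)
    return bool(np.array_equal(strong_inhibition_step(dec, s), s))


@dataclass(frozen=True)
class Trajectory:
    """Synchronous trajectory with a terminal descriptor.

    ``states`` starts at the initial state; ``status`` is ``"fixed_point"``
    (last state maps to itself), ``"cycle"`` (last state equals the state
    at index ``cycle_start`` < len-1), or ``"exhausted"`` (step budget hit
    before any repeat).
    """

    states: tuple[str, ...]
    status: str
    cycle_start: int | None = None

    def __len__(self) -> int:
        return len(self.states)


def trajectory(
    dec: RegulatoryDecomposition,
    start: str | Sequence[int],
    max_steps: int = 10_000,
) -> Trajectory:
    """Iterate the strong-inhibition update until a repeat or the step budget."""
    s = as_state(start, dec.n_nodes)
    seen: dict[str, int] = {}
    states: list[str] = []
    cur = format_state(s)
    for _ in range(max_steps + 1):
        if cur in seen:
            first = seen[cur]
            if first == len(states) - 1:
                return Trajectory(tuple(states), "fixed_point")
            return Trajectory(tuple(states), "cycle", cycle_start=first)
        seen[cur] = len(states)
        states.append(cur)
        s = strong_inhibition_step(dec, s)
        cur = format_state(s)
    return Trajectory(tuple(states), "exhausted")
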