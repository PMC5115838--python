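"""Readers and writers for networks and results, plus bundled fixture networks.

Two plain-text network encodings are supported.

Matrix format
    N rows by N columns, delimited by tabs, commas or whitespace, entries
    in {-1, 0, 1}.  ``a[i][j]`` is the effect of node j (column) on node
    i (row).  An optional header row and an optional leading label column
    carry node names; lines starting with ``#`` are comments.

Edge-list format
    Three columns ``source  target  sign`` with sign in {-1, +1}.
    Endpoints are 1-based node indices (or labels, numbered by first
    appearance).  The edge acts from source to target, i.e. it sets
    ``a[target][source]``.

States and attractors are written as bitstrings with node 1 leftmost,
ordered lexicographically; JSON output carries a schema tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from ._search import SearchStats
from .network_model import SignedNetwork
from .preimage_search import BasinLayers

__all__ = [
    "NetworkParseError",
    "NetworkFixture",
    "read_network",
    "write_network",
    "write_results",
    "results_payload",
    "load_fixture",
    "budding_yeast",
    "list_fixtures",
]

_VALID_TOKENS = {"-1", "0", "1", "+1"}


class NetworkParseError(ValueError):
    """Parse failure, carrying file and line context."""

    def __init__(self, path, line_no: int | None, message: str) -> None:
        where = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{where}: {message}")


def _tokenize(line: str) -> list[str]:
    if "\t" in line:
        return [t.strip() for t in line.split("\t")]
    if "," in line:
        return [t.strip() for t in line.split(",")]
    return line.split()


def _content_lines(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.append((no, _tokenize(line)))
    return out


def _parse_matrix(path, rows: list[tuple[int, list[str]]]) -> SignedNetwork:
    if not rows:
        raise NetworkParseError(path, None, "file contains no data lines")
    header: list[str] | None = None
    body = rows
    # header row: any token that is not a valid entry (labels)
    if any(t not in _VALID_TOKENS for t in rows[0][1]):
        first_data = rows[0][1]
        if all(t not in _VALID_TOKENS for t in first_data if t):
            header = [t for t in first_data if t]
            body = rows[1:]
    if not body:
        raise NetworkParseError(path, None, "matrix has a header but no rows")
    row_labels: list[str] = []
    data: list[list[int]] = []
    width = None
    for no, toks in body:
        if toks and toks[0] not in _VALID_TOKENS:
            row_labels.append(toks[0])
            toks = toks[1:]
        for t in toks:
            if t not in _VALID_TOKENS:
                raise NetworkParseError(
                    path, no, f"matrix entry {t!r} not in {{-1, 0, 1}}"
                )
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise NetworkParseError(
                path, no, f"row has {len(toks)} entries, expected {width}"
            )
        data.append([int(t) for t in toks])
    n = len(data)
    if width != n:
        raise NetworkParseError(
            path, None, f"matrix is {n} rows by {width} columns, must be square"
        )
    labels = None
    if row_labels and len(row_labels) == n:
        labels = tuple(row_labels)
    elif header and len(header) == n:
        labels = tuple(header)
    elif header and len(header) == n + 1:  # corner cell above the label column
        labels = tuple(header[1:])
    return SignedNetwork(a=np.array(data, dtype=np.int8), node_labels=labels)


def _parse_edge_list(
    path, rows: list[tuple[int, list[str]]], n_nodes: int | None
) -> SignedNetwork:
    if not rows:
        raise NetworkParseError(path, None, "file contains no data lines")
    triples: list[tuple[int, str, str, int]] = []
    for no, toks in rows:
        if len(toks) != 3:
            raise NetworkParseError(
                path, no, f"expected 3 columns (source, target, sign), got {len(toks)}"
            )
        src, tgt, sign_tok = toks
        if sign_tok not in {"-1", "1", "+1"}:
            raise NetworkParseError(path, no, f"edge sign {sign_tok!r} must be -1 or +1")
        triples.append((no, src, tgt, int(sign_tok)))

    def _is_index(tok: str) -> bool:
        return tok.isdigit() and int(tok) >= 1

    numeric = all(_is_index(s) and _is_index(t) for _, s, t, _ in triples)
    labels: list[str] | None = None
    if numeric:
        n = max(max(int(s), int(t)) for _, s, t, _ in triples)
        if n_nodes is not None:
            if n_nodes < n:
                raise NetworkParseError(
                    path, None, f"n_nodes={n_nodes} but edge list references node {n}"
                )
            n = n_nodes
        index = {str(k): k - 1 for k in range(1, n + 1)}
    else:
        seen: dict[str, int] = {}
        for _, s, t, _ in triples:
            for tok in (s, t):
                if tok not in seen:
                    seen[tok] = len(seen)
        n = len(seen)
        index = seen
        labels = list(seen)
    a = np.zeros((n, n), dtype=np.int8)
    for no, s, t, sign in triples:
        i, j = index[t], index[s]  # edge from source j to target i
        if a[i, j] != 0 and a[i, j] != sign:
            raise NetworkParseError(
                path, no, f"conflicting duplicate edge {s!r} -> {t!r}"
            )
        a[i, j] = sign
    return SignedNetwork(a=a, node_labels=tuple(labels) if labels else None)


def read_network(path, fmt: str = "auto", n_nodes: int | None = None) -> SignedNetwork:
    """Read a signed network from a matrix or edge-list file.

    ``fmt`` is ``"matrix"``, ``"edge-list"`` or ``"auto"``; auto first
    attempts the matrix format and falls back to the edge list.  Pass an
    explicit format for the (rare) three-node files that parse as both.
    """
    rows = _content_lines(path)
    if fmt == "matrix":
        return _parse_matrix(path, rows)
    if fmt in ("edge-list", "edgelist", "edges"):
        return _parse_edge_list(path, rows, n_nodes)
    if fmt != "auto":
        raise ValueError(f"unknown format {fmt!r}")
    try:
        return _parse_matrix(path, rows)
    except NetworkParseError as matrix_err:
        try:
            return _parse_edge_list(path, rows, n_nodes)
        except NetworkParseError:
            raise matrix_err from None


def write_network(net: SignedNetwork, path, fmt: str = "matrix") -> None:
    """Write a network as a tab-separated matrix or signed edge list."""
    path = Path(path)
    lines: list[str] = ["# sibnet network; a[i][j] = effect of node j (column) on node i (row)"]
    if fmt == "matrix":
        if net.node_labels:
            lines.append("\t".join(net.node_labels))
        for i in range(net.n_nodes):
            row = [str(int(x)) for x in net.a[i]]
            if net.node_labels:
                row.insert(0, net.node_labels[i])
            lines.append("\t".join(row))
    elif fmt in ("edge-list", "edgelist", "edges"):
        # 1-based indices keep the node order exact on read-back; labelled
        # edge lists (reader-supported) number nodes by first appearance
        lines.append("# source\ttarget\tsign")
        for i in range(net.n_nodes):
            for j in range(net.n_nodes):
                if net.a[i, j]:
                    lines.append(f"{j + 1}\t{i + 1}\t{int(net.a[i, j])}")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# result serialisation

SCHEMA = "sibnet/1"


def results_payload(result, stats: SearchStats | None = None) -> dict:
    """JSON-ready dict for an attractor/pre-image set or a basin."""
    if isinstance(result, BasinLayers):
        payload: dict = {
            "schema": SCHEMA,
            "kind": "basin",
            "attractor": result.attractor,
            "size": result.size,
            "layers": [sorted(layer) for layer in result.layers],
        }
    else:
        payload = {
            "schema": SCHEMA,
            "kind": "states",
            "count": len(result),
            "states": sorted(result),
        }
    if stats is not None:
        payload["stats"] = stats.as_dict()
    return payload


def write_results(result, path, fmt: str = "json", stats: SearchStats | None = None) -> None:
    """Write a state set or basin to ``path`` as JSON or plain text.

    Text output is one bitstring per line in lexicographic order (basin
    layers separated by ``# layer d`` comment lines); JSON output is the
    :func:`results_payload` document.
    """
    path = Path(path)
    if fmt == "json":
        path.write_text(
            json.dumps(results_payload(result, stats), indent=2) + "\n",
            encoding="utf-8",
        )
        return
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    lines: list[str] = []
    if isinstance(result, BasinLayers):
        for d, layer in enumerate(result.layers):
            lines.append(f"# layer {d}")
            lines.extend(sorted(layer))
    else:
        lines.extend(sorted(result))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class NetworkFixture:
    """A bundled benchmark network with its known fixed-point count."""

    name: str
    source: str
    network: SignedNetwork
    expected_attractor_count: int | None = None


_FIXTURES = {
    "budding_yeast": (
        "budding_yeast.tsv",
        7,
        "Budding-yeast cell-cycle network (Li et al. 2004, PNAS 101:4781), "
        "11 nodes / 34 edges including five self-degradation loops.",
    ),
}


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str) -> NetworkFixture:
    """Load a bundled fixture network by name (see :func:`list_fixtures`)."""
    try:
        filename, count, source = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {list_fixtures()}") from None
    ref = resources.files("sibnet").joinpath("fixtures", filename)
    with resources.as_file(ref) as path:
        net = read_network(path, fmt="matrix")
    return NetworkFixture(
        name=name, source=source, network=net, expected_attractor_count=count
    )


def budding_yeast() -> SignedNetwork:
    """The 11-node, 34-edge budding-yeast cell-cycle network."""
    return load_fixture("budding_yeast").network
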