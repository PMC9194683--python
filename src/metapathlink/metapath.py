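"""Metapath schemas and metapath-instance enumeration/sampling.

A metapath is a pattern of node types such as microbe-drug-microbe
("m-c-m"); a metapath instance is a concrete node sequence following it
through the network. For a symmetric metapath the returning instance
that ends at the start node itself is a valid instance.

Enumeration is exhaustive depth-first search over the typed adjacency
structure; sampling draws uniformly without replacement from the full
enumeration, capped at a configurable budget per target node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .network import ABBREV_OF, TYPE_ABBREV, NetworkError, TripartiteNetwork

MAX_METAPATH_LEN = 5

# default catalog: the four patterns used for microbe/disease embeddings
# plus drug-centred patterns so intermediate drug nodes are refreshed in
# multi-layer stacks
DEFAULT_CATALOG = {
    "microbe": ("m-c-m", "m-d-m"),
    "disease": ("d-m-d", "d-c-d"),
    "drug": ("c-m-c", "c-d-c"),
}


@dataclass(frozen=True)
class Metapath:
    """A node-type pattern, e.g. (microbe, drug, microbe)."""

    type_sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.type_sequence) < 2:
            raise ValueError("metapath needs at least two node types")
        if len(self.type_sequence) > MAX_METAPATH_LEN:
            raise ValueError(f"metapath longer than {MAX_METAPATH_LEN} not supported")
        for a, b in zip(self.type_sequence, self.type_sequence[1:]):
            if a == b:
                raise ValueError(f"consecutive identical types in metapath: {a}")

    @property
    def name(self) -> str:
        return "-".join(ABBREV_OF[t] for t in self.type_sequence)

    @property
    def start_type(self) -> str:
        return self.type_sequence[0]

    @property
    def end_type(self) -> str:
        return self.type_sequence[-1]

    @property
    def is_symmetric(self) -> bool:
        return self.type_sequence == self.type_sequence[::-1]

    def reversed(self) -> "Metapath":
        return Metapath(self.type_sequence[::-1])

    def __len__(self) -> int:
        return len(self.type_sequence)


@dataclass(frozen=True)
class MetapathInstance:
    """A concrete node sequence conforming to a metapath."""

    metapath: Metapath
    node_sequence: tuple[str, ...]

    @property
    def target(self) -> str:
        return self.node_sequence[0]

    @property
    def endpoint(self) -> str:
        return self.node_sequence[-1]


def intermediate_nodes(inst: MetapathInstance) -> set[str]:
    """Nodes of the sequence minus target and endpoint (the context set)."""
    return set(inst.node_sequence) - {inst.target, inst.endpoint}


def parse_metapath(spec: str) -> Metapath:
    """Parse "m-c-m" or "mcm" into a validated :class:`Metapath`."""
    tokens = list(spec) if "-" not in spec else spec.split("-")
    types = []
    for tok in tokens:
        tok = tok.strip().lower()
        if tok not in TYPE_ABBREV:
            raise ValueError(f"unknown node-type token {tok!r} in metapath {spec!r}")
        types.append(TYPE_ABBREV[tok])
    return Metapath(tuple(types))


def parse_catalog(raw: dict) -> dict[str, tuple[Metapath, ...]]:
    """Parse a {type: [schema strings]} mapping; every metapath must start
    and end at its key type."""
    catalog: dict[str, tuple[Metapath, ...]] = {}
    for type_key, specs in raw.items():
        node_type = TYPE_ABBREV.get(type_key, type_key)
        paths = []
        for s in specs:
            mp = parse_metapath(s)
            if mp.start_type != node_type or mp.end_type != node_type:
                raise ValueError(
                    f"metapath {mp.name!r} does not start and end at {node_type!r}"
                )
            paths.append(mp)
        if not paths:
            raise ValueError(f"empty metapath list for type {node_type!r}")
        catalog[node_type] = tuple(paths)
    return catalog


def default_catalog() -> dict[str, tuple[Metapath, ...]]:
    return parse_catalog(DEFAULT_CATALOG)


# ---------------------------------------------------------------------
# typed adjacency (index space) and enumeration


def typed_adjacency(net: TripartiteNetwork) -> dict[tuple[str, str], list[np.ndarray]]:
    """Adjacency lists between ordered type pairs in dense index space.

    ``adj[(a, b)][i]`` is the sorted array of type-``b`` indices adjacent
    to the ``i``-th node of type ``a``.
    """
    cat = net.catalog
    adj: dict[tuple[str, str], list[list[int]]] = {}
    for (a_type, b_type), edges in net.edge_sets().items():
        fwd: list[list[int]] = [[] for _ in range(cat.size_of(a_type))]
        rev: list[list[int]] = [[] for _ in range(cat.size_of(b_type))]
        ai, bi = cat.index[a_type], cat.index[b_type]
        for a, b in edges:
            fwd[ai[a]].append(bi[b])
            rev[bi[b]].append(ai[a])
        adj[(a_type, b_type)] = fwd
        adj[(b_type, a_type)] = rev
    return {
        key: [np.array(sorted(nbrs), dtype=np.intp) for nbrs in lists]
        for key, lists in adj.items()
    }


def enumerate_instances_idx(adj: dict, metapath: Metapath,
                            start_idx: int) -> np.ndarray:
    """All instances of ``metapath`` from a start node, as an (N, L) index
    array. Depth-first expansion over the typed adjacency."""
    types = metapath.type_sequence
    paths = np.array([[start_idx]], dtype=np.intp)
    for a_type, b_type in zip(types, types[1:]):
        nbr = adj[(a_type, b_type)]
        rows = []
        for path in paths:
            nxt = nbr[path[-1]]
            if len(nxt):
                rows.append(np.column_stack([
                    np.broadcast_to(path, (len(nxt), len(path))), nxt]))
        if not rows:
            return np.empty((0, len(types)), dtype=np.intp)
        paths = np.concatenate(rows, axis=0)
    return paths


def enumerate_all_instances_idx(adj: dict, metapath: Metapath,
                                n_start: int) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate instances for every start node of the metapath's type.

    Returns ``(instances, counts)`` where ``instances`` is (N, L) with
    rows grouped by start node and ``counts[i]`` is the number of
    instances whose target is node ``i``.
    """
    blocks = []
    counts = np.zeros(n_start, dtype=np.intp)
    for i in range(n_start):
        block = enumerate_instances_idx(adj, metapath, i)
        counts[i] = len(block)
        if len(block):
            blocks.append(block)
    if not blocks:
        return np.empty((0, len(metapath)), dtype=np.intp), counts
    return np.concatenate(blocks, axis=0), counts


def sample_instances(net: TripartiteNetwork, metapath: Metapath, node_id: str,
                     k: int, seed: int,
                     adj: dict | None = None) -> list[MetapathInstance]:
    """Uniformly sample up to ``k`` metapath instances starting at a node.

    With ``k`` at least the total count this is the full enumeration (in
    deterministic order). Sampling is without replacement and reproducible
    from ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cat = net.catalog
    start_type = metapath.start_type
    if node_id not in cat.index[start_type]:
        raise NetworkError(
            f"node {node_id!r} is not a {start_type}; cannot start metapath {metapath.name}"
        )
    if adj is None:
        adj = typed_adjacency(net)
    idx_paths = enumerate_instances_idx(adj, metapath, cat.index[start_type][node_id])
    if len(idx_paths) > k:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(idx_paths), size=k, replace=False)
        idx_paths = idx_paths[np.sort(chosen)]
    ids_by_type = [cat.ids_of(t) for t in metapath.type_sequence]
    return [
        MetapathInstance(
            metapath=metapath,
            node_sequence=tuple(ids_by_type[pos][j] for pos, j in enumerate(row)),
        )
        for row in idx_paths
    ]


def subsample_grouped(instances: np.ndarray, counts: np.ndarray, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-target uniform subsample of a grouped instance array.

    ``instances`` rows are grouped by target (group ``i`` has ``counts[i]``
    rows); each group keeps at most ``k`` rows, drawn without replacement.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    keep_rows = []
    offset = 0
    for c in counts:
        if c <= k:
            keep_rows.append(np.arange(offset, offset + c))
        else:
            chosen = rng.choice(c, size=k, replace=False)
            keep_rows.append(offset + np.sort(chosen))
        offset += c
    return instances[np.concatenate(keep_rows)] if keep_rows else instances
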