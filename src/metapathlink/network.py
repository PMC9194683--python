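"""Tripartite microbe-drug-disease network container and I/O.

The network has three node types (microbe ``m``, drug ``c``, disease ``d``)
and three undirected, unweighted relations: microbe-disease, microbe-drug
and disease-drug. Node identifiers are opaque strings; within each type
they are ordered lexicographically so every downstream index, matrix row
and column is reproducible regardless of input file order.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

NODE_TYPES = ("microbe", "drug", "disease")
TYPE_ABBREV = {"m": "microbe", "c": "drug", "d": "disease"}
ABBREV_OF = {v: k for k, v in TYPE_ABBREV.items()}


class NetworkError(ValueError):
    """Raised when an edge list or network violates a structural invariant."""


@dataclass(frozen=True)
class NodeCatalog:
    """Ordered node identifiers per type with dense 0-based indices.

    ``index[type][node_id]`` is the node's position within its type;
    positions are contiguous and follow lexicographic id order.
    """

    microbes: tuple[str, ...]
    drugs: tuple[str, ...]
    diseases: tuple[str, ...]
    index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        idx = {
            "microbe": {n: i for i, n in enumerate(self.microbes)},
            "drug": {n: i for i, n in enumerate(self.drugs)},
            "disease": {n: i for i, n in enumerate(self.diseases)},
        }
        for t, names in (("microbe", self.microbes), ("drug", self.drugs),
                         ("disease", self.diseases)):
            if len(idx[t]) != len(names):
                raise NetworkError(f"duplicate node ids within type {t!r}")
        object.__setattr__(self, "index", idx)

    @property
    def n_m(self) -> int:
        return len(self.microbes)

    @property
    def n_c(self) -> int:
        return len(self.drugs)

    @property
    def n_d(self) -> int:
        return len(self.diseases)

    def ids_of(self, node_type: str) -> tuple[str, ...]:
        return {"microbe": self.microbes, "drug": self.drugs,
                "disease": self.diseases}[node_type]

    def size_of(self, node_type: str) -> int:
        return len(self.ids_of(node_type))


@dataclass(frozen=True)
class TripartiteNetwork:
    """Typed node catalog plus the three undirected relation edge sets.

    Edges are stored as frozensets of (id, id) tuples in canonical order
    (microbe, disease) / (microbe, drug) / (disease, drug).
    """

    catalog: NodeCatalog
    md_edges: frozenset
    mc_edges: frozenset
    dc_edges: frozenset

    def validate(self) -> None:
        for (a_type, b_type), edges in self.edge_sets().items():
            a_ids = self.catalog.index[a_type]
            b_ids = self.catalog.index[b_type]
            for a, b in edges:
                if a not in a_ids:
                    raise NetworkError(f"edge endpoint {a!r} missing from {a_type} catalog")
                if b not in b_ids:
                    raise NetworkError(f"edge endpoint {b!r} missing from {b_type} catalog")

    def edge_sets(self) -> dict:
        return {
            ("microbe", "disease"): self.md_edges,
            ("microbe", "drug"): self.mc_edges,
            ("disease", "drug"): self.dc_edges,
        }

    def counts(self) -> dict:
        return {
            "n_microbes": self.catalog.n_m,
            "n_drugs": self.catalog.n_c,
            "n_diseases": self.catalog.n_d,
            "n_md_edges": len(self.md_edges),
            "n_mc_edges": len(self.mc_edges),
            "n_dc_edges": len(self.dc_edges),
        }

    def drop_md_edges(self, pairs: Iterable[tuple[str, str]]) -> "TripartiteNetwork":
        """Return a copy with the given microbe-disease pairs removed.

        Node catalogs are unchanged (transductive setting: held-out edges
        leave the message-passing graph, their endpoints remain).
        """
        drop = {tuple(p) for p in pairs}
        return TripartiteNetwork(
            catalog=self.catalog,
            md_edges=frozenset(e for e in self.md_edges if e not in drop),
            mc_edges=self.mc_edges,
            dc_edges=self.dc_edges,
        )


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary microbe x disease matrix B; rows/columns follow catalog order."""

    B: np.ndarray
    microbes: tuple[str, ...]
    diseases: tuple[str, ...]

    @property
    def density(self) -> float:
        if self.B.size == 0:
            return 0.0
        return float(self.B.sum()) / self.B.size

    def to_mtx(self, path: str | Path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), sp.coo_matrix(self.B))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.B, index=list(self.microbes),
                     columns=list(self.diseases)).to_csv(path)


def _sniff_delimiter(sample: str) -> str:
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def read_edge_list(path: str | Path, type_pair: tuple[str, str],
                   delimiter: str | None = None) -> set:
    """Read a two-column delimited edge list into a set of id pairs.

    Delimiter is auto-detected between comma and tab unless given. A
    header row is skipped when its first field matches common column
    labels. Duplicate rows are dropped (count logged); a row joining an
    id to itself is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    with open(path, newline="") as fh:
        text_rows = [ln for ln in fh]
    if not text_rows:
        return pairs
    delim = delimiter or _sniff_delimiter(text_rows[0])
    reader = csv.reader(text_rows, delimiter=delim)
    for lineno, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 2:
            raise NetworkError(f"{path}:{lineno}: expected >=2 fields, got {len(row)}")
        a, b = row[0].strip(), row[1].strip()
        if lineno == 1 and _looks_like_header(a, b, type_pair):
            continue
        if not a or not b:
            raise NetworkError(f"{path}:{lineno}: empty node id")
        if a == b:
            raise NetworkError(f"{path}:{lineno}: edge joins id {a!r} to itself")
        if (a, b) in pairs:
            dropped += 1
        else:
            pairs.add((a, b))
    if dropped:
        logger.info("%s: dropped %d duplicate edges", path, dropped)
    return pairs


_HEADER_WORDS = {"microbe", "drug", "disease", "source", "target", "id",
                 "node1", "node2", "from", "to"}


def _looks_like_header(a: str, b: str, type_pair: tuple[str, str]) -> bool:
    return a.lower() in _HEADER_WORDS and b.lower() in _HEADER_WORDS


def _check_case_collisions(ids: Iterable[str], node_type: str) -> None:
    seen: dict[str, str] = {}
    for i in ids:
        key = i.strip().lower()
        if key in seen and seen[key] != i:
            logger.warning(
                "%s ids %r and %r differ only by case/whitespace", node_type, seen[key], i
            )
        seen.setdefault(key, i)


def build_network(md: Iterable[tuple[str, str]], mc: Iterable[tuple[str, str]],
                  dc: Iterable[tuple[str, str]],
                  catalog: NodeCatalog | None = None) -> TripartiteNetwork:
    """Assemble a validated tripartite network from the three pair sets.

    The catalog is the union of all ids seen in the edge lists (plus any
    supplied catalog), sorted lexicographically within each type. An id
    appearing with two different types raises a type-conflict error.
    """
    md = {tuple(p) for p in md}
    mc = {tuple(p) for p in mc}
    dc = {tuple(p) for p in dc}

    typed: dict[str, set[str]] = {"microbe": set(), "drug": set(), "disease": set()}
    if catalog is not None:
        typed["microbe"].update(catalog.microbes)
        typed["drug"].update(catalog.drugs)
        typed["disease"].update(catalog.diseases)
    for a, b in md:
        typed["microbe"].add(a)
        typed["disease"].add(b)
    for a, b in mc:
        typed["microbe"].add(a)
        typed["drug"].add(b)
    for a, b in dc:
        typed["disease"].add(a)
        typed["drug"].add(b)

    for t1 in NODE_TYPES:
        for t2 in NODE_TYPES:
            if t1 < t2:
                clash = typed[t1] & typed[t2]
                if clash:
                    raise NetworkError(
                        f"ids appear as both {t1} and {t2}: {sorted(clash)[:5]}"
                    )
    for t in NODE_TYPES:
        _check_case_collisions(typed[t], t)

    cat = NodeCatalog(
        microbes=tuple(sorted(typed["microbe"])),
        drugs=tuple(sorted(typed["drug"])),
        diseases=tuple(sorted(typed["disease"])),
    )
    net = TripartiteNetwork(catalog=cat, md_edges=frozenset(md),
                            mc_edges=frozenset(mc), dc_edges=frozenset(dc))
    net.validate()
    return net


def association_matrix(net: TripartiteNetwork) -> AssociationMatrix:
    """Build the binary microbe x disease adjacency matrix B."""
    cat = net.catalog
    B = np.zeros((cat.n_m, cat.n_d), dtype=np.int8)
    mi = cat.index["microbe"]
    di = cat.index["disease"]
    for m, d in net.md_edges:
        B[mi[m], di[d]] = 1
    return AssociationMatrix(B=B, microbes=cat.microbes, diseases=cat.diseases)


def write_edge_list(pairs: Iterable[tuple[str, str]], path: str | Path,
                    delimiter: str = ",") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for a, b in sorted(pairs):
            writer.writerow([a, b])
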