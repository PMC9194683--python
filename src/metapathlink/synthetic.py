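"""Seed-reproducible synthetic tripartite networks with planted blocks.

Every node (microbe, drug, disease) is assigned to one of ``n_blocks``
communities; each cross-type pair is linked independently with
probability ``p_in`` when the two nodes share a block and ``p_out``
otherwise. Because the same block structure drives all three relations,
microbe-disease association signal is transitive through drugs:
same-block microbes and diseases share drug neighbourhoods, which is
exactly the kind of structure metapath aggregation can exploit. The
default parameters produce a sparse network in the density regime of
real microbe-disease compilations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import TripartiteNetwork, build_network, write_edge_list


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block generator."""

    n_m: int = 150
    n_c: int = 40
    n_d: int = 60
    n_blocks: int = 3
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if min(self.n_m, self.n_c, self.n_d) < self.n_blocks:
            raise ValueError("every type needs at least n_blocks nodes")


def _block_assignment(n: int, n_blocks: int) -> np.ndarray:
    # contiguous blocks, remainder spread over the first blocks
    sizes = np.full(n_blocks, n // n_blocks)
    sizes[: n % n_blocks] += 1
    return np.repeat(np.arange(n_blocks), sizes)


def _pad_ids(prefix: str, n: int) -> list[str]:
    width = max(len(str(n - 1)), 1)
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_synthetic(spec: SyntheticSpec
                       ) -> tuple[TripartiteNetwork, dict[str, np.ndarray]]:
    """Draw a planted-block tripartite network.

    Returns the network and the ground-truth block assignment per type
    (arrays aligned with catalog order; ids are zero-padded so that
    lexicographic catalog order matches generation order).
    """
    rng = np.random.default_rng(spec.seed)
    ids = {
        "microbe": _pad_ids("m", spec.n_m),
        "drug": _pad_ids("c", spec.n_c),
        "disease": _pad_ids("d", spec.n_d),
    }
    blocks = {
        "microbe": _block_assignment(spec.n_m, spec.n_blocks),
        "drug": _block_assignment(spec.n_c, spec.n_blocks),
        "disease": _block_assignment(spec.n_d, spec.n_blocks),
    }

    def draw(a: str, b: str) -> set:
        same = blocks[a][:, None] == blocks[b][None, :]
        prob = np.where(same, spec.p_in, spec.p_out)
        hit = rng.random(prob.shape) < prob
        ii, jj = np.nonzero(hit)
        return {(ids[a][i], ids[b][j]) for i, j in zip(ii, jj)}

    md = draw("microbe", "disease")
    mc = draw("microbe", "drug")
    dc = draw("disease", "drug")
    # pass the full catalog so isolated nodes stay in it; zero-padded ids
    # keep lexicographic catalog order aligned with the block arrays
    from .network import NodeCatalog

    catalog = NodeCatalog(microbes=tuple(ids["microbe"]),
                          drugs=tuple(ids["drug"]),
                          diseases=tuple(ids["disease"]))
    net = build_network(md, mc, dc, catalog=catalog)
    return net, blocks


def fixture_small() -> TripartiteNetwork:
    """Hard-coded 8-node network (3 microbes, 2 drugs, 3 diseases) used
    throughout the unit tests; contains at least one instance of every
    default metapath and is byte-stable across calls."""
    md = {("m1", "d1"), ("m2", "d2"), ("m3", "d1")}
    mc = {("m1", "c1"), ("m2", "c1"), ("m3", "c2")}
    dc = {("d1", "c1"), ("d2", "c2"), ("d3", "c2")}
    return build_network(md, mc, dc)


def write_synthetic(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the three edge-list files the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, _ = generate_synthetic(spec)
    paths = {
        "md": out_dir / "microbe_disease.csv",
        "mc": out_dir / "microbe_drug.csv",
        "dc": out_dir / "disease_drug.csv",
    }
    write_edge_list(net.md_edges, paths["md"])
    write_edge_list(net.mc_edges, paths["mc"])
    write_edge_list(net.dc_edges, paths["dc"])
    return paths
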