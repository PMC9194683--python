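"""Metapath-aggregated graph attention model for tripartite link prediction.

The model learns embeddings for microbes, drugs and diseases on the
tripartite heterogeneous network in three stages per layer:

1. *Instance encoding*: every sampled metapath instance is summarised
   into one vector by a relational-rotation encoder. Each relation
   (microbe-drug, microbe-disease, disease-drug) carries a learnable
   unit-modulus complex vector, stored as phase angles so unit modulus
   holds by construction; traversing an edge rotates the running
   accumulator in complex coordinate pairs (even columns real, odd
   imaginary), and the final accumulator is divided by the path length.
2. *Intra-metapath aggregation*: per target node, a multi-head graph
   attention over its instance encodings (LeakyReLU-scored softmax),
   head outputs passed through ELU and concatenated.
3. *Inter-metapath aggregation*: a semantic attention in which each
   metapath is summarised by the tanh-transformed mean over all nodes of
   its type, scored by a learnable attention vector, softmax-normalised,
   and used to blend the per-metapath embeddings. A linear output map
   plus ELU closes the layer.

Microbe-disease association scores are the sigmoid of the inner product
of the final microbe and disease embeddings.

Functions prefixed ``encode_instance_`` / ``intra_`` / ``inter_`` are the
single-case reference surface operating on plain numpy arrays; the
``MetapathAttentionModel`` class runs the same mathematics batched over
all instances through the autodiff graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import ModelConfig
from .metapath import (Metapath, enumerate_all_instances_idx, parse_catalog,
                       subsample_grouped, typed_adjacency)
from .network import TripartiteNetwork

# canonical direction of each relation; traversing the other way applies
# the conjugate (negated phase) rotation
_CANONICAL = {
    ("microbe", "disease"): ("md", +1), ("disease", "microbe"): ("md", -1),
    ("microbe", "drug"): ("mc", +1), ("drug", "microbe"): ("mc", -1),
    ("disease", "drug"): ("dc", +1), ("drug", "disease"): ("dc", -1),
}

EPS = 1e-12


# ---------------------------------------------------------------------
# single-instance reference operations (numpy surface)


def encode_instance_rotate(node_vectors: Sequence[np.ndarray],
                           relations: Sequence[np.ndarray]) -> np.ndarray:
    """Relational-rotation encoding of one metapath instance.

    ``node_vectors`` are real d-vectors viewed as d/2 complex coordinates;
    ``relations`` are the d/2-dim unit-modulus complex rotation vectors of
    the traversed edges (one fewer than nodes). The accumulator starts at
    the first node, and each step adds the next node's vector to the
    rotated accumulator; the result is the final accumulator divided by
    the instance length.
    """
    if len(node_vectors) < 1:
        raise ValueError("need at least one node vector")
    if len(relations) != len(node_vectors) - 1:
        raise ValueError("need exactly one relation per traversed edge")
    d = len(node_vectors[0])
    if d % 2 != 0:
        raise ValueError("vector dimension must be even")
    for r in relations:
        if not np.allclose(np.abs(r), 1.0, atol=1e-8):
            raise ValueError("relation vectors must have unit modulus")
    o = _to_complex(np.asarray(node_vectors[0], dtype=float))
    for h, r in zip(node_vectors[1:], relations):
        o = _to_complex(np.asarray(h, dtype=float)) + o * np.asarray(r)
    return _to_real(o / len(node_vectors))


def encode_instance_mean(node_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Coordinate-wise mean of the instance's node vectors."""
    if len(node_vectors) == 0:
        raise ValueError("need at least one node vector")
    return np.mean(np.asarray(node_vectors, dtype=float), axis=0)


def _to_complex(v: np.ndarray) -> np.ndarray:
    return v[0::2] + 1j * v[1::2]


def _to_real(z: np.ndarray) -> np.ndarray:
    out = np.empty(2 * len(z))
    out[0::2] = z.real
    out[1::2] = z.imag
    return out


def intra_aggregate(target_vec: np.ndarray,
                    instance_encodings: Sequence[np.ndarray],
                    deltas: Sequence[np.ndarray],
                    leaky_slope: float = 0.01
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Multi-head attention over one node's metapath-instance encodings.

    ``deltas`` holds one attention vector per head, each of length
    ``2 d`` (scores the concatenation of the target's own vector with an
    instance encoding). Returns the concatenated per-head outputs and the
    (K, N) attention coefficient matrix; each row of coefficients sums
    to 1.
    """
    if len(instance_encodings) == 0:
        raise ValueError("need at least one metapath instance")
    enc = np.asarray(instance_encodings, dtype=float)
    if enc.shape[1] != len(target_vec):
        raise ValueError("encoding dimension must match target dimension")
    outputs, alphas = [], []
    for delta in deltas:
        if len(delta) != 2 * len(target_vec):
            raise ValueError("attention vector must have length 2*d")
        feats = np.concatenate(
            [np.broadcast_to(target_vec, enc.shape), enc], axis=1)
        e = feats @ delta
        e = np.where(e > 0, e, leaky_slope * e)
        e = e - e.max()
        alpha = np.exp(e) / np.exp(e).sum()
        out = alpha @ enc
        outputs.append(_elu(out))
        alphas.append(alpha)
    return np.concatenate(outputs), np.asarray(alphas)


def metapath_summary(embeddings: np.ndarray, W: np.ndarray,
                     b: np.ndarray) -> np.ndarray:
    """Type-level summary of a metapath: mean over nodes of
    tanh(W h + b)."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or embeddings.shape[0] == 0:
        raise ValueError("need a non-empty (nodes x dim) embedding matrix")
    return np.tanh(embeddings @ W.T + b).mean(axis=0)


def inter_aggregate(per_metapath: Sequence[np.ndarray],
                    summaries: Sequence[np.ndarray],
                    c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Semantic attention across metapaths.

    ``per_metapath`` holds one (nodes x dim) embedding matrix per
    metapath; ``summaries`` their type-level summary vectors. Returns the
    blended embeddings and the metapath weights beta (summing to 1, and
    shared by every node of the type since summaries are type-level).
    """
    if len(per_metapath) == 0:
        raise ValueError("need at least one metapath")
    dims = {np.asarray(h).shape for h in per_metapath}
    if len(dims) != 1:
        raise ValueError("per-metapath embeddings must share one shape")
    e = np.array([float(np.dot(c, s)) for s in summaries])
    e = e - e.max()
    beta = np.exp(e) / np.exp(e).sum()
    fused = sum(b * np.asarray(h) for b, h in zip(beta, per_metapath))
    return fused, beta


def predict_score(h_m: np.ndarray, h_d: np.ndarray) -> float:
    """Association score: sigmoid of the embedding inner product."""
    h_m = np.asarray(h_m, dtype=float)
    h_d = np.asarray(h_d, dtype=float)
    if h_m.shape != h_d.shape:
        raise ValueError("embedding dimensions must match")
    return float(1.0 / (1.0 + np.exp(-float(h_m @ h_d))))


def bce_loss(pos_scores: np.ndarray, neg_scores: np.ndarray,
             reduction: str = "mean") -> float:
    """Binary cross-entropy with negative sampling:
    -sum log(score) over positives - sum log(1 - score) over negatives."""
    import logging

    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if np.any(pos <= 0) or np.any(pos >= 1) or np.any(neg <= 0) or np.any(neg >= 1):
        logging.getLogger(__name__).warning(
            "scores at {0,1} clamped by epsilon before log")
    pos = np.clip(pos, EPS, 1 - EPS)
    neg = np.clip(neg, EPS, 1 - EPS)
    total = -np.log(pos).sum() - np.log1p(-neg).sum()
    if reduction == "sum":
        return float(total)
    if reduction == "mean":
        return float(total / max(len(pos) + len(neg), 1))
    raise ValueError(f"unknown reduction {reduction!r}")


def _elu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    return np.where(x > 0, x, alpha * np.expm1(x))


# ---------------------------------------------------------------------
# learnable parameters


@dataclass
class ModelParams:
    """All learnable tensors, grouped for the optimiser.

    ``feat[a]`` is the type projection applied to one-hot inputs, i.e.
    row i is node i's initial embedding. ``phases[r]`` are relation
    rotation angles (d/2 per relation, shared across layers). Per layer
    and node type: intra-attention vectors (heads x 2d) per metapath,
    semantic-attention parameters (W, b, c) and the output map W_o.
    """

    feat: dict = field(default_factory=dict)
    phases: dict = field(default_factory=dict)
    delta: list = field(default_factory=list)   # [layer][type][metapath] -> (K, 2d)
    sem_W: list = field(default_factory=list)   # [layer][type] -> (A, K*d)
    sem_b: list = field(default_factory=list)   # [layer][type] -> (A,)
    sem_c: list = field(default_factory=list)   # [layer][type] -> (A,)
    out_W: list = field(default_factory=list)   # [layer][type] -> (d, K*d)

    def all_tensors(self) -> list[Tensor]:
        out = list(self.feat.values()) + list(self.phases.values())
        for layer in self.delta:
            for by_type in layer.values():
                out.extend(by_type.values())
        for group in (self.sem_W, self.sem_b, self.sem_c, self.out_W):
            for layer in group:
                out.extend(layer.values())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {t.name: t.data.copy() for t in self.all_tensors()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for t in self.all_tensors():
            t.data = state[t.name].copy()

    def check_finite(self) -> bool:
        return all(np.all(np.isfinite(t.data)) for t in self.all_tensors())


def init_params(net: TripartiteNetwork, cfg: ModelConfig,
                seed: int) -> ModelParams:
    """Seeded Glorot-style initialisation of every learnable tensor."""
    rng = np.random.default_rng(seed)
    d, K, A = cfg.hidden_dim, cfg.heads, cfg.attention_dim
    catalog = parse_catalog(cfg.metapaths)
    params = ModelParams()
    for a in catalog:
        n_a = net.catalog.size_of(a)
        if n_a == 0:
            raise ValueError(f"cannot embed node type {a!r} with zero nodes")
        params.feat[a] = ad.parameter(rng, (n_a, d), name=f"feat.{a}")
    for rel in ("md", "mc", "dc"):
        params.phases[rel] = Tensor(rng.uniform(-np.pi, np.pi, size=d // 2),
                                    requires_grad=True, name=f"phase.{rel}")
    for l in range(cfg.layers):
        params.delta.append({
            a: {mp.name: ad.parameter(rng, (K, 2 * d), name=f"delta.{l}.{a}.{mp.name}")
                for mp in catalog[a]}
            for a in catalog
        })
        params.sem_W.append({a: ad.parameter(rng, (A, K * d), name=f"semW.{l}.{a}")
                             for a in catalog})
        params.sem_b.append({a: Tensor(np.zeros(A), requires_grad=True,
                                       name=f"semb.{l}.{a}") for a in catalog})
        params.sem_c.append({a: ad.parameter(rng, (A,), name=f"semc.{l}.{a}")
                             for a in catalog})
        params.out_W.append({a: ad.parameter(rng, (d, K * d), name=f"outW.{l}.{a}")
                             for a in catalog})
    return params


# ---------------------------------------------------------------------
# batched model


class MetapathAttentionModel:
    """Batched forward pass over a fixed network and metapath catalog.

    Instance enumeration is done once per network; per-epoch the trainer
    draws a capped uniform subsample per target node. The three ablation
    variants differ only inside this class: ``nb`` encodes target and
    endpoint with the composed rotation (intermediate context dropped),
    ``avg`` replaces the rotation encoder by the coordinate-wise mean,
    and ``sm`` is expressed upstream by a singleton metapath catalog.
    """

    def __init__(self, net: TripartiteNetwork, cfg: ModelConfig,
                 variant: str = "full") -> None:
        if variant not in ("full", "nb", "sm", "avg"):
            raise ValueError(f"unknown variant {variant!r}")
        self.net = net
        self.cfg = cfg
        self.variant = variant
        self.catalog = parse_catalog(cfg.metapaths)
        self.adj = typed_adjacency(net)
        # full enumeration per (type, metapath), rows grouped by target
        self._enum: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for a, paths in self.catalog.items():
            n_a = net.catalog.size_of(a)
            for mp in paths:
                self._enum[(a, mp.name)] = enumerate_all_instances_idx(
                    self.adj, mp, n_a)

    # -- instance sampling --------------------------------------------
    def sample_epoch(self, rng: np.random.Generator
                     ) -> dict[tuple[str, str], np.ndarray]:
        """Subsample up to ``cfg.neighbors`` instances per target node."""
        k = self.cfg.neighbors
        return {
            key: subsample_grouped(inst, counts, k, rng)
            for key, (inst, counts) in self._enum.items()
        }

    # -- forward -------------------------------------------------------
    def forward(self, params: ModelParams,
                sampled: dict[tuple[str, str], np.ndarray],
                train: bool = False,
                dropout_rng: np.random.Generator | None = None
                ) -> dict[str, Tensor]:
        """Run all layers; returns final embeddings per node type.

        In training mode dropout masks (rate ``cfg.dropout``) are applied
        to layer inputs and attention coefficients.
        """
        cfg = self.cfg
        h: dict[str, Tensor] = {a: params.feat[a] for a in self.catalog}
        for l in range(cfg.layers):
            h = self._layer(params, h, sampled, l, train, dropout_rng)
        return h

    def _dropout(self, t: Tensor, rng: np.random.Generator | None) -> Tensor:
        p = self.cfg.dropout
        if p <= 0 or rng is None:
            return t
        mask = (rng.random(t.shape) >= p) / (1.0 - p)
        return t * Tensor(mask)

    def _layer(self, params: ModelParams, h: dict[str, Tensor],
               sampled: dict, l: int, train: bool,
               rng: np.random.Generator | None) -> dict[str, Tensor]:
        cfg = self.cfg
        h_in = {a: (self._dropout(v, rng) if train else v) for a, v in h.items()}
        h_next: dict[str, Tensor] = {}
        for a, paths in self.catalog.items():
            n_a = self.net.catalog.size_of(a)
            per_path: list[Tensor] = []
            for mp in paths:
                enc, seg = self._encode_metapath(params, h_in, sampled[(a, mp.name)],
                                                 mp, n_a, h_in[a])
                per_path.append(self._intra(params, h_in[a], enc, seg, n_a, a,
                                            mp.name, l, train, rng))
            h_next[a] = self._inter_and_project(params, per_path, a, l)
        return h_next

    def _rotation(self, params: ModelParams, a_type: str, b_type: str
                  ) -> Tensor:
        """Signed phase vector for traversing a_type -> b_type."""
        rel, sign = _CANONICAL[(a_type, b_type)]
        return params.phases[rel] * float(sign)

    def _encode_metapath(self, params: ModelParams, h_in: dict,
                         inst: np.ndarray, mp: Metapath, n_a: int,
                         h_self: Tensor) -> tuple[Tensor, np.ndarray]:
        """Encode all sampled instances of one metapath.

        Returns the (N', d) encoding tensor and target segment ids,
        where nodes without any instance contribute a fallback
        self-instance (their own vector) so every node is represented.
        """
        types = mp.type_sequence
        if len(inst) == 0:
            # every node falls back to its self-instance
            return h_self, np.arange(n_a, dtype=np.intp)
        seg = inst[:, 0]
        if self.variant == "avg":
            acc = h_in[types[0]].gather_rows(inst[:, 0])
            for t in range(1, len(types)):
                acc = acc + h_in[types[t]].gather_rows(inst[:, t])
            enc = acc * (1.0 / len(types))
        elif self.variant == "nb":
            # target and endpoint only, rotated by the composed relation
            start = h_in[types[0]].gather_rows(inst[:, 0])
            end = h_in[types[-1]].gather_rows(inst[:, -1])
            theta = self._composed_rotation(params, types)
            enc = (end + ad.rotate_complex(start, theta)) * 0.5
        else:
            acc = h_in[types[0]].gather_rows(inst[:, 0])
            for t in range(1, len(types)):
                theta = self._rotation(params, types[t - 1], types[t])
                acc = h_in[types[t]].gather_rows(inst[:, t]) + \
                    ad.rotate_complex(acc, theta)
            enc = acc * (1.0 / len(types))
        # fallback self-instances for targets with no sampled instance
        present = np.zeros(n_a, dtype=bool)
        present[seg] = True
        missing = np.flatnonzero(~present)
        if len(missing):
            enc = ad.concat([enc, h_self.gather_rows(missing)], axis=0)
            seg = np.concatenate([seg, missing])
            order = np.argsort(seg, kind="stable")  # segment ops want sorted groups
            enc = enc.gather_rows(order)
            seg = seg[order]
        return enc, seg

    def _composed_rotation(self, params: ModelParams, types: tuple[str, ...]
                           ) -> Tensor:
        theta = None
        for a, b in zip(types, types[1:]):
            rel, sign = _CANONICAL[(a, b)]
            t = params.phases[rel] * float(sign)
            theta = t if theta is None else theta + t
        return theta

    def _intra(self, params: ModelParams, h_a: Tensor, enc: Tensor,
               seg: np.ndarray, n_a: int, a: str, mp_name: str, l: int,
               train: bool, rng: np.random.Generator | None) -> Tensor:
        feats = ad.concat([h_a.gather_rows(seg), enc], axis=1)  # (N, 2d)
        delta = params.delta[l][a][mp_name]                      # (K, 2d)
        scores = feats @ _transpose(delta)                       # (N, K)
        scores = scores.leaky_relu(self.cfg.leaky_slope)
        alpha = ad.segment_softmax(scores, seg, n_a)             # (N, K)
        if train:
            alpha = self._dropout(alpha, rng)
        # fused pooling: per-head weighted sums, head-major concatenation
        return ad.attention_pool(alpha, enc, seg, n_a).elu()     # (n_a, K*d)

    def _inter_and_project(self, params: ModelParams, per_path: list[Tensor],
                           a: str, l: int) -> Tensor:
        W, b, c = params.sem_W[l][a], params.sem_b[l][a], params.sem_c[l][a]
        summaries = [ (hp @ _transpose(W) + b).tanh().mean(axis=0) for hp in per_path ]
        e = ad.concat([ (s * c).sum(keepdims=False).reshape(1) for s in summaries ],
                      axis=0)                                    # (S,)
        e_shift = e - Tensor(np.max(e.data))
        ex = e_shift.exp()
        beta = ex / ex.sum()
        fused = None
        for p, hp in enumerate(per_path):
            term = hp * ad.gather_cols(beta.reshape(1, -1), np.array([p]))
            fused = term if fused is None else fused + term
        out = fused @ _transpose(params.out_W[l][a])
        return out.elu()

    # -- scoring -------------------------------------------------------
    @staticmethod
    def pair_scores(h_m: Tensor, h_d: Tensor, m_idx: np.ndarray,
                    d_idx: np.ndarray) -> Tensor:
        """Sigmoid inner-product scores for aligned index arrays."""
        hm = h_m.gather_rows(m_idx)
        hd = h_d.gather_rows(d_idx)
        return (hm * hd).sum(axis=1).sigmoid()

    @staticmethod
    def loss(pos: Tensor, neg: Tensor) -> Tensor:
        """Mean binary cross-entropy over positive and negative scores."""
        n = pos.shape[0] + neg.shape[0]
        pos_c = pos.clip(EPS, 1 - EPS)
        neg_c = neg.clip(EPS, 1 - EPS)
        total = -(pos_c.log().sum()) - ((1.0 - neg_c).log().sum())
        return total * (1.0 / n)


def _transpose(t: Tensor) -> Tensor:
    """2-D transpose as an autodiff op."""
    def backward(g: np.ndarray) -> None:
        if t.requires_grad:
            t._accumulate(g.T)

    return t._make(t.data.T, (t,), backward)


def final_embeddings(model: MetapathAttentionModel, params: ModelParams,
                     sampled: dict | None = None,
                     seed: int = 0) -> dict[str, np.ndarray]:
    """Deterministic evaluation-mode embeddings (no dropout)."""
    if sampled is None:
        sampled = model.sample_epoch(np.random.default_rng(seed))
    h = model.forward(params, sampled, train=False)
    return {a: t.data.copy() for a, t in h.items()}


def score_matrix(h_m: np.ndarray, h_d: np.ndarray) -> np.ndarray:
    """Full microbe x disease score matrix (reconstructed associations)."""
    z = h_m @ h_d.T
    return 1.0 / (1.0 + np.exp(-z))
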