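"""Independent straight-line oracles used by the test suite.

These deliberately re-derive results with plain python loops and direct
formula evaluation, sharing no vectorised code paths with the package.
"""

import numpy as np

from metapathlink.metapath import parse_catalog, sample_instances
from metapathlink.model import (encode_instance_mean, encode_instance_rotate,
                                inter_aggregate, intra_aggregate,
                                metapath_summary)

_CANON = {
    ("microbe", "disease"): ("md", +1), ("disease", "microbe"): ("md", -1),
    ("microbe", "drug"): ("mc", +1), ("drug", "microbe"): ("mc", -1),
    ("disease", "drug"): ("dc", +1), ("drug", "disease"): ("dc", -1),
}


def elu(x):
    return np.where(np.asarray(x) > 0, x, np.expm1(x))


def straightline_forward(net, cfg, state, variant="full"):
    """Per-node, per-instance re-implementation of the layered forward
    pass using only the single-case reference functions and loops."""
    catalog = parse_catalog(cfg.metapaths)
    cat = net.catalog
    h = {a: state[f"feat.{a}"].copy() for a in catalog}
    for l in range(cfg.layers):
        h_next = {}
        for a, paths in catalog.items():
            ids = cat.ids_of(a)
            per_path = []
            for mp in paths:
                rows = []
                for i, nid in enumerate(ids):
                    insts = sample_instances(net, mp, nid, 10**9, seed=0)
                    encs = []
                    for inst in insts:
                        types = mp.type_sequence
                        vecs = [h[t][cat.index[t][n]]
                                for t, n in zip(types, inst.node_sequence)]
                        rels = [np.exp(1j * sign * state[f"phase.{rel}"])
                                for rel, sign in
                                (_CANON[(t1, t2)]
                                 for t1, t2 in zip(types, types[1:]))]
                        if variant == "avg":
                            encs.append(encode_instance_mean(vecs))
                        elif variant == "nb":
                            comp = np.prod(np.stack(rels), axis=0)
                            encs.append(encode_instance_rotate(
                                [vecs[0], vecs[-1]], [comp]))
                        else:
                            encs.append(encode_instance_rotate(vecs, rels))
                    if not encs:  # fallback: the node alone
                        encs = [h[a][i]]
                    out_i, _ = intra_aggregate(
                        h[a][i], encs, state[f"delta.{l}.{a}.{mp.name}"],
                        cfg.leaky_slope)
                    rows.append(out_i)
                per_path.append(np.asarray(rows))
            summaries = [metapath_summary(hp, state[f"semW.{l}.{a}"],
                                          state[f"semb.{l}.{a}"])
                         for hp in per_path]
            fused, _ = inter_aggregate(per_path, summaries,
                                       state[f"semc.{l}.{a}"])
            h_next[a] = elu(fused @ state[f"outW.{l}.{a}"].T)
        h = h_next
    return h


def auc_bruteforce(labels, scores):
    """All pos-neg pairs; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_bruteforce(labels, scores):
    """Threshold sweep over distinct scores; sum of recall-step times
    precision rectangles."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    area, prev_recall = 0.0, 0.0
    n_pos = labels.sum()
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]] == 1
            fp += labels[order[j]] == 0
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area
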