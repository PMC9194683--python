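"""Training protocol: negative sampling, stratified splitting, Adam
optimisation with early stopping, and the ablation variants.

Protocol defaults follow the published setup: negatives drawn uniformly
from unobserved microbe-disease cells at a 1:1 ratio, an 8:1:1
train/validation/test split stratified by label, Adam with dropout 0.5,
early stopping on validation AUC, and an upper bound of 100 epochs.
Held-out positive edges are removed from the message-passing graph
during training (transductive hygiene; can be disabled).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Adam
from .config import ModelConfig, TrainingConfig
from .evaluation import EvalReport, evaluate_pairs
from .model import (MetapathAttentionModel, ModelParams, init_params,
                    score_matrix)
from .network import TripartiteNetwork

logger = logging.getLogger(__name__)


@dataclass
class LabeledPairs:
    """Microbe-disease pairs with binary labels for one partition."""

    pairs: pd.DataFrame  # columns: microbe, disease, label
    tag: str

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class TrainResult:
    params: ModelParams
    model: MetapathAttentionModel
    history: pd.DataFrame
    splits: dict[str, LabeledPairs]
    eval_sampled: dict = field(repr=False, default_factory=dict)
    best_epoch: int = -1
    best_val_auc: float = float("nan")


def negative_sample(net: TripartiteNetwork, positives: set, ratio: float,
                    seed: int) -> set:
    """Uniform sample of unobserved (microbe, disease) cells, disjoint
    from the positives, without replacement, reproducible by seed."""
    cat = net.catalog
    n_cells = cat.n_m * cat.n_d
    n_needed = int(round(len(positives) * ratio))
    pos_flat = np.fromiter(
        (cat.index["microbe"][m] * cat.n_d + cat.index["disease"][d]
         for m, d in positives),
        dtype=np.int64, count=len(positives))
    if n_cells - len(positives) < n_needed:
        raise ValueError(
            f"cannot draw {n_needed} negatives from {n_cells - len(positives)} "
            "unobserved cells")
    candidates = np.setdiff1d(np.arange(n_cells, dtype=np.int64), pos_flat)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_needed, replace=False)
    return {(cat.microbes[f // cat.n_d], cat.diseases[f % cat.n_d])
            for f in chosen}


def split_pairs(pos: set, neg: set, fractions: tuple[float, float, float],
                seed: int) -> dict[str, LabeledPairs]:
    """Label-stratified train/val/test split at the given fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_parts_needed = sum(f > 0 for f in fractions)
    rng = np.random.default_rng(seed)
    parts: dict[str, list] = {"train": [], "val": [], "test": []}
    for label, pairs in ((1, pos), (0, neg)):
        if len(pairs) < n_parts_needed:
            raise ValueError(
                f"need at least {n_parts_needed} pairs of label {label}")
        arr = sorted(pairs)
        order = rng.permutation(len(arr))
        n_val = int(round(len(arr) * fractions[1]))
        n_test = int(round(len(arr) * fractions[2]))
        n_train = len(arr) - n_val - n_test
        for rank, idx in enumerate(order):
            m, d = arr[idx]
            tag = ("train" if rank < n_train
                   else "val" if rank < n_train + n_val else "test")
            parts[tag].append((m, d, label))
    out = {}
    for tag, rows in parts.items():
        df = pd.DataFrame(rows, columns=["microbe", "disease", "label"])
        out[tag] = LabeledPairs(pairs=df, tag=tag)
    return out


def _pair_indices(df: pd.DataFrame, net: TripartiteNetwork
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mi = net.catalog.index["microbe"]
    di = net.catalog.index["disease"]
    m_idx = df["microbe"].map(mi).to_numpy(dtype=np.intp)
    d_idx = df["disease"].map(di).to_numpy(dtype=np.intp)
    return m_idx, d_idx, df["label"].to_numpy()


def _score_partition(model: MetapathAttentionModel, params: ModelParams,
                     sampled: dict, part: LabeledPairs) -> pd.DataFrame:
    h = model.forward(params, sampled, train=False)
    m_idx, d_idx, labels = _pair_indices(part.pairs, model.net)
    scores = model.pair_scores(h["microbe"], h["disease"], m_idx, d_idx).data
    out = part.pairs.copy()
    out["score"] = scores
    return out


def train(net: TripartiteNetwork, model_cfg: ModelConfig,
          train_cfg: TrainingConfig) -> TrainResult:
    """Full training run; returns the best-validation-AUC checkpoint.

    All randomness (negative sampling, splitting, parameter init,
    per-epoch instance sampling, dropout) derives from ``train_cfg.seed``.
    """
    from .evaluation import auc as auc_fn

    seed = train_cfg.seed
    positives = set(net.md_edges)
    negatives = negative_sample(net, positives, train_cfg.neg_ratio, seed)
    splits = split_pairs(positives, negatives, train_cfg.split, seed + 1)

    msg_net = net
    if train_cfg.remove_heldout_edges:
        heldout = [
            (m, d)
            for tag in ("val", "test")
            for m, d, lab in splits[tag].pairs.itertuples(index=False)
            if lab == 1
        ]
        msg_net = net.drop_md_edges(heldout)

    model = MetapathAttentionModel(msg_net, model_cfg, train_cfg.variant)
    params = init_params(msg_net, model_cfg, seed + 2)
    opt = Adam(params.all_tensors(), lr=train_cfg.learning_rate,
               weight_decay=train_cfg.weight_decay)

    eval_sampled = model.sample_epoch(np.random.default_rng(seed + 3))
    frozen_sampled = eval_sampled if not train_cfg.resample_each_epoch else None

    tr_m, tr_d, tr_lab = _pair_indices(splits["train"].pairs, msg_net)
    va_m, va_d, va_lab = _pair_indices(splits["val"].pairs, msg_net)
    tr_pos, tr_neg = np.flatnonzero(tr_lab == 1), np.flatnonzero(tr_lab == 0)

    history_rows = []
    best_auc, best_state, best_epoch = -np.inf, None, -1
    stale = 0
    for epoch in range(train_cfg.epochs):
        if frozen_sampled is not None:
            sampled = frozen_sampled
        else:
            sampled = model.sample_epoch(
                np.random.default_rng((seed + 10) * 1000 + epoch))
        drop_rng = np.random.default_rng((seed + 20) * 1000 + epoch)
        h = model.forward(params, sampled, train=True, dropout_rng=drop_rng)
        pos_scores = model.pair_scores(h["microbe"], h["disease"],
                                       tr_m[tr_pos], tr_d[tr_pos])
        neg_scores = model.pair_scores(h["microbe"], h["disease"],
                                       tr_m[tr_neg], tr_d[tr_neg])
        loss = model.loss(pos_scores, neg_scores)
        train_loss = float(loss.data)
        if not np.isfinite(train_loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={train_loss}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        # validation in evaluation mode on the frozen instance sample
        h_eval = model.forward(params, eval_sampled, train=False)
        va_scores = model.pair_scores(h_eval["microbe"], h_eval["disease"],
                                      va_m, va_d)
        va_pos = va_scores.data[va_lab == 1]
        va_neg = va_scores.data[va_lab == 0]
        val_loss = float(model.loss(
            va_scores.gather_rows(np.flatnonzero(va_lab == 1)),
            va_scores.gather_rows(np.flatnonzero(va_lab == 0))).data)
        val_auc = auc_fn(va_lab, va_scores.data) if len(va_pos) and len(va_neg) \
            else float("nan")
        history_rows.append({"epoch": epoch, "train_loss": train_loss,
                             "val_loss": val_loss, "val_auc": val_auc})

        if val_auc > best_auc:
            best_auc, best_epoch, stale = val_auc, epoch, 0
            best_state = params.state_dict()
        else:
            stale += 1
            # optimisation is two-phase (alignment plateau, then loss
            # collapse); stopping decisions before min_epochs are noise
            if stale > train_cfg.patience and epoch + 1 >= train_cfg.min_epochs:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    if best_state is not None:
        params.load_state_dict(best_state)
    return TrainResult(params=params, model=model,
                       history=pd.DataFrame(history_rows), splits=splits,
                       eval_sampled=eval_sampled, best_epoch=best_epoch,
                       best_val_auc=float(best_auc))


def evaluate(result: TrainResult, partition: str = "test") -> EvalReport:
    """Score one partition with the trained model and compute AUC/AUPR."""
    scored = _score_partition(result.model, result.params,
                              result.eval_sampled, result.splits[partition])
    report = evaluate_pairs(scored)
    report.extras["partition"] = partition
    report.extras["best_epoch"] = result.best_epoch
    report.extras["val_auc"] = result.best_val_auc
    return report


def predict_matrix(result: TrainResult) -> np.ndarray:
    """Reconstructed microbe x disease association score matrix."""
    h = result.model.forward(result.params, result.eval_sampled, train=False)
    return score_matrix(h["microbe"].data, h["disease"].data)


def run_variant(variant: str, net: TripartiteNetwork, model_cfg: ModelConfig,
                train_cfg: TrainingConfig) -> EvalReport:
    """Train and evaluate one model variant on the test partition.

    ``full``/``nb``/``avg`` train directly. ``sm`` trains every singleton
    metapath catalog (one metapath per scored type; auxiliary types keep
    their first metapath) and reports the combination with the best
    validation AUC.
    """
    if variant not in ("full", "nb", "sm", "avg"):
        raise ValueError(f"unknown variant {variant!r}")
    cfg = replace(train_cfg, variant=variant)
    if variant != "sm":
        result = train(net, model_cfg, cfg)
        report = evaluate(result)
        report.extras.update({"variant": variant,
                              "history": result.history})
        return report

    scored_types = ("microbe", "disease")
    base = model_cfg.metapaths
    choices = [[(t, p) for p in base[t]] for t in scored_types if t in base]
    best: tuple[float, EvalReport] | None = None
    for combo in itertools.product(*choices):
        catalog = {t: [paths[0]] for t, paths in base.items()}
        for t, p in combo:
            catalog[t] = [p]
        m_cfg = replace(model_cfg, metapaths=catalog)
        result = train(net, m_cfg, cfg)
        report = evaluate(result)
        report.extras.update({
            "variant": "sm",
            "metapaths": {t: list(v) for t, v in catalog.items()},
            "history": result.history,
        })
        if best is None or result.best_val_auc > best[0]:
            best = (result.best_val_auc, report)
    assert best is not None
    return best[1]
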