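"""Ranking metrics and case-study candidate ranking.

AUC is the area under the ROC curve (probability that a random positive
outranks a random negative, ties counted one half); AUPR is the area
under the non-interpolated precision-recall step curve. Both delegate to
scikit-learn. Candidate ranking removes a disease's known microbes and
sorts the remainder by predicted score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class EvalReport:
    """Metrics plus per-pair scores for one evaluation partition."""

    auc: float
    aupr: float
    scored_pairs: pd.DataFrame  # columns: microbe, disease, label, score
    rankings: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both a positive and a negative example")
    return float(roc_auc_score(labels, scores))


def aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() < 1:
        raise ValueError("AUPR needs at least one positive example")
    return float(average_precision_score(labels, scores))


def evaluate_pairs(pairs: pd.DataFrame) -> EvalReport:
    """Build an EvalReport from a (microbe, disease, label, score) frame."""
    return EvalReport(
        auc=auc(pairs["label"].to_numpy(), pairs["score"].to_numpy()),
        aupr=aupr(pairs["label"].to_numpy(), pairs["score"].to_numpy()),
        scored_pairs=pairs.reset_index(drop=True),
    )


def rank_candidates(disease_id: str, score_matrix: np.ndarray,
                    microbes: tuple[str, ...], diseases: tuple[str, ...],
                    known_md: set, top: int | None = None) -> pd.DataFrame:
    """Rank candidate microbes for one disease.

    Microbes with a known association to the disease are removed, the
    rest sorted by descending score with lexicographic id tie-break.
    """
    if disease_id not in diseases:
        raise KeyError(f"unknown disease {disease_id!r}")
    j = diseases.index(disease_id)
    known = {m for (m, d) in known_md if d == disease_id}
    rows = [(m, float(score_matrix[i, j]))
            for i, m in enumerate(microbes) if m not in known]
    rows.sort(key=lambda r: (-r[1], r[0]))
    if top is not None:
        rows = rows[:top]
    return pd.DataFrame(
        {"rank": np.arange(1, len(rows) + 1),
         "microbe": [m for m, _ in rows],
         "score": [s for _, s in rows]}
    )
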