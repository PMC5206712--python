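"""Co-citation truth network and precision-recall / ROC evaluation.

A predicted same-disease interaction (Ma-Dx, Mb-Dx) counts as
true/validated when at least one single PubMed ID in the source records
associates both miRNAs with that disease; every other same-disease pair is
unknown/unverified and is treated as a negative for curve purposes.  Since
"unverified" may simply mean "not yet studied", precision is the more
meaningful axis of the resulting curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import ConsensusResult
from .networks import classify_edge_type, split_label
from .records import Dataset

__all__ = [
    "TruthNetwork",
    "PRCurve",
    "build_truth_network",
    "label_edges",
    "precision_recall_curve",
]


@dataclass
class TruthNetwork:
    """Validated (mirna_a, mirna_b, disease) triples, symmetric in the miRNAs."""

    validated: set[tuple[str, str, str]]

    @staticmethod
    def key(mirna_a: str, mirna_b: str, disease: str) -> tuple[str, str, str]:
        a, b = sorted((mirna_a, mirna_b))
        return (a, b, disease)

    def __contains__(self, triple: tuple[str, str, str]) -> bool:
        return self.key(*triple) in self.validated

    def __len__(self) -> int:
        return len(self.validated)


def build_truth_network(data: Dataset) -> TruthNetwork:
    """Pair up miRNAs co-cited for the same disease under one PubMed ID.

    Records are first deduplicated by (pmid, mirna, disease) so that a PMID
    repeated across studies contributes each pair once.
    """
    by_pmid_disease: dict[tuple[str, str], set[str]] = {}
    for rec in data.records:
        by_pmid_disease.setdefault((rec.pmid, rec.disease), set()).add(rec.mirna)
    validated: set[tuple[str, str, str]] = set()
    for (pmid, disease), mirnas in by_pmid_disease.items():
        for a, b in combinations(sorted(mirnas), 2):
            validated.add(TruthNetwork.key(a, b, disease))
    return TruthNetwork(validated)


def label_edges(
    consensus: ConsensusResult, truth: TruthNetwork
) -> dict[tuple[str, str], int]:
    """Label each same-disease (type 3) consensus edge 1 if validated, else 0.

    Raises if a non-type-3 edge is present: the truth network is only defined
    for pairs of different miRNAs under one disease.
    """
    labels: dict[tuple[str, str], int] = {}
    for edge in consensus.final_rank:
        if classify_edge_type(edge) != 3:
            raise ValueError(f"edge {edge} is not a same-disease miRNA pair")
        disease_a, mirna_a = split_label(edge[0])
        _, mirna_b = split_label(edge[1])
        labels[edge] = 1 if (mirna_a, mirna_b, disease_a) in truth else 0
    return labels


@dataclass
class PRCurve:
    """Confusion counts and PR/ROC coordinates per descending threshold."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    auroc: float
    aupr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "tn": self.tn,
                "precision": self.precision,
                "recall": self.recall,
                "fpr": self.fpr,
            }
        )

    def to_csv(self, sink: str | Path) -> None:
        self.to_frame().to_csv(sink, index=False)


def precision_recall_curve(scores, labels) -> PRCurve:
    """Sweep every distinct score (descending) as a classification threshold.

    At each threshold t an edge is predicted positive iff score >= t.
    Emits precision = tp/(tp+fp), recall = tp/(tp+fn), fpr = fp/(fp+tn) and
    trapezoidal areas under the ROC (recall vs fpr, anchored at (0,0) and
    (1,1)) and PR curves.

    ``scores`` and ``labels`` may be aligned mappings over edges or plain
    sequences.
    """
    if isinstance(scores, dict):
        keys = list(scores)
        s = np.asarray([scores[k] for k in keys], dtype=float)
        y = np.asarray([labels[k] for k in keys], dtype=int)
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d collections")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # last index of each distinct-score block -> cumulative counts at >= t
    distinct = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    cum_tp = np.cumsum(y_sorted)
    tp = cum_tp[distinct]
    pred_pos = distinct + 1
    fp = pred_pos - tp
    fn = n_pos - tp
    tn = n_neg - fp
    precision = tp / pred_pos
    recall = tp / n_pos
    fpr = fp / n_neg

    roc_x = np.r_[0.0, fpr, 1.0]
    roc_y = np.r_[0.0, recall, 1.0]
    auroc = float(np.trapezoid(roc_y, roc_x))
    aupr = float(np.trapezoid(np.r_[precision[0], precision], np.r_[0.0, recall]))
    return PRCurve(
        thresholds=s_sorted[distinct],
        tp=tp.astype(int),
        fp=fp.astype(int),
        fn=fn.astype(int),
        tn=tn.astype(int),
        precision=precision,
        recall=recall,
        fpr=fpr,
        auroc=auroc,
        aupr=aupr,
    )
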