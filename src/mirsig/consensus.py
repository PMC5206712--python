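"""Borda-count consensus over the per-algorithm interaction rankings.

Each inference algorithm produces a ranked list of all directed MD-MD
interactions (self-loops excluded).  A rank r among n candidates earns
n - r Borda points, normalized by the maximum n - 1 to a relative Borda
rank in [0, 1]; an interaction's final consensus rank is the mean of its K
normalized Borda ranks.  An edge ranked first by every algorithm scores 1,
ranked last by every algorithm scores 0.

Two arithmetic modes are provided: ``exact`` keeps full precision, while
``paper_truncated`` truncates every Borda rank and the final average to two
decimals, matching the convention of published worked examples where 2/3 is
carried as 0.66 before averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import ScoreMatrix

__all__ = [
    "Edge",
    "RankedList",
    "ConsensusResult",
    "interaction_space",
    "rank_descending",
    "ranked_list_from_order",
    "borda_normalize",
    "average_rank_consensus",
    "truncate2",
]

#: A directed interaction between two MD-node labels.
Edge = tuple[str, str]


def interaction_space(n_nodes: int) -> int:
    """Number of potential ordered MD-MD interactions for n nodes (n^2)."""
    return n_nodes * n_nodes


def truncate2(x: float) -> float:
    """Truncate towards zero at two decimals (2/3 -> 0.66), float-noise safe."""
    return math.floor(round(x * 100.0, 6)) / 100.0


@dataclass
class RankedList:
    """One algorithm's ranking of the edge universe (1 = best, ties averaged)."""

    algorithm: str
    edge_ranks: dict[Edge, float]

    def __len__(self) -> int:
        return len(self.edge_ranks)


def rank_descending(scores: ScoreMatrix) -> RankedList:
    """Rank all off-diagonal directed edges by descending score.

    The highest score gets rank 1; equal scores share the average of the
    ranks they span.  Both orientations of a symmetric scorer's edge appear
    (with equal score, hence tied ranks).
    """
    values = scores.values()
    if not np.all(np.isfinite(values)):
        raise ValueError("scores must be finite")
    nodes = scores.nodes
    p = len(nodes)
    off = ~np.eye(p, dtype=bool)
    flat = values[off]
    ranks = stats.rankdata(-flat, method="average")
    edges = [(nodes[i], nodes[j]) for i in range(p) for j in range(p) if i != j]
    return RankedList(scores.algorithm, dict(zip(edges, ranks.tolist())))


def ranked_list_from_order(algorithm: str, order: Sequence[Edge | str]) -> RankedList:
    """Build a RankedList from an explicit best-to-worst candidate order."""
    return RankedList(algorithm, {e: float(r) for r, e in enumerate(order, start=1)})


def borda_normalize(ranks: RankedList, n: int | None = None) -> dict[Edge, float]:
    """Normalized Borda points: rank r of n earns (n - r)/(n - 1) in [0, 1].

    A single-candidate ranking maps to 1.0 by convention.  Fractional
    (tie-averaged) ranks share points linearly.
    """
    n = n if n is not None else len(ranks)
    if n < 1:
        raise ValueError("need at least one ranked edge")
    if n == 1:
        return {e: 1.0 for e in ranks.edge_ranks}
    return {e: (n - r) / (n - 1) for e, r in ranks.edge_ranks.items()}


@dataclass
class ConsensusResult:
    """Final consensus rank in [0, 1] per directed edge, K algorithms fused."""

    final_rank: dict[Edge, float]
    k_algorithms: int
    algorithms: list[str] = field(default_factory=list)

    @property
    def edges(self) -> list[Edge]:
        return list(self.final_rank)

    def to_table(self) -> pd.DataFrame:
        """Ranked listing: rank, "source => target", score, best first."""
        items = sorted(self.final_rank.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(items) + 1),
                "interaction": [f"{a} => {b}" for (a, b), _ in items],
                "source": [a for (a, _), _ in items],
                "target": [b for (_, b), _ in items],
                "score": [s for _, s in items],
            }
        )

    def to_csv(self, sink: str | Path) -> None:
        self.to_table().to_csv(sink, index=False)

    @classmethod
    def from_csv(cls, source: str | Path, k_algorithms: int = 0) -> "ConsensusResult":
        frame = pd.read_csv(source)
        ranks = {
            (str(r.source), str(r.target)): float(r.score)
            for r in frame.itertuples(index=False)
        }
        return cls(final_rank=ranks, k_algorithms=k_algorithms)


def average_rank_consensus(
    ranked: Iterable[RankedList], mode: str = "exact"
) -> ConsensusResult:
    """Fuse K rankings: final rank = mean of the K normalized Borda ranks.

    In ``paper_truncated`` mode each normalized Borda rank and the final mean
    are truncated to two decimals; ``exact`` keeps full precision.
    """
    if mode not in ("exact", "paper_truncated"):
        raise ValueError(f"mode must be exact or paper_truncated, got {mode!r}")
    ranked = list(ranked)
    if not ranked:
        raise ValueError("need at least one ranked list")
    edge_set = set(ranked[0].edge_ranks)
    for rl in ranked[1:]:
        if set(rl.edge_ranks) != edge_set:
            raise ValueError(
                f"ranked lists cover different edge sets "
                f"({rl.algorithm} differs from {ranked[0].algorithm})"
            )
    k = len(ranked)
    totals: dict[Edge, float] = {e: 0.0 for e in ranked[0].edge_ranks}
    for rl in ranked:
        borda = borda_normalize(rl)
        for e, b in borda.items():
            totals[e] += truncate2(b) if mode == "paper_truncated" else b
    final = {
        e: (truncate2(t / k) if mode == "paper_truncated" else t / k)
        for e, t in totals.items()
    }
    return ConsensusResult(
        final_rank=final, k_algorithms=k, algorithms=[rl.algorithm for rl in ranked]
    )
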