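"""Score every MD-MD pair with each of six network-inference algorithms.

The six scorers span complementary inference families — linear correlation
(Pearson), monotone correlation (Spearman), general dependence (distance
correlation), information theory (plug-in mutual information refined by CLR
background correction and by MRNETB redundancy-aware predictor selection),
and regression (randomized tree-ensemble importances).  Each returns an
N x N nonnegative score matrix over the MD-node universe where higher means
a stronger predicted interaction; the diagonal (self-loops) is never used
downstream.

Missing cells are resolved by the expression-matrix completion policy before
any scorer runs; scorers themselves never see missingness (Pearson/Spearman
optionally use pairwise-complete rows instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .matrices import ExpressionMatrix

__all__ = [
    "ScoreMatrix",
    "MIEstimatorConfig",
    "ALGORITHMS",
    "correlation_scores",
    "distance_correlation_scores",
    "mutual_information_matrix",
    "clr_scores",
    "mrnetb_scores",
    "genie3_scores",
    "score_all",
]

ALGORITHMS = ("clr", "mrnetb", "pearson", "spearman", "dcor", "genie3")


@dataclass
class ScoreMatrix:
    """One algorithm's N x N interaction scores over MD-node labels."""

    algorithm: str
    scores: pd.DataFrame
    directed: bool = False

    @property
    def nodes(self) -> list[str]:
        return list(self.scores.columns)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy()

    def to_csv(self, sink: str | Path) -> None:
        self.scores.to_csv(sink, index_label="node")

    @classmethod
    def from_csv(cls, source: str | Path, algorithm: str, directed: bool = False) -> "ScoreMatrix":
        return cls(algorithm, pd.read_csv(source, index_col="node"), directed)


@dataclass
class MIEstimatorConfig:
    """Equal-frequency plug-in MI estimator settings (natural log).

    ``bin_count`` defaults to floor(sqrt(#samples)), never below 2 — the
    conventional bin budget for histogram MI estimators.
    """

    bin_count: int | None = None

    def resolve_bins(self, n_rows: int) -> int:
        b = self.bin_count if self.bin_count is not None else int(math.isqrt(n_rows))
        b = max(2, b)
        if b > n_rows:
            raise ValueError(f"bin_count {b} exceeds sample count {n_rows}")
        return b


def _frame(values: np.ndarray, labels, algorithm: str, directed: bool = False) -> ScoreMatrix:
    df = pd.DataFrame(values, index=labels, columns=labels)
    return ScoreMatrix(algorithm=algorithm, scores=df, directed=directed)


def _require_rows(x: pd.DataFrame, minimum: int) -> None:
    if len(x) < minimum:
        raise ValueError(f"need at least {minimum} samples, got {len(x)}")


def correlation_scores(
    matrix: ExpressionMatrix,
    method: str = "pearson",
    missing_policy: str = "pairwise_complete",
) -> ScoreMatrix:
    """Absolute Pearson or Spearman correlation between all column pairs.

    Absolute values are used because downstream ranking rewards interaction
    strength, not sign, and keeps correlations comparable with the
    nonnegative MI-family scores.  Zero-variance columns score 0 everywhere.

    Correlation has a natural pairwise-complete definition, so by default
    each pair is computed over the samples where both MDs were observed
    (pairs with fewer than 3 shared samples score 0); ``zero_fill`` instead
    scores unobserved cells as no differential expression, which lets shared
    sparsity patterns masquerade as correlation.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be pearson or spearman, got {method!r}")
    frame = matrix.completed(missing_policy)
    _require_rows(frame, 3)
    corr = frame.corr(method=method, min_periods=3)
    out = corr.abs().to_numpy()
    np.fill_diagonal(out, 1.0)
    out = np.nan_to_num(out, nan=0.0)
    return _frame(out, frame.columns, method)


def _centered_distances(x: np.ndarray) -> np.ndarray:
    """Double-centered Euclidean distance matrix of a 1-d sample."""
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def _dcor_pair(x: np.ndarray, y: np.ndarray) -> float:
    a, b = _centered_distances(x), _centered_distances(y)
    dcov2 = max((a * b).mean(), 0.0)
    dvx, dvy = (a * a).mean(), (b * b).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return float(np.sqrt(dcov2) / (dvx * dvy) ** 0.25)


def distance_correlation_scores(
    matrix: ExpressionMatrix, missing_policy: str = "pairwise_complete"
) -> ScoreMatrix:
    """Sample distance correlation for every column pair.

    dCor(x, y) = dCov(x, y) / sqrt(dVar(x) dVar(y)) where dCov^2 is the mean
    elementwise product of the two double-centered pairwise-distance
    matrices.  Values lie in [0, 1]; constant columns score 0.  Like the
    linear correlations, each pair is evaluated by default over the samples
    where both MDs were observed (fewer than 3 shared samples scores 0).
    """
    frame = matrix.completed(missing_policy)
    _require_rows(frame, 3)
    x = frame.to_numpy()
    n, p = x.shape
    if not np.isnan(x).any():
        # complete matrix: one stacked pass over all pairs
        flat = np.stack([_centered_distances(x[:, j]).ravel() for j in range(p)])
        dcov2 = flat @ flat.T / (n * n)
        dcov2 = np.clip(dcov2, 0.0, None)
        dvar = np.diag(dcov2).copy()
        denom = np.sqrt(np.outer(dvar, dvar))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.sqrt(dcov2) / np.sqrt(denom)
        out[~np.isfinite(out)] = 0.0
        np.fill_diagonal(out, np.where(dvar > 0, 1.0, 0.0))
        return _frame(np.clip(out, 0.0, 1.0), frame.columns, "dcor")
    observed = ~np.isnan(x)
    out = np.zeros((p, p))
    for i in range(p):
        out[i, i] = 1.0 if np.unique(x[observed[:, i], i]).size > 1 else 0.0
        for j in range(i + 1, p):
            both = observed[:, i] & observed[:, j]
            if both.sum() < 3:
                continue
            out[i, j] = out[j, i] = _dcor_pair(x[both, i], x[both, j])
    return _frame(np.clip(out, 0.0, 1.0), frame.columns, "dcor")


def _equal_frequency_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize into ~equal-count bins.

    Tied values share a bin (average-rank placement): splitting a run of
    identical values across bins by storage order would fabricate mutual
    information between any two columns sharing a long constant run, e.g.
    the zero-filled block of samples from other diseases.
    """
    n = len(x)
    ranks = stats.rankdata(x, method="average") - 0.5  # mid-ranks in (0, n)
    return np.minimum((ranks * bins / n).astype(int), bins - 1)


def _plugin_mi(codes_a: np.ndarray, codes_b: np.ndarray, bins: int) -> float:
    """Maximum-likelihood MI (nats) from the joint contingency table."""
    joint = np.zeros((bins, bins))
    np.add.at(joint, (codes_a, codes_b), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])))


def mutual_information_matrix(
    matrix: ExpressionMatrix, cfg: MIEstimatorConfig | None = None
) -> ScoreMatrix:
    """Pairwise plug-in MI after equal-frequency discretization.

    The diagonal holds each column's entropy (MI of a variable with itself);
    columns whose values are all identical carry zero information and score 0
    against every partner.
    """
    cfg = cfg or MIEstimatorConfig()
    frame = matrix.completed("zero_fill")
    x = frame.to_numpy()
    n, p = x.shape
    bins = cfg.resolve_bins(n)
    constant = np.array([np.unique(x[:, j]).size < 2 for j in range(p)])
    codes = np.stack([_equal_frequency_codes(x[:, j], bins) for j in range(p)])
    out = np.zeros((p, p))
    for i in range(p):
        if constant[i]:
            continue
        for j in range(i, p):
            if constant[j] and j != i:
                continue
            out[i, j] = out[j, i] = _plugin_mi(codes[i], codes[j], bins)
    return _frame(out, frame.columns, "mi")


def clr_scores(mi: ScoreMatrix) -> ScoreMatrix:
    """Context Likelihood of Relatedness background correction.

    Each MI value is converted to a z-score against the off-diagonal
    background of its row (clamped at 0; a zero-spread background yields
    z = 0) and the two directions combine as sqrt(z_i^2 + z_j^2).
    """
    m = mi.values().astype(float).copy()
    p = m.shape[0]
    off = ~np.eye(p, dtype=bool)
    mean = np.array([m[i, off[i]].mean() for i in range(p)]) if p > 1 else np.zeros(p)
    sd = np.array([m[i, off[i]].std() for i in range(p)]) if p > 1 else np.zeros(p)
    # a numerically flat background carries no context: force sd to exact 0
    sd[sd <= 1e-12 * np.maximum(1.0, np.abs(mean))] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (m - mean[:, None]) / sd[:, None]
    z[~np.isfinite(z)] = 0.0
    z = np.clip(z, 0.0, None)
    out = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(out, 0.0)
    return _frame(out, mi.nodes, "clr")


def _mrnetb_select(rel: np.ndarray, red: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Backward elimination + sequential replacement on the MRMR objective.

    The subset objective is Q(S) = sum_{j in S} [rel_j - mean redundancy of j
    within S]; returns the selected mask and the per-variable objective in
    the final subset (0 for unselected variables), clamped at 0.  At an
    elimination tie the later variable is dropped, so of two duplicated
    predictors the first-indexed one stays selected.
    """
    p = rel.size
    sel = np.ones(p, dtype=bool)
    eps = 1e-12

    def q_terms(mask: np.ndarray) -> np.ndarray:
        m = int(mask.sum())
        idx = np.flatnonzero(mask)
        if m == 1:
            return rel[idx]
        w = red[np.ix_(idx, idx)].sum(axis=1)
        return rel[idx] - w / (m - 1)

    # backward elimination: drop the variable whose removal best improves Q
    while sel.sum() > 1:
        idx = np.flatnonzero(sel)
        q_now = q_terms(sel).sum()
        best_q, best_j = q_now, -1
        for j in idx[::-1]:
            trial = sel.copy()
            trial[j] = False
            q_trial = q_terms(trial).sum()
            if q_trial > best_q + eps:
                best_q, best_j = q_trial, j
        if best_j < 0:
            break
        sel[best_j] = False

    # sequential replacement: swap one in / one out while Q improves
    for _ in range(2 * p):
        idx_in = np.flatnonzero(sel)
        idx_out = np.flatnonzero(~sel)
        if idx_out.size == 0:
            break
        q_now = q_terms(sel).sum()
        best_q, best_pair = q_now, None
        for j in idx_in:
            for k in idx_out:
                trial = sel.copy()
                trial[j], trial[k] = False, True
                q_trial = q_terms(trial).sum()
                if q_trial > best_q + eps:
                    best_q, best_pair = q_trial, (j, k)
        if best_pair is None:
            break
        sel[best_pair[0]], sel[best_pair[1]] = False, True

    out = np.zeros(p)
    out[np.flatnonzero(sel)] = np.clip(q_terms(sel), 0.0, None)
    return sel, out


def mrnetb_scores(mi: ScoreMatrix) -> ScoreMatrix:
    """Maximum-relevance minimum-redundancy backward predictor selection.

    For each target variable, a predictor subset maximizing the MRMR
    objective (MI with the target minus mean MI with the other selected
    predictors) is found by backward elimination followed by sequential
    replacement; a selected predictor's edge score is its objective value in
    the final subset.  The two directions are symmetrized by elementwise
    maximum.
    """
    m = mi.values().astype(float)
    p = m.shape[0]
    out = np.zeros((p, p))
    for t in range(p):
        others = np.arange(p) != t
        rel = m[others, t]
        red = m[np.ix_(others, others)].copy()
        np.fill_diagonal(red, 0.0)
        out[others, t] = _mrnetb_select(rel, red)[1]
    out = np.maximum(out, out.T)
    np.fill_diagonal(out, 0.0)
    return _frame(out, mi.nodes, "mrnetb")


def genie3_scores(
    matrix: ExpressionMatrix,
    n_trees: int = 100,
    k_candidates: str | int = "sqrt",
    seed: int = 0,
) -> ScoreMatrix:
    """Tree-ensemble regression importances as directed edge scores.

    Each column is regressed in turn on all other columns with a randomized
    forest of ``n_trees`` regression trees sampling ``k_candidates`` features
    per split; the variance-reduction importance of predictor i for target j
    becomes score[i, j], normalized to sum to 1 per target (degenerate
    targets with nothing to explain keep all-zero importances).  A fixed seed
    gives identical output.
    """
    frame = matrix.completed("zero_fill")
    _require_rows(frame, 5)
    x = frame.to_numpy()
    n, p = x.shape
    out = np.zeros((p, p))
    rng = np.random.default_rng(seed)
    target_seeds = rng.integers(0, 2**31 - 1, size=p)
    for t in range(p):
        y = x[:, t]
        if np.unique(y).size < 2:
            continue
        predictors = np.arange(p) != t
        model = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=k_candidates,
            random_state=int(target_seeds[t]),
            n_jobs=1,
        )
        model.fit(x[:, predictors], y)
        imp = model.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        out[predictors, t] = imp
    return _frame(out, frame.columns, "genie3", directed=True)


def score_all(
    matrix: ExpressionMatrix,
    algorithms: tuple[str, ...] = ALGORITHMS,
    seed: int = 0,
    mi_cfg: MIEstimatorConfig | None = None,
    n_trees: int = 100,
    corr_missing_policy: str = "pairwise_complete",
) -> dict[str, ScoreMatrix]:
    """Run the requested scorers, sharing one MI matrix for CLR and MRNETB.

    ``corr_missing_policy`` applies to the correlation family
    (Pearson/Spearman/dCor); the scorers that require a complete matrix
    (MI family, trees) zero-fill unobserved cells.
    """
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    results: dict[str, ScoreMatrix] = {}
    mi = None
    if {"clr", "mrnetb"} & set(algorithms):
        mi = mutual_information_matrix(matrix, mi_cfg)
    for alg in algorithms:
        if alg in ("pearson", "spearman"):
            results[alg] = correlation_scores(matrix, alg, corr_missing_policy)
        elif alg == "dcor":
            results[alg] = distance_correlation_scores(matrix, corr_missing_policy)
        elif alg == "clr":
            results[alg] = clr_scores(mi)
        elif alg == "mrnetb":
            results[alg] = mrnetb_scores(mi)
        elif alg == "genie3":
            results[alg] = genie3_scores(matrix, n_trees=n_trees, seed=seed)
    return results
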