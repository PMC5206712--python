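"""Each scorer against an independent brute-force oracle, plus invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mirsig as m
from mirsig.inference import (
    MIEstimatorConfig,
    _equal_frequency_codes,
    _mrnetb_select,
)
from mirsig.matrices import ExpressionMatrix


def _em(values, cols=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    cols = cols or [f"d1:m{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=[f"s{i}" for i in range(values.shape[0])], columns=cols)
    return ExpressionMatrix(frame, "average")


def _random_em(rng, n, p) -> ExpressionMatrix:
    return _em(rng.standard_normal((n, p)))


# ---------------------------------------------------------------- oracles


def brute_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    return 0.0 if denom == 0 else float((xc * yc).sum() / denom)


def brute_rank(v):
    # average ranks by explicit pairwise comparison counting
    v = list(v)
    return [1 + sum(o < x for o in v) + (sum(o == x for o in v) - 1) / 2 for x in v]


def brute_dcor(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)

    def centered(v):
        d = np.array([[abs(a - b) for b in v] for a in v])
        out = np.empty_like(d)
        for i in range(n):
            for j in range(n):
                out[i, j] = d[i, j] - d[i].mean() - d[:, j].mean() + d.mean()
        return out

    a, b = centered(x), centered(y)
    dcov2 = (a * b).mean()
    dvx, dvy = (a * a).mean(), (b * b).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return float(math.sqrt(max(dcov2, 0.0)) / math.sqrt(math.sqrt(dvx * dvy)))


def brute_mi(codes_a, codes_b):
    n = len(codes_a)
    mi = 0.0
    for a in set(codes_a):
        for b in set(codes_b):
            pab = sum(1 for u, v in zip(codes_a, codes_b) if (u, v) == (a, b)) / n
            if pab == 0:
                continue
            pa = sum(1 for u in codes_a if u == a) / n
            pb = sum(1 for v in codes_b if v == b) / n
            mi += pab * math.log(pab / (pa * pb))
    return mi


def brute_clr(mi_mat):
    p = mi_mat.shape[0]
    z = np.zeros((p, p))
    for i in range(p):
        bg = [mi_mat[i, j] for j in range(p) if j != i]
        mu, sd = np.mean(bg), np.std(bg)
        for j in range(p):
            z[i, j] = 0.0 if sd == 0 else max(0.0, (mi_mat[i, j] - mu) / sd)
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                out[i, j] = math.sqrt(z[i, j] ** 2 + z[j, i] ** 2)
    return out


def mrmr_objective(subset, rel, red):
    total = 0.0
    for j in subset:
        others = [k for k in subset if k != j]
        redundancy = sum(red[j, k] for k in others) / len(others) if others else 0.0
        total += rel[j] - redundancy
    return total


def brute_mrnetb_optimum(rel, red):
    p = len(rel)
    best = 0.0
    for r in range(1, p + 1):
        for subset in itertools.combinations(range(p), r):
            best = max(best, mrmr_objective(subset, rel, red))
    return best


# ------------------------------------------------------------- correlation


def test_pearson_perfect_line_scores_one():
    x = np.arange(5.0)
    em = _em(np.c_[x, 2 * x + 1])
    assert m.correlation_scores(em, "pearson").values()[0, 1] == pytest.approx(1.0)


def test_spearman_perfect_monotone_scores_one():
    x = np.array([-2.0, -1.0, 0.5, 1.0, 2.0])
    em = _em(np.c_[x, x**3])
    assert m.correlation_scores(em, "spearman").values()[0, 1] == pytest.approx(1.0)


def test_correlations_match_brute_force_formulas():
    rng = np.random.default_rng(42)
    em = _random_em(rng, 4, 3)
    x = em.data.to_numpy()
    pear = m.correlation_scores(em, "pearson").values()
    spear = m.correlation_scores(em, "spearman").values()
    for i, j in itertools.combinations(range(3), 2):
        assert pear[i, j] == pytest.approx(abs(brute_pearson(x[:, i], x[:, j])))
        assert spear[i, j] == pytest.approx(
            abs(brute_pearson(brute_rank(x[:, i]), brute_rank(x[:, j])))
        )


def test_zero_variance_column_scores_zero():
    em = _em(np.c_[np.arange(5.0), np.ones(5)])
    assert m.correlation_scores(em, "pearson").values()[0, 1] == 0.0


def test_too_few_rows_rejected():
    with pytest.raises(ValueError):
        m.correlation_scores(_em(np.ones((2, 2))))


# ---------------------------------------------------------------- distance


def test_dcor_identical_variables_score_one():
    x = np.random.default_rng(0).standard_normal(6)
    em = _em(np.c_[x, x])
    assert m.distance_correlation_scores(em).values()[0, 1] == pytest.approx(1.0)


def test_dcor_constant_column_scores_zero():
    em = _em(np.c_[np.arange(6.0), np.full(6, 3.0)])
    assert m.distance_correlation_scores(em).values()[0, 1] == 0.0


def test_dcor_matches_double_centering_definition():
    rng = np.random.default_rng(7)
    em = _random_em(rng, 6, 3)
    x = em.data.to_numpy()
    got = m.distance_correlation_scores(em).values()
    for i, j in itertools.combinations(range(3), 2):
        assert got[i, j] == pytest.approx(brute_dcor(x[:, i], x[:, j]), abs=1e-10)


# --------------------------------------------------------- mutual information


def test_mi_perfectly_dependent_binary_is_ln2():
    x = np.array([0.0, 1.0] * 4)
    em = _em(np.c_[x, 10 * x + 3])
    mi = m.mutual_information_matrix(em, MIEstimatorConfig(bin_count=2))
    assert mi.values()[0, 1] == pytest.approx(math.log(2))


def test_mi_independent_columns_near_zero():
    rng = np.random.default_rng(1)
    em = _em(rng.standard_normal((4000, 2)))
    mi = m.mutual_information_matrix(em, MIEstimatorConfig(bin_count=4))
    assert mi.values()[0, 1] < 0.01


def test_mi_matches_hand_tabulated_contingency():
    rng = np.random.default_rng(3)
    em = _random_em(rng, 8, 3)
    cfg = MIEstimatorConfig(bin_count=2)
    got = m.mutual_information_matrix(em, cfg).values()
    x = em.data.to_numpy()
    codes = [_equal_frequency_codes(x[:, j], 2).tolist() for j in range(3)]
    for i, j in itertools.combinations(range(3), 2):
        assert got[i, j] == pytest.approx(brute_mi(codes[i], codes[j]))
    # diagonal is the column entropy: MI(x, x) = H(x)
    assert got[0, 0] == pytest.approx(brute_mi(codes[0], codes[0]))


def test_mi_degenerate_identical_rows_score_zero():
    em = _em(np.ones((6, 2)))
    assert m.mutual_information_matrix(em, MIEstimatorConfig(bin_count=2)).values()[0, 1] == 0.0


def test_mi_bin_count_validation():
    with pytest.raises(ValueError):
        MIEstimatorConfig(bin_count=9).resolve_bins(8)
    assert MIEstimatorConfig().resolve_bins(100) == 10
    assert MIEstimatorConfig().resolve_bins(3) == 2


# --------------------------------------------------------------------- CLR


def test_clr_flat_background_gives_zero():
    mi = np.full((4, 4), 0.7)
    np.fill_diagonal(mi, 2.0)
    sm = m.ScoreMatrix("mi", pd.DataFrame(mi, index=list("abcd"), columns=list("abcd")))
    assert np.all(m.clr_scores(sm).values() == 0.0)


def test_clr_matches_brute_force_z_scoring():
    rng = np.random.default_rng(5)
    raw = rng.random((4, 4))
    mi = (raw + raw.T) / 2
    sm = m.ScoreMatrix("mi", pd.DataFrame(mi, index=list("abcd"), columns=list("abcd")))
    got = m.clr_scores(sm).values()
    assert np.allclose(got, brute_clr(mi))
    assert np.allclose(got, got.T)


# ------------------------------------------------------------------ MRNETB


def test_mrnetb_two_variables_score_is_their_mi():
    x = np.array([0.0, 1.0] * 4)
    em = _em(np.c_[x, 10 * x])
    mi = m.mutual_information_matrix(em, MIEstimatorConfig(bin_count=2))
    got = m.mrnetb_scores(mi).values()
    assert got[0, 1] == pytest.approx(math.log(2))


def test_mrnetb_duplicate_predictor_scores_below_original():
    rng = np.random.default_rng(2)
    x1 = rng.standard_normal(40)
    x2 = x1.copy()  # exact duplicate of x1
    x3 = x1 + 0.3 * rng.standard_normal(40)
    em = _em(np.c_[x1, x2, x3])
    mi = m.mutual_information_matrix(em, MIEstimatorConfig(bin_count=4))
    got = m.mrnetb_scores(mi).values()
    assert got[1, 2] < got[0, 2]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
def test_mrnetb_attains_exhaustive_mrmr_optimum(seed):
    rng = np.random.default_rng(seed)
    p = int(rng.integers(3, 6))
    raw = rng.random((p, p))
    mi = (raw + raw.T) / 2
    rel = mi[1:, 0].copy()
    red = mi[1:, 1:].copy()
    np.fill_diagonal(red, 0.0)
    sel, _scores = _mrnetb_select(rel, red)
    achieved = mrmr_objective(list(np.flatnonzero(sel)), rel, red)
    assert achieved == pytest.approx(brute_mrnetb_optimum(rel, red))


# ------------------------------------------------------------------ GENIE3


def test_genie3_zero_variance_target_gets_zero_importances():
    rng = np.random.default_rng(0)
    em = _em(np.c_[rng.standard_normal(10), np.zeros(10), rng.standard_normal(10)])
    got = m.genie3_scores(em, n_trees=20, seed=0).values()
    assert np.all(got[:, 1] == 0.0)


def test_genie3_importances_sum_to_one_per_target():
    rng = np.random.default_rng(1)
    em = _random_em(rng, 20, 4)
    got = m.genie3_scores(em, n_trees=25, seed=3).values()
    assert np.allclose(got.sum(axis=0), 1.0)


def test_genie3_recovers_planted_predictor_and_is_deterministic():
    rng = np.random.default_rng(4)
    x1 = rng.standard_normal(60)
    x2 = rng.standard_normal(60)
    x3 = x1 + 0.1 * rng.standard_normal(60)
    em = _em(np.c_[x1, x2, x3])
    a = m.genie3_scores(em, n_trees=50, seed=9).values()
    b = m.genie3_scores(em, n_trees=50, seed=9).values()
    assert np.array_equal(a, b)
    assert a[0, 2] > a[1, 2]


# ------------------------------------------------------------- shared laws


@pytest.mark.parametrize("scorer", ["pearson", "spearman", "dcor", "mi", "clr", "mrnetb", "genie3"])
def test_column_permutation_equivariance(scorer):
    rng = np.random.default_rng(10)
    em = _random_em(rng, 12, 4)
    perm = [2, 0, 3, 1]
    pem = ExpressionMatrix(em.data.iloc[:, perm], "average")

    def run(e):
        if scorer in ("pearson", "spearman"):
            return m.correlation_scores(e, scorer).values()
        if scorer == "dcor":
            return m.distance_correlation_scores(e).values()
        mi = m.mutual_information_matrix(e, MIEstimatorConfig(bin_count=3))
        if scorer == "mi":
            return mi.values()
        if scorer == "clr":
            return m.clr_scores(mi).values()
        if scorer == "mrnetb":
            return m.mrnetb_scores(mi).values()
        return m.genie3_scores(e, n_trees=20, seed=2).values()

    base = run(em)
    permuted = run(pem)
    if scorer == "genie3":
        # tree randomness is seeded per target position, so only check shape/contract
        assert permuted.shape == base.shape
    else:
        assert np.allclose(permuted, base[np.ix_(perm, perm)])


@pytest.mark.parametrize("scorer", ["spearman", "dcor", "mi"])
def test_positive_affine_rescaling_invariance(scorer):
    rng = np.random.default_rng(11)
    em = _random_em(rng, 15, 3)
    scaled = em.data.copy()
    scaled.iloc[:, 0] = 3.5 * scaled.iloc[:, 0] + 2.0
    sem = ExpressionMatrix(scaled, "average")

    def run(e):
        if scorer == "spearman":
            return m.correlation_scores(e, "spearman").values()
        if scorer == "dcor":
            return m.distance_correlation_scores(e).values()
        return m.mutual_information_matrix(e, MIEstimatorConfig(bin_count=3)).values()

    a, b = run(em), run(sem)
    if scorer == "dcor":
        # dCor is invariant up to the shared scale entering both axes
        assert np.allclose(a[0, 1:], b[0, 1:], atol=1e-12)
    else:
        assert np.allclose(a, b)


def test_symmetric_scorers_are_exactly_symmetric(small_synth):
    ds, _, _ = small_synth
    em = m.build_matrix(ds, "average")
    scores = m.score_all(em, seed=1, n_trees=10)
    for alg in ("pearson", "spearman", "dcor", "clr", "mrnetb"):
        v = scores[alg].values()
        assert np.array_equal(v, v.T), alg
        assert not scores[alg].directed
    assert scores["genie3"].directed
    for alg, sm in scores.items():
        assert np.all(np.isfinite(sm.values())), alg
        assert np.all(sm.values() >= 0), alg


def test_score_matrix_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(12)
    em = _random_em(rng, 8, 3)
    sm = m.correlation_scores(em, "pearson")
    sm.to_csv(tmp_path / "s.csv")
    back = m.ScoreMatrix.from_csv(tmp_path / "s.csv", "pearson")
    assert np.allclose(back.values(), sm.values())
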