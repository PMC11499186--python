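"""Unit and oracle tests for the BAG statistics battery."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from brainage.stats import (PredictionRecord, bag, bland_altman,
                            bonferroni, compare_groups, mae, mann_whitney_u,
                            mean_bag, partial_spearman, spearman)
import pandas as pd


# ---------------------------------------------------------------------------
# bag / mae / mean_bag
# ---------------------------------------------------------------------------

def test_bag_sign_convention():
    assert bag(54, 37) == 17
    assert bag(40, 40) == 0
    assert bag(40, 50) == -10


def test_prediction_record_bag():
    r = PredictionRecord("s1", chronological_age=37.0, predicted_age=54.0)
    assert r.bag == 17.0


def test_mae_and_mean_bag():
    recs = [PredictionRecord("a", 50, 48), PredictionRecord("b", 50, 52)]
    assert mae(recs) == 2.0
    mean, sd = mean_bag(recs)
    assert mean == 0.0
    assert sd == pytest.approx(np.std([-2, 2], ddof=1))


def test_mae_perfect_predictions():
    recs = [PredictionRecord(str(i), 40 + i, 40 + i) for i in range(5)]
    assert mae(recs) == 0.0


def test_mae_geq_abs_mean_bag():
    rng = np.random.default_rng(0)
    for _ in range(20):
        bags = rng.normal(0, 5, size=10)
        recs = [PredictionRecord(str(i), 50, 50 + b)
                for i, b in enumerate(bags)]
        mean, _ = mean_bag(recs)
        assert mae(recs) >= abs(mean) - 1e-12


def test_mae_empty_error():
    with pytest.raises(ValueError):
        mae([])


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def test_bland_altman_zero_variance():
    recs = [PredictionRecord(str(i), 40, 43) for i in range(4)]
    ba = bland_altman(recs)
    assert ba.mean_diff == 3.0
    assert ba.lower_limit == pytest.approx(3.0)
    assert ba.upper_limit == pytest.approx(3.0)


def test_bland_altman_limits_symmetric():
    rng = np.random.default_rng(3)
    recs = [PredictionRecord(str(i), a, a + d) for i, (a, d) in
            enumerate(zip(rng.uniform(20, 80, 50), rng.normal(2, 4, 50)))]
    ba = bland_altman(recs)
    assert ba.upper_limit - ba.mean_diff == \
        pytest.approx(ba.mean_diff - ba.lower_limit)
    assert ba.upper_limit == pytest.approx(ba.mean_diff + 1.96 * ba.sd_diff)


def test_bland_altman_monte_carlo_coverage():
    # ~95% of Normal diffs inside the limits, +/- 0.7%
    rng = np.random.default_rng(7)
    diffs = rng.normal(2.0, 3.0, size=10_000)
    recs = [PredictionRecord(str(i), 50.0, 50.0 + d)
            for i, d in enumerate(diffs)]
    ba = bland_altman(recs)
    inside = np.mean((diffs >= ba.lower_limit) & (diffs <= ba.upper_limit))
    assert inside == pytest.approx(0.95, abs=0.007)


def test_bland_altman_too_few():
    with pytest.raises(ValueError):
        bland_altman([PredictionRecord("a", 40, 42)])


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _brute_force_mw(x, y):
    """Independent enumeration oracle for the exact two-sided p."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, m = len(x), len(y)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    dev = abs(u_obs - n * m / 2)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        total += 1
        if abs(u - n * m / 2) >= dev - 1e-12:
            count += 1
    return u_obs, count / total


def test_mw_exact_small_example():
    res = mann_whitney_u([1, 2], [3, 4], mode="exact")
    assert res.statistic == 0
    assert res.p_value == pytest.approx(2 / 6)


def test_mw_identical_samples_p_one():
    x = [1.0, 2.0, 3.0]
    res = mann_whitney_u(x, x, mode="exact")
    assert res.p_value == 1.0
    res = mann_whitney_u(x, x, mode="normal_approx")
    assert res.p_value == 1.0


@pytest.mark.parametrize("n,m", [(2, 2), (3, 4), (5, 5), (8, 8), (8, 3)])
def test_mw_exact_matches_enumeration_oracle(n, m):
    rng = np.random.default_rng(n * 100 + m)
    for trial in range(5):
        # include ties on some trials
        if trial % 2:
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, m).astype(float)
        else:
            x = rng.normal(size=n)
            y = rng.normal(size=m)
        res = mann_whitney_u(x, y, mode="exact")
        u_oracle, p_oracle = _brute_force_mw(x, y)
        assert res.statistic == pytest.approx(u_oracle)
        assert res.p_value == pytest.approx(p_oracle)


def test_mw_approx_close_to_exact():
    # |delta p| <= 0.01 for n = m = 20 (forced modes on the same data)
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 8)
    y = rng.normal(0.5, 1, 8)
    exact = mann_whitney_u(x, y, mode="exact")
    approx = mann_whitney_u(x, y, mode="normal_approx")
    assert abs(exact.p_value - approx.p_value) <= 0.01


def test_mw_approx_matches_scipy():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, 25)
    y = rng.normal(0.8, 1, 30)
    res = mann_whitney_u(x, y, mode="normal_approx")
    ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_mw_auto_mode_switch():
    small = mann_whitney_u(np.arange(8.0), np.arange(8.0) + 0.5)
    assert small.method == "mann-whitney-exact"
    big = mann_whitney_u(np.arange(9.0), np.arange(8.0) + 0.5)
    assert big.method == "mann-whitney-normal-approx"


def test_mw_empty_error():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone():
    x = np.array([1.0, 2.5, 3.0, 7.0])
    assert spearman(x, x ** 3).statistic == pytest.approx(1.0)


def test_spearman_rank_difference_formula():
    # rho = 1 - 6 * sum(d^2) / (n (n^2 - 1)) for untied data
    res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
    assert res.statistic == pytest.approx(1 - 6 * 4 / (4 * 15))


def test_spearman_symmetry():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=12), rng.normal(size=12)
    assert spearman(x, y).statistic == pytest.approx(
        spearman(y, x).statistic)


def test_spearman_matches_scipy():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    res = spearman(x, y)
    ref = sps.spearmanr(x, y)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


def test_spearman_constant_error():
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_exact_permutation():
    res = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4], exact=True)
    # p = fraction of the 120 permutations with |rho| >= rho_obs
    assert res.method == "spearman-exact-permutation"
    assert 0 < res.p_value <= 1


# ---------------------------------------------------------------------------
# Partial Spearman
# ---------------------------------------------------------------------------

def _brute_partial_spearman(x, y, covs):
    """Explicit rank/residual arithmetic, written independently."""
    def rank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        ranks[order] = np.arange(1, len(v) + 1)
        # midranks for ties
        for val in np.unique(v):
            sel = v == val
            ranks[sel] = ranks[sel].mean()
        return ranks

    rx, ry = rank(x), rank(y)
    cols = [np.ones(len(rx))]
    for c in covs:
        c = np.asarray(c, dtype=float)
        cols.append(rank(c) if len(np.unique(c)) > 2 else c)
    design = np.column_stack(cols)
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    return float(ex @ ey / np.sqrt((ex ** 2).sum() * (ey ** 2).sum()))


def test_partial_spearman_empty_covariates_reduces_to_spearman():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=30), rng.normal(size=30)
    a = partial_spearman(x, y)
    b = spearman(x, y)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-10)


def test_partial_spearman_conditional_independence():
    rng = np.random.default_rng(6)
    n = 1000
    z = rng.normal(size=n)
    x = z + rng.normal(size=n)
    y = z + rng.normal(size=n)
    marginal = spearman(x, y).statistic
    partial = partial_spearman(x, y, {"z": z}).statistic
    assert marginal > 0.2  # the confound is real
    assert abs(partial) < 0.08


def test_partial_spearman_oracle_equivalence():
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(15, 40))
        x = rng.normal(size=n)
        y = x * 0.3 + rng.normal(size=n)
        covs = [rng.normal(size=n), rng.integers(0, 2, n).astype(float)]
        res = partial_spearman(x, y, {"c1": covs[0], "sex": covs[1]})
        oracle = _brute_partial_spearman(x, y, covs)
        assert res.statistic == pytest.approx(oracle, abs=1e-10)


def test_partial_spearman_binary_string_covariate():
    rng = np.random.default_rng(10)
    n = 50
    x, y = rng.normal(size=n), rng.normal(size=n)
    sex = np.where(rng.integers(0, 2, n) == 0, "M", "F")
    res = partial_spearman(x, y, {"sex": sex})
    oracle = _brute_partial_spearman(x, y, [(sex == "F").astype(float)])
    assert res.statistic == pytest.approx(oracle, abs=1e-10)


def test_partial_spearman_collinear_error():
    rng = np.random.default_rng(11)
    n = 30
    x, y = rng.normal(size=n), rng.normal(size=n)
    c = rng.normal(size=n)
    with pytest.raises(ValueError, match="dup"):
        partial_spearman(x, y, {"c": c, "dup": 2 * c + 1})


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def test_bonferroni_paper_threshold():
    assert bonferroni(0.05, 102) == pytest.approx(0.00049, abs=5e-7)


def test_bonferroni_identity_and_monotone():
    assert bonferroni(0.05, 1) == 0.05
    thresholds = [bonferroni(0.05, m) for m in range(1, 20)]
    assert all(a > b for a, b in zip(thresholds, thresholds[1:]))


def test_bonferroni_invalid():
    with pytest.raises(ValueError):
        bonferroni(0.05, 0)
    with pytest.raises(ValueError):
        bonferroni(1.5, 3)


# ---------------------------------------------------------------------------
# compare_groups
# ---------------------------------------------------------------------------

def _toy_frame(rng, n=60):
    age = rng.uniform(20, 60, n)
    sex = np.where(rng.integers(0, 2, n) == 0, "M", "F")
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "age": age, "sex": sex,
        "bag": rng.normal(5, 4, n),
        "lesion_volume": rng.gamma(2.0, 1.0, n),
        "edss": rng.uniform(0, 6, n)})


def test_compare_groups_identical_groups_p_one():
    rng = np.random.default_rng(12)
    df = _toy_frame(rng, 30)
    dup = pd.concat([df, df], ignore_index=True)
    dup["flag"] = [True] * 30 + [False] * 30
    table = compare_groups(dup, "flag", ["lesion_volume", "edss"])
    assert (table["mann_whitney_p"] == 1.0).all()


def test_compare_groups_missing_variable():
    rng = np.random.default_rng(13)
    df = _toy_frame(rng)
    df["flag"] = df["bag"] < 0
    with pytest.raises(ValueError, match="not_there"):
        compare_groups(df, "flag", ["not_there"])


def test_compare_groups_power_on_generated_signal():
    # bag increasing in lesion_volume -> positive partial rho, significant
    rng = np.random.default_rng(14)
    df = _toy_frame(rng, 150)
    df["bag"] = 2.0 * df["lesion_volume"] + rng.normal(0, 1, len(df))
    df["flag"] = rng.integers(0, 2, len(df)).astype(bool)
    table = compare_groups(df, "flag", ["lesion_volume"])
    row = table.iloc[0]
    assert row["partial_rho"] > 0.5
    assert row["partial_p"] < 0.001


def test_compare_groups_type_one_error_rate():
    # coin-flip grouping on exchangeable data: ~5% false positives
    rng = np.random.default_rng(15)
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        vals = rng.normal(size=40)
        flip = rng.integers(0, 2, 40).astype(bool)
        if not flip.any() or flip.all():
            continue
        p = mann_whitney_u(vals[flip], vals[~flip],
                           mode="normal_approx").p_value
        hits += p < 0.05
    assert hits / n_rep == pytest.approx(0.05, abs=0.025)
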