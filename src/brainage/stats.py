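"""Brain-age-gap statistics.

BAG follows the convention ``predicted - chronological``: positive
values mean an older-appearing brain. The module provides the summary
measures (MAE, mean BAG, Bland-Altman limits of agreement) and the
rank-based battery used for group comparison: Mann-Whitney U (exact by
enumeration for small samples, tie- and continuity-corrected normal
approximation otherwise), Spearman correlation, partial Spearman
correlation by rank residualization, and Bonferroni correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_ENUMERATION_LIMIT = 16  # n + m at or below this -> exact in auto mode


@dataclass
class PredictionRecord:
    subject_id: str
    chronological_age: float
    predicted_age: float

    @property
    def bag(self) -> float:
        return self.predicted_age - self.chronological_age


@dataclass
class StatResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    corrected_alpha: float | None = None


@dataclass
class BlandAltmanSummary:
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    pairs: np.ndarray = field(repr=False, default=None)  # (mean age, diff)


def bag(predicted: float, chronological: float):
    """Brain age gap in years: predicted minus chronological age."""
    return predicted - chronological


def _bags(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records["bag"].to_numpy(dtype=float)
    vals = [r.bag if hasattr(r, "bag") else float(r) for r in records]
    return np.asarray(vals, dtype=float)


def mae(records) -> float:
    """Mean absolute error of the age predictions (mean |bag|)."""
    b = _bags(records)
    if b.size == 0:
        raise ValueError("mae requires at least one record")
    return float(np.abs(b).mean())


def mean_bag(records) -> tuple[float, float]:
    """(mean, sample SD) of the brain age gap."""
    b = _bags(records)
    if b.size < 2:
        raise ValueError("mean_bag requires at least two records")
    return float(b.mean()), float(b.std(ddof=1))


def bland_altman(records) -> BlandAltmanSummary:
    """Limits of agreement: mean difference +/- 1.96 x SD."""
    if isinstance(records, pd.DataFrame):
        diffs = records["bag"].to_numpy(dtype=float)
        means = ((records["predicted_age"] + records["chronological_age"])
                 / 2.0).to_numpy(dtype=float)
    else:
        records = list(records)
        diffs = np.array([r.bag for r in records], dtype=float)
        means = np.array([(r.predicted_age + r.chronological_age) / 2.0
                          for r in records])
    if diffs.size < 2:
        raise ValueError("bland_altman requires at least two records")
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanSummary(
        mean_diff=mean_diff, sd_diff=sd,
        lower_limit=mean_diff - 1.96 * sd,
        upper_limit=mean_diff + 1.96 * sd,
        pairs=np.column_stack([means, diffs]))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, computed from midranks of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(x, y, mode: str = "auto") -> StatResult:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates every assignment of the pooled (mid)ranks to
    the two groups; ``normal_approx`` uses the tie-corrected normal
    approximation with continuity correction; ``auto`` picks exact when
    n + m <= 16.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    n, m = x.size, y.size
    if mode == "auto":
        mode = "exact" if n + m <= EXACT_ENUMERATION_LIMIT else "normal_approx"
    u_obs = _u_statistic(x, y)
    mu = n * m / 2.0

    if mode == "exact":
        ranks = sps.rankdata(np.concatenate([x, y]))
        offset = n * (n + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        total = 0
        extreme = 0
        for combo in itertools.combinations(range(n + m), n):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / total
        method = "mann-whitney-exact"
    else:
        pooled = np.concatenate([x, y])
        nt = n + m
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts ** 3 - counts).sum()) / (nt * (nt - 1)))
        sigma2 = n * m / 12.0 * ((nt + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * sps.norm.sf(z))
        method = "mann-whitney-normal-approx"
    return StatResult(statistic=u_obs, p_value=float(p), method=method,
                      n=(n, m))


# ---------------------------------------------------------------------------
# Spearman and partial Spearman
# ---------------------------------------------------------------------------

def spearman(x, y, exact: bool = False) -> StatResult:
    """Spearman rank correlation with midrank ties.

    p-value from the t approximation, or by full permutation
    enumeration when ``exact=True`` (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (rxc[perms] @ ryc) / denom
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
        return StatResult(statistic=rho, p_value=p,
                          method="spearman-exact-permutation", n=(n,))
    p = _t_pvalue(rho, df=n - 2)
    return StatResult(statistic=rho, p_value=p, method="spearman-t", n=(n,))


def _t_pvalue(r: float, df: int) -> float:
    if df <= 0:
        raise ValueError("not enough observations for a p-value")
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def _encode_column(col: np.ndarray, name: str) -> np.ndarray:
    """Numeric passthrough; binary string covariates (e.g. sex) -> 0/1."""
    arr = np.asarray(col)
    if arr.dtype.kind in "fiub":
        return arr.astype(float)
    levels = sorted(set(arr.tolist()))
    if len(levels) > 2:
        raise ValueError(
            f"covariate {name!r} is non-numeric with >2 levels")
    mapping = {lev: i for i, lev in enumerate(levels)}
    return np.array([mapping[v] for v in arr], dtype=float)


def partial_spearman(x, y, covariates: Mapping[str, Sequence] | None = None
                     ) -> StatResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (covariates too, except binary
    ones which enter as 0/1); the ranks of x and y are residualized on
    the covariate columns (with intercept) by least squares, and the
    Pearson correlation of the residuals is reported with a t-test at
    ``df = n - k - 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    covariates = dict(covariates or {})
    k = len(covariates)
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if k == 0:
        rho = float(np.corrcoef(rx, ry)[0, 1])
        return StatResult(statistic=rho, p_value=_t_pvalue(rho, n - 2),
                          method="partial-spearman", n=(n,))
    cols = []
    names = list(covariates)
    for name in names:
        col = _encode_column(np.asarray(covariates[name]), name)
        if np.ptp(col) == 0:
            cols.append(np.zeros(n))  # constant column, caught below
        else:
            cols.append(sps.rankdata(col) if len(set(col)) > 2 else col)
    design = np.column_stack([np.ones(n)] + cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"collinear covariate columns: {bad}")
    resx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    resy = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((resx ** 2).sum() * (resy ** 2).sum())
    if denom == 0:
        raise ValueError("residuals are constant; correlation undefined")
    rho = float((resx @ resy) / denom)
    return StatResult(statistic=rho, p_value=_t_pvalue(rho, n - k - 2),
                      method="partial-spearman", n=(n,))


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    kept = [design[:, 0]]
    for j, name in enumerate(names, start=1):
        trial = np.column_stack(kept + [design[:, j]])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            bad.append(name)
        else:
            kept.append(design[:, j])
    return bad or names


def bonferroni(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Group comparison tables
# ---------------------------------------------------------------------------

def _iqr(vals: np.ndarray) -> float:
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
    return float(q3 - q1)


def compare_groups(df: pd.DataFrame,
                   grouping: str | Callable[[pd.DataFrame], pd.Series],
                   variables: Sequence[str],
                   bag_col: str = "bag",
                   covariates: Sequence[str] = ("age", "sex"),
                   covariate_overrides: Mapping[str, Sequence[str]]
                   | None = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Two-group medians/IQRs with Mann-Whitney p, plus univariate and
    partial Spearman correlations of each variable with the BAG.

    ``grouping`` is a boolean column name or a callable producing one.
    ``covariate_overrides`` maps a variable to its own covariate list
    (e.g. age-at-onset controlled for sex only).
    """
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValueError(f"variables missing from manifest: {missing}")
    mask = (df[grouping] if isinstance(grouping, str)
            else grouping(df)).astype(bool).to_numpy()
    if mask.all() or (~mask).all():
        raise ValueError("grouping must yield two non-empty groups")
    overrides = dict(covariate_overrides or {})
    bag_vals = df[bag_col].to_numpy(dtype=float)
    rows = []
    for var in variables:
        vals = df[var].to_numpy(dtype=float)
        g1, g0 = vals[mask], vals[~mask]
        mw = mann_whitney_u(g1, g0, mode="auto")
        uni = spearman(vals, bag_vals)
        cov_names = list(overrides.get(var, covariates))
        covs = {c: df[c].to_numpy() for c in cov_names}
        part = partial_spearman(vals, bag_vals, covs)
        rows.append({
            "variable": var,
            "median_group1": float(np.median(g1)),
            "iqr_group1": _iqr(g1),
            "median_group0": float(np.median(g0)),
            "iqr_group0": _iqr(g0),
            "mann_whitney_p": mw.p_value,
            "spearman_rho": uni.statistic,
            "spearman_p": uni.p_value,
            "partial_rho": part.statistic,
            "partial_p": part.p_value,
            "partial_covariates": ",".join(cov_names),
        })
    out = pd.DataFrame(rows)
    out["significant"] = out["mann_whitney_p"] < alpha
    return out
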