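"""SmoothGrad saliency maps and regional saliency scoring.

A saliency map is the average absolute input gradient of the age
prediction over noise-perturbed copies of a volume. Maps are linearly
mapped to [0, 255], denoised by discarding the bottom tail of positive
intensities, scored per parcellation region (coverage percentage times
a min-max-scaled mean-intensity weight), averaged over sex-balanced
groups per age band, binarized, and compared across groups with Dice
overlap and Mann-Whitney tests under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phantom import Parcellation
from .stats import bonferroni, mann_whitney_u

# Age bands used for group averaging: label -> [lo, hi) in years.
AGE_BANDS: dict[str, tuple[float, float]] = {
    "<30": (0.0, 30.0),
    "30-39": (30.0, 40.0),
    "40-49": (40.0, 50.0),
    "50-59": (50.0, 60.0),
}
# The youngest band uses a half-size sample (5M/5F instead of 10M/10F).
N_PER_SEX = {"<30": 5, "30-39": 10, "40-49": 10, "50-59": 10}


@dataclass
class SaliencyMap:
    data: np.ndarray
    subject_id: str = ""
    n_samples: int = 1
    noise_fraction: float = 0.0
    seed: int = 0


@dataclass
class GroupMap:
    data: np.ndarray  # binary {0, 1}
    cohort: str
    age_band: str
    member_ids: list[str] = field(default_factory=list)
    sex_composition: dict[str, int] = field(default_factory=dict)


def smoothgrad(model, vol: np.ndarray, n_samples: int = 25,
               noise_fraction: float = 0.10, seed: int = 0,
               subject_id: str = "") -> SaliencyMap:
    """Mean absolute input gradient over noise-perturbed copies.

    ``model`` must expose ``value_and_input_grad(volume)``. Noise is
    i.i.d. Normal per voxel with sigma = noise_fraction * (max - min of
    the volume). ``n_samples=1, noise_fraction=0`` reduces to the plain
    gradient-magnitude map.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    vol = np.asarray(vol, dtype=np.float32)
    sigma = float(noise_fraction) * float(vol.max() - vol.min())
    rng = np.random.default_rng(seed)
    acc = np.zeros(vol.shape, dtype=np.float64)
    for _ in range(n_samples):
        if sigma > 0:
            perturbed = vol + rng.normal(0.0, sigma, size=vol.shape) \
                .astype(np.float32)
        else:
            perturbed = vol
        _, grad = model.value_and_input_grad(perturbed)
        acc += np.abs(grad)
    return SaliencyMap(data=acc / n_samples, subject_id=subject_id,
                       n_samples=n_samples, noise_fraction=noise_fraction,
                       seed=seed)


def _data(m) -> np.ndarray:
    if isinstance(m, (SaliencyMap, GroupMap)):
        return m.data
    return np.asarray(m)


def rescale_0_255(smap) -> np.ndarray:
    """Affine map of intensities to [0, 255]; a constant map -> zeros."""
    data = _data(smap).astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return np.zeros_like(data)
    # divide before scaling so the maximum maps to exactly 255.0
    return (data - lo) / (hi - lo) * 255.0


def denoise_threshold(smap, pct: float = 5.0,
                      mode: str = "percentile") -> np.ndarray:
    """Zero out the bottom ``pct`` of a saliency map.

    ``mode="percentile"``: the threshold is the ``pct``-th percentile of
    the strictly positive voxel values, applied with a strict
    comparison, so ``pct=0`` is the identity on positive voxels and
    ``pct=100`` clears the map.

    ``mode="range"``: the threshold is ``pct``% of the maximum
    intensity (i.e. of the [0, 255] scale after rescaling); voxels at
    or below it are zeroed. Saliency maps are heavily right-skewed, so
    this removes most of the dim background and leaves a focal support,
    which is what makes group-map Dice overlap discriminative.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError("pct must be in [0, 100]")
    if mode not in ("percentile", "range"):
        raise ValueError(f"unknown mode {mode!r}")
    data = _data(smap).astype(np.float64).copy()
    if pct == 100.0:
        return np.zeros_like(data)
    if mode == "range":
        cut = pct / 100.0 * float(data.max())
        data[data <= cut] = 0.0
        return data
    positive = data[data > 0]
    if positive.size == 0:
        return data
    thr = np.percentile(positive, pct)
    data[data < thr] = 0.0
    return data


def region_scores(smap, parcellation: Parcellation) -> pd.DataFrame:
    """Weighted saliency score per region.

    coverage_pct = 100 x fraction of non-zero voxels in the region;
    weight = min-max-scaled mean region intensity (all-equal means ->
    every weight 1); weighted_score = coverage_pct x weight.
    """
    data = _data(smap)
    labels = parcellation.label_grid
    if data.shape != labels.shape:
        raise ValueError("saliency map and parcellation shapes differ")
    rows = []
    for region in parcellation.regions:
        mask = labels == region.region_id
        n = int(mask.sum())
        if n == 0:
            raise ValueError(
                f"region {region.region_id} ({region.name} "
                f"{region.hemisphere}) has no voxels")
        vals = data[mask]
        rows.append({
            "region_id": region.region_id,
            "name": region.name,
            "hemisphere": region.hemisphere,
            "coverage_pct": 100.0 * float((vals != 0).sum()) / n,
            "mean_intensity": float(vals.mean()),
        })
    table = pd.DataFrame(rows)
    means = table["mean_intensity"].to_numpy()
    lo, hi = means.min(), means.max()
    if hi == lo:
        table["weight"] = 1.0
    else:
        table["weight"] = (means - lo) / (hi - lo)
    table["weighted_score"] = table["coverage_pct"] * table["weight"]
    return table


def _band_mask(ages: np.ndarray, band: str) -> np.ndarray:
    lo, hi = AGE_BANDS[band]
    return (ages >= lo) & (ages < hi)


def group_average_map(maps: Mapping[str, np.ndarray] | Sequence,
                      manifest: pd.DataFrame, cohort: str, age_band: str,
                      seed: int = 0, threshold_pct: float | None = None,
                      ) -> GroupMap:
    """Sex-balanced group mean of (thresholded) maps, then binarized.

    ``maps`` maps subject_id -> thresholded saliency array (SaliencyMap
    accepted). Samples ``N_PER_SEX[age_band]`` subjects per sex without
    replacement from the manifest rows matching cohort and band. If
    ``threshold_pct`` is given, the denoising threshold is applied here
    (for the average-then-threshold order, pass raw maps plus the pct).
    """
    if age_band not in AGE_BANDS:
        raise ValueError(f"unknown age band {age_band!r}; "
                         f"expected one of {list(AGE_BANDS)}")
    if not isinstance(maps, Mapping):
        maps = {m.subject_id: m for m in maps}
    maps = {str(k): _data(v) for k, v in maps.items()}
    n_per_sex = N_PER_SEX[age_band]
    sub = manifest[(manifest["cohort"] == cohort)
                   & _band_mask(manifest["age"].to_numpy(dtype=float),
                                age_band)
                   & manifest["subject_id"].astype(str).isin(maps)]
    rng = np.random.default_rng(seed)
    member_ids: list[str] = []
    for sex in ("M", "F"):
        ids = sorted(sub.loc[sub["sex"] == sex, "subject_id"].astype(str))
        if len(ids) < n_per_sex:
            raise ValueError(
                f"need {n_per_sex} {sex} subjects in cohort {cohort!r} band "
                f"{age_band!r} with maps, found {len(ids)}")
        pick = rng.choice(len(ids), size=n_per_sex, replace=False)
        member_ids += [ids[i] for i in sorted(pick)]
    stack = np.stack([maps[i] for i in member_ids])
    mean = stack.mean(axis=0)
    if threshold_pct is not None:
        mean = denoise_threshold(mean, threshold_pct)
    binary = (mean > 0).astype(np.uint8)
    return GroupMap(data=binary, cohort=cohort, age_band=age_band,
                    member_ids=member_ids,
                    sex_composition={"M": n_per_sex, "F": n_per_sex})


def dice(a, b) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary maps."""
    am = _data(a) != 0
    bm = _data(b) != 0
    if am.shape != bm.shape:
        raise ValueError("maps must share one shape")
    na, nb = int(am.sum()), int(bm.sum())
    if na + nb == 0:
        raise ValueError("both maps are empty; Dice undefined")
    return 2.0 * int((am & bm).sum()) / (na + nb)


def compare_region_scores(healthy_tables: Sequence[pd.DataFrame],
                          ms_tables: Sequence[pd.DataFrame],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-region Mann-Whitney comparison of weighted saliency scores.

    Regions are ranked by the mean healthy-group weighted score; the
    significance threshold is Bonferroni-corrected by the number of
    regions.
    """
    if len(healthy_tables) < 2 or len(ms_tables) < 2:
        raise ValueError("need at least two subjects per group")

    def _collect(tables):
        scores: dict[int, list[float]] = {}
        meta = {}
        for t in tables:
            for r in t.itertuples():
                scores.setdefault(int(r.region_id), []).append(
                    float(r.weighted_score))
                meta[int(r.region_id)] = (r.name, r.hemisphere)
        return scores, meta

    h_scores, meta = _collect(healthy_tables)
    m_scores, _ = _collect(ms_tables)
    if set(h_scores) != set(m_scores):
        raise ValueError("region sets differ between groups")
    threshold = bonferroni(alpha, len(h_scores))
    rows = []
    for rid in h_scores:
        h = np.asarray(h_scores[rid])
        m = np.asarray(m_scores[rid])
        res = mann_whitney_u(h, m, mode="auto")
        name, hemi = meta[rid]
        rows.append({
            "region_id": rid, "name": name, "hemisphere": hemi,
            "mean_score_healthy": float(h.mean()),
            "mean_score_ms": float(m.mean()),
            "p_value": res.p_value,
            "significant_after_bonferroni": res.p_value < threshold,
        })
    out = pd.DataFrame(rows).sort_values(
        "mean_score_healthy", ascending=False, ignore_index=True)
    out.attrs["bonferroni_threshold"] = threshold
    return out
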