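"""End-to-end experiment orchestration.

Chains the stages on a synthetic cohort: generate phantoms -> zero-mean
rescale -> population crop (bounds frozen on the healthy training
split) -> stratified split + CNN training -> predictions and BAG
statistics -> SmoothGrad saliency, regional scores, group maps and Dice
overlaps. Both the CLI ``run`` command and the acceptance tests drive
this module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import model as model_mod
from . import phantom, preprocess, saliency, stats
from .phantom import CohortConfig, Parcellation
from .preprocess import CropBounds


@dataclass
class TinyPreset:
    """Desk-scale experiment configuration (32^3 grid, small filters)."""

    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_healthy=300, n_ms=60, age_range=(20.0, 89.0),
        ms_age_range=(25.0, 55.0), grid_shape=(32, 32, 32),
        ms_offset_mean=8.0, ms_offset_sd=2.0))
    spec: model_mod.ModelSpec = field(
        default_factory=lambda: model_mod.ModelSpec(
            conv_block_filters=[8, 8, 16, 16], post_block_filters=16,
            dropout_rate=0.2))
    train: model_mod.TrainConfig = field(
        default_factory=lambda: model_mod.TrainConfig(
            epochs=40, batch_size=8, max_shift=2, augment_prob=0.5,
            learning_rate=0.01))


@dataclass
class PaperPreset:
    """Published-scale configuration (not runnable at desk scale)."""

    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_healthy=5294, n_ms=195, grid_shape=(182, 218, 182)))
    spec: model_mod.ModelSpec = field(default_factory=model_mod.ModelSpec)
    train: model_mod.TrainConfig = field(
        default_factory=model_mod.TrainConfig)


PRESETS = {"tiny": TinyPreset, "paper": PaperPreset}


@dataclass
class ExperimentResult:
    manifest: pd.DataFrame            # per-subject records + split column
    crop_bounds: CropBounds
    parcellation: Parcellation        # cropped to the analysis grid
    trained: model_mod.TrainedModel
    predictions: pd.DataFrame         # subject_id, cohort, split, ages, bag
    healthy_test_bag: tuple[float, float]
    ms_bag: tuple[float, float]
    ms_vs_healthy_p: float
    volumes: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def prepare_cohort(cfg: CohortConfig, split_seed: int = 0
                   ) -> tuple[dict[str, np.ndarray], pd.DataFrame,
                              CropBounds, Parcellation]:
    """Generate, rescale, split and crop a cohort.

    Returns (volumes by subject id, manifest with a ``split`` column,
    frozen crop bounds, cropped parcellation). MS subjects are never in
    the training splits; their split is recorded as ``ms``.
    """
    dataset, parc = phantom.generate_cohort(cfg)
    records = [rec for _, rec in dataset]
    healthy = [r for r in records if r.cohort == "healthy"]
    assignment = model_mod.stratified_split(healthy, seed=split_seed)

    rescaled = {rec.subject_id: preprocess.rescale_zero_mean(vol)
                for vol, rec in dataset}
    train_vols = [rescaled[r.subject_id] for r in healthy
                  if assignment[r.subject_id] == "train"]
    if not train_vols:
        raise ValueError("empty training split")
    bounds = preprocess.compute_crop_bounds(train_vols)
    volumes = {sid: preprocess.apply_crop(bounds, v).data.astype(np.float32)
               for sid, v in rescaled.items()}

    manifest = pd.DataFrame([dataclasses.asdict(r) for r in records])
    manifest["split"] = [assignment.get(r.subject_id, "ms")
                         for r in records]
    parc_cropped = Parcellation(
        label_grid=parc.label_grid[bounds.slices()], regions=parc.regions)
    return volumes, manifest, bounds, parc_cropped


def _stack(volumes: dict[str, np.ndarray],
           ids: Sequence[str]) -> np.ndarray:
    return np.stack([volumes[i] for i in ids])


def run_experiment(preset: TinyPreset | None = None, seed: int = 0,
                   ) -> ExperimentResult:
    """Full tiny-scale pipeline; deterministic for a given seed."""
    preset = preset or TinyPreset()
    cohort_cfg = dataclasses.replace(preset.cohort, seed=seed)
    train_cfg = dataclasses.replace(preset.train, seed=seed)

    volumes, manifest, bounds, parc = prepare_cohort(cohort_cfg,
                                                     split_seed=seed)
    by_split = {name: manifest.loc[manifest["split"] == name]
                for name in ("train", "validation", "test", "ms")}
    ages = manifest.set_index("subject_id")["age"]

    input_shape = bounds.shape
    net = model_mod.build_model(preset.spec, input_shape, seed=seed)
    trained = model_mod.train(
        net,
        (_stack(volumes, by_split["train"]["subject_id"]),
         ages[by_split["train"]["subject_id"]].to_numpy()),
        (_stack(volumes, by_split["validation"]["subject_id"]),
         ages[by_split["validation"]["subject_id"]].to_numpy()),
        train_cfg)

    eval_ids = list(by_split["test"]["subject_id"]) \
        + list(by_split["ms"]["subject_id"])
    recs = manifest.set_index("subject_id", drop=False).loc[eval_ids]
    preds = model_mod.predict(trained, _stack(volumes, eval_ids),
                              recs.to_dict("records"))
    pred_df = pd.DataFrame([{
        "subject_id": p.subject_id,
        "chronological_age": p.chronological_age,
        "predicted_age": p.predicted_age,
        "bag": p.bag} for p in preds])
    pred_df = pred_df.merge(
        manifest[["subject_id", "cohort", "split", "sex", "ms_offset"]],
        on="subject_id")

    healthy_test = pred_df[pred_df["split"] == "test"]
    ms = pred_df[pred_df["cohort"] == "MS"]
    mw = stats.mann_whitney_u(ms["bag"], healthy_test["bag"],
                              mode="normal_approx")
    return ExperimentResult(
        manifest=manifest, crop_bounds=bounds, parcellation=parc,
        trained=trained, predictions=pred_df,
        healthy_test_bag=stats.mean_bag(healthy_test),
        ms_bag=stats.mean_bag(ms),
        ms_vs_healthy_p=mw.p_value,
        volumes=volumes)


@dataclass
class SaliencyResult:
    maps: dict[str, np.ndarray]           # thresholded, [0, 255] scale
    score_tables: dict[str, pd.DataFrame]
    comparison: pd.DataFrame | None = None


def compute_saliency(result: ExperimentResult, subject_ids: Sequence[str],
                     n_samples: int = 12, noise_fraction: float = 0.10,
                     threshold_pct: float = 5.0,
                     threshold_mode: str = "range", seed: int = 0
                     ) -> SaliencyResult:
    """SmoothGrad -> [0, 255] -> bottom-5% denoising -> region scores,
    for each requested subject.

    The default denoising reads "bottom 5%" as a fraction of the
    intensity range, which leaves a focal map support; see
    :func:`brainage.saliency.denoise_threshold` for both readings.
    """
    maps: dict[str, np.ndarray] = {}
    tables: dict[str, pd.DataFrame] = {}
    for i, sid in enumerate(subject_ids):
        smap = saliency.smoothgrad(
            result.trained.model, result.volumes[sid],
            n_samples=n_samples, noise_fraction=noise_fraction,
            seed=seed + i, subject_id=sid)
        scaled = saliency.rescale_0_255(smap)
        cleaned = saliency.denoise_threshold(scaled, threshold_pct,
                                             mode=threshold_mode)
        maps[sid] = cleaned
        tables[sid] = saliency.region_scores(cleaned, result.parcellation)
    return SaliencyResult(maps=maps, score_tables=tables)


def dice_matrix(maps: dict[str, np.ndarray], manifest: pd.DataFrame,
                bands_healthy: Sequence[str], bands_ms: Sequence[str],
                seed: int = 0) -> pd.DataFrame:
    """Dice overlap between binarized group maps of healthy vs MS bands."""
    groups: dict[tuple[str, str], saliency.GroupMap] = {}
    for band in bands_healthy:
        groups[("healthy", band)] = saliency.group_average_map(
            maps, manifest, "healthy", band, seed=seed)
    for band in bands_ms:
        groups[("MS", band)] = saliency.group_average_map(
            maps, manifest, "MS", band, seed=seed)
    rows = []
    for mb in bands_ms:
        for hb in bands_healthy:
            rows.append({
                "ms_band": mb, "healthy_band": hb,
                "dice": saliency.dice(groups[("MS", mb)],
                                      groups[("healthy", hb)])})
    return pd.DataFrame(rows)
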