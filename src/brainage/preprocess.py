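"""Numeric preprocessing for template-space brain volumes.

Volumes arrive skull-stripped and affinely registered to a common
template, with background exactly zero. Preprocessing is intensity
rescaling to a zero mean over the brain mask, a population-wide crop to
the tightest box containing every subject's non-zero voxels, and QC
exclusion bookkeeping. Crop bounds are computed once (on the training
population) and applied unchanged everywhere else.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing and a space tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space: str = "template"
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.brain_mask is not None \
                and self.brain_mask.shape != self.data.shape:
            raise ValueError("brain_mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CropBounds:
    """Half-open 0-based (low, high) voxel bounds per axis."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if lo >= hi:
                raise ValueError(f"invalid bounds ({lo}, {hi}): low < high "
                                 "required")
            if lo < 0:
                raise ValueError("bounds must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in self.bounds)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.bounds)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"bounds": self.bounds}))

    @classmethod
    def from_json(cls, path: str | Path) -> "CropBounds":
        raw = json.loads(Path(path).read_text())
        return cls(tuple(tuple(b) for b in raw["bounds"]))


def rescale_zero_mean(vol: ImageVolume) -> ImageVolume:
    """Subtract the mean over the brain mask; background stays 0.

    The mask defaults to the non-zero voxels of the (skull-stripped)
    volume. Idempotent and equivariant to adding a constant on the mask.
    """
    mask = vol.brain_mask if vol.brain_mask is not None else vol.data != 0
    if not mask.any():
        raise ValueError("empty brain mask: cannot rescale")
    out = np.zeros_like(vol.data, dtype=np.float64)
    out[mask] = vol.data[mask] - vol.data[mask].mean()
    return ImageVolume(data=out, spacing=vol.spacing, space=vol.space,
                      brain_mask=mask)


def compute_crop_bounds(vols: Sequence[ImageVolume | np.ndarray]
                        ) -> CropBounds:
    """Tightest box containing the union of non-zero voxels."""
    vols = list(vols)
    if not vols:
        raise ValueError("no volumes given")
    arrays = [v.data if isinstance(v, ImageVolume) else np.asarray(v)
              for v in vols]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all volumes must share one grid shape")
    union = np.zeros(shape, dtype=bool)
    for a in arrays:
        union |= a != 0
    if not union.any():
        raise ValueError("all volumes are identically zero; nothing to crop")
    bounds = []
    for ax in range(3):
        other = tuple(i for i in range(3) if i != ax)
        hit = union.any(axis=other)
        idx = np.flatnonzero(hit)
        bounds.append((int(idx[0]), int(idx[-1]) + 1))
    return CropBounds(tuple(bounds))


def apply_crop(bounds: CropBounds, vol: ImageVolume) -> ImageVolume:
    sl = bounds.slices()
    mask = vol.brain_mask[sl] if vol.brain_mask is not None else None
    return ImageVolume(data=vol.data[sl], spacing=vol.spacing,
                      space=vol.space, brain_mask=mask)


def population_crop(vols: Sequence[ImageVolume]
                    ) -> tuple[CropBounds, list[ImageVolume]]:
    """Crop every volume with one common tightest bounding box."""
    bounds = compute_crop_bounds(vols)
    return bounds, [apply_crop(bounds, v) for v in vols]


@dataclass
class ExclusionReport:
    per_cohort: dict[str, dict[str, int]] = field(default_factory=dict)
    unknown_ids: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return sum(v["excluded"] for v in self.per_cohort.values())


def apply_exclusions(manifest: pd.DataFrame,
                     exclusion_ids: Iterable[str]
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop QC-excluded subjects and report per-cohort counts.

    Rows are removed when their id is in ``exclusion_ids`` or their
    ``qc_excluded`` flag is already set. Unknown exclusion ids are
    logged as warnings, not fatal.
    """
    exclusion_ids = [str(i) for i in exclusion_ids]
    known = set(manifest["subject_id"].astype(str))
    unknown = [i for i in exclusion_ids if i not in known]
    for i in unknown:
        logger.warning("exclusion id %s not present in manifest", i)
    drop = manifest["subject_id"].astype(str).isin(set(exclusion_ids))
    if "qc_excluded" in manifest.columns:
        drop |= manifest["qc_excluded"].astype(bool)
    retained = manifest.loc[~drop].copy()
    report = ExclusionReport(unknown_ids=unknown)
    cohorts = manifest["cohort"].unique() if "cohort" in manifest.columns \
        else ["all"]
    for cohort in cohorts:
        if "cohort" in manifest.columns:
            before = int((manifest["cohort"] == cohort).sum())
            after = int((retained["cohort"] == cohort).sum())
        else:
            before, after = len(manifest), len(retained)
        report.per_cohort[str(cohort)] = {
            "before": before, "after": after, "excluded": before - after}
    return retained, report
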