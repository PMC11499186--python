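"""Synthetic template-space brain phantoms with a known aging signal.

Each phantom is a nested-ellipsoid "brain": an outer cortical shell
(gray matter) around a white-matter interior containing bilateral
lateral ventricles, midline third and fourth ventricles, and two
subcortical nuclei. Morphology is driven by a single *effective age*
``age + ms_offset``: ventricles grow and the cortical ribbon thins
monotonically with effective age, so a regressor trained on healthy
phantoms recovers the injected MS offset as a brain age gap. The MS
condition additionally seeds focal CSF-intensity ("black hole") lesions
in the white matter.

Shapes are rendered with ~1-voxel soft (partial-volume) boundaries so
that sub-voxel morphology changes move image intensities continuously;
tissue contrast follows T1 ordering CSF < GM < WM. Background voxels
are exactly zero. All randomness is derived from the config seed, so a
given config reproduces the dataset bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import ImageVolume

# Tissue intensities (arbitrary units, T1-like ordering CSF < GM < WM).
CSF_INTENSITY = 10.0
GM_INTENSITY = 70.0
SUBCORTICAL_INTENSITY = 85.0
WM_INTENSITY = 110.0

# Subject-level tissue label codes (per-phantom hard segmentation).
LBL_BACKGROUND = 0
LBL_VENTRICLE = 1
LBL_CORTEX = 2
LBL_WM = 3
LBL_SUBCORTICAL = 4
LBL_LESION = 5

MAX_EFFECTIVE_AGE = 110.0  # parcellation accommodates structures up to here


class ConfigurationError(ValueError):
    pass


@dataclass
class MorphologyParams:
    """Geometry in voxel units at the reference 32-voxel scale."""

    ventricle_radius: float
    cortical_thickness: float
    third_ventricle_radius: float
    fourth_ventricle_radius: float
    gm_intensity: float = GM_INTENSITY
    wm_intensity: float = WM_INTENSITY
    csf_intensity: float = CSF_INTENSITY
    lesion_count: int = 0
    lesion_radius: float = 0.0


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: str  # "M" or "F"
    cohort: str  # "healthy" or "MS"
    ms_offset: float = 0.0  # ground-truth brain-age offset, 0 for healthy
    edss: float = 0.0
    disease_duration: float = 0.0
    age_at_onset: float = 0.0
    lesion_volume: float = 0.0
    bpf: float = float("nan")
    qc_excluded: bool = False

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.cohort not in ("healthy", "MS"):
            raise ValueError(f"unknown cohort {self.cohort!r}")


@dataclass
class CohortConfig:
    n_healthy: int = 100
    n_ms: int = 20
    age_range: tuple[float, float] = (20.0, 89.0)
    ms_age_range: tuple[float, float] | None = None  # defaults to age_range
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    ms_offset_mean: float = 8.0
    ms_offset_sd: float = 2.0
    noise_sd: float = 0.05 * WM_INTENSITY
    sex_effect: float = 0.0  # optional ventricle-scale dimorphism, off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_ms < 0:
            raise ConfigurationError("cohort counts must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy min < max")
        if any(int(g) < 16 for g in self.grid_shape):
            raise ConfigurationError(
                f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if self.noise_sd < 0 or self.ms_offset_sd < 0:
            raise ConfigurationError("noise_sd and ms_offset_sd must be >= 0")


@dataclass
class Region:
    region_id: int
    name: str
    hemisphere: str  # "L", "R" or "midline"


@dataclass
class Parcellation:
    label_grid: np.ndarray
    regions: list[Region]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(ids) != len(set(ids)):
            raise ValueError("region ids must be unique")
        if any(i <= 0 for i in ids):
            raise ValueError("region ids must be positive (0 = background)")
        present = set(np.unique(self.label_grid).tolist()) - {0}
        missing = present - set(ids)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from the "
                             "region table")

    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.regions])

    def by_name(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Morphology model
# ---------------------------------------------------------------------------

def morphology_params(age: float, ms_offset: float = 0.0) -> MorphologyParams:
    """Deterministic effective-age -> geometry map (reference scale).

    Shared fields depend only on ``effective_age = age + ms_offset``;
    lesion fields depend only on ``ms_offset``.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    ea = age + ms_offset
    if ea < 0:
        raise ValueError("effective age (age + ms_offset) must be >= 0")
    ea = min(ea, MAX_EFFECTIVE_AGE)
    if ms_offset <= 0:
        lesion_count, lesion_radius = 0, 0.0
    else:
        lesion_count = int(min(8, 1 + ms_offset // 3))
        lesion_radius = 0.9 + 0.03 * ms_offset
    return MorphologyParams(
        ventricle_radius=1.3 + 0.032 * ea,
        cortical_thickness=max(0.8, 4.0 - 0.022 * ea),
        third_ventricle_radius=0.5 + 0.015 * ea,
        fourth_ventricle_radius=0.4 + 0.010 * ea,
        lesion_count=lesion_count,
        lesion_radius=lesion_radius,
    )


class _Geometry:
    """Grid-dependent positions/sizes, all proportional to the grid."""

    def __init__(self, grid_shape: Sequence[int]) -> None:
        self.shape = tuple(int(g) for g in grid_shape)
        nx, ny, nz = self.shape
        self.scale = min(self.shape) / 32.0
        self.center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
        # outer brain ellipsoid semi-axes (fixed over age)
        self.brain_axes = np.array([0.42 * nx, 0.44 * ny, 0.40 * nz])
        s = self.scale
        c = self.center
        self.ventricle_centers = {
            "L": c + np.array([-3.4 * s, 0.8 * s, 1.0 * s]),
            "R": c + np.array([+3.4 * s, 0.8 * s, 1.0 * s]),
        }
        self.third_center = c + np.array([0.0, -0.5 * s, 0.0])
        self.fourth_center = c + np.array([0.0, -2.5 * s, -4.5 * s])
        self.subcortical_centers = {
            "L": c + np.array([-5.8 * s, -1.5 * s, 0.0]),
            "R": c + np.array([+5.8 * s, -1.5 * s, 0.0]),
        }
        self.subcortical_radius = 2.2 * s
        ix, iy, iz = np.indices(self.shape)
        self._coords = np.stack([ix, iy, iz], axis=-1).astype(np.float64)

    # soft occupancy fields ---------------------------------------------
    def sphere(self, center: np.ndarray, radius: float) -> np.ndarray:
        d = np.linalg.norm(self._coords - center, axis=-1)
        return np.clip(radius - d + 0.5, 0.0, 1.0)

    def ellipsoid(self, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
        rho = np.linalg.norm((self._coords - center) / axes, axis=-1)
        k = float(min(axes))
        return np.clip((1.0 - rho) * k + 0.5, 0.0, 1.0)

    def brain(self) -> np.ndarray:
        return self.ellipsoid(self.center, self.brain_axes)

    def inner(self, cortical_thickness: float) -> np.ndarray:
        axes = self.brain_axes - cortical_thickness * self.scale
        if np.any(axes <= 1.0):
            raise ConfigurationError("grid too small for cortical thickness")
        return self.ellipsoid(self.center, axes)

    def ventricles(self, params: MorphologyParams) -> np.ndarray:
        s = self.scale
        occ = np.zeros(self.shape)
        for ctr in self.ventricle_centers.values():
            occ = np.maximum(occ, self.sphere(ctr,
                                              params.ventricle_radius * s))
        occ = np.maximum(occ, self.sphere(
            self.third_center, params.third_ventricle_radius * s))
        occ = np.maximum(occ, self.sphere(
            self.fourth_center, params.fourth_ventricle_radius * s))
        return occ

    def lesions(self, params: MorphologyParams,
                rng: np.random.Generator) -> np.ndarray:
        occ = np.zeros(self.shape)
        if params.lesion_count == 0:
            return occ
        s = self.scale
        for _ in range(params.lesion_count):
            # random position inside the white matter, away from midline
            # ventricles: radial band of the inner ellipsoid
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = rng.uniform(0.45, 0.70)
            pos = self.center + u * r * (self.brain_axes - 4.0 * s)
            occ = np.maximum(occ, self.sphere(pos, params.lesion_radius * s))
        return occ


def _check_fit(geom: _Geometry) -> None:
    """Verify that max-age structures stay inside the white matter."""
    s = geom.scale
    pmax = morphology_params(MAX_EFFECTIVE_AGE, 0.0)
    inner_axes = geom.brain_axes - pmax.cortical_thickness * s
    for ctr in geom.ventricle_centers.values():
        rel = np.abs(ctr - geom.center) + pmax.ventricle_radius * s
        if np.any(rel / inner_axes > 1.0):
            raise ConfigurationError(
                "grid too small: ventricles would leave the white matter")


def render_phantom(age: float, ms_offset: float, geom: _Geometry,
                   noise_sd: float, rng: np.random.Generator,
                   sex: str = "F", sex_effect: float = 0.0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns (image, tissue label grid)."""
    params = morphology_params(age, ms_offset)
    vr_scale = 1.0 + (sex_effect if sex == "M" else 0.0)
    if vr_scale != 1.0:
        params = dataclasses.replace(
            params, ventricle_radius=params.ventricle_radius * vr_scale)
    brain = geom.brain()
    inner = geom.inner(params.cortical_thickness)
    cortex = np.clip(brain - inner, 0.0, 1.0)
    subcort = np.zeros(geom.shape)
    for ctr in geom.subcortical_centers.values():
        subcort = np.maximum(subcort, geom.sphere(ctr,
                                                  geom.subcortical_radius))
    subcort = np.minimum(subcort, inner)
    vent = np.minimum(geom.ventricles(params), inner)
    lesions = np.minimum(geom.lesions(params, rng), inner)
    csf = np.maximum(vent, lesions)

    img = WM_INTENSITY * inner + GM_INTENSITY * cortex
    img = img * (1.0 - subcort) + SUBCORTICAL_INTENSITY * subcort
    img = img * (1.0 - csf) + CSF_INTENSITY * csf

    labels = np.full(geom.shape, LBL_BACKGROUND, dtype=np.int16)
    in_brain = brain >= 0.5
    labels[in_brain & (inner >= 0.5)] = LBL_WM
    labels[in_brain & (inner < 0.5)] = LBL_CORTEX
    labels[in_brain & (subcort >= 0.5)] = LBL_SUBCORTICAL
    labels[in_brain & (lesions >= 0.5)] = LBL_LESION
    labels[in_brain & (vent >= 0.5)] = LBL_VENTRICLE

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=geom.shape) * in_brain
    return img, labels


def ventricle_soft_volume(age: float, ms_offset: float,
                          grid_shape: Sequence[int] = (32, 32, 32)) -> float:
    """Sum of ventricle occupancy: strictly increasing in effective age."""
    geom = _Geometry(grid_shape)
    params = morphology_params(age, ms_offset)
    vent = np.minimum(geom.ventricles(params),
                      geom.inner(params.cortical_thickness))
    return float(vent.sum())


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

REGION_DEFS = [
    (1, "lateral_ventricle", "L"),
    (2, "lateral_ventricle", "R"),
    (3, "third_ventricle", "midline"),
    (4, "fourth_ventricle", "midline"),
    (5, "subcortical", "L"),
    (6, "subcortical", "R"),
    (7, "cortex", "L"),
    (8, "cortex", "R"),
    (9, "white_matter", "L"),
    (10, "white_matter", "R"),
]


def build_parcellation(grid_shape: Sequence[int]) -> Parcellation:
    """Age-independent region labels covering every brain voxel.

    Ventricle parcels are sized for the maximum effective age, so the
    aging signal always falls inside them; remaining brain voxels are
    cortex (outer ribbon at maximum thickness) or white matter, split
    into hemispheres at the midline.
    """
    geom = _Geometry(grid_shape)
    s = geom.scale
    pmax = morphology_params(MAX_EFFECTIVE_AGE, 0.0)
    p0 = morphology_params(0.0, 0.0)
    brain = geom.brain() >= 0.5
    inner_thick = geom.inner(p0.cortical_thickness) >= 0.5  # thickest cortex
    labels = np.zeros(geom.shape, dtype=np.int16)
    cx = geom.center[0]
    ix = np.indices(geom.shape)[0]
    left = ix < cx

    labels[brain & inner_thick] = 9  # WM, split below
    labels[brain & ~inner_thick] = 7  # cortex, split below
    right_adjust = np.isin(labels, (7, 9)) & ~left
    labels[right_adjust] += 1

    for hemi, ctr in geom.subcortical_centers.items():
        mask = geom.sphere(ctr, geom.subcortical_radius + 0.5) >= 0.5
        labels[brain & mask] = 5 if hemi == "L" else 6

    vmax = pmax.ventricle_radius * s + 1.0
    for hemi, ctr in geom.ventricle_centers.items():
        mask = geom.sphere(ctr, vmax) >= 0.5
        labels[brain & mask] = 1 if hemi == "L" else 2
    labels[brain & (geom.sphere(
        geom.third_center, pmax.third_ventricle_radius * s + 1.0) >= 0.5)] = 3
    labels[brain & (geom.sphere(
        geom.fourth_center,
        pmax.fourth_ventricle_radius * s + 1.0) >= 0.5)] = 4

    regions = [Region(i, n, h) for i, n, h in REGION_DEFS]
    present = set(np.unique(labels).tolist()) - {0}
    regions = [r for r in regions if r.region_id in present]
    return Parcellation(label_grid=labels, regions=regions)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def sample_covariates(record: SubjectRecord, seed: int) -> SubjectRecord:
    """Fill clinical covariates with a documented generative model.

    With ``ea = age + ms_offset`` and rng ~ seeded Generator:

    * ``bpf = clip(0.85 - 0.003 * ea + N(0, 0.008), 0.40, 0.95)``
      (decreasing in effective age),
    * healthy subjects: all MS covariates are 0,
    * MS: ``disease_duration = clip(N(10, 5), 0.5, age - 18)``,
      ``age_at_onset = age - disease_duration``,
      ``lesion_volume = max(0.01, 0.45*off + 0.15*off*N(0,1) + |N(0,0.2)|)``
      (increasing in ms_offset),
      ``edss = clip(round2(0.5 + 0.25*off + 0.05*duration + N(0,1)), 0, 10)``
      in half-point steps (noisily increasing in ms_offset).
    """
    rng = np.random.default_rng(seed)
    ea = record.age + record.ms_offset
    bpf = float(np.clip(0.85 - 0.003 * ea + rng.normal(0.0, 0.008),
                        0.40, 0.95))
    if record.cohort == "healthy":
        return dataclasses.replace(record, bpf=bpf, edss=0.0,
                                   disease_duration=0.0, age_at_onset=0.0,
                                   lesion_volume=0.0)
    off = record.ms_offset
    duration = float(np.clip(rng.normal(10.0, 5.0), 0.5,
                             max(0.5, record.age - 18.0)))
    onset = record.age - duration
    lesion_volume = float(max(0.01, 0.45 * off + 0.15 * off * rng.normal()
                              + abs(rng.normal(0.0, 0.2))))
    edss_raw = 0.5 + 0.25 * off + 0.05 * duration + rng.normal()
    edss = float(np.clip(np.round(edss_raw * 2.0) / 2.0, 0.0, 10.0))
    return dataclasses.replace(record, bpf=bpf, edss=edss,
                               disease_duration=duration, age_at_onset=onset,
                               lesion_volume=lesion_volume)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(cfg: CohortConfig
                    ) -> tuple[list[tuple[ImageVolume, SubjectRecord]],
                               Parcellation]:
    """Generate ``n_healthy + n_ms`` phantoms on a shared grid.

    Ages are uniform over the cohort age range; sexes alternate M/F so
    strata stay balanced. MS offsets are Normal(mean, sd) truncated at
    zero. Bit-identical output for identical config.
    """
    geom = _Geometry(cfg.grid_shape)
    _check_fit(geom)
    root = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_healthy + cfg.n_ms
    children = root.spawn(n_total + 1)
    master = np.random.default_rng(children[0])

    dataset: list[tuple[ImageVolume, SubjectRecord]] = []
    ms_lo, ms_hi = cfg.ms_age_range or cfg.age_range
    for i in range(n_total):
        is_ms = i >= cfg.n_healthy
        rng = np.random.default_rng(children[i + 1])
        if is_ms:
            age = float(master.uniform(ms_lo, ms_hi))
            if cfg.ms_offset_sd == 0:
                offset = float(cfg.ms_offset_mean)
            else:
                offset = -1.0
                while offset < 0:
                    offset = float(master.normal(cfg.ms_offset_mean,
                                                 cfg.ms_offset_sd))
        else:
            age = float(master.uniform(*cfg.age_range))
            offset = 0.0
        sex = "M" if i % 2 == 0 else "F"
        sid = (f"MS{i - cfg.n_healthy + 1:04d}" if is_ms
               else f"HC{i + 1:04d}")
        record = SubjectRecord(subject_id=sid, age=age, sex=sex,
                               cohort="MS" if is_ms else "healthy",
                               ms_offset=offset)
        record = sample_covariates(record, seed=int(rng.integers(2 ** 31)))
        img, _ = render_phantom(age, offset, geom, cfg.noise_sd, rng,
                                sex=sex, sex_effect=cfg.sex_effect)
        vol = ImageVolume(data=img.astype(np.float32), space="template")
        dataset.append((vol, record))
    parcellation = build_parcellation(cfg.grid_shape)
    return dataset, parcellation


def subject_tissue_labels(record: SubjectRecord, cfg: CohortConfig,
                          index: int) -> np.ndarray:
    """Re-render the hard tissue segmentation of cohort subject ``index``
    (same seeds as :func:`generate_cohort`)."""
    geom = _Geometry(cfg.grid_shape)
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_healthy + cfg.n_ms + 1)
    rng = np.random.default_rng(children[index + 1])
    rng.integers(2 ** 31)  # covariate seed draw, keep stream aligned
    _, labels = render_phantom(record.age, record.ms_offset, geom,
                               0.0, rng, sex=record.sex,
                               sex_effect=cfg.sex_effect)
    return labels


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.tsv"
PARCELLATION_NAME = "parcellation.nii.gz"
REGIONS_NAME = "regions.tsv"


def write_dataset(dataset: Sequence[tuple[ImageVolume, SubjectRecord]],
                  parcellation: Parcellation, out_dir: str | Path,
                  force: bool = False) -> Path:
    """Write one NIfTI per subject plus parcellation and TSV manifest.

    Refuses to overwrite an existing manifest unless ``force`` is set.
    Returns the manifest path.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    manifest_path = out_dir / MANIFEST_NAME
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{manifest_path} exists; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol, rec in dataset:
        affine = np.diag(list(vol.spacing) + [1.0])
        fname = f"{rec.subject_id}_T1w.nii.gz"
        nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine),
                 out_dir / fname)
        row = dataclasses.asdict(rec)
        row["filename"] = fname
        rows.append(row)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(parcellation.label_grid.astype(np.int16),
                             affine), out_dir / PARCELLATION_NAME)
    parcellation.region_table().to_csv(out_dir / REGIONS_NAME, sep="\t",
                                       index=False)
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_dataset(in_dir: str | Path
                 ) -> tuple[list[tuple[ImageVolume, SubjectRecord]],
                            Parcellation, pd.DataFrame]:
    """Round-trip loader for :func:`write_dataset` output."""
    import nibabel as nib

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / MANIFEST_NAME, sep="\t")
    dataset = []
    for _, row in manifest.iterrows():
        img = nib.load(in_dir / row["filename"])
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        vol = ImageVolume(data=np.asarray(img.dataobj, dtype=np.float32),
                          spacing=spacing, space="template")
        fields = {f.name: row[f.name] for f in
                  dataclasses.fields(SubjectRecord)}
        fields["qc_excluded"] = bool(fields["qc_excluded"])
        dataset.append((vol, SubjectRecord(**fields)))
    label_img = nib.load(in_dir / PARCELLATION_NAME)
    labels = np.asarray(label_img.dataobj, dtype=np.int16)
    regions_df = pd.read_csv(in_dir / REGIONS_NAME, sep="\t")
    regions = [Region(int(r.region_id), str(r.name), str(r.hemisphere))
               for r in regions_df.itertuples()]
    return dataset, Parcellation(labels, regions), manifest
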