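# brainage

Brain-age-gap (BAG) analysis as a tested, reusable pipeline, exercised
end to end on synthetic brain phantoms:

1. **`brainage.phantom`** — generates cohorts of template-space brain
   phantoms (nested ellipsoids with T1-like contrast, CSF < GM < WM)
   whose morphology encodes a known aging signal: ventricles grow and
   the cortical ribbon thins monotonically with *effective age* =
   chronological age + a ground-truth "MS offset". The MS condition
   additionally seeds focal CSF-intensity white-matter lesions and
   clinical covariates (EDSS, disease duration, lesion volume, BPF)
   with a documented generative model.
2. **`brainage.preprocess`** — zero-mean intensity rescaling over the
   brain mask, population-wide background cropping (bounds frozen on
   the training split), QC-exclusion bookkeeping.
3. **`brainage.model`** — a 3D CNN age regressor:
   `[3x3x3 conv -> batch norm -> 2x2x2 max pool -> ReLU]` blocks
   (default filters 32/64/128/256/256), a `1x1x1 conv` block (64
   filters), global average pooling, dropout 0.5 and a linear output.
   Stratified 75/22.5/2.5 splitting by (age bin x sex), ±5-voxel
   translation augmentation, Adam with weight decay, and
   best-validation-MAE checkpointing. The network and its backward
   passes are implemented directly on numpy (`brainage.nn`), so the
   pipeline trains and differentiates with no deep-learning framework.
4. **`brainage.stats`** — BAG (= predicted − chronological age; positive
   means an older-appearing brain), MAE, Bland–Altman limits of
   agreement, Mann–Whitney U (exact enumeration for n+m ≤ 16, tie- and
   continuity-corrected normal approximation otherwise), Spearman
   correlation (t-approximation; exact permutation for n ≤ 10), partial
   Spearman by rank residualization, Bonferroni correction, and a
   two-group comparison table (medians/IQRs, univariate + partial
   correlations with BAG).
5. **`brainage.saliency`** — SmoothGrad saliency maps (mean absolute
   input gradient over noise-perturbed copies), linear [0, 255]
   mapping, bottom-5% denoising, per-region weighted saliency scores
   (coverage % x min-max-scaled mean intensity), sex-balanced group
   averaging per age band (10M/10F, or 5M/5F for the <30 band),
   binarization, Dice overlap, and per-region group comparison with
   Bonferroni correction.
6. **`brainage.cli` / `brainage.pipeline`** — configuration-driven
   orchestration with seed management and a JSON run manifest.

## CLI

```bash
brainage run --preset tiny --seed 1 --out runs/demo
brainage run --preset tiny --seed 1 --out runs/demo --stages generate,preprocess
brainage train --config my_config.yaml --seed 2 --out runs/custom
```

Available stages: `generate`, `preprocess`, `train`, `predict`,
`stats`, `saliency` (each also exists as its own subcommand). The YAML
config has sections `phantom`, `model`, `train`, `saliency`, `stats`
mirroring the dataclasses in each module; anything not given falls back
to the preset (`tiny` or `paper`). Outputs land under `--out`:

- `dataset/` — one NIfTI per subject, `parcellation.nii.gz`,
  `regions.tsv` (region_id, name, hemisphere), `manifest.tsv` with all
  subject fields (subject_id, age, sex, cohort, ms_offset, edss,
  disease_duration, age_at_onset, lesion_volume, bpf, qc_excluded,
  filename),
- `processed/` — cropped zero-mean volumes, `crop_bounds.json`, split
  manifest,
- `model/` — checkpoint (npz + JSON sidecar), training history TSV,
- `predictions.tsv`, `stats_summary.json`, `group_comparison.tsv`,
- `saliency/` — region scores, per-region group comparison, Dice table,
  group-map membership JSON,
- `run_manifest.json` — config hash, seeds, per-stage summaries.

## Notes on p-values

Spearman p-values use the t approximation (recommended for n ≥ 10); an
exact permutation p is available via `spearman(..., exact=True)` for
n ≤ 10. The exact Mann–Whitney mode enumerates all assignments of the
pooled midranks, handling ties by enumeration. Age-bias correction of
the BAG (over/underestimation at the extremes of the age range) is
deliberately not implemented.
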