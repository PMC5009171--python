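# tractconcord

Toolkit for validating tract localization by probabilistic tractography
against a histology-style reference, exercised end to end on synthetic
phantoms:

- **`phantom`** — builds a ground-truth pair of decussating tubular
  tracts (seed blob → contralateral target blob) with a crossing-fiber
  midline zone, per-voxel fiber populations (orientation, volume
  fraction, Watson dispersion), seed/target/exclusion masks, ROI labels
  (dentate / peduncle / decussation analogs), and a textured intensity
  volume. Also simulates serial sectioning (fine sections, every k-th
  retained, block-face references, ≥6 landmarks per slice) and smooth
  random per-slice deformations with exact stored ground-truth warps.
- **`tractography`** — probabilistic streamline propagation (0.5 mm
  steps, 2000 samples per seed voxel, 0.2 curvature threshold ≈ 78°
  maximum turn by default), bidirectional from jittered seed points,
  with target/exclusion semantics and normalized connectivity maps.
- **`reconstruction`** — landmark-based 2D affine registration of each
  slice to its block face, stacking, and iterative multivariate
  demons-style nonlinear refinement driven by the two neighbouring
  slices plus the matching reference slice (the reference anchoring is
  what prevents curved structures from straightening — the "banana
  problem").
- **`overlap`** — voxel-wise concordance: confusion counts, TPR/FPR,
  Dice similarity (SI) curves over a threshold sweep, trapezoidal AUC,
  optimal-threshold selection, false-negative dilation profiles, and
  rater averaging.
- **`pipeline` / `io` / `cli`** — one-command reproducible runs with a
  manifest, NIfTI/TIFF/CSV/JSON/YAML/SVG artifacts, and deterministic
  named-substream seeding.

## CLI

```sh
# full pipeline into ./out
tractconcord run --seed 11 --out out

# or stage by stage (stages share the output directory)
tractconcord phantom  --seed 11 --out out
tractconcord track    --seed 11 --out out --samples 2000 --curvature 0.2
tractconcord section  --seed 11 --out out
tractconcord recon    --seed 11 --out out --iters 20 --w-ref 0.5
tractconcord evaluate --seed 11 --out out --thresholds 100
```

All settings can also be given as a YAML file via `--config run.yaml`
(see `tractconcord.pipeline.RunConfig`). Two runs with the same config
produce byte-identical reports.

## Conventions

World coordinates are in mm; voxel/pixel indices are 0-based with
centers at `(i + 0.5) × spacing`; the sectioning axis is axis 2; the
midline (left/right) axis is axis 0. Displacement fields store the
pull-back map `T` with `deformed(x) = reference(T(x))`; landmark rows
are `(x_src, y_src, x_dst, y_dst)` with sources in the deformed slice
and destinations in its block face.
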