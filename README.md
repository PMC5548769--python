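# ossimetry

A synthetic micro-CT bone-morphometry pipeline for small ossified bodies
("ossicles"), built so that every stage of a propagation-based phase-contrast
tomography study can be verified without real scan data:

- **phantom** — voxelized ossicle generators (sphere, pyramid, crescent
  "lunula") with analytically known ground truth, optional sealed internal
  porosity, and a stochastic surface-erosion operator that programs a target
  BV/TV decrease while preserving connectivity.
- **forward_model** — parallel-beam Beer–Lambert projection (mass-conserving
  splat projector), propagation edge enhancement (exact algebraic inverse of
  the retrieval filter), Poisson counting noise, and offset-detector
  (extended field of view) splitting of 360° scans.
- **recon** — flat/dark correction, 360° stitching, single-distance phase
  retrieval (`H = 1 / (1 + λ·D·(δ/β)/(4π)·(u²+v²))` on a mirror-padded
  Fourier grid), and filtered back projection (Ram-Lak, linear-interpolation
  backprojection, optional cosine apodization).
- **segmentation** — 3D median filter, Otsu auto-threshold (lowest maximizing
  bin edge), 6-connected labelling, and overlap-based volume-of-interest
  matching against reference labels.
- **morphometry** — per-label BV (voxel count), BS (marching-cubes
  triangulation with one-voxel anti-aliasing), TV (hole filling with
  26-connected background), and the BV/TV, BS/BV, BS/TV ratios in mm units.
- **stats** — unpaired Welch two-sample t-test (Welch–Satterthwaite df,
  two-sided p) and a cohort study runner that pushes control/arthritis
  phantom pairs through the full chain and reports group means ± SD, percent
  change and raw p per parameter and ossicle class.

Default acquisition parameters model a synchrotron protocol: 2 µm detector
pixels, 15 cm propagation distance, 25 keV, δ/β = 300, 2400 projections over
360°.

## CLI

One entry point with stage subcommands (`--seed` is global):

```sh
ossimetry --seed 1 phantom make --shape pyramid --cavity-fraction 0.25 --output p.tiff
ossimetry --seed 1 phantom erode --input p.tiff --target-drop 0.11 --output e.tiff
ossimetry --seed 1 acquire --phantom e.tiff --config cfg.yaml --output proj.tiff
ossimetry recon --projections proj.tiff --delta-beta 300 --output vol.tiff
ossimetry segment --input vol.tiff --output labels.tiff
ossimetry morpho --labels labels.tiff --output morpho.csv
ossimetry --seed 1 study run --config study.yaml --out study_out/
```

Volumes and projections are multi-page TIFF with YAML sidecars; tables are
CSV; configuration is validated YAML (unknown keys rejected, empty file =
protocol defaults).

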