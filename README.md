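# structcov

Regional brain morphometry and structural covariance network analysis for
atlas-segmented volumes, with a ground-truthed synthetic cohort generator.

Given a subjects × regions table of absolute volumes (mm³), a design table
(sex ∈ {M, F}, group ∈ {treated, control}) and an atlas hierarchy mapping
each region to an anatomical area and one of six covariance clusters, the
package provides:

- **volumes_io** — validated readers/writers for volume, design, hierarchy
  and behavior tables; regional volume extraction from NIfTI label images
  by voxel counting; total brain volume.
- **regional_stats** — total-brain-volume ANOVA with Tukey pairwise tests;
  per-region Welch comparisons of absolute and relative volumes with
  BH or adaptive two-stage step-up FDR and Cohen's d; area-level effect
  averaging; sexual-dimorphism-loss testing.
- **structural_covariance** — per-group Pearson correlation matrices over
  clustered regions; cluster-pair block extraction (Cartesian-product or
  unique-pair conventions); four-group Kruskal–Wallis comparison with
  two-stage FDR, a large-effect filter (rank η² > 0.14, strict) and
  post-hoc effect classification (treatment / sex-within-treated).
- **brain_behavior** — sex- and group-stratified Pearson correlations of
  regional volume against behavioral measures (uncorrected by design,
  pairwise-complete missing handling) with UPGMA/Euclidean heatmap
  ordering.
- **synthetic_data** — multivariate-normal cohorts with block-structured
  correlation (PD-repaired by eigenvalue clipping), cell-specific mean
  shifts and correlation deltas, behavior couplings, and a
  `SyntheticTruth` record for recovery testing. `paper_scenario()` is a
  preset with 159 regions in clusters of 19/13/24/40/9/51, cells of
  11/11/12/11 subjects, female-only enlargement, control-only dimorphism,
  hindbrain desynchronization and sex-opposed behavior couplings.
- **cli** — `structcov` command with `extract`, `regional`, `covariance`,
  `behavior`, `simulate`, `full` and `report` subcommands; every output
  directory carries a `manifest.json`; CSV columns are documented in
  `src/structcov/data/column_schema.json`.

## CLI quick start

```sh
# simulate a preset cohort with ground truth
structcov simulate --preset paper --seed 7 --out cohort/

# run every analysis on it and render a summary
structcov full --volumes cohort/volumes.csv --design cohort/design.csv \
    --behavior cohort/behavior.csv --hierarchy cohort/hierarchy.tsv --out results/

# or do both in one step
structcov full --seed 7 --out results/

# regional volumes from a label image (0.040 mm isotropic, for example)
structcov extract --labels labels.nii --label-map map.json --out extracted/
```

Exit codes: 0 success, 1 statistical degeneracy, 2 usage/validation error.

## Conventions

- Cohen's d is signed treated − control (male − female in dimorphism
  tests); pooled-SD definition.
- Relative volume is region / subject TBV; TBV defaults to the sum of all
  atlas regions unless an explicit `tbv` column is supplied.
- Intra-cluster block vectors include the diagonal and both symmetric
  copies under the default (`paper`) convention — length k² for a cluster
  of k regions; pass `--convention unique` for distinct pairs only. The
  entries are not independent observations and a warning says so.
- No resampling is applied to label images; volumes are voxel count ×
  voxel volume.
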