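# modscape

Multi-omic ligand-perturbation analysis pipeline with a fully synthetic,
planted-ground-truth test bench. Given feature×sample matrices from several
assay modalities (count, log-intensity and z-score scales) over a
ligand × time × replicate design, plus single-cell imaging tables and lineage
tracks, it provides:

- **`synthetic_data`** — generators for every input the pipeline consumes:
  the sample design, per-assay matrices with planted co-regulated modules and
  planted covariate variance fractions, spatial cell tables (CSR / Thomas /
  grid patterns with bimodal DAPI/EdU mixtures), branching lineage tracks, and
  module-coupled well phenotypes. All generators are pure functions of
  (spec, seed) via named substreams.
- **`differential`** — CTRL_0-relative log2 fold changes (median over
  replicates), per-feature Welch tests (optional pooled-variance shrinkage)
  with Benjamini–Hochberg correction per assay×condition, signature selection
  (q < 0.01, |log2FC| ≥ 1.5), per-assay module-feature selection rules,
  Unique/Shared set analysis, cross-assay concordance counts and the
  matched-vs-mismatched correlation test.
- **`scaling`** — per-feature Gaussianizing transform (signed Box-Cox /
  asinh families selected by profile likelihood over fixed parameter grids),
  z-scaling, and stacking of assays into one integrated matrix.
- **`variance_attribution`** — winsorize → median-center within replicate →
  correlation-scale PCA → 0.7 eigenvalue cutoff → per-covariate PC assignment
  (stratified-permutation silhouette test for categorical covariates, lasso
  for continuous) → weighted variance sums with Venn-region overlaps.
- **`module_detection`** — gap statistic with firstSEmax and
  structure-preserving permutation references, seeded PAM (k-medoids) with a
  fast vectorized swap phase, two-level consensus ensembles (100 inner × 25
  outer) under a hard least-squares membership-matrix consensus, co-assignment
  matrices, and correlated-cluster merging.
- **`phenotype_metrics`** — neighbor counts within a radius (border-corrected),
  k-NN distances normalized by the exact Poisson CSR expectation, flat-kernel
  mean-shift cluster sizes, Forgy 2-means DAPI cell-cycle gating, EdU
  fractions, lineage back-tracing migration distances, and the
  Kruskal–Wallis / Wilcoxon (BH) and ANOVA / Tukey HSD comparisons.
- **`association`** — module expression scores (mean of member features) and
  OLS module–phenotype association with BH correction over the full grid.
- **`pipeline.run_pipeline`** — end-to-end driver
  (simulate → diff → select → scale → gap → consensus modules → merge →
  scores → associate) with the ground truth carried along for evaluation.

## CLI

The `modscape` entry point exposes one subcommand per stage:

```sh
modscape simulate --config cfg.yaml --out data/ --seed 1
modscape diff     --in data/ --out diff.tsv
modscape signatures --diff diff.tsv --q 0.01 --lfc 1.5 --out sig.tsv
modscape setanalysis --signatures sig.tsv --out sets.tsv
modscape scale    --in data/ --out scaled.tsv
modscape modules  --in scaled.tsv --kmax 25 --b 100 --inner 100 --outer 25 \
                  --merge-r 0.85 --seed 1 --out modules.tsv
modscape mavric   --in data/RPPA.tsv --meta data/sample_meta.tsv \
                  --covariates ligand,time,replicate --out attribution.json
modscape phenotype --cells data/cells.csv --tracks data/tracks.csv \
                  --field 2000,2000 --out phenotypes.tsv
modscape associate --scores scores.tsv --phenotypes phenotypes.tsv --out assoc.tsv
```

All inputs and outputs are plain-text TSV/CSV/JSON. The simulate config is a
YAML file overriding `DesignSpec` / `ModuleSpec` / cell / track / coupling
defaults (see `modscape/cli.py`).

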