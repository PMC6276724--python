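# brainclass

A tested, reusable pipeline for case-control neuroanatomic classification
studies on regional brain-feature tables. The package covers the full
analysis chain on synthetic data:

- **simulate** — four-cell (diagnosis x sex) cohorts with age, site, and
  head-size (TICV) covariates; subjects x (region, measure) feature tables
  (5 measures per region: thickness, area, volume, curvature, connectivity
  density) under a configurable linear-additive effect model; toy sphere
  meshes and streamline sets for the connectivity stage.
- **connectivity** — turning-angle streamline filtering, per-streamline mean
  FA, endpoint snapping into a vertex connectivity matrix, geodesic
  neighborhoods, per-vertex connectivity density (CD), geodesic Gaussian
  surface smoothing, and area-weighted parcel aggregation.
- **preprocess** — TICV normalization, OLS residualization of age/site,
  standardization (n-1 convention), and PCA with a cumulative
  explained-variance retention rule (default 95%).
- **svm** — a from-scratch soft-margin kernel SVM trained by sequential
  minimal optimization (maximal-violating-pair working sets), per-class box
  constraints N/(2 N_class) for unbalanced designs, KKT verification, and a
  one-vs-one multiclass ensemble with majority voting.
- **evaluation** — repeated 10-fold cross-validation, modal
  prediction-scenario selection, and confusion matrix/tensor summaries with
  sensitivity/specificity and half-up-rounded cohort percentages.
- **stats** — Welch's t-test, four-group ANOVA (one-way or Welch),
  Benjamini-Hochberg FDR, 2x2 chi-square, and the combined per-feature
  screen.
- **mds** — classical (Torgerson) multidimensional scaling with 3-D
  coordinate export.
- **pipeline** — end-to-end orchestration with YAML configs and
  byte-reproducible report bundles.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked-example
confusion arithmetic, structural constants, SVM-vs-QP oracle equivalence,
statistical calibration, parameter recovery, geometry properties).

## Command line

The `brainclass` executable exposes each stage:

```sh
brainclass simulate --n-per-cell 55 55 43 40 --n-sites 4 --n-regions 165 \
    --seed 1 --outdir out/sim
brainclass classify --features out/sim/features.tsv --cohort out/sim/cohort.tsv \
    --mode two --reps 50 --outdir out/cv
brainclass posthoc --features out/sim/features.tsv --cohort out/sim/cohort.tsv \
    --out out/posthoc.tsv
brainclass mds --features out/sim/features.tsv --cohort out/sim/cohort.tsv \
    --outdir out/mds
brainclass toy-brain --n-vertices 642 --n-streamlines 50 --outdir out/geo
brainclass connectivity --mesh out/geo/mesh.obj \
    --streamlines out/geo/streamlines.tsv \
    --parcellation out/geo/parcellation.tsv --outdir out/conn
brainclass run-study --config config.yaml --outdir out/study
```

All tables are TSV with one-line headers; meshes are Wavefront OBJ;
streamlines use a long-format TSV (streamline_id, point_index, x, y, z, fa).

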