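# dynlat

Dynamic hemispheric laterality analysis for resting-state fMRI, with a
synthetic cohort generator for end-to-end testing.

The pipeline computes, for every sliding window, each ROI's **dynamic
laterality index** — the difference of Fisher-z-transformed Pearson
correlations between the ROI's signal and the left vs right hemisphere
global signals — then:

- summarises laterality per subject as **MLI** (mean over a window set)
  and **LF** (standard deviation over a window set), at node,
  subnetwork-by-hemisphere and hemisphere levels;
- discovers recurring **laterality states** by three-stage temporal
  clustering: per-subject spherical (cosine) k-means, pooling of the
  per-subject centroids into a cosine-similarity graph, and a
  multi-resolution community-detection sweep (uniform self-loops of
  strength r ∈ {0.1, …, 1.5}, modularity maximisation, most persistent
  community count selects k), followed by final k-means and
  nearest-centroid window assignment;
- runs the statistics layer: two-sample pooled-variance t-tests with
  Benjamini–Hochberg FDR control within each comparison family, Spearman
  correlations against clinical severity scores (BPRS/SANS/YMRS-like),
  chi-square and t-test demographics tables.

Because the study cohort is not redistributable, the `synthetic` module
generates cohorts with planted laterality states (latent hemisphere
drivers with state-switching loadings), planted group effects in a
designated subnetwork, and clinical scores correlated with each
patient's realised effect — so every downstream stage is testable and
calibratable offline.

## Test

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py` with one test per
acceptance criterion (window-count identity, printed statistics,
oracle equivalences including exhaustive-partition modularity checks,
planted-state recovery, type-I/power calibration, antisymmetry).
One acceptance test (`test_criterion_3_spearman_p_consistency`) is
expected to fail: it asserts a published p-value that is inconsistent
with its own rounded correlation coefficient (0.320 at n = 48 gives
p = 0.0266 → 0.027, not 0.026); the honest value is asserted in the
regular suite.

## CLI

```bash
# generate a synthetic cohort (TSV matrices + atlas + manifest + scores)
dynlat simulate --config cfg.yaml --out cohort/

# full run: simulate (or load) -> laterality -> states -> stats
dynlat run --config cfg.yaml --out run/ --seed 1

# analyse an existing TSV cohort directory
dynlat analyse --in cohort/ --config cfg.yaml --out run/

dynlat info --in cohort/
```

The YAML config mirrors `dynlat.pipeline.RunConfig`; all defaults follow
the reference protocol (50-TR windows, step 1, resolution grid
0.1–1.5 step 0.1, α = 0.05, k1 = 5). A run directory contains the
cohort export, per-subject laterality TSVs, state centroids/assignments
and sweep record, per-state laterality correlation matrices, the tidy
metric table, group-comparison and clinical-correlation CSVs, the
demographics table, and a provenance JSON. Identical config + seed
reproduce byte-identical numeric outputs.

Input modes: ROI-by-time TSV matrices (header = ROI ids) with an atlas
TSV (`roi_id, name, hemisphere, subnetwork`), or 4D NIfTI plus an
integer-labelled atlas volume via `dynlat.io.extract_roi_means`.
In-scope preprocessing (initial-volume discard, linear detrend +
nuisance regression, 0.01–0.1 Hz zero-phase band-pass) is available for
raw matrix input; scanner-level preprocessing is out of scope.

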