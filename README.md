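# towheesong

A fully synthetic, ground-truth-driven re-implementation of a two-species
birdsong divergence analysis. The package generates towhee-like songs (short
introductory notes plus a fast trill) along a longitudinal cline with a zone
of species co-occurrence, then runs the complete downstream pipeline:

- **`towheesong.synth`** — song synthesis with known syllable-level ground
  truth, geographic/metadata sampling, and two-population nucleotide
  alignment generation.
- **`towheesong.spectro`** — peak-normalized dB spectrograms, quantile-based
  syllable segmentation (sound/silence with minimum-duration rules),
  connected-component noise filtering, and 224×224 RGB spectrogram image
  export.
- **`towheesong.features`** — per-syllable duration/frequency measures,
  percent-overlap syllable typing, the 16 song features, and the natural-log
  transform.
- **`towheesong.geo`** — recording/sighting deduplication, breeding-season
  filtering (April–August), per-longitude species proportions, overlap-zone
  detection, hybrid-rate estimates, and WGS84 geodesic distance matrices.
- **`towheesong.stats`** — per-feature log-link GLMs, PCA, LDA (including the
  2-D linear partition on PC/UMAP coordinates), UMAP wrapper, Procrustes
  superimposition with a permutation test, and Spearman Mantel tests.
- **`towheesong.classify`** — balanced 75/25 and region-stratified splits,
  pluggable classifier backends (random forest, gradient boosting, MLP, LDA,
  and an optional torch CNN on spectrogram images), permutation-null
  significance, per-tree vote-confidence maps, and multi-seed confidence
  intervals.
- **`towheesong.popgen`** — aligned-FASTA I/O, SNP matrices, pairwise sequence
  distances, and ΦST via two-level AMOVA.
- **`towheesong.cli`** — YAML-configured orchestration of all stages with
  deterministic per-stage seeding.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact worked
arithmetic, 200-song segmentation recovery, per-song feature identities,
metric oracles against exhaustive enumeration, permutation-test null
calibration, parameter recovery against an analytic Bayes rate, the
directional in-zone/out-of-zone accuracy check, and AMOVA edge cases.

## CLI

```sh
towheesong run-all --seed 1 --out-dir results_run
towheesong synth --seed 1 --out-dir data_run      # dataset only
towheesong validate --config my_config.yaml
```

A YAML config can override any default (see
`towheesong.cli.DEFAULT_CONFIG`); unknown keys and out-of-range values are
rejected before any stage runs. A full run writes a WAV/CSV/JSON dataset,
a per-song feature table, and one `results.json` bundle; a fixed master
seed yields byte-identical bundles.

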