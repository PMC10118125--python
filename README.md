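# sporesol

Analysis pipeline for sedimentation-proteomics protein solubility
trajectories during spore germination, plus the accompanying biophysical
quantifications. The package covers:

- **quantio** — strict readers/writers for fractionation quant tables,
  phosphopeptide tables, wide trajectory matrices, annotation maps and
  interaction edge lists (CSV/TSV in, CSV + JSON manifest out).
- **pindex** — detection filters (sequence coverage ≥ 10%, ≥ 2 peptides,
  supernatant+pellet > 0 in every replicate at every time point) and the
  pellet-share solubility statistic `pellet / (supernatant + pellet)`,
  replicate means and pairwise Pearson correlations, and phosphopeptide
  relative abundance.
- **solclust** — complete-linkage hierarchical clustering of mean
  trajectories cut to five clusters, rule-based labeling of the five
  canonical solubility classes, changing-set extraction, property PCA
  and an interaction-pair scan.
- **enrich** — exact upper-tail hypergeometric over-representation of
  annotation terms per cluster against the detected background, with
  Benjamini–Hochberg q-values.
- **biophys** — particle detection, trajectory linking, per-particle and
  ensemble mean squared displacement, diffusion-coefficient fitting
  (MSD = 4Dτ), four-parameter-logistic pH calibration and inversion,
  growth-curve AUC heat-resistance scoring, fluorescence heterogeneity
  (CV) and trehalose arithmetic.
- **synthetic** — deterministic generators for every pipeline input with
  planted ground truth (five trajectory-class archetypes, 2-D Brownian
  tracks, sigmoid calibration data, logistic growth curves, cell
  images), so the whole pipeline is testable offline.
- **cli** — the `spore-solubilome` entry point.

## Run the pipeline

```sh
# write every default setting to a file you can edit
spore-solubilome config init --out config.yaml

# full simulated end-to-end run (895-protein default preset)
spore-solubilome all --config config.yaml --set out_dir=results/run --set seed=1

# or stage by stage
spore-solubilome simulate --config config.yaml
spore-solubilome pindex   --config config.yaml
spore-solubilome cluster  --config config.yaml
spore-solubilome enrich   --config config.yaml
spore-solubilome msd      --config config.yaml
spore-solubilome ph       --config config.yaml
spore-solubilome growth   --config config.yaml
```

Each run writes its output tables, a `run_manifest.json` (row counts and
SHA-256 checksums), a `log.jsonl` event log and the resolved
configuration into `out_dir`. To run on real data instead of the
simulator, point the `input:` block of the config at your files and use
the `columns:` block to map your column names onto the canonical schema.
Exit codes: 0 success, 1 runtime error (e.g. missing upstream file),
2 configuration error.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (one test per
criterion). The deposited-trajectory benchmark is skipped unless you
export the published supplementary trajectory table to
`data/s3_pindex_table.csv` (wide CSV: protein id column first, one
column per time point).

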