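# hemibrain

Hemispheric network analysis of parcellated resting-state functional
connectivity: mirror-symmetric community detection across hemispheres,
inter-hemispheric segregation and homotopic integration statistics,
intra-hemispheric integration via participation coefficients, and
covariate-adjusted age associations — together with a synthetic cohort
generator that plants known aging effects for end-to-end validation.

## What it computes

Given per-subject time series on a mirror-paired parcellation (equal L/R
region counts, homotopic pairs aligned):

1. **Screening** — subjects excluded by mean framewise displacement
   (Power-style FD, rotations scaled to a 50 mm radius; default
   threshold 0.2 mm); homotopic region *pairs* excluded when their
   subject-averaged SNR (mean/sd of the time series) falls more than
   2 sd from the across-region mean.
2. **Connectivity** — Pearson correlation over time, Fisher z-transform,
   then either absolute thresholding (default: keep z strictly above 0.2)
   or proportional thresholding to a target edge density.
3. **Communities** — weighted Louvain modularity maximisation (own
   two-phase implementation), 150 runs per subject and hemisphere into an
   agreement matrix; subject agreements averaged per hemisphere, the two
   hemispheric matrices fused (pair-aligned mean), and consensus
   clustering (repeated Louvain on the tau-thresholded agreement matrix
   until all runs coincide) yields one mirror-symmetric group partition.
   Re-run per age stratum (19–40, 41–60, 61–80) for community-flow
   contingency tables (greedy maximum-Jaccard label matching).
4. **Metrics** per (network, hemisphere) —
   * segregation = (ΣZ_within − ΣZ_homotopic) / ΣZ_within on the
     unthresholded z matrix,
   * inter-hemispheric integration = ΣZ_homotopic,
   * intra-hemispheric integration = mean weighted participation
     coefficient on the thresholded within-hemisphere subgraph,
   * plus the summed z to the entire contralateral hemisphere.
5. **Statistics** — partial Pearson correlation of each metric with age
   controlling sex and mean FD; Bonferroni correction within the
   segregation and inter-integration families, Benjamini–Hochberg FDR for
   intra-integration.

## CLI

Every stage is a subcommand of `hemibrain`; a single YAML config drives
the whole run and is echoed into the output directory.

```bash
hemibrain run --config examples/synthetic.yaml --out results/run1
hemibrain simulate --config examples/synthetic.yaml --out data/sim
hemibrain report --out results/run1
```

Minimal config:

```yaml
seed: 7
simulate:                 # or: data: {dir: path/with/regions.csv,covariates.csv,timeseries/}
  n_subjects: 60
  networks: {SMN: 5, VN: 5, FPN: 5, DMN: 5}
  t_points: 230
  within_network_r: 0.5
  between_network_r: 0.1
  homotopic_r0: 0.5
  homotopic_age_slope: {FPN: -0.004}
screening: {fd_max: 0.2, snr_k: 2.0}
threshold: {method: absolute, value: 0.2}
community: {gamma: 1.0, n_runs_subject: 150, n_runs_consensus: 100, tau: 0.5}
```

Outputs: `partition.json` (+ one per age stratum), `metrics.csv` (one row
per subject × network × hemisphere), `associations.csv`, `flow/` tables,
SNR/FD exclusion logs, `manifest.json` with config hash and output file
hashes. Identical config + seed ⇒ byte-identical result files.

Real data are consumed as already-parcellated time series (CSV, one
column per region, header of region ids); `hemibrain.io_core.
extract_parcel_timeseries` can average a 4-D NIfTI over an integer atlas
on an identical voxel grid. No voxel-level preprocessing is performed.

## Layout

```
src/hemibrain/
  io_core.py         domain types (region table, matrices, partitions, results) + I/O
  connectivity.py    FD/SNR screening, Fisher-z matrices, thresholding
  community.py       Louvain, agreement/consensus, symmetric group partition, flows
  metrics.py         segregation / integration statistics, participation coefficients
  stats.py           partial correlations, multiple-comparison control, age strata
  synthetic_data.py  block-covariance cohort simulator with planted age effects
  cli.py             pipeline orchestration, manifest, click commands
```
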