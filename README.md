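# petconn

Region-of-interest functional-connectivity analysis for PET rCBF volumes,
bundled with a synthetic-cohort generator so the whole pipeline can be
exercised, calibrated, and validated without any real imaging data.

The pipeline stages are:

1. **synthetic** (`petconn.synthetic`) — generate region masks (spheres or
   boxes in mm coordinates), per-scan 3D volumes with planted inter-region
   correlation structure, a global (whole-brain) signal, voxel noise and
   optional Gaussian smoothness, plus a scan manifest and a clinical score
   table with a planted connectivity→response slope. Every injected latent
   is recorded as ground truth.
2. **roi_signals** (`petconn.roi_signals`) — Gaussian smoothing, grouping of
   scans into 4D stacks of analysis units (replicates averaged voxelwise),
   and extraction of the first eigenvariate per region plus a whole-brain
   covariate (mean-centered SVD, unit variance, sign aligned to the mask
   mean signal).
3. **connectivity** (`petconn.connectivity`) — partial correlations between
   region eigenvariates controlling for the whole-brain covariate, Fisher
   r-to-z, and per-edge significance via `t = r*sqrt(df/(1-r^2))` with
   `df = n - 3`.
4. **comparison** (`petconn.comparison`) — directional Fisher z-difference
   tests between sessions (`(z_B - z_A)/sqrt(1/(n_A-3) + 1/(n_B-3))`),
   Benjamini–Hochberg step-up adjustment over the edge family, and Pearson
   association between treatment response and per-participant edge
   connectivity surrogates.
5. **maps** (`petconn.maps`) — voxelwise paired-t contrasts between sessions
   with cluster-extent inference by sign-flip permutation (6-connected
   clusters, max-extent null, step-up adjustment across observed clusters).
6. **pipeline / cli** — end-to-end orchestration with a single seed,
   deterministic outputs, a JSON summary and a checksum manifest.

## CLI

All verbs take a YAML run config (`-c config.yaml`):

```bash
petconn all -c config.yaml         # every stage end to end
petconn simulate -c config.yaml    # just the synthetic cohort
petconn extract -c config.yaml     # eigenvariate tables
petconn connect -c config.yaml     # per-session edge tables
petconn compare -c config.yaml     # between-session z tests + adjustment
petconn map -c config.yaml         # voxelwise cluster inference
petconn associate -c config.yaml   # response association
```

A minimal config:

```yaml
out_dir: runs/demo
seed: 1
synthetic:
  n_participants: 12
  sessions: [baseline, week1, week6]
  conditions: [rest, SMC, DEC]
n_permutations: 500
```

Outputs land under `out_dir`: `eigenvariates_*.tsv`, per-session
`connectivity_*_combined.tsv` matrix tables, a long-format `edges.tsv`,
`comparisons.tsv`, `clusters_*.tsv` plus `tmap_*.nii.gz`,
`association.tsv`, `summary.json` and `checksums.tsv`. Exit code 2 marks a
config error, 1 a data/stage error.

## Notes on conventions

- The eigenvariate is computed on column-mean-centered data, scaled to unit
  population variance, and sign-fixed against the mask mean signal, making
  it deterministic and scale-invariant.
- Replicate scans of a condition are averaged voxelwise before extraction
  (`use_replicates: first` keeps the first instead).
- The "combined" condition stacks the per-condition analysis units of a
  session (n adds across conditions) and gets its own extraction.
- Cluster inference uses face (6-) connectivity and a default forming
  threshold of voxelwise two-sided p < 0.001; with fewer pairs than
  `log2(n_permutations)` the sign-flip null is enumerated exhaustively.
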