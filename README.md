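# intpipe

Intrinsic neural timescale (INT) analysis for resting-state fMRI, built as a
tested, config-driven pipeline with a synthetic-cohort generator in place of
real scanner data.

The INT index of a voxel is the sum of its leading positive sample
autocorrelation values (scanning from lag 1 until the ACF first turns
negative), multiplied by the repetition time. The pipeline maps this index
voxelwise, discovers case–control clusters on a discovery dataset, freezes
them as ROIs, and runs ROI-level inference (Welch t, Hedges g, Bonferroni,
correlations, additive-model main effects) on replication datasets, before
and after a two-phase greedy framewise-displacement (FD) group-matching
step.

## Modules

| Module | Purpose |
| --- | --- |
| `intpipe.timescale` | sample ACF, scalar and voxelwise INT estimation |
| `intpipe.mapping` | voxelwise two-sample t-maps, cluster extraction (6/18/26-connectivity, BH-FDR at peaks), ROI means |
| `intpipe.motion` | Power-convention FD from 6-parameter motion traces; greedy two-phase FD group matching |
| `intpipe.inference` | Welch t (raw or summary inputs), Hedges g, Bonferroni, Pearson r, Type II main effects, Yates χ² |
| `intpipe.synth` | seeded AR(1) synthetic cohorts with planted timescale effects, FD shifts and symptom coupling |
| `intpipe.pipeline` | YAML-driven orchestration of the full discovery → replication design |

## CLI

```sh
# full study from a config
intpipe run config.yaml

# generate a synthetic cohort to disk
intpipe synth --spec cohort.yaml --out cohort/ --seed 7

# one INT map
intpipe int-map --bold sub-01_bold.nii.gz --mask mask.nii.gz \
    --tr 2.0 --sessions 321,321 --out sub-01_int.nii.gz

# FD matching on a mean-FD table
intpipe fd-match --fd fd.tsv --out match.json
```

A minimal pipeline config:

```yaml
seed: 7
output_dir: out
analysis: {p_thresh: 0.001, connectivity: 18, min_cluster_size: 5, min_group: 10}
datasets:
  - name: discovery
    role: discovery
    tr: 2.0
    synthetic:
      n_per_group: 16
      grid_shape: [18, 18, 18]
      n_frames: 240
      planted_regions:
        - {name: r1, center: [4, 4, 4], size: [3, 3, 3],
           phi_control: 0.6, phi_patient: 0.3}
  - name: replication
    role: replication
    tr: 2.0
    manifest: cohort/manifest.json
```

Real datasets are consumed through the same manifest format the synthetic
writer produces: per-subject 4-D NIfTI volumes, a 3-D mask NIfTI, and a
participants TSV (`subject_id`, `group` ∈ {HC, SZ}, `sex`, `age`,
`mean_fd`, `cpz`, symptom columns).

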