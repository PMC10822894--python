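# decflow

Dynamic effective-connectivity analysis of multichannel component time
courses, driven end-to-end by a synthetic state-switching MVAR cohort
generator so every stage is testable without external data.

Pipeline stages:

1. **synthdata** — hidden-Markov regime-switching VAR cohort simulator with
   known ground truth (coupling matrices, state sequences, group effects) and
   a matching synthetic clinical table (HbA1c, MoCA, DBP, education years).
2. **groupica** — optional desk-scale temporal-concatenation group ICA
   (PCA reduction, infomax unmixing, back-reconstruction, rule-based
   component selection). The pipeline bypasses this stage when component
   time courses are supplied directly.
3. **dynec** — rectangular sliding-window segmentation (default width 18,
   step 2, strict `start + width < T` convention) and per-window MVAR
   influence estimation: signed lag coefficients (`coef`, default) or
   frequency-averaged partial directed coherence (`pdc`); whole-scan static
   EC too.
4. **states** — k-means decomposition of the pooled windowed matrices
   (off-diagonal entries, L2 default with an L1 option) into recurring
   states, renumbered by descending occupancy.
5. **netmetrics** — per-component in-/out-/net-weighted causal-flow degrees
   and per-subject temporal properties: fractional windows (F), mean dwell
   time (MDT, in windows), number of transitions (NT).
6. **inference** — edgewise Welch tests with BH-FDR, NBS-style permutation
   component inference, Spearman clinical associations, and ICC(2,1)
   reliability of temporal properties across window settings.
7. **cli_io** — strict YAML configuration, TSV/JSON/npz I/O, and a
   one-command reproducible runner.

## CLI

```sh
# full pipeline with defaults (76 simulated subjects, 170 time points,
# 12 components, w=18/s=2, k=2):
decflow run -o out

# or stage by stage:
decflow simulate -o cohort
decflow dynec -i cohort -o stacks --width 18 --step 2
decflow states -i stacks -o partition -k 2
decflow metrics --stacks stacks --partition partition -o metrics.tsv
decflow stats --metrics metrics.tsv --clinical cohort/clinical.tsv -o assoc.tsv
```

`decflow run -c config.yaml` accepts a YAML file mirroring
`decflow.config.PipelineConfig`; unknown keys are rejected. Every run
directory is named by the config hash and seed, and two runs with the same
config and seed produce byte-identical reports.

Python API: see `decflow.simulate_cohort`, `decflow.windowed_ec`,
`decflow.cluster_states`, `decflow.cohort_metrics_table`, and the
`decflow.inference` module.

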