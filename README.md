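# quiescreen

Integrative multi-omics screening toolkit for two-group tumor cohorts.
It implements the analysis chain used to show that a tumor type can be
genetically quiescent yet epigenetically silence a driver gene:

- **cnv** — recursive arc-based segmentation of marker-level log2-ratio
  tracks with permutation testing, the ≥8-marker / |log2| > 0.5 segment
  filter, and per-sample quiescence summaries.
- **variants** — somatic filter cascade (somatic score ≥ −10, somatic rank
  ≥ 0.1, FET score ≥ 13), RNA-seq expression verification (coverage ≥ 10,
  VAF ≥ 0.2), germline candidate triage with the COSMIC rescue clause, an
  exact binomial recurrence test, and fusion-caller consensus.
- **expression** — moderated two-group d statistic with permutation
  q-values, fold changes, target-gene correlation screening (|PCC| ≥ 0.5),
  weighted running-sum gene-set enrichment with phenotype permutation, and
  average-linkage Pearson clustering with Newick export.
- **methylation** — probe-to-gene mapping (gene body ± 10 kb), probeset
  collapsing by highest mean expression, per-pair regression of expression
  on β with BH adjustment, candidate-gene selection (≥ 5 significant probes
  with mean β > 0.75 or < 0.25 and SD < 0.25), and bisulfite peak-ratio
  methylation calls (≤ 0.20 / ≤ 0.80 / > 0.80 classes).
- **qpcr** — comparative-Ct relative quantitation against a calibrator with
  housekeeping normalization.
- **synthetic_data** — deterministic cohort generators (13 tumor vs 76
  comparator design, 11-sample methylation subset, implanted copy-number
  segments, a hypermethylated/silenced driver gene with a co-regulated
  module, variant tables with pass/fail truth) emitting a truth table for
  every dataset.
- **io_formats** — Broad-dialect SEG, GMT, TSV matrices and a flat YAML run
  config whose defaults are the published thresholds; every output embeds
  the seed and a config hash.

Internal coordinates are 0-based half-open; SEG and gene-model files are
1-based inclusive on disk.

## CLI

```sh
quiescreen simulate --seed 1 --out bundle/          # synthetic fixture bundle + truth.json
quiescreen screen --bundle bundle/ --seed 1 --out run/   # full pipeline
```

Individual stages: `segment`, `filter-segments`, `variants`, `express`,
`gsea`, `integrate`, `bisulfite`, `qpcr`. Each accepts `--config` (flat
YAML; CLI flags override) plus `--seed` and `--out`.

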