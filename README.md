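# momics

Multi-omics prognostic subtyping pipeline: signed non-negative matrix
factorization (sNMF) consensus bi-clustering of expression data with
seven-metric rank selection against a randomized control, Kaplan–Meier /
log-rank subtype survival comparison (overall survival and distant-brain-
failure endpoints), empirical-Bayes moderated differential analysis of
protein and metabolite layers (including derived ratio indicators), and
integrated two-layer pathway scoring — exercised end-to-end on a synthetic
multi-omics cohort generator with full planted ground truth.

## Layout

| module | purpose |
|---|---|
| `momics.synthetic` | overlapping three-layer cohorts with planted clusters, signatures, log-fold-changes, and subtype-dependent survival |
| `momics.preprocess` | low-detection filtering; log / center / RMS-scale normalization |
| `momics.snmf` | sign-split stacking, Frobenius multiplicative-update NMF, multi-restart consensus, sample labels, signed gene associations |
| `momics.model_selection` | cophenetic, dispersion, evar, residuals, RSS, silhouette, Hoyer sparseness per k; randomized negative control; rank choice |
| `momics.survival` | Kaplan–Meier with Greenwood SE and log(−log) CIs; two-group log-rank; subtype comparisons |
| `momics.differential` | moderated t with moment-matched variance prior; BH FDR; metabolite ratio indicators |
| `momics.integration` | label transfer, hypergeometric GMT enrichment, summed two-layer pathway scores, cohort-overlap accounting |
| `momics.io` / `momics.pipeline` / `momics.cli` | TSV/CSV/GMT/YAML formats, manifest-tracked end-to-end driver, CLI |

## CLI

```sh
momics simulate --out cohort/ --seed 1            # synthetic cohort
momics preprocess --matrix cohort/rna.tsv --layer rna --out norm.tsv
momics select-k --matrix norm.tsv --k-min 2 --k-max 6 --restarts 50 \
    --seed 1 --out metrics.csv
momics subtype --matrix norm.tsv --k 4 --restarts 50 --seed 1 --out-dir sub/
momics survival --labels sub/subtype_labels.csv --clinical cohort/clinical.csv \
    --endpoint os --out-dir surv/
momics diff --matrix cohort/protein.tsv --layer protein \
    --labels sub/subtype_labels.csv --out diff.csv
momics enrich --gmt sets.gmt --rna-selected genes.txt --rna-universe 2000 \
    --out pathways.csv
momics run --config pipeline.yaml                 # all stages + manifest
```

`pipeline.yaml` keys mirror `momics.pipeline.PipelineConfig` (paths to the
layer matrices, clinical table, gene sets, indicator definitions; k range,
restarts, tau, FDR threshold, seed, output directory).

## Conventions

- "Detectable" means a finite, strictly positive value; features
  undetected in more than half the samples are discarded (exactly half
  survives).
- Per-feature normalization: log2 with pseudocount 1 for RNA (half the
  smallest positive value for other layers), mean-centered, scaled by the
  population root mean square.
- Signed data enters NMF as stacked positive/negative parts; signed
  gene-cluster loadings are recovered as top-half minus bottom-half of the
  basis matrix.
- Survival simulation is exponential (rate ln2 / median); censoring is
  independent uniform applied to a Bernoulli-selected subset.
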