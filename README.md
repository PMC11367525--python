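# omiclag

Paired transcriptome–proteome time-course analysis for developmental
experiments, built around an explicit mRNA→protein kinetic lag. The package
covers both modalities end to end:

- **synthetic_data** — generator for paired RNA-seq counts and protein
  log-intensities: archetypal mRNA trajectories, protein obtained by
  integrating `dP/dt = αM(t) − δP` (effective translation lag ≈ 1/δ hours),
  negative-binomial count noise, log-normal intensity noise,
  intensity-dependent (MNAR) protein dropout, and a shared per-plate noise
  term coupling the RNA/protein pair from one plate.
- **data_model_io** — TSV/GMT readers and writers with validation,
  transcript→protein collapsing, expression filtering, and the
  quantification-completeness partition (direct / imputable / unquantified).
- **transcript_de** — median-of-ratios normalization, negative-binomial GLM
  likelihood-ratio test of time-dependent vs constant expression, BH
  correction, log2 fold changes vs the baseline time point, and a
  normal-prior ridge shrinkage of fold changes.
- **protein_de** — probabilistic-minimum (MinProb) imputation for
  missing-not-at-random intensities and an empirical-Bayes moderated F-test
  with digamma/trigamma moment-matched hyperparameters.
- **cluster_enrich** — hierarchical clustering of logFC profiles,
  Fisher-exact gene-set enrichment with fold enrichment, top-variable-gene
  PCA, and per-gene z-score trajectories.
- **concordance** — fraction-of-total scaling, across-gene Spearman
  correlation at and across time points (the lag matrix and the offset that
  maximizes it), ranged-major-axis regression, per-gene Pearson
  correlations over plate-paired samples, the matched-vs-mismatched plate
  permutation test, and top-k abundance shares.
- **ratios** — protein:mRNA ratio trajectories, up/down classification by
  final-time fold change, and Dunnett many-to-one contrasts vs baseline
  with a Monte-Carlo max-|t| adjustment.
- **factor_integration** — deterministic multi-view SVD factor
  decomposition with per-view variance explained, loading-threshold gene
  classification, and permutation GSEA on factor weights.
- **report** — end-to-end pipeline orchestration and the accounting summary
  table (counts and one-decimal percentages).

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests for the stated
invariants (ODE vs closed form, oracle equivalences for the correlation /
Fisher / RMA statistics, null calibration of the three tests, determinism),
and `tests/test_acceptance.py` with the end-to-end acceptance criteria.

## CLI

The `omiclag` entry point exposes the stages:

```sh
omiclag simulate --seed 7 bundle/           # write a synthetic dataset bundle
omiclag validate bundle/                    # validate a bundle directory
omiclag de-rna --counts bundle/counts.tsv --samples bundle/samples.tsv --out de_rna.tsv
omiclag de-protein --intensities bundle/intensities.tsv --samples bundle/samples.tsv \
    --q 0.01 --seed 7 --out de_prot.tsv
omiclag cluster --de de_rna.tsv --k 4 --out clusters.tsv
omiclag enrich --clusters clusters.tsv --background genes.txt --gmt go.gmt --out enrich.tsv
omiclag concordance --rna bundle/counts.tsv --prot imputed.tsv \
    --samples bundle/samples.tsv --n-perm 1000 --seed 7
omiclag ratios --rna bundle/counts.tsv --prot imputed.tsv \
    --samples bundle/samples.tsv --de de_rna.tsv --seed 7 --out ratios.tsv
omiclag factors --rna logged.tsv --prot imputed.tsv --samples bundle/samples.tsv \
    --k 3 --threshold 0.45 --gmt go.gmt --seed 7
omiclag run --out results/                  # full pipeline on synthetic data
```

`omiclag run` writes a results directory containing the dataset bundle
(`dataset/`), per-modality DE tables (`de_rna.tsv`, `de_protein.tsv`),
cluster assignments, PCA scores, the lag matrix and per-gene correlations,
RMA fits, ratio/Dunnett tables, factor values / loadings / variance
explained, the summary table, and a `manifest.json` with seeds and stage
timings. Reruns with the same config are bit-identical.

## Data formats

All matrices are tab-delimited UTF-8 with a header row and `gene_id` as the
first column. Missing protein intensities are empty cells; counts may not
be missing. The sample table has columns `sample_id`, `modality`
(`transcript`/`protein`), `time_h` (numeric hours), `replicate`, and
`plate` (pairing key, empty for unpaired samples). Gene sets use GMT;
simulation configs use YAML.
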