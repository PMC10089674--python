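# aberrant

Aberrant-expression outlier detection for RNA-Seq gene×sample count
matrices, plus the inverse procedure for injecting confounder-masked
artificial outliers for benchmarking.

## Method

1. **Normalization** (`aberrant.zscores`): median-of-ratios size factors,
   pseudocounted log2 fold change against each gene's mean controlled count,
   gene-wise standardization to a z-score matrix. Every intermediate is kept
   so the chain can be inverted back to integer counts exactly.
2. **Confounder removal** (`aberrant.oht`): SVD of the z-score matrix and a
   hard threshold on the singular values at `omega(beta) * sigma_median`,
   where `omega` is calibrated against the median of the Marčenko–Pastur
   distribution. Components above the threshold form a low-rank "signal"
   (confounder structure); the residual "noise" matrix carries Gaussian noise
   and any sparse outlier impulses.
3. **Scoring** (`aberrant.scoring`): the noise matrix is re-standardized per
   gene; two-sided standard-normal P-values are corrected matrix-wide with
   the Benjamini–Yekutieli step-up and thresholded at a configurable FDR.
4. **Injection** (`aberrant.injection`): the same pipeline run backwards —
   selected cells of the noise matrix are overwritten with
   `mean + sign*magnitude*sd`, the signal is re-added, and the normalization
   inverted, yielding integer counts containing outliers of known location
   and z-magnitude hidden behind the dataset's own confounders.

Supporting modules: `aberrant.simulate` (negative-binomial count simulator
with optional low-rank confounders and per-sample depth), `aberrant.evaluation`
(precision-recall curves, average precision, truth ranks, bootstrap bands),
`aberrant.matrix_io` (TSV dialect, zero-count gene filter).

## CLI

```sh
# simulate a confounded count matrix
aberrant simulate --genes 2000 --samples 100 --confounders 3 --seed 1 --out sim/

# inject one |z|=6 outlier per sample (both directions)
aberrant inject sim/counts.tsv --magnitude 6 --scheme both --seed 1 --out inj/

# detect outliers; writes zhat/pvalues/qvalues TSVs and a summary
aberrant detect inj/counts_injected.tsv --fdr 0.05 --out det/

# evaluate the ranking against the injected truth
aberrant evaluate det/pvalues.tsv inj/truth.tsv --bootstrap 200 --out eval/
```

Counts are plain TSV (header: label + sample IDs; rows: gene ID + counts);
`.gz` files are handled transparently. All commands are deterministic given
a seed; `detect` is fully deterministic.

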