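# decomod

Detection and analysis of **overlapping co-expressed gene modules** from a
bulk or single-cell gene-expression matrix, using matrix decomposition
(FastICA or independent principal component analysis) instead of hard
clustering.

Most co-expression tools partition genes into disjoint clusters. Real
regulatory programs share genes: a transcription factor's targets sit in
several pathways at once, and a program may be active in only a subset of
samples. `decomod` addresses both by factoring the expression matrix

```
X (genes × samples)  ≈  S (genes × k) · P (k × samples)
```

where each column of `S` is a **signature** (one weight per gene) and each
row of `P` is the paired **pattern** (the program's profile over samples).
Every signature is thresholded *independently* into a module, so genes can
belong to any number of modules, and local (sample-subset) co-expression is
captured by the pattern.

The pipeline:

1. **Preprocess** — drop outlier samples (standardized sample-connectivity
   z-score below −2.5) and standardize each gene to mean 0, sd 1.
2. **Choose k** — permutation parallel analysis: the variance fraction of
   each singular value is compared against its distribution under
   within-gene-row permutation; `k` is the initial run of components with
   empirical `p < α`. The same stage recommends ICA or IPCA (whichever
   retains more heavy-tailed signatures; ties go to IPCA, which is more
   robust to dense noise).
3. **Decompose** — symmetric FastICA in gene space (logcosh negentropy
   contrast, α = 1), or IPCA: deflation FastICA applied to the top-k PCA
   loading vectors.
4. **Filter** — keep signatures with Pearson kurtosis `m₄/m₂² ≥ 3` (the
   Gaussian reference value); only heavy-tailed signatures carry module
   information.
5. **Assign** — per signature, genes in the tails join the module, by
   tail-area FDR from a two-component mixture with a Gaussian null fitted
   around the median (`Fdr < 0.001`), or by z-score (`|z| > 3σ`).
6. **Hubs** — the top members by |weight| per module (both tails).
7. **Associate** — Pearson correlation of each pattern with each clinical
   feature, with two-sided t-test p-values and Benjamini–Hochberg
   adjustment; plus a utility that cross-correlates patterns with module
   eigengenes from external clusterings (e.g. WGCNA-style) to find modules
   the other method missed.

A seeded synthetic-data generator (`decomod.synthetic`) plants overlapping
Laplace-weight signatures with Gaussian patterns and noise, so the whole
pipeline is testable without external data.

## Worked example

Generate a benchmark with 3 planted overlapping modules, let the tool pick
`k` and a method, then run the full pipeline:

```bash
decomod simulate --n-genes 2000 --n-samples 100 --true-k 3 --seed 11 --outdir demo/sim
decomod optimize --input demo/sim/expression.tsv --k-max 8 -B 50 --seed 1 --outdir demo/opt
# {"chosen_k": 3, "recommended_method": "IPCA"}
decomod run --input demo/sim/expression.tsv --clinical demo/sim/clinical.tsv \
    --method ICA --k 3 --assign ICA-FDR --seed 1 --outdir demo/run
```

`optimize` correctly reports the planted `k = 3`: the first three
candidates get the smallest attainable permutation p-value while the fourth
is indistinguishable from noise (`demo/opt/selection.tsv`):

```
candidate_k  variance_fraction  perm_pvalue  significant
1            0.0544             0.0196       True
2            0.0411             0.0196       True
3            0.0382             0.0196       True
```

`demo/run/` then contains every stage output. Hub genes are the strongest
weights of each module (`hub_genes.tsv`):

```
module  gene    weight  rank
oM1     g00189  4.709   1
oM1     g00113  4.709   2
oM1     g00116  4.703   3
```

and `associations.tsv` shows each module's pattern locking onto its planted
clinical trait (r ≈ 0.98, BH-adjusted p ≈ 6e-69) while unrelated and
pure-noise traits stay flat (|r| < 0.15, adjusted p > 0.26):

```
module  feature    r       p        p_bh     n
oM1     trait_M1   0.086   0.394    0.442    100
oM1     trait_M2   0.979   9.6e-70  5.8e-69  100
oM1     trait_M3  -0.149   0.139    0.264    100
oM1     trait_noise 0.084  0.406    0.442    100
```

(Planted module order is arbitrary — here the component labeled oM1 matched
the trait built from planted pattern M2.)

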