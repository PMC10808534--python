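# kaede-dcflow

Analysis pipeline for photoconversion ("time-stamping") studies of tumour
dendritic cells, together with a synthetic-data generator that emulates the
experimental design end to end.

In these experiments, mice expressing the photoconvertible protein Kaede
carry a subcutaneous tumour; a pulse of violet light at time *t*conv switches
every tumour-resident cell from green to red fluorescence. Cells entering
the tumour afterwards remain green, and red cells found in the draining
lymph node (dLN) must have emigrated from the tumour after conversion — so
the red/green label encodes *tumour dwell time*. Conventional DCs (cDC)
that take up tumour antigen mature into activated CCR7⁺ DC states before
egressing to the dLN; the analytical question throughout is how label
composition, expression programs, cell–cell interactions, spatial
organisation and patient survival vary along that maturation path.

## What the package implements

- **`synthetic`** — a per-cell continuous-time Markov chain
  cDC → DC1 → {DC2, DC3} with state-dependent dLN egress, Poisson tumour
  entry, photoconversion labelling, and negative-binomial expression with
  planted gene programs; plus correlated-score spot lattices, centroid
  fields, and survival cohorts with signature-dependent hazard. The
  expected per-state Kaede-red fraction
  `N_red,s(Δ) / (N_red,s(Δ) + N_green,s(Δ))` has a matrix-exponential
  closed form (`expected_red_fraction`) used as the simulator's oracle.
- **`sc_core`** — QC filtering (cells mapped to > 6000 or < 1000 genes
  removed, mitochondrial fraction < 7.5%, genes in ≥ 3 cells), total-count
  normalisation to 10⁴ + log1p, binned-control signature scoring, Wilcoxon
  rank-sum DE with Benjamini–Hochberg correction, state-signature
  extraction (padj < 0.05, log₂FC > 1), Kaede composition statistics, and
  PCA-projection label transfer.
- **`pseudobulk`** — the bootstrapped pseudo-bulk ranking: cells of each
  group are randomly partitioned into pseudo-replicates (default 3), summed
  counts are normalised by median-of-ratios size factors and tested
  per gene with a negative-binomial Wald test; the gene rank metric is the
  **mean Wald statistic** over B = 11 bootstrap re-partitions. Pseudo-bulk
  PCA with top-100-loading hypergeometric over-representation completes the
  stage.
- **`gsea`** — preranked GSEA (running-sum ES, gene-set permutation null,
  BH, leading edge, signed −log₁₀ padj) and ssGSEA with 0–1 scaling.
- **`interactions`** — CellPhoneDB-style ligand–receptor scoring:
  `(mean ligand in sender + mean receptor in receiver) / 2` with a 10%
  expression-fraction filter and a global cluster-label permutation null.
- **`coloc`** — spot-neighbourhood Pearson correlation (spot + k = 6
  nearest neighbours, detection-in-all-spots and p < 0.05 filters) and
  200 µm grid-binned class-count correlation for segmented microscopy.
- **`cohort`** — ssGSEA signature scoring of bulk cohorts, median split
  into high/low, Kaplan–Meier curves and the log-rank test (lifelines).
- **`pipeline` / CLI `kaede-dcflow`** — end-to-end orchestration with
  per-stage seeds and a hash manifest; identical configs give
  byte-identical runs.

## Worked example

```sh
kaede-dcflow run --seed 0 --out demo/
cat demo/summary.json
```

prints (abridged):

```json
{
  "composition": {"S0_cDC": 0.215, "S1_DC1": 0.329,
                  "S2_DC2": 0.805, "S3_DC3": 0.802},
  "gsea":        {"activation_es": 0.962, "activation_padj": 0.00144,
                  "activation_called": true},
  "lr":          {"planted_pair_p": 0.000999},
  "grid":        {"r": 0.917, "n_grids": 108},
  "survival":    {"logrank_stat": 61.87, "logrank_p": 3.66e-15,
                  "median_survival": {"high": 50.3, "low": 13.0}}
}
```

Reading the numbers: pooled over harvests, activated DC2/DC3 cells are ~80%
Kaede-red (long tumour dwell) while cDCs are mostly recent green entrants —
the label composition rises along the maturation chain exactly as the
occupancy oracle predicts. The bootstrap ranking of DC2 vs DC3 puts the
planted DC2 markers on top, the planted activation program is called by
preranked GSEA (ES 0.96, padj 0.0014), the planted ligand–receptor pair is
significant at the permutation floor, jitter-coupled centroid classes
co-localise at grid R ≈ 0.92, and the protective synthetic signature splits
the cohort into high/low groups with median survival 50 vs 13 months
(log-rank p ≈ 4 × 10⁻¹⁵).

Each stage is also exposed directly (`simulate`, `qc`, `score`, `de`,
`composition`, `transfer`, `pseudobulk-rank`, `gsea`, `lr`, `spatial`,
`grid`, `survival`); see `kaede-dcflow <cmd> --help`.

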