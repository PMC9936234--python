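# repclon

Characterisation of the tumor-infiltrating B- and T-cell receptor repertoire
from bulk RNA-seq clonotype tables, aimed at studies of muscle-invasive
bladder cancer (MIBC) and its consensus molecular subtypes (LumP, LumNS,
LumU, Stroma-rich, Ba/Sq). The package is for computational immunologists
and cancer genomicists who have aligner-derived clonotype exports (e.g.
MiXCR) plus per-sample clinical annotations and want reproducible,
cohort-level repertoire statistics without touching FASTQ files.

## What it computes

Per sample and receptor chain (IGH, IGK, IGL, TRA, TRB; the sparse γδ
chains TRD/TRG are filtered out):

- **Clones.** Records sharing the same V gene, J gene, and CDR3 length are
  linked when their CDR3 nucleotide identity reaches 90% (BCR) or 95%
  (TCR); clones are the connected components (single linkage).
- **Richness (expression).** `Ig/TR = M / (N + M)` — receptor-mapped reads
  `M` over total sequenced reads, normalising infiltration for depth.
- **Diversity (Shannon entropy).** `H = −Σᵢ pᵢ log₂ pᵢ` in bits over clone
  read-frequencies `pᵢ`; monoclonal repertoires give 0, absent chains give
  an *undefined* (missing) entropy.
- **Clonality networks.** Per receptor class, vertices are unique sequences
  (size = identical-chain count), edges follow the clone rule, clusters are
  clones. The Gini index `G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄)` over vertex sizes
  measures **clonal expansion** and over cluster sizes **clonal
  dominance/diversification**.
- **Inflammatory score.** The sum of 22 deconvolved immune-cell relative
  fractions (monocyte/macrophage/dendritic/mast/granulocyte/B/T/NK
  subsets).
- **Cohort statistics.** Pairwise Wilcoxon rank-sum contrasts between
  subtypes; Spearman correlations of the measures with silent and
  non-silent mutation rates and the inflammatory score (pooled and by
  subtype); Cox proportional-hazards models of overall survival adjusted
  for age, region, and stage, with optional measure × subtype interaction.

A synthetic-cohort generator with known ground truth (Dirichlet clone
frequencies, founder/variant CDR3s inside the identity thresholds, copula-
linked mutation rates, exponential survival with a known hazard ratio per
entropy bit) stands in for protected patient data and backs the test suite.

## Worked example

Simulate the default 396-sample five-subtype cohort and run the full
analysis:

```sh
repclon simulate --seed 7 --out sim
repclon analyze --clonotypes sim/clonotypes.tsv --metadata sim/metadata.csv --out results
```

`results/metrics.tsv` starts:

```
sample_id  chain  n_records  n_reads  expression    n_clones  entropy
LumP-001   IGH    150        5387     4.700348e-05  100       6.2479
LumP-001   IGK    107        1195     1.042680e-05  71        5.7225
```

LumP-001 has 150 distinct IGH clonotypes carrying 5 387 reads out of
~1.1×10⁸ sequenced (expression 4.7×10⁻⁵) which cluster into 100 clones of
6.25 bits entropy — a diverse, unexpanded B-cell repertoire.
`results/network.tsv` gives the clonality network summary:

```
sample_id  receptor_class  n_vertices  n_clusters  gini_vertex  gini_cluster
BaSq-001   BCR             422         277         0.7058       0.2294
BaSq-001   TCR             52          42          0.5245       0.1465
```

so this Ba/Sq tumor's B-cell repertoire is markedly expanded (vertex-size
Gini 0.71) with modest clone dominance (cluster-size Gini 0.23).
`results/contrasts.tsv` reports, e.g., that IGH entropy in LumP is lower
than in Stroma-rich (rank-sum p ≈ 1.1×10⁻²², `***`), and
`results/survival.tsv` contains per-stratum hazard ratios such as

```
subtype      chain  measure  n   events  hazard_ratio  ci_low  ci_high
Stroma-rich  TRB    entropy  45  38      0.818         0.446   1.501
```

an estimated HR of 0.82 per bit of TRB diversity in the Stroma-rich
stratum (the generator's true value for that subtype is 0.6; a 45-sample
stratum is compatible with both). Re-running either command with the same
seed reproduces every table byte-for-byte; `results/manifest.json` records
the configuration hash.

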