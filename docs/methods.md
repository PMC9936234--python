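# Methods

## Clone definition and identity metric

A clone groups receptor records with the same V gene, same J gene, same
CDR3 length, and CDR3 nucleotide identity at or above a receptor-class
threshold: 0.90 for B-cell chains (IGH/IGK/IGL), 0.95 for T-cell chains
(TRA/TRB). Thresholds are inclusive (≥). Because equal CDR3 length is part
of the grouping key, identity is computed position-wise (Hamming identity)
with no alignment or gap model; this is the one parameter-free reading
consistent with a length-keyed rule, and it makes the linkage criterion a
simple mismatch budget `d ≤ ⌊(1−t)·L⌋`. Within a (V, J, length) group any
qualifying pair is linked and clones are the connected components
(single linkage), so linkage is transitive through intermediates. V and J
genes are compared at gene level: allele suffixes (`*01`) and score
annotations are stripped at read time, and when an aligner lists several
hits the first (highest-scoring) one is used. CDR3s are uppercased;
ambiguity codes are rejected rather than coerced, because Hamming identity
needs an exact four-letter alphabet.

The γδ T-cell chains TRD and TRG carry too few reads and clones in bulk
tumor RNA-seq to support the metrics and are filtered out by default; rows
without an estimated CDR3 are dropped and counted in a drop log.

## Repertoire measures

**Richness (expression)** is `M/(N+M)`: receptor-mapped reads over total
sequenced reads in the library, i.e. a depth-normalised infiltration
abundance. It is 0 for a chain with no records — a true measurement of
absent infiltration. The denominator (`total_reads`) is taken from the
metadata table rather than recomputed, since the pipeline starts
downstream of alignment.

**Diversity** is Shannon entropy `H = −Σ pᵢ log₂ pᵢ` in bits, with `pᵢ`
the read-based frequency of clone *i* within its sample × chain (read
counts, not distinct-sequence counts, since bulk abundance is read-based).
No normalisation by `log₂ N` is applied. An empty repertoire has
*undefined* entropy, reported as missing and excluded pairwise from
downstream tests — collapsing it to 0 bits would conflate "no
infiltration" with "monoclonal".

## Clonality networks and Gini indices

Per sample and receptor class (BCR pools IGH/IGK/IGL, TCR pools TRA/TRB),
unique sequences keyed by (chain, V, J, CDR3) become vertices sized by
their summed read count; edges follow the clone rule at the class
threshold; connected components are clones. The Gini index — relative mean
absolute difference, `G = Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄)`, with no small-sample
correction — is computed over vertex sizes (clonal expansion) and cluster
sizes (clonal dominance). Cluster size defaults to the number of vertices
per component, contrasting the read-level unit of vertex size with a
sequence-level unit; a read-weighted variant sits behind
`weighted_clusters` for sensitivity analysis. The implementation uses the
algebraically identical sorted cumulative form
`G = 2Σᵢ i·x₍ᵢ₎/(nΣx) − (n+1)/n`, O(n log n); tests cross-check it against
the explicit double sum to 1e-12. Graph layout is presentation-only and
out of scope; an edge-list export is provided for external tools.

## Inflammatory score

The sum of the relative fractions of 22 inflammation-related immune cell
types within the leukocyte compartment, taken as supplied (no
renormalisation). The tracked panel includes a generic T-helper fraction
rather than plasma cells, so the 22 values need not sum to 1. A missing
cell type is a hard error, never a silent zero.

## Cohort statistics

Subtype contrasts use the two-sided Wilcoxon rank-sum test per unordered
subtype pair: exact when both groups have ≤ 25 tie-free values, else the
normal approximation with tie and continuity correction — matching common
reference behaviour at these group sizes. Stars follow the conventional
0.05/0.01/0.001 thresholds, reported per pair without multiplicity
correction by default (Benjamini–Hochberg q-values behind a flag).
Correlations are tie-corrected Spearman, pooled and per subtype; fewer
than 3 complete pairs or a constant vector yields a missing coefficient.

Survival uses Cox proportional hazards (Efron tie handling via lifelines)
adjusted for age in years (continuous), region (reference USA+Canada), and
stage (reference I-II). Richness enters as log10(expression) with
zero-expression samples excluded (no pseudo-count); entropy enters in raw
bits; both scales are configurable. Strata need ≥ 10 samples and ≥ 3
events (configurable); indicator covariates with fewer than 3
observations in a level are dropped within a stratum to avoid separation;
non-convergence flags the row rather than failing the panel. The
interaction analysis fits one all-sample model with measure × subtype
product terms and reports per-subtype slopes with variances combined from
the coefficient covariance. All tests are two-sided; no direction is
pre-specified.

## Synthetic cohort generator

The generator emulates the statistical structure of a TCGA-scale MIBC
repertoire study, not its biology. Per sample × chain it draws a clone
count log-normally (default mean 10² clones per B-cell chain, 10^1.5 per
T-cell chain, σ = 0.15 dex), clone frequencies from a symmetric
Dirichlet(α) — α is the expansion dial, mapping monotonically onto the
vertex-size Gini — a founder CDR3 of random length 24–60 nt (multiple of
3) per clone, and a Poisson number of variants per clone (mean 1.6
sequences/clone) at Hamming distance strictly inside the class identity
threshold (default 1 mismatch), so the true partition is unambiguous under
the clone rule; infeasible length/budget draws are redrawn. V/J genes come
from 45 × 6 pools, key-separating any two clones with probability ≈ 0.9997,
and random founders keep even key-colliding clones below the identity
threshold. Reads are allocated multinomially at a per-chain depth.

The five default profiles mirror the study cohort: 396 samples split
126 (LumP) / 20 (LumNS) / 53 (LumU) / 45 (Stroma-rich) / 152 (Ba/Sq);
B-cell read depths span 8 000 (LumP) to 42 000 (Stroma-rich) per sample
against T-cell depths of 100–404, echoing the observed BCR≫TCR imbalance
and its subtype gradient; the Dirichlet concentration encodes the B-cell
expansion ordering (Stroma-rich 0.15 … LumP 1.5); `total_reads` is
log-normal around 10⁸. Clone counts and depths are kept modest so a full
cohort simulates and analyses in well under a minute — the package's own
choice of problem size for its test fixtures.

Metadata structure: age ~ N(66.5, 9.5) clipped to 30–90; sex, region,
histology and per-subtype stage frequencies follow the cohort's published
composition. Mutation rates are log-normal (NSMR median 5, SMR median 2,
σ = 0.8 on the log) rank-coupled to each sample's overall log-richness
through a Gaussian copula at the profile's `target_rho`; the 22 immune
fractions are a 23-part Dirichlet draw (22 tracked + one untracked
remainder whose concentration sets the subtype's mean inflammatory score),
with whole fraction vectors rank-reassigned by the same copula. Survival
is exponential with hazard `h₀·exp(β_HR·(H_TRB − 3.5) + 0.02·(age−66.5) +
stage effects)` where `h₀ = ln2/1095 d⁻¹` and `β_HR` is the profile's true
log hazard ratio per bit of TRB entropy (defaults: ln 0.6 Stroma-rich,
ln 0.8 Ba/Sq, 0 for luminal subtypes, matching the direction of the
subtype-specific protective associations the pipeline is designed to
detect); censoring is uniform on 1–10 years.

What the generator does **not** emulate: real V(D)J recombination and
germline gene usage, somatic hypermutation hotspots, sequencing error,
isotypes, and clonal overlap between chains of one cell. Passing tests
therefore demonstrate correctness of the measures and the inference
machinery under a controlled data-generating process — not that the
biological conclusions of any particular cohort would replicate.

## Numerical and design choices

- Clone and cluster labels are deterministic (ordered by first member in
  input order), so repeated runs are byte-identical.
- The mismatch budget `⌊(1−t)·L⌋` is evaluated with a 1e-9 slack so exact
  boundary products (e.g. 0.05 × 20) are not lost to floating point.
- Entropy of an empty vector is NaN by contract; Gini of an all-zero or
  empty vector is an error (no meaningful inequality exists).
- `assign_clones` uses its own union-find; the networkx component route
  appears only in tests as an independent oracle.
- Statistical floors (Cox: 10 samples / 3 events) and the indicator-level
  floor (3) are pragmatic small-stratum guards, all configurable.
- Simulation-based checks freeze their seeds; coverage-style assertions
  allow for binomial noise at the replicate counts used (e.g. null CI
  coverage asserted within [86%, 100%] at 50 replicates).

## Known limitations

- Hamming identity cannot absorb indel variants of a clone; clones whose
  members differ in CDR3 length are split by construction. This mirrors
  the length-keyed clone rule but is a modelling choice worth a
  sensitivity analysis with an alignment-based identity.
- Expression depends on the supplied `total_reads`; inconsistent
  denominators across cohorts bias cross-cohort comparisons.
- The Cox panel reports a convergence flag but no proportional-hazards
  diagnostics.
- No automated outlier exclusion is implemented (e.g. aberrant TCR read
  totals); such filtering is left to the analyst's judgment upstream.
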