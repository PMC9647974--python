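# Methods

This note documents the models, algorithms, numerical choices, and
limitations behind `metahic`. It is the design record for maintainers;
the README covers usage.

## Coordinate model

All coordinates are 0-based, half-open internally; GTF input (1-based,
closed) is converted on parse. A `BinnedGenome` fixes a resolution `r`
(bp per bin) and assigns each chromosome `ceil(length / r)` contiguous
global bin indices; the final bin is truncated at the chromosome end.
Genes carry strand-oriented TSS/TES: for a minus-strand gene the stored
TSS is the exclusive end of the span, so the occupied span is always
`[min(tss, tes), max(tss, tes))` and the first transcribed base sits at
`tss − 1`. TSS-bin lookups (compartment labels, eQTL candidates) use that
transcribed base.

Gene-pair distance for distance thresholds is the **gap between gene
spans** (0 when they overlap). TSS-to-TSS distance is an equivalent,
selectable alternative (`distance="tss"`); the choice matters only near
the threshold and both are exposed because neither convention is
universal. "Autosome" is species-specific, so autosome restriction is a
named chromosome allow-list (presets: human chr1–22, mouse chr1–19, fly
chr2L/2R/3L/3R/4), applied by the caller to the chromosome table.

## Contact matrices

Matrices are stored upper-triangularly (`i ≤ j`, weights ≥ 0) with
symmetric semantics; lower-triangle input records are folded by
summation. I/O supports a COO TSV dialect (`#resolution=` header) and an
HDF5 layout mirroring HiCMatrix (CSR arrays under `matrix/`, bin
intervals under `intervals/`). Aggregation is the entrywise sum — it is
exact, commutative, and associative, so run→project→meta order cannot
change the meta map. Mixing balanced and raw matrices in one sum is
rejected. Depth is the total weight, reported separately for cis and
trans.

### Balancing

`kr_balance` finds a positive per-bin vector `d` with
`d_i · (C d)_i = 1` over the selected mode: cis mode balances each
chromosome block independently; trans mode balances the genome-wide
matrix with cis entries excluded from row sums. Because every stored
entry touches two bins with positive row sums, bins with zero in-mode
row sum have no in-mode entries; they are masked out (`balanced_mask`)
and nothing of theirs is rescaled. Out-of-mode entries pass through
unchanged, so balancing cis and trans separately and re-aggregating
reconstructs the full normalized map.

The solver is the Knight–Ruiz inner-outer Newton/CG iteration with an
automatic fallback to symmetric Sinkhorn–Knopp
(`x ← sqrt(x / (C x))`) when KR leaves the positive cone or stalls. Both
converge to the same balanced matrix whenever one exists; KR is kept
primary for its quadratic local convergence on well-supported matrices.
Each block is preconditioned by its mean row sum before iterating, which
makes the computation *exactly* invariant to an overall scaling of the
input (the scaling cancels bitwise). Defaults: tolerance 1e-6 on the
maximum absolute row-sum deviation, 1000 iterations; non-convergence
raises with the final residual rather than returning a partial result.
Sparse matrices without total support (e.g. effectively bipartite
blocks) are genuinely unbalanceable and surface as that error.

## Gene networks

Contact-to-gene mapping takes the **maximum** contact weight over the
rectangle of bin pairs the two genes occupy (computed as a row-max then
column-max, which is exact for rectangles). The max rule makes the gene
weight monotone under added contacts and insensitive to gene length.
Genes un-mappable onto the matrix genome are dropped and counted.

Rank standardization replaces each unordered pair's weight by its
average-tie rank divided by the number of scored pairs `m`; undefined
pairs take the median rank `(m_def + 1) / 2` of the defined ones. With a
tie-free top weight the maximum standardized weight is exactly 1; under
ties it is the tied mean rank over `m`, which is the behaviour the
aggregate-coexpression recipe expects.

Coexpression networks: per dataset, Spearman correlation over samples
(ranks within gene, average ties, then Pearson), rank-standardized with
the NA rule above, then averaged across datasets on the union gene set.
Datasets with fewer than 3 samples are skipped with a warning — a
2-sample correlation is ±1 by construction and only adds noise.

Top-partner labels: among a gene's eligible partners (defined weights,
mask), the `k = max(1, ceil(fraction · m))` highest-weight partners are
positives. Ties at the threshold are broken by a permutation drawn from
a generator keyed by a global tie seed and the gene index — reproducible
but not biased by input order. The `max(1, ·)` floor keeps small
neighborhoods scoreable.

## Structural units

Compartments follow the classic pipeline: observed/expected transform
(per-diagonal means; zero-expected offsets map to 0), Pearson
correlation matrix over bins with nonzero rows, then the first principal
component of that correlation matrix (column-centered, leading
eigenvector of its covariance). Bins are partitioned by PC1 sign, and
the sign group with the higher mean gene density is called A — that
orientation rule makes the labels invariant to the arbitrary sign of an
eigenvector. When the contact graph over unmasked bins has several
connected components, each component with ≥ 3 bins is decomposed and
density-oriented independently. A constant correlation matrix (uniform
block) has no compartment structure and raises rather than guessing.
Genes take the label of their TSS bin; a gene spanning bins with
conflicting labels therefore follows its promoter, the site most
relevant to the expression-based metrics.

TADs use "topdom-lite": `binSignal(i)` is the mean of the
`window × window` diamond spanning rows `(i−window+1 .. i)` and columns
`(i+1 .. i+window)`, clipped at chromosome edges; boundaries are bins
whose signal is strictly lower than every other defined signal within
±window; domains are the intervals between consecutive boundaries.
TopDom's rank-sum false-boundary filter is deliberately omitted — the
downstream uses (exact-interval overlap counting and shared-TAD
coexpression) depend only on the interval sets — and outputs carry the
`topdom-lite` caller tag. TAD overlap across experiments is exact
(chrom, start, end) identity at one resolution; a one-bin shift is a
different TAD.

Shared-unit aggregation binarizes each experiment (1 if both genes carry
the same label) and averages: the weight is the fraction of experiments
in which the pair shares a unit, with per-pair support counts; pairs
never co-labelled are undefined and excluded per gene. TAD labels are
chromosome-scoped ids, so cross-chromosome pairs share a TAD with
probability 0 by construction, while A/B labels are genome-comparable
and do inform trans pairs.

## AUROC machinery

The AUROC is the Mann–Whitney statistic with average ranks, so tied
scores get half credit — a constant score vector scores exactly 0.5. It
is undefined without both a positive and a negative, and such entities
are skipped with a reason code (`no-edges`, `no-positives`,
`no-negatives`) rather than imputed; summaries (mean primary, median
also reported) cover scored entities only. An independent brute-force
pair-counting oracle in the test suite pins the implementation to 1e-12.

eQTL metrics: variants inside coding intervals or within 1 kb of any
TSS/TES are removed variant-level. Candidates are same-chromosome
annotation genes whose TSS bin (at the 1-kb matrix resolution) contains
no other gene's TSS — bin-sharing genes are all excluded, avoiding an
order-dependent pick. Signed variant–TSS distance comes from the table
when present (GTEx convention) and from the annotation otherwise.
Distance thresholds are strict (`> min_distance`). The contact and
proximity metrics share one candidate/skip construction, so their scored
variant sets are identical and their AUCs directly comparable.

## Cross-species comparison

Ortholog maps must be 1:1; pairs missing from either network or
annotation are dropped with a count. The edge universe is restricted to
pairs whose cis/trans status agrees in *both* species (a pair cis in one
and trans in the other is excluded from both scopes), and top-fraction
labels are computed within that restricted universe — they must be
computable for both species. Contact conservation averages the per-gene
AUCs of both prediction directions; an explicit gene-subset argument
supports same-ortholog-set controls. Contact-coexpression conservation
is one-directional (A contacts → B coexpression labels) and accepts a
coexpression-quantile floor for strength-threshold sweeps.

## Synthetic data

The generator's defaults are the package's study conditions: 3
chromosomes × 2 Mb at 10-kb bins (600 bins), 200 genes, 200 expression
samples, 10⁶ contacts, coupling κ = 0.6. Structure:

* cis probability `∝ (1 + |i−j|)^(−α)` with α = 1 (a standard contact
  decay slope), times a plaid boost of 3 for same-compartment bin pairs
  (alternating A/B blocks of 10 bins);
* genes are placed one per bin with 2× propensity for A bins (A is the
  gene-dense compartment, which is what makes density orientation
  meaningful);
* trans cells carry a uniform base weight (0.01 relative units, putting
  ~16% of reads in trans) plus planted functional gene pairs whose
  TSS-bin cells are boosted 30× — planting at TSS bins means the
  max-over-bins gene mapping captures them deterministically;
* eQTL variants are planted in non-coding bins > 1 kb from every
  TSS/TES, each with a 30× contact boost to its true eGene's TSS bin,
  so the planted table survives the paper-style variant filter intact;
* expression is `sqrt(κ)·factor + sqrt(1−κ)·noise` per sample, where the
  factor is the gene's functional-pair group if it has one, else its
  (chromosome, compartment) block — so cis coexpression tracks the plaid
  and trans coexpression tracks the planted pairs;
* species B reuses the probability structure with a fraction δ of the
  planted pairs rewired to random new pairs (identity ortholog map);
  rewired positions are uniform over trans pairs, so at δ = 1 the
  expected conservation is exactly the 0.5 null.

Contacts are drawn multinomially over unordered bin pairs with the total
depth fixed — conditionally equivalent to independent Poisson cells but
exact for depth sweeps — and `subsample_contacts` thins a drawn matrix
hypergeometrically, which is marginally identical to sampling at the
lower depth while coupling the sweep points (a variance-reduction
design: monotonicity in depth is then tested against shared noise).

What the generator does **not** emulate: restriction-site and mappability
bias, copy-number artifacts, distance-dependent noise spectra, tissue
heterogeneity, or realistic gene architecture. Passing tests therefore
demonstrate that the *analysis machinery* recovers planted signal under
controlled conditions, not that real Hi-C data carries that signal.

## Validation experiments

The acceptance suite checks the values the metric definitions force:
perfect-prediction and null boundaries of contact coexpression (1 and
0.5 ± 0.02 at 500 genes), the contact-eQTL boundary (1), and
self-conservation (1); the AUROC against the exhaustive oracle; the
balancing contract (row sums within 1e-6, scale invariance within
1e-8); and two recovery sweeps run at desk-scale sizes chosen to keep
the whole suite under a few minutes:

* depth sweep — default config, κ = 0.6, nested depths
  {10⁴, 10⁵, 10⁶, 10⁷}: genome-wide contact coexpression must be
  non-decreasing in depth and beat the κ = 0 null at 10⁶ by ≥ 0.1. The
  genome-wide (cis + trans) network is used because it is the package's
  headline metric and both planted signals contribute.
* divergence sweep — 200 genes with dense trans planting (1400 pairs,
  200× boost, 2×10⁶ reads), chosen so each gene's top decile of trans
  partners is essentially its planted set: conservation then saturates
  near 1 at δ = 0, decreases monotonically, and nulls at δ = 1. The
  planting density matters: with sparse planting the top-decile labels
  are dominated by sampling noise and the δ = 0 ceiling drops well below
  0.9 for structural rather than inferential reasons.

## Known limitations

* The simplified TAD caller has no statistical boundary filtering and no
  hierarchy; its boundaries are sensitive to the window on noisy input.
* Compartment calling assigns no label to zero-coverage bins and whole
  chromosomes can fail (degenerate correlation); callers must tolerate
  partial label sets.
* Trans balancing treats the genome-wide trans graph jointly; per
  chromosome-pair balancing is not implemented.
* The eQTL machinery scores prioritization only — it neither calls
  eQTLs nor models tissues; tissue collapsing is assumed done upstream.
* Aggregation assumes compatible genomes and resolutions; no liftover.
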