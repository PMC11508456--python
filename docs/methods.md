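# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Univariate differential abundance

For proteoform *i* with case samples C and control samples H, the fold
change is the ratio of group mean abundances and the reported statistic is
log2((mean_C + c)/(mean_H + c)). The pseudocount *c* defaults to half the
smallest positive value in the matrix: it keeps the statistic finite for
proteins not detected (zero) in one group without materially shifting
well-measured proteins. With `pseudocount=0`, zero means produce ±inf with a
warning; rows are never dropped silently.

The test is the two-sided Wilcoxon rank-sum (Mann–Whitney). The exact null
distribution is used whenever the combined sample size is ≤ 30 and the row
has no ties — which covers the 10-vs-20 design this package targets — and
the normal approximation with tie and continuity corrections otherwise
(zero-inflated rows always tie, so they take the asymptotic path). A
constant row is defined to have p = 1. Multiplicity is handled by
Benjamini–Hochberg step-up adjustment across all proteoforms.

The selection gate is joint: |log2FC| ≥ log2(fc_threshold) AND FDR strictly
below alpha. The default threshold 1.3 is read on the *ratio* scale (a ±30%
change, log2 1.3 ≈ 0.3785); `fc_scale="log2"` reads the same number on the
log2 scale instead, a much stricter gate (≈ 2.46-fold). The ratio reading is
the default because it is the one consistent with moderate-fold-change
proteins (|log2FC| ≈ 0.4) passing a univariate FDR gate in panels of this
kind.

## PLS-DA and recursive feature elimination

The classifier is PLS1 on the autoscaled matrix (columns centered and
scaled to unit variance; constant columns are given SD 1 so they map to
zero) against a centered 0/1 group indicator y. For two classes a single
indicator column is equivalent to two-column one-hot coding up to scaling.
The component-1 weight vector u is X'y normalised — equivalently the
leading eigenvector of the rank-one penalised covariance structure
Z = X'y y'X — so the sample scores satisfy the identity
S_j = Σ_i u_i1 r_ij exactly (asserted to 1e-8 in the tests). Later
components come from standard NIPALS deflation X ← X − t p', which leaves
component 1 untouched and makes score vectors mutually orthogonal. The
per-component "eigenvalue" is (y't_k)²; variance explained is the fraction
of the total autoscaled sum of squares captured by regressing the matrix on
each component's scores (additive across components because the scores are
orthogonal). Sparsity, when requested, soft-thresholds each weight vector
at the smallest surviving magnitude so exactly `keep_per_component` proteins
stay nonzero, then renormalises.

RFE refits on the surviving proteins (re-autoscaling each time) and removes
the protein with the smallest absolute component-1 loading, one per
iteration by default, until ceil(target_fraction × initial count) proteins
remain — ceil(0.05 × 2815) = 141. Choices made here:

- **|u| rather than signed u.** A signed minimum would preferentially
  discard one regulation direction, which is biologically indefensible for
  a panel meant to contain both up- and down-regulated markers.
- **Tie-break** on equal |loading|: the lexicographically smallest accession
  goes first, for determinism.
- **One protein per iteration** is the reference behaviour; `chunk > 1`
  removes several per refit as a speed option and reaches the same target
  count (the elimination *order* may differ).
- The per-iteration fit computes only the component-1 weight vector; since
  deflation never alters component 1, this is identical to reading u_·1
  from a full multi-component fit, and makes the full 2815-protein chunk-1
  run take a few seconds.
- During RFE the per-iteration fit is dense (no soft-thresholding) by
  default: the elimination loop is itself the feature selector, and
  thresholding would only re-order eliminations among already-negligible
  loadings. `keep_per_component` enables the sparse variant.

The component count is chosen by repeated stratified k-fold cross-validation
(default 5 folds × 10 repeats), classifying held-out samples by the nearest
group centroid in score space and scoring balanced error. The selection uses
the one-standard-error parsimony rule: the smallest count whose mean error
is within one SE (plus a 0.01 tolerance) of the best count's, so a flat
profile — pure noise — returns 1. The pipeline default is 2 components,
appropriate for a two-group design of this size.

PLS-DA is fitted on the autoscaled raw abundances (not log-transformed):
autoscaling already removes the dominant per-protein magnitude differences,
and keeping the fitted matrix identical to the one the score identity is
stated on keeps the contract simple.

## Merge and isoform collapse

Proteoform IDs follow the UniProt dash convention: base accession plus an
optional isoform index (`P14618-2`). The merged candidate list is the plain
set union with inclusion–exclusion counts reported. Collapsing replaces
every member by its base and deduplicates; when each isoform's base is also
present, |unique| = |input| − n_isoforms. After collapsing, a base inherits
the statistics of its most significant proteoform (smallest FDR, smallest
raw ID on ties) — pathway and interaction databases track proteins, not
isoforms, so downstream stages need one row per base.

## PPI network

MITAB input is parsed leniently: at least the 15 core tab-separated columns;
interactor-type columns (21/22 of the extended dialect) are used when
present and assumed to denote protein when absent. UniProt accessions are
extracted from the primary-identifier columns and isoform suffixes stripped;
non-uniprotkb identifiers are kept but flagged. Filtering requires *both*
taxids to equal the target (default 9606, removing homology-inferred
cross-species rows) and, by default, both interactor types to be protein.
Pruning keeps edges with both endpoints in the candidate list (this is what
removes first interactors), drops self-loops — including isoform pairs that
collapse to the same base — collapses unordered duplicates, and reports only
connected (degree ≥ 1) proteins. Node direction is the sign of the
univariate log2FC (zero counts as down; in continuous data an exact zero
does not occur). The packaged 48-protein OSCC saliva panel
(`proteomark/data/oscc_saliva_panel.tsv`, 30 up / 18 down) serves as a
reference node table for this stage's bookkeeping.

## Over-representation analysis

For each gene set, members and input list are intersected with the universe
(background). The p-value is the upper-tail hypergeometric probability
P(X ≥ k) for drawing n list members from a universe of N containing m set
members; enrichment ratio (k/n)/(m/N); BH FDR across all tested sets;
significance at FDR ≤ 0.05. Only over-representation is tested. The default
universe is the union of all set members plus the input list — the
pragmatic offline stand-in for a "protein-coding genome" background, which
can be supplied explicitly instead.

Redundancy reduction clusters the significant sets with affinity
propagation on Jaccard similarity of their member sets (damping 0.5,
preference = median similarity, max 500 iterations, fixed random state:
deterministic). Two degenerate cases are short-circuited rather than sent
to message passing: a single significant set is its own exemplar, and
all-pairwise-disjoint sets (all off-diagonal similarities zero, where AP is
ill-posed) each become their own exemplar. Non-convergence falls back to
flagging every significant set, with a warning.

## Synthetic data

The generator emulates a label-free salivary cohort: log2 abundances are
Gaussian around per-protein baselines drawn uniformly on [10, 25] (typical
log2 intensity range), with noise decomposed into an equicorrelated
block-shared factor and an idiosyncratic residual
(σ·(√ρ·z_block + √(1−ρ)·ε)), exponentiated to the nonnegative raw scale.
Planted markers get a ±effect shift of the case-group mean on the log2
scale, so their true log2FC is exactly ±effect_log2fc. Defaults: 10 cases,
20 controls, 2815 proteoforms, 5% markers, effect 2, noise SD 0.5, blocks
of 50 at ρ = 0.5, 10% isoform rows, no missingness. Block correlation
creates the correlated protein communities that motivate the multivariate
stage; isoform rows reuse an existing row's base accession with a dash
suffix so the collapse arithmetic is exercised. Missingness, when enabled,
is encoded as zeros (the non-detection convention of salivary abundance
matrices) and absorbed by the univariate pseudocount.

The interactome writer emits 36-column MITAB (the 15-column core padded to
the extended dialect, because interactor-type filtering needs columns
21/22), containing the planted marker path, Bernoulli background edges,
duplicated rows (some order-swapped), self-loops, non-human decoy rows and
non-protein-type decoys — every artefact the filters must handle. The
gene-set writer plants one marker-enriched set among uniform draws.

What the generator does *not* emulate: intensity-dependent missingness,
batch effects, heavy-tailed or count-valued abundances, realistic
interactome topology (hubs, communities), or hierarchically overlapping
pathway structure. Tests passing on this generator therefore demonstrate
correctness of the algorithms and calibration under the stated model, not
performance on real cohorts.

## Problem sizes and numerics

The test suite runs the full 2815-protein RFE (a few seconds) and otherwise
uses matrices of 100–500 proteins; the Monte-Carlo checks use 20 seeds for
effect recovery, 50 replicates for null FDR calibration, and 60
permutations for the RFE permutation null (whose per-permutation retention
fractions are strongly dependent across markers, so the Monte-Carlo error
is estimated from the per-permutation spread, not the binomial formula).
Exact rank-sum and hypergeometric oracles in the tests are independent
enumerations (dynamic programming over rank-sums; binomial-coefficient
tail sums). Floating-point contracts: score identity to 1e-8, oracle
agreements to relative 1e-9, BH to 1e-12.

## Known limitations

- The rank-sum exact path requires tie-free rows; zero-inflated data always
  takes the asymptotic path, which is slightly conservative at n = 30.
- Balanced-error CV with 10 cases is noisy; the one-SE rule deliberately
  biases toward fewer components.
- Affinity propagation's exemplar count is sensitive to the preference
  parameter; the median-similarity default matches common practice but is
  not canonical.
- The ORA universe default (union of sets plus input) is smaller than a
  true protein-coding background and makes p-values conservative for sets
  well covered by the collection; supply a fixed universe to mimic a
  genome-wide background.
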