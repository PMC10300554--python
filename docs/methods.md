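# Methods

This note records the models, conventions and parameter choices behind each
module, and what the synthetic generators do and deliberately do not emulate.

## Coordinate and distance conventions

All intervals are half-open `[start, end)`. The gap between two intervals is
`max(start_b - end_a, start_a - end_b, 0)`: touching or overlapping
intervals have distance 0. A point (SNP) versus an interval uses
`max(pos - end, start - pos - 1, 0)`, which is the same convention with the
point treated as the one-base interval `[pos, pos + 1)`. These definitions
are shared by feature–gene linking, locus enrichment and the distance-decayed
GWAS predictor, so a distance threshold means the same thing everywhere.

## Capture-C read processing (`capturec`)

The pipeline mirrors the standard flashed-ditag design:

- **Pair merging.** R1 and the reverse complement of R2 are merged at the
  overlap maximising the number of matched bases, requiring ≥ 10 overlapping
  bases and a mismatch density ≤ 0.25. An exact-suffix/prefix fast path
  handles the common error-free case.
- **In-silico digestion.** Merged reads are split immediately *before* each
  `GATC` occurrence, matching DpnII fragment boundaries, so each sub-read
  carries the restriction site that starts its fragment.
- **Micro-mapper.** Sub-reads are placed by exact match against a seed index
  of 20-mers over both strands. A unique placement gets MAPQ 42; multiple
  placements get MAPQ 0 and are discarded as low-quality. Sub-reads shorter
  than the seed are flagged short. A sub-read that fails to map is retried
  with a trailing ligation-junction `GATC` trimmed, rescuing reads whose
  junction falls inside the sub-read.
- **Ditag classification.** Precedence: any short sub-read → `short_subread`;
  any MAPQ-0 sub-read → `low_quality`; then fragment logic: all pieces on the
  same fragment → `self_ligation` when strands oppose, otherwise `internal`;
  adjacent fragment ids on the same chromosome → `re_ligation`; otherwise
  `valid` when the tag touches exactly one bait fragment, `bait_to_bait` when
  it touches two or more, `unbaited` when none.
- **De-duplication.** The key is the *set* of `(chrom, fragment, strand)`
  pieces, so PCR duplicates collapse regardless of read orientation.
  De-duplication is idempotent.
- **Reporter counting.** Each valid tag contributes one count per non-bait
  fragment to its bait's track, excluding fragments within ± 1 fragment of
  the bait (undigested/re-ligation shadow). Bait-to-bait tags are set aside
  and reported in QC rather than counted.
- **Summaries.** Counts can be binned onto a fixed 400 bp grid anchored at
  genome coordinate 0 (a fragment's count is assigned by its midpoint), and
  a region is scored as the median of the top decile of its bin values —
  robust to a single spike while rewarding consistent enrichment.

## Capture-C simulator (`simulate`)

Reads are drawn from a generative model whose defaults are the study
conditions used throughout the tests: a 2 Mb single-chromosome genome,
75 bp paired reads, 50 000 pairs, and artifact rates of 0.1 (self-ligation),
0.1 (re-ligation) and 0.3 (duplicates).

A valid molecule is a three-fragment ligation: a bait-fragment suffix, a
reporter-fragment prefix and a uniformly chosen bystander prefix, each
≥ 25 bp, with total length in `[75, min(130, capped piece sum)]` so that
every valid pair merges with an exact overlap of ≥ 20 bp. Reporters are
drawn with probability ∝ `(distance + 1000)^-1`, times a per-fragment
multiplier for planted interactions; this reproduces the strong proximity
decay of chromatin contact data. Truth counts increment both the reporter
and the bystander fragment, because the pipeline cannot (and should not)
distinguish them — both are genuine ligation partners of the bait.

Two design choices make *exact* truth recovery a fair target rather than an
approximation:

- the molecule-length bounds guarantee every valid pair merges; pieces of
  ≥ 25 bp on a random 2 Mb sequence map uniquely with overwhelming
  probability, and the mapper's junction-trim rescue removes the one
  systematic failure mode (a ligation `GATC` absorbed into a sub-read);
- when a newly drawn valid molecule would collide with an existing one under
  the fragment-set de-duplication key, its bystander is resampled, so the
  de-duplicated pipeline output equals the truth exactly instead of
  truth-minus-collisions.

Artifacts are generated explicitly: self-ligations join the suffix and
prefix of one fragment, re-ligations join adjacent fragments, and duplicates
re-emit a previous read pair verbatim. The simulator does not model
sequencing errors, trans contacts beyond the uniform bystander, or mapping
bias; it isolates the combinatorial bookkeeping the pipeline must get right.

## Differential chromatin states (`chromstate`)

Each sample is a per-bin state assignment over a common tiling (14 states,
state 14 = quiescent). Analysis is presence/absence per (bin, state):

- **Polymorphic bin selection.** A bin is tested only if it has ≥ 2 distinct
  states across samples and fewer than two-thirds of samples quiescent; a
  state is tested in a bin only if ≥ one-third of samples carry it. This
  focuses the test on bins where a difference is observable.
- **Per-bin test.** Fisher's exact test (two-sided) on the 2×2 table of
  state presence versus group. With 4 cases and 4 controls the fully
  separated table (4, 0) has p = 2/70 ≈ 0.0286 by hypergeometric
  enumeration, and (4,0)/(0,4) are the *only* patterns below 0.05 — so at
  this sample size a per-bin call means full separation.
- **Per-state permutation test.** The statistic is the number of tested bins
  with Fisher p < α for that state. It is recomputed under all C(8,4) = 70
  case/control relabelings (vectorised via a p-value lookup table and matrix
  products), and the empirical p is `(1 + #{labelings with a strictly
  greater count}) / 70`. Strictly-greater matters: the complement labeling
  always ties the observed one, so the attainable floor is exactly 1/70,
  never 0. A state with zero observed significant bins is reported with
  p = 1 (not assessable). A warning is emitted when fewer than 20 labelings
  exist.
- **Consensus transitions.** Per group, each bin's consensus is the modal
  state (ties to the smaller state id); a transition table crosses control
  consensus (rows) with case consensus (columns).

### State-matrix simulator

Per-bin dominant states are drawn from a quiescent-heavy prior (2% for each
of states 1–11, 10% for 12 and 13, 58% for state 14), and each sample takes
the dominant state with probability 0.95, otherwise a uniform other state.
The closed form for the chance a null (bin, state) fully separates follows
directly and gives ≈ 0.02 expected fully separated null bins per default
dataset — so roughly 98% of simulated datasets have *no* null state at the
permutation floor, which is what makes the planted-state specificity claim
testable. Planting writes the chosen state into the present group's samples
over a bin range, and *scrambles* the other group's samples in those bins to
distinct non-planted states; the scrambling prevents the displaced original
state from becoming fully separated in the opposite direction, an artifact
that would otherwise flood the floor with spurious states.

## Features and differential testing (`features`)

- **eRNA calling** keeps intergenic peaks strictly more than 3 kb from any
  coding interval that carry at least one uniquely mapped RNA read.
- **Feature–gene linking** uses promoter proximity (< 50 kb, strict) or a
  chromatin loop whose anchor overlaps strictly more than half of the
  feature; links are de-duplicated on (feature, gene, evidence).
- **Differential testing** is Welch's t on `log2(CPM + 1)` with
  Benjamini–Hochberg correction; a feature is significant when adjusted
  p < 0.05 *and* fold change (larger mean over smaller) > 1.5. On simulated
  negative-binomial null data the realised type-I rate sits near the nominal
  0.05 (validated at 500 features × 50 seeds).
- **Allelic ratios** pool alt/total read counts across individuals passing a
  per-individual depth filter (≥ 5 reads).

## Enrichment (`enrich`)

2×2 enrichment uses Fisher's exact test; the Haldane–Anscombe 0.5 correction
is applied *only* to the odds ratio and its Woolf confidence interval, never
to the p-value. GWAS SNPs are stratified into cumulative significance tiers
(all, p < 0.1, p < 5e-7, p < 5e-8; strict inequalities), and a feature class
is tested for proximity (gap ≤ window) enrichment per tier, with Bonferroni
correction across tiers and an `assessable` flag that requires all four
table margins to be nonzero. Pathway enrichment uses the hypergeometric
upper tail `sf(x - 1, N, K, n)` with exact mean/variance standardisation and
BH q-values, after intersecting everything with the analysis universe.

## Prioritization (`prioritize`)

- **Network propagation.** The adjacency matrix is column-normalised
  (isolated nodes get self-loops) and evidence vectors are L1-normalised,
  then iterated as `p ← (1 − r)·W·p + r·p0` with restart r = 0.75 to an L1
  tolerance of 1e-9. Column stochasticity conserves probability mass; on the
  two-node chain with a unit seed the fixed point is exactly (0.8, 0.2).
- **Predictors.** Eight evidence channels are supported (GWAS proximity with
  linear decay over 500 kb, eQTL and Capture-C linked genes, differential
  RNA, ATAC, eRNA and histone-mark linkage). Feature-linked channels use
  only significant features; RNA uses `−log10(adjusted p)` for all genes.
- **Combination.** Propagated channels are converted to fractional ranks
  (average ties), averaged, and scaled to a 0–5 rating.
- **Benchmarking.** AUC uses the rank formulation with half-credit for ties
  against seeded, sampled negatives; adding an informative predictor never
  lowers the mean AUC over paired seeds.
- **Pathway crosstalk.** Gene scores are ratings minus the
  `(1 − top_fraction)` rating quantile. For networks with ≤ 15 nodes the
  maximum-score connected subgraph containing the top gene is found by
  exhaustive enumeration of connected vertex subsets — greedy expansion is
  provably suboptimal when a negative-scoring hub gates access to several
  positive leaves. Above that size a greedy search with two-step bridging
  through single negative intermediates is used, which remains exact on the
  hub motif.

## Multi-omics bundle simulator

`simulate_omics_bundle` produces a coherent toy cohort: 200 genes on a
synthetic genome; 100 ATAC peaks split exactly (by rounding) into distal
(> 3 kb from coding) and non-distal; GWAS SNPs spanning all significance
tiers with the strongest hits placed near a subset of 20 designated positive
genes; loops and eQTLs linking to positives (with decoys); gamma-Poisson
(negative-binomial, dispersion 0.05) RNA and ATAC count matrices with a
4-fold change planted on positives and random genes; and a
preferential-attachment gene network (1 + m(n − 2) edges, m = 2) whose
degree-weighted sampling makes positives well-connected. Positives are
enriched — not deterministic — in every channel, so prioritization AUCs are
realistically below 1.

## Reproducibility

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawn keys, one stream per generator component
(reference, Capture-C library, states, omics), so components can be re-drawn
independently without correlated artifacts. `scripts/acceptance.py` derives
per-section sub-seeds the same way and writes the headline quantities to
JSON; `tests/test_acceptance.py` asserts each guarantee at full problem size
with explicit time budgets.
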