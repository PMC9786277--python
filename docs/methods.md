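# Methods

## Pipeline model

The package implements a deterministic prioritization pipeline, not a
fitted statistical model: every stage is a pure function of its input
tables and thresholds, so a run is exactly reproducible from the config
file alone.

**Variant selection.** An association row survives when
*p* ≤ `p_max` (inclusive; default 10⁻⁵) and OR > `or_min` (exclusive;
default 1). Rows without a reported odds ratio are dropped and counted:
the selection rule cannot be evaluated without the effect size.
Deduplication keeps the first row per rsID, unions its mapped-gene cells
and accumulates row multiplicity (`n_hits`) so catalog-hit counts survive
deduplication. LD expansion is a single hop: a proxy is admitted when its
index SNP is already selected and r² passes the cut. The default is the
conventional inclusive r² ≥ 0.8 (`r2_inclusive=True`); a strict > 0.8 cut
is a config switch. Proxies of proxies are never chased — transitive
chaining would make the expansion depend on table order and blow up the
set with weak composite LD.

**Gene summaries.** The per-gene hit table keeps multi-gene mapped cells
("SLC7A8, CEBPE") as single group labels rather than exploding them, so
its shape matches how association catalogs print such rows; totals count
distinct SNPs and summed hits. Rows with no known mapped gene are grouped
under a "Not known genes" label and excluded from the gene pool (their
count is reported).

**Six-criterion scoring.** Evidence is presence-based except KEGG:
missense and GO criteria are satisfied by at least one annotation of the
right kind (GO is per-namespace: BP, CC, MF), the cis-eQTL criterion by a
significant record in the configured tissue (default "whole blood",
matched case-insensitively), and the KEGG criterion by membership in at
least one pathway set that is *enriched* in the gene list. GO presence
(not GO enrichment) is deliberate: observed coverage as high as ~80% of a
candidate list is characteristic of annotation presence, not of
per-namespace significance. The score is the criterion count (0–6) and
genes with score ≥ `score_threshold` (default 2) are classified as
biological risk genes.

**Enrichment statistic.** The EASE score: for an overlap of k list genes
with a K-gene set in an N-gene background and an n-gene list,
p = P(X ≥ k−1) with X ~ Hypergeometric(N, K, n); k ≤ 1 gives exactly 1.
This is the conservative default of the DAVID-style annotation tools this
stage stands in for; plain one-tailed Fisher (P(X ≥ k)) is available as
`method="fisher"`. Sets are filtered at `p_cut` (default 0.05) with no
multiple-testing correction — a single-threshold filter, as typical
interactive enrichment use reports. p-values are computed with
`scipy.stats.hypergeom`; the test suite pins them to exhaustive
`math.comb` enumeration to 10⁻¹² for all N ≤ 25.

**Network expansion.** Candidate interactors are non-seed genes adjacent
to ≥ 1 seed via an edge with confidence ≥ `min_confidence` (default 0.4,
the customary "medium confidence" cut; the right value is data-dependent
and therefore config). They are ranked by (max edge confidence to any
seed, then sum of qualifying confidences, then gene symbol) and the top
`max_interactors` (default 50) are appended. The max-confidence-first key
mimics how interaction browsers order first-shell partners; the explicit
ranking makes the output invariant under edge-list permutation. The
default budget of 50 interactors over a 42-gene seed set yields the
92-gene expanded list the downstream stages assume.

**Druggability.** "Pharmacological action known" is a boolean field,
"human efficacy" an organism string (must equal "Humans",
case-insensitive), and development status a set drawn from
{approved, investigational, experimental, other}; the default allowed set
excludes bare "other". Drug names are trimmed and case-folded for the
distinct-drug count only; display names are preserved.

**Connectivity ranking.** Connectivity scores are inputs on their native
−100…100 scale; the package never recomputes or rescales them (the
transcriptome-signature computation behind them is out of scope). The
comparator drug is removed from the candidates if present, the
strong-positive threshold is exclusive (score > +80), and ties are broken
by drug name.

## Synthetic data generator

`genodrug.simulate` emulates every input table with planted truth. Its
defaults are the study conditions: 74 surviving variants over 57 genes
with hit inflation (128−74)/74 ≈ 0.73 extra rows per variant (~128
catalog rows); criterion probabilities equal to the published marginals
(7/57, 12/57, 30/57, 36/57, 47/57, 5/57 for missense, cis-eQTL, BP, CC,
MF, KEGG); a preferential-attachment (scale-free) interaction network of
400 non-seed genes with a tunable attachment exponent (1 = linear);
37 drugs with a druggable fraction of 15/92; and a comparator-correlation
parameter interpreted as the per-candidate probability of a strong
positive (> +80), default 5/37 so about five candidates pass, as in the
study the defaults emulate.

Recoverability is engineered, not hoped for:

- decoy association rows each fail exactly one predicate; decoy proxies
  sit below the LD cut or hang off rejected index SNPs;
- planted interactors receive seed-edges with confidence in (0.85, 0.99)
  while every other edge is ≤ 0.80, so the top-50 shell is exactly the
  planted set;
- criterion memberships are drawn independently per gene (only marginals
  are specified by the emulated conditions; independence makes recovery
  provable). The KEGG column is realized as one pathway set containing
  exactly the planted member genes over a ~500-gene background; because
  EASE cannot reach p ≤ 0.05 for overlaps ≤ 2 at that background size,
  the column is redrawn (bounded rejection, deterministic per seed) until
  the planted set is empty or recoverable, falling back to all-false;
- strong candidates get scores in (80.5, 99), the rest in (−99, 79), so
  the exclusive +80 cut separates them with margin.

What the generator does **not** emulate: realistic LD block structure
(proxies are independent rows, not haplotype blocks), GO DAG topology
(terms are flat tokens), correlated criteria, drug polypharmacology
beyond random multi-target assignment, and the distributional shape of
real connectivity scores. Passing tests therefore demonstrate that the
pipeline's logic is exact on tables with known truth — not that the
thresholds are optimal for any particular real dataset.

Determinism: all draws come from `numpy.random.default_rng` seeded by
`(seed, stream)` pairs, floats are serialized via `repr`, and written
bundles are byte-identical across runs and output directories for the
same seed.

## Numerical and design choices

- Percentages are rounded half-up to one decimal (via `decimal.Decimal`),
  matching how such tables are conventionally printed; banker's rounding
  would flip boundary cases.
- The packaged 57-gene evidence fixture realizes the published row and
  column marginals simultaneously with a Gale–Ryser greedy (each gene
  takes its criteria from the columns with most remaining capacity). The
  BP/CC/MF counts 30/36/47 are the unique counts in 0..57 whose
  percentages round to the published 52.6/63.2/82.5 (exhaustive scan,
  asserted in tests). The score histogram beyond the published
  0:4, 1:11, 3:19 and the single score-5 gene is pinned by the marginal
  total (137 points): 2:12 and 4:10. Which five criteria the top gene
  fulfils is not published; the greedy assigns it the five
  largest-capacity columns (MF, CC, BP, cis-eQTL, missense).
- Empty mapped-gene cells are allowed on association records (they occur
  in real catalogs); they contribute to an "unknown" counter, never to
  the gene pool.
- `write_table` needs an explicit `format_name` only for empty tables,
  where the dialect cannot be inferred from the record type.
- Degenerate inputs are defined, not errors: an empty association table
  runs the whole pipeline to all-zero counts with exit 0; an empty edge
  list returns the seeds unchanged with a warning; an empty seed set
  skips expansion.

## Problem sizes

The test suite and acceptance script run at the study scale (57 genes,
74 variants, ~400-node networks) or smaller: oracle comparisons use
≤ 25-element random instances over 1,000 trials, enrichment enumeration
covers all backgrounds N ≤ 25, and end-to-end recovery uses 20 seeds at
200 network genes. These sizes were chosen because the pipeline's
correctness properties are scale-free — every stage is an exact set
operation, so small instances exercise the same code paths exhaustively.

## Known limitations

- Gene symbols are opaque identifiers; no alias/ortholog resolution.
- Single-tissue eQTL gate; the significance call is upstream of this
  package.
- No multiple-testing correction across pathway sets (by design, see
  above).
- The connectivity stage consumes scores; it cannot detect upstream
  signature-level artifacts (cell line, dose, time disaggregation).
- The clinical-trial review step of the workflow this package automates
  is a manual literature task and is out of scope.
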