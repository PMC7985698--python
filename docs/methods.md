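# Methods

## The analysis this package implements

Carbon catabolite repression (CCR) in filamentous fungi is mediated by the
C2H2 zinc-finger repressor CreA (CRE1 in some species), which binds
5'-SYGGRG-3' sites — preferentially two adjacent sites — in the upstream
regulatory region of its target genes.  A standard way to characterize the
CreA regulon is: (i) define differentially expressed genes (DEGs) between a
*creA* deletion strain and its reference; (ii) extract fixed-length promoter
windows for all genes; (iii) scan promoters on both strands for the
repressor motif, its sub-motifs (5'-SYGGGG-3', 5'-SYGGAG-3'), and the binding
motifs of pathway-specific activators (XlnR, AraR, RhaR, GaaR, AmyR);
(iv) test whether motif presence — single sites or adjacent pairs — is
enriched in the DEG set relative to the genome background; (v) test GO-term
enrichment; and (vi) compare regulons across species through ortholog
clusters.  `creascan` implements each of these stages as a reusable,
separately testable library function, plus a synthetic-data generator so the
whole pipeline can be validated against planted ground truth without any
genome download.

## Promoter extraction

* Window length: 1000 bp upstream of the annotated gene start (default,
  configurable).  The anchor is the gene-level start coordinate; transcript
  isoforms and per-CDS anchoring are out of scope.
* Plus-strand genes take `genome[start-L, start)`; minus-strand genes take
  the reverse complement of `genome[end, end+L)`.  Sequences are written
  5'→3' with the base adjacent to the coding start last, so a shorter window
  is always a suffix of a longer one.
* Windows clipped by a contig edge are kept and flagged `truncated`; genes
  flush against the edge (empty window) are skipped with a logged warning.
  Overlap with upstream genes is *not* trimmed — the full window is used,
  which is the simplest reproducible rule; users who need trimming can
  filter on the flag and source coordinates.
* IUPAC ambiguity codes other than N in genome input are degraded to N with
  a warning; N never satisfies an informative motif position, so ambiguous
  regions cannot create spurious sites.

## Motif model and scanning

A motif is a named IUPAC string; bracket classes (`[AG]` → R) and gap syntax
(`N{8}` → eight N positions) are normalized at parse time.  Matching
semantics: a pattern N matches any sequence base including N ("don't care");
every other pattern position requires one of its concrete bases — a sequence
N never satisfies it.  Scanning tests every offset on the forward pattern
(+ strand) and on the reverse-complemented pattern (− strand) of the same
promoter string; overlapping hits are all reported, and a palindromic window
yields one hit per strand.  Internally each pattern compiles to a regular
expression wrapped in a zero-width lookahead, which gives C-speed scanning
while preserving overlap semantics; the test suite checks equivalence
against a naive expand-and-slide oracle on thousands of random sequences.

Adjacent pairs — the proxy for the tandem repressor sites CreA prefers — are
unordered pairs of distinct matches (distinct (start, strand)) whose
start-to-start distance is ≤ 100 bp (inclusive, configurable).  Strand
combination is unrestricted and overlapping matches may pair; these are the
simplest consistent conventions and are stated here so users can tighten
them.  Pair counts are monotone in the window by construction.

## Enrichment statistics

* **Fisher's exact test (two-sided)** on the disjoint 2×2 table (set genes
  with/without the feature vs background-minus-set genes with/without).
  The p-value follows the ≤-probability rule: every table with the observed
  margins whose hypergeometric probability is at most that of the observed
  table (relative tolerance 1e-7 on the comparison) contributes.  For grand
  totals ≤ 2000 the computation is exact integer arithmetic (binomial-
  coefficient weights, rational division); larger tables switch to a
  log-space evaluation via log-gamma and logsumexp.  The reported odds ratio
  is the sample odds ratio a·d/(b·c), ∞ when b·c = 0 with a·d > 0, NaN when
  both products vanish.
* **Reported proportions**: the test uses the disjoint table, but the
  background proportion and the percent increase
  (100·(prop_set/prop_bg − 1)) are computed against the *full-genome*
  proportion (set included), so printed percentages are directly comparable
  to whole-genome occurrence figures.  Percent increases always use
  unrounded proportions.
* **GO enrichment** uses the hypergeometric upper tail
  P(X ≥ k | N, K, n), evaluated in log space via `scipy`.  Gene→term
  annotations are first closed over the ancestor relation from a child→parent
  table (cycles are detected and reported); terms with no annotated gene in
  the query set are not tested, and testing can be restricted to a supplied
  term list (e.g. a GO slim).
* **Multiple testing**: Benjamini–Hochberg within each analysis family (one
  motif-enrichment run, one GO run, one co-occurrence report); both raw and
  adjusted p are emitted.

## DEG filtering and regulon assembly

Significant DEGs are defined by fold change ≥ 4 and adjusted p < 0.01:
interpreted as |log2FC| ≥ 2 inclusive and padj strictly < 0.01, the only
reading consistent with symmetric up/down sets.  Rows with missing padj are
excluded; a non-finite log2FC is an error.  The differential-expression
model itself is not reimplemented — any table with gene_id/log2fc/padj
columns is accepted.  Regulons combine per-condition up/down sets with
explicit `direction` (up/down/both) and `combine` (union/intersection)
parameters rather than hard-coding any particular published set.

## Cross-species comparison

The unit of comparison is the ortholog cluster: a species "shares" a target
if any of its regulon genes maps to the cluster.  For every non-empty
species combination the exact count of clusters hit by precisely that
combination is reported (UpSet semantics), together with per-species totals
and the percent of each species' clusters shared by more than one species.
Cluster inference (OrthoMCL) is an input contract, not reimplemented.

## Synthetic data: what it emulates and what it does not

Backgrounds are i.i.d. bases with P(G)=P(C)=gc/2 (default gc = 0.5,
promoter length 1000 bp, matching the real pipeline's window).  Planting
overwrites background bases with a concrete instance drawn uniformly from
the motif's IUPAC expansion, on a uniform strand, at a uniform valid offset;
pair mode writes two instances with start distance uniform on
[motif length, max_gap] (non-overlapping by default).  Every planted site is
guaranteed to re-scan as a match.  DE tables draw true effects as
lfc_magnitude + |N(0, 0.5)| with padj ~ U[0, 0.01) — a shifted half-normal,
so every true effect is at least the stated magnitude and is recovered by
thresholding by construction — and null genes as log2fc ~ N(0, 0.3),
padj ~ U[0, 1).  Ortholog clusters include each species independently with
probability 1 − orphan_rate.

The generator deliberately omits dinucleotide composition, nucleosome
positioning signals, promoter-length variation, correlated expression noise
and read-level count simulation.  Passing tests therefore demonstrate the
*algorithmic* correctness and statistical calibration of the pipeline under
an i.i.d. background, not that any particular biological genome satisfies
those assumptions.

A practical consequence of the i.i.d. model worth knowing: a 6-bp degenerate
motif like SYGGGG has per-window probability 1/1024 per strand at gc = 0.5,
so ≈ 86% of random 1000-bp promoters carry at least one spontaneous hit —
single-site presence of short motifs is nearly saturated, exactly as in real
genomes (where ~matching fractions of all promoters carry such sites).
Planted-recovery scenarios therefore use the longest ungapped built-in motif
(the AraR site CGG[AGT]TAA[AT], spontaneous presence ≈ 0.17) as the marker,
so that presence/absence remains informative about planting; the adjacent-
pair feature serves the same purpose for the short repressor motif in real
analyses.

## Problem sizes and numerical choices

Validation runs use 500 + 500 genes × 1000 bp for enrichment-recovery
scenarios (20 effect seeds, 200 null seeds), 1000 random 200-bp sequences ×
8 motifs for scanner–oracle equivalence, every 2×2 table with grand total
≤ 60 (635,375 tables) for Fisher exactness, 1000-gene DE tables for filter
recovery, and 5-species maps of up to 500 clusters for intersection counts
— sizes at which the exact oracles remain feasible while binomial standard
errors are small enough for the stated tolerances.  Deterministic tie-break
rules: scan output sorted by (start, strand); presence tables sorted by
(gene_id, motif); enrichment tables keep configured motif order (co-
occurrence) or sorted motif/term order.  Degenerate inputs: single-point
Fisher supports give p = 1; empty promoters give zero counts; k = 0 terms
are untested; empty backgrounds are errors.

## Known limitations

* Gene-level promoter anchoring only; no transcript isoforms, no repeat
  masking, no trimming at upstream genes.
* Position-weight-matrix scoring and background-model match significance are
  out of scope — motif presence is binary.
* GO parsing expects a prepared child→parent table, not OBO files.
* The Fisher integer path is exact but switches to floating log-space above
  a grand total of 2000; agreement there is ~1e-12 relative, not exact.
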