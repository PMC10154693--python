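# Methods

This note records the models, conventions and numerical choices behind
tr1seq, in the spirit of a package methods appendix: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and do
not demonstrate.

## Clonotype classification

### The recombinome

TCR rearrangements delete germline ends and insert non-templated
nucleotides, so a read or assembled contig spanning the junction aligns
poorly to any single germline segment. The recombinome sidesteps this:
for each chain, every V×J combination is concatenated as
`V + N^s + J`, with a spacer of `s = 50` neutral `N` characters. The
spacer length equals the junction-length cap used at contig assembly
(50 nt), so any plausible junction fits inside the neutral region and
never distorts the score. Entry offsets (`v_end`, `j_start`) are
0-based half-open throughout.

### Alignment model

Contigs are aligned with an affine-gap Gotoh scheme:

* match +1, mismatch −1; gap of length L costs 2 + L (open −2 charged
  once, extend −1 per base);
* the contig is global (every base accounted for), the entry has free
  end gaps (leading/trailing germline can be skipped);
* `N` is neutral: substitutions against `N` score 0 in both directions,
  and **deleting an `N` position is free**. The second rule extends the
  neutrality of the spacer to the gap states — without it every entry
  would pay an O(spacer) deletion penalty for the part of the spacer its
  junction does not cover, systematically penalizing short junctions.
  One consequence: a deletion run that enters at an `N` position is not
  charged the open penalty even if it continues into germline sequence;
  the spacer is transparent to the deletion state.
* both orientations are scored and the better kept (forward wins ties);
  ties across entries break by longest V match, then lexicographically
  smallest `Vname|Jname` — fully deterministic.

The batch scorer runs the recurrence column-by-column over entry
positions, vectorized across contigs and entries simultaneously; the
insertion state is resolved per column with a prefix-max scan (exactly
one insertion run can end in a column, so the scan is exact), and the
V+spacer prefix columns shared by all entries of one V are computed
once. A single-pair variant with full matrices and traceback recovers
contig coordinates for the winning entry. The two paths are
algebraically identical, and a test asserts score equality.

`min_score` defaults to 30 — the length of the shortest admissible V
segment. A true contig scores near |V|+|J| (≳ 130 under the default
germline); a random 300-mer scores far below zero under contig-global
alignment because every base must be matched (expected −0.5/base) or
inserted (−1/base), so the threshold separates the two regimes by a
wide margin rather than sitting near either.

### Identifiers, CDR3 and productivity

A chain is identified as `V-junction-J`, the junction being
`contig[v_match.end : j_match.start)` (possibly empty). A cell's paired
identifier is the lexicographically sorted tuple of all productive
per-chain identifiers, so dual-α cells form their own clonotypes; cells
with more than two productive chains at one locus are flagged ambiguous
and excluded from grouping by default. Identifiers never depend on
scores or orientation.

CDR3 runs from the conserved V cysteine codon (position 1) through the
first J phenylalanine/tryptophan codon, in the frame fixed by the V. A
span is unproductive when the two anchors are out of frame or a stop
codon intervenes; translation uses the standard codon table. CDR3β
positions P2/P3 — where acidic residues mediate recognition of the
insulin B:12-20 register — are the two residues after the cysteine.

## Repertoire statistics

* **Usage skewing.** Element usage is counted over chains, not cells
  (dual-α cells contribute two α chains), which is why chain totals can
  exceed cell counts. The chi-square runs on the 2×k used/not-used
  table without continuity correction (the printed counts are
  large-sample); for two pools with any expected count below 5 Fisher's
  exact test substitutes. Scaling every count by c scales the statistic
  by c — the test detects proportions, not magnitudes.
* **Motif fraction.** The D/E-at-P2/P3 fraction is computed over
  distinct clonotypes, not cells, so clonal expansions do not inflate
  it. CDR3s shorter than three residues leave the denominator.
* **Positional enrichment.** Entry (p, a) is the pool frequency of
  residue a at position p divided by its background frequency, the
  background defaulting to all analyzed pools combined (a per-pool or
  uniform background is selectable). Short CDR3s contribute only to the
  positions they cover; zero-background entries are NaN.
* **SEM of a singleton is defined as 0** (ddof = 1 otherwise).

## Expression analysis

* **QC**: strictly more than 300 genes detected and strictly below 10%
  mitochondrial content; both boundary cells are excluded. The filter is
  idempotent.
* **Normalization**: per-cell scaling to 10,000 counts then log2(1+x).
  Normalization feeds clustering only; differential expression always
  runs on raw counts with offsets.
* **Clustering** operates on the PCA embedding (default 20 components)
  with k-means (k = 3, 10 restarts, fixed seed); t-SNE is considered a
  display device, not a quantitative surface. Raw k-means labels are
  canonicalized by size (cluster 0 largest); since k-means indices carry
  no biology, the pipeline additionally maps the three clusters onto
  states — 0 Tconv-like, 1 TFH-like, 2 TR1-like — by mean z-scored
  signature expression (highest TR1 score → 2; higher TFH score of the
  remainder → 1). All cluster-indexed outputs downstream use the state
  labels.
* **Differential expression** fits, per gene, an NB2 model
  (variance μ + μ²/θ) with a group indicator and a log library-size
  offset. Group means are profiled by vectorized Newton iteration;
  dispersion is estimated by maximizing the Cox–Reid-adjusted profile
  likelihood on log θ (numeric second-order steps, clipped to
  [10⁻³, 10⁶]) with a method-of-moments start and fallback — the CR
  adjustment (−½ log det of the expected information, i.e. the
  per-group sums of working weights) removes most of the downward bias
  of plug-in dispersion at these group sizes, which is what keeps the
  likelihood-ratio test calibrated (the null simulation lands within
  the binomial band around 0.05). The reported fold-change is
  log2((m_A + pc)/(m_B + pc)) on the normalized scale with pseudo-count
  pc = 1/n_cells; significance requires |log₂FC| ≥ 2 **and** BH-adjusted
  p ≤ 0.01. Swapping groups negates log FC and preserves p-values.
  All-zero genes are flagged degenerate with p = 1. A statsmodels
  NegativeBinomial fit per gene serves as the independent oracle in the
  test suite; it is never the implementation (it would be ~50× slower
  across thousands of genes).
* **Fold-change sign convention**: log FC = log2(group_A / group_B)
  with group A named first in the call, applied uniformly; published
  tables sometimes flip this sign between tables, so the convention is
  fixed here once.
* **Concordance** between two comparisons: Pearson r over paired log
  FCs of genes significant in at least one comparison, plus the
  fraction with equal sign and |Δlog₂FC| ≤ 1.
* **Signature overlap**: per signature and cluster, the percentage of
  genes significantly upregulated there; the chi-square (Fisher
  fallback) tests signature membership against the cluster of specific
  upregulation (genes up in exactly one cluster).

## Lineage sharing

Only repeated clonotypes (size > 1) enter the clonotype × cluster
table. Each is classified by nonzero membership in the TFH-like and
TR1-like clusters (shared / only 1 / only 2); clonotypes with cells only
in cluster 0 are reported as excluded. The proportionality statement —
clonotype splits parallel cluster sizes — has no published test behind
it, so the package supplies an explicit surrogate: a two-sided binomial
test per clonotype of its cluster-2 share against n₂/(n₁+n₂), cluster-0
cells ignored, summarized as the fraction of clonotypes with p ≥ 0.05.

## Reporter assay

SI = (RLU_sample/RLU_unstim) ÷ (RLU_negctrl/RLU_negctrl,unstim), in
that order; replicates are pooled before lysis, hence before
normalization. SI is scale-invariant and the negative control is 1 by
construction. The reactivity threshold (default 3.0) is a package
convention — the underlying summaries are qualitative — and raising it
can only remove positives.

## Synthetic data

The generators define the study conditions every benchmark runs under.

**Repertoire.** Five pools (Tconv, R1, R2, R3, BDC) with cell counts
181/144/94/155/190 — the sequenced-TCR counts for the tetramer+ pools,
QC-passing cell counts otherwise. Clone sizes are geometric with
per-pool parameter p (mean size 1/p): 0.8 for R1 (~114 clonotypes in
144 cells), 0.37 / 0.24 for R2 / R3 (matching ~13 and ~9 expected
singletons via E[singletons] ≈ n·p²), 0.9 / 0.3 for Tconv / BDC. V/J
usage weights hit configured expected fractions for named elements
exactly (uniform otherwise); the defaults encode the reported chain
fractions of TRAV5D-4, TRAJ18 and TRBV1 per pool. Junctions are drawn
in whole sense codons (2–16 codons, truncated geometric, ≤ 48 nt under
the 50-nt cap), so chains are productive by construction: the V
cysteine and J F/W anchors stay in frame and no stop can intervene.
Nucleotide-resolution junction lengths and unproductive rearrangements
are therefore not modeled. The charged-CDR3β motif is pinned per
clonotype with exactly the configured probability (forced or suppressed
at P2/P3), defaulting to the reported clonotype fractions
0.372/0.101/0.512 for R1/R2/R3 and a neutral 0.15/0.20 for Tconv/BDC.
Two mechanisms couple pools: a low-avidity leak copies each repeated R1
clonotype into the Tconv gate with probability 0.4 (~10 shared
clonotypes), and two R3 clones reuse R2 identities (register-shifting
cross-reactivity). Distinct clones are guaranteed distinct paired
identifiers, so with zero error rate the clonal partition is exactly
the string-equality partition — the ARI = 1 benchmark tests the
analysis, not a lucky absence of collisions. Sequencing noise is
substitution-only at a configurable per-base rate; indels, chimeras and
doublets are not simulated, so the benchmarks bound performance under
clean assembly, not assembler failure modes.

**Expression.** Counts are gamma-Poisson (NB) with variance μ + μ²/θ,
shared θ = 2 by default, lognormal baseline means (median 2 counts) and
lognormal library factors (σ = 0.3). Signature genes carry planted
log2 effects per cluster: the TR1 column uses the reported tetramer+
vs Tconv magnitudes with the sign the biology dictates (cytokine and
co-inhibitory genes up, naive/circulating markers down); the TFH column
puts the TFH hallmark genes (Cxcr5, Il4, Tox2, Cxcr4, Nfia, Bcl6)
strictly above their TR1-like level and attenuates the remaining TR1
effects to 0.3× (an intermediate state). Mitochondrial fraction is
Beta(2, 48) (mean 4%), independent of cluster and truncated below the
10% QC cutoff for healthy cells; planted QC failures (5% of cells by
default) get either mito ≥ 10% or a 100-fold collapsed library, so the
QC filter's recovery can be asserted exactly. Real data's gene–gene
correlation, zero-inflation beyond NB, batch effects and
cluster-dependent library sizes are not emulated; passing benchmarks
show the statistics behave as designed under their own model, not that
real cluster percentages would reproduce.

## Benchmarks and problem sizes

The test suite and the acceptance script use 500-cell repertoires for
partition/junction recovery, 1,000 contigs for the brute-force
alignment agreement check (oracle: Biopython PairwiseAligner with the
same substitution scheme and free entry end gaps; agreement is on the
chosen V/J pair, ≥ 99%, discrepancies confined to near-ties of the gap
models), a 5,000-gene / 100 + 100-cell null for DE calibration, a
300-cell three-cluster benchmark (30 genes at |log₂FC| = 2) for
clustering recovery, and one full-scale default study run (764 cells)
for the structural quantities. These sizes give the stochastic checks
comfortable binomial margins while a full run stays in minutes.

## Known limitations

* The recombinome approach cannot sub-assign the β D segment inside the
  junction, by design.
* Alignment assumes substitution-dominated noise; contigs with large
  indels inside V or J will lose junction-boundary precision even when
  the V/J assignment is right.
* The NB test assumes a common dispersion per gene across groups and
  no gene–gene dependence; p-values are asymptotic (LRT, df = 1).
* Signature-based cluster-state mapping presumes the three expected
  states are present; with k ≠ 3 the raw size-ordered labels are kept.
* Deposited-data quantities that depend on the study's raw reads or
  supplementary tables (exact cluster percentages, per-clonotype
  tables) are outside what the synthetic conditions can pin down; the
  package reproduces their structure and the printed-count statistics.
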