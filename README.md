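# tr1seq

Single-cell TCR clonotype and transcriptome analysis of
pMHCII-nanomedicine-induced regulatory T cells.

Nanoparticles coated with peptide–MHC class II (pMHCII) complexes expand
cognate CD4+ T cells in vivo and re-program them into IL-10-producing
T-regulatory type 1 (TR1) cells that co-exist with T-follicular-helper
(TFH)-like precursors. Characterizing that response from paired
single-cell TCR-seq and scRNA-seq data requires a chain of analyses that
this package implements as a tested, reusable pipeline:

- **Clonotype classification against a recombinome.** For each TCR chain
  a reference is built holding every germline V×J combination as
  `V + N···N + J` (a neutral spacer of 50 `N`s separates the segments so
  a contig spanning any junction aligns onto one entry). Each assembled
  contig is aligned semi-globally (contig global, entry ends free;
  match +1, mismatch −1, gap open −2, extend −1; `N` neutral), the
  junctional nucleotides between the V match end and J match start are
  extracted, and the chain is identified as `V-junction-J`. Cells with
  identical sorted per-chain identifiers on both chains form one
  clonotype.
- **Repertoire statistics.** Clonal size distributions, clonotype
  sharing between sorted pools, V/J element usage with a Pearson
  chi-square test of skewing (2×k used/not-used table, Fisher's exact
  fallback), CDR3 length summaries (mean ± SEM), positional residue
  enrichment over the first six CDR3 residues (P1 = conserved cysteine),
  and the fraction of clonotypes carrying Asp/Glu at CDR3β P2/P3.
- **Expression analysis.** QC (cells with >300 genes detected and <10%
  mitochondrial content), library-size log-normalization, PCA + k-means
  clustering (k = 3: Tconv-like, TFH-like, TR1-like), and per-gene
  negative-binomial differential expression — NB2 regression with a
  group indicator and library-size offset, likelihood-ratio p-values,
  Benjamini–Hochberg FDR, significance when |log₂FC| ≥ 2 and adjusted
  p ≤ 0.01 — plus log-fold-change concordance between comparisons and
  TFH/TR1 signature–cluster overlap with a chi-square test.
- **Lineage sharing.** Repeated clonotypes cross-tabulated against
  expression clusters, the shared / only-TFH / only-TR1 breakdown, and a
  per-clonotype binomial test of whether each clonotype's split between
  the two states parallels the cluster sizes.
- **Reporter assay.** Luciferase stimulation indexes,
  `SI = (RLU_sample/RLU_unstim) / (RLU_negctrl/RLU_negctrl,unstim)`, and
  threshold-based reactivity patterns.
- **Synthetic data generators.** First-class, tested simulators for
  germline references, oligoclonal paired-chain repertoires (skewed V/J
  usage, controllable charged-CDR3β motifs, low-avidity leak into the
  tetramer-negative gate) and NB count matrices with planted TFH/TR1
  signatures, so every stage is verifiable end to end without any
  download.

## Worked example

```python
import tr1seq as t

germline = t.generate_germline_reference(seed=0)
cfg = t.RepertoireConfig(n_cells={"Tconv": 60, "R1": 60, "R2": 40, "R3": 40})
truth = t.simulate_repertoire(germline, cfg, seed=1)
recombinome = t.build_recombinome(germline)

cells = t.call_clonotypes(
    {cid: truth.contigs_of(cid) for cid in truth.cells.cell_id}, recombinome
)
pool_of = truth.cells.set_index("cell_id")["pool"]
groups = {
    pool: t.group_clonotypes([c for c in cells if pool_of[c.cell_id] == pool])
    for pool in ("Tconv", "R1", "R2", "R3")
}
for pool, gs in groups.items():
    print(f"{pool}: {len(gs)} clonotypes in {sum(g.size for g in gs)} cells")
print("R1 clonotypes also in the tetramer-negative gate:",
      len(t.shared_clonotypes(groups["R1"], groups["Tconv"])))

betas = {
    call.identifier: call.cdr3_aa
    for c in cells if pool_of[c.cell_id] == "R1"
    for call in c.calls if call.chain == "beta" and call.cdr3_aa
}
frac = t.charged_p2p3_fraction(list(betas.values()))
print(f"R1 clonotypes with D/E at CDR3beta P2-P3: {100 * frac:.1f}%")
```

prints

```
Tconv: 59 clonotypes in 67 cells
R1: 46 clonotypes in 60 cells
R2: 15 clonotypes in 40 cells
R3: 11 clonotypes in 40 cells
R1 clonotypes also in the tetramer-negative gate: 5
R1 clonotypes with D/E at CDR3beta P2-P3: 37.0%
```

The register-1 (R1) pool is mostly unique while R2/R3 are strongly
clonal; five repeated R1 clonotypes also surface in the
tetramer-negative gate (the simulated low-avidity leak), and 37% of R1
CDR3β clonotypes carry an acidic residue at position 2 or 3 — the motif
associated with recognition of the insulin B:12-20 register.

A one-command run of the whole pipeline on simulated inputs:

```sh
tr1seq run-all --seed 0 --out out/
```

writes clonotype/DE/sharing tables, a JSON report and a checksum
manifest. `tr1seq simulate` writes a plain-text fixture bundle, and
`call-clonotypes`, `repertoire-stats`, `expression`, `lineage` and
`assay` run the individual stages on files.

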