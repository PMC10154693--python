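"""End-to-end pipeline driver.

Runs simulation (or file loading), clonotype calling, repertoire
statistics, expression QC/clustering/differential expression and
lineage-sharing analysis, writing every artifact plus a JSON report and
a checksum manifest into the output directory. Fully deterministic for
a given seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as tio
from .align import AlignmentScoring, DEFAULT_MIN_SCORE, DEFAULT_SCORING
from .clonotypes import (
    CellClonotype,
    call_clonotypes,
    clonotype_table,
    group_clonotypes,
)
from .errors import ParameterError, Tr1seqError
from .expression import (
    cluster_cells,
    de_negative_binomial,
    identify_cluster_states,
    logfc_concordance,
    normalize_log,
    qc_filter,
    signature_cluster_overlap,
)
from .germline import generate_germline_reference, germline_from_fasta
from .recombinome import DEFAULT_SPACER_LEN, build_recombinome
from .repstats import (
    charged_p2p3_fraction,
    chi_square_independence,
    cdr3_length_summary,
    clonal_size_distribution,
    positional_residue_enrichment,
    shared_clonotypes,
    vj_usage,
)
from .sharing import clonotype_cluster_table, proportionality_check, sharing_summary
from .sim_expression import ExpressionConfig, simulate_expression
from .sim_repertoire import RepertoireConfig, simulate_repertoire
from .signatures import tfh_gene_set, tr1_gene_set

log = logging.getLogger("tr1seq")

FOCAL_ELEMENTS = (
    ("TRAV5D-4", "alpha", "V"),
    ("TRAJ18", "alpha", "J"),
    ("TRBV1", "beta", "V"),
)


@dataclass
class PipelineConfig:
    """Paths, parameters and the global seed for one pipeline run."""

    out_dir: str = "tr1seq_out"
    seed: int = 0
    # input paths; when germline/contigs are None the pipeline simulates
    germline_fasta: str | None = None
    contigs_fasta: str | None = None
    counts_mtx: str | None = None
    genes_tsv: str | None = None
    barcodes_tsv: str | None = None
    metadata_tsv: str | None = None
    # stage parameters
    spacer_len: int = DEFAULT_SPACER_LEN
    min_score: float = DEFAULT_MIN_SCORE
    k: int = 3
    n_pcs: int = 20
    enrichment_background: str = "combined"
    concordance_band: float = 1.0
    repertoire: RepertoireConfig = field(default_factory=RepertoireConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    scoring: AlignmentScoring = DEFAULT_SCORING

    def validate(self) -> None:
        if self.seed < 0:
            raise ParameterError("seed must be a non-negative integer")
        simulating = self.contigs_fasta is None
        if not simulating:
            paths = [self.germline_fasta, self.contigs_fasta, self.metadata_tsv]
            if self.counts_mtx is not None:
                paths += [self.counts_mtx, self.genes_tsv, self.barcodes_tsv]
            for p in paths:
                if p is None or not Path(p).exists():
                    raise ParameterError(f"configured input path missing: {p}")
        self.repertoire.validate()
        self.expression.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        rep = RepertoireConfig(**data.pop("repertoire", {}))
        expr = ExpressionConfig(**data.pop("expression", {}))
        return cls(repertoire=rep, expression=expr, **data)


class StageFailure(Tr1seqError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageFailure(name, exc) from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return result

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the JSON-serializable report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    report: dict = {"seed": config.seed, "parameters": {"k": config.k, "n_pcs": config.n_pcs}}
    rng_seed = int(config.seed)
    log.info("seed=%d out=%s", rng_seed, out)

    # ---------------- inputs (simulate or load)
    @_stage("inputs")
    def load_inputs():
        if config.contigs_fasta is None:
            germline = generate_germline_reference(seed=rng_seed)
            truth = simulate_repertoire(germline, config.repertoire, seed=rng_seed + 1)
            cluster_of = truth.cells.set_index("cell_id")["true_cluster"]
            expr = simulate_expression(
                config.expression,
                seed=rng_seed + 2,
                cluster_labels=cluster_of.to_numpy(),
                cell_ids=list(cluster_of.index),
            )
            meta = truth.cells.merge(
                expr.mito_fraction.rename_axis("cell_id").reset_index(), on="cell_id"
            )
            contigs = truth.contigs
            counts = expr.counts
            return germline, contigs, meta, counts, truth
        germline = germline_from_fasta(config.germline_fasta)
        contigs = tio.read_contig_fasta(config.contigs_fasta)[
            ["cell_id", "chain", "sequence"]
        ]
        meta = tio.read_table(config.metadata_tsv)
        counts = None
        if config.counts_mtx is not None:
            counts = tio.read_counts(
                config.counts_mtx, config.genes_tsv, config.barcodes_tsv
            )
        return germline, contigs, meta, counts, None

    germline, contigs, meta, counts, truth = load_inputs()
    pool_of = meta.set_index("cell_id")["pool"]

    # ---------------- clonotype calling
    @_stage("clonotypes")
    def call_all() -> list[CellClonotype]:
        recombinome = build_recombinome(germline, config.spacer_len)
        cell_contigs = {
            cell_id: list(zip(sub.chain, sub.sequence))
            for cell_id, sub in contigs.groupby("cell_id", sort=True)
        }
        return call_clonotypes(
            cell_contigs,
            recombinome,
            scoring=config.scoring,
            min_score=config.min_score,
        )

    cells = call_all()
    groups = group_clonotypes(cells)
    calls_df = clonotype_table(cells, groups)
    tio.write_table(calls_df, out / "clonotypes.tsv")
    files.append("clonotypes.tsv")

    # ---------------- repertoire statistics
    @_stage("repertoire_stats")
    def rep_stats() -> dict:
        pools = sorted(pool_of.unique())
        groups_per_pool = {
            p: group_clonotypes([c for c in cells if pool_of.get(c.cell_id) == p])
            for p in pools
        }
        calls_per_pool = {
            p: [
                call
                for c in cells
                if pool_of.get(c.cell_id) == p
                for call in c.calls
                if call.productive
            ]
            for p in pools
        }
        sizes, singletons = clonal_size_distribution(groups)
        tio.write_table(sizes, out / "clone_sizes.tsv")
        files.append("clone_sizes.tsv")

        usage_report = {}
        for element, chain, cls in FOCAL_ELEMENTS:
            try:
                table = vj_usage(calls_per_pool, element, chain, cls)
            except Tr1seqError:
                continue
            stat, df, p = chi_square_independence(table)
            tio.write_table(table, out / f"usage_{element.replace('/', '_')}.tsv")
            files.append(f"usage_{element.replace('/', '_')}.tsv")
            usage_report[element] = {
                "counts": table.to_dict("records"),
                "chi2": None if np.isnan(stat) else stat,
                "df": df,
                "p": p,
            }

        cdr3_by_pool_chain = {}
        charged = {}
        for p in pools:
            for chain in ("alpha", "beta"):
                cdr3s = [
                    c.cdr3_aa
                    for c in calls_per_pool[p]
                    if c.chain == chain and c.cdr3_aa
                ]
                if cdr3s:
                    s = cdr3_length_summary(cdr3s)
                    cdr3_by_pool_chain[f"{p}_{chain}"] = {
                        "mean": s.mean,
                        "sem": s.sem,
                        "n": s.n,
                    }
            # charged-motif fraction over distinct beta clonotypes
            betas = {}
            for c in cells:
                if pool_of.get(c.cell_id) != p:
                    continue
                for call in c.calls:
                    if call.chain == "beta" and call.productive and call.cdr3_aa:
                        betas[call.identifier] = call.cdr3_aa
            if betas:
                charged[p] = charged_p2p3_fraction(list(betas.values()))

        beta_sets = {
            p: [c.cdr3_aa for c in calls_per_pool[p] if c.chain == "beta" and c.cdr3_aa]
            for p in pools
        }
        beta_sets = {p: v for p, v in beta_sets.items() if v}
        enrich = positional_residue_enrichment(
            beta_sets, background=config.enrichment_background
        )
        for p, mat in enrich.items():
            mat.to_csv(out / f"enrichment_beta_{p}.tsv", sep="\t")
            files.append(f"enrichment_beta_{p}.tsv")

        shared = {}
        for i, a in enumerate(pools):
            for b in pools[i + 1 :]:
                shared[f"{a}|{b}"] = len(
                    shared_clonotypes(groups_per_pool[a], groups_per_pool[b])
                )
        return {
            "n_groups": len(groups),
            "singletons": singletons,
            "clonotypes_per_pool": {p: len(groups_per_pool[p]) for p in pools},
            "singletons_per_pool": {
                p: clonal_size_distribution(groups_per_pool[p])[1] for p in pools
            },
            "usage": usage_report,
            "cdr3_length": cdr3_by_pool_chain,
            "charged_p2p3": charged,
            "shared": shared,
        }

    report["repertoire"] = rep_stats()

    # ---------------- expression
    labels = None
    if counts is not None:
        @_stage("expression")
        def expression_stage() -> tuple:
            mito = meta.set_index("cell_id")["mito_fraction"]
            qc, filtered = qc_filter(counts, mito)
            tio.write_table(
                qc.rename_axis("cell_id").reset_index(), out / "qc_report.tsv"
            )
            files.append("qc_report.tsv")
            norm = normalize_log(filtered)
            lab = cluster_cells(norm, k=config.k, n_pcs=config.n_pcs, seed=rng_seed)
            lab = identify_cluster_states(norm, lab, tr1_gene_set(), tfh_gene_set())
            tio.write_table(
                lab.labels.rename_axis("cell_id").reset_index(),
                out / "cluster_labels.tsv",
            )
            files.append("cluster_labels.tsv")

            cluster_sizes = lab.labels.value_counts().to_dict()
            de_by_cluster = {}
            for c in range(1, config.k):
                a = list(lab.labels[lab.labels == c].index)
                b = list(lab.labels[lab.labels == 0].index)
                if len(a) >= 3 and len(b) >= 3:
                    de = de_negative_binomial(filtered, a, b)
                    de_by_cluster[c] = de
                    tio.write_table(
                        de.rename_axis("gene").reset_index(),
                        out / f"de_cluster{c}_vs_0.tsv",
                    )
                    files.append(f"de_cluster{c}_vs_0.tsv")

            # per-pool tetramer+ vs Tconv comparisons for concordance
            pool_de = {}
            tconv_cells = [
                c for c in filtered.columns if pool_of.get(c) == "Tconv"
            ]
            for p in sorted(pool_of.unique()):
                if p == "Tconv":
                    continue
                pc = [c for c in filtered.columns if pool_of.get(c) == p]
                if len(pc) >= 3 and len(tconv_cells) >= 3:
                    pool_de[p] = de_negative_binomial(filtered, pc, tconv_cells)
            conc = {}
            pools_done = sorted(pool_de)
            for i, a in enumerate(pools_done):
                for b in pools_done[i + 1 :]:
                    try:
                        r = logfc_concordance(
                            pool_de[a], pool_de[b], band=config.concordance_band
                        )
                    except Tr1seqError:
                        continue
                    conc[f"{a}|{b}"] = {
                        "pearson_r": r.pearson_r,
                        "p_value": r.p_value,
                        "concordant_fraction": r.concordant_fraction,
                        "n_genes": r.n_genes,
                    }
            overlap = None
            if {1, 2} <= set(de_by_cluster):
                overlap = signature_cluster_overlap(
                    {"TFH": tfh_gene_set(), "TR1": tr1_gene_set()},
                    {1: de_by_cluster[1], 2: de_by_cluster[2]},
                )
            expr_report = {
                "n_cells_pass_qc": int(filtered.shape[1]),
                "cluster_sizes": {int(k): int(v) for k, v in cluster_sizes.items()},
                "de_significant": {
                    int(c): int(de["significant"].sum())
                    for c, de in de_by_cluster.items()
                },
                "concordance": conc,
                "signature_overlap": overlap,
            }
            return lab, expr_report

        labels, report["expression"] = expression_stage()

    # ---------------- lineage sharing
    if labels is not None:
        @_stage("lineage_sharing")
        def sharing_stage() -> dict:
            tet_cells = [
                c for c in cells if pool_of.get(c.cell_id) not in (None, "Tconv")
            ]
            tet_groups = group_clonotypes(tet_cells)
            table = clonotype_cluster_table(tet_groups, labels)
            tio.write_table(
                table.reset_index(), out / "clonotype_cluster_table.tsv"
            )
            files.append("clonotype_cluster_table.tsv")
            summary = sharing_summary(table)
            sizes = labels.labels.value_counts().to_dict()
            frac_consistent = float("nan")
            if len(table) and sizes.get(1, 0) > 0 and sizes.get(2, 0) > 0:
                _, frac_consistent = proportionality_check(
                    table, {1: sizes.get(1, 0), 2: sizes.get(2, 0)}
                )
            return {
                "shared": summary.shared,
                "only_1": summary.only_1,
                "only_2": summary.only_2,
                "excluded": summary.excluded,
                "cells_covered": summary.cells_covered,
                "fractions": summary.fractions,
                "fraction_proportional": frac_consistent,
            }

        report["lineage_sharing"] = sharing_stage()

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float) + "\n")
    files.append("report.json")
    tio.write_manifest(out, files)
    return report
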