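"""On-disk fixture bundles tying the two generators together.

``write_fixture_bundle`` emits everything the pipeline consumes —
germline FASTA, contig FASTA, counts (Matrix Market + index files), cell
metadata and truth tables — plus a checksum manifest, so a full analysis
can be round-tripped from plain-text files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import io as tio
from .germline import GermlineSegment, germline_to_fasta
from .sim_expression import ExpressionTruth
from .sim_repertoire import RepertoireTruth


def write_fixture_bundle(
    truth: RepertoireTruth,
    expr: ExpressionTruth | None,
    out_dir,
    germline: list[GermlineSegment] | None = None,
) -> dict:
    """Write a complete fixture bundle; returns the checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    if germline is not None:
        (out / "germline.fasta").write_text(germline_to_fasta(germline))
        files.append("germline.fasta")

    tio.write_contig_fasta(truth.contigs, out / "contigs.fasta")
    files.append("contigs.fasta")

    meta = truth.cells.copy()
    if expr is not None:
        meta = meta.merge(
            pd.DataFrame(
                {
                    "cell_id": expr.cell_ids,
                    "mito_fraction": expr.mito_fraction.to_numpy(),
                }
            ),
            on="cell_id",
            how="left",
        )
    tio.write_table(meta, out / "cell_metadata.tsv")
    files.append("cell_metadata.tsv")

    tio.write_table(truth.clone_table, out / "truth_clones.tsv")
    files.append("truth_clones.tsv")
    tio.write_table(truth.cells, out / "truth_cells.tsv")
    files.append("truth_cells.tsv")

    if expr is not None:
        tio.write_counts(
            expr.counts, out / "counts.mtx", out / "genes.tsv", out / "barcodes.tsv"
        )
        files += ["counts.mtx", "genes.tsv", "barcodes.tsv"]
        truth_expr = pd.DataFrame(
            {
                "cell_id": expr.cell_ids,
                "true_cluster": expr.true_cluster.to_numpy(),
                "qc_fail": expr.qc_fail.to_numpy(),
            }
        )
        tio.write_table(truth_expr, out / "truth_expression.tsv")
        files.append("truth_expression.tsv")

    return tio.write_manifest(out, files)
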