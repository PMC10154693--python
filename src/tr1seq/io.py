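"""Readers and writers for the pipeline's interchange formats.

FASTA via Biopython, counts in Matrix Market coordinate format plus
``genes.tsv``/``barcodes.tsv`` index files, tabular data as tab-separated
UTF-8 with a header row. All readers validate rather than coerce.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError


def read_contig_fasta(path) -> pd.DataFrame:
    """Read contigs whose headers are ``cellID|chain|index``.

    Returns a DataFrame (cell_id, chain, index, sequence); sequences are
    uppercased on read.
    """
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise FormatError(
                f"contig header {rec.id!r}: expected cellID|chain|index"
            )
        cell_id, chain, idx = parts
        if chain not in ("alpha", "beta"):
            raise FormatError(f"contig header {rec.id!r}: unknown chain {chain!r}")
        try:
            idx = int(idx)
        except ValueError as exc:
            raise FormatError(f"contig header {rec.id!r}: non-integer index") from exc
        rows.append(
            {
                "cell_id": cell_id,
                "chain": chain,
                "index": idx,
                "sequence": str(rec.seq).upper(),
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "chain", "index", "sequence"])


def write_contig_fasta(contigs: pd.DataFrame, path) -> None:
    """Write contigs (cell_id, chain, sequence) with ``cellID|chain|index``
    headers; the per-cell index numbers chains in row order."""
    records = []
    counters: dict[str, int] = {}
    for row in contigs.itertuples(index=False):
        i = counters.get(row.cell_id, 0)
        counters[row.cell_id] = i + 1
        records.append(
            SeqRecord(Seq(row.sequence), id=f"{row.cell_id}|{row.chain}|{i}", description="")
        )
    SeqIO.write(records, str(path), "fasta")


def read_counts(mtx_path, genes_path, cells_path) -> pd.DataFrame:
    """Read a Matrix Market counts matrix with its gene/cell index files.

    Returns a dense genes x cells integer DataFrame; duplicate coordinate
    entries are summed per the Matrix Market convention.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:
        raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}") from exc
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].tolist()
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match index files "
            f"({len(genes)} genes, {len(cells)} cells)"
        )
    dense = mat.toarray()
    if (dense < 0).any():
        raise FormatError("counts matrix contains negative entries")
    return pd.DataFrame(dense.astype("int64"), index=genes, columns=cells)


def write_counts(counts: pd.DataFrame, mtx_path, genes_path, cells_path) -> None:
    sparse = scipy.sparse.coo_matrix(counts.to_numpy())
    scipy.io.mmwrite(str(mtx_path), sparse)
    pd.Series(counts.index).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(counts.columns).to_csv(cells_path, sep="\t", header=False, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, files: list[str]) -> dict:
    """Checksum manifest over ``files`` (paths relative to ``out_dir``)."""
    out_dir = Path(out_dir)
    manifest = {
        "files": {f: sha256_of(out_dir / f) for f in sorted(files)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
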