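"""Readers and writers for the on-disk formats.

Canonical interchange format is TSV (genes as rows for count matrices).
MatrixMarket is supported for counts only, with plain-text sidecar files
``<path>.rows`` / ``<path>.cols`` carrying gene and cell identifiers.
Genomic intervals use BED conventions: 0-based, half-open.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import CellRecord, CountMatrix
from .occupancy import GenomicInterval, TSSRecord

log = logging.getLogger("trajkl")


def setup_logging(level: int = logging.INFO) -> None:
    """Stage-tagged log lines on standard error; stdout stays clean."""
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log.handlers[:] = [h]
    log.setLevel(level)


# ---------------------------------------------------------------------------
# count matrices


def _infer_format(path: Path) -> str:
    return "mtx" if path.suffix == ".mtx" else "tsv"


def read_count_matrix(path: str | Path, format: str | None = None) -> CountMatrix:
    """Read a genes x cells matrix from TSV or MatrixMarket.

    TSV layout: gene ids in the first column, cell ids in the header row.
    Duplicate gene/cell ids and non-numeric entries are hard errors that
    name the offending id or coordinate.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        m = scipy.io.mmread(path)
        genes = Path(f"{path}.rows").read_text().split()
        cells = Path(f"{path}.cols").read_text().split()
        values = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=float)
        return CountMatrix(genes, cells, values)
    if fmt != "tsv":
        raise ValueError(f"unknown count-matrix format {fmt!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup_cells = sorted({c for c in header if header.count(c) > 1})
    if dup_cells:
        raise ValueError(f"duplicate cell id(s) in {path}: {dup_cells}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValueError(f"duplicate gene id(s) in {path}: {dup_genes}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for gene, row in df.iterrows():
            for cell, v in row.items():
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {v!r} at gene {gene!r}, cell {cell!r} in {path}"
                    ) from None
        raise
    return CountMatrix(list(df.index), list(df.columns), values)


def write_count_matrix(matrix: CountMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        vals = matrix.values
        if np.array_equal(vals, np.round(vals)):
            vals = vals.astype(int)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(vals))
        Path(f"{path}.rows").write_text("\n".join(matrix.genes) + "\n")
        Path(f"{path}.cols").write_text("\n".join(matrix.cells) + "\n")
    elif fmt == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", index_label="gene", float_format="%.10g")
    else:
        raise ValueError(f"unknown count-matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# cell metadata


def read_cell_metadata(path: str | Path, capture_set: Sequence[float] | None = None) -> list[CellRecord]:
    """Read per-cell metadata (cell_id, capture_time_h, mapped_reads[, label]).

    If ``capture_set`` is given, any capture time outside it is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    required = {"cell_id", "capture_time_h", "mapped_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path} missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        t = float(row["capture_time_h"])
        if capture_set is not None and t not in {float(x) for x in capture_set}:
            raise ValueError(
                f"cell {row['cell_id']!r}: capture_time_h {t} not in capture set {sorted(capture_set)}"
            )
        records.append(
            CellRecord(
                cell_id=str(row["cell_id"]),
                capture_time_h=t,
                mapped_reads=int(row["mapped_reads"]),
                label=str(row.get("label", "")) if "label" in df.columns else "",
            )
        )
    ids = [r.cell_id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate cell id(s) in metadata: {dups}")
    return records


def write_cell_metadata(records: Iterable[CellRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "capture_time_h": [r.capture_time_h for r in records],
            "mapped_reads": [r.mapped_reads for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals and TSS tables


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read chrom/start/end from a BED file (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    out = []
    for _, row in df.iterrows():
        out.append(GenomicInterval(chrom=str(row[0]), start=int(row[1]), end=int(row[2])))
    return out


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_tss_bed(path: str | Path) -> list[TSSRecord]:
    """Read a 6-column BED of TSS annotations.

    The TSS position of a + gene is the interval start; for a - gene it is
    ``end - 1`` (the last covered base under half-open semantics), so a
    1-bp interval ``[pos, pos+1)`` denotes position ``pos`` on either strand.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 6:
        raise ValueError(f"TSS table {path} must have 6 BED columns (chrom start end name score strand)")
    out = []
    for _, row in df.iterrows():
        strand = str(row[5])
        if strand not in ("+", "-"):
            raise ValueError(f"TSS table {path}: bad strand {strand!r} for {row[3]!r}")
        pos = int(row[1]) if strand == "+" else int(row[2]) - 1
        out.append(TSSRecord(gene=str(row[3]), chrom=str(row[0]), position=pos, strand=strand))
    return out


def write_tss_bed(records: Iterable[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.gene}\t0\t{r.strand}\n")
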