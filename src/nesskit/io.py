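"""Readers and writers for the plain-text exchange formats.

Matrices travel as MTX-style sparse triplets with TSV sidecar files for
cell and feature ids; tables (cell metadata, embeddings, gene tables,
link tables) are tab-separated with headers; peaks are BED.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import CountMatrix, Embedding, GeneRecord, PeakRecord, validate_cell_meta

logger = logging.getLogger(__name__)

MATRIX_FILE = "matrix.mtx"
CELLS_FILE = "cells.tsv"
FEATURES_FILE = "features.tsv"


def _read_ids(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path: str | os.PathLike, modality: str) -> CountMatrix:
    """Read a sparse count matrix from ``path``.

    ``path`` is a directory holding ``matrix.mtx`` (cells x features,
    1-based triplets per the MatrixMarket convention), ``cells.tsv`` and
    ``features.tsv``. ATAC counts are binarized on load.
    """
    path = Path(path)
    mat = scipy.io.mmread(path / MATRIX_FILE)
    cells = _read_ids(path / CELLS_FILE)
    features = _read_ids(path / FEATURES_FILE)
    if mat.shape != (len(cells), len(features)):
        raise ValueError(
            f"matrix header {mat.shape} does not match sidecars "
            f"({len(cells)} cells, {len(features)} features)"
        )
    return CountMatrix(cells=cells, features=features, counts=sp.csr_matrix(mat), modality=modality)


def write_counts(cm: CountMatrix, path: str | os.PathLike) -> None:
    """Write a CountMatrix as MTX triplets plus id sidecars."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / MATRIX_FILE, cm.counts.tocoo(), field="integer")
    (path / CELLS_FILE).write_text("".join(f"{c}\n" for c in cm.cells))
    (path / FEATURES_FILE).write_text("".join(f"{f}\n" for f in cm.features))


def read_intervals(path: str | os.PathLike) -> list[PeakRecord]:
    """Read a 3+ column BED file into peak records.

    Records are returned sorted by (chrom, start, end). A missing name
    column is synthesized as ``chrom:start-end``. Records with
    ``end <= start`` are rejected with a logged warning.
    """
    records: list[PeakRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED requires >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                logger.warning("%s:%d: rejected interval with end <= start (%d >= %d)",
                               path, ln, start, end)
                continue
            peak_id = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") \
                else f"{chrom}:{start}-{end}"
            records.append(PeakRecord(peak_id=peak_id, chrom=chrom, start=start, end=end))
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def write_intervals(peaks: list[PeakRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


def read_genes(path: str | os.PathLike, one_based: bool = False) -> list[GeneRecord]:
    """Read a gene table TSV (columns: gene_id, chrom, strand, tss).

    ``one_based=True`` converts a 1-based TSS to the internal 0-based
    convention on read. Promoters are derived strand-aware (TSS extended
    2 kb upstream).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    offset = 1 if one_based else 0
    return [
        GeneRecord(gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
                   tss=int(row.tss) - offset)
        for row in df.itertuples(index=False)
    ]


def read_cell_meta(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    return validate_cell_meta(meta)


def write_cell_meta(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_embedding(path: str | os.PathLike) -> Embedding:
    """Read an embedding TSV: first column cell_id, remaining columns coords."""
    df = pd.read_csv(path, sep="\t")
    cells = df.iloc[:, 0].astype(str).tolist()
    coords = df.iloc[:, 1:].to_numpy(dtype=float)
    return Embedding(cells=cells, coords=coords)


def write_embedding(emb: Embedding, path: str | os.PathLike) -> None:
    df = pd.DataFrame(emb.coords, columns=[f"dim_{i}" for i in range(emb.coords.shape[1])])
    df.insert(0, "cell_id", emb.cells)
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any result table as TSV with header (the package-wide output format)."""
    df.to_csv(path, sep="\t", index=False)
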