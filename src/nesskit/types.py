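"""Core in-memory containers shared by all analysis stages.

Coordinate convention: all genomic intervals are 0-based half-open (BED
dialect). Gene tables supplied 1-based must be converted on read (see
:func:`nesskit.io.read_genes` with ``one_based=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

PROMOTER_UPSTREAM_BP = 2000

#: Columns a cell metadata table may carry. ``cell_id`` is mandatory and
#: unique; the rest are required only by the stages that consume them.
CELL_META_COLUMNS = (
    "cell_id",
    "sample_id",
    "rt_barcode",
    "region",
    "region_subclass",
    "cell_class",
    "cell_subtype",
    "cluster_id",
    "doublet_score",
    "total_umi",
    "n_genes",
    "mito_frac",
    "frip",
)

_UNIT_INTERVAL_COLUMNS = ("doublet_score", "mito_frac", "frip")


def validate_cell_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell metadata table.

    Checks that ``cell_id`` is present and unique and that score-like
    columns lie in [0, 1] where not null. Returns the table unchanged.
    """
    if "cell_id" not in meta.columns:
        raise ValueError("cell metadata requires a 'cell_id' column")
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id: {dup!r}")
    for col in _UNIT_INTERVAL_COLUMNS:
        if col in meta.columns:
            vals = pd.to_numeric(meta[col], errors="coerce")
            bad = vals.dropna()
            if len(bad) and ((bad < 0) | (bad > 1)).any():
                raise ValueError(f"column {col!r} must lie in [0, 1]")
    return meta


@dataclass
class CountMatrix:
    """Sparse cell x feature count matrix.

    ``modality`` is ``"rna"`` (UMI counts) or ``"atac"`` (binarized
    accessibility: 1 open, 0 closed). ATAC matrices are binarized at load
    time so every downstream stage sees a single representation.
    """

    cells: list[str]
    features: list[str]
    counts: sp.csr_matrix
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.features)} features"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts are not allowed")
        if self.modality == "atac":
            self.counts.data = np.minimum(self.counts.data, 1)
            self.counts.eliminate_zeros()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cells)}

    def subset_cells(self, cell_ids: list[str]) -> "CountMatrix":
        idx = self.cell_index()
        rows = [idx[c] for c in cell_ids]
        return CountMatrix(
            cells=list(cell_ids),
            features=list(self.features),
            counts=self.counts[rows],
            modality=self.modality,
        )


@dataclass
class Embedding:
    """Low-dimensional cell coordinates used for kNN search and metacells."""

    cells: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 2:
            raise ValueError("embedding must be a cells x d matrix with d >= 2")
        if self.coords.shape[0] != len(self.cells):
            raise ValueError("row count does not match number of cell ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class GeneRecord:
    """Gene anchor for peak pairing: strand-aware TSS plus the promoter
    interval obtained by extending the TSS 2 kb upstream (half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    promoter_start: int = field(default=-1)
    promoter_end: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")
        if self.promoter_start < 0:  # derive from strand-aware TSS
            if self.strand == "+":
                start, end = max(0, self.tss - PROMOTER_UPSTREAM_BP), self.tss + 1
            else:
                start, end = self.tss, self.tss + 1 + PROMOTER_UPSTREAM_BP
            object.__setattr__(self, "promoter_start", start)
            object.__setattr__(self, "promoter_end", end)
        if self.promoter_end <= self.promoter_start:
            raise ValueError("promoter_end must exceed promoter_start")


@dataclass(frozen=True)
class PeakRecord:
    """An accessible-chromatin peak interval (0-based half-open)."""

    peak_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak {self.peak_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start
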