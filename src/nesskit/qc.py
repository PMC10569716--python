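"""Nucleus- and cluster-level QC rules and the barcode-contamination screen.

Boundary semantics follow the printed inequalities exactly: RNA keeps
``umi >= 100`` (inclusive), ``genes < 2500`` and ``mito < 0.05`` (strict);
ATAC keeps ``umi >= 1000`` (inclusive), ``umi < 100000`` (strict) and
``frip >= 0.30`` (inclusive). Doublet flags use strict ``>`` cuts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regional import jsd

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Default numeric cuts for nucleus filtering and flagging rules."""

    rna_min_umi: int = 100
    rna_max_genes: int = 2500
    rna_max_mito: float = 0.05
    atac_min_umi: int = 1000
    atac_max_umi: int = 100_000
    atac_min_frip: float = 0.30
    cell_doublet_cut: float = 0.20
    cluster_doublet_cut: float = 0.15
    barcode_min_cells: int = 10_000
    barcode_class_jsd_cut: float = 0.15
    barcode_subtype_jsd_cut: float = 0.075


# reason codes report the FIRST failing filter in this fixed order
_RNA_FILTERS = ("min_umi", "max_genes", "max_mito")
_ATAC_FILTERS = ("umi_low", "umi_high", "frip")


def filter_nuclei(
    meta: pd.DataFrame, thresholds: QCThresholds | None = None, modality: str = "rna"
) -> tuple[list[str], pd.Series]:
    """Apply the per-nucleus numeric filters for one modality.

    Returns the kept cell ids and a per-cell reason Series ("pass" or the
    first failing filter's code, in the fixed order umi/genes/mito for RNA
    and umi_low/umi_high/frip for ATAC).
    """
    t = thresholds or QCThresholds()
    if modality == "rna":
        checks = [
            ("min_umi", meta["total_umi"] >= t.rna_min_umi),
            ("max_genes", meta["n_genes"] < t.rna_max_genes),
            ("max_mito", meta["mito_frac"] < t.rna_max_mito),
        ]
    elif modality == "atac":
        if "frip" not in meta.columns or meta["frip"].isna().all():
            raise ValueError("atac filtering requires a 'frip' column")
        checks = [
            ("umi_low", meta["total_umi"] >= t.atac_min_umi),
            ("umi_high", meta["total_umi"] < t.atac_max_umi),
            ("frip", meta["frip"] >= t.atac_min_frip),
        ]
    else:
        raise ValueError(f"unknown modality {modality!r}")

    reasons = pd.Series("pass", index=meta.index, dtype=object)
    for code, ok in reversed(checks):  # earlier filters overwrite later ones
        reasons[~ok.fillna(False)] = code
    reasons.index = meta["cell_id"].to_numpy()
    kept = meta.loc[(reasons == "pass").to_numpy(), "cell_id"].tolist()
    return kept, reasons


def flag_doublet_cells(meta: pd.DataFrame, cut: float = 0.20) -> pd.Series:
    """Per-cell doublet flag: score strictly greater than the cut.

    Null scores yield null flags (logged), never False.
    """
    scores = meta["doublet_score"]
    if scores.isna().any():
        logger.warning("%d cells have null doublet scores; flags are null",
                       int(scores.isna().sum()))
    flags = pd.Series(pd.array(scores > cut, dtype="boolean"), index=meta["cell_id"].to_numpy())
    flags[scores.isna().to_numpy()] = pd.NA
    return flags


def flag_doublet_clusters(meta: pd.DataFrame, cut: float = 0.15) -> set:
    """Clusters whose mean doublet score strictly exceeds the cut.

    All member cells of a flagged cluster are marked for removal by the
    caller. Clusters with no scored cells are skipped with a warning.
    """
    flagged = set()
    for cluster, grp in meta.groupby("cluster_id", dropna=True):
        scores = grp["doublet_score"].dropna()
        if scores.empty:
            logger.warning("cluster %r has no doublet scores; skipped", cluster)
            continue
        if scores.mean() > cut:
            flagged.add(cluster)
    return flagged


def _proportions(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.div(counts.sum(axis=1), axis=0)


def _barcode_jsd(meta: pd.DataFrame, label_col: str) -> pd.Series:
    """Per-barcode JSD of label proportions vs the unweighted mean
    proportion vector across all barcodes of the same sample.

    Labels absent from a barcode but present in the sample enter as
    zeros (JSD stays finite through the mixture term).
    """
    out = {}
    for sample, sub in meta.groupby("sample_id"):
        counts = pd.crosstab(sub["rt_barcode"], sub[label_col])
        props = _proportions(counts)
        mean_props = props.mean(axis=0).to_numpy()
        mean_props = mean_props / mean_props.sum()
        for barcode, row in props.iterrows():
            out[barcode] = jsd(row.to_numpy(), mean_props)
    return pd.Series(out, name=f"{label_col}_jsd")


def screen_barcodes(
    meta: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[set, pd.DataFrame]:
    """Screen RT barcodes for cross-well contamination.

    For each barcode (within its sample) the cell class and cell subtype
    proportion vectors are compared, via Jensen-Shannon divergence, with
    the mean proportion vector across all barcodes of that sample. A
    barcode is flagged iff it has more than ``barcode_min_cells`` cells
    AND class JSD > ``barcode_class_jsd_cut`` AND subtype JSD >
    ``barcode_subtype_jsd_cut``. Flagged cells should be excluded from
    downstream regional proportion analyses.

    Returns the flagged barcode set and a per-barcode table with
    ``n_cells``, ``class_jsd``, ``subtype_jsd`` and ``flagged``.
    """
    t = thresholds or QCThresholds()
    class_jsd = _barcode_jsd(meta, "cell_class")
    subtype_jsd = _barcode_jsd(meta, "cell_subtype")
    n_cells = meta.groupby("rt_barcode").size()
    table = pd.DataFrame({
        "n_cells": n_cells,
        "class_jsd": class_jsd,
        "subtype_jsd": subtype_jsd,
    })
    table["flagged"] = (
        (table["n_cells"] > t.barcode_min_cells)
        & (table["class_jsd"] > t.barcode_class_jsd_cut)
        & (table["subtype_jsd"] > t.barcode_subtype_jsd_cut)
    )
    table.index.name = "rt_barcode"
    return set(table.index[table["flagged"]]), table.reset_index()
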