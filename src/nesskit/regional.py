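"""Regional composition statistics.

Jensen-Shannon regional-specificity scores for cell types, and the
capped log2 composition-ratio matrix contrasting a subtype's
within-region proportion against its cross-region average.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-9


def jsd(p, q, base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two probability vectors.

    JSD(p, q) = 1/2 KL(p || m) + 1/2 KL(q || m) with m = (p + q)/2 and
    0 * log(0/x) taken as 0. With base-2 logarithms (the default) the
    value is bounded in [0, 1]: 0 iff p = q, 1 for disjoint supports.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-d vectors of equal length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probability vectors must be non-negative")
    if abs(p.sum() - 1.0) > _SUM_TOL or abs(q.sum() - 1.0) > _SUM_TOL:
        raise ValueError("probability vectors must each sum to 1")
    # scipy returns the JS *distance* (square root of the divergence)
    with np.errstate(invalid="ignore"):
        dist = jensenshannon(p, q, base=base)
    if np.isnan(dist):  # rounding can push the divergence below zero for p ~ q
        return 0.0
    return float(dist**2)


def _as_counts(comp: pd.DataFrame) -> pd.DataFrame:
    counts = comp.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("composition counts must be non-negative")
    return counts


def regional_specificity(comp: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """Per-group regional-specificity scores.

    ``comp`` is a groups x categories count table (e.g. cell subtypes x
    brain regions). Each group's score is the Jensen-Shannon divergence
    between its own distribution across categories and the global
    distribution (column sums over all groups). Groups with zero total
    get a null score with a warning.

    Returns a DataFrame indexed by group with columns ``score`` and
    ``n_cells``.
    """
    counts = _as_counts(comp)
    if counts.shape[1] < 2:
        raise ValueError("at least 2 categories are required")
    global_counts = counts.sum(axis=0).to_numpy()
    global_p = global_counts / global_counts.sum()
    scores = []
    for group, row in counts.iterrows():
        total = row.sum()
        if total == 0:
            logger.warning("group %r has zero total count; score is null", group)
            scores.append(np.nan)
        else:
            scores.append(jsd(row.to_numpy() / total, global_p, base=base))
    return pd.DataFrame(
        {"score": scores, "n_cells": counts.sum(axis=1).astype(int)}, index=counts.index
    )


def composition_log_ratio(
    comp: pd.DataFrame,
    cap: float = 2.0,
    min_cells: int = 100,
    pooled_mean: bool = False,
) -> pd.DataFrame:
    """Capped log2 ratios of within-region subtype composition vs the
    cross-region average.

    ``comp`` is a regions x subtypes count table. For region r and
    subtype s, the entry is ``clamp(log2(prop(s in r) / mean_r'
    prop(s in r')), -cap, +cap)`` where ``prop(s in r)`` is s's share of
    region r's cells. The denominator is by default the unweighted mean
    of per-region proportions; ``pooled_mean=True`` uses the pooled
    (all-regions-combined) proportion instead.

    Subtypes with fewer than ``min_cells`` total cells are dropped
    (display rule, exposed as a parameter). A zero within-region
    proportion is replaced by half the subtype's minimum nonzero
    proportion before taking the log; the cap bounds the effect.
    Regions with zero cells yield null rows.
    """
    counts = _as_counts(comp)
    counts = counts.loc[:, counts.sum(axis=0) >= min_cells]
    region_totals = counts.sum(axis=1)
    props = counts.div(region_totals, axis=0)  # rows with 0 total -> NaN
    empty = region_totals == 0
    if empty.any():
        logger.warning("regions with zero cells: %s", list(counts.index[empty]))

    filled = props.copy()
    for s in filled.columns:
        col = filled[s]
        nonzero = col[col > 0]
        pseudo = nonzero.min() / 2 if len(nonzero) else np.nan
        filled[s] = col.mask(col == 0, pseudo)

    if pooled_mean:
        denom = counts.sum(axis=0) / counts.to_numpy().sum()
    else:
        denom = props.mean(axis=0)  # unweighted mean over regions
    ratio = np.log2(filled.div(denom, axis=1))
    return ratio.clip(lower=-cap, upper=cap)


def composition_table(
    meta: pd.DataFrame, group_col: str, category_col: str
) -> pd.DataFrame:
    """Cross-tabulate cell metadata into a groups x categories count table."""
    return pd.crosstab(meta[group_col], meta[category_col])
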