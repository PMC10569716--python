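"""TF activity-sign classification.

A transcription factor acting as an activator should be highly expressed
in the cell groups where its binding motif is most accessible; a
repressor shows the opposite pattern. Given aligned per-group summaries
of motif accessibility and cognate-gene expression (groups are typically
cell class x region subclass combinations), the Pearson correlation
across groups classifies each TF: r > 0 activator, r < 0 repressor,
constant input undetermined. How the per-group summaries are aggregated
upstream is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_GROUPS = 3


@dataclass
class TFGroupProfile:
    """Aligned per-group motif accessibility and expression for one TF."""

    tf_id: str
    groups: list[str]
    motif_accessibility: np.ndarray
    expression: np.ndarray

    def __post_init__(self) -> None:
        self.motif_accessibility = np.asarray(self.motif_accessibility, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if not (len(self.groups) == len(self.motif_accessibility) == len(self.expression)):
            raise ValueError("group labels and both vectors must align")


def tf_correlation(
    profile: TFGroupProfile, method: str = "pearson"
) -> tuple[float, str]:
    """Correlate motif accessibility with TF expression across groups.

    Returns (r, classification) with classification ``activator`` for
    r > 0, ``repressor`` for r < 0, and ``undetermined`` when either
    vector is constant (rather than reporting a spurious r = 0).
    ``method="spearman"`` rank-transforms both vectors first.
    """
    x, y = profile.motif_accessibility, profile.expression
    if len(x) < MIN_GROUPS:
        raise ValueError(f"at least {MIN_GROUPS} groups are required")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("vectors must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), "undetermined"
    if method == "spearman":
        r = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        r = stats.pearsonr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    if r > 0:
        return float(r), "activator"
    if r < 0:
        return float(r), "repressor"
    return float(r), "undetermined"


def classify_tf_panel(
    accessibility: pd.DataFrame, expression: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Classify every TF in a panel.

    Inputs are two groups x TF tables aligned on both axes. Returns a
    per-TF table with columns ``r`` and ``classification``.
    """
    if not accessibility.index.equals(expression.index):
        raise ValueError("group rows must align between the two tables")
    if not accessibility.columns.equals(expression.columns):
        raise ValueError("TF columns must align between the two tables")
    rows = []
    for tf in accessibility.columns:
        profile = TFGroupProfile(
            tf_id=tf,
            groups=list(accessibility.index),
            motif_accessibility=accessibility[tf].to_numpy(),
            expression=expression[tf].to_numpy(),
        )
        r, cls = tf_correlation(profile, method=method)
        rows.append((tf, r, cls))
    return pd.DataFrame(rows, columns=["tf_id", "r", "classification"])
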