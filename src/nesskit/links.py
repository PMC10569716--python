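"""Metacell-based peak-gene cis-regulatory inference.

Pipeline: k-means metacells on a joint embedding -> pseudobulk log2CPM
expression per metacell -> candidate peak-gene pairs within a 150 kb
window of the gene promoter (strand-aware TSS extended 2 kb upstream) ->
per-pair logistic regression of single-cell peak accessibility (1 open,
0 closed) on the cell's metacell expression -> BH adjustment and
combination with an external evidence stream (both adjusted p < 0.05)
-> direction from the sign of the logistic coefficient. A separate
one-vs-rest differential-accessibility test calls marker peaks per cell
class (regularized LR coefficient > 0, log2FC > 0, t-test P_adj < 0.05).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, Embedding, GeneRecord, PeakRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 150_000
DEFAULT_TARGET_PER_METACELL = 250
MAX_LOGIT_ITER = 100
BETA_CAP = 25.0

LINK_COLUMNS = [
    "gene_id", "peak_id", "signed_distance", "beta", "p", "p_adj",
    "external_score", "external_p_adj", "candidate", "direction",
]


@dataclass
class MetacellAssignment:
    """Per-cell metacell membership from k-means on the joint embedding."""

    cells: list[str]
    metacell_id: np.ndarray
    n_meta: int
    target_per_metacell: int = DEFAULT_TARGET_PER_METACELL

    def __post_init__(self) -> None:
        self.metacell_id = np.asarray(self.metacell_id, dtype=int)
        if self.metacell_id.shape[0] != len(self.cells):
            raise ValueError("metacell ids must align with cells")
        if self.metacell_id.min() < 0 or self.metacell_id.max() >= self.n_meta:
            raise ValueError("metacell ids must lie in [0, n_meta)")


def choose_n_meta(n_cells: int, target: int = DEFAULT_TARGET_PER_METACELL) -> int:
    """Number of metacells targeting a mean of ``target`` cells each:
    floor(n_cells / target)."""
    if target < 1:
        raise ValueError("target must be >= 1")
    if n_cells < target:
        raise ValueError("need at least `target` cells to form one metacell")
    return n_cells // target


def build_metacells(embedding: Embedding, n_meta: int, seed: int = 0) -> MetacellAssignment:
    """k-means metacells (k-means++ init, fixed seed) on the embedding."""
    if n_meta >= embedding.n_cells:
        raise ValueError("n_meta must be smaller than the number of cells")
    km = KMeans(n_clusters=n_meta, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(embedding.coords)
    return MetacellAssignment(cells=list(embedding.cells), metacell_id=labels, n_meta=n_meta)


def pseudobulk_log2cpm(counts: CountMatrix, assign: MetacellAssignment) -> pd.DataFrame:
    """Sum counts per metacell and return log2(CPM + 1) values.

    Rows are metacell ids, columns gene ids. Metacells with zero total
    count get null rows with a warning.
    """
    if counts.cells != assign.cells:
        raise ValueError("counts and assignment must cover the same cells in order")
    n_meta = assign.n_meta
    indicator = sp.csr_matrix(
        (np.ones(len(assign.cells)), (assign.metacell_id, np.arange(len(assign.cells)))),
        shape=(n_meta, len(assign.cells)),
    )
    sums = np.asarray((indicator @ counts.counts).todense(), dtype=float)
    totals = sums.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("%d metacells have zero total count; rows are null", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        cpm = sums / totals[:, None] * 1e6
    cpm[empty] = np.nan
    return pd.DataFrame(np.log2(cpm + 1), index=np.arange(n_meta), columns=counts.features)


def pair_peaks_genes(
    peaks: list[PeakRecord],
    genes: list[GeneRecord],
    window: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Candidate peak-gene pairs within ``window`` bp of the promoter.

    A pair is retained iff the minimum genomic gap between the peak
    interval and the promoter interval is <= ``window`` (inclusive;
    overlap counts as gap 0). ``signed_distance`` is the signed minimal
    distance from the peak to the strand-aware TSS point: negative when
    the peak lies upstream of the gene, positive downstream, 0 when the
    peak overlaps the TSS. Chromosomes present in only one input are
    skipped with a warning.
    """
    peak_chroms = {p.chrom for p in peaks}
    gene_chroms = {g.chrom for g in genes}
    unmatched = peak_chroms ^ gene_chroms
    if unmatched:
        logger.warning("chromosomes present in only one input are skipped: %s",
                       sorted(unmatched))
    shared = peak_chroms & gene_chroms

    rows = []
    peaks_by_chrom: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    for g in genes:
        if g.chrom not in shared:
            continue
        for p in peaks_by_chrom[g.chrom]:
            # gap between [p.start, p.end) and [promoter_start, promoter_end)
            gap = max(g.promoter_start - p.end + 1, p.start - g.promoter_end + 1, 0)
            if gap > window:
                continue
            if p.start <= g.tss < p.end:
                signed = 0
            else:
                # unsigned minimal distance from the TSS point to the interval
                dist = p.start - g.tss if p.start > g.tss else g.tss - (p.end - 1)
                downstream = (p.start > g.tss) == (g.strand == "+")
                signed = dist if downstream else -dist
            rows.append((g.gene_id, p.peak_id, signed))
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "signed_distance"])


def fit_link_logistic(
    atac_open: np.ndarray,
    assign: MetacellAssignment,
    gene_expr: pd.Series | np.ndarray,
) -> tuple[float | None, float | None, str]:
    """Logistic regression of per-cell peak accessibility on metacell
    expression.

    ``atac_open`` is the binary open/closed vector for one peak over the
    ATAC cells; ``gene_expr`` the per-metacell log2CPM of one gene,
    indexed by metacell id. Returns (beta, p, reason). Degenerate inputs
    give null estimates with a reason code: ``constant_response``,
    ``constant_predictor``; quasi-separation or non-convergence reports
    the capped coefficient with p = null (``separation``).
    """
    y = np.asarray(atac_open, dtype=float)
    if y.shape[0] != len(assign.cells):
        raise ValueError("accessibility vector must align with the ATAC cells")
    expr = np.asarray(pd.Series(gene_expr).reindex(np.arange(assign.n_meta)))
    x = expr[assign.metacell_id]
    if np.isnan(x).any():
        raise ValueError("every ATAC cell needs a metacell with non-null expression")
    if y.min() == y.max():
        return None, None, "constant_response"
    if x.min() == x.max():
        return None, None, "constant_predictor"
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            # separation/non-convergence is detected and reported below
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=MAX_LOGIT_ITER)
    except Exception:
        return None, None, "fit_failed"
    beta = float(res.params[1])
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged or abs(beta) > BETA_CAP:
        return float(np.clip(beta, -BETA_CAP, BETA_CAP)), None, "separation"
    return beta, float(res.pvalues[1]), "ok"


def fit_links(
    pairs: pd.DataFrame,
    atac: CountMatrix,
    assign: MetacellAssignment,
    expr: pd.DataFrame,
) -> pd.DataFrame:
    """Fit the logistic link model for every pair and BH-adjust p-values
    across all tested pairs in one family.

    ``pairs`` needs columns gene_id/peak_id (signed_distance carried
    through when present); ``expr`` is the metacell x gene log2CPM table.
    """
    peak_index = {p: i for i, p in enumerate(atac.features)}
    mat = atac.counts.tocsc()
    betas, ps, reasons = [], [], []
    for row in pairs.itertuples(index=False):
        open_vec = np.asarray(mat[:, peak_index[row.peak_id]].todense()).ravel()
        beta, p, reason = fit_link_logistic(open_vec, assign, expr[row.gene_id])
        betas.append(beta)
        ps.append(p)
        reasons.append(reason)
    out = pairs.copy()
    out["beta"] = pd.array(betas, dtype=float)
    out["p"] = pd.array(ps, dtype=float)
    out["reason"] = reasons
    out["p_adj"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def permutation_p_adj(scores: pd.Series, n_perm: int = 1000, seed: int = 0) -> pd.Series:
    """Null-permutation p-values (BH-adjusted) for a user-supplied pair
    score, for building an external evidence stream from any score table.

    The null is the empirical distribution of the pooled scores; the
    one-sided p per pair is the fraction of permuted draws at least as
    large.
    """
    rng = np.random.default_rng(seed)
    vals = scores.to_numpy(dtype=float)
    null = rng.choice(vals, size=n_perm, replace=True)
    p = np.array([(np.sum(null >= v) + 1) / (n_perm + 1) for v in vals])
    return pd.Series(multipletests(p, method="fdr_bh")[1], index=scores.index)


def combine_evidence(links: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Combine the logistic stream with the external evidence stream.

    A pair is a candidate cis-regulatory link iff both BH-adjusted
    p-values are below ``alpha``; candidates get a direction from the
    sign of the logistic coefficient. Pairs missing external evidence
    are untestable: candidate stays null, not False.
    """
    out = links.copy()
    has_ext = out["external_p_adj"].notna()
    cand = (out["p_adj"] < alpha) & (out["external_p_adj"] < alpha)
    out["candidate"] = pd.array(cand, dtype="boolean")
    out.loc[~has_ext, "candidate"] = pd.NA
    direction = np.where(out["beta"] > 0, "positive", "negative")
    out["direction"] = pd.array(
        np.where(out["candidate"].fillna(False).to_numpy(), direction, None), dtype=object
    )
    return out


def differential_accessibility(
    atac: CountMatrix,
    classes: pd.Series | np.ndarray,
    alpha: float = 0.05,
    pseudocount: float = 1e-9,
    max_iter: int = 200,
) -> pd.DataFrame:
    """One-vs-rest marker-peak calling per cell class.

    For every peak x class: (i) the class's coefficient from one
    multinomial L2-regularized logistic regression over all peaks;
    (ii) log2 fold change of mean accessibility (class vs rest, with a
    pseudocount on both means); (iii) Welch t-test p, BH-adjusted across
    peaks within class. ``is_marker`` iff coefficient > 0, log2FC > 0 and
    adjusted p < ``alpha``. Classes with fewer than 2 cells are skipped.
    """
    labels = pd.Series(np.asarray(pd.Series(classes)), dtype=object)
    if labels.shape[0] != len(atac.cells):
        raise ValueError("class labels must align with the ATAC cells")
    sizes = labels.value_counts()
    usable = sorted(sizes.index[sizes >= 2])
    skipped = sorted(set(sizes.index) - set(usable))
    if skipped:
        logger.warning("classes with < 2 cells skipped: %s", skipped)
    if len(usable) < 2:
        raise ValueError("need at least 2 classes with >= 2 cells")
    keep = labels.isin(usable).to_numpy()
    X = atac.counts[keep]
    y = labels[keep].to_numpy()

    # one-vs-rest: one regularized binary fit per class over all peaks
    coef = {}
    for cls in usable:
        clf = LogisticRegression(max_iter=max_iter)  # L2-regularized by default
        clf.fit(X, y == cls)
        sign = 1.0 if clf.classes_[-1] else -1.0
        coef[cls] = sign * clf.coef_.ravel()

    Xc = sp.csr_matrix(X)
    Xsq = Xc.multiply(Xc)
    rows = []
    for cls in usable:
        in_cls = y == cls
        n1, n0 = int(in_cls.sum()), int((~in_cls).sum())
        m1 = np.asarray(Xc[in_cls].mean(axis=0)).ravel()
        m0 = np.asarray(Xc[~in_cls].mean(axis=0)).ravel()
        v1 = np.asarray(Xsq[in_cls].mean(axis=0)).ravel() - m1 ** 2
        v0 = np.asarray(Xsq[~in_cls].mean(axis=0)).ravel() - m0 ** 2
        # unbiased variances for the Welch test
        v1 = v1 * n1 / max(n1 - 1, 1)
        v0 = v0 * n0 / max(n0 - 1, 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_res = stats.ttest_ind_from_stats(
                m1, np.sqrt(v1), n1, m0, np.sqrt(v0), n0, equal_var=False
            )
        p = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
        p_adj = multipletests(p, method="fdr_bh")[1]
        log2fc = np.log2((m1 + pseudocount) / (m0 + pseudocount))
        cls_coef = coef[cls]
        for j, peak in enumerate(atac.features):
            rows.append((peak, cls, cls_coef[j], log2fc[j], p_adj[j]))
    out = pd.DataFrame(
        rows, columns=["peak_id", "cell_class", "reg_lr_coef", "log2fc", "t_p_adj"]
    )
    out["is_marker"] = (
        (out["reg_lr_coef"] > 0) & (out["log2fc"] > 0) & (out["t_p_adj"] < alpha)
    )
    return out


def rank_variable_genes(counts: CountMatrix, n_top: int | None = None) -> pd.Series:
    """Rank genes by normalized-count variance (a caller-side helper for
    restricting link testing to the most variable genes)."""
    mat = counts.counts.astype(float)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    norm = sp.diags(1e4 / totals) @ mat
    mean = np.asarray(norm.mean(axis=0)).ravel()
    meansq = np.asarray(norm.multiply(norm).mean(axis=0)).ravel()
    var = meansq - mean ** 2
    ranked = pd.Series(var, index=counts.features).sort_values(ascending=False)
    return ranked.head(n_top) if n_top else ranked
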