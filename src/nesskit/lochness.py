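"""Per-cell regional neighborhood-enrichment scores (lochNESS).

For a cell type with N cells across M regions, the raw score of cell n
for region m is

    lochNESS(n, m) = (#region-m cells among the k nearest neighbors of n / k)
                     / (#region-m cells in the cell type / N)

so 1 means the cell's transcriptional neighborhood reflects the region's
overall share, >1 regional enrichment, <1 depletion. Neighbors are found
by Euclidean distance in a low-dimensional embedding, excluding the cell
itself; ties at the k-th neighbor break by ascending cell index for
determinism. A normalized variant divides each row by its sum over the
regions of interest so scores are comparable across regions, and each
cell can be summarized by its argmax region.

A per-gene count GLM on the M lochNESS covariates then flags genes whose
expression tracks regional enrichment (region-biased genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .types import CountMatrix, Embedding

logger = logging.getLogger(__name__)

#: above this many cells the exact all-pairs search switches to an
#: approximate (but seeded) tree-based search
EXACT_KNN_MAX_N = 50_000


@dataclass
class LochnessMatrix:
    """Cell x region enrichment scores for one cell type."""

    cells: list[str]
    regions: list[str]
    raw: np.ndarray
    k: int
    N: int
    normalized: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.cells), len(self.regions)):
            raise ValueError("raw matrix shape does not match cell/region lists")
        if np.nanmin(self.raw, initial=0.0) < 0:
            raise ValueError("raw lochNESS scores must be non-negative")
        if not self.k < self.N:
            raise ValueError("k must be smaller than the number of cells N")

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        mat = self.normalized if normalized else self.raw
        if mat is None:
            raise ValueError("normalized scores have not been computed")
        return pd.DataFrame(mat, index=self.cells, columns=self.regions)


def _knn_indices_exact(coords: np.ndarray, k: int, chunk: int = 1024) -> np.ndarray:
    """Exact kNN (self excluded) with deterministic (distance, index) ties."""
    n = coords.shape[0]
    out = np.empty((n, k), dtype=np.intp)
    idx = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(coords[start:stop], coords)
        d[np.arange(stop - start), idx[start:stop]] = np.inf  # exclude self
        # lexsort: primary key distance, secondary key ascending index
        order = np.lexsort((np.broadcast_to(idx, d.shape), d), axis=1)
        out[start:stop] = order[:, :k]
    return out


def _knn_indices_approx(coords: np.ndarray, k: int, seed: int) -> np.ndarray:
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto")
    nn.fit(coords)
    ind = nn.kneighbors(coords, return_distance=False)
    # drop the self column (first hit at distance 0)
    rows = np.arange(coords.shape[0])[:, None]
    keep = ind != rows
    out = np.empty((coords.shape[0], k), dtype=np.intp)
    for i in range(coords.shape[0]):
        out[i] = ind[i][keep[i]][:k]
    return out


def compute_lochness(
    embedding: Embedding,
    region_labels: pd.Series | np.ndarray,
    k: int,
    seed: int = 0,
) -> LochnessMatrix:
    """Compute raw lochNESS scores for every cell and region.

    ``region_labels`` gives each cell's region, aligned with
    ``embedding.cells``. Regions with no cells in the cell type yield a
    null column with a warning. Requires ``1 <= k < N``.
    """
    series = pd.Series(region_labels).reset_index(drop=True)
    N = embedding.n_cells
    if len(series) != N:
        raise ValueError("region labels must align with embedding cells")
    if series.isna().any():
        raise ValueError("every cell requires a region label")
    if not 1 <= k < N:
        raise ValueError(f"k must satisfy 1 <= k < N (k={k}, N={N})")

    if isinstance(series.dtype, pd.CategoricalDtype):
        regions = list(series.cat.categories)  # declared set, may include empty regions
    else:
        regions = sorted(series.unique().tolist())
    region_index = {r: j for j, r in enumerate(regions)}
    codes = np.array([region_index[r] for r in series])
    region_counts = np.bincount(codes, minlength=len(regions)).astype(float)
    empty_regions = region_counts == 0
    if empty_regions.any():
        logger.warning("regions with no cells in this cell type yield null columns: %s",
                       [r for r, e in zip(regions, empty_regions) if e])

    if N <= EXACT_KNN_MAX_N:
        nbrs = _knn_indices_exact(embedding.coords, k)
    else:
        nbrs = _knn_indices_approx(embedding.coords, k, seed)

    neighbor_codes = codes[nbrs]  # (N, k)
    counts = np.zeros((N, len(regions)))
    for j in range(len(regions)):
        counts[:, j] = (neighbor_codes == j).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (counts / k) / (region_counts / N)[None, :]
    raw[:, empty_regions] = np.nan
    return LochnessMatrix(cells=list(embedding.cells), regions=regions, raw=raw, k=k, N=N)


def normalize_lochness(
    L: LochnessMatrix, regions_of_interest: list[str] | None = None
) -> LochnessMatrix:
    """Row-normalize raw scores over a region subset (lochNESS*).

    Each row is divided by its sum over the subset so rows sum to 1 and
    scores become comparable across the regions of interest. All-zero
    rows yield null rows with a warning.
    """
    subset = list(regions_of_interest) if regions_of_interest is not None else list(L.regions)
    if not subset:
        raise ValueError("regions_of_interest must be non-empty")
    missing = [r for r in subset if r not in L.regions]
    if missing:
        raise ValueError(f"unknown regions: {missing}")
    cols = [L.regions.index(r) for r in subset]
    raw = L.raw[:, cols]
    row_sums = raw.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        logger.warning("%d cells have all-zero scores over the subset; rows are null",
                       int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = raw / row_sums[:, None]
    normalized[zero] = np.nan
    return LochnessMatrix(
        cells=list(L.cells), regions=subset, raw=raw, k=L.k, N=L.N, normalized=normalized
    )


def argmax_region(L: LochnessMatrix) -> pd.DataFrame:
    """Summarize each cell by the region with the largest raw score.

    Ties break by region order (a ``tie`` flag marks them); all-null rows
    yield a null label.
    """
    raw = L.raw
    labels: list[object] = []
    ties = []
    for row in raw:
        if np.all(np.isnan(row)):
            labels.append(None)
            ties.append(False)
            continue
        best = np.nanargmax(row)
        labels.append(L.regions[best])
        ties.append(int(np.sum(row == row[best])) > 1)
    return pd.DataFrame({"cell_id": L.cells, "region": labels, "tie": ties})


def default_size_factors(counts: CountMatrix) -> np.ndarray:
    """Total UMI divided by the median total UMI."""
    totals = np.asarray(counts.counts.sum(axis=1)).ravel().astype(float)
    return totals / np.median(totals)


def lochness_glm(
    counts: CountMatrix,
    L: LochnessMatrix,
    size_factors: np.ndarray | None = None,
    family: str = "nb",
    alpha_bh: float = 0.05,
) -> pd.DataFrame:
    """Per-gene regression of expression on the M lochNESS covariates.

    Fits, for each gene, a log-link count GLM

        log E[y] = b0 + b1 * lochNESS_region1 + ... + bM * lochNESS_regionM
                   + log(size_factor)

    The default family is negative binomial with a per-gene
    method-of-moments dispersion estimated from a Poisson pre-fit,
    matching the overdispersion of single-cell UMI counts;
    ``family="poisson"`` fits Poisson with overdispersion-robust (HC0
    sandwich) standard errors instead. Wald p-values per coefficient are
    BH-adjusted across all gene x region tests in one family. Genes with
    zero total count are skipped with null rows.

    The M lochNESS columns plus an intercept are exactly collinear by
    construction (the region-share-weighted sum of a cell's scores is 1),
    so collinear columns are dropped from the right with a warning and
    coefficients read as contrasts against the dropped region.

    Returns a long DataFrame with columns gene_id, region, beta, p, p_adj
    plus one intercept row per fitted gene (region = "(intercept)").
    """
    if counts.cells != L.cells:
        raise ValueError("counts and lochNESS matrix must cover the same cells in order")
    if size_factors is None:
        size_factors = default_size_factors(counts)
    size_factors = np.asarray(size_factors, dtype=float)
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")

    usable = [j for j in range(len(L.regions)) if not np.isnan(L.raw[:, j]).all()]
    X = np.column_stack([np.ones(len(L.cells)), L.raw[:, usable]])
    col_regions = [L.regions[j] for j in usable]
    # drop collinear columns from the right until full rank
    while np.linalg.matrix_rank(X) < X.shape[1] and X.shape[1] > 1:
        logger.warning("design is rank-deficient; dropping lochNESS column %r",
                       col_regions[-1])
        X = X[:, :-1]
        col_regions = col_regions[:-1]
    offset = np.log(size_factors)

    if family not in ("nb", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    mat = counts.counts.tocsc()
    rows = []
    for gi, gene in enumerate(counts.features):
        y = np.asarray(mat[:, gi].todense()).ravel()
        if y.sum() == 0:
            rows.append((gene, None, np.nan, np.nan))
            continue
        try:
            if family == "poisson":
                res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit(
                    cov_type="HC0"
                )
            else:
                pre = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
                mu = pre.fittedvalues
                # method-of-moments NB dispersion; ~0 recovers the Poisson fit
                alpha = max(((y - mu) ** 2 - mu).sum() / (mu**2).sum(), 1e-8)
                res = sm.GLM(
                    y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                ).fit()
        except Exception as exc:  # non-convergence on degenerate genes
            logger.warning("GLM failed for gene %r: %s", gene, exc)
            rows.append((gene, None, np.nan, np.nan))
            continue
        rows.append((gene, "(intercept)", res.params[0], res.pvalues[0]))
        for j, region in enumerate(col_regions, start=1):
            rows.append((gene, region, res.params[j], res.pvalues[j]))

    table = pd.DataFrame(rows, columns=["gene_id", "region", "beta", "p"])
    table["p_adj"] = np.nan
    testable = table["region"].notna() & (table["region"] != "(intercept)") & table["p"].notna()
    if testable.any():
        table.loc[testable, "p_adj"] = multipletests(
            table.loc[testable, "p"], method="fdr_bh"
        )[1]
    table["significant"] = table["p_adj"] < alpha_bh
    return table
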