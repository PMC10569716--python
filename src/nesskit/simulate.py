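"""Synthetic multi-region paired RNA/ATAC single-cell data with planted
ground truth.

The generator emulates the statistical structure the analysis stages
assume, so every stage can be verified end to end without any download:

* per-cell-type multinomial composition across regions;
* negative-binomial UMI counts (fixed dispersion; Poisson as a limiting
  flag) with multiplicative region-biased effects on chosen genes;
* a low-dimensional embedding built directly (transcriptionally similar
  cells are near each other; regions carrying biased genes get a
  coordinate shift) rather than recomputed by PCA/UMAP;
* mixture doublets placed at parent-mean rates and coordinates, with
  doublet scores drawn Beta(8, 2) against a Beta(2, 18) singlet
  background (bimodal, with the singlet mode safely below the
  cluster-mean doublet cut);
* cross-well barcode contamination as label reassignment from a donor
  sample's composition;
* peak accessibility linked logistically to metacell expression for
  planted peak-gene pairs, constant base rate elsewhere.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .links import MetacellAssignment, pseudobulk_log2cpm
from .types import CountMatrix, Embedding

DOUBLET_SCORE_AB = (8.0, 2.0)
SINGLET_SCORE_AB = (2.0, 18.0)


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    ``composition`` maps each cell type to its per-region weights
    (defaults to uniform); ``region_bias`` plants multiplicative
    ``2**log2_effect`` expression effects for (gene, region) pairs;
    ``planted_links`` are (peak_id, gene_id, beta) logistic links from
    metacell expression to peak accessibility.
    """

    n_cells: int = 2000
    n_genes: int = 200
    n_peaks: int = 100
    regions: list[str] = field(default_factory=lambda: ["A", "B", "C", "D"])
    cell_types: list[str] = field(default_factory=lambda: ["T1", "T2", "T3"])
    composition: dict[str, list[float]] | None = None
    type_profiles: dict[str, list[float]] | None = None  # relative expression weights
    region_bias: list[tuple[str, str, float]] = field(default_factory=list)
    doublet_frac: float = 0.0
    barcodes_per_sample: int = 6
    contaminated_barcodes: list[tuple[str, float, str]] = field(default_factory=list)
    planted_links: list[tuple[str, str, float]] = field(default_factory=list)
    mean_umi: float = 265.0
    umi_sigma: float = 0.35
    dispersion: float | None = 0.5  # NB dispersion; None = Poisson
    embedding_dim: int = 10
    type_separation: float = 8.0
    region_shift: float = 3.0
    embedding_noise_sd: float = 1.0
    marker_boost: float = 8.0
    atac_intercept: float = 0.0
    atac_base_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.doublet_frac < 0.5:
            raise ValueError("doublet_frac must lie in [0, 0.5)")
        if self.composition is None:
            w = [1.0 / len(self.regions)] * len(self.regions)
            self.composition = {t: list(w) for t in self.cell_types}
        for t, w in self.composition.items():
            if t not in self.cell_types:
                raise ValueError(f"composition references unknown cell type {t!r}")
            if len(w) != len(self.regions) or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"composition weights for {t!r} must sum to 1 "
                                 f"over {len(self.regions)} regions")
        for barcode, frac, _donor in self.contaminated_barcodes:
            # 0 is a permitted no-op; >= 1 or negative is a config error
            if not 0 <= frac < 1:
                raise ValueError(f"mixing fraction for {barcode!r} must lie in [0, 1)")

    @property
    def gene_ids(self) -> list[str]:
        return [f"gene_{i:04d}" for i in range(self.n_genes)]

    @property
    def peak_ids(self) -> list[str]:
        return [f"peak_{i:04d}" for i in range(self.n_peaks)]


@dataclass
class Truth:
    """Planted ground truth for downstream verification."""

    is_doublet: np.ndarray
    contaminated_barcodes: set
    biased_genes: list[tuple[str, str, float]]
    planted_links: list[tuple[str, str, float]]
    cell_types: np.ndarray
    expected_rates: np.ndarray | None = None


def _type_profiles(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-type relative expression profiles (rows sum to 1).

    Explicit ``type_profiles`` in the config take precedence; otherwise a
    shared gamma baseline with a disjoint block of boosted marker genes
    per type is drawn.
    """
    if config.type_profiles is not None:
        rng.gamma(2.0, 1.0, size=config.n_genes)  # keep the draw sequence stable
        profiles = np.array([config.type_profiles[t] for t in config.cell_types], float)
        if profiles.shape != (len(config.cell_types), config.n_genes):
            raise ValueError("type_profiles must give one weight per gene per cell type")
        return profiles / profiles.sum(axis=1, keepdims=True)
    base = rng.gamma(2.0, 1.0, size=config.n_genes)
    n_types = len(config.cell_types)
    profiles = np.tile(base, (n_types, 1))
    block = max(1, config.n_genes // (2 * n_types))
    for ti in range(n_types):
        lo = ti * block
        profiles[ti, lo:lo + block] *= config.marker_boost
    return profiles / profiles.sum(axis=1, keepdims=True)


def _sample_counts(mu: np.ndarray, dispersion: float | None,
                   rng: np.random.Generator) -> np.ndarray:
    """NB draws via the gamma-Poisson mixture; Poisson when dispersion is None."""
    if dispersion is None:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_rna(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, Embedding, Truth]:
    """Generate the RNA count matrix, cell metadata, embedding and truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    regions = config.regions
    types = config.cell_types
    type_idx = rng.integers(0, len(types), size=n)
    region_labels = np.empty(n, dtype=object)
    for ti, t in enumerate(types):
        mask = type_idx == ti
        region_labels[mask] = rng.choice(regions, size=int(mask.sum()),
                                         p=config.composition[t])

    profiles = _type_profiles(config, rng)
    libsize = np.exp(rng.normal(np.log(config.mean_umi), config.umi_sigma, size=n))
    mu = libsize[:, None] * profiles[type_idx]

    gene_pos = {g: i for i, g in enumerate(config.gene_ids)}
    for gene, region, effect in config.region_bias:
        if gene not in gene_pos:
            raise ValueError(f"region_bias references unknown gene {gene!r}")
        if region not in regions:
            raise ValueError(f"region_bias references unknown region {region!r}")
        in_region = region_labels == region
        mu[in_region, gene_pos[gene]] *= 2.0 ** effect

    # embedding: type centers, a shift for regions carrying biased genes,
    # isotropic noise
    d = config.embedding_dim
    centers = rng.normal(0.0, config.type_separation, size=(len(types), d))
    coords = centers[type_idx] + rng.normal(0.0, config.embedding_noise_sd, size=(n, d))
    shifted_regions = sorted({r for _g, r, _e in config.region_bias})
    for r in shifted_regions:
        direction = rng.normal(size=d)
        direction /= np.linalg.norm(direction)
        coords[region_labels == r] += config.region_shift * direction

    # doublets: the last fraction of cells become mixtures of themselves
    # and a random partner (parent-mean rates and coordinates)
    is_doublet = np.zeros(n, dtype=bool)
    n_doub = int(round(config.doublet_frac * n))
    if n_doub:
        doub = np.arange(n - n_doub, n)
        partners = rng.integers(0, n - n_doub, size=n_doub)
        mu[doub] = (mu[doub] + mu[partners]) / 2.0
        coords[doub] = (coords[doub] + coords[partners]) / 2.0
        is_doublet[doub] = True

    counts = _sample_counts(mu, config.dispersion, rng)

    score = rng.beta(*SINGLET_SCORE_AB, size=n)
    score[is_doublet] = rng.beta(*DOUBLET_SCORE_AB, size=n_doub)
    cluster = type_idx.astype(int)
    cluster[is_doublet] = len(types)  # dedicated doublet cluster

    # samples follow regions; barcodes round-robin within each sample
    sample_ids = np.array([f"sample_{r}" for r in region_labels], dtype=object)
    barcode_counter = {r: 0 for r in regions}
    barcodes = np.empty(n, dtype=object)
    for i in range(n):
        r = region_labels[i]
        barcodes[i] = f"{sample_ids[i]}_bc{barcode_counter[r] % config.barcodes_per_sample}"
        barcode_counter[r] += 1

    cell_ids = [f"cell_{i:06d}" for i in range(n)]
    meta = pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": sample_ids,
        "rt_barcode": barcodes,
        "region": region_labels,
        "region_subclass": region_labels,
        "cell_class": np.array(types, dtype=object)[type_idx],
        "cell_subtype": [
            f"{types[t]}_s{s}" for t, s in zip(type_idx, rng.integers(0, 2, size=n))
        ],
        "cluster_id": cluster,
        "doublet_score": score,
        "total_umi": counts.sum(axis=1),
        "n_genes": (counts > 0).sum(axis=1),
        "mito_frac": rng.beta(1.0, 40.0, size=n),
        "frip": rng.beta(12.0, 12.0, size=n),
    })

    cm = CountMatrix(cells=cell_ids, features=config.gene_ids,
                     counts=sp.csr_matrix(counts), modality="rna")
    emb = Embedding(cells=cell_ids, coords=coords)
    truth = Truth(
        is_doublet=is_doublet,
        contaminated_barcodes=set(),
        biased_genes=list(config.region_bias),
        planted_links=list(config.planted_links),
        cell_types=np.array(types, dtype=object)[type_idx],
        expected_rates=mu,
    )
    return cm, meta, emb, truth


def simulate_atac(
    config: SimConfig, rna: CountMatrix, metacells: MetacellAssignment
) -> CountMatrix:
    """Generate binarized peak accessibility tied to metacell expression.

    For each planted link (peak, gene, beta) the per-cell open
    probability is ``sigmoid(atac_intercept + beta * (x - mean(x)))``
    where x is the log2CPM of the gene in the cell's metacell (the
    predictor is centered so ``atac_intercept`` sets the open rate at
    average expression; the slope is unchanged). Unplanted peaks open at
    the constant ``atac_base_rate``.
    """
    if metacells.cells != rna.cells:
        raise ValueError("metacell assignment must cover the RNA cells in order")
    rng = np.random.default_rng(config.seed + 1)
    expr = pseudobulk_log2cpm(rna, metacells)
    gene_set = set(rna.features)
    n = len(rna.cells)
    prob = np.full((n, config.n_peaks), config.atac_base_rate)
    peak_pos = {p: i for i, p in enumerate(config.peak_ids)}
    for peak, gene, beta in config.planted_links:
        if gene not in gene_set:
            raise ValueError(f"planted link references unknown gene {gene!r}")
        if peak not in peak_pos:
            raise ValueError(f"planted link references unknown peak {peak!r}")
        x = expr[gene].to_numpy()[metacells.metacell_id]
        eta = config.atac_intercept + beta * (x - np.nanmean(x))
        prob[:, peak_pos[peak]] = 1.0 / (1.0 + np.exp(-eta))
    opens = rng.random((n, config.n_peaks)) < prob
    return CountMatrix(cells=list(rna.cells), features=config.peak_ids,
                       counts=sp.csr_matrix(opens.astype(np.int8)), modality="atac")


def inject_barcode_contamination(
    meta: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, set]:
    """Reassign labels for a fraction of cells in contaminated barcodes.

    For each configured (barcode, fraction, donor_sample) the stated
    fraction of the barcode's cells receives cell class/subtype labels
    drawn from the donor sample's empirical composition. Returns the
    updated metadata and the set of contaminated barcodes.
    """
    rng = np.random.default_rng(config.seed + 2)
    out = meta.copy()
    flagged = set()
    for barcode, frac, donor in config.contaminated_barcodes:
        in_bc = out["rt_barcode"] == barcode
        if not in_bc.any():
            raise ValueError(f"contaminated barcode {barcode!r} not present")
        donor_cells = out[out["sample_id"] == donor]
        if donor_cells.empty:
            raise ValueError(f"donor sample {donor!r} not present")
        idx = out.index[in_bc]
        n_swap = int(round(frac * len(idx)))
        swap = rng.choice(idx, size=n_swap, replace=False)
        draws = rng.integers(0, len(donor_cells), size=n_swap)
        out.loc[swap, "cell_class"] = donor_cells["cell_class"].to_numpy()[draws]
        out.loc[swap, "cell_subtype"] = donor_cells["cell_subtype"].to_numpy()[draws]
        flagged.add(barcode)
    return out, flagged


def simulate_dataset(config: SimConfig, target_per_metacell: int = 50):
    """Run the full generator: RNA, metadata (with contamination),
    embedding, metacells, ATAC and truth.

    Returns a dict with keys ``rna``, ``atac``, ``meta``, ``embedding``,
    ``metacells`` and ``truth``.
    """
    from .links import build_metacells, choose_n_meta

    rna, meta, emb, truth = simulate_rna(config)
    if config.contaminated_barcodes:
        meta, flagged = inject_barcode_contamination(meta, config)
        truth.contaminated_barcodes = flagged
    n_meta = max(1, choose_n_meta(config.n_cells, min(target_per_metacell, config.n_cells)))
    metacells = build_metacells(emb, n_meta, seed=config.seed)
    atac = simulate_atac(config, rna, metacells)
    return {"rna": rna, "atac": atac, "meta": meta, "embedding": emb,
            "metacells": metacells, "truth": truth}
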