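import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given
from hypothesis import strategies as st

from nesskit.links import (
    MetacellAssignment,
    build_metacells,
    choose_n_meta,
    combine_evidence,
    differential_accessibility,
    fit_link_logistic,
    fit_links,
    pair_peaks_genes,
    permutation_p_adj,
    pseudobulk_log2cpm,
)
from nesskit.types import CountMatrix, Embedding, GeneRecord, PeakRecord


class TestChooseNMeta:
    @pytest.mark.parametrize("n,target,expected", [
        (2_583_967, 250, 10_335),   # the study's worked example
        (1000, 250, 4),
        (999, 250, 3),              # floor semantics
    ])
    def test_values(self, n, target, expected):
        assert choose_n_meta(n, target) == expected

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            choose_n_meta(100, 250)

    @given(n=st.integers(1, 10**7), t=st.integers(1, 1000))
    def test_floor_bracket_invariant(self, n, t):
        if n < t:
            return
        k = choose_n_meta(n, t)
        assert k * t <= n < (k + 1) * t


class TestBuildMetacells:
    def test_single_metacell(self, rng):
        emb = Embedding(cells=[f"c{i}" for i in range(10)], coords=rng.normal(size=(10, 3)))
        assign = build_metacells(emb, 1, seed=0)
        assert set(assign.metacell_id) == {0}

    def test_two_blobs_recovered(self, rng):
        blob = np.vstack([rng.normal(0, 0.1, size=(30, 2)),
                          rng.normal(10, 0.1, size=(30, 2))])
        emb = Embedding(cells=[f"c{i}" for i in range(60)], coords=blob)
        assign = build_metacells(emb, 2, seed=0)
        first, second = assign.metacell_id[:30], assign.metacell_id[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert set(first) != set(second)

    def test_deterministic_given_seed(self, rng):
        emb = Embedding(cells=[f"c{i}" for i in range(50)], coords=rng.normal(size=(50, 4)))
        a = build_metacells(emb, 5, seed=3)
        b = build_metacells(emb, 5, seed=3)
        assert np.array_equal(a.metacell_id, b.metacell_id)

    def test_too_many_metacells_rejected(self, rng):
        emb = Embedding(cells=["a", "b"], coords=rng.normal(size=(2, 2)))
        with pytest.raises(ValueError):
            build_metacells(emb, 2, seed=0)


def _assign(ids, n_meta):
    return MetacellAssignment(cells=[f"c{i}" for i in range(len(ids))],
                              metacell_id=np.asarray(ids), n_meta=n_meta)


class TestPseudobulk:
    def test_hand_arithmetic(self):
        counts = sp.csr_matrix(np.array([[10, 990]]))
        cm = CountMatrix(cells=["c0"], features=["g0", "g1"], counts=counts, modality="rna")
        out = pseudobulk_log2cpm(cm, _assign([0], 1))
        # CPM of g0 = 1e6 * 10 / 1000 = 10,000 -> log2(10,001)
        assert out.loc[0, "g0"] == pytest.approx(np.log2(10_001), abs=1e-9)

    def test_zero_count_gene_is_zero(self):
        counts = sp.csr_matrix(np.array([[5, 0]]))
        cm = CountMatrix(cells=["c0"], features=["g0", "g1"], counts=counts, modality="rna")
        out = pseudobulk_log2cpm(cm, _assign([0], 1))
        assert out.loc[0, "g1"] == 0.0

    def test_cpm_rows_sum_to_one_million(self, rng):
        counts = sp.csr_matrix(rng.integers(0, 20, size=(30, 8)))
        cm = CountMatrix(cells=[f"c{i}" for i in range(30)],
                         features=[f"g{j}" for j in range(8)],
                         counts=counts, modality="rna")
        out = pseudobulk_log2cpm(cm, _assign(rng.integers(0, 3, 30), 3))
        cpm = 2.0 ** out.to_numpy() - 1
        assert np.allclose(cpm.sum(axis=1), 1e6)

    def test_cell_order_invariance(self, rng):
        counts = rng.integers(0, 9, size=(20, 5))
        ids = rng.integers(0, 4, 20)
        cm = CountMatrix(cells=[f"c{i}" for i in range(20)],
                         features=[f"g{j}" for j in range(5)],
                         counts=sp.csr_matrix(counts), modality="rna")
        out1 = pseudobulk_log2cpm(cm, _assign(ids, 4))
        perm = rng.permutation(20)
        cm2 = CountMatrix(cells=[f"c{i}" for i in perm],
                          features=cm.features,
                          counts=sp.csr_matrix(counts[perm]), modality="rna")
        assign2 = MetacellAssignment(cells=cm2.cells, metacell_id=ids[perm], n_meta=4)
        out2 = pseudobulk_log2cpm(cm2, assign2)
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_metacell_null_row(self, caplog):
        counts = sp.csr_matrix(np.array([[5], [5]]))
        cm = CountMatrix(cells=["c0", "c1"], features=["g0"], counts=counts, modality="rna")
        with caplog.at_level("WARNING"):
            out = pseudobulk_log2cpm(cm, _assign([0, 0], 2))
        assert np.isnan(out.loc[1, "g0"])


def brute_force_pairs(peaks, genes, window):
    """All-pairs oracle over every peak x gene, interval gap by scanning."""
    rows = []
    for g in genes:
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            # closest-base distance between the half-open intervals
            if p.start < g.promoter_end and g.promoter_start < p.end:
                gap = 0
            elif p.end <= g.promoter_start:
                gap = g.promoter_start - (p.end - 1)
            else:
                gap = p.start - (g.promoter_end - 1)
            if gap <= window:
                rows.append((g.gene_id, p.peak_id))
    return set(rows)


class TestPairPeaksGenes:
    def gene(self, tss=10_000, strand="+", chrom="chr1"):
        return GeneRecord(gene_id="g", chrom=chrom, strand=strand, tss=tss)

    def test_overlapping_promoter_paired_at_zero_distance(self):
        g = self.gene()
        p = PeakRecord("p", "chr1", 9_900, 10_100)  # spans the TSS
        out = pair_peaks_genes([p], [g])
        assert len(out) == 1 and out["signed_distance"].iloc[0] == 0

    def test_window_boundary_inclusive_then_strict(self):
        g = self.gene(tss=200_000)  # promoter [198000, 200001)
        inside = PeakRecord("in", "chr1", 350_000, 350_100)   # gap 150,000
        outside = PeakRecord("out", "chr1", 350_001, 350_101)  # gap 150,001
        out = pair_peaks_genes([inside, outside], [g], window=150_000)
        assert out["peak_id"].tolist() == ["in"]

    def test_signed_distance_strand_aware(self):
        plus = self.gene(tss=10_000, strand="+")
        minus = GeneRecord(gene_id="g2", chrom="chr1", strand="-", tss=10_000)
        peak = PeakRecord("p", "chr1", 11_000, 11_100)  # 1000 bp right of the TSS
        out = pair_peaks_genes([peak], [plus, minus])
        dist = out.set_index("gene_id")["signed_distance"]
        assert dist["g"] == 1000    # downstream of a + gene
        assert dist["g2"] == -1000  # upstream of a - gene

    def test_chromosome_mismatch_warned_and_skipped(self, caplog):
        g = self.gene(chrom="chr1")
        p = PeakRecord("p", "chr2", 100, 200)
        with caplog.at_level("WARNING"):
            out = pair_peaks_genes([p], [g])
        assert out.empty
        assert any("only one input" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chroms = ["chr1", "chr2"]
        peaks = [
            PeakRecord(f"p{i}", rng.choice(chroms), s := int(rng.integers(0, 400_000)),
                       s + int(rng.integers(100, 2000)))
            for i in range(8)
        ]
        genes = [
            GeneRecord(gene_id=f"g{i}", chrom=rng.choice(chroms),
                       strand=rng.choice(["+", "-"]), tss=int(rng.integers(0, 400_000)))
            for i in range(3)
        ]
        out = pair_peaks_genes(peaks, genes, window=150_000)
        got = set(zip(out["gene_id"], out["peak_id"]))
        assert got == brute_force_pairs(peaks, genes, 150_000)


class TestFitLinkLogistic:
    def test_constant_predictor(self):
        assign = _assign([0, 0, 1, 1], 2)
        beta, p, reason = fit_link_logistic(
            np.array([0, 1, 0, 1]), assign, pd.Series([2.0, 2.0]))
        assert (beta, p, reason) == (None, None, "constant_predictor")

    def test_constant_response(self):
        assign = _assign([0, 0, 1, 1], 2)
        beta, p, reason = fit_link_logistic(
            np.array([1, 1, 1, 1]), assign, pd.Series([1.0, 2.0]))
        assert (beta, p, reason) == (None, None, "constant_response")

    def test_planted_slope_recovered(self, rng):
        n, n_meta = 5000, 50
        ids = rng.integers(0, n_meta, n)
        expr = pd.Series(rng.normal(0, 1, n_meta))
        x = expr.to_numpy()[ids]
        prob = 1 / (1 + np.exp(-(0.0 + 2.0 * x)))
        y = (rng.random(n) < prob).astype(int)
        beta, p, reason = fit_link_logistic(y, _assign(ids, n_meta), expr)
        assert reason == "ok"
        assert beta == pytest.approx(2.0, abs=0.5)
        assert p < 1e-10

    def test_null_pairs_calibrated(self, rng):
        n, n_meta = 800, 20
        ids = rng.integers(0, n_meta, n)
        expr = pd.Series(rng.normal(0, 1, n_meta))
        hits = 0
        n_pairs = 200
        for _ in range(n_pairs):
            y = (rng.random(n) < 0.3).astype(int)
            _beta, p, reason = fit_link_logistic(y, _assign(ids, n_meta), expr)
            hits += (reason == "ok" and p < 0.05)
        assert hits / n_pairs == pytest.approx(0.05, abs=0.035)

    def test_separation_capped(self):
        # perfectly separated: open iff expression positive
        ids = np.arange(20) % 2
        expr = pd.Series([-5.0, 5.0])
        y = ids.copy()
        beta, p, reason = fit_link_logistic(y, _assign(ids, 2), expr)
        assert reason == "separation"
        assert p is None and abs(beta) <= 25.0


class TestCombineEvidence:
    def _links(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "peak_id", "beta",
                                           "p_adj", "external_p_adj"])

    def test_rule_application(self):
        out = combine_evidence(self._links([
            ("g", "p1", 1.3, 0.01, 0.02),
            ("g", "p2", -0.7, 0.01, 0.2),
            ("g", "p3", -2.0, 0.003, 0.04),
        ]))
        assert out["candidate"].tolist() == [True, False, True]
        assert out["direction"].tolist() == ["positive", None, "negative"]

    def test_missing_external_is_untestable(self):
        out = combine_evidence(self._links([("g", "p1", 1.0, 0.01, None)]))
        assert pd.isna(out["candidate"].iloc[0])
        assert out["direction"].iloc[0] is None

    def test_permutation_p_adj_monotone(self, rng):
        scores = pd.Series(rng.normal(size=100))
        padj = permutation_p_adj(scores, n_perm=2000, seed=1)
        # higher score -> smaller (or equal) adjusted p
        order = scores.sort_values(ascending=False).index
        assert (padj[order].diff().dropna() >= -1e-12).all()


class TestDifferentialAccessibility:
    def _toy(self, rng, n_per=100):
        # peak 0: open in 90% of A, 5% elsewhere; peak 1: 40% everywhere;
        # peak 2: closed everywhere
        labels = np.array(["A"] * n_per + ["B"] * n_per)
        col0 = np.where(labels == "A", rng.random(2 * n_per) < 0.9,
                        rng.random(2 * n_per) < 0.05)
        col1 = rng.random(2 * n_per) < 0.4
        col2 = np.zeros(2 * n_per, dtype=bool)
        X = sp.csr_matrix(np.column_stack([col0, col1, col2]).astype(np.int8))
        cm = CountMatrix(cells=[f"c{i}" for i in range(2 * n_per)],
                         features=["pk0", "pk1", "pk2"], counts=X, modality="atac")
        return cm, labels

    def test_specific_peak_is_marker(self, rng):
        cm, labels = self._toy(rng)
        out = differential_accessibility(cm, labels).set_index(["peak_id", "cell_class"])
        assert out.loc[("pk0", "A"), "is_marker"]
        assert not out.loc[("pk0", "B"), "is_marker"]

    def test_uniform_peak_not_marker(self, rng):
        cm, labels = self._toy(rng)
        out = differential_accessibility(cm, labels)
        assert not out.loc[out["peak_id"] == "pk1", "is_marker"].any()

    def test_closed_peak_zero_log2fc(self, rng):
        cm, labels = self._toy(rng)
        out = differential_accessibility(cm, labels)
        sub = out[out["peak_id"] == "pk2"]
        assert (sub["log2fc"] == 0).all() and not sub["is_marker"].any()

    def test_cell_order_invariance(self, rng):
        cm, labels = self._toy(rng)
        out1 = differential_accessibility(cm, labels)
        perm = rng.permutation(len(labels))
        cm2 = CountMatrix(cells=[cm.cells[i] for i in perm],
                          features=cm.features,
                          counts=cm.counts[perm], modality="atac")
        out2 = differential_accessibility(cm2, labels[perm])
        merged = out1.merge(out2, on=["peak_id", "cell_class"], suffixes=("_1", "_2"))
        assert (merged["is_marker_1"] == merged["is_marker_2"]).all()
        assert np.allclose(merged["log2fc_1"], merged["log2fc_2"])

    def test_small_class_skipped(self, rng, caplog):
        cm, labels = self._toy(rng)
        labels = labels.copy()
        labels[:1] = "rare"
        labels = np.where(np.arange(len(labels)) == 0, "rare", labels)
        with caplog.at_level("WARNING"):
            out = differential_accessibility(cm, labels)
        assert "rare" not in set(out["cell_class"])


def test_fit_links_bh_family_is_pooled(rng):
    n, n_meta = 400, 10
    ids = rng.integers(0, n_meta, n)
    expr = pd.DataFrame({"g0": rng.normal(0, 1, n_meta), "g1": rng.normal(0, 1, n_meta)})
    open0 = (rng.random(n) < 1 / (1 + np.exp(-3 * expr["g0"].to_numpy()[ids]))).astype(np.int8)
    open1 = (rng.random(n) < 0.3).astype(np.int8)
    atac = CountMatrix(cells=[f"c{i}" for i in range(n)], features=["p0", "p1"],
                       counts=sp.csr_matrix(np.column_stack([open0, open1])),
                       modality="atac")
    pairs = pd.DataFrame({"gene_id": ["g0", "g1"], "peak_id": ["p0", "p1"]})
    assign = MetacellAssignment(cells=atac.cells, metacell_id=ids, n_meta=n_meta)
    out = fit_links(pairs, atac, assign, expr)
    assert out.loc[0, "p_adj"] < 0.05
    assert out.loc[0, "beta"] > 0
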