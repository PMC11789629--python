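"""Bin/peak matrices, TF-IDF, LSI, pseudobulks, markers, locus signal."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from epihet.intervals import GenomicInterval, count_overlaps, make_genome_bins
from epihet.io import FragmentSet
from epihet.matrix import (
    CellFeatureMatrix,
    build_matrix,
    find_marker_peaks,
    locus_cell_signal,
    lsi_embed,
    pseudobulk_downsample,
    tfidf_normalize,
)

GENOME = {"chr1": 10_000}


def fragset(rows):
    return FragmentSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"]), GENOME)


class TestBuildMatrix:
    def test_single_fragment_single_bin(self):
        fs = fragset([("chr1", 100, 150, "A", 1)])
        bins = make_genome_bins(GENOME, 1000)
        m = build_matrix(fs, bins)
        assert m.matrix.sum() == 1
        assert m.matrix[0, 0] == 1

    def test_boundary_spanning_fragment_hits_both_bins(self):
        fs = fragset([("chr1", 950, 1050, "A", 1)])
        m = build_matrix(fs, make_genome_bins(GENOME, 1000))
        col = np.asarray(m.matrix.todense()).ravel()
        assert col[0] == 1 and col[1] == 1 and col.sum() == 2

    def test_matches_brute_force_on_random_overlapping_features(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(400):
            s = int(rng.integers(0, 9_000))
            rows.append(("chr1", s, s + int(rng.integers(1, 600)), f"c{i % 5}", 1))
        feats = []
        for _ in range(60):
            s = int(rng.integers(0, 9_000))
            feats.append(GenomicInterval("chr1", s, s + int(rng.integers(50, 2000))))
        feat_frame = pd.DataFrame(
            {"chrom": "chr1", "start": [f.start for f in feats], "end": [f.end for f in feats]}
        )
        fs = fragset(rows)
        m = build_matrix(fs, feat_frame)
        dense = np.asarray(m.matrix.todense())
        cells = m.cells
        for j, cell in enumerate(cells):
            sub = [r for r in rows if r[3] == cell]
            expected = [
                sum(1 for _, s, e, _, _ in sub if s < f.end and f.start < e) for f in feats
            ]
            np.testing.assert_array_equal(dense[:, j], expected)

    def test_column_sums_equal_overlap_totals(self, small_cohort, small_truth):
        fragments, _ = small_cohort
        sub = FragmentSet(fragments.frame.head(20_000).copy(), fragments.genome)
        bins = make_genome_bins(small_truth.config.genome, 10_000)
        m = build_matrix(sub, bins)
        colsums = np.asarray(m.matrix.sum(axis=0)).ravel()
        per_cell = (
            pd.Series(count_overlaps(sub.frame, bins) * 0 + 1)  # each fragment overlaps >=1 tiling bin
        )
        # every fragment overlaps at least one bin; spanning fragments add extra
        totals = sub.frame.groupby("barcode").size().reindex(m.cells).to_numpy()
        assert (colsums >= totals).all()
        # and the excess is exactly the number of boundary-spanning fragments
        width = 10_000
        spans = ((sub.frame["start"] // width) != (sub.frame["end"] - 1) // width)
        extra = sub.frame.assign(s=spans).groupby("barcode")["s"].sum().reindex(m.cells).to_numpy()
        np.testing.assert_array_equal(colsums, totals + extra)


class TestTFIDF:
    def test_single_entry_closed_form(self):
        m = CellFeatureMatrix(
            sp.csr_matrix(np.array([[1]])),
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}),
            ["A"],
        )
        out = tfidf_normalize(m)
        assert out.matrix[0, 0] == pytest.approx(np.log(1 + 1e4))

    def test_equal_depth_ubiquitous_feature_symmetric(self):
        counts = np.array([[2, 2, 2], [3, 3, 3]])
        m = CellFeatureMatrix(
            sp.csr_matrix(counts),
            pd.DataFrame({"chrom": "chr1", "start": [0, 100], "end": [100, 200]}),
            ["A", "B", "C"],
        )
        out = np.asarray(tfidf_normalize(m).matrix.todense())
        assert np.ptp(out, axis=1).max() < 1e-12

    def test_depth_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(30, 8))
        counts[0] += 1  # no empty cells
        feats = pd.DataFrame({"chrom": "chr1", "start": np.arange(30) * 100, "end": np.arange(30) * 100 + 50})
        cells = [f"c{i}" for i in range(8)]
        a = tfidf_normalize(CellFeatureMatrix(sp.csr_matrix(counts), feats, cells))
        b = tfidf_normalize(CellFeatureMatrix(sp.csr_matrix(counts * 2), feats, cells))
        assert abs((a.matrix - b.matrix)).max() < 1e-12

    def test_zero_cell_rejected(self):
        m = CellFeatureMatrix(
            sp.csr_matrix(np.array([[1, 0]])),
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}),
            ["A", "B"],
        )
        with pytest.raises(ValueError, match="zero total"):
            tfidf_normalize(m)


class TestLSI:
    def _tfidf(self, small_cohort, small_truth, small_peaks):
        fragments, labels = small_cohort
        keep = set(labels.loc[labels.subpop == "normal", "barcode"])
        fs = FragmentSet(
            fragments.frame[fragments.frame["barcode"].isin(keep)].reset_index(drop=True),
            fragments.genome,
        )
        return tfidf_normalize(build_matrix(fs, small_peaks)), labels

    def test_orthonormal_embedding(self, small_cohort, small_truth, small_peaks):
        tfidf, _ = self._tfidf(small_cohort, small_truth, small_peaks)
        u, s = lsi_embed(tfidf, dims=10, seed=0, drop_first=False)
        np.testing.assert_allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-8)
        assert (np.diff(s) <= 0).all()

    def test_conditions_separate_in_embedding(self, small_cohort, small_truth, small_peaks):
        """Cells of distinct conditions separate on LSI components 2:6
        (cosine similarity, the usual metric for this embedding)."""
        from sklearn.metrics import silhouette_score

        tfidf, labels = self._tfidf(small_cohort, small_truth, small_peaks)
        u, _ = lsi_embed(tfidf, dims=5, seed=0, drop_first=True)
        lab = labels.set_index("barcode").loc[tfidf.cells, "condition"]
        assert silhouette_score(u, lab, metric="cosine") > 0.5

    def test_deterministic_given_seed(self, small_cohort, small_truth, small_peaks):
        tfidf, _ = self._tfidf(small_cohort, small_truth, small_peaks)
        u1, _ = lsi_embed(tfidf, dims=5, seed=3)
        u2, _ = lsi_embed(tfidf, dims=5, seed=3)
        np.testing.assert_array_equal(u1, u2)


class TestPseudobulk:
    def _matrix(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 6, size=(50, 4))
        feats = pd.DataFrame({"chrom": "chr1", "start": np.arange(50) * 100, "end": np.arange(50) * 100 + 50})
        return CellFeatureMatrix(sp.csr_matrix(counts), feats, ["a1", "a2", "b1", "b2"]), counts

    def test_totals_equalized(self):
        m, counts = self._matrix()
        pb, target = pseudobulk_downsample(m, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, seed=0)
        assert (pb.sum(axis=0) == target).all()
        assert target == min(counts[:, :2].sum(), counts[:, 2:].sum())

    def test_equal_totals_identity(self):
        counts = np.ones((10, 2), dtype=int)
        feats = pd.DataFrame({"chrom": "chr1", "start": np.arange(10), "end": np.arange(10) + 1})
        m = CellFeatureMatrix(sp.csr_matrix(counts), feats, ["a", "b"])
        pb, _ = pseudobulk_downsample(m, {"A": ["a"], "B": ["b"]}, seed=0)
        np.testing.assert_array_equal(pb["A"].to_numpy(), counts[:, 0])

    def test_seeded_determinism_and_containment(self):
        m, counts = self._matrix()
        pb1, _ = pseudobulk_downsample(m, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, seed=5)
        pb2, _ = pseudobulk_downsample(m, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, seed=5)
        pd.testing.assert_frame_equal(pb1, pb2)
        agg_a = counts[:, :2].sum(axis=1)
        assert (pb1["A"].to_numpy() <= agg_a).all()


class TestMarkers:
    def test_exclusive_peak_top_ranked(self):
        counts = np.zeros((20, 12), dtype=int) + 1
        counts[3, :6] = 30  # hot in condition A only
        feats = pd.DataFrame({"chrom": "chr1", "start": np.arange(20) * 100, "end": np.arange(20) * 100 + 50})
        cells = [f"c{i}" for i in range(12)]
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=cells)
        tfidf = tfidf_normalize(CellFeatureMatrix(sp.csr_matrix(counts), feats, cells))
        table = find_marker_peaks(tfidf, labels, alpha=0.05)
        top_a = table[(table.condition == "A")].sort_values("rank").iloc[0]
        assert top_a["feature"] == 3

    def test_permuted_labels_control_false_positives(self, small_cohort, small_truth):
        fragments, labels = small_cohort
        keep = set(labels.loc[labels.subpop == "normal", "barcode"])
        fs = FragmentSet(
            fragments.frame[fragments.frame["barcode"].isin(keep)].reset_index(drop=True),
            fragments.genome,
        )
        bins = make_genome_bins(small_truth.config.genome, 10_000)
        tfidf = tfidf_normalize(build_matrix(fs, bins))
        rng = np.random.default_rng(0)
        lab = labels.set_index("barcode").loc[tfidf.cells, "condition"]
        perm = pd.Series(rng.permutation(lab.to_numpy()), index=lab.index)
        table = find_marker_peaks(tfidf, perm, alpha=0.05)
        assert len(table) / (len(bins) * 3) <= 0.05 + 0.02

    def test_planted_markers_recovered(self, small_cohort, small_truth, small_peaks, pipeline_config):
        """Planted module peaks dominate the top-N marker list per condition.

        At this miniature scale the copy-number landscape covers a large
        genome share, so CN-driven peaks legitimately compete; full-scale
        recovery is asserted in the end-to-end suite.
        """
        from epihet.matrix import build_matrix

        fragments, labels = small_cohort
        keep = set(labels.loc[labels.subpop.isin(["normal", "transitional"]), "barcode"])
        fs = FragmentSet(
            fragments.frame[fragments.frame["barcode"].isin(keep)].reset_index(drop=True),
            fragments.genome,
        )
        tfidf = tfidf_normalize(build_matrix(fs, small_peaks))
        lab = labels.set_index("barcode").loc[tfidf.cells, "condition"]
        table = find_marker_peaks(tfidf, lab, alpha=0.05)
        top_n = small_truth.config.module_n_peaks
        for cond in small_truth.config.conditions:
            sub = table[table.condition == cond].sort_values("rank").head(top_n)
            top = small_peaks.iloc[sub["feature"].to_numpy()]
            hits = count_overlaps(small_truth.module_peaks[cond], top)
            assert (hits > 0).mean() >= 0.7


class TestLocusSignal:
    def test_empty_region_zeros(self):
        fs = fragset([("chr1", 5000, 5100, "A", 1), ("chr1", 8000, 8200, "B", 1)])
        res = locus_cell_signal(fs, ("chr1", 0, 1000))
        assert (res["counts"] == 0).all()

    def test_whole_genome_equals_umr(self, small_cohort):
        fragments, _ = small_cohort
        res1 = locus_cell_signal(fragments, ("chr1", 0, 1_000_000))
        res2 = locus_cell_signal(fragments, ("chr2", 0, 1_000_000))
        total = res1["counts"] + res2["counts"]
        umr = fragments.frame.groupby("barcode").size().reindex(total.index)
        np.testing.assert_array_equal(total.to_numpy(), umr.to_numpy())

    def test_amplified_locus_group_comparison(self, amplicon_cohort):
        """CN=4 vs CN=2 at the planted amplicon: amplified cells carry about
        twice the in-locus density, rank-sum p < 0.01."""
        truth, fragments, labels = amplicon_cohort
        chrom, s, e, cond, _ = truth.config.amplicon
        groups = {
            "MET": labels.loc[labels.condition == cond, "barcode"].tolist(),
            "PRI": labels.loc[labels.condition == "PRI", "barcode"].tolist(),
        }
        res = locus_cell_signal(fragments, (chrom, s, e), groups=groups)
        assert res["comparison"]["p"] < 0.01
        # in/out odds ratio removes the depth renormalization: ~2 exactly
        fr = fragments.frame
        inside = (fr["chrom"] == chrom) & (fr["start"] < e) & (fr["end"] > s)

        def odds(cells):
            sub = inside[fr["barcode"].isin(set(cells)).to_numpy()]
            return sub.sum() / (~sub).sum()

        ratio = odds(groups["MET"]) / odds(groups["PRI"])
        assert 1.7 < ratio < 2.3
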