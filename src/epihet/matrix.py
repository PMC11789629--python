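"""Cell x feature matrices, TF-IDF/LSI, pseudobulks and marker peaks.

Fragment-to-feature assignment is by >= 1 bp overlap: a fragment spanning k
features increments all k (this changes counts for boundary-spanning
fragments relative to midpoint assignment, and is stated as the package's
convention).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .intervals import count_overlaps, intervals_to_frame, make_genome_bins
from .io import FragmentSet

log = logging.getLogger("epihet")


@dataclass
class CellFeatureMatrix:
    """Sparse features x cells matrix with its interval features."""

    matrix: sp.csr_matrix
    features: pd.DataFrame          # chrom, start, end (row order)
    cells: List[str]                # column order
    kind: str = "raw"               # raw | tfidf

    def __post_init__(self):
        if self.matrix.shape != (len(self.features), len(self.cells)):
            raise ValueError("matrix shape must match feature/cell names")

    @property
    def feature_names(self) -> List[str]:
        return [f"{c}:{s}-{e}" for c, s, e in self.features[["chrom", "start", "end"]].itertuples(index=False)]


def build_matrix(
    fragments: FragmentSet, features: pd.DataFrame, cells: Optional[Sequence[str]] = None
) -> CellFeatureMatrix:
    """Count fragments per (feature, cell); overlap = >= 1 shared bp.

    Works for arbitrary (possibly overlapping) feature sets; tiling-bin
    matrices are just the special case features = make_genome_bins(...).
    """
    frame = fragments.frame
    if cells is None:
        cells = sorted(frame["barcode"].unique())
    cell_idx = {b: i for i, b in enumerate(cells)}
    col = frame["barcode"].map(cell_idx)
    keep = col.notna().to_numpy()
    frame = frame[keep]
    col = col[keep].astype(int).to_numpy()

    rows_parts, cols_parts = [], []
    feat = features.reset_index(drop=True)
    for chrom, fsub in feat.groupby("chrom", sort=False):
        m = (frame["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        fs = frame.loc[m, "start"].to_numpy()
        fe = frame.loc[m, "end"].to_numpy()
        fcol = col[m]
        order = np.argsort(fsub["start"].to_numpy(), kind="stable")
        starts = fsub["start"].to_numpy()[order]
        ends = fsub["end"].to_numpy()[order]
        ridx = fsub.index.to_numpy()[order]
        if np.all(starts[1:] >= ends[:-1]):
            # non-overlapping features: each fragment hits the contiguous
            # run [lo, hi) of sorted features -> fully vectorized expansion
            lo = np.searchsorted(ends, fs, side="right")
            hi = np.searchsorted(starts, fe, side="left")
            n_hit = np.maximum(hi - lo, 0)
            total = int(n_hit.sum())
            if total == 0:
                continue
            offsets = np.repeat(np.cumsum(n_hit) - n_hit, n_hit)
            local = np.arange(total) - offsets + np.repeat(lo, n_hit)
            rows_parts.append(ridx[local])
            cols_parts.append(np.repeat(fcol, n_hit))
        else:
            # overlapping features (rare; small sets): candidate window by
            # start coordinate, exact overlap scan within it
            hi = np.searchsorted(starts, fe, side="left")
            r_out, c_out = [], []
            for i in range(len(fs)):
                js = np.flatnonzero(ends[: hi[i]] > fs[i])
                r_out.extend(ridx[js])
                c_out.extend([fcol[i]] * len(js))
            rows_parts.append(np.asarray(r_out, dtype=np.int64))
            cols_parts.append(np.asarray(c_out, dtype=np.int64))
    if rows_parts:
        rows_out = np.concatenate(rows_parts)
        cols_out = np.concatenate(cols_parts)
    else:
        rows_out = np.empty(0, dtype=np.int64)
        cols_out = np.empty(0, dtype=np.int64)
    data = np.ones(len(rows_out), dtype=np.int64)
    mat = sp.coo_matrix(
        (data, (rows_out, cols_out)), shape=(len(feat), len(cells))
    ).tocsr()
    return CellFeatureMatrix(mat, feat[["chrom", "start", "end"]].copy(), list(cells), "raw")


def tfidf_normalize(cfm: CellFeatureMatrix, scale: float = 1e4) -> CellFeatureMatrix:
    """log(1 + TF * IDF * scale): TF = count / cell total, IDF = n_cells /
    n_cells-with-feature.  Features present in no cell get 0."""
    if cfm.kind != "raw":
        raise ValueError("tfidf_normalize expects a raw matrix")
    X = cfm.matrix.tocsc().astype(np.float64)
    colsum = np.asarray(X.sum(axis=0)).ravel()
    if (colsum == 0).any():
        raise ValueError("cells with zero total counts must be removed before TF-IDF")
    n_cells = X.shape[1]
    df = np.asarray((X > 0).sum(axis=1)).ravel()
    idf = np.zeros_like(df, dtype=np.float64)
    nz = df > 0
    idf[nz] = n_cells / df[nz]
    tf = X.multiply(1.0 / colsum[None, :])
    out = tf.multiply(idf[:, None] * scale).tocsr()
    out.data = np.log1p(out.data)
    return CellFeatureMatrix(out, cfm.features, cfm.cells, "tfidf")


def lsi_embed(
    cfm: CellFeatureMatrix, dims: int = 30, seed: int = 0, drop_first: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Truncated SVD of the TF-IDF matrix; cells in rows.

    Uses an ARPACK solver with a seeded start vector, so the embedding is
    reproducible and the left singular vectors are orthonormal to machine
    precision.  Component 1, which tracks sequencing depth in this kind of
    data, is dropped by default (analysis on dims 2..k).
    """
    X = cfm.matrix.T.astype(np.float64)  # cells x features
    k = min(dims, min(X.shape) - 1)
    rng = np.random.Generator(np.random.PCG64(seed))
    v0 = rng.standard_normal(min(X.shape))
    u, s, _ = svds(X, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    u, s = u[:, order], s[order]
    if drop_first:
        u, s = u[:, 1:], s[1:]
    return u, s


def pseudobulk_downsample(
    cfm: CellFeatureMatrix, groups: Dict[str, Sequence[str]] | pd.Series, seed: int = 0
) -> Tuple[pd.DataFrame, int]:
    """Per-group per-feature counts, depth-equalized by sampling without
    replacement down to the smallest group total.

    Returns (features x groups frame, target total).  Sampling uses the
    multivariate hypergeometric distribution, which is exactly uniform
    sampling of fragments without replacement.
    """
    if isinstance(groups, pd.Series):
        groups = {g: list(groups.index[groups == g]) for g in groups.unique()}
    cell_idx = {b: i for i, b in enumerate(cfm.cells)}
    X = cfm.matrix.tocsc()
    agg = {}
    for g, barcodes in groups.items():
        idx = [cell_idx[b] for b in barcodes if b in cell_idx]
        agg[g] = np.asarray(X[:, idx].sum(axis=1)).ravel().astype(np.int64)
    totals = {g: int(v.sum()) for g, v in agg.items()}
    target = min(totals.values())
    rng = np.random.Generator(np.random.PCG64(seed))
    out = {}
    for g, v in agg.items():
        if totals[g] == target:
            out[g] = v
        else:
            out[g] = rng.multivariate_hypergeometric(v, target, method="marginals")
    frame = pd.DataFrame(out)
    frame.index.name = "feature"
    return frame, target


def find_marker_peaks(
    tfidf: CellFeatureMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    raw_p: Optional[float] = None,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker test per feature per condition.

    Effect size is the difference of group means of TF-IDF values; p-values
    are BH-adjusted across features within each condition.  Features are
    ranked by effect size among those significant at ``alpha`` (or at raw
    p < ``raw_p`` if given).
    """
    if tfidf.kind != "tfidf":
        log.warning("marker test usually runs on TF-IDF values")
    X = np.asarray(tfidf.matrix.todense())
    lab = labels.reindex(tfidf.cells)
    results = []
    for cond in lab.dropna().unique():
        in_g = (lab == cond).to_numpy()
        x, y = X[:, in_g], X[:, ~in_g]
        with np.errstate(all="ignore"):
            stat, p = mannwhitneyu(x, y, axis=1, alternative="two-sided", method="asymptotic")
        p = np.nan_to_num(p, nan=1.0)
        effect = x.mean(axis=1) - y.mean(axis=1)
        _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        sub = pd.DataFrame(
            {
                "feature": np.arange(X.shape[0]),
                "feature_name": tfidf.feature_names,
                "condition": cond,
                "effect": effect,
                "p": p,
                "p_adj": p_adj,
            }
        )
        sig = sub["p"] < raw_p if raw_p is not None else sub["p_adj"] < alpha
        sub = sub[sig & (sub["effect"] > 0)].sort_values("effect", ascending=False)
        sub["rank"] = np.arange(1, len(sub) + 1)
        results.append(sub)
    if not results:
        return pd.DataFrame(columns=["feature", "feature_name", "condition", "effect", "p", "p_adj", "rank"])
    return pd.concat(results, ignore_index=True)


def locus_cell_signal(
    fragments: FragmentSet,
    region: Tuple[str, int, int],
    groups: Optional[Dict[str, Sequence[str]]] = None,
) -> Dict[str, object]:
    """Per-cell fragment counts in a region, with an optional two-group
    rank-sum comparison (as used for amplified-locus single-cell signal)."""
    chrom, start, end = region
    frame = fragments.frame
    hit = (
        (frame["chrom"] == chrom)
        & (frame["start"] < end)
        & (frame["end"] > start)
    )
    counts = frame[hit].groupby("barcode").size()
    counts = counts.reindex(fragments.barcodes, fill_value=0)
    out: Dict[str, object] = {"counts": counts}
    if groups is not None:
        if len(groups) != 2:
            raise ValueError("exactly two groups required for the comparison")
        (ga, ca), (gb, cb) = groups.items()
        a = counts.reindex(ca, fill_value=0).to_numpy()
        b = counts.reindex(cb, fill_value=0).to_numpy()
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        out["comparison"] = {
            "groups": (ga, gb),
            "median": (float(np.median(a)), float(np.median(b))),
            "statistic": float(stat),
            "p": float(p),
        }
    return out


__all__ = [
    "CellFeatureMatrix",
    "make_genome_bins",
    "build_matrix",
    "tfidf_normalize",
    "lsi_embed",
    "pseudobulk_downsample",
    "find_marker_peaks",
    "locus_cell_signal",
]
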