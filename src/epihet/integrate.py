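"""Gene copy number x chromatin state x expression integration.

Each gene gets a promoter chromatin-state category from the 200 bp
segmentation (strand-oriented window, 2000 bp upstream to 3000 bp
downstream of the TSS), an integer copy number (segment containing the
TSS, grouped 1 / 2 / 3 / 4+), and an expression Z-score; the CN effect on
expression within each state category is quantified by median (quantile)
regression, and chromatin-state transitions between two conditions are
linked to expression changes by odds-ratio enrichment.
"""
from __future__ import annotations

import logging
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import GeneAnnotation
from .hmm import Segmentation

log = logging.getLogger("epihet")

STATE_CATEGORIES = ("both_marks", "H3K4me3_only", "H3K27ac_only", "none", "heterochromatin")

#: E-label -> which activating mark(s) it carries
_ACTIVATING = {"E1": "H3K4me3", "E2": "both", "E3": "H3K27ac"}


def expression_zscore(
    counts: pd.DataFrame, condition_map: Dict[str, str], min_samples: int = 2
) -> pd.DataFrame:
    """Per-gene expression Z-scores collapsed to one column per condition.

    Counts are library-size normalized, log2(x/s + 1) transformed (a
    simplified variance-stabilizing step; the fitted mean-dispersion VST is
    out of scope here), standardized per gene across samples (mean 0, sd 1),
    then replicate Z-scores are averaged per condition.  Genes with zero
    variance across samples are dropped and counted.
    """
    if counts.shape[1] < min_samples:
        raise ValueError("need at least two samples")
    libsize = counts.sum(axis=0).to_numpy(dtype=float)
    sf = libsize / libsize.mean()
    norm = np.log2(counts.to_numpy(dtype=float) / sf[None, :] + 1.0)
    mu = norm.mean(axis=1, keepdims=True)
    sd = norm.std(axis=1, ddof=1, keepdims=True)
    keep = (sd > 0).ravel()
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning("dropped %d zero-variance genes from expression table", n_drop)
    z = (norm[keep] - mu[keep]) / sd[keep]
    zf = pd.DataFrame(z, index=counts.index[keep], columns=counts.columns)
    cond = pd.Series({s: condition_map[s] for s in counts.columns})
    return zf.T.groupby(cond).mean().T


def promoter_state_call(labels: Sequence[str], config: PipelineConfig | None = None) -> str:
    """Chromatin-state category of one promoter window from its bin labels.

    Decision cascade over the printed rules:
      (i)  with <= 2 bins carrying an activating state (E1/E2/E3) the gene
           has no activating mark: heterochromatin if > 60% of bins are E5,
           otherwise none;
      (ii) both marks if the modal state over all bins is E2, or if the
           E1:E3 balance among marked bins falls in the similar-proportion
           band (default 40-60%);
      (iii) a single mark if > 60% of all bins carry that one state;
      (iv) otherwise none.
    """
    cfg = config or PipelineConfig()
    labels = list(labels)
    n = len(labels)
    if n == 0:
        return "none"
    counts = Counter(labels)
    n_marked = counts["E1"] + counts["E2"] + counts["E3"]
    if n_marked <= cfg.min_marked_bins:
        if counts["E5"] / n > cfg.hetero_fraction:
            return "heterochromatin"
        return "none"
    modal = max(counts, key=lambda k: counts[k])
    if modal == "E2":
        return "both_marks"
    n_e1, n_e3 = counts["E1"], counts["E3"]
    if n_e1 + n_e3 == 0:
        # marked bins are all E2 without E2 being modal: both marks present
        return "both_marks"
    lo, hi = cfg.similar_band
    frac_e1 = n_e1 / (n_e1 + n_e3)
    if lo <= frac_e1 <= hi:
        return "both_marks"
    if counts["E1"] / n > cfg.single_mark_fraction:
        return "H3K4me3_only"
    if counts["E3"] / n > cfg.single_mark_fraction:
        return "H3K27ac_only"
    return "none"


def assign_gene_states(
    segmentation: Segmentation, annotation: GeneAnnotation, config: PipelineConfig | None = None
) -> pd.Series:
    """Promoter chromatin-state category per gene.

    The promoter window is strand-oriented: for "+" genes it spans
    [TSS - upstream, TSS + downstream); for "-" genes upstream extends to
    larger coordinates.  Windows leaving the chromosome are truncated.
    """
    cfg = config or PipelineConfig()
    bins = segmentation.bins
    width = int((bins["end"] - bins["start"]).iloc[0])
    labels = segmentation.state_labels
    offsets: Dict[str, Tuple[int, int]] = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        offsets[chrom] = (int(sub.index.min()), len(sub))
    out = {}
    for row in annotation.frame.itertuples(index=False):
        if row.chrom not in offsets:
            out[row.symbol] = "none"
            continue
        off, nb = offsets[row.chrom]
        if row.strand == "-":
            w_s = row.tss - cfg.promoter_downstream
            w_e = row.tss + cfg.promoter_upstream
        else:
            w_s = row.tss - cfg.promoter_upstream
            w_e = row.tss + cfg.promoter_downstream
        b0 = max(w_s // width, 0)
        b1 = min((w_e - 1) // width, nb - 1)
        if b0 > b1:
            out[row.symbol] = "none"
            continue
        out[row.symbol] = promoter_state_call(labels[off + b0 : off + b1 + 1], cfg)
    return pd.Series(out, name="state_category")


def cn_at_tss(annotation: GeneAnnotation, segments: pd.DataFrame) -> pd.Series:
    """Integer CN of the segment containing each gene's TSS (NaN if none)."""
    out = {}
    for row in annotation.frame.itertuples(index=False):
        hit = segments[
            (segments["chrom"] == row.chrom)
            & (segments["start"] <= row.tss)
            & (segments["end"] > row.tss)
        ]
        out[row.symbol] = int(hit["cn"].iloc[0]) if len(hit) else np.nan
    return pd.Series(out, name="cn")


def cn_group(cn: float) -> str:
    """Clamp integer CN into the printed groups 1 / 2 / 3 / 4+."""
    c = int(np.clip(cn, 1, 4))
    return "4+" if c == 4 else str(c)


def join_gene_tables(
    states: pd.Series, cn: pd.Series, z: pd.Series
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Inner join on gene symbol; genes missing any field are dropped and
    counted by cause."""
    s_ok = set(states.dropna().index)
    c_ok = set(cn.dropna().index)
    z_ok = set(z.dropna().index)
    dropped = {
        "missing_state": len((c_ok & z_ok) - s_ok),
        "missing_cn": len((s_ok & z_ok) - c_ok),
        "missing_expression": len((s_ok & c_ok) - z_ok),
    }
    frame = pd.concat(
        [states.rename("state_category"), cn.rename("cn"), z.rename("z")], axis=1, join="inner"
    ).dropna()
    frame["cn"] = frame["cn"].astype(int)
    frame["cn_group"] = frame["cn"].map(cn_group)
    frame.index.name = "symbol"
    return frame, dropped


def quantile_regression(
    records: pd.DataFrame, tau: float = 0.5, min_cn: int = 2
) -> pd.DataFrame:
    """Median regression of expression Z on CN group within each chromatin-
    state category.

    CN groups 2 / 3 / 4+ are coded 2, 3, 4 (CN < ``min_cn`` excluded, as in
    the CN = 2..4+ comparisons); also reports the mean-Z difference between
    the 4+ and diploid groups.  Groups with a singular design (fewer than
    two CN levels) get NaN slopes, flagged.
    """
    rows = []
    code = {"2": 2, "3": 3, "4+": 4}
    for cat, sub in records.groupby("state_category", sort=False):
        sub = sub[sub["cn"] >= min_cn]
        x = sub["cn_group"].map(code).to_numpy(dtype=float)
        y = sub["z"].to_numpy(dtype=float)
        mean_diff = (
            sub.loc[sub["cn_group"] == "4+", "z"].mean() - sub.loc[sub["cn_group"] == "2", "z"].mean()
        )
        if len(np.unique(x)) < 2:
            rows.append((cat, np.nan, np.nan, len(sub), mean_diff, True))
            continue
        model = QuantReg(y, sm.add_constant(x))
        with np.errstate(all="ignore"):
            fit = model.fit(q=tau)
        rows.append((cat, float(fit.params[1]), float(fit.params[0]), len(sub), mean_diff, False))
    return pd.DataFrame(
        rows, columns=["state_category", "slope", "intercept", "n_genes", "mean_diff_4p_vs_2", "singular"]
    )


def bootstrap_slope_ci(
    records: pd.DataFrame,
    category: str,
    n_boot: int = 200,
    seed: int = 0,
    tau: float = 0.5,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for one state category's median-regression slope."""
    sub = records[records["state_category"] == category]
    rng = np.random.Generator(np.random.PCG64(seed))
    slopes = []
    for _ in range(n_boot):
        take = sub.iloc[rng.integers(0, len(sub), size=len(sub))]
        res = quantile_regression(take, tau=tau)
        s = res.loc[res["state_category"] == category, "slope"]
        if len(s) and np.isfinite(s.iloc[0]):
            slopes.append(float(s.iloc[0]))
    lo, hi = np.quantile(slopes, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def transition_expression_enrichment(
    states_a: pd.Series,
    states_b: pd.Series,
    de_table: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Enrichment of expression change per promoter-state transition.

    Genes are classed up (log2FC > 1, p < 0.001), down (log2FC < -0.5,
    p < 0.001) or neither; for each (state in A -> state in B) transition
    and each class, the odds ratio of class membership inside versus
    outside that transition is computed with a Fisher exact p, BH-adjusted.
    """
    cfg = config or PipelineConfig()
    genes = states_a.dropna().index.intersection(states_b.dropna().index).intersection(de_table.index)
    lfc = de_table.loc[genes, "log2fc"]
    p = de_table.loc[genes, "p"]
    cls = pd.Series("neither", index=genes)
    cls[(lfc > cfg.up_lfc) & (p < cfg.de_pvalue)] = "up"
    cls[(lfc < cfg.down_lfc) & (p < cfg.de_pvalue)] = "down"
    trans = states_a.loc[genes].astype(str) + "->" + states_b.loc[genes].astype(str)
    rows = []
    for t in trans.unique():
        in_t = trans == t
        for c in ("up", "down"):
            is_c = cls == c
            a = int((in_t & is_c).sum())
            b = int((in_t & ~is_c).sum())
            cc = int((~in_t & is_c).sum())
            d = int((~in_t & ~is_c).sum())
            odds, pv = fisher_exact([[a, b], [cc, d]])
            rows.append((t, c, a, b, cc, d, odds, pv))
    out = pd.DataFrame(
        rows, columns=["transition", "class", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    if len(out):
        _, p_adj, _, _ = multipletests(out["p"], method="fdr_bh")
        out["p_adj"] = p_adj
    return out
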