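"""Peak modules, per-cell deviation Z-scores, ternary gating.

A *module* is a condition's top-N marker peaks (default N = 50).  A cell's
raw deviation for a module is (observed - expected) / expected, where the
expectation is the cell's total count times the module's share of the grand
total — so deviations are invariant to per-cell depth rescaling.  The
deviation Z standardizes against size-matched background peak sets sampled
within accessibility strata (deciles of per-peak total count), giving the
chromVAR-style score: how far this cell's profile deviates from the cohort
average within the module's peaks.

Three module scores per cell (primary / metastatic / cisplatin-resistant)
are shifted non-negative (one cohort-wide constant, preserving between-cell
order) and normalized to sum to one; cells with two coordinates above the
gate threshold (default 0.4) are called transitional (preMET / prePCR).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .config import PipelineConfig
from .matrix import CellFeatureMatrix

log = logging.getLogger("epihet")


@dataclass
class PeakModule:
    condition: str
    peaks: np.ndarray  # feature row indices, ranked

    def __len__(self) -> int:
        return len(self.peaks)


def define_modules(marker_table: pd.DataFrame, top_n: int = 50) -> List[PeakModule]:
    """Top-N ranked marker peaks per condition (warn when fewer exist)."""
    modules = []
    for cond, sub in marker_table.groupby("condition", sort=False):
        sub = sub.sort_values("rank")
        if len(sub) < top_n:
            log.warning("condition %s has only %d significant peaks (< %d)", cond, len(sub), top_n)
        modules.append(PeakModule(cond, sub["feature"].to_numpy()[:top_n]))
    return modules


def raw_deviations(
    counts: np.ndarray, module_idx: np.ndarray, share: Optional[float] = None
) -> np.ndarray:
    """(observed - expected)/expected module counts per cell.

    ``counts`` is peaks x cells (raw).  Expected per cell = cell total x
    module share of the grand total (overridable via ``share`` for
    closed-form checks).  Cells with zero expectation get NaN.
    """
    cell_tot = counts.sum(axis=0)
    grand = cell_tot.sum()
    if share is None:
        share = counts[module_idx].sum() / grand if grand > 0 else 0.0
    expected = cell_tot * share
    observed = counts[module_idx].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (observed - expected) / expected
    d[expected == 0] = np.nan
    return d


def _background_sets(
    counts: np.ndarray, module_idx: np.ndarray, n_background: int, n_strata: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample accessibility-matched background peak sets.

    Peaks are stratified into quantile bins of total count; each background
    set replaces every module peak with a random peak from its stratum.
    Returns (n_background, module_size) indices.
    """
    peak_tot = counts.sum(axis=1)
    ranks = pd.Series(peak_tot).rank(method="first").to_numpy()
    strata = np.minimum((ranks - 1) * n_strata // len(ranks), n_strata - 1).astype(int)
    pools = {s: np.flatnonzero(strata == s) for s in range(n_strata)}
    module_strata = strata[module_idx]
    out = np.empty((n_background, len(module_idx)), dtype=np.int64)
    for j, s in enumerate(module_strata):
        pool = pools[s]
        out[:, j] = pool[rng.integers(0, len(pool), size=n_background)]
    return out


def deviation_zscores(
    cfm: CellFeatureMatrix,
    module: PeakModule,
    n_background: int = 50,
    seed: int = 0,
    n_strata: int = 10,
) -> pd.Series:
    """Per-cell deviation Z for one module against seeded background sets.

    Standard deviation across backgrounds uses the unbiased estimator.
    Cells with zero totals get NaN and are excluded from downstream gating.
    """
    if cfm.kind != "raw":
        raise ValueError("deviation scores are computed on raw counts")
    if len(module) == 0:
        raise ValueError("module is empty")
    counts = np.asarray(cfm.matrix.todense(), dtype=np.float64)
    rng = np.random.Generator(np.random.PCG64(seed))
    d = raw_deviations(counts, module.peaks)
    bg = _background_sets(counts, module.peaks, n_background, n_strata, rng)
    d_bg = np.stack([raw_deviations(counts, bg[b]) for b in range(n_background)])
    mean_bg = np.nanmean(d_bg, axis=0)
    sd_bg = np.nanstd(d_bg, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d - mean_bg) / sd_bg
    return pd.Series(z, index=cfm.cells, name=module.condition)


def score_modules(
    cfm: CellFeatureMatrix, modules: Sequence[PeakModule], n_background: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Deviation Z for every module; cells x modules."""
    cols = {}
    for i, module in enumerate(modules):
        cols[module.condition] = deviation_zscores(cfm, module, n_background, seed + i)
    return pd.DataFrame(cols)


def normalize_ternary(scores: pd.DataFrame, shift_scope: str = "cohort") -> pd.DataFrame:
    """Shift scores non-negative and normalize each cell's three to sum 1.

    ``cohort`` scope (default) adds one constant — the absolute value of
    the lowest negative score anywhere in the cohort — to every score of
    every cell, preserving between-cell ordering; ``per_cell`` shifts each
    cell by its own minimum.  Cells whose shifted scores sum to 0 are
    dropped with a warning.
    """
    if scores.shape[1] != 3:
        raise ValueError("ternary normalization needs exactly three module scores")
    vals = scores.to_numpy(dtype=float)
    if shift_scope == "cohort":
        m = np.nanmin(vals)
        if m < 0:
            vals = vals + abs(m)
    elif shift_scope == "per_cell":
        m = np.nanmin(vals, axis=1, keepdims=True)
        vals = np.where(m < 0, vals + np.abs(m), vals)
    else:
        raise ValueError(f"unknown shift scope {shift_scope!r}")
    sums = vals.sum(axis=1)
    bad = ~np.isfinite(sums) | (sums == 0)
    if bad.any():
        log.warning("%d cells with undefined ternary coordinates dropped", int(bad.sum()))
    out = pd.DataFrame(vals / sums[:, None], index=scores.index, columns=scores.columns)
    return out[~bad]


def gate_subpopulation(
    coords: pd.DataFrame,
    axes: Tuple[str, str],
    threshold: float = 0.4,
    label: str = "transitional",
    variant: str = "both_above",
) -> pd.Series:
    """Label cells whose two named coordinates both strictly exceed the
    threshold.  At thresholds > 1/3 a cell can satisfy at most one two-axis
    gate (the two coordinates already sum past 2/3).

    ``variant='first_above_second_below'`` selects the alternative gate
    (first axis above, second axis below threshold).
    """
    a, b = axes
    if variant == "both_above":
        hit = (coords[a] > threshold) & (coords[b] > threshold)
    elif variant == "first_above_second_below":
        hit = (coords[a] > threshold) & (coords[b] < threshold)
    else:
        raise ValueError(f"unknown gate variant {variant!r}")
    return pd.Series(np.where(hit, label, "none"), index=coords.index, name="label")


def subpopulation_report(
    labels: pd.Series,
    scores: pd.DataFrame,
    qc_table: pd.DataFrame,
    parent_cells: Sequence[str],
    progressed_cells: Sequence[str],
    progressed_module: str,
) -> Dict[str, object]:
    """Summary for one gated subpopulation.

    Reports size and parent fraction, mean module scores, rank-sum tests of
    UMR and FRiP against the remaining parent cells (confounder check), and
    the ordering remaining-parent < transitional < progressed on the
    progressed module's mean raw score.
    """
    sub = labels.index[labels != "none"]
    parent = pd.Index(parent_cells)
    sub = pd.Index(sub).intersection(parent)
    rest = parent.difference(sub)
    out: Dict[str, object] = {
        "n": int(len(sub)),
        "parent_fraction": len(sub) / len(parent) if len(parent) else 0.0,
        "mean_scores": scores.loc[scores.index.intersection(sub)].mean().to_dict() if len(sub) else {},
    }
    qc = qc_table.set_index("barcode")
    for metric in ("umr", "frip"):
        a = qc.loc[qc.index.intersection(sub), metric].to_numpy()
        b = qc.loc[qc.index.intersection(rest), metric].to_numpy()
        if len(a) and len(b):
            _, p = mannwhitneyu(a, b, alternative="two-sided")
            out[f"{metric}_ranksum_p"] = float(p)
        else:
            out[f"{metric}_ranksum_p"] = np.nan
    m = scores[progressed_module]
    means = {
        "remaining_parent": float(m.reindex(rest).mean()),
        "transitional": float(m.reindex(sub).mean()) if len(sub) else np.nan,
        "progressed": float(m.reindex(pd.Index(progressed_cells)).mean()),
    }
    out["progressed_module_means"] = means
    out["ordering_check"] = bool(
        len(sub) and means["remaining_parent"] < means["transitional"] < means["progressed"]
    )
    return out


def ternary_plot(coords: pd.DataFrame, labels: Optional[pd.Series] = None, path: str | None = None):
    """Scatter of cells on the 2-simplex (matplotlib; SVG/PNG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b, c = coords.columns
    x = coords[b] + 0.5 * coords[c]
    y = np.sqrt(3) / 2 * coords[c]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    if labels is not None:
        for lab in labels.reindex(coords.index).fillna("none").unique():
            m = (labels.reindex(coords.index) == lab).to_numpy()
            ax.scatter(x[m], y[m], s=6, label=str(lab), alpha=0.7)
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(x, y, s=6, alpha=0.7)
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="0.3", lw=0.8)
    for pos, name in zip(tri[:3], (a, b, c)):
        ax.annotate(name, pos, textcoords="offset points", xytext=(0, -12 if pos[1] == 0 else 8), ha="center")
    ax.set_axis_off()
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
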