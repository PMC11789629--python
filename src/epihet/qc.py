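"""Per-cell quality control and cell exclusion.

Metrics per barcode: UMR (number of deduplicated fragment records), FRiP
(fraction of fragments sharing >= 1 bp with a peak), blacklist read
fraction, TSS enrichment (mean per-bp coverage at TSS +/- 100 bp over mean
per-bp coverage in the 900-1000 bp flanks, with a one-fragment pseudocount
in the denominator) and nucleosome signal (mono-nucleosomal / sub-
nucleosomal fragment-length ratio with pseudocount 1).

Exclusion applies the printed thresholds with strict inequalities; a cell
with any missing metric is excluded.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import count_overlaps, intervals_to_frame, merge_intervals, overlap_bp
from .io import FragmentSet, GeneAnnotation

log = logging.getLogger("epihet")

METRICS = ["umr", "frip", "blacklist_fraction", "tss_enrichment", "nucleosome_signal"]


def compute_umr(fragments: FragmentSet, barcode: str) -> int:
    """Number of (deduplicated) fragment records for one barcode."""
    n = int((fragments.frame["barcode"] == barcode).sum())
    if n == 0:
        log.warning("barcode %s has no fragments", barcode)
    return n


def _overlap_flags(fragments: FragmentSet, subjects) -> np.ndarray:
    subj = subjects if isinstance(subjects, pd.DataFrame) else intervals_to_frame(list(subjects))
    return count_overlaps(fragments.frame, subj) > 0


def compute_frip(fragments: FragmentSet, peaks, barcode: str) -> Optional[float]:
    """Fraction of the barcode's fragments overlapping a peak (>= 1 bp)."""
    sub = fragments.for_barcode(barcode)
    if len(sub) == 0:
        return None
    flags = _overlap_flags(FragmentSet(sub, fragments.genome), peaks)
    return float(flags.mean())


def compute_blacklist_fraction(fragments: FragmentSet, blacklist, barcode: str) -> Optional[float]:
    """Fraction of the barcode's fragments overlapping the blacklist."""
    return compute_frip(fragments, blacklist, barcode)


def compute_nucleosome_signal(lengths: np.ndarray, config: PipelineConfig | None = None) -> float:
    """Mono-nucleosomal over sub-nucleosomal fragment count (pseudocount 1)."""
    cfg = config or PipelineConfig()
    lo, hi = cfg.nucleosome_mono_range
    n_mono = int(((lengths >= lo) & (lengths <= hi)).sum())
    n_sub = int((lengths < cfg.nucleosome_sub_max).sum())
    return n_mono / (n_sub + 1)


def _tss_windows(annotation: GeneAnnotation, config: PipelineConfig):
    ann = annotation.frame
    hw = config.tss_center_halfwidth
    f0, f1 = config.tss_flank
    center = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "start": np.maximum(ann["tss"] - hw, 0),
            "end": ann["tss"] + hw,
        }
    )
    flank = pd.concat(
        [
            pd.DataFrame(
                {"chrom": ann["chrom"], "start": np.maximum(ann["tss"] - f1, 0), "end": np.maximum(ann["tss"] - f0, 0)}
            ),
            pd.DataFrame({"chrom": ann["chrom"], "start": ann["tss"] + f0, "end": ann["tss"] + f1}),
        ],
        ignore_index=True,
    )
    flank = flank[flank["end"] > flank["start"]]
    return merge_intervals(center), merge_intervals(flank)


def compute_tss_enrichment(
    fragments: FragmentSet, annotation: GeneAnnotation, barcode: str, config: PipelineConfig | None = None
) -> float:
    """Center-over-flank per-bp coverage ratio around TSSs for one cell."""
    cfg = config or PipelineConfig()
    sub = fragments.for_barcode(barcode)
    if len(sub) == 0:
        return 0.0
    center, flank = _tss_windows(annotation, cfg)
    c_bp = overlap_bp(sub, center).sum()
    f_bp = overlap_bp(sub, flank).sum()
    if c_bp + f_bp == 0:
        return 0.0
    c_w = float((center["end"] - center["start"]).sum())
    f_w = float((flank["end"] - flank["start"]).sum())
    return float((c_bp / c_w) / ((f_bp + 1) / f_w))


def compute_qc_table(
    fragments: FragmentSet,
    peaks,
    blacklist,
    annotation: GeneAnnotation,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """All QC metrics for every barcode, vectorized, plus the pass flag."""
    cfg = config or PipelineConfig()
    frame = fragments.frame
    peaks_f = peaks if isinstance(peaks, pd.DataFrame) else intervals_to_frame(list(peaks))
    black_f = blacklist if isinstance(blacklist, pd.DataFrame) else intervals_to_frame(list(blacklist))

    in_peak = count_overlaps(frame, peaks_f) > 0
    in_black = count_overlaps(frame, black_f) > 0
    center, flank = _tss_windows(annotation, cfg)
    c_bp = overlap_bp(frame, center)
    f_bp = overlap_bp(frame, flank)
    lengths = (frame["end"] - frame["start"]).to_numpy()
    lo, hi = cfg.nucleosome_mono_range

    per = pd.DataFrame(
        {
            "barcode": frame["barcode"],
            "in_peak": in_peak,
            "in_black": in_black,
            "c_bp": c_bp,
            "f_bp": f_bp,
            "mono": (lengths >= lo) & (lengths <= hi),
            "sub": lengths < cfg.nucleosome_sub_max,
        }
    )
    agg = per.groupby("barcode", sort=False).agg(
        umr=("in_peak", "size"),
        n_peak=("in_peak", "sum"),
        n_black=("in_black", "sum"),
        c_bp=("c_bp", "sum"),
        f_bp=("f_bp", "sum"),
        n_mono=("mono", "sum"),
        n_sub=("sub", "sum"),
    )
    c_w = float((center["end"] - center["start"]).sum())
    f_w = float((flank["end"] - flank["start"]).sum())
    out = pd.DataFrame(index=agg.index)
    out["umr"] = agg["umr"]
    out["frip"] = np.where(agg["umr"] > 0, agg["n_peak"] / agg["umr"], np.nan)
    out["blacklist_fraction"] = np.where(agg["umr"] > 0, agg["n_black"] / agg["umr"], np.nan)
    covered = (agg["c_bp"] + agg["f_bp"]) > 0
    out["tss_enrichment"] = np.where(covered, (agg["c_bp"] / c_w) / ((agg["f_bp"] + 1) / f_w), 0.0)
    out["nucleosome_signal"] = agg["n_mono"] / (agg["n_sub"] + 1)
    out = out.reset_index()
    out["pass"] = [apply_qc_filters(row, cfg) for row in out.to_dict(orient="records")]
    return out


def apply_qc_filters(metrics, config: PipelineConfig | None = None) -> bool:
    """True iff the cell is kept.

    Exclusion criteria (strict inequalities, as printed): umr < 1000,
    umr > 100000, frip < 0.25, blacklist fraction > 0.01, nucleosome
    signal > 5, TSS enrichment < 0.5.  Missing metrics exclude the cell.
    """
    cfg = config or PipelineConfig()
    t = cfg.qc
    get = metrics.get if isinstance(metrics, dict) else lambda k: getattr(metrics, k)
    vals = {m: get(m) for m in METRICS}
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals.values()):
        return False
    return not (
        vals["umr"] < t.umr_min
        or vals["umr"] > t.umr_max
        or vals["frip"] < t.frip_min
        or vals["blacklist_fraction"] > t.blacklist_max
        or vals["nucleosome_signal"] > t.nucleosome_max
        or vals["tss_enrichment"] < t.tss_min
    )


def filter_fragments(fragments: FragmentSet, qc_table: pd.DataFrame) -> FragmentSet:
    """Fragments of passing cells only."""
    keep = qc_table.loc[qc_table["pass"], "barcode"]
    return fragments.subset(keep.tolist())
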