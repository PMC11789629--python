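"""Genomic intervals and the overlap-counting engine.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; 1-based coordinates appear only in rendered text.  Two intervals
overlap iff they share at least one base pair, i.e. ``a.start < b.end and
b.start < a.end``.  Chromosome names are taken verbatim ("chr1" != "1").
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": np.asarray([iv.start for iv in intervals], dtype=np.int64),
            "end": np.asarray([iv.end for iv in intervals], dtype=np.int64),
        }
    )


def count_overlaps(
    queries: Sequence[GenomicInterval] | pd.DataFrame,
    subjects: Sequence[GenomicInterval] | pd.DataFrame,
) -> np.ndarray:
    """Number of subject intervals sharing >= 1 bp with each query.

    Runs in O((n + m) log m) per chromosome via sorted endpoint counting:
    the number of subjects overlapping [s, e) equals
    ``#{subj.start < e} - #{subj.end <= s}``, which holds because subject
    intervals are non-degenerate (end > start).
    """
    q = queries if isinstance(queries, pd.DataFrame) else intervals_to_frame(list(queries))
    s = subjects if isinstance(subjects, pd.DataFrame) else intervals_to_frame(list(subjects))
    out = np.zeros(len(q), dtype=np.int64)
    if len(q) == 0 or len(s) == 0:
        return out
    for chrom, sub in s.groupby("chrom", sort=False):
        mask = (q["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        qs = q.loc[mask, "start"].to_numpy()
        qe = q.loc[mask, "end"].to_numpy()
        n_started = np.searchsorted(starts, qe, side="left")
        n_finished = np.searchsorted(ends, qs, side="right")
        out[mask] = n_started - n_finished
    return out


def merge_intervals(frame: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting intervals per chromosome (sorted output)."""
    pieces = []
    for chrom, sub in frame.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        merged_s, merged_e = [starts[0]], [ends[0]]
        for s0, e0 in zip(starts[1:], ends[1:]):
            if s0 <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e0)
            else:
                merged_s.append(s0)
                merged_e.append(e0)
        pieces.append(pd.DataFrame({"chrom": chrom, "start": merged_s, "end": merged_e}))
    return pd.concat(pieces, ignore_index=True) if pieces else frame.iloc[:0].copy()


def overlap_bp(
    frame: pd.DataFrame, windows: pd.DataFrame
) -> np.ndarray:
    """Shared base pairs between each row of ``frame`` and a merged window set.

    ``windows`` must be non-overlapping (use :func:`merge_intervals` first).
    Uses cumulative window coverage + searchsorted per chromosome.
    """
    out = np.zeros(len(frame), dtype=np.int64)

    def coverage_before(pos, ws, we, cum):
        # total window bp strictly below ``pos``; windows sorted, disjoint
        i = np.searchsorted(ws, pos, side="right")
        inside = np.where(i > 0, np.clip(we[np.maximum(i - 1, 0)] - pos, 0, None), 0)
        return cum[i] - inside

    for chrom, wsub in windows.groupby("chrom", sort=False):
        mask = (frame["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        wsub = wsub.sort_values("start")
        ws = wsub["start"].to_numpy()
        we = wsub["end"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(we - ws)])
        fs = frame.loc[mask, "start"].to_numpy()
        fe = frame.loc[mask, "end"].to_numpy()
        out[mask] = coverage_before(fe, ws, we, cum) - coverage_before(fs, ws, we, cum)
    return out


def make_genome_bins(genome: Dict[str, int], width: int) -> pd.DataFrame:
    """Tile each chromosome with half-open bins of ``width`` bp.

    Bins partition the genome exactly: non-overlapping, contiguous, and the
    last bin on each chromosome is truncated at the chromosome end.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for chrom, length in genome.items():
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    bins = pd.concat(rows, ignore_index=True)
    bins.index.name = "bin"
    return bins


def bin_index_range(
    bins_per_chrom: Dict[str, Tuple[int, int]],
    width: int,
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
):
    """First/last tiling-bin global index hit by each half-open interval.

    ``bins_per_chrom`` maps chromosome -> (global offset, n_bins).  Returns
    (first, last) inclusive global bin indices, or first = -1 for unknown
    chromosomes.
    """
    first = np.full(len(chrom), -1, dtype=np.int64)
    last = np.full(len(chrom), -1, dtype=np.int64)
    for c, (offset, n) in bins_per_chrom.items():
        m = chrom == c
        if not m.any():
            continue
        f = start[m] // width
        l = (end[m] - 1) // width
        first[m] = offset + np.clip(f, 0, n - 1)
        last[m] = offset + np.clip(l, 0, n - 1)
    return first, last
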