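"""Readers and writers for the formats the pipeline touches.

Fragment files are 5-column TSV (chrom, start, end, barcode, count),
optionally gzip-compressed.  Peaks/blacklist are BED3+; gene annotation is
a 4-column TSV (symbol, chrom, tss, strand); matrices go to Matrix Market
with row/column name sidecars.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .intervals import GenomicInterval

log = logging.getLogger("epihet")


@dataclass
class FragmentSet:
    """Per-cell genomic fragments plus the genome they live on.

    ``frame`` columns: chrom (str), start/end (int64, half-open), barcode
    (str), count (int64 >= 1).
    """

    frame: pd.DataFrame
    genome: Dict[str, int]

    def __post_init__(self):
        required = ["chrom", "start", "end", "barcode", "count"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def barcodes(self) -> List[str]:
        return list(pd.unique(self.frame["barcode"]))

    def for_barcode(self, barcode: str) -> pd.DataFrame:
        return self.frame[self.frame["barcode"] == barcode]

    def subset(self, barcodes: Sequence[str]) -> "FragmentSet":
        keep = self.frame["barcode"].isin(set(barcodes))
        return FragmentSet(self.frame[keep].reset_index(drop=True), dict(self.genome))


@dataclass
class GeneAnnotation:
    """Gene symbols with TSS positions.  Symbols must be unique."""

    frame: pd.DataFrame  # columns: symbol, chrom, tss, strand

    def __post_init__(self):
        required = ["symbol", "chrom", "tss", "strand"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.frame["symbol"].duplicated().any():
            dup = self.frame.loc[self.frame["symbol"].duplicated(), "symbol"].iloc[0]
            raise ValueError(f"duplicate gene symbol: {dup}")

    def __len__(self) -> int:
        return len(self.frame)


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path: str | Path, genome: Dict[str, int]) -> FragmentSet:
    """Parse a 5-column fragment file, validating against chromosome sizes.

    Coordinates are 0-based half-open.  Records on unknown chromosomes or
    with malformed fields raise with the offending line number; records out
    of chromosome bounds are rejected and counted in a warning.
    """
    # fast path: vectorized parse; on any violation fall back to the
    # line-by-line parser to report the offending line number
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "barcode", "count"],
            usecols=range(5),
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "barcode": str, "count": np.int64},
        )
    except Exception:
        frame = None
    if frame is not None and len(frame):
        ok = (
            frame["chrom"].isin(genome).all()
            and (frame["start"] >= 0).all()
            and (frame["end"] > frame["start"]).all()
            and (frame["count"] >= 1).all()
            and frame["barcode"].notna().all()
            and (frame["barcode"] != "").all()
        )
        if ok:
            lengths = frame["chrom"].map(genome).to_numpy()
            in_bounds = frame["end"].to_numpy() <= lengths
            n_bad = int((~in_bounds).sum())
            if n_bad:
                log.warning("rejected %d out-of-bounds fragment records in %s", n_bad, path)
                frame = frame[in_bounds].reset_index(drop=True)
            return FragmentSet(frame, dict(genome))
    elif frame is not None:
        log.warning("fragment file %s is empty", path)
        return FragmentSet(frame, dict(genome))

    chroms, starts, ends, barcodes, counts = [], [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"line {lineno}: expected 5 tab-separated fields, got {len(parts)}")
            chrom, s, e, bc, cnt = parts[:5]
            try:
                s, e, cnt = int(s), int(e), int(cnt)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate or count") from exc
            if chrom not in genome:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
            if e <= s or s < 0:
                raise ValueError(f"line {lineno}: invalid interval [{s}, {e})")
            if cnt < 1:
                raise ValueError(f"line {lineno}: count must be >= 1, got {cnt}")
            if not bc:
                raise ValueError(f"line {lineno}: empty barcode")
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
            barcodes.append(bc)
            counts.append(cnt)
    frame = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "end": np.asarray(ends, dtype=np.int64),
            "barcode": barcodes,
            "count": np.asarray(counts, dtype=np.int64),
        }
    )
    if len(frame) == 0:
        log.warning("fragment file %s is empty", path)
        return FragmentSet(frame, dict(genome))
    lengths = frame["chrom"].map(genome).to_numpy()
    in_bounds = frame["end"].to_numpy() <= lengths
    n_bad = int((~in_bounds).sum())
    if n_bad:
        log.warning("rejected %d out-of-bounds fragment records in %s", n_bad, path)
        frame = frame[in_bounds].reset_index(drop=True)
    return FragmentSet(frame, dict(genome))


def write_fragments(fragments: FragmentSet, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for row in fragments.frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.barcode}\t{row.count}\n")


def read_intervals(path: str | Path) -> List[GenomicInterval]:
    """Read BED3/BED6 intervals, preserving file order; no implicit merging."""
    out: List[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric coordinates") from exc
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else None
            try:
                out.append(GenomicInterval(parts[0], start, end, name, score, strand))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields += [
                    iv.name if iv.name is not None else ".",
                    str(iv.score) if iv.score is not None else ".",
                    iv.strand if iv.strand is not None else ".",
                ]
            fh.write("\t".join(fields) + "\n")


def read_gene_annotation(path: str | Path, genome: Dict[str, int] | None = None) -> GeneAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "tss": np.int64, "strand": str})
    ann = GeneAnnotation(frame)
    if genome is not None:
        lengths = frame["chrom"].map(genome)
        if lengths.isna().any():
            bad = frame.loc[lengths.isna(), "chrom"].iloc[0]
            raise ValueError(f"annotation references unknown chromosome {bad!r}")
        if ((frame["tss"] < 0) | (frame["tss"] >= lengths)).any():
            raise ValueError("annotation TSS outside chromosome bounds")
    return ann


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    ann.frame.to_csv(path, sep="\t", index=False)


def write_matrix(matrix: sp.spmatrix, features: Sequence[str], cells: Sequence[str], prefix: str | Path) -> None:
    """Write a sparse matrix as MTX with feature/cell name sidecars."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(matrix))
    Path(str(prefix) + ".features.txt").write_text("\n".join(features) + "\n")
    Path(str(prefix) + ".cells.txt").write_text("\n".join(cells) + "\n")


def read_matrix(prefix: str | Path):
    prefix = Path(prefix)
    mat = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    features = Path(str(prefix) + ".features.txt").read_text().splitlines()
    cells = Path(str(prefix) + ".cells.txt").read_text().splitlines()
    return mat, features, cells
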