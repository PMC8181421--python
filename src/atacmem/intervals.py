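"""Genomic interval primitives, BED-style I/O and interval set operations.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Peaks carry a summit (the single bp of maximal signal)
which anchors every window operation downstream (count windows, motif
windows, tag-density profiles).  Strand is carried on intervals and genes
but ignored by the set operations — ATAC peaks are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "merge_intervals",
    "intersect_peaks",
    "closest_gene",
    "closest_genes",
]


class BedParseError(ValueError):
    """Raised for malformed BED lines; carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """An accessible-chromatin peak: an interval plus summit and caller score."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, "
                f"{self.interval.end}) on {self.interval.chrom}"
            )
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS, the anchor for peak-to-gene assignment."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


# ---------------------------------------------------------------------------
# BED I/O
#
# Dialects: BED3 (chrom/start/end), BED5 (+name/score), BED6 (+strand), and a
# "summit column" dialect where column 7 holds the summit either as an offset
# from start (summit_mode="offset") or an absolute coordinate ("absolute").
# A peak read without a summit column gets the interval midpoint (floor).
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, summit_mode: str = "offset") -> list[Peak]:
    """Read peaks from a BED file, in file order.

    Parameters
    ----------
    path
        BED3/BED5/BED6 file, optionally with a 7th summit column.
    summit_mode
        How to interpret the summit column when present: ``"offset"``
        (relative to ``start``) or ``"absolute"``.
    """
    if summit_mode not in ("offset", "absolute"):
        raise ValueError(f"summit_mode must be 'offset' or 'absolute', got {summit_mode!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                iv = GenomicInterval(chrom, start, end, strand if strand in "+-." else ".")
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if len(fields) > 6:
                try:
                    raw = int(fields[6])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad summit column: {exc}") from exc
                summit = start + raw if summit_mode == "offset" else raw
            else:
                summit = (start + end) // 2
            try:
                peaks.append(Peak(iv, summit=summit, score=score, name=name))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(
    peaks: Iterable[Peak],
    path: str | Path,
    summit_mode: str | None = "offset",
) -> None:
    """Write peaks as BED6 plus an optional summit column (``summit_mode=None`` omits it)."""
    if summit_mode not in ("offset", "absolute", None):
        raise ValueError(f"bad summit_mode {summit_mode!r}")
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            cols = [
                p.chrom,
                str(p.start),
                str(p.end),
                p.name or f"peak_{i}",
                format(p.score, "g"),
                p.interval.strand,
            ]
            if summit_mode == "offset":
                cols.append(str(p.summit - p.start))
            elif summit_mode == "absolute":
                cols.append(str(p.summit))
            fh.write("\t".join(cols) + "\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene table with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    genes = [
        GeneModel(row.gene_id, row.chrom, int(row.tss), row.strand)
        for row in df.itertuples(index=False)
    ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in gene table")
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Set operations
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and book-ended intervals (gap 0 merges).

    Output is sorted by (chrom, start); base-pair coverage is preserved.
    """
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = ordered[0].chrom, ordered[0].start, ordered[0].end
    for iv in ordered[1:]:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


def _by_chrom_sorted(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts sorted ascending, running max of ends) arrays."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        chroms.setdefault(p.chrom, []).append((p.start, p.end))
    for chrom, pairs in chroms.items():
        pairs.sort()
        starts = np.array([s for s, _ in pairs], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([e for _, e in pairs], dtype=np.int64))
        out[chrom] = (starts, ends)
    return out


def intersect_peaks(a: Sequence[Peak], b: Sequence[Peak]) -> list[Peak]:
    """Members of ``a`` overlapping (>=1 bp) any member of ``b``, in a's order."""
    if not a or not b:
        return []
    index = _by_chrom_sorted(b)
    kept: list[Peak] = []
    for p in a:
        entry = index.get(p.chrom)
        if entry is None:
            continue
        starts, max_ends = entry
        # candidates: b-intervals with start < p.end; overlap iff their max end > p.start
        i = int(np.searchsorted(starts, p.end, side="left"))
        if i > 0 and max_ends[i - 1] > p.start:
            kept.append(p)
    return kept


def closest_gene(peak: Peak, genes: Sequence[GeneModel]) -> tuple[str, int]:
    """Nearest gene to a peak by |summit - tss| on the same chromosome.

    Returns ``(gene_id, signed_distance)`` with distance ``tss - summit``.
    Ties break by smaller tss, then lexicographic gene_id.  Raises
    ``LookupError`` when no gene lies on the peak's chromosome.
    """
    result = closest_genes([peak], genes)
    return result[0]


def closest_genes(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> list[tuple[str, int]]:
    """Vectorised :func:`closest_gene` over many peaks (same tie rules)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.tss, g.gene_id))
        index[chrom] = (np.array([g.tss for g in gs], dtype=np.int64), gs)

    out: list[tuple[str, int]] = []
    for p in peaks:
        if p.chrom not in index:
            raise LookupError(f"no gene on chromosome {p.chrom}")
        tss_arr, gs = index[p.chrom]
        i = int(np.searchsorted(tss_arr, p.summit))
        candidates = []  # distinct tss values flanking the summit
        if i > 0:
            candidates.append(int(tss_arr[i - 1]))
        if i < len(tss_arr):
            candidates.append(int(tss_arr[i]))
        # winning tss: minimal |summit - tss|, tie -> smaller tss
        best_tss = min(candidates, key=lambda t: (abs(t - p.summit), t))
        # among genes sharing best_tss, lexicographically smallest gene_id
        j = int(np.searchsorted(tss_arr, best_tss, side="left"))
        gid = gs[j].gene_id
        out.append((gid, best_tss - p.summit))
    return out
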