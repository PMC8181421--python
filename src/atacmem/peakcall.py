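"""Peak calling from Tn5 cut tracks and master peak-set construction.

The caller is a transparent local-Poisson scan: a sliding window's cut count
is tested against the larger of the genome-wide rate and a local background
rate, significant windows are merged, and the summit is the bp of maximal
combined-strand cut count in each merged region.  It stands in for a
MACS-style caller so the pipeline has no external binary dependency.

Replicate concordance follows the study design: the top-k peaks (by score)
of two replicates are intersected, condition sets are merged into a master
set, and Tn5 insertions are counted in fixed windows around each master
summit (default +/-200 bp) to build the count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, Peak, merge_intervals, intersect_peaks

__all__ = [
    "CutTrack",
    "CountMatrix",
    "call_peaks",
    "top_k",
    "concordant_peaks",
    "build_master_set",
    "count_in_windows",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass
class CutTrack:
    """Per-base Tn5 insertion counts for one chromosome, strands separate."""

    chrom: str
    fwd: np.ndarray  # int counts, length = chromosome length
    rev: np.ndarray

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd)
        self.rev = np.asarray(self.rev)
        if self.fwd.shape != self.rev.shape:
            raise ValueError("forward/reverse arrays must have equal length")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise ValueError("cut counts must be non-negative")

    def __len__(self) -> int:
        return len(self.fwd)

    @property
    def total(self) -> np.ndarray:
        return self.fwd + self.rev

    def add(self, other: "CutTrack") -> None:
        """In-place accumulation (used to pool samples for footprinting)."""
        if other.chrom != self.chrom or len(other) != len(self):
            raise ValueError("cannot pool tracks over different chromosomes")
        self.fwd = self.fwd + other.fwd
        self.rev = self.rev + other.rev


@dataclass
class CountMatrix:
    """Integer counts (features x samples) with sample metadata.

    ``samples`` is indexed by sample id and must carry ``condition`` and
    ``replicate`` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples.index.is_unique:
            raise ValueError("sample ids must be unique")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns must match sample sheet index")
        for col in ("condition", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    def samples_of(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        return cls(counts, samples)


# ---------------------------------------------------------------------------
# bedGraph I/O (run-length encoded per-base values)
# ---------------------------------------------------------------------------


def write_bedgraph(values: np.ndarray, chrom: str, path: str | Path, append: bool = False) -> None:
    """Write a per-base integer array as run-length-encoded bedGraph (zeros skipped)."""
    values = np.asarray(values)
    # run boundaries where the value changes
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    with open(path, "a" if append else "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path: str | Path, genome: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-base arrays, one per chromosome in ``genome``."""
    arrays = {chrom: np.zeros(length, dtype=np.int64) for chrom, length in genome.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split("\t")
            if chrom in arrays:
                arrays[chrom][int(s): int(e)] = int(float(v))
    return arrays


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


def _window_sums(values: np.ndarray, window: int) -> np.ndarray:
    """Sum of ``values[i:i+window]`` for every valid start i (length n-window+1)."""
    c = np.concatenate([[0], np.cumsum(values, dtype=np.int64)])
    return c[window:] - c[:-window]


def call_peaks(
    track: CutTrack,
    window: int = 150,
    min_pvalue: float = 1e-5,
    local_background: int = 10_000,
    summit_smooth: int = 21,
) -> list[Peak]:
    """Call peaks on one chromosome by a sliding-window Poisson test.

    Each window's combined-strand count is compared to a Poisson null whose
    rate is the maximum of the genome-wide mean and the local mean over
    ``local_background`` bp centred on the window.  Overlapping significant
    windows are merged; the summit is the bp maximising the
    ``summit_smooth``-bp moving sum of cuts (leftmost on ties), and the score
    is the -log10 Poisson p of the window centred at the summit.
    """
    if window < 50:
        raise ValueError("window must be >= 50 bp")
    if local_background <= window:
        raise ValueError("local_background must exceed window")
    total = track.total.astype(np.int64)
    n = len(total)
    if n == 0 or total.sum() == 0:
        return []

    global_rate = total.sum() / n
    win_counts = _window_sums(total, window)  # length n - window + 1

    # local background: mean rate over local_background bp centred on each window
    half_bg = local_background // 2
    c = np.concatenate([[0], np.cumsum(total, dtype=np.int64)])
    centers = np.arange(len(win_counts)) + window // 2
    lo = np.maximum(centers - half_bg, 0)
    hi = np.minimum(centers + half_bg, n)
    local_rate = (c[hi] - c[lo]) / (hi - lo)

    lam = np.maximum(global_rate, local_rate) * window
    # Poisson upper tail P(X >= k) = sf(k - 1)
    pvals = stats.poisson.sf(win_counts - 1, lam)
    sig = np.flatnonzero(pvals < min_pvalue)
    if sig.size == 0:
        return []

    # coverage mask of all significant windows, then merged runs
    mask = np.zeros(n + 1, dtype=np.int32)
    np.add.at(mask, sig, 1)
    np.add.at(mask, np.minimum(sig + window, n), -1)
    covered = np.cumsum(mask[:-1]) > 0
    edges = np.flatnonzero(np.diff(np.concatenate([[0], covered.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]

    kernel = np.ones(summit_smooth, dtype=np.int64)
    peaks: list[Peak] = []
    for s, e in zip(starts, ends):
        # smoothed per-bp signal within the region (moving sum, centred)
        pad = summit_smooth // 2
        lo_p, hi_p = max(0, s - pad), min(n, e + pad)
        smoothed = np.convolve(total[lo_p:hi_p], kernel, mode="same")
        region = smoothed[s - lo_p: e - lo_p]
        # ties on the smoothed plateau resolve by raw cut count, then leftmost
        plateau = np.flatnonzero(region == region.max())
        summit = s + int(plateau[np.argmax(total[s + plateau])])
        # score: -log10 p of the window centred on the summit
        ws = min(max(summit - window // 2, 0), max(n - window, 0))
        k = int(total[ws: ws + window].sum())
        lam_s = max(global_rate, float(local_rate[min(ws, len(local_rate) - 1)])) * window
        p = float(stats.poisson.sf(k - 1, lam_s))
        score = -np.log10(max(p, 1e-300))
        peaks.append(Peak(GenomicInterval(track.chrom, int(s), int(e)), summit=int(summit), score=score))
    return peaks


def top_k(peaks: Sequence[Peak], k: int) -> list[Peak]:
    """The k highest-score peaks; ties broken by (chrom, start)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))
    return ordered[:k]


def concordant_peaks(rep1: Sequence[Peak], rep2: Sequence[Peak], k: int = 35_000) -> list[Peak]:
    """Replicate-concordant peaks: top-k of each replicate, intersected.

    Replicate 1's coordinates and summits are kept for the surviving peaks.
    The default k of 35,000 matches the study's high-confidence summit sets.
    """
    return intersect_peaks(top_k(rep1, k), top_k(rep2, k))


def build_master_set(condition_sets: Sequence[Sequence[Peak]]) -> list[Peak]:
    """Merge per-condition concordant peak sets into one master set.

    Overlapping/book-ended peaks across conditions collapse into one region;
    the merged region inherits the summit and score of its highest-score
    contributor (ties by leftmost summit).
    """
    if not condition_sets:
        raise ValueError("need at least one condition peak set")
    all_peaks = [p for s in condition_sets for p in s]
    if not all_peaks:
        return []
    merged = merge_intervals([p.interval for p in all_peaks])

    # map each contributor to its merged region, keep the best-scoring summit
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(merged):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    starts_index = {
        chrom: (np.array([s for s, _, _ in lst]), lst)
        for chrom, lst in by_chrom.items()
    }
    best: dict[int, Peak] = {}
    for p in all_peaks:
        starts, lst = starts_index[p.chrom]
        j = int(np.searchsorted(starts, p.start, side="right")) - 1
        _, _, idx = lst[j]
        cur = best.get(idx)
        if cur is None or (p.score, -p.summit) > (cur.score, -cur.summit):
            best[idx] = p
    out = []
    for idx, iv in enumerate(merged):
        contrib = best[idx]
        out.append(Peak(iv, summit=contrib.summit, score=contrib.score, name=f"master_{idx}"))
    return out


def count_in_windows(
    tracks: Mapping[str, Mapping[str, CutTrack]],
    peaks: Sequence[Peak],
    samples: pd.DataFrame,
    halfwidth: int = 200,
) -> CountMatrix:
    """Count Tn5 insertions (both strands) in ``[summit-halfwidth, summit+halfwidth)``.

    ``tracks`` maps sample id -> chrom -> CutTrack.  Windows are clipped at
    chromosome ends.  The +/-200 bp default matches the study's summit-window
    counting.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    feature_ids = [p.name or f"peak_{i}" for i, p in enumerate(peaks)]
    data = {}
    for sample_id in samples.index:
        chrom_tracks = tracks[sample_id]
        col = np.zeros(len(peaks), dtype=np.int64)
        cums = {
            chrom: np.concatenate([[0], np.cumsum(t.total, dtype=np.int64)])
            for chrom, t in chrom_tracks.items()
        }
        for i, p in enumerate(peaks):
            if p.chrom not in chrom_tracks:
                raise ValueError(f"no track for chromosome {p.chrom} in sample {sample_id}")
            c = cums[p.chrom]
            length = len(c) - 1
            if not (0 <= p.summit < length):
                raise ValueError(f"summit {p.summit} outside chromosome {p.chrom}")
            lo = max(p.summit - halfwidth, 0)
            hi = min(p.summit + halfwidth, length)
            col[i] = c[hi] - c[lo]
        data[sample_id] = col
    counts = pd.DataFrame(data, index=pd.Index(feature_ids, name="feature_id"))
    return CountMatrix(counts, samples.copy())
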