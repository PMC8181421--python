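"""Consensus motif scanning, enrichment, Tn5 footprint scoring and profiles.

Motifs are plain IUPAC consensus strings matched exactly (optionally with a
mismatch budget) on both strands within summit-centred windows (+/-100 bp
by default).  Enrichment of a motif in a target peak set versus a
background set is a hypergeometric upper-tail test on the number of peaks
containing at least one hit.

Footprints follow the strand-aware logic of ATAC footprinting: a bound
factor shields its motif from Tn5, so insertions inside the motif are
depleted relative to flanking "shoulder" sequence.  The forward strand is
compared against the upstream shoulder and the reverse strand against the
downstream shoulder; each strand yields a binomial lower-tail p-value for
the footprint count given footprint+shoulder counts, and the combined
score is the sum of the two -log10 p values (pass at score >= 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak
from .peakcall import CutTrack

__all__ = [
    "IUPAC_CODES",
    "MotifModel",
    "MotifInstance",
    "FootprintCall",
    "EnrichmentResult",
    "reverse_complement",
    "scan_motifs",
    "motif_enrichment",
    "footprint_score",
    "average_cut_profile",
    "tag_density_profile",
    "DEFAULT_MOTIF_PANEL",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(consensus: str) -> str:
    return consensus.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A transcription-factor binding consensus in IUPAC alphabet."""

    name: str
    consensus: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.consensus) < 5:
            raise ValueError("consensus must be >= 5 bp")
        bad = set(self.consensus.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"non-IUPAC characters in consensus: {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    def __len__(self) -> int:
        return len(self.consensus)


# A literature-derived consensus panel for the TF families that dominate
# T-cell enhancers.  Configurable: any TSV of (name, consensus) works.
DEFAULT_MOTIF_PANEL: tuple[MotifModel, ...] = (
    MotifModel("ETS", "AGGAAGTG"),
    MotifModel("RUNX", "TGTGGTTT"),
    MotifModel("AP-1", "TGASTCA"),
    MotifModel("TCF_LEF", "CTTTGWW"),
    MotifModel("T-box", "AGGTGTGA"),
    MotifModel("NFAT", "TTTTCCA"),
    MotifModel("EGR", "GCGBGGGCG"),
)


@dataclass(frozen=True)
class MotifInstance:
    """One motif match, reported in forward-strand coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    motif: str
    peak_name: str = ""

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class FootprintCall:
    instance: GenomicInterval
    fwd_score: float
    rev_score: float
    score: float
    passed: bool


@dataclass(frozen=True)
class EnrichmentResult:
    motif: str
    target_hits: int
    n_target: int
    background_hits: int
    n_background: int
    fold: float
    pvalue: float


def _allowed_table(consensus: str) -> np.ndarray:
    """Boolean (motif_len x 4) table of permitted bases per position."""
    table = np.zeros((len(consensus), 4), dtype=bool)
    for i, code in enumerate(consensus.upper()):
        for base in IUPAC_CODES[code]:
            table[i, _BASE_INDEX[base]] = True
    return table


def _encode(seq: str) -> np.ndarray:
    """Sequence -> int codes; non-ACGT bases map to 4 (matches nothing)."""
    lut = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
        lut[ord(base.lower())] = idx
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _scan_codes(codes: np.ndarray, table: np.ndarray, max_mm: int) -> np.ndarray:
    """Start offsets of all (possibly overlapping) matches of the motif table."""
    L = table.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    # pad the allowed table with a 5th column of False for non-ACGT codes
    padded = np.concatenate([table, np.zeros((L, 1), dtype=bool)], axis=1)
    mismatches = np.zeros(n, dtype=np.int32)
    for l in range(L):
        mismatches += ~padded[l, codes[l: l + n]]
    return np.flatnonzero(mismatches <= max_mm).astype(np.int64)


def scan_motifs(
    genome: Mapping[str, str],
    peaks: Sequence[Peak],
    motif: MotifModel,
    halfwidth: int = 100,
) -> list[MotifInstance]:
    """All motif matches on both strands within ``[summit-halfwidth, summit+halfwidth)``.

    Reverse-strand hits are reported with forward coordinates and a ``-``
    strand flag; a palindromic consensus therefore yields one hit per strand
    at the same position.  Windows are clipped at chromosome ends.
    """
    fwd_table = _allowed_table(motif.consensus)
    rev_table = _allowed_table(reverse_complement(motif.consensus))
    L = len(motif)
    out: list[MotifInstance] = []
    for i, p in enumerate(peaks):
        seq = genome[p.chrom]
        lo = max(p.summit - halfwidth, 0)
        hi = min(p.summit + halfwidth, len(seq))
        codes = _encode(seq[lo:hi])
        name = p.name or f"peak_{i}"
        for strand, table in (("+", fwd_table), ("-", rev_table)):
            for off in _scan_codes(codes, table, motif.max_mismatches):
                out.append(
                    MotifInstance(p.chrom, lo + int(off), lo + int(off) + L, strand, motif.name, name)
                )
    return out


def motif_enrichment(
    target_peaks: Sequence[Peak],
    background_peaks: Sequence[Peak],
    motif: MotifModel,
    genome: Mapping[str, str],
    halfwidth: int = 100,
) -> EnrichmentResult:
    """Hypergeometric enrichment of a motif in target vs background peaks.

    The unit is the peak: a peak "has" the motif when >=1 hit falls in its
    summit window.  p is the upper tail of drawing ``target_hits`` or more
    motif-positive peaks when sampling ``len(target)`` peaks from the pooled
    collection.
    """
    if not target_peaks or not background_peaks:
        raise ValueError("target and background peak sets must be non-empty")

    def n_hit(peaks: Sequence[Peak]) -> int:
        hits = scan_motifs(genome, peaks, motif, halfwidth)
        return len({h.peak_name for h in hits})

    t_hits = n_hit(target_peaks)
    b_hits = n_hit(background_peaks)
    n_t, n_b = len(target_peaks), len(background_peaks)
    t_frac = t_hits / n_t
    b_frac = b_hits / n_b
    fold = float("inf") if b_frac == 0 and t_frac > 0 else (t_frac / b_frac if b_frac else 1.0)
    pvalue = float(stats.hypergeom.sf(t_hits - 1, n_t + n_b, t_hits + b_hits, n_t))
    return EnrichmentResult(motif.name, t_hits, n_t, b_hits, n_b, fold, pvalue)


def footprint_score(
    track: CutTrack,
    instance: GenomicInterval,
    shoulder: int = 35,
    threshold: float = 10.0,
) -> FootprintCall:
    """Strand-aware binomial footprint score for one motif instance.

    Forward-strand cuts inside the footprint are compared against the
    upstream shoulder, reverse-strand cuts against the downstream shoulder.
    Per strand, p = P[Binomial(n = footprint+shoulder cuts,
    q = len_fp/(len_fp+len_sh)) <= footprint cuts]; the combined score is
    the sum of the two -log10 p values.  Zero total cuts scores 0.
    """
    fp_len = instance.end - instance.start
    if shoulder < fp_len:
        raise ValueError("shoulder must be >= footprint length")
    n = len(track)
    fp_slice = slice(max(instance.start, 0), min(instance.end, n))
    up_slice = slice(max(instance.start - shoulder, 0), max(instance.start, 0))
    down_slice = slice(min(instance.end, n), min(instance.end + shoulder, n))

    def strand_score(values: np.ndarray, sh_slice: slice) -> float:
        k_fp = int(values[fp_slice].sum())
        k_sh = int(values[sh_slice].sum())
        total = k_fp + k_sh
        if total == 0:
            return 0.0
        sh_len = sh_slice.stop - sh_slice.start
        if sh_len == 0:
            return 0.0
        q = fp_len / (fp_len + sh_len)
        p = float(stats.binom.cdf(k_fp, total, q))
        return float(-np.log10(max(p, 1e-300)))

    fwd = strand_score(track.fwd, up_slice)
    rev = strand_score(track.rev, down_slice)
    score = fwd + rev
    return FootprintCall(instance, fwd, rev, score, score >= threshold)


def average_cut_profile(
    tracks: Mapping[str, CutTrack],
    instances: Sequence[MotifInstance],
    window: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-bp forward/reverse cut counts around motif centers.

    Reverse-strand instances are flipped (strands swapped, positions
    mirrored) so that all instances share the motif's own orientation.
    Returns ``(fwd_mean, rev_mean)`` arrays of length ``window``; position
    ``window // 2`` is the motif center.
    """
    if window % 2:
        raise ValueError("window must be even")
    if not instances:
        raise ValueError("no motif instances supplied")
    half = window // 2
    fwd_sum = np.zeros(window)
    rev_sum = np.zeros(window)
    used = 0
    for inst in instances:
        track = tracks[inst.chrom]
        c = inst.center
        lo, hi = c - half, c + half
        if lo < 0 or hi > len(track):
            continue  # clip policy: skip instances without a full window
        f = track.fwd[lo:hi].astype(float)
        r = track.rev[lo:hi].astype(float)
        if inst.strand == "-":
            f, r = r[::-1], f[::-1]
        fwd_sum += f
        rev_sum += r
        used += 1
    if used == 0:
        raise ValueError("no instance had a full window inside the chromosome")
    return fwd_sum / used, rev_sum / used


def tag_density_profile(
    tracks: Mapping[str, CutTrack],
    peaks: Sequence[Peak],
    window: int = 2000,
    bin_size: int = 10,
    size_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned tag-density matrix around peak summits plus its column means.

    Each row is one summit's combined-strand counts over
    ``[summit - window/2, summit + window/2)`` summed in ``bin_size`` bp
    bins and divided by ``size_factor``.  Out-of-chromosome positions
    contribute zeros.  Defaults (2000 bp window, 10 bp bins) match the
    study's heatmap parameters.
    """
    if window % bin_size:
        raise ValueError("window must be divisible by bin_size")
    n_bins = window // bin_size
    half = window // 2
    matrix = np.zeros((len(peaks), n_bins))
    for i, p in enumerate(peaks):
        track = tracks[p.chrom]
        n = len(track)
        lo, hi = p.summit - half, p.summit + half
        row = np.zeros(window, dtype=np.int64)
        src_lo, src_hi = max(lo, 0), min(hi, n)
        if src_hi > src_lo:
            row[src_lo - lo: src_hi - lo] = track.total[src_lo:src_hi]
        matrix[i] = row.reshape(n_bins, bin_size).sum(axis=1) / size_factor
    return matrix, matrix.mean(axis=0)
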