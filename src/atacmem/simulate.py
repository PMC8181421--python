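"""Truth-labeled synthetic data: peaks, counts, cut tracks, genome, expression.

The generator emulates the multi-condition ATAC experiment the pipeline is
built for: naive T cells (N), memory timepoints (M7/M28/M56) and
antigen-restimulated memory (M28Ag/M56Ag), two replicates each.  Planted
peak categories carry per-condition accessibility multipliers:

* ``mDHS``   — gained in memory (memory/naive >= effect size), with
  stability sub-structure at the late timepoint (stable / partial / lost);
* ``nDHS``   — lost from naive, with a transient sub-fraction that is
  suppressed at day 7 but restored by day 28;
* ``iDHS``   — induced by antigen (stimulated/resting >= effect size);
* ``dDHS``   — diminished by antigen (the reciprocal);
* ``constitutive`` — flat within 1.25x across conditions.

Window counts are negative-binomial (variance = mu + alpha mu^2) around
mean = depth x multiplier x sample size factor.  Cut tracks place per-base
Tn5 insertions under a peaked (truncated-Gaussian) or uniform profile, with
protected planted motifs depleted 10-fold and their 10 bp flanks enhanced
1.5-fold — the minimal footprint shape.  Expression counts for each peak's
nearest gene follow the peak's category with configurable coupling.

Everything is deterministic given the config seed; independent substreams
are derived per product so regenerating one output never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, Peak, GeneModel
from .peakcall import CutTrack, CountMatrix
from .motifs import IUPAC_CODES, MotifModel

__all__ = [
    "CATEGORIES",
    "PlantedMotif",
    "TruthPeak",
    "SimulationConfig",
    "simulate_truth",
    "simulate_counts",
    "simulate_cut_tracks",
    "pooled_cut_tracks",
    "simulate_genome",
    "simulate_expression",
    "truth_table",
    "write_truth",
]

CATEGORIES = ("mDHS", "nDHS", "iDHS", "dDHS", "constitutive")

# substream tags (second entry of the rng seed sequence)
_STREAM_TRUTH, _STREAM_COUNTS, _STREAM_EXPR, _STREAM_CUTS, _STREAM_GENOME, _STREAM_SF = range(6)


@dataclass(frozen=True)
class PlantedMotif:
    name: str
    consensus: str
    offset: int  # motif start relative to the peak summit
    protected: bool


@dataclass
class TruthPeak:
    peak: Peak
    category: str
    multipliers: dict[str, float]  # condition -> accessibility multiplier
    gene_id: str
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    subtype: str = ""  # stability/transience sub-class, "" when not applicable


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment (defaults = the standard design)."""

    n_peaks: dict[str, int] = field(
        default_factory=lambda: {
            "mDHS": 300, "nDHS": 300, "iDHS": 300, "dDHS": 300, "constitutive": 600,
        }
    )
    n_dual_gene_pairs: int = 100  # genes given both an mDHS and an iDHS peak
    conditions: tuple[str, ...] = ("N", "M7", "M28", "M56", "M28Ag", "M56Ag")
    memory_conditions: tuple[str, ...] = ("M7", "M28", "M56", "M28Ag", "M56Ag")
    stimulated_conditions: tuple[str, ...] = ("M28Ag", "M56Ag")
    replicates: int = 2
    depth: float = 100.0  # expected cuts per constitutive peak window per sample
    dispersion: float = 0.1
    effect_size: float = 8.0
    size_factors: dict[str, float] | None = None  # sample -> factor; None = drawn
    size_factor_range: tuple[float, float] = (0.6, 1.6)
    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    peak_width: int = 200
    min_spacing: int = 2000  # minimum gap between peak edges
    gene_max_offset: int = 800  # |TSS - summit| upper bound for the linked gene
    # cut-track shape
    cut_profile: str = "peaked"  # or "uniform"
    cut_sigma: float | None = None  # default peak_width / 4
    background_cut_rate: float = 0.005  # cuts/bp (both strands) outside peaks
    footprint_protection: float = 0.1
    flank_enhancement: float = 1.5
    flank_width: int = 10
    # motif planting: category -> list of (name, consensus); protected flag applies
    motif_plants: dict[str, tuple[tuple[str, str], ...]] = field(
        default_factory=lambda: {"mDHS": (("ETS", "AGGAAGTG"), ("RUNX", "TGTGGTTT"))}
    )
    plant_fraction: float = 0.75
    plant_protected: bool = True
    # category dynamics
    mdhs_stable_fraction: float = 0.83
    mdhs_partial_fraction: float = 0.145  # late multiplier between 2x and 3x
    ndhs_transient_fraction: float = 0.45
    # expression coupling
    gene_base_mean: float = 100.0
    coupling_log2fc: float = 2.0
    dual_boost_log2fc: float = 1.0
    decoupled_fraction: float = 0.1
    expr_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need >= 2 conditions")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        for key, val in self.n_peaks.items():
            if key not in CATEGORIES:
                raise ValueError(f"unknown peak category {key!r}")
            if val < 0:
                raise ValueError("peak numbers must be >= 0")
        if self.depth <= 0 or self.dispersion < 0 or self.effect_size <= 1:
            raise ValueError("depth > 0, dispersion >= 0, effect_size > 1 required")
        if self.cut_profile not in ("peaked", "uniform"):
            raise ValueError("cut_profile must be 'peaked' or 'uniform'")

    # -- sample bookkeeping -------------------------------------------------
    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            (f"{cond}_r{r}", cond, r)
            for cond in self.conditions
            for r in range(1, self.replicates + 1)
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"])
        return df.set_index("sample_id")

    def sample_size_factors(self) -> pd.Series:
        sheet = self.sample_sheet()
        if self.size_factors is not None:
            s = pd.Series(self.size_factors).reindex(sheet.index)
            if s.isna().any():
                raise ValueError("size_factors missing for some samples")
            return s
        rng = np.random.default_rng([self.seed, _STREAM_SF])
        lo, hi = self.size_factor_range
        return pd.Series(rng.uniform(lo, hi, size=len(sheet)), index=sheet.index)


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------


def _category_multipliers(
    config: SimulationConfig, category: str, rng: np.random.Generator
) -> tuple[dict[str, float], str]:
    """Per-condition multipliers plus the dynamics subtype for one peak."""
    e = config.effect_size
    mult = {c: 1.0 for c in config.conditions}
    subtype = ""
    if category == "constitutive":
        for c in config.conditions:
            mult[c] = rng.uniform(0.9, 1.1)
    elif category == "mDHS":
        u = rng.random()
        if u < config.mdhs_stable_fraction:
            subtype, late = "stable", e
        elif u < config.mdhs_stable_fraction + config.mdhs_partial_fraction:
            subtype, late = "partial", 2.5
        else:
            subtype, late = "lost", 1.5
        for c in config.memory_conditions:
            mult[c] = e
        for c in ("M56", "M56Ag"):
            if c in mult:
                mult[c] = late
    elif category == "nDHS":
        mult["N"] = e
        if rng.random() < config.ndhs_transient_fraction:
            subtype = "transient"
            # suppressed at day 7 (M7/N = 1/e) but restored by day 28
            for c in ("M28", "M56", "M28Ag", "M56Ag"):
                if c in mult:
                    mult[c] = 0.8 * e
        else:
            subtype = "stable"
    elif category == "iDHS":
        for c in config.stimulated_conditions:
            mult[c] = e
    elif category == "dDHS":
        for c in config.stimulated_conditions:
            mult[c] = 1.0 / e
    return mult, subtype


def _plant_motifs(
    config: SimulationConfig, category: str, rng: np.random.Generator
) -> list[PlantedMotif]:
    plants: list[PlantedMotif] = []
    occupied: list[tuple[int, int]] = []
    span = 45
    for name, consensus in config.motif_plants.get(category, ()):
        if rng.random() >= config.plant_fraction:
            continue
        # draw an offset whose motif (plus flanks) does not overlap earlier plants
        for _ in range(50):
            offset = int(rng.integers(-span, span - len(consensus) + 1))
            lo = offset - config.flank_width
            hi = offset + len(consensus) + config.flank_width
            if all(hi <= o_lo or lo >= o_hi for o_lo, o_hi in occupied):
                occupied.append((lo, hi))
                plants.append(PlantedMotif(name, consensus, offset, config.plant_protected))
                break
    return plants


def simulate_truth(config: SimulationConfig) -> tuple[list[TruthPeak], list[GeneModel]]:
    """Place truth peaks and their nearest genes on the synthetic genome.

    Peaks are laid out with >= ``min_spacing`` bp between edges; each peak's
    gene TSS lies within ``gene_max_offset`` bp of its summit, which (given
    the spacing) guarantees the planted gene is the nearest one.  Dual
    gene pairs place an mDHS and an iDHS 1.2 kb apart sharing one gene
    between them.  Deterministic given the seed.
    """
    rng = np.random.default_rng([config.seed, _STREAM_TRUTH])
    width = config.peak_width

    units: list[tuple[str, bool]] = []  # (category, is_dual_pair)
    for cat in CATEGORIES:
        units.extend((cat, False) for _ in range(config.n_peaks.get(cat, 0)))
    units.extend(("dual", True) for _ in range(config.n_dual_gene_pairs))
    if not units:
        return [], []
    rng.shuffle(units)

    # capacity check: worst-case span per unit
    unit_span = 2 * width + 1200 + config.min_spacing + 1000
    genome_len = sum(length for _, length in config.genome)
    if len(units) * unit_span + 2000 * len(config.genome) > genome_len:
        raise ValueError(
            f"genome too small: need ~{len(units) * unit_span} bp for {len(units)} units"
        )

    truth: list[TruthPeak] = []
    genes: list[GeneModel] = []
    chrom_iter = list(config.genome)
    per_chrom = int(np.ceil(len(units) / len(chrom_iter)))
    unit_idx = 0
    peak_idx = 0
    gene_idx = 0

    def new_peak(chrom: str, start: int, category: str) -> TruthPeak:
        nonlocal peak_idx
        summit = start + width // 2
        peak = Peak(
            GenomicInterval(chrom, start, start + width),
            summit=summit,
            score=0.0,
            name=f"peak_{peak_idx:05d}",
        )
        peak_idx += 1
        mult, subtype = _category_multipliers(config, category, rng)
        plants = _plant_motifs(config, category, rng)
        return TruthPeak(peak, category, mult, "", plants, subtype)

    for chrom, length in chrom_iter:
        cursor = 1000
        placed = 0
        while unit_idx < len(units) and placed < per_chrom:
            category, is_dual = units[unit_idx]
            gap = int(rng.integers(config.min_spacing, config.min_spacing + 1000))
            needed = (2 * width + 1200 if is_dual else width) + gap
            if cursor + needed + 1000 > length:
                break
            cursor += gap
            gid = f"gene_{gene_idx:05d}"
            gene_idx += 1
            if is_dual:
                tp_a = new_peak(chrom, cursor, "mDHS")
                tp_b = new_peak(chrom, cursor + width + 1200, "iDHS")
                tp_a.gene_id = gid
                tp_b.gene_id = gid
                tss = (tp_a.peak.summit + tp_b.peak.summit) // 2
                tp_a.subtype = tp_b.subtype = "dual"
                truth.extend([tp_a, tp_b])
                cursor += 2 * width + 1200
            else:
                tp = new_peak(chrom, cursor, category)
                tp.gene_id = gid
                off = int(rng.integers(-config.gene_max_offset, config.gene_max_offset + 1))
                tss = max(tp.peak.summit + off, 0)
                truth.append(tp)
                cursor += width
            genes.append(GeneModel(gid, chrom, tss, "+" if rng.random() < 0.5 else "-"))
            unit_idx += 1
            placed += 1
    if unit_idx < len(units):
        raise ValueError("could not place all peaks; enlarge the genome or reduce n_peaks")
    return truth, genes


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-9:
        return rng.poisson(mean)
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(n, p)


def simulate_counts(truth: Sequence[TruthPeak], config: SimulationConfig) -> CountMatrix:
    """NB window counts for every truth peak x sample (seed-deterministic)."""
    rng = np.random.default_rng([config.seed, _STREAM_COUNTS])
    sheet = config.sample_sheet()
    sf = config.sample_size_factors()
    data = {}
    mult = np.array(
        [[tp.multipliers[cond] for cond in sheet["condition"]] for tp in truth]
    ) if truth else np.zeros((0, len(sheet)))
    means = config.depth * mult * sf.to_numpy()[None, :]
    draws = _nb_draw(rng, means, config.dispersion)
    for j, sample in enumerate(sheet.index):
        data[sample] = draws[:, j] if len(truth) else np.array([], dtype=int)
    idx = pd.Index([tp.peak.name for tp in truth], name="feature_id")
    return CountMatrix(pd.DataFrame(data, index=idx, dtype=np.int64), sheet)


# ---------------------------------------------------------------------------
# Cut tracks
# ---------------------------------------------------------------------------


def _peak_weights(tp: TruthPeak, config: SimulationConfig) -> np.ndarray:
    """Per-bp cut placement weights over the peak window."""
    width = tp.peak.end - tp.peak.start
    if config.cut_profile == "uniform":
        w = np.ones(width)
    else:
        sigma = config.cut_sigma or config.peak_width / 4
        x = np.arange(width) + tp.peak.start - tp.peak.summit
        w = np.exp(-0.5 * (x / sigma) ** 2)
    for pm in tp.planted_motifs:
        if not pm.protected:
            continue
        m_lo = tp.peak.summit + pm.offset - tp.peak.start
        m_hi = m_lo + len(pm.consensus)
        f_lo = max(m_lo - config.flank_width, 0)
        f_hi = min(m_hi + config.flank_width, width)
        w[f_lo:m_lo] *= config.flank_enhancement
        w[m_hi:f_hi] *= config.flank_enhancement
        w[max(m_lo, 0):m_hi] *= config.footprint_protection
    return w / w.sum()


def _sample_track(
    truth: Sequence[TruthPeak],
    config: SimulationConfig,
    condition: str,
    size_factor: float,
    rng: np.random.Generator,
) -> dict[str, CutTrack]:
    tracks = {
        chrom: CutTrack(chrom, np.zeros(n, dtype=np.int32), np.zeros(n, dtype=np.int32))
        for chrom, n in config.genome
    }
    # background cuts
    for chrom, n in config.genome:
        n_bg = rng.poisson(config.background_cut_rate * n)
        pos = rng.integers(0, n, size=n_bg)
        strand_fwd = rng.random(n_bg) < 0.5
        np.add.at(tracks[chrom].fwd, pos[strand_fwd], 1)
        np.add.at(tracks[chrom].rev, pos[~strand_fwd], 1)
    # peak cuts
    for tp in truth:
        mean = config.depth * tp.multipliers[condition] * size_factor
        n_cuts = rng.poisson(mean)
        if n_cuts == 0:
            continue
        w = _peak_weights(tp, config)
        offsets = rng.choice(len(w), size=n_cuts, p=w)
        pos = tp.peak.start + offsets
        strand_fwd = rng.random(n_cuts) < 0.5
        track = tracks[tp.peak.chrom]
        np.add.at(track.fwd, pos[strand_fwd], 1)
        np.add.at(track.rev, pos[~strand_fwd], 1)
    return tracks


def simulate_cut_tracks(
    truth: Sequence[TruthPeak], config: SimulationConfig
) -> Iterator[tuple[str, dict[str, CutTrack]]]:
    """Yield ``(sample_id, {chrom: CutTrack})`` per sample, lazily.

    Each sample uses its own seed substream, so tracks are identical across
    re-runs regardless of which samples are consumed.
    """
    sheet = config.sample_sheet()
    sf = config.sample_size_factors()
    for j, (sample_id, row) in enumerate(sheet.iterrows()):
        rng = np.random.default_rng([config.seed, _STREAM_CUTS, j])
        yield sample_id, _sample_track(truth, config, row["condition"], float(sf[sample_id]), rng)


def pooled_cut_tracks(
    truth: Sequence[TruthPeak],
    config: SimulationConfig,
    samples: Sequence[str] | None = None,
) -> dict[str, CutTrack]:
    """Sum cut tracks over samples (all by default) — the footprinting input."""
    pooled: dict[str, CutTrack] | None = None
    wanted = set(samples) if samples is not None else None
    for sample_id, tracks in simulate_cut_tracks(truth, config):
        if wanted is not None and sample_id not in wanted:
            continue
        if pooled is None:
            pooled = tracks
        else:
            for chrom, t in tracks.items():
                pooled[chrom].add(t)
    if pooled is None:
        raise ValueError("no samples selected")
    return pooled


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------


def simulate_genome(truth: Sequence[TruthPeak], config: SimulationConfig) -> dict[str, str]:
    """Random ACGT sequence with planted motif realizations written in.

    Degenerate IUPAC positions of a planted consensus are realized by a
    seeded draw among the permitted bases.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {}
    for chrom, n in config.genome:
        seqs[chrom] = bases[rng.integers(0, 4, size=n)].copy()
    for tp in truth:
        for pm in tp.planted_motifs:
            start = tp.peak.summit + pm.offset
            arr = seqs[tp.peak.chrom]
            if start < 0 or start + len(pm.consensus) > len(arr):
                continue
            realized = [
                IUPAC_CODES[c][rng.integers(0, len(IUPAC_CODES[c]))]
                for c in pm.consensus.upper()
            ]
            arr[start: start + len(realized)] = np.frombuffer(
                "".join(realized).encode(), dtype=np.uint8
            )
    return {chrom: arr.tobytes().decode() for chrom, arr in seqs.items()}


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(
    truth: Sequence[TruthPeak],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
) -> CountMatrix:
    """Gene-level NB counts whose condition structure follows linked peaks.

    mDHS-linked genes go up in memory, nDHS-linked down in memory,
    iDHS-linked up on stimulation, dDHS-linked down on stimulation; genes
    linked to both an mDHS and an iDHS receive an extra stimulated-memory
    boost.  A ``decoupled_fraction`` of genes ignores its peaks entirely.
    """
    rng = np.random.default_rng([config.seed, _STREAM_EXPR])
    sheet = config.sample_sheet()
    sf = config.sample_size_factors()

    cats_by_gene: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for tp in truth:
        cats_by_gene.setdefault(tp.gene_id, set()).add(tp.category)

    c_up = 2.0 ** config.coupling_log2fc
    boost = 2.0 ** config.dual_boost_log2fc
    mem = set(config.memory_conditions)
    stim = set(config.stimulated_conditions)

    mult_rows = []
    gene_ids = [g.gene_id for g in genes]
    for g in genes:
        cats = cats_by_gene[g.gene_id]
        decoupled = rng.random() < config.decoupled_fraction
        row = []
        for cond in sheet["condition"]:
            m = 1.0
            if not decoupled:
                if "mDHS" in cats and cond in mem:
                    m *= c_up
                if "nDHS" in cats and cond in mem:
                    m /= c_up
                if "iDHS" in cats and cond in stim:
                    m *= c_up
                if "dDHS" in cats and cond in stim:
                    m /= c_up
                if "mDHS" in cats and "iDHS" in cats and cond in stim:
                    m *= boost
            row.append(m)
        mult_rows.append(row)
    mult = np.array(mult_rows) if genes else np.zeros((0, len(sheet)))
    means = config.gene_base_mean * mult * sf.to_numpy()[None, :]
    draws = _nb_draw(rng, means, config.expr_dispersion)
    counts = pd.DataFrame(
        draws, index=pd.Index(gene_ids, name="feature_id"), columns=sheet.index, dtype=np.int64
    )
    return CountMatrix(counts, sheet)


# ---------------------------------------------------------------------------
# Truth export
# ---------------------------------------------------------------------------


def truth_table(truth: Sequence[TruthPeak], config: SimulationConfig) -> pd.DataFrame:
    """Flat truth table (one row per peak) for downstream scoring."""
    rows = []
    for tp in truth:
        row = {
            "peak_id": tp.peak.name,
            "chrom": tp.peak.chrom,
            "start": tp.peak.start,
            "end": tp.peak.end,
            "summit": tp.peak.summit,
            "category": tp.category,
            "subtype": tp.subtype,
            "gene_id": tp.gene_id,
            "n_planted_motifs": len(tp.planted_motifs),
        }
        for cond in config.conditions:
            row[f"mult_{cond}"] = tp.multipliers[cond]
        rows.append(row)
    return pd.DataFrame(rows)


def write_truth(
    truth: Sequence[TruthPeak], config: SimulationConfig, path: str | Path
) -> None:
    truth_table(truth, config).to_csv(path, sep="\t", index=False)
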