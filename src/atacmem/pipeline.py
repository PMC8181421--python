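"""End-to-end orchestration: simulate -> call -> count -> test -> classify -> integrate.

Every stage writes plain files (BED, bedGraph, TSV, JSON) into the run
directory so any stage can be re-run standalone on user data, and the run
manifest records every threshold, the seed, and a checksum per output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from . import classify as clf
from . import diffaccess as da
from . import integrate as ig
from . import motifs as mo
from . import peakcall as pc
from . import simulate as sim
from .intervals import write_bed, write_gene_table, closest_genes

log = logging.getLogger("atacmem")

__all__ = ["Contrast", "RunConfig", "run_pipeline", "report"]


@dataclass(frozen=True)
class Contrast:
    """One two-condition comparison; ``up_label``/``down_label`` name the categories."""

    name: str
    condition_a: str
    condition_b: str
    fold: float = 3.0
    up_label: str = "up"
    down_label: str = "down"


DEFAULT_CONTRASTS = (
    Contrast("M28-vs-N", "N", "M28", up_label="mDHS", down_label="nDHS"),
    Contrast("M7-vs-N", "N", "M7", up_label="mDHS", down_label="nDHS"),
    Contrast("M56-vs-N", "N", "M56", up_label="mDHS", down_label="nDHS"),
    Contrast("M28Ag-vs-M28", "M28", "M28Ag", up_label="iDHS", down_label="dDHS"),
)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults mirror the study's Methods values."""

    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    contrasts: tuple[Contrast, ...] = DEFAULT_CONTRASTS
    top_k: int = 35_000
    count_halfwidth: int = 200
    norm_top_n: int = 30_000
    padj_threshold: float = 0.05
    min_reads: float = 20.0
    call_window: int = 150
    call_pvalue: float = 1e-5
    call_local_background: int = 10_000
    motif_halfwidth: int = 100
    footprint_shoulder: int = 35
    footprint_threshold: float = 10.0
    profile_window: int = 2000
    profile_bin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        conds = set(self.sim.conditions)
        for c in self.contrasts:
            if c.condition_a not in conds or c.condition_b not in conds:
                raise ValueError(f"contrast {c.name} references unknown condition")
            if c.fold <= 0:
                raise ValueError("fold thresholds must be positive")
        # one seed drives everything
        self.sim = sim_replace_seed(self.sim, self.seed)


def sim_replace_seed(cfg: sim.SimulationConfig, seed: int) -> sim.SimulationConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path, write_tracks: bool = False) -> Path:
    """Execute the full synthetic-to-report run; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}, "parameters": {}}
    manifest["parameters"] = {
        "top_k": config.top_k,
        "count_halfwidth": config.count_halfwidth,
        "norm_top_n": config.norm_top_n,
        "padj_threshold": config.padj_threshold,
        "min_reads": config.min_reads,
        "call_window": config.call_window,
        "call_pvalue": config.call_pvalue,
        "call_local_background": config.call_local_background,
        "motif_halfwidth": config.motif_halfwidth,
        "footprint_shoulder": config.footprint_shoulder,
        "footprint_threshold": config.footprint_threshold,
        "profile_window": config.profile_window,
        "profile_bin": config.profile_bin,
        "contrasts": [asdict(c) for c in config.contrasts],
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}

    stage = "simulate"
    try:
        log.info("stage %s", stage)
        truth, genes = sim.simulate_truth(config.sim)
        sim.write_truth(truth, config.sim, outdir / "truth.tsv")
        record("truth", outdir / "truth.tsv")
        write_bed([tp.peak for tp in truth], outdir / "truth_peaks.bed")
        record("truth_peaks", outdir / "truth_peaks.bed")
        write_gene_table(genes, outdir / "genes.tsv")
        record("genes", outdir / "genes.tsv")
        sheet = config.sim.sample_sheet()
        sheet.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample_id")
        record("samples", outdir / "samples.tsv")
        manifest["stages"][stage] = {"n_peaks": len(truth), "n_genes": len(genes)}

        # -- per-sample calling (tracks regenerated lazily; RAM-bounded) ---
        stage = "callpeaks"
        log.info("stage %s", stage)
        per_sample_peaks: dict[str, list] = {}
        for sample_id, tracks in sim.simulate_cut_tracks(truth, config.sim):
            called = []
            for chrom in sorted(tracks):
                called.extend(
                    pc.call_peaks(
                        tracks[chrom],
                        window=config.call_window,
                        min_pvalue=config.call_pvalue,
                        local_background=config.call_local_background,
                    )
                )
            per_sample_peaks[sample_id] = called
            if write_tracks:
                for chrom, tr in tracks.items():
                    pc.write_bedgraph(tr.fwd, chrom, outdir / f"cuts_{sample_id}_fwd.bedGraph",
                                      append=chrom != sorted(tracks)[0])
                    pc.write_bedgraph(tr.rev, chrom, outdir / f"cuts_{sample_id}_rev.bedGraph",
                                      append=chrom != sorted(tracks)[0])
        manifest["stages"][stage] = {s: len(p) for s, p in per_sample_peaks.items()}

        stage = "master"
        log.info("stage %s", stage)
        condition_sets = []
        for cond in config.sim.conditions:
            reps = list(sheet.index[sheet["condition"] == cond])
            concordant = pc.concordant_peaks(
                per_sample_peaks[reps[0]], per_sample_peaks[reps[1]], k=config.top_k
            )
            condition_sets.append(concordant)
        master = pc.build_master_set(condition_sets)
        write_bed(master, outdir / "master_peaks.bed")
        record("master_peaks", outdir / "master_peaks.bed")
        manifest["stages"][stage] = {"n_master": len(master)}

        stage = "count"
        log.info("stage %s", stage)
        cols = {}
        for sample_id, tracks in sim.simulate_cut_tracks(truth, config.sim):
            cm_one = pc.count_in_windows(
                {sample_id: tracks}, master, sheet.loc[[sample_id]], halfwidth=config.count_halfwidth
            )
            cols[sample_id] = cm_one.counts[sample_id]
        counts = pc.CountMatrix(pd.DataFrame(cols)[list(sheet.index)], sheet)
        counts.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
        record("counts", outdir / "counts.tsv")
        manifest["stages"][stage] = {"shape": list(counts.counts.shape)}

        stage = "normalize"
        factors = da.size_factors_topN(counts, n_top=config.norm_top_n)
        norm = da.normalize(counts, factors)
        factors.rename("size_factor").to_csv(outdir / "size_factors.tsv", sep="\t")
        record("size_factors", outdir / "size_factors.tsv")
        manifest["stages"][stage] = {"factors": factors.round(4).to_dict()}

        stage = "difftest+classify"
        log.info("stage %s", stage)
        category_tables = {}
        for c in config.contrasts:
            ga = list(sheet.index[sheet["condition"] == c.condition_a])
            gb = list(sheet.index[sheet["condition"] == c.condition_b])
            res = da.nb_wald_test(counts.counts, factors, (ga, gb))
            table = clf.classify_dhs(
                res, norm, ga, gb,
                fold=c.fold, padj=config.padj_threshold, min_reads=config.min_reads,
            )
            table.to_csv(outdir / f"diff_{c.name}.tsv", sep="\t", index_label="feature_id")
            record(f"diff_{c.name}", outdir / f"diff_{c.name}.tsv")
            category_tables[c.name] = table
        manifest["stages"][stage] = {
            name: dict(t["category"].value_counts()) for name, t in category_tables.items()
        }

        stage = "integrate"
        log.info("stage %s", stage)
        gene_map = dict(
            zip([p.name for p in master], [g for g, _ in closest_genes(master, genes)])
        )
        summary: dict = {}
        mem_contrast = next((c for c in config.contrasts if c.up_label == "mDHS"), None)
        stim_contrast = next((c for c in config.contrasts if c.up_label == "iDHS"), None)
        if mem_contrast and stim_contrast:
            mem_t = category_tables[mem_contrast.name]
            stim_t = category_tables[stim_contrast.name]
            cats: dict[str, set[str]] = {}
            for pid in mem_t.index:
                c_set = set()
                if mem_t.loc[pid, "category"] == "up":
                    c_set.add("mDHS")
                elif mem_t.loc[pid, "category"] == "down":
                    c_set.add("nDHS")
                if stim_t.loc[pid, "category"] == "up":
                    c_set.add("iDHS")
                elif stim_t.loc[pid, "category"] == "down":
                    c_set.add("dDHS")
                cats[pid] = c_set
            gene_table = ig.assign_genes(cats, gene_map)
            gene_table.to_csv(outdir / "gene_categories.tsv", sep="\t", index=False)
            record("gene_categories", outdir / "gene_categories.tsv")

            expr = sim.simulate_expression(truth, genes, config.sim)
            expr.to_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
            record("expression", outdir / "expression.tsv")
            e_factors = da.size_factors_median_of_ratios(expr)
            ga = list(sheet.index[sheet["condition"] == stim_contrast.condition_a])
            gb = list(sheet.index[sheet["condition"] == stim_contrast.condition_b])
            expr_diff = da.nb_wald_test(expr.counts, e_factors, (ga, gb))
            sets = {
                cls: gene_table.loc[gene_table["exclusive_class"] == cls, "gene_id"]
                for cls in ("mDHS-only", "iDHS-only", "mDHS+iDHS", "dDHS-only")
            }
            sets = {k: list(v) for k, v in sets.items() if len(v)}
            if sets:
                fc_summary = ig.mean_expression_fc(sets, expr_diff["log2fc"], seed=config.seed)
                fc_summary.to_csv(outdir / "gene_set_fc.tsv", sep="\t", index=False)
                record("gene_set_fc", outdir / "gene_set_fc.tsv")
                summary["gene_set_fc"] = fc_summary.to_dict(orient="records")
        manifest["stages"][stage] = summary or {"skipped": "no mDHS/iDHS contrasts"}

        stage = "motifs"
        log.info("stage %s", stage)
        genome_seq = sim.simulate_genome(truth, config.sim)
        truth_by_name = {tp.peak.name: tp for tp in truth}
        if mem_contrast:
            mem_t = category_tables[mem_contrast.name]
            up_ids = set(mem_t.index[mem_t["category"] == "up"])
            target = [p for p in master if p.name in up_ids]
            bg_ids = {tp.peak.name for tp in truth if tp.category == "constitutive"}
            bg_master = [
                p for p in master
                if p.name not in up_ids
            ]
            enrich_rows = []
            if target and bg_master:
                for motif in mo.DEFAULT_MOTIF_PANEL:
                    r = mo.motif_enrichment(target, bg_master, motif, genome_seq,
                                            halfwidth=config.motif_halfwidth)
                    enrich_rows.append(asdict_enrich(r))
                pd.DataFrame(enrich_rows).to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
                record("motif_enrichment", outdir / "motif_enrichment.tsv")
            manifest["stages"][stage] = {"n_motifs": len(enrich_rows)}
        else:
            manifest["stages"][stage] = {"skipped": "no memory contrast"}

        manifest["runtime_s"] = round(time.time() - t0, 2)
        manifest["status"] = "complete"
    except Exception as exc:  # record partial progress, then re-raise
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir


def asdict_enrich(r: mo.EnrichmentResult) -> dict:
    return {
        "motif": r.motif,
        "target_hits": r.target_hits,
        "n_target": r.n_target,
        "background_hits": r.background_hits,
        "n_background": r.n_background,
        "fold": r.fold,
        "pvalue": r.pvalue,
    }


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run (truth metrics when present)."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = [f"atacmem run report — seed {manifest.get('seed')}, status {manifest.get('status')}"]
    stages = manifest.get("stages", {})
    if "master" in stages:
        lines.append(f"master peaks: {stages['master'].get('n_master')}")
    if "difftest+classify" in stages:
        lines.append("category counts per contrast:")
        for name, counts in stages["difftest+classify"].items():
            lines.append(f"  {name}: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    truth_path = run_dir / "truth.tsv"
    master_path = run_dir / "master_peaks.bed"
    diff_files = sorted(run_dir.glob("diff_*.tsv"))
    if truth_path.exists() and master_path.exists() and diff_files:
        from .intervals import read_bed, GenomicInterval, Peak as _Peak

        truth = pd.read_csv(truth_path, sep="\t")
        master = read_bed(master_path)
        # map each truth peak to the master feature it overlaps (if any)
        by_chrom: dict[str, list] = {}
        for p in master:
            by_chrom.setdefault(p.chrom, []).append(p)
        truth_to_master: dict[str, str] = {}
        for row in truth.itertuples(index=False):
            for p in by_chrom.get(row.chrom, []):
                if p.start < row.end and row.start < p.end:
                    truth_to_master[row.peak_id] = p.name
                    break
        lines.append("truth-comparison (sensitivity per planted category):")
        for f in diff_files:
            table = pd.read_csv(f, sep="\t", index_col="feature_id")
            contrast = f.stem.removeprefix("diff_")
            for cat, direction in (("mDHS", "up"), ("nDHS", "down"), ("iDHS", "up"), ("dDHS", "down")):
                planted = [
                    truth_to_master[pid]
                    for pid in truth.loc[truth["category"] == cat, "peak_id"]
                    if pid in truth_to_master and truth_to_master[pid] in table.index
                ]
                if not planted:
                    continue
                hit = (table.loc[planted, "category"] == direction).mean()
                lines.append(f"  {contrast} {cat}: {hit:.3f} (n={len(planted)})")
    else:
        lines.append("(no truth files present; truth section omitted)")
    missing = [k for k, v in manifest.get("outputs", {}).items()
               if not (run_dir / v["path"]).exists()]
    if missing:
        lines.append("absent outputs: " + ", ".join(missing))
    return "\n".join(lines)
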