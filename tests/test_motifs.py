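"""Motif scanning, enrichment, footprint scores, cut and tag-density profiles."""

import numpy as np
import pytest
from scipy import stats

from atacmem.intervals import GenomicInterval, Peak
from atacmem.motifs import (
    DEFAULT_MOTIF_PANEL,
    IUPAC_CODES,
    MotifModel,
    MotifInstance,
    average_cut_profile,
    footprint_score,
    motif_enrichment,
    reverse_complement,
    scan_motifs,
    tag_density_profile,
)
from atacmem.peakcall import CutTrack
from atacmem.simulate import SimulationConfig, pooled_cut_tracks, simulate_genome, simulate_truth


def _peak(seq_pos, width=200, chrom="chr1"):
    start = seq_pos - width // 2
    return Peak(GenomicInterval(chrom, start, start + width), seq_pos)


def _iupac_match(seq, consensus):
    return len(seq) == len(consensus) and all(
        b in IUPAC_CODES[c] for b, c in zip(seq, consensus))


class TestScan:
    def test_ets_core_found_on_forward_strand(self):
        genome = {"chr1": "T" * 96 + "TTAGGAAGTGTT" + "T" * 92}
        hits = scan_motifs(genome, [_peak(100)], MotifModel("ETS", "AGGAAGTG"))
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].start == 98

    def test_palindrome_reported_once_per_strand(self):
        pal = "GGATCGATCC"  # reverse complement of itself
        genome = {"chr1": "A" * 95 + pal + "A" * 95}
        hits = scan_motifs(genome, [_peak(100)], MotifModel("pal", pal))
        assert len(hits) == 2
        assert {h.strand for h in hits} == {"+", "-"}
        assert len({(h.start, h.strand) for h in hits}) == 2

    def test_against_naive_per_position_oracle(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=3000))
        genome = {"chr1": seq}
        peaks = [_peak(int(c)) for c in rng.integers(150, 2850, size=8)]
        for motif in (MotifModel("ETS", "AGGAAGTG"), MotifModel("TCF", "CTTTGWW")):
            got = {(h.start, h.strand) for h in scan_motifs(genome, peaks, motif)}
            expected = set()
            rc = reverse_complement(motif.consensus)
            for p in peaks:
                lo, hi = p.summit - 100, p.summit + 100
                for i in range(lo, hi - len(motif) + 1):
                    if _iupac_match(seq[i: i + len(motif)], motif.consensus):
                        expected.add((i, "+"))
                    if _iupac_match(seq[i: i + len(motif)], rc):
                        expected.add((i, "-"))
            assert got == expected

    def test_window_clipped_at_chromosome_edge(self):
        genome = {"chr1": "AGGAAGTG" + "T" * 300}
        p = Peak(GenomicInterval("chr1", 0, 100), 10)
        hits = scan_motifs(genome, [p], MotifModel("ETS", "AGGAAGTG"))
        assert any(h.start == 0 for h in hits)

    def test_consensus_validation(self):
        with pytest.raises(ValueError):
            MotifModel("short", "GGAA")
        with pytest.raises(ValueError):
            MotifModel("bad", "GGAAXQ")


class TestEnrichment:
    def test_equal_hit_fractions_not_enriched(self):
        genome = {"chr1": ("TTAGGAAGTGTT" + "C" * 400) * 40}
        peaks = [_peak(100 + 412 * i) for i in range(20)]
        r = motif_enrichment(peaks[:10], peaks[10:], MotifModel("ETS", "AGGAAGTG"), genome)
        assert r.fold == pytest.approx(1.0)
        assert r.pvalue >= 0.5

    def test_exact_hypergeometric_sum_oracle(self, rng):
        # construct 50 target peaks all containing the motif, 5/500 background
        motif = MotifModel("ETS", "AGGAAGTG")
        block = "C" * 206
        seqs = []
        for i in range(550):
            has = i < 50 or (500 <= i < 505) or (50 <= i < 55)
            seqs.append("C" * 99 + "AGGAAGTG" + "C" * 99 if has else block)
        genome = {"chr1": "".join(seqs)}
        peaks = [_peak(206 * i + 103) for i in range(550)]
        target, background = peaks[:50], peaks[50:]
        r = motif_enrichment(target, background, motif, genome)
        # brute-force upper-tail hypergeometric sum
        N, K, n = 550, r.target_hits + r.background_hits, 50
        p_brute = sum(
            stats.hypergeom.pmf(k, N, K, n) for k in range(r.target_hits, min(K, n) + 1)
        )
        assert r.target_hits == 50
        assert r.pvalue == pytest.approx(p_brute, rel=1e-8)

    def test_monotone_in_target_hit_count(self):
        # p decreases as the target hit count rises at fixed totals
        pvals = [stats.hypergeom.sf(k - 1, 600, 60, 50) for k in range(5, 45, 5)]
        assert all(a > b for a, b in zip(pvals, pvals[1:]))

    def test_planted_motifs_rank_top2_of_panel(self):
        cfg = SimulationConfig(
            seed=21,
            n_peaks={"mDHS": 120, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 240},
            n_dual_gene_pairs=0,
            genome=(("chr1", 2_500_000),),
        )
        truth, _ = simulate_truth(cfg)
        genome = simulate_genome(truth, cfg)
        target = [tp.peak for tp in truth if tp.category == "mDHS"]
        background = [tp.peak for tp in truth if tp.category == "constitutive"]
        results = sorted(
            (motif_enrichment(target, background, m, genome) for m in DEFAULT_MOTIF_PANEL),
            key=lambda r: r.pvalue,
        )
        assert {results[0].motif, results[1].motif} == {"ETS", "RUNX"}


class TestFootprint:
    def test_closed_form_zero_footprint_cuts(self):
        # 0 cuts in a 10 bp footprint, 40 shoulder cuts per strand, shoulder 35
        track = CutTrack("chr1", np.zeros(1000, dtype=int), np.zeros(1000, dtype=int))
        track.fwd[455:490] = 0
        # place 40 forward cuts upstream, 40 reverse cuts downstream
        track.fwd[465:490] = 0
        track.fwd[np.arange(465, 500, 35 // 35)] = 0
        fp = GenomicInterval("chr1", 500, 510)
        up = np.linspace(465, 499, 40).astype(int)
        for u in up:
            track.fwd[u] += 1
        down = np.linspace(510, 544, 40).astype(int)
        for d in down:
            track.rev[d] += 1
        call = footprint_score(track, fp, shoulder=35)
        q = 10 / 45
        expected_per_strand = -np.log10((1 - q) ** 40)
        assert call.fwd_score == pytest.approx(expected_per_strand, rel=1e-9)
        assert call.rev_score == pytest.approx(expected_per_strand, rel=1e-9)
        assert call.score == pytest.approx(2 * expected_per_strand, rel=1e-9)

    def test_zero_cuts_scores_zero(self):
        track = CutTrack("chr1", np.zeros(200, dtype=int), np.zeros(200, dtype=int))
        call = footprint_score(track, GenomicInterval("chr1", 100, 110))
        assert call.score == 0 and not call.passed

    def test_default_threshold_is_ten(self):
        import inspect

        assert inspect.signature(footprint_score).parameters["threshold"].default == 10.0

    def test_uniform_null_pass_rate_below_one_percent(self):
        cfg = SimulationConfig(
            seed=31, cut_profile="uniform", plant_protected=False,
            motif_plants={"constitutive": (("ETS", "AGGAAGTG"),)}, plant_fraction=1.0,
            n_peaks={"constitutive": 1000, "mDHS": 0, "nDHS": 0, "iDHS": 0, "dDHS": 0},
            n_dual_gene_pairs=0, genome=(("chr1", 6_000_000),),
        )
        truth, _ = simulate_truth(cfg)
        pooled = pooled_cut_tracks(truth, cfg)
        scores = []
        for tp in truth:
            for pm in tp.planted_motifs:
                s = tp.peak.summit + pm.offset
                iv = GenomicInterval(tp.peak.chrom, s, s + len(pm.consensus))
                scores.append(footprint_score(pooled[tp.peak.chrom], iv).score)
        assert len(scores) >= 1000
        assert np.mean(np.asarray(scores) >= 10) <= 0.01

    def test_protected_score_exceeds_unprotected_at_equal_depth(self):
        common = dict(
            n_peaks={"mDHS": 150, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 0},
            n_dual_gene_pairs=0, plant_fraction=1.0, genome=(("chr1", 2_000_000),),
        )
        scores = {}
        for label, protected in (("protected", True), ("unprotected", False)):
            cfg = SimulationConfig(seed=41, plant_protected=protected, **common)
            truth, _ = simulate_truth(cfg)
            pooled = pooled_cut_tracks(truth, cfg)
            vals = []
            for tp in truth:
                for pm in tp.planted_motifs:
                    s = tp.peak.summit + pm.offset
                    iv = GenomicInterval(tp.peak.chrom, s, s + len(pm.consensus))
                    vals.append(footprint_score(pooled[tp.peak.chrom], iv).score)
            scores[label] = np.median(vals)
        assert scores["protected"] > scores["unprotected"]


class TestProfiles:
    def test_single_instance_is_its_own_profile(self, rng):
        fwd = rng.integers(0, 5, 400)
        rev = rng.integers(0, 5, 400)
        track = CutTrack("chr1", fwd, rev)
        inst = MotifInstance("chr1", 196, 204, "+", "m")
        f, r = average_cut_profile({"chr1": track}, [inst], window=200)
        assert np.array_equal(f, fwd[100:300])
        assert np.array_equal(r, rev[100:300])

    def test_reverse_instance_flipped(self, rng):
        fwd = rng.integers(0, 5, 400)
        rev = rng.integers(0, 5, 400)
        track = CutTrack("chr1", fwd, rev)
        inst = MotifInstance("chr1", 196, 204, "-", "m")
        f, r = average_cut_profile({"chr1": track}, [inst], window=200)
        assert np.array_equal(f, rev[100:300][::-1])
        assert np.array_equal(r, fwd[100:300][::-1])

    def test_no_instances_raises(self):
        track = CutTrack("chr1", np.zeros(10, dtype=int), np.zeros(10, dtype=int))
        with pytest.raises(ValueError):
            average_cut_profile({"chr1": track}, [], window=4)

    def test_planted_depletion_at_center(self):
        cfg = SimulationConfig(
            seed=51, cut_profile="uniform",
            n_peaks={"mDHS": 150, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 0},
            n_dual_gene_pairs=0, plant_fraction=1.0, genome=(("chr1", 2_000_000),),
        )
        truth, _ = simulate_truth(cfg)
        pooled = pooled_cut_tracks(truth, cfg)
        instances = []
        for tp in truth:
            for pm in tp.planted_motifs:
                s = tp.peak.summit + pm.offset
                instances.append(MotifInstance(tp.peak.chrom, s, s + len(pm.consensus), "+", pm.name))
        f, r = average_cut_profile(pooled, instances, window=100)
        total = f + r
        center = total[48:52].mean()
        flank = np.concatenate([total[20:35], total[65:80]]).mean()
        assert center < 0.5 * flank

    def test_unprotected_center_flank_ratio_near_one(self):
        cfg = SimulationConfig(
            seed=61, cut_profile="uniform", plant_protected=False,
            n_peaks={"mDHS": 200, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 0},
            n_dual_gene_pairs=0, plant_fraction=1.0, genome=(("chr1", 2_500_000),),
        )
        truth, _ = simulate_truth(cfg)
        pooled = pooled_cut_tracks(truth, cfg)
        instances = []
        for tp in truth:
            for pm in tp.planted_motifs:
                s = tp.peak.summit + pm.offset
                instances.append(MotifInstance(tp.peak.chrom, s, s + len(pm.consensus), "+", pm.name))
        f, r = average_cut_profile(pooled, instances, window=100)
        total = f + r
        center = total[46:54].mean()
        flank = np.concatenate([total[20:35], total[65:80]]).mean()
        assert 0.8 < center / flank < 1.2


class TestTagDensity:
    def test_defaults_match_study_parameters(self):
        import inspect

        sig = inspect.signature(tag_density_profile)
        assert sig.parameters["window"].default == 2000
        assert sig.parameters["bin_size"].default == 10

    def test_empty_track_zero_matrix(self):
        track = CutTrack("chr1", np.zeros(5000, dtype=int), np.zeros(5000, dtype=int))
        m, means = tag_density_profile({"chr1": track}, [_peak(2500)])
        assert m.shape == (1, 200) and (m == 0).all() and (means == 0).all()

    def test_against_block_sum_oracle(self, rng):
        n = 6000
        track = CutTrack("chr1", rng.integers(0, 3, n), rng.integers(0, 3, n))
        peaks = [_peak(2500), _peak(3100)]
        m, means = tag_density_profile({"chr1": track}, peaks, window=400, bin_size=10, size_factor=2.0)
        for i, p in enumerate(peaks):
            window = track.total[p.summit - 200: p.summit + 200]
            oracle = window.reshape(40, 10).sum(axis=1) / 2.0
            assert np.allclose(m[i], oracle)
        assert np.allclose(means, m.mean(axis=0))

    def test_row_sum_matches_window_count(self, rng):
        # internal consistency with summit-window counting at halfwidth = window/2
        import pandas as pd
        from atacmem.peakcall import count_in_windows

        n = 6000
        track = CutTrack("chr1", rng.integers(0, 3, n), rng.integers(0, 3, n))
        peaks = [_peak(2500, width=400)]
        m, _ = tag_density_profile({"chr1": track}, peaks, window=400, bin_size=10)
        samples = pd.DataFrame({"condition": ["A"], "replicate": [1]},
                               index=pd.Index(["s1"], name="sample_id"))
        cm = count_in_windows({"s1": {"chr1": track}}, peaks, samples, halfwidth=200)
        assert m[0].sum() == cm.counts.iloc[0, 0]
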