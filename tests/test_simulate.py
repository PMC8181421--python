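"""Synthetic-data generator: determinism, planted structure, marginals."""

import numpy as np
import pandas as pd
import pytest

from atacmem.simulate import (
    SimulationConfig,
    pooled_cut_tracks,
    simulate_counts,
    simulate_cut_tracks,
    simulate_expression,
    simulate_genome,
    simulate_truth,
    truth_table,
)


def tiny_config(**overrides):
    base = dict(
        seed=5,
        n_peaks={"mDHS": 20, "nDHS": 20, "iDHS": 20, "dDHS": 20, "constitutive": 40},
        n_dual_gene_pairs=5,
        genome=(("chr1", 800_000),),
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestTruth:
    def test_zero_peaks_gives_empty_truth(self):
        cfg = tiny_config(n_peaks={c: 0 for c in ("mDHS", "nDHS", "iDHS", "dDHS", "constitutive")},
                          n_dual_gene_pairs=0)
        truth, genes = simulate_truth(cfg)
        assert truth == [] and genes == []

    def test_same_seed_identical_truth(self):
        cfg = tiny_config()
        t1 = truth_table(simulate_truth(cfg)[0], cfg)
        t2 = truth_table(simulate_truth(cfg)[0], cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_effect_sizes_by_construction(self, small_config, small_truth):
        truth, _ = small_truth
        e = small_config.effect_size
        for tp in truth:
            m = tp.multipliers
            if tp.category == "mDHS":
                assert m["M28"] / m["N"] >= e
            elif tp.category == "nDHS":
                assert m["N"] / min(m["M7"], m["M28"]) >= e or m["N"] / m["M7"] >= e
            elif tp.category == "iDHS":
                assert m["M28Ag"] / m["M28"] >= e
            elif tp.category == "dDHS":
                assert m["M28"] / m["M28Ag"] >= e
            else:
                vals = [m[c] for c in small_config.conditions]
                assert max(vals) / min(vals) <= 1.25

    def test_nearest_gene_is_the_planted_link(self, small_truth):
        from atacmem.intervals import closest_genes

        truth, genes = small_truth
        assigned = closest_genes([tp.peak for tp in truth], genes)
        mismatches = sum(1 for tp, (gid, _) in zip(truth, assigned) if gid != tp.gene_id)
        assert mismatches == 0

    def test_infeasible_placement_raises(self):
        with pytest.raises(ValueError, match="genome too small|could not place"):
            simulate_truth(tiny_config(genome=(("chr1", 10_000),)))


class TestCounts:
    def test_poisson_limit_variance_matches_mean(self):
        cfg = tiny_config(dispersion=0.0, replicates=2, size_factors=None)
        cfg = tiny_config(dispersion=0.0)
        # equal multipliers, many replicate draws via constitutive peaks
        truth, _ = simulate_truth(cfg)
        cm = simulate_counts(truth, cfg)
        sf = cfg.sample_size_factors()
        norm = cm.counts / sf
        cons = [tp.peak.name for tp in truth if tp.category == "constitutive"]
        vals = norm.loc[cons].to_numpy()
        # Poisson: variance ~= mean (ratio near 1 when pooled over many peaks)
        ratio = vals.var(axis=1).mean() / vals.mean()
        assert 0.6 < ratio < 1.6

    def test_flat_multiplier_mean_within_3_se(self):
        cfg = tiny_config(
            n_peaks={"constitutive": 0, "mDHS": 0, "nDHS": 0, "iDHS": 0, "dDHS": 0},
            n_dual_gene_pairs=0,
        )
        # build flat-multiplier truth by hand: every multiplier exactly 1
        cfg2 = tiny_config()
        truth, _ = simulate_truth(cfg2)
        for tp in truth:
            tp.multipliers = {c: 1.0 for c in cfg2.conditions}
        cm = simulate_counts(truth, cfg2)
        sf = cfg2.sample_size_factors()
        for sample in cm.counts.columns:
            mean = cm.counts[sample].mean()
            expected = cfg2.depth * sf[sample]
            se = np.sqrt(expected * (1 + cfg2.dispersion * expected) / len(truth))
            assert abs(mean - expected) < 3.5 * se

    def test_planted_8x_ratio_recovered(self):
        cfg = tiny_config(n_peaks={"mDHS": 50, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 0},
                          n_dual_gene_pairs=0, size_factors=None)
        truth, _ = simulate_truth(cfg)
        cm = simulate_counts(truth, cfg)
        sf = cfg.sample_size_factors()
        norm = cm.counts / sf
        mem = norm[cm.samples_of("M28")].mean(axis=1)
        naive = norm[cm.samples_of("N")].mean(axis=1)
        ratio = (mem.sum() / naive.sum())
        assert 5 < ratio < 13

    def test_counts_are_nonneg_integers_and_deterministic(self, small_config, small_truth):
        truth, _ = small_truth
        cm1 = simulate_counts(truth, small_config)
        cm2 = simulate_counts(truth, small_config)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        assert (cm1.counts.to_numpy() >= 0).all()
        assert np.issubdtype(cm1.counts.to_numpy().dtype, np.integer)


class TestCutTracks:
    def _protected_scores(self, cfg):
        truth, _ = simulate_truth(cfg)
        pooled = pooled_cut_tracks(truth, cfg)
        inside, flank = [], []
        for tp in truth:
            for pm in tp.planted_motifs:
                s = tp.peak.summit + pm.offset
                track = pooled[tp.peak.chrom]
                inside.append(track.total[s: s + len(pm.consensus)].mean())
                flank.append(
                    np.concatenate([
                        track.total[s - 10: s], track.total[s + len(pm.consensus): s + len(pm.consensus) + 10]
                    ]).mean()
                )
        return np.array(inside), np.array(flank)

    def test_protection_depletes_motif_interior(self):
        cfg = tiny_config(
            n_peaks={"mDHS": 100, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 0},
            n_dual_gene_pairs=0, plant_fraction=1.0, genome=(("chr1", 1_500_000),),
        )
        inside, flank = self._protected_scores(cfg)
        assert len(inside) >= 100
        assert inside.mean() < 0.5 * flank.mean()

    def test_protection_factor_one_means_no_footprint(self):
        cfg = tiny_config(
            n_peaks={"mDHS": 100, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 0},
            n_dual_gene_pairs=0, plant_fraction=1.0, footprint_protection=1.0,
            flank_enhancement=1.0, cut_profile="uniform", genome=(("chr1", 1_500_000),),
        )
        inside, flank = self._protected_scores(cfg)
        assert 0.8 < inside.mean() / flank.mean() < 1.2

    def test_protection_zero_gives_zero_cuts_inside(self):
        cfg = tiny_config(
            n_peaks={"mDHS": 30, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 0},
            n_dual_gene_pairs=0, plant_fraction=1.0, footprint_protection=0.0,
            background_cut_rate=0.0,
        )
        inside, _ = self._protected_scores(cfg)
        assert inside.sum() == 0

    def test_tracks_deterministic_per_sample(self):
        cfg = tiny_config(n_peaks={"mDHS": 10, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 10},
                          n_dual_gene_pairs=0, genome=(("chr1", 300_000),))
        truth, _ = simulate_truth(cfg)
        first = dict(simulate_cut_tracks(truth, cfg))
        second = dict(simulate_cut_tracks(truth, cfg))
        for sid in first:
            assert np.array_equal(first[sid]["chr1"].fwd, second[sid]["chr1"].fwd)
            assert np.array_equal(first[sid]["chr1"].rev, second[sid]["chr1"].rev)


class TestGenome:
    def test_planted_consensus_present_at_offset(self, small_config, small_truth):
        truth, _ = small_truth
        genome = simulate_genome(truth, small_config)
        from atacmem.motifs import IUPAC_CODES

        checked = 0
        for tp in truth:
            for pm in tp.planted_motifs:
                s = tp.peak.summit + pm.offset
                seq = genome[tp.peak.chrom][s: s + len(pm.consensus)]
                assert all(base in IUPAC_CODES[c] for base, c in zip(seq, pm.consensus))
                checked += 1
        assert checked > 0


class TestExpression:
    def test_zero_coupling_gives_no_systematic_fc(self):
        cfg = tiny_config(coupling_log2fc=0.0, dual_boost_log2fc=0.0,
                          n_peaks={"mDHS": 150, "nDHS": 150, "iDHS": 100, "dDHS": 100, "constitutive": 100},
                          n_dual_gene_pairs=0, genome=(("chr1", 3_500_000),))
        truth, genes = simulate_truth(cfg)
        expr = simulate_expression(truth, genes, cfg)
        sf = cfg.sample_size_factors()
        norm = expr.counts / sf
        lfc = np.log2(norm[expr.samples_of("M28")].mean(axis=1) + 0.5) - np.log2(
            norm[expr.samples_of("N")].mean(axis=1) + 0.5)
        gene_cat = {tp.gene_id: tp.category for tp in truth}
        for cat in ("mDHS", "nDHS"):
            sel = [g for g, c in gene_cat.items() if c == cat]
            assert abs(lfc.loc[sel].mean()) < 0.2

    def test_coupling_recovered_in_band(self):
        cfg = tiny_config(n_peaks={"mDHS": 100, "nDHS": 0, "iDHS": 0, "dDHS": 0, "constitutive": 0},
                          n_dual_gene_pairs=0, decoupled_fraction=0.0, genome=(("chr1", 1_500_000),))
        truth, genes = simulate_truth(cfg)
        expr = simulate_expression(truth, genes, cfg)
        sf = cfg.sample_size_factors()
        norm = expr.counts / sf
        lfc = np.log2(norm[expr.samples_of("M28")].mean(axis=1)) - np.log2(
            norm[expr.samples_of("N")].mean(axis=1))
        assert 1.6 < lfc.mean() < 2.4

    def test_same_seed_identical_matrix(self, small_config, small_truth):
        truth, genes = small_truth
        e1 = simulate_expression(truth, genes, small_config)
        e2 = simulate_expression(truth, genes, small_config)
        pd.testing.assert_frame_equal(e1.counts, e2.counts)
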