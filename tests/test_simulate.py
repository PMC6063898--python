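"""Synthetic scenario generator: determinism, placement, planted effects."""

import numpy as np
import pandas as pd
import pytest

from diffenh.genome import mean_signal, rpkm_normalize
from diffenh.linkage import expression_fold_change
from diffenh.simulate import (
    GroundTruth,
    ScenarioConfig,
    SizingError,
    make_genome,
    read_ground_truth,
    score_recovery,
    simulate_mark_tracks,
    simulate_rnaseq,
    write_ground_truth,
)

TINY = dict(genome_length=500_000, n_genes=20, n_enhancers=40, n_activated=5)


class TestMakeGenome:
    def test_seeded_determinism(self):
        t1 = make_genome(ScenarioConfig(**TINY, seed=1))
        t2 = make_genome(ScenarioConfig(**TINY, seed=1))
        assert t1.genes == t2.genes
        assert t1.enhancers == t2.enhancers
        assert t1.activated_set == t2.activated_set
        pd.testing.assert_frame_equal(t1.states, t2.states)

    def test_different_seeds_differ(self):
        t1 = make_genome(ScenarioConfig(**TINY, seed=1))
        t2 = make_genome(ScenarioConfig(**TINY, seed=2))
        assert t1.enhancers != t2.enhancers

    def test_no_enhancers_is_valid_degenerate_case(self):
        cfg = ScenarioConfig(**{**TINY, "n_enhancers": 0, "n_activated": 0})
        truth = make_genome(cfg)
        assert truth.enhancers == []
        assert len(truth.genes) == 20
        assert (truth.true_expr_fc == 1.0).all()

    def test_gene_bodies_never_overlap_pairwise(self):
        cfg = ScenarioConfig(genome_length=5_000_000, n_genes=50, n_enhancers=0, n_activated=0, seed=3)
        genes = make_genome(cfg).genes
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1 :]:
                assert not g1.interval.overlaps(g2.interval)

    def test_enhancers_intergenic_and_separated(self):
        cfg = ScenarioConfig(**TINY, seed=4)
        truth = make_genome(cfg)
        for iv in truth.enhancers:
            for g in truth.genes:
                assert not iv.overlaps(g.interval)
        ivs = sorted(truth.enhancers, key=lambda v: v.start)
        for a, b in zip(ivs, ivs[1:]):
            assert b.start - a.end >= cfg.enhancer_gap

    def test_infeasible_packing_raises_sizing_error(self):
        cfg = ScenarioConfig(
            genome_length=100_000, n_genes=5, n_enhancers=500, n_activated=0,
            bin_size=50, seed=0,
        )
        with pytest.raises(SizingError):
            make_genome(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_enhancers=10, n_activated=11).validate()
        with pytest.raises(ValueError):
            ScenarioConfig(background_rate=0.0).validate()
        with pytest.raises(ValueError):
            ScenarioConfig(genome_length=1_000_001, bin_size=50).validate()

    def test_activated_states_go_primed_to_active(self):
        truth = make_genome(ScenarioConfig(**TINY, seed=5))
        for name in truth.activated_set:
            assert truth.states.loc[name, "A"] == "primed"
            assert truth.states.loc[name, "B"] == "active"
        # every planted expression effect traces back to an activated enhancer
        assert set(truth.gene_links) == truth.activated_set

    def test_ground_truth_json_round_trip(self, tmp_path):
        truth = make_genome(ScenarioConfig(**TINY, seed=6))
        path = tmp_path / "truth.json"
        write_ground_truth(truth, path)
        back = read_ground_truth(path)
        assert back.activated_set == truth.activated_set
        assert back.enhancers == truth.enhancers
        assert back.genes == truth.genes
        pd.testing.assert_series_equal(back.true_expr_fc, truth.true_expr_fc)


class TestMarkTracks:
    def test_seeded_determinism_and_conservation(self, small_truth, small_config):
        tracks = simulate_mark_tracks(small_truth, small_config)
        again = simulate_mark_tracks(small_truth, small_config)
        for key, track in tracks.items():
            np.testing.assert_array_equal(track.data["chr1"], again[key].data["chr1"])
            assert track.total_mapped == track.total_signal()

    def test_k27ac_rises_at_activated_enhancer(self, small_truth, small_config):
        tracks = simulate_mark_tracks(small_truth, small_config)
        name = sorted(small_truth.activated_set)[0]
        iv = small_truth.enhancer_by_id(name)
        sig_a = mean_signal(tracks[("H3K27ac", "A")], iv)
        sig_b = mean_signal(tracks[("H3K27ac", "B")], iv)
        assert sig_b > sig_a * 2

    def test_k27ac_mean_higher_in_b_across_replicate_draws(self):
        cfg = ScenarioConfig(**TINY)
        truth = make_genome(ScenarioConfig(**TINY, seed=11))
        name = sorted(truth.activated_set)[0]
        iv = truth.enhancer_by_id(name)
        means_a, means_b = [], []
        for s in range(30):
            c = ScenarioConfig(**{**cfg.__dict__, "seed": s})
            tr = simulate_mark_tracks(truth, c)
            means_a.append(mean_signal(tr[("H3K27ac", "A")], iv))
            means_b.append(mean_signal(tr[("H3K27ac", "B")], iv))
        assert np.mean(means_b) > np.mean(means_a)

    def test_background_region_matches_background_rate(self, small_truth, small_config):
        tracks = simulate_mark_tracks(small_truth, small_config)
        track = tracks[("H3K27ac", "A")]
        # mask out all footprints; remaining bins are pure background
        bs = small_config.bin_size
        mask = np.ones(len(track.data["chr1"]), dtype=bool)
        for iv in small_truth.enhancers:
            mask[iv.start // bs : (iv.end - 1) // bs + 1] = False
        for g in small_truth.genes:
            mask[g.interval.start // bs - 20 : (g.interval.end // bs) + 20] = False
        background = track.data["chr1"][mask]
        assert len(background) > 1_000
        se = np.sqrt(small_config.background_rate / len(background))
        assert abs(background.mean() - small_config.background_rate) < 3 * se

    def test_h3k4me3_confined_to_tss_footprints(self, small_truth, small_config):
        tracks = simulate_mark_tracks(small_truth, small_config)
        track = tracks[("H3K4me3", "A")]
        # enhancer footprints carry only background H3K4me3
        vals = [mean_signal(track, iv) for iv in small_truth.enhancers[:50]]
        assert np.mean(vals) < 2 * small_config.background_rate

    def test_null_effect_tracks_indistinguishable_at_enhancers(self):
        from scipy import stats

        cfg = ScenarioConfig(
            **{**TINY, "peak_enrichment": 1.0, "mark_effect_log2fc": 0.0, "noise_sd": 0.0}
        )
        truth = make_genome(ScenarioConfig(**TINY, seed=21))
        pvals = []
        for s in range(40):
            c = ScenarioConfig(**{**cfg.__dict__, "seed": s})
            tr = simulate_mark_tracks(truth, c)
            iv = truth.enhancers[s % len(truth.enhancers)]
            bs = c.bin_size
            a = tr[("H3K4me1", "A")].data[iv.chrom][iv.start // bs : iv.end // bs]
            b = tr[("H3K4me1", "B")].data[iv.chrom][iv.start // bs : iv.end // bs]
            pvals.append(stats.mannwhitneyu(a, b).pvalue)
        # under the null, p-values should not pile up near zero
        assert np.mean(np.array(pvals) < 0.05) < 0.2


class TestRnaseq:
    def test_planted_sixteen_fold_recovered_on_average(self):
        cfg = ScenarioConfig(
            genome_length=1_000_000, n_genes=50, n_enhancers=20, n_activated=1,
            expr_log2fc=4.0, seed=0,
        )
        estimates = []
        for s in range(50):
            c = ScenarioConfig(**{**cfg.__dict__, "seed": s})
            truth = make_genome(c)
            planted = list(truth.gene_links.values())[0]
            ca, cb = simulate_rnaseq(truth, c)
            fc = expression_fold_change(ca, cb)
            estimates.append(fc[planted])
        assert 12.0 <= np.mean(estimates) <= 20.0

    def test_null_effect_gives_unit_median_fold_change(self):
        cfg = ScenarioConfig(**{**TINY, "expr_log2fc": 0.0, "seed": 31})
        truth = make_genome(cfg)
        ca, cb = simulate_rnaseq(truth, cfg)
        fc = expression_fold_change(ca, cb)
        assert np.median(fc) == pytest.approx(1.0, abs=0.15)

    def test_unequal_library_sizes_unbiased_after_normalization(self):
        cfg = ScenarioConfig(**{**TINY, "expr_log2fc": 0.0})
        truth = make_genome(ScenarioConfig(**{**TINY, "expr_log2fc": 0.0, "seed": 41}))
        medians = []
        for s in range(20):
            c = ScenarioConfig(**{**cfg.__dict__, "seed": s})
            ca, cb = simulate_rnaseq(truth, c, libsize_a=1_000_000, libsize_b=500_000)
            medians.append(np.median(expression_fold_change(ca, cb)))
        assert np.mean(medians) == pytest.approx(1.0, abs=0.1)

    def test_seeded_determinism(self, small_truth, small_config):
        a1, b1 = simulate_rnaseq(small_truth, small_config)
        a2, b2 = simulate_rnaseq(small_truth, small_config)
        pd.testing.assert_series_equal(a1, a2)
        pd.testing.assert_series_equal(b1, b2)


class TestScoreRecovery:
    def test_perfect_prediction_scores_one(self, small_truth):
        predicted = [small_truth.enhancer_by_id(n) for n in small_truth.activated_set]
        precision, recall = score_recovery(predicted, small_truth)
        assert precision == 1.0 and recall == 1.0

    def test_empty_prediction_has_zero_recall(self, small_truth):
        precision, recall = score_recovery([], small_truth)
        assert np.isnan(precision) and recall == 0.0
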