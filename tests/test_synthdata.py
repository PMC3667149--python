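import numpy as np
import pandas as pd
import pytest

from chiptile import profiles, synthdata as sd, tfbs
from chiptile.annotate import GenomeAnnotator


class TestGenome:
    def test_gc_content_at_megabase_scale(self):
        cfg = sd.SyntheticConfig(
            seed=3, n_chromosomes=1, chrom_length=1_000_000, gc_content=0.5
        )
        (seq,) = sd.generate_genome(cfg).values()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.01

    def test_deterministic_under_seed(self):
        cfg = sd.SyntheticConfig(seed=9, n_chromosomes=2, chrom_length=10_000)
        assert sd.generate_genome(cfg) == sd.generate_genome(cfg)

    def test_zero_length_rejected(self):
        cfg = sd.SyntheticConfig()
        cfg.chrom_length = 0
        with pytest.raises(ValueError, match="positive"):
            sd.generate_genome(cfg)
        with pytest.raises(ValueError):
            sd.SyntheticConfig(chrom_length=-5)


class TestGeneModels:
    def test_invariants_hold(self, small_study):
        genes = small_study.genes
        assert len(genes) == 15
        for g in genes:
            assert g.exons, "at least one exon"
            for s, e in g.exons:
                assert g.tx_start <= s < e <= g.tx_end
            assert g.tx_start <= g.cds_start <= g.cds_end <= g.tx_end

    def test_strand_convention(self):
        from chiptile.types import GeneModel

        g = GeneModel(
            gene_id="g", chrom="chr1", tx_start=1000, tx_end=5000, strand="-",
            exons=[(1000, 2000), (4000, 5000)], cds_start=1500, cds_end=4500,
        )
        assert g.tss == 5000 and g.tes == 1000

    def test_both_strands_used(self, default_study):
        strands = {g.strand for g in default_study.genes}
        assert strands == {"+", "-"}
        plus = sum(g.strand == "+" for g in default_study.genes)
        assert 0.3 < plus / len(default_study.genes) < 0.7

    def test_capacity_exhaustion_raises(self):
        cfg = sd.SyntheticConfig(
            n_chromosomes=1, chrom_length=30_000, n_genes=50, seed=0
        )
        genome = sd.generate_genome(cfg)
        with pytest.raises(ValueError, match="capacity"):
            sd.generate_gene_models(genome, cfg)


class TestPlantEnrichment:
    def test_degenerate_mix_all_introns(self, small_config):
        genome = sd.generate_genome(small_config)
        genes = sd.generate_gene_models(genome, small_config)
        cfg = sd.SyntheticConfig(
            **{
                **small_config.__dict__,
                "n_true_peaks": 50,
                "category_proportions": {"intron": 1.0},
            }
        )
        peaks, truth = sd.plant_enrichment(genome, genes, cfg)
        assert truth.peak_categories == ["intron"] * 50

    def test_truth_labels_match_classifier(self, default_study):
        annot = GenomeAnnotator(default_study.genes)
        for iv, cat in zip(
            default_study.truth.planted_peaks, default_study.truth.peak_categories
        ):
            if cat != "unlabeled":
                assert annot.classify(iv.chrom, iv.midpoint) == cat

    def test_planted_peaks_disjoint_and_in_bounds(self, default_study):
        by_chrom = {}
        for iv in default_study.peaks:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start
            assert ivs[-1].end <= len(default_study.genome[chrom])

    def test_infeasible_category_named(self, small_config):
        genome = sd.generate_genome(small_config)
        cfg = sd.SyntheticConfig(
            **{
                **small_config.__dict__,
                "category_proportions": {"intron": 1.0},
            }
        )
        with pytest.raises(ValueError, match="intron"):
            sd.plant_enrichment(genome, [], cfg)

    def test_length_law_mean(self):
        cfg = sd.SyntheticConfig(seed=21)
        rng = np.random.default_rng(0)
        lengths = [sd._draw_peak_length(cfg, rng) for _ in range(2000)]
        assert all(l >= cfg.peak_length_min for l in lengths)
        assert abs(np.mean(lengths) - 692) < 0.10 * 692


class TestProbeTrack:
    def test_enriched_probe_mean(self, default_study):
        cfg = default_study.config
        in_peak = []
        for tr in default_study.tracks:
            mids = tr.positions + cfg.probe_length // 2
            for iv in default_study.peaks:
                if iv.chrom != tr.chrom:
                    continue
                sel = (mids >= iv.start) & (mids < iv.end)
                in_peak.extend(tr.ratios[sel])
        assert len(in_peak) >= 400
        assert abs(np.mean(in_peak) - cfg.enrich_mu) < 0.1

    def test_null_track_mean(self):
        cfg = sd.SyntheticConfig(seed=2, n_chromosomes=1, chrom_length=500_000)
        genome = sd.generate_genome(cfg)
        (tr,) = sd.simulate_probe_track(genome, [], cfg)
        n = len(tr)
        assert abs(tr.ratios.mean()) < 3 * cfg.noise_sigma / np.sqrt(n)

    def test_positions_regular(self, default_study):
        for tr in default_study.tracks:
            diffs = np.diff(tr.positions)
            assert np.all(diffs == tr.spacing)


class TestPlantMotifs:
    def _study_with_rate(self, rate, seed=5):
        cfg = sd.SyntheticConfig(
            seed=seed, n_chromosomes=1, chrom_length=500_000, n_genes=10,
            n_true_peaks=40, category_proportions={"unlabeled": 1.0},
            motif_plant_rate=rate,
        )
        genome = sd.generate_genome(cfg)
        genes = sd.generate_gene_models(genome, cfg)
        peaks, truth = sd.plant_enrichment(genome, genes, cfg)
        genome, truth = sd.plant_motifs(genome, peaks, sd.DEFAULT_MOTIF, cfg, truth)
        return genome, peaks, truth

    def test_rate_one_every_peak_matches(self):
        genome, peaks, truth = self._study_with_rate(1.0)
        assert all(truth.motif_flags)
        pat = tfbs.ConsensusPattern(sd.DEFAULT_MOTIF)
        counts, frac = tfbs.scan_consensus(sd.peak_sequences(genome, peaks), pat)
        assert frac == 1.0

    def test_rate_zero_all_false(self):
        _, _, truth = self._study_with_rate(0.0)
        assert not any(truth.motif_flags)

    def test_placement_recorded_correctly(self):
        genome, peaks, truth = self._study_with_rate(1.0)
        from chiptile.types import revcomp

        pat_sets = tfbs.parse_pattern(sd.DEFAULT_MOTIF)
        for iv, placement in zip(peaks, truth.motif_placements):
            off, strand = placement
            word = genome[iv.chrom][iv.start + off : iv.start + off + len(pat_sets)]
            if strand == "-":
                word = revcomp(word)
            assert all(b in s for b, s in zip(word, pat_sets))

    def test_width_exceeding_peak_warns_and_flags_false(self):
        cfg = sd.SyntheticConfig(seed=1, n_chromosomes=1, chrom_length=50_000,
                                 n_genes=0, n_true_peaks=0)
        genome = sd.generate_genome(cfg)
        from chiptile.types import GenomicInterval

        peaks = [GenomicInterval("chr1", 100, 105)]
        with pytest.warns(UserWarning, match="width"):
            _, truth = sd.plant_motifs(genome, peaks, sd.DEFAULT_MOTIF, cfg, rate=1.0)
        assert truth.motif_flags == [False]


class TestExpression:
    def test_exact_de_counts(self, default_study):
        expr = default_study.expression
        assert (expr["fold_change"] > 1.5).sum() == 26
        assert (expr["fold_change"] < -1.5).sum() == 47

    def test_values_distinct(self, default_study):
        assert default_study.expression["expr"].is_unique

    def test_zero_de(self, small_config):
        genes = sd.generate_gene_models(
            sd.generate_genome(small_config), small_config
        )
        cfg = sd.SyntheticConfig(
            **{**small_config.__dict__, "de_up": 0, "de_down": 0}
        )
        expr = sd.simulate_expression_and_de(genes, cfg)
        assert (expr["fold_change"].abs() > 1.5).sum() == 0

    def test_too_many_de_rejected(self, small_config):
        genes = sd.generate_gene_models(
            sd.generate_genome(small_config), small_config
        )
        cfg = sd.SyntheticConfig(
            **{**small_config.__dict__, "de_up": 10, "de_down": 10}
        )
        with pytest.raises(ValueError, match="de_up"):
            sd.simulate_expression_and_de(genes, cfg)


class TestDhs:
    def test_rate_one_full_cooccurrence(self, small_config):
        genome = sd.generate_genome(small_config)
        genes = sd.generate_gene_models(genome, small_config)
        peaks, truth = sd.plant_enrichment(genome, genes, small_config)
        dhs, truth = sd.simulate_dhs(genome, peaks, small_config, truth, rate=1.0)
        frac, _ = profiles.dhs_cooccurrence(peaks, dhs)
        assert frac == 1.0

    def test_rate_zero_far_placement(self, small_config):
        genome = sd.generate_genome(small_config)
        genes = sd.generate_gene_models(genome, small_config)
        peaks, truth = sd.plant_enrichment(genome, genes, small_config)
        dhs, truth = sd.simulate_dhs(genome, peaks, small_config, truth, rate=0.0)
        assert not any(truth.dhs_flags)
        frac, _ = profiles.dhs_cooccurrence(peaks, dhs)
        assert frac == 0.0


class TestTruthLedger:
    def test_every_planted_object_recorded_once(self, default_study):
        truth = default_study.truth
        n = len(default_study.peaks)
        assert len(truth.planted_peaks) == n
        assert len(truth.peak_categories) == n
        assert len(truth.motif_flags) == n
        assert len(truth.dhs_flags) == n
        assert sum(p is not None for p in truth.motif_placements) == sum(
            truth.motif_flags
        )
        assert set(truth.de_labels) == set(default_study.expression["gene_id"])
        frame = truth.to_frame()
        assert len(frame) == n

    def test_planted_rates_within_four_se(self, default_study):
        truth = default_study.truth
        n = len(truth.planted_peaks)
        for rate, hits in [
            (default_study.config.motif_plant_rate, sum(truth.motif_flags)),
            (default_study.config.dhs_overlap_rate, sum(truth.dhs_flags)),
        ]:
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(hits / n - rate) <= 4 * se


def test_study_determinism():
    a = sd.generate_study(sd.SyntheticConfig(seed=17, n_chromosomes=1,
                                             chrom_length=300_000, n_genes=10,
                                             n_true_peaks=15, de_up=2, de_down=2))
    b = sd.generate_study(sd.SyntheticConfig(seed=17, n_chromosomes=1,
                                             chrom_length=300_000, n_genes=10,
                                             n_true_peaks=15, de_up=2, de_down=2))
    assert a.genome == b.genome
    assert a.truth.to_frame().equals(b.truth.to_frame())
    pd.testing.assert_frame_equal(a.expression, b.expression)
    for ta, tb in zip(a.tracks, b.tracks):
        np.testing.assert_array_equal(ta.ratios, tb.ratios)
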