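import numpy as np
import pytest

from chiptile import annotate as ann
from chiptile import synthdata as sd
from chiptile.types import GeneModel, GenomicInterval


def gene(gid, chrom, start, end, strand="+", exons=None, cds=None):
    exons = exons or [(start, end)]
    cds = cds or (exons[0][0], exons[-1][1])
    return GeneModel(
        gene_id=gid, chrom=chrom, tx_start=start, tx_end=end, strand=strand,
        exons=exons, cds_start=cds[0], cds_end=cds[1],
    )


def peak_at(mid, chrom="chr1", half=50):
    return GenomicInterval(chrom, mid - half, mid + half)


@pytest.fixture
def two_gene_fixture():
    """Gene A (20k-40k, +, 3 exons) and gene B (52k-60k, +).

    Positions inside A's tail are also within 10 kb upstream of B's TSS,
    exercising every precedence conflict against the promoter category.
    """
    a = gene(
        "A", "chr1", 20_000, 40_000,
        exons=[(20_000, 22_000), (30_000, 32_000), (38_000, 40_000)],
        cds=(21_000, 39_000),
    )
    b = gene("B", "chr1", 52_000, 60_000)
    return [a, b]


class TestAssignCategory:
    def test_promoter_upstream_plus_strand(self, two_gene_fixture):
        # 3 kb upstream of A's TSS (position 17000)
        assert ann.assign_category(peak_at(17_000), two_gene_fixture) == "promoter"

    def test_intron(self, two_gene_fixture):
        assert ann.assign_category(peak_at(25_000), two_gene_fixture) == "intron"

    def test_precedence_promoter_over_coding(self, two_gene_fixture):
        # midpoint 45,000: inside nothing; 45,500 is 6.5 kb upstream of B and
        # also within 10 kb downstream of A's TES -> promoter wins over tes
        assert ann.assign_category(peak_at(45_500), two_gene_fixture) == "promoter"
        # inside A's CDS exon at 31,000 but also within 10 kb upstream of B?
        # no (21 kb away) - build the direct conflict instead:
        genes = [
            gene("C", "chr1", 20_000, 40_000, cds=(20_500, 39_500)),
            gene("D", "chr1", 45_000, 55_000),
        ]
        # 38,000 is in C's CDS and 7 kb upstream of D's TSS
        assert ann.assign_category(peak_at(38_000), genes) == "promoter"

    def test_precedence_tes_over_intron(self):
        # point inside E's intron, within 10 kb downstream of F's TES (F on -,
        # TES = tx_start, downstream extends to the left... use + gene ending
        # just before E's intron)
        e = gene(
            "E", "chr1", 30_000, 50_000,
            exons=[(30_000, 31_000), (49_000, 50_000)], cds=(30_500, 49_500),
        )
        f = gene("F", "chr1", 10_000, 28_000)
        # 35,000: intron of E, 7 kb downstream of F's TES (28,000)
        assert ann.assign_category(peak_at(35_000), [e, f]) == "tes"

    def test_precedence_coding_over_exon_and_intron(self, two_gene_fixture):
        # 31,000 sits in A's middle exon inside the CDS
        assert ann.assign_category(peak_at(31_000), two_gene_fixture) == "coding"

    def test_exon_outside_cds(self, two_gene_fixture):
        # 20,500 is in A's first exon but upstream of the CDS start
        assert ann.assign_category(peak_at(20_500), two_gene_fixture) == "exon"

    def test_intergenic(self, two_gene_fixture):
        assert (
            ann.assign_category(peak_at(80_000), two_gene_fixture) == "intergenic"
        )

    def test_minus_strand_promoter(self):
        g = gene("M", "chr1", 50_000, 60_000, strand="-")
        # upstream of a minus-strand gene is to the right of tx_end
        assert ann.assign_category(peak_at(63_000), [g]) == "promoter"
        assert ann.assign_category(peak_at(47_000), [g]) == "tes"


class TestSummaries:
    def test_all_intergenic(self, two_gene_fixture):
        peaks = [peak_at(100_000 + i * 1000) for i in range(5)]
        table = ann.summarize_categories(peaks, two_gene_fixture)
        pct = dict(zip(table["category"], table["percent"]))
        assert pct["intergenic"] == 100.0

    def test_percentages_total_100(self, default_study):
        table = ann.summarize_categories(default_study.peaks, default_study.genes)
        assert table["percent"].sum() == pytest.approx(100.0)
        assert table["count"].sum() == len(default_study.peaks)

    def test_empty_peaks_rejected(self, two_gene_fixture):
        with pytest.raises(ValueError):
            ann.summarize_categories([], two_gene_fixture)


class TestPeakGeneLinks:
    def test_peak_at_tss(self):
        g = gene("G", "chr1", 50_000, 60_000)
        links, n_peaks, n_genes = ann.map_peaks_to_genes([peak_at(50_000)], [g])
        assert len(links) == 1 and links[0].offset == 0
        assert (n_peaks, n_genes) == (1, 1)

    def test_window_boundary_closed(self):
        g = gene("G", "chr1", 50_000, 60_000)
        at_edge = ann.map_peaks_to_genes([peak_at(40_000)], [g])[0]
        beyond = ann.map_peaks_to_genes([peak_at(39_999)], [g])[0]
        assert len(at_edge) == 1 and at_edge[0].offset == -10_000
        assert beyond == []

    def test_window_must_be_positive(self):
        g = gene("G", "chr1", 50_000, 60_000)
        with pytest.raises(ValueError):
            ann.map_peaks_to_genes([peak_at(50_000)], [g], window=0)

    def test_matches_all_pairs_oracle(self, default_study):
        peaks = default_study.peaks[:200]
        genes = default_study.genes[:50]
        links, _, _ = ann.map_peaks_to_genes(peaks, genes)
        got = {(l.peak_index, l.gene_id, l.offset) for l in links}
        want = set()
        for pi, p in enumerate(peaks):
            for g in genes:
                if g.chrom != p.chrom:
                    continue
                delta = p.midpoint - g.tss
                off = delta if g.strand == "+" else -delta
                if abs(off) <= 10_000:
                    want.add((pi, g.gene_id, off))
        assert got == want

    def test_reflection_symmetry(self, small_study):
        """Reflecting every coordinate and flipping strands preserves links."""
        L = small_study.config.chrom_length
        genes_r = []
        for g in small_study.genes:
            exons_r = sorted((L - e, L - s) for s, e in g.exons)
            genes_r.append(
                GeneModel(
                    gene_id=g.gene_id, chrom=g.chrom,
                    tx_start=L - g.tx_end, tx_end=L - g.tx_start,
                    strand="-" if g.strand == "+" else "+",
                    exons=exons_r,
                    cds_start=L - g.cds_end, cds_end=L - g.cds_start,
                )
            )
        peaks_r = [
            GenomicInterval(p.chrom, L - p.end, L - p.start)
            for p in small_study.peaks
        ]
        links_f, _, _ = ann.map_peaks_to_genes(small_study.peaks, small_study.genes)
        links_r, _, _ = ann.map_peaks_to_genes(peaks_r, genes_r)
        fwd = sorted((l.peak_index, l.gene_id, l.offset) for l in links_f)
        # reflected peak midpoints shift by 1 bp when the length is even
        rev = sorted(
            (l.peak_index, l.gene_id, l.offset) for l in links_r
        )
        assert len(fwd) == len(rev)
        for (pi_f, gid_f, off_f), (pi_r, gid_r, off_r) in zip(fwd, rev):
            assert (pi_f, gid_f) == (pi_r, gid_r)
            assert abs(off_f - off_r) <= 1


class TestDensity:
    def test_log2_of_count_plus_one(self):
        peaks = [peak_at(500 + i, half=10) for i in range(8)]
        table = ann.density_track(peaks, {"chr1": 2_000_000}, bin=1_000_000)
        assert table.loc[0, "count"] == 8
        assert table.loc[0, "log2_density"] == pytest.approx(np.log2(9), abs=1e-3)
        assert table.loc[1, "count"] == 0 and table.loc[1, "log2_density"] == 0

    def test_counts_conserved(self, default_study):
        chrom_lens = {c: len(s) for c, s in default_study.genome.items()}
        table = ann.density_track(default_study.peaks, chrom_lens)
        assert table["count"].sum() == len(default_study.peaks)

    def test_bin_validated(self):
        with pytest.raises(ValueError):
            ann.density_track([], {"chr1": 100}, bin=0)


class TestDensityCorrelation:
    def test_identical_counts_give_one(self):
        genes, peaks = [], []
        for b in range(5):  # bin b holds b genes and b peaks
            for j in range(b):
                start = b * 100_000 + j * 10_000 + 1000
                genes.append(gene(f"g{b}_{j}", "chr1", start, start + 5000))
                peaks.append(peak_at(start + 2000))
        r = ann.gene_peak_density_correlation(
            peaks, genes, {"chr1": 500_000}, bin=100_000
        )
        assert r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        genes = []
        peaks = [peak_at(1000)]
        r = ann.gene_peak_density_correlation(peaks, genes, {"chr1": 500_000})
        assert r is None

    def test_genic_planting_correlates(self):
        cfg = sd.SyntheticConfig(
            seed=6, n_true_peaks=400,
            category_proportions={"intron": 0.6, "coding": 0.2, "exon": 0.2},
        )
        genome = sd.generate_genome(cfg)
        genes = sd.generate_gene_models(genome, cfg)
        peaks, _ = sd.plant_enrichment(genome, genes, cfg)
        r = ann.gene_peak_density_correlation(
            peaks, genes, {c: len(s) for c, s in genome.items()}, bin=100_000
        )
        assert r > 0.5

    def test_independent_placement_uncorrelated(self):
        rs = []
        for seed in range(10):
            cfg = sd.SyntheticConfig(
                seed=seed, n_chromosomes=1, chrom_length=1_000_000,
                n_genes=20, n_true_peaks=100,
                category_proportions={"unlabeled": 1.0},
            )
            genome = sd.generate_genome(cfg)
            genes = sd.generate_gene_models(genome, cfg)
            peaks, _ = sd.plant_enrichment(genome, genes, cfg)
            rs.append(
                ann.gene_peak_density_correlation(
                    peaks, genes, {c: len(s) for c, s in genome.items()},
                    bin=100_000,
                )
            )
        assert abs(np.mean(rs)) < 0.3
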