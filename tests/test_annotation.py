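"""Promoter/enhancer windows, feature assignment and GTF round-trips."""

import pytest

from cooccupy import (
    FeatureCategory,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    ValidationError,
    assign_feature,
    enhancer_regions,
    feature_distribution,
    nearest_promoter_gene,
    promoter_windows,
    read_gtf,
    write_gtf,
)
from conftest import covered_positions


def make_gene(gene_id="g1", chrom="c1", strand="+", tss=10_000, exon_bounds=None):
    exon_bounds = exon_bounds or [(10_000, 10_500), (11_000, 12_000)]
    if strand == "-":
        # keep the TSS at the rightmost base by default
        exon_bounds = exon_bounds
    exons = [GenomicInterval(chrom, s, e, gene_id, None, strand) for s, e in exon_bounds]
    return GeneModel(gene_id, chrom, strand, tss, exons)


class TestPromoterWindows:
    def test_plus_strand_window(self):
        g = make_gene(strand="+", tss=10_000)
        (w,) = promoter_windows([g])
        assert (w.interval.start, w.interval.end) == (8000, 10_500)
        assert w.anchor == 10_000 and w.strand == "+"

    def test_minus_strand_window_is_mirror(self):
        g = GeneModel("g1", "c1", "-", 10_000,
                      [GenomicInterval("c1", 8000, 10_001, "g1", None, "-")])
        (w,) = promoter_windows([g])
        assert (w.interval.start, w.interval.end) == (9501, 12_001)
        assert w.interval.end - w.interval.start == 2500

    def test_clipping_at_chrom_start(self):
        g = GeneModel("g1", "c1", "+", 300,
                      [GenomicInterval("c1", 300, 900, "g1", None, "+")])
        (w,) = promoter_windows([g], genome={"c1": 100_000})
        assert (w.interval.start, w.interval.end) == (0, 800)

    def test_negative_window_rejected(self):
        with pytest.raises(ValidationError):
            promoter_windows([make_gene()], upstream=-1)

    def test_strand_mirror_property(self):
        """Reflecting coordinates about the TSS maps +- windows onto each other."""
        tss, L = 50_000, 200_000
        plus = promoter_windows([GeneModel("p", "c1", "+", tss,
                                           [GenomicInterval("c1", tss, tss + 100, "p", None, "+")])])[0]
        minus = promoter_windows([GeneModel("m", "c1", "-", tss,
                                            [GenomicInterval("c1", tss - 100, tss + 1, "m", None, "-")])])[0]
        # position x in the + window maps to 2*tss - x in the reflected genome;
        # half-open [s, e) reflects to (2*tss - e, 2*tss - s] = [2*tss-e+1, 2*tss-s+1)
        reflected = (2 * tss - plus.interval.end + 1, 2 * tss - plus.interval.start + 1)
        assert (minus.interval.start, minus.interval.end) == reflected


class TestEnhancerRegions:
    def test_midpoint_window(self):
        s = IntervalSet([GenomicInterval("c1", 1000, 1200)])
        (r,) = enhancer_regions(s)
        assert r.anchor == 1100
        assert (r.interval.start, r.interval.end) == (100, 2100)
        assert r.strand == "."

    def test_single_bp_enhancer(self):
        s = IntervalSet([GenomicInterval("c1", 500, 501)])
        (r,) = enhancer_regions(s, half_width=100)
        assert r.anchor == 500
        assert (r.interval.start, r.interval.end) == (400, 600)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            enhancer_regions(IntervalSet())

    def test_random_anchors_match_midpoint_oracle(self, rng):
        from conftest import random_intervals
        ivs = random_intervals(rng, 100, max_pos=100_000)
        regions = enhancer_regions(IntervalSet(ivs), half_width=50)
        expected = sorted((iv.start + iv.end) // 2 for iv in ivs)
        assert sorted(r.anchor for r in regions) == expected


class TestAssignFeature:
    def test_promoter_beats_intron(self):
        ga = make_gene("ga", tss=10_000)
        gb = make_gene("gb", tss=50_000,
                       exon_bounds=[(50_000, 50_100), (60_000, 60_100)])
        proms = promoter_windows([ga, gb])
        # site inside ga's promoter window and gb's intron
        site = GenomicInterval("c1", 9000, 9100)
        assert assign_feature(site, [ga, gb], proms) == FeatureCategory.PROMOTER

    def test_gene_free_chrom_is_distal(self):
        g = make_gene()
        site = GenomicInterval("cX", 0, 100)
        assert assign_feature(site, [g], promoter_windows([g])) == FeatureCategory.DISTAL

    def test_random_sites_match_per_base_priority_scan(self, rng):
        genes = [
            make_gene("g1", tss=10_000),
            GeneModel("g2", "c1", "-", 29_999,
                      [GenomicInterval("c1", 25_000, 26_000, "g2", None, "-"),
                       GenomicInterval("c1", 28_000, 30_000, "g2", None, "-")],
                      utr5=[GenomicInterval("c1", 29_800, 30_000, "g2", None, "-")],
                      utr3=[GenomicInterval("c1", 25_000, 25_200, "g2", None, "-")]),
            make_gene("g3", chrom="c2", tss=5_000,
                      exon_bounds=[(5_000, 5_400), (6_000, 7_000)]),
        ]
        proms = promoter_windows(genes)
        # independent per-base oracle honoring the priority order
        feature_pos = {
            FeatureCategory.PROMOTER: covered_positions([p.interval for p in proms]),
            FeatureCategory.UTR5: covered_positions([u for g in genes for u in g.utr5]),
            FeatureCategory.UTR3: covered_positions([u for g in genes for u in g.utr3]),
            FeatureCategory.EXON: covered_positions([e for g in genes for e in g.exons]),
            FeatureCategory.INTRON: covered_positions(
                [i for g in genes for i in g.introns()]),
        }
        for _ in range(200):
            chrom = ["c1", "c2"][int(rng.integers(2))]
            start = int(rng.integers(0, 40_000))
            site = GenomicInterval(chrom, start, start + int(rng.integers(1, 500)))
            site_pos = covered_positions([site])
            expected = FeatureCategory.DISTAL
            for cat in (FeatureCategory.PROMOTER, FeatureCategory.UTR5,
                        FeatureCategory.UTR3, FeatureCategory.EXON,
                        FeatureCategory.INTRON):
                if site_pos & feature_pos[cat]:
                    expected = cat
                    break
            assert assign_feature(site, genes, proms) == expected


class TestFeatureDistribution:
    def test_all_promoter(self):
        g = make_gene()
        proms = promoter_windows([g])
        sites = IntervalSet([GenomicInterval("c1", 9000, 9100),
                             GenomicInterval("c1", 9500, 9600)])
        dist = feature_distribution(sites, [g], proms)
        assert dist[FeatureCategory.PROMOTER] == 100.0
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    def test_planted_split_recovered(self):
        """A 30/38/32 promoter/distal/exon planting is recovered exactly."""
        g = GeneModel("g1", "c1", "+", 1_000_000,
                      [GenomicInterval("c1", 1_000_000, 1_200_000, "g1", None, "+")])
        proms = promoter_windows([g])
        sites = []
        for i in range(30):  # promoter
            sites.append(GenomicInterval("c1", 998_000 + i * 10, 998_005 + i * 10))
        for i in range(38):  # distal
            sites.append(GenomicInterval("c1", 10_000 + i * 100, 10_050 + i * 100))
        for i in range(32):  # exon (beyond the promoter window's +500 end)
            sites.append(GenomicInterval("c1", 1_100_000 + i * 100, 1_100_050 + i * 100))
        dist = feature_distribution(IntervalSet(sites), [g], proms)
        assert dist[FeatureCategory.PROMOTER] == pytest.approx(30.0)
        assert dist[FeatureCategory.DISTAL] == pytest.approx(38.0)
        assert dist[FeatureCategory.EXON] == pytest.approx(32.0)

    def test_empty_sites_rejected(self):
        g = make_gene()
        with pytest.raises(ValidationError):
            feature_distribution(IntervalSet(), [g], promoter_windows([g]))

    def test_invariant_under_chrom_relabeling(self):
        import numpy as np
        coords = np.random.default_rng(3).integers(0, 20_000, size=40)

        def build(chrom):
            g = make_gene("g1", chrom=chrom)
            proms = promoter_windows([g])
            sites = IntervalSet([GenomicInterval(chrom, int(s), int(s) + 50)
                                 for s in coords])
            return feature_distribution(sites, [g], proms)

        assert build("c1") == build("chrOther")


class TestGeneLinks:
    def test_nearest_tss_wins_with_gene_id_tiebreak(self):
        g1 = make_gene("aaa", tss=10_000)
        g2 = make_gene("bbb", tss=12_000,
                       exon_bounds=[(12_000, 12_500), (13_000, 13_500)])
        proms = promoter_windows([g1, g2], upstream=3000, downstream=1500)
        site = GenomicInterval("c1", 10_900, 11_100)  # midpoint 11000, equidistant
        assert nearest_promoter_gene(site, proms) == "aaa"
        site2 = GenomicInterval("c1", 11_300, 11_500)  # midpoint 11400: nearer bbb
        assert nearest_promoter_gene(site2, proms) == "bbb"


class TestGtfRoundtrip:
    def test_write_then_read_preserves_models(self, tmp_path):
        genes = [
            make_gene("g1", strand="+", tss=10_000),
            GeneModel("g2", "c2", "-", 19_999,
                      [GenomicInterval("c2", 15_000, 16_000, "g2", None, "-"),
                       GenomicInterval("c2", 18_000, 20_000, "g2", None, "-")],
                      utr5=[GenomicInterval("c2", 19_800, 20_000, "g2", None, "-")]),
        ]
        p = tmp_path / "genes.gtf"
        write_gtf(genes, p)
        back = read_gtf(p)
        assert [g.gene_id for g in back] == ["g1", "g2"]
        for orig, rt in zip(genes, back):
            assert rt.strand == orig.strand
            assert rt.tss == orig.tss
            assert [(e.start, e.end) for e in rt.exons] == \
                [(e.start, e.end) for e in orig.exons]
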