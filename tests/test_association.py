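import numpy as np
import pytest

from zicreg.core import GeneAnnotation, GenomicInterval, PeakCall
from zicreg.association import (
    associate_peaks_great,
    associate_peaks_radius,
    association_summary,
    build_regulatory_domains,
    nearest_gene_distances,
)

from oracles import brute_domains, brute_great_association, brute_radius_association


def make_peak(summit, pid="p", chrom="chr1", half=300, stage="s"):
    return PeakCall(
        pid, GenomicInterval(chrom, summit - half, summit + half), summit, 1.0, stage
    )


def gene(gid, tss, strand="+", length=4000, chrom="chr1"):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + length, "+")
    else:
        iv = GenomicInterval(chrom, tss - length + 1, tss + 1, "-")
    return GeneAnnotation(gid, iv)


def random_instance(rng, chrom_len=400_000, n_genes=8, n_peaks=25):
    genes = []
    for i in range(n_genes):
        tss = int(rng.integers(10_000, chrom_len - 10_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(gene(f"g{i}", tss, strand, length=int(rng.integers(1000, 8000))))
    peaks = [
        make_peak(int(rng.integers(1000, chrom_len - 1000)), pid=f"p{j}")
        for j in range(n_peaks)
    ]
    return genes, peaks, {"chr1": chrom_len}


class TestRegulatoryDomains:
    def test_isolated_gene_domain_arithmetic(self):
        """An isolated + gene gets basal [TSS-5k, TSS+1k) extended 100 kb."""
        g = gene("g", 1_000_000)
        (d,) = build_regulatory_domains([g], {"chr1": 10_000_000})
        assert d.basal == (995_000, 1_001_000)
        assert d.extended == (895_000, 1_101_000)

    def test_extension_stops_at_neighbor_basal_boundary(self):
        g1 = gene("g1", 100_000)
        g2 = gene("g2", 110_000)
        domains = {d.gene_id: d for d in build_regulatory_domains([g1, g2], {"chr1": 10_000_000})}
        # downstream gene's upstream extension stops at g1's basal end
        assert domains["g2"].extended[0] == domains["g1"].basal[1] == 101_000
        # and g1's downstream extension stops at g2's basal start
        assert domains["g1"].extended[1] == domains["g2"].basal[0] == 105_000

    def test_clamped_at_chromosome_start(self):
        g = gene("g", 2_000)
        (d,) = build_regulatory_domains([g], {"chr1": 10_000_000})
        assert d.basal[0] == 0 and d.extended[0] == 0

    def test_matches_brute_force_construction(self, rng):
        for _ in range(200):
            genes, _, sizes = random_instance(rng)
            fast = {
                d.gene_id: (d.basal, d.extended)
                for d in build_regulatory_domains(genes, sizes)
            }
            assert fast == brute_domains(genes, sizes)

    def test_domains_never_cross_other_basal_regions(self, rng):
        for _ in range(50):
            genes, _, sizes = random_instance(rng, n_genes=12)
            domains = build_regulatory_domains(genes, sizes)
            basals = {d.gene_id: d.basal for d in domains}
            for d in domains:
                for gid, (bs, be) in basals.items():
                    if gid == d.gene_id:
                        continue
                    # extension beyond the own basal may not pass a
                    # neighbor basal boundary that lies wholly outside it
                    if be <= d.basal[0]:
                        assert d.extended[0] >= be
                    if bs >= d.basal[1]:
                        assert d.extended[1] <= bs


class TestGreatAssociation:
    def test_none_one_two_distribution(self):
        g1 = gene("g1", 100_000)
        g2 = gene("g2", 110_000)
        genes = [g1, g2]
        domains = build_regulatory_domains(genes, {"chr1": 10_000_000})
        peaks = [
            make_peak(100_500, "in_both"),   # in g1 basal and g2 extended? -> check
            make_peak(103_000, "between"),   # between basals: g1 ext + g2 ext
            make_peak(500_000, "far"),       # in no domain
        ]
        assignments = {a.peak_id: a for a in associate_peaks_great(peaks, domains, genes)}
        assert len(assignments["far"].genes) == 0
        assert len(assignments["between"].genes) == 2
        summary = association_summary(list(assignments.values()))
        assert summary["none"] + summary["one"] + summary["two_plus"] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        """Interval-tree GREAT association equals the brute-force loop on
        500 random instances."""
        for _ in range(500):
            genes, peaks, sizes = random_instance(
                rng, n_genes=int(rng.integers(2, 9)), n_peaks=int(rng.integers(1, 15))
            )
            domains = build_regulatory_domains(genes, sizes)
            fast = {
                a.peak_id: sorted(g for g, _ in a.genes)
                for a in associate_peaks_great(peaks, domains, genes)
            }
            assert fast == brute_great_association(peaks, domains)

    def test_gene_count_monotone_in_extension(self, rng):
        for _ in range(30):
            genes, peaks, sizes = random_instance(rng)
            d0 = build_regulatory_domains(genes, sizes, extension=0)
            d1 = build_regulatory_domains(genes, sizes, extension=100_000)
            a0 = associate_peaks_great(peaks, d0, genes)
            a1 = associate_peaks_great(peaks, d1, genes)
            for x, y in zip(a0, a1):
                assert len(y.genes) >= len(x.genes)


class TestRadiusAssociation:
    def test_peak_94_7_kb_downstream_is_associated_at_100kb(self):
        g = gene("oep", 1_000_000)
        mapping = associate_peaks_radius([make_peak(1_094_700)], [g], radius=100_000)
        assert [pid for pid, _ in mapping["oep"]] == ["p"]

    def test_peak_147_9_kb_upstream_needs_500kb_radius(self):
        g = gene("axin2", 1_000_000)
        peak = make_peak(1_000_000 - 147_900)
        assert not associate_peaks_radius([peak], [g], radius=100_000)["axin2"]
        assert associate_peaks_radius([peak], [g], radius=500_000)["axin2"]

    def test_boundary_is_inclusive(self):
        g = gene("g", 1_000_000)
        peak = make_peak(1_100_000)  # exactly at the radius
        assert associate_peaks_radius([peak], [g], radius=100_000)["g"]

    def test_edge_rule_counts_interval_overlap(self):
        g = gene("g", 1_000_000)
        # summit at 100.2 kb but the peak edge reaches within 100 kb
        peak = make_peak(1_100_200, half=300)
        assert not associate_peaks_radius([peak], [g], radius=100_000)["g"]
        assert associate_peaks_radius([peak], [g], radius=100_000, from_summit=False)["g"]

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(500):
            genes, peaks, sizes = random_instance(
                rng, n_genes=int(rng.integers(1, 8)), n_peaks=int(rng.integers(1, 12))
            )
            radius = int(rng.integers(1_000, 200_000))
            fast = {
                gid: sorted(pid for pid, _ in items)
                for gid, items in associate_peaks_radius(peaks, genes, radius=radius).items()
            }
            assert fast == brute_radius_association(peaks, genes, radius)

    def test_nearest_gene_distances_signed(self):
        gp = gene("gp", 1_000_000, "+")
        gm = gene("gm", 2_000_000, "-")
        peaks = [make_peak(990_000, "a"), make_peak(2_010_000, "b")]
        mapping = associate_peaks_radius(peaks, [gp, gm], radius=100_000)
        assert mapping["gp"] == [("a", -10_000)]
        assert mapping["gm"] == [("b", -10_000)]
        domains = build_regulatory_domains([gp, gm], {"chr1": 10_000_000})
        assignments = associate_peaks_great(peaks, domains, [gp, gm])
        assert nearest_gene_distances(assignments) == [-10_000, -10_000]
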