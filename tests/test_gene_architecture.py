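import numpy as np
import pytest

from hairpinrule.gene_architecture import (
    architecture_stats,
    build_coding_mask,
    classify_sites,
    metagene_profile,
)
from hairpinrule.genome_io import GeneModel, GenomeRecord, revcomp
from hairpinrule.hairpin_scan import PalindromeSite


def site_at(center, L=None):
    left = center - 11
    if L is not None:
        left %= L
    return PalindromeSite(f"s{center}", left, 10, 3, 0, center, (left, left + 23))


class TestBuildCodingMask:
    def test_single_gene_fraction(self):
        genome = GenomeRecord("g", "A" * 100)
        mask = build_coding_mask(genome, [GeneModel("a", 10, 60, "+")])
        assert mask.coding_fraction == pytest.approx(0.5)

    def test_overlapping_genes_union(self):
        genome = GenomeRecord("g", "A" * 100)
        genes = [GeneModel("a", 10, 60, "+"), GeneModel("b", 50, 80, "-")]
        mask = build_coding_mask(genome, genes)
        assert mask.coding_fraction == pytest.approx(0.7)

    def test_origin_spanning_gene(self):
        genome = GenomeRecord("g", "A" * 100, circular=True)
        mask = build_coding_mask(genome, [GeneModel("a", 90, 10, "+")])
        assert mask.coding_fraction == pytest.approx(0.2)
        assert mask.mask[95] and mask.mask[5] and not mask.mask[50]

    def test_wrap_on_linear_rejected(self):
        genome = GenomeRecord("g", "A" * 100, circular=False)
        with pytest.raises(ValueError):
            build_coding_mask(genome, [GeneModel("a", 90, 10, "+")])


class TestArchitectureStats:
    def test_linear_single_run(self):
        genome = GenomeRecord("g", "A" * 100, circular=False)
        genes = [GeneModel("a", 0, 30, "+"), GeneModel("b", 60, 100, "-")]
        stats = architecture_stats(genome, genes)
        assert stats.mean_intergenic_len == pytest.approx(30.0)

    def test_circular_run_through_origin_merges(self):
        genome = GenomeRecord("g", "A" * 100, circular=True)
        genes = [GeneModel("a", 10, 40, "+"), GeneModel("b", 60, 90, "-")]
        # circular runs: [40,60) and [90,100)+[0,10) -> 20 and 20
        stats = architecture_stats(genome, genes)
        assert stats.mean_intergenic_len == pytest.approx(20.0)

    def test_mean_protein_len_subtracts_stop(self):
        genome = GenomeRecord("g", "A" * 100)
        stats = architecture_stats(genome, [GeneModel("a", 0, 90, "+")])
        assert stats.mean_protein_len == pytest.approx(29.0)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            architecture_stats(GenomeRecord("g", "A" * 10), [])


class TestClassifySites:
    def test_small_example(self):
        genome = GenomeRecord("g", "A" * 30)
        mask = build_coding_mask(genome, [GeneModel("a", 10, 20, "+")])
        sites = [site_at(5, 30), site_at(15, 30), site_at(25, 30)]
        assert classify_sites(sites, mask) == (1, 2)

    def test_empty(self):
        genome = GenomeRecord("g", "A" * 30)
        mask = build_coding_mask(genome, [GeneModel("a", 10, 20, "+")])
        assert classify_sites([], mask) == (0, 0)

    def test_matches_positionwise_recount(self, rng):
        L = 2000
        genome = GenomeRecord("g", "A" * L, circular=True)
        genes = [
            GeneModel(f"g{i}", int(s), int(s) + 50, "+")
            for i, s in enumerate(rng.integers(0, L - 50, 15))
        ]
        mask = build_coding_mask(genome, genes)
        sites = [site_at(int(c), L) for c in rng.integers(0, L, 200)]
        n_c, n_i = classify_sites(sites, mask)
        recount = sum(1 for s in sites if bool(mask.mask[s.center]))
        assert (n_c, n_i) == (recount, len(sites) - recount)
        assert n_c + n_i == len(sites)


def mirror_instance(genome, genes, sites):
    """Reverse-complement the genome, flip strands and map coordinates."""
    L = genome.length
    m_genome = GenomeRecord(genome.id, revcomp(genome.seq), genome.circular)
    m_genes = [
        GeneModel(
            g.gene_id,
            (L - g.end) % L,
            (L - g.start - 1) % L + 1,
            "+" if g.strand == "-" else "-",
        )
        for g in genes
    ]
    m_sites = [
        PalindromeSite(
            s.site_id, (L - 1 - s.center) % L - s.stem_len - (s.loop_len - 1) // 2,
            s.stem_len, s.loop_len, s.mismatches, (L - 1 - s.center) % L,
            s.span,
        )
        for s in sites
    ]
    return m_genome, m_genes, m_sites


class TestMetageneProfile:
    def make_instance(self):
        L = 5000
        genome = GenomeRecord("g", "A" * L, circular=True)
        genes = [GeneModel("g1", 11, 101, "+"), GeneModel("g2", 2000, 2300, "+")]
        sites = [site_at(120, L)]
        return genome, genes, sites

    def test_downstream_site_counts_at_plus_offset(self):
        genome, genes, sites = self.make_instance()
        prof = metagene_profile(sites, genes, genome, anchor="stop", window=300)
        # g1 stops at 100; site center 120 is +20 downstream; the
        # downstream gene g2 is on the same strand
        assert prof.counts["same_orientation"][300 + 20] == 1
        assert prof.counts["opposite_orientation"].sum() == 0

    def test_empty_sites_zero_profile(self):
        genome, genes, _ = self.make_instance()
        prof = metagene_profile([], genes, genome, anchor="start", window=300)
        assert prof.total == 0

    def test_minus_strand_gene_flips_offsets(self):
        L = 5000
        genome = GenomeRecord("g", "A" * L, circular=True)
        genes = [GeneModel("g1", 900, 1200, "-"), GeneModel("g2", 3000, 3300, "-")]
        # '-' gene g1 stops at position 900; downstream in reading
        # direction is decreasing coordinates
        sites = [site_at(870, L)]
        prof = metagene_profile(sites, genes, genome, anchor="stop", window=300)
        assert prof.counts["same_orientation"][300 + 30] == 1

    def test_strand_symmetry(self, rng):
        L = 4000
        genome = GenomeRecord(
            "g", "".join(rng.choice(list("ACGT"), size=L)), circular=True
        )
        starts = np.arange(100, 3800, 380)
        genes = [
            GeneModel(f"g{i}", int(s), int(s + 200), str(rng.choice(["+", "-"])))
            for i, s in enumerate(starts)
        ]
        sites = [site_at(int(c), L) for c in rng.integers(0, L, 60)]
        m_genome, m_genes, m_sites = mirror_instance(genome, genes, sites)
        for anchor in ("start", "stop"):
            p = metagene_profile(sites, genes, genome, anchor=anchor, window=200)
            m = metagene_profile(m_sites, m_genes, m_genome, anchor=anchor, window=200)
            for stratum in p.counts:
                assert np.array_equal(p.counts[stratum], m.counts[stratum]), (
                    anchor,
                    stratum,
                )

    def test_total_matches_naive_double_loop(self, rng):
        L = 4000
        genome = GenomeRecord("g", "A" * L, circular=True)
        starts = np.arange(50, 3900, 300)
        genes = [
            GeneModel(f"g{i}", int(s), int(s + 180), str(rng.choice(["+", "-"])))
            for i, s in enumerate(starts)
        ]
        sites = [site_at(int(c), L) for c in rng.integers(0, L, 80)]
        window = 150
        prof = metagene_profile(sites, genes, genome, anchor="start", window=window)
        naive = 0
        for g in genes:
            apos = g.start if g.strand == "+" else g.end - 1
            for s in sites:
                delta = (s.center - apos) % L
                if delta > L // 2:
                    delta -= L
                if g.strand == "-":
                    delta = -delta
                if -window <= delta <= window:
                    naive += 1
        assert prof.total == naive

    def test_requires_genes(self):
        genome = GenomeRecord("g", "A" * 100)
        with pytest.raises(ValueError):
            metagene_profile([], [], genome)
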