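"""Hotspot discovery, guide matching, the enumeration oracle, amplicon rates."""

import numpy as np
import pytest

import pemseq as pq
from pemseq._seq import revcomp
from pemseq.guides import SITE_LEN, cut_site_for
from pemseq.offtargets import (
    amplicon_indel_rate,
    confirm_cut_site,
    discover_offtargets,
    enumerate_offtargets_bruteforce,
    find_hotspots,
    match_guide,
)
from pemseq.simulate import simulate_amplicon_reads


class TestFindHotspots:
    def test_cluster_above_support_becomes_candidate(self):
        junctions = [("chr2", 5000 + i) for i in (0, 10, 20, 40, 80)]
        hs = find_hotspots(junctions, bin_size=100, min_support=3)
        assert len(hs) == 1 and hs[0][3] == 5

    def test_scattered_junctions_yield_nothing(self):
        junctions = [("chr2", 1000 * i) for i in range(1, 11)]
        assert find_hotspots(junctions, bin_size=100, min_support=3) == []

    def test_straddling_clusters_merged_by_smoothing(self):
        a = [("chr2", 5000 + i) for i in (0, 5, 10)]
        b = [("chr2", 5120 + i) for i in (0, 5, 10)]
        hs = find_hotspots(a + b, bin_size=100, min_support=3)
        assert len(hs) == 1
        chrom, lo, hi, support = hs[0]
        assert support == 6 and lo <= 5000 and hi > 5130


class TestMatchGuide:
    def test_exact_site_zero_mismatches(self, genome):
        guide = genome.guide
        assert guide.site_seq == "GACCCTGGTGGACATCTTCCAGG"
        window = "ACGT" * 10 + guide.site_seq + "TGCA" * 10
        off, strand, mm = match_guide(window, guide)
        assert (off, strand, mm) == (40, "+", 0)

    def test_planted_sites_found_at_recorded_distance(self, genome):
        for chrom, start, strand, n_mm in genome.planted_offtargets:
            window = genome.chromosomes[chrom][start - 30 : start + SITE_LEN + 30]
            off, s, mm = match_guide(window, genome.guide)
            assert (off, s, mm) == (30, strand, n_mm)

    def test_nine_mismatch_lookalike_rejected(self, genome):
        site = list(genome.guide.site_seq)
        for i in range(0, 18, 2):  # 9 substitutions
            site[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[i]]
        window = "ACGT" * 8 + "".join(site) + "ACGT" * 8
        assert match_guide(window, genome.guide) is None

    def test_short_window_rejected(self, genome):
        with pytest.raises(ValueError):
            match_guide("ACGTACGT", genome.guide)


class TestEnumerationOracle:
    def test_toy_genome_yields_exactly_target_plus_plants(self, genome):
        sites = enumerate_offtargets_bruteforce(genome.chromosomes, genome.guide, 8)
        assert sites[0] == ("chr1", 30000, "+", 0)
        assert set(sites[1:]) == set(genome.planted_offtargets)

    def test_zero_mismatch_budget_finds_only_target(self, genome):
        sites = enumerate_offtargets_bruteforce(genome.chromosomes, genome.guide, 0)
        assert sites == [("chr1", 30000, "+", 0)]

    def test_reverse_complement_symmetry(self, genome):
        """Reverse-complementing every chromosome mirrors each site."""
        fwd = enumerate_offtargets_bruteforce(genome.chromosomes, genome.guide, 8)
        rc_chroms = {c: revcomp(s) for c, s in genome.chromosomes.items()}
        rev = enumerate_offtargets_bruteforce(rc_chroms, genome.guide, 8)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (c, len(genome.chromosomes[c]) - p - SITE_LEN, flip[s], m) for c, p, s, m in fwd
        }
        assert set(rev) == mirrored


class TestConfirmCutSite:
    def test_centered_cluster_passes(self):
        assert confirm_cut_site(5017, [5016, 5017, 5017, 5018])

    def test_shifted_cluster_fails(self):
        assert not confirm_cut_site(5017, [5067, 5067, 5068])

    def test_widening_tolerance_is_monotone(self):
        for positions in ([5016, 5019, 5020], [5010, 5011], [5017] * 3):
            if confirm_cut_site(5017, positions, tol=3):
                assert confirm_cut_site(5017, positions, tol=10)

    def test_microhomology_span_resolves_downstream_bias(self):
        # every junction sits 6 bp downstream but may shift back through MH
        assert confirm_cut_site(5017, [5023] * 5, mh_spans=[-8] * 5)
        assert not confirm_cut_site(5017, [5023] * 5, mh_spans=[0] * 5)


class TestDiscovery:
    def test_planted_sites_discovered_and_subset_of_oracle(self, genome, vector):
        """Hotspot + similarity + cut-site filter recovers exactly the
        planted sites, each present in the brute-force enumeration."""
        from pemseq.simulate import SimConfig, simulate_library

        cfg = SimConfig(
            class_fractions={"uncut": 0.5, "indel": 0.2, "offtarget_translocation": 0.15,
                             "general_translocation": 0.05, "aav_fusion": 0.1},
            n_molecules=1_200, seed=5, error_rate=0.0,
        )
        reads, _ = simulate_library(genome, vector, cfg)
        res = pq.run_pipeline(reads, genome, vector, discover=True)
        found = {(s.chrom, s.start, s.strand, s.n_mismatches) for s in res.offtarget_sites}
        assert found == set(genome.planted_offtargets)
        oracle = set(enumerate_offtargets_bruteforce(genome.chromosomes, genome.guide, 8))
        assert found <= oracle
        for s in res.offtarget_sites:
            assert s.support >= 3
            assert s.cut_site == cut_site_for(s.start, s.strand)


@pytest.fixture(scope="module")
def amplicon(genome):
    return genome.chromosomes["chr1"][29_800:30_200]


class TestAmpliconIndelRate:
    def test_counting_definition(self, amplicon):
        intact = [("r%d" % i, amplicon) for i in range(93)]
        edited = [("d%d" % i, amplicon[:217] + amplicon[220:]) for i in range(7)]
        res = amplicon_indel_rate(intact + edited, amplicon, cut=217)
        assert res.indel_pct == 7.0 and not res.low_coverage

    def test_all_exact_reads_zero_rate(self, amplicon):
        res = amplicon_indel_rate([("r", amplicon)] * 120, amplicon, cut=217)
        assert res.indel_pct == 0.0

    def test_low_coverage_flagged(self, amplicon):
        res = amplicon_indel_rate([("r", amplicon)] * 10, amplicon, cut=217)
        assert res.low_coverage

    def test_planted_fraction_recovered(self, amplicon):
        """Simulation recovery: planted 7.4% indel pool, estimate within
        3 binomial SE at n=5,000."""
        reads = simulate_amplicon_reads(amplicon, 217, 0.074, 5_000, seed=2)
        res = amplicon_indel_rate(reads, amplicon, 217)
        se = 100 * np.sqrt(0.074 * (1 - 0.074) / 5_000)
        assert abs(res.indel_pct - 7.4) <= 3 * se

    def test_indel_far_from_cut_not_counted(self, amplicon):
        reads = [("r", amplicon[:50] + amplicon[53:])] * 120
        res = amplicon_indel_rate(reads, amplicon, cut=217)
        assert res.indel_pct == 0.0
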