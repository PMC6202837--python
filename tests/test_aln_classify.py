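"""Site classification, strand guard, and per-alignment feature extraction."""

import numpy as np
import pytest
from scipy.stats import ranksums

from conftest import make_aln
from spuriometer.aln_classify import (
    AlnClass,
    classified_to_frame,
    classify_alignment,
    classify_at_site,
    corrected_mismatches,
    count_indels,
    raw_mismatches,
    strand_guard,
    substitution_spectrum,
    terminal_ct_flags,
)
from spuriometer.io import MutatedSite, MutatedSiteTable, ReferenceGenome
from spuriometer.simdata import SimConfig, simulate_contaminant, simulate_endogenous


class TestClassifyAtSite:
    def test_reference_base_is_true(self):
        aln = make_aln("AAAAA" + "A" * 15, start=95)
        site = MutatedSite("chr1", 99, "A", "G")
        assert classify_at_site(aln, site) == (AlnClass.TRUE_HOMININ, "reference")

    def test_mutated_base_is_spurious(self):
        aln = make_aln("AAAA" + "G" + "A" * 15, start=95)
        site = MutatedSite("chr1", 99, "A", "G")
        assert classify_at_site(aln, site) == (AlnClass.SPURIOUS, "mutated")

    def test_third_allele_is_spurious(self):
        aln = make_aln("AAAA" + "T" + "A" * 15, start=95)
        site = MutatedSite("chr1", 99, "A", "G")
        assert classify_at_site(aln, site) == (AlnClass.SPURIOUS, "other")

    def test_forward_guard_on_mutated_c_regardless_of_read_base(self):
        site = MutatedSite("chr1", 99, "A", "C")
        for base in "ACGT":
            aln = make_aln("AAAA" + base + "A" * 15, start=95)
            assert classify_at_site(aln, site)[0] is AlnClass.EXCLUDED_STRAND

    def test_reverse_guard_on_original_g(self):
        site = MutatedSite("chr1", 99, "G", "A")
        aln = make_aln("AAAA" + "G" + "A" * 15, start=95, reverse=True)
        assert classify_at_site(aln, site)[0] is AlnClass.EXCLUDED_STRAND

    def test_forward_c_site_not_guarded_on_reverse_strand(self):
        site = MutatedSite("chr1", 99, "C", "A")
        aln = make_aln("AAAA" + "C" + "A" * 15, start=95, reverse=True)
        assert classify_at_site(aln, site) == (AlnClass.TRUE_HOMININ, "reference")

    def test_deletion_spanning_site_is_no_site(self):
        aln = make_aln("A" * 20, start=95, cigar="4M2D16M")
        site = MutatedSite("chr1", 100, "A", "G")
        assert classify_at_site(aln, site)[0] is AlnClass.NO_SITE

    def test_read_n_is_no_site(self):
        aln = make_aln("AAAA" + "N" + "A" * 15, start=95)
        site = MutatedSite("chr1", 99, "A", "G")
        assert classify_at_site(aln, site)[0] is AlnClass.NO_SITE

    def test_guard_fires_on_exactly_the_enumerated_combinations(self):
        # forward: original or mutated C; reverse: original or mutated G
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                site = MutatedSite("chr1", 0, ref, alt)
                assert strand_guard(site, False) == ("C" in (ref, alt))
                assert strand_guard(site, True) == ("G" in (ref, alt))


class TestMismatchFeatures:
    def test_true_alignment_subtracts_one(self):
        # reference AAAA...; read has 2 raw mismatches vs the mutated ref:
        # the site (read shows original A over mutated G) plus one real one
        mutated = ReferenceGenome({"chr1": "A" * 99 + "G" + "A" * 100})
        aln = make_aln("AAAA" + "A" + "T" + "A" * 14, start=95)
        site = MutatedSite("chr1", 99, "A", "G")
        assert raw_mismatches(aln, mutated) == 2
        count, prop = corrected_mismatches(aln, [site], mutated)
        assert count == 1
        assert prop == pytest.approx(1 / 20)

    def test_mutated_carrier_gets_no_subtraction(self):
        mutated = ReferenceGenome({"chr1": "A" * 99 + "G" + "A" * 100})
        aln = make_aln("AAAA" + "G" + "TT" + "A" * 13, start=95)
        site = MutatedSite("chr1", 99, "A", "G")
        assert corrected_mismatches(aln, [site], mutated)[0] == 2

    def test_floor_at_zero(self):
        mutated = ReferenceGenome({"chr1": "A" * 200})
        aln = make_aln("A" * 20, start=95)
        site = MutatedSite("chr1", 99, "C", "T")  # read base A != alt T: subtract
        assert corrected_mismatches(aln, [site], mutated) == (0, 0.0)

    def test_md_tag_used_when_present(self):
        aln = make_aln("A" * 20, start=95, md="4A10C4")
        assert raw_mismatches(aln) == 2

    @pytest.mark.parametrize(
        "cigar,expected", [("25M", 0), ("10M1I9M", 1), ("5M2D10M1I5M", 2)]
    )
    def test_count_indels_counts_events_not_bases(self, cigar, expected):
        from spuriometer.io import parse_cigar

        ops = parse_cigar(cigar)
        qlen = sum(n for op, n in ops if op in "MIS")
        aln = make_aln("A" * qlen, cigar=cigar)
        assert count_indels(aln) == expected


class TestTerminalCT:
    def test_forward_first_base_ct(self):
        original = ReferenceGenome({"chr1": "C" + "A" * 100})
        aln = make_aln("T" + "A" * 19, start=0)
        assert terminal_ct_flags(aln, original) == (True, False)

    def test_reverse_strand_g_to_a_is_five_prime_ct(self):
        # reference-forward last aligned base shows G->A; in read orientation
        # (reverse strand) that is the first base showing C->T
        original = ReferenceGenome({"chr1": "A" * 19 + "G" + "A" * 100})
        aln = make_aln("A" * 19 + "A", start=0, reverse=True)
        assert terminal_ct_flags(aln, original) == (True, False)

    def test_identical_read_has_no_flags(self):
        original = ReferenceGenome({"chr1": "C" + "A" * 50 + "C" + "A" * 100})
        aln = make_aln("C" + "A" * 19, start=0)
        assert terminal_ct_flags(aln, original) == (False, False)

    def test_terminal_base_in_insertion_never_flags(self):
        original = ReferenceGenome({"chr1": "C" * 200})
        aln = make_aln("T" + "C" * 19, start=10, cigar="1I19M")
        assert terminal_ct_flags(aln, original) == (False, False)

    def test_three_prime_flag(self):
        original = ReferenceGenome({"chr1": "A" * 19 + "C" + "A" * 100})
        aln = make_aln("A" * 19 + "T", start=0)
        assert terminal_ct_flags(aln, original) == (False, True)


class TestSubstitutionSpectrum:
    def test_mismatch_free_alignments_zero_everywhere(self):
        original = ReferenceGenome({"chr1": "ACGT" * 50})
        alns = [make_aln("ACGT" * 5, start=4 * i) for i in range(5)]
        spec = substitution_spectrum(alns, original)
        assert np.nansum(spec.to_numpy()) == 0

    def test_constructed_ct_frequency(self):
        original = ReferenceGenome({"chr1": "C" + "A" * 100})
        alns = [make_aln(("T" if i < 4 else "C") + "A" * 19, start=0, qname=f"r{i}")
                for i in range(10)]
        spec = substitution_spectrum(alns, original)
        assert spec.loc[0, "C>T"] == pytest.approx(0.4)

    def test_simulated_damage_elevated_at_termini(self):
        from spuriometer.simdata import simulate_reference

        g = simulate_reference(20_000, seed=41)
        cfg = SimConfig(divergence=0.0, deam_p0=0.3, deam_decay=0.5, seed=41)
        reads = simulate_endogenous(g, cfg, 3000)
        alns = []
        for r in reads:
            a = r.to_alignment()
            alns.append(a)
        spec = substitution_spectrum(alns, g)
        ct = spec["C>T"]
        # terminal ~p0, decaying inward; interior ~0
        assert ct.iloc[0] == pytest.approx(0.3, abs=0.05)
        assert ct.iloc[1] == pytest.approx(0.15, abs=0.05)
        assert ct.iloc[8:12].mean() < 0.02


class TestClassifyAlignment:
    @pytest.fixture
    def setup(self):
        original = ReferenceGenome({"chr1": "A" * 300})
        mutated = ReferenceGenome({"chr1": "A" * 99 + "G" + "A" * 99 + "T" + "A" * 100})
        table = MutatedSiteTable(
            [MutatedSite("chr1", 99, "A", "G"), MutatedSite("chr1", 199, "A", "T")]
        )
        return original, mutated, table

    def test_partition_true_or_spurious(self, setup):
        original, mutated, table = setup
        for base, expect in [("A", AlnClass.TRUE_HOMININ), ("G", AlnClass.SPURIOUS),
                             ("T", AlnClass.SPURIOUS), ("C", AlnClass.SPURIOUS)]:
            aln = make_aln("AAAA" + base + "A" * 15, start=95)
            rec = classify_alignment(aln, table, mutated, original)
            assert rec.cls is expect

    def test_no_overlap_is_no_site(self, setup):
        original, mutated, table = setup
        rec = classify_alignment(make_aln("A" * 20, start=120), table, mutated, original)
        assert rec.cls is AlnClass.NO_SITE

    def test_classified_frame_columns(self, setup):
        original, mutated, table = setup
        recs = [classify_alignment(make_aln("A" * 20, start=95), table, mutated, original)]
        df = classified_to_frame(recs)
        assert list(df.columns) == [
            "qname", "chrom", "pos0", "len", "strand", "class", "allele",
            "mm_corr", "mm_prop", "indels", "ct5", "ct3",
        ]

    def test_feature_separation_endogenous_vs_contaminant(self):
        # contaminant alignments carry more mismatches and indels than
        # endogenous ones; rank-sum on the direct-mode mixture
        from spuriometer.simdata import simulate_classified_mixture

        cfg = SimConfig(p_spur=0.5, seed=17)
        df, labels = simulate_classified_mixture(cfg, 10_000)
        spur = labels["origin"].to_numpy() == "contaminant"
        mm = df["mm_prop"].to_numpy()
        ind = df["indels"].to_numpy()
        assert ranksums(mm[spur], mm[~spur]).pvalue < 0.01
        assert mm[spur].mean() > mm[~spur].mean()
        assert ranksums(ind[spur], ind[~spur]).pvalue < 0.01
        assert ind[spur].mean() > ind[~spur].mean()
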