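"""Informative sites, derived-allele sharing, and the Fisher exact machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import fisher_oracle, make_aln
from spuriometer.lineage import (
    ClassSharing,
    InformativeSite,
    Lineage,
    SharingResult,
    adjust_pvalues,
    build_informative_sites,
    call_ancestral,
    classify_informative_site,
    derived_sharing,
    lineage_test,
    sample_allele,
)


class TestCallAncestral:
    @pytest.mark.parametrize(
        "column,expected",
        [
            (["A"] * 5, "A"),
            (["A", "A", "A", "A", "C"], "A"),
            (["A", "A", "A", "C", "C"], None),
            (["A", "A", "A", "A", None], "A"),
            (["A", "A", "A", None, None], None),
        ],
    )
    def test_at_least_four_agree(self, column, expected):
        assert call_ancestral(column) == expected


class TestSampleAllele:
    def test_homozygous_deterministic(self, rng):
        assert sample_allele("A/A", rng) == "A"

    def test_missing_skipped(self, rng):
        assert sample_allele("./.", rng) is None

    def test_heterozygous_fair_coin(self):
        rng = np.random.default_rng(77)
        draws = [sample_allele("A/G", rng) for _ in range(10_000)]
        frac_a = draws.count("A") / len(draws)
        assert abs(frac_a - 0.5) < 0.02


class TestClassifyInformativeSite:
    def test_neandertal_site(self):
        assert classify_informative_site("A", "G", "A", "A") == (Lineage.NEANDERTAL, "G")

    def test_neandertal_denisovan_site(self):
        assert classify_informative_site("A", "G", "G", "A") == (
            Lineage.NEANDERTAL_DENISOVAN,
            "G",
        )

    def test_mh_plus_archaic_pattern_rejected(self):
        assert classify_informative_site("G", "G", "A", "A") is None

    def test_triallelic_rejected(self):
        assert classify_informative_site("C", "G", "A", "A") is None

    def test_exhaustive_carrier_patterns(self):
        # all 8 carrier subsets of {MH, Nea, Den}; exactly 4 map to a class
        anc, der = "A", "G"
        expected = {
            frozenset(): None,
            frozenset({"mh"}): Lineage.MODERN_HUMAN,
            frozenset({"nea"}): Lineage.NEANDERTAL,
            frozenset({"den"}): Lineage.DENISOVAN,
            frozenset({"mh", "nea"}): None,
            frozenset({"mh", "den"}): None,
            frozenset({"nea", "den"}): Lineage.NEANDERTAL_DENISOVAN,
            frozenset({"mh", "nea", "den"}): None,
        }
        for carriers, want in expected.items():
            mh = der if "mh" in carriers else anc
            nea = der if "nea" in carriers else anc
            den = der if "den" in carriers else anc
            got = classify_informative_site(mh, nea, den, anc)
            if want is None:
                assert got is None
            else:
                assert got == (want, der)


class TestBuildInformativeSites:
    def test_join_and_filtering(self):
        genotypes = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "pos0": [10, 20, 30, 40],
                "gt_mh": ["A/A", "A/A", "./.", "A/A"],
                "gt_nea": ["G/G", "A/A", "A/A", "G/G"],
                "gt_den": ["A/A", "A/A", "A/A", "G/G"],
            }
        )
        primates = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "pos0": [10, 20, 30, 40],
                "p1": ["A", "A", "A", "A"],
                "p2": ["A", "A", "A", "A"],
                "p3": ["A", "A", "A", "A"],
                "p4": ["A", "C", "A", "A"],
                "p5": ["C", "C", "A", "A"],
            }
        )
        sites = build_informative_sites(genotypes, primates, seed=0)
        # pos 10: Nea-derived; pos 20: no ancestral consensus (3 A, 2 C);
        # pos 30: missing MH genotype; pos 40: Nea+Den derived
        assert [(s.pos0, s.lineage) for s in sites] == [
            (10, Lineage.NEANDERTAL),
            (40, Lineage.NEANDERTAL_DENISOVAN),
        ]


class TestDerivedSharing:
    def _sites(self):
        return [
            InformativeSite("chr1", 10 + 30 * i, "A", "G", Lineage.NEANDERTAL)
            for i in range(20)
        ]

    def test_all_ancestral_reads_share_zero(self):
        sites = self._sites()
        alns = [make_aln("A" * 21, start=s.pos0 - 10, qname=f"r{i}")
                for i, s in enumerate(sites)]
        res = derived_sharing(alns, sites)
        cs = res.classes[Lineage.NEANDERTAL]
        assert (cs.n, cs.k) == (20, 0) and cs.pct == 0.0

    def test_constructed_35_percent(self):
        sites = self._sites()
        alns = []
        for i, s in enumerate(sites):
            base = "G" if i < 7 else "A"
            alns.append(
                make_aln("A" * 10 + base + "A" * 10, start=s.pos0 - 10, qname=f"r{i}")
            )
        res = derived_sharing(alns, sites)
        cs = res.classes[Lineage.NEANDERTAL]
        assert (cs.n, cs.k) == (20, 7)
        assert cs.pct == pytest.approx(35.0)
        lo, hi = cs.ci()
        assert 0 <= lo < 35 < hi <= 100

    def test_terminal_t_discarded(self):
        # derived T at the read's penultimate position: dropped from n
        site = InformativeSite("chr1", 28, "C", "T", Lineage.NEANDERTAL)
        aln = make_aln("A" * 18 + "T" + "A", start=10)
        res = derived_sharing([aln], [site])
        assert res.classes[Lineage.NEANDERTAL].n == 0
        assert res.n_discarded_terminal_t == 1

    def test_terminal_t_rule_reverse_strand_uses_read_orientation(self):
        # reference-forward base A at the alignment's left edge is T on the
        # reverse read's 3' end -> discarded
        site = InformativeSite("chr1", 11, "C", "A", Lineage.NEANDERTAL)
        aln = make_aln("A" * 20, start=10, reverse=True)
        res = derived_sharing([aln], [site])
        assert res.classes[Lineage.NEANDERTAL].n == 0
        assert res.n_discarded_terminal_t == 1

    def test_interior_t_kept(self):
        site = InformativeSite("chr1", 20, "C", "T", Lineage.DENISOVAN)
        aln = make_aln("A" * 10 + "T" + "A" * 10, start=10)
        res = derived_sharing([aln], [site])
        assert res.classes[Lineage.DENISOVAN] == ClassSharing(n=1, k=1)

    def test_other_base_discarded_not_counted(self):
        site = InformativeSite("chr1", 20, "A", "G", Lineage.MODERN_HUMAN)
        aln = make_aln("A" * 10 + "C" + "A" * 10, start=10)
        res = derived_sharing([aln], [site])
        assert res.classes[Lineage.MODERN_HUMAN].n == 0
        assert res.n_discarded_other_base == 1

    def test_bookkeeping_conserved(self, rng):
        sites = self._sites()
        alns = []
        for i, s in enumerate(sites):
            base = "ACGT"[rng.integers(0, 4)]
            offset = int(rng.integers(1, 20))
            alns.append(
                make_aln("A" * offset + base + "A" * (20 - offset),
                         start=s.pos0 - offset, qname=f"r{i}")
            )
        res = derived_sharing(alns, sites)
        n_kept = sum(cs.n for cs in res.classes.values())
        assert n_kept + res.n_discarded_terminal_t + res.n_discarded_other_base == 20


class TestLineageTest:
    def test_identical_proportions_p_one(self):
        sharing = SharingResult()
        sharing.classes[Lineage.NEANDERTAL] = ClassSharing(n=10, k=5)
        sharing.classes[Lineage.DENISOVAN] = ClassSharing(n=10, k=5)
        assert lineage_test(sharing) == pytest.approx(1.0)

    def test_strong_difference_matches_enumeration(self):
        sharing = SharingResult()
        sharing.classes[Lineage.NEANDERTAL] = ClassSharing(n=10, k=9)
        sharing.classes[Lineage.DENISOVAN] = ClassSharing(n=10, k=1)
        p = lineage_test(sharing)
        assert p == pytest.approx(fisher_oracle(9, 10, 1, 10), rel=1e-9)
        # exact enumeration: tables no likelier than observed are
        # x in {0, 1, 9, 10}, total probability 202 / C(20,10)
        assert p == pytest.approx(202 / 184756, rel=1e-12)

    def test_fisher_matches_oracle_on_small_tables(self):
        for n1, n2 in itertools.product(range(1, 9), repeat=2):
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    sharing = SharingResult()
                    sharing.classes[Lineage.NEANDERTAL] = ClassSharing(n=n1, k=k1)
                    sharing.classes[Lineage.DENISOVAN] = ClassSharing(n=n2, k=k2)
                    assert lineage_test(sharing) == pytest.approx(
                        fisher_oracle(k1, n1, k2, n2), rel=1e-7, abs=1e-12
                    )

    def test_bh_adjustment_monotone(self):
        ps = {"a": 0.001, "b": 0.02, "c": 0.7, "d": 0.04}
        adj = adjust_pvalues(ps)
        assert all(adj[k] >= ps[k] for k in ps)
        assert adj["a"] < adj["b"] <= adj["d"] < adj["c"]
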