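"""Seed-site scanning: complementarity, Poisson enrichment, consensus filter."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirsnpkit import (
    MiRNA,
    UTRRegion,
    annotate_pvalues,
    consensus_filter,
    find_mres,
    poisson_pvalue,
    revcomp,
)
from mirsnpkit.simulate import brute_force_sites, random_mirna, rng_for

rna = st.text(alphabet="ACGU", min_size=1, max_size=60)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ACGU", "ACGU"),      # self-reverse-complementary
        ("AAAA", "UUUU"),
        ("GAUC", "GAUC"),      # palindrome under reverse complement
        ("AAAT", "ATTT"),      # DNA in, DNA out
        ("acgu", "ACGU"),
    ],
)
def test_revcomp_examples(seq, expected):
    assert revcomp(seq) == expected


def test_revcomp_rejects_non_nucleotide_with_position():
    with pytest.raises(ValueError, match="position 3"):
        revcomp("ACXGU")


@given(rna)
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq


@given(rna)
def test_revcomp_pairs_strictly_watson_crick(seq):
    rc = revcomp(seq)
    pairs = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    assert all((a, b) in pairs for a, b in zip(seq, reversed(rc)))


class TestFindMres:
    def test_recovers_planted_site_with_maximal_length(self):
        mirna = MiRNA("mir-x", "UGAGGUAGUAGGUUGUAUAGUU")
        planted = revcomp(mirna.sequence[:8])
        # C flanks cannot extend the match (miRNA nt 9 is U, complement A)
        utr = UTRRegion("g", "C" * 100 + planted + "C" * 100)
        sites = find_mres(mirna, utr, min_match=7)
        assert [(s.utr_start, s.utr_end, s.match_len) for s in sites] == [(101, 108, 8)]
        assert sites[0].matched_prefix == mirna.sequence[:8]

    def test_empty_and_short_utrs_yield_no_sites(self):
        mirna = MiRNA("mir-x", "UGAGGUAGUAGGUUGUAUAGUU")
        assert find_mres(mirna, UTRRegion("g", ""), min_match=7) == []
        assert find_mres(mirna, UTRRegion("g", "ACGUA"), min_match=7) == []

    def test_rejects_min_match_below_six(self):
        mirna = MiRNA("mir-x", "UGAGGUAGUAGGUUGUAUAGUU")
        with pytest.raises(ValueError):
            find_mres(mirna, UTRRegion("g", "ACGU" * 10), min_match=5)

    def test_dna_utr_and_rna_mirna_are_interchangeable(self):
        mirna = MiRNA("mir-x", "UGAGGUAGUAGGUUGUAUAGUU")
        planted = revcomp(mirna.sequence[:8]).replace("U", "T")
        utr = UTRRegion("g", "CGCG" * 20 + planted + "GCGC" * 20)
        sites = find_mres(mirna, utr, min_match=8)
        assert len(sites) == 1 and sites[0].match_len == 8

    def test_prefix_start_two_anchors_the_seed(self):
        mirna = MiRNA("mir-x", "UGAGGUAGUAGGUUGUAUAGUU")
        planted = revcomp(mirna.sequence[1:9])  # nts 2..9
        utr = UTRRegion("g", "C" * 50 + planted + "C" * 50)
        sites = find_mres(mirna, utr, min_match=7, prefix_start=2)
        assert [(s.utr_start, s.utr_end) for s in sites] == [(51, 58)]
        assert sites[0].matched_prefix == mirna.sequence[1:9]

    def test_agrees_with_bruteforce_scanner_on_random_sequences(self):
        # oracle equivalence on >= 100 random miRNA/UTR pairs
        rng = rng_for(424242, "scan_oracle")
        checked = 0
        for _ in range(120):
            mirna = random_mirna(rng, length=int(rng.integers(18, 24)))
            utr_seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(50, 400))))
            utr = UTRRegion("g", utr_seq)
            min_match = int(rng.integers(6, 9))
            got = [
                (s.utr_start, s.utr_end, s.match_len)
                for s in find_mres(mirna, utr, min_match=min_match)
            ]
            assert got == brute_force_sites(utr_seq, mirna.sequence, min_match)
            checked += 1
        assert checked >= 100


def test_published_table_descending_coordinates_map_to_ascending(published_sites):
    row = next(t for t in published_sites if t.gene == "HBEGF" and t.mirna == "hsa-mir-379")
    assert (row.utr_start, row.utr_end, row.match_len) == (1826, 1833, 8)
    assert (row.start_reported, row.end_reported) == (1833, 1826)


class TestPoissonPvalue:
    def test_zero_observed_sites_gives_one(self):
        p, _ = poisson_pvalue(UTRRegion("g", "ACGU" * 500), 8, 0)
        assert p == 1.0

    def test_single_site_closed_form(self):
        # lam = (L - k + 1) * 4^-k; P(X >= 1) = 1 - exp(-lam)
        utr = UTRRegion("g", "A" * 2000)
        p, model = poisson_pvalue(utr, 8, 1)
        lam = 1993 * 0.25**8
        assert model.lam == pytest.approx(lam, abs=0)
        assert p == pytest.approx(-math.expm1(-lam), rel=1e-12)
        assert p == pytest.approx(0.0300, abs=5e-4)

    def test_two_sites_closed_form(self):
        utr = UTRRegion("g", "A" * 2000)
        p, _ = poisson_pvalue(utr, 8, 2)
        lam = 1993 * 0.25**8
        assert p == pytest.approx(1 - math.exp(-lam) * (1 + lam), rel=1e-9)

    def test_monotone_nonincreasing_in_observed_count(self):
        utr = UTRRegion("g", "G" * 1000)
        ps = [poisson_pvalue(utr, 7, m)[0] for m in range(5)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_longer_matches_are_rarer(self):
        # lam shrinks with k, so the single-site p-value shrinks too
        utr = UTRRegion("g", "C" * 1000)
        ps = [poisson_pvalue(utr, k, 1)[0] for k in range(6, 12)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_match_longer_than_utr_degenerates_to_one(self):
        with pytest.warns(UserWarning):
            p, _ = poisson_pvalue(UTRRegion("g", "ACGU"), 8, 1)
        assert p == 1.0

    def test_empirical_background_uses_site_composition(self):
        # AU-rich UTR makes an AU-only site more probable than under uniform
        utr = UTRRegion("g", "AU" * 400 + "GC" * 100)
        p_emp, m_emp = poisson_pvalue(utr, 8, 1, background="empirical", site="AUAUAUAU")
        p_uni, m_uni = poisson_pvalue(utr, 8, 1, background="uniform", site="AUAUAUAU")
        assert m_emp.lam > m_uni.lam
        assert p_emp > p_uni

    def test_annotate_attaches_pvalues_per_pair(self):
        mirna = MiRNA("mir-x", "UGAGGUAGUAGGUUGUAUAGUU")
        utr = UTRRegion("g", "C" * 300 + revcomp(mirna.sequence[:8]) + "C" * 300)
        sites = annotate_pvalues(find_mres(mirna, utr), utr)
        assert len(sites) == 1
        L = utr.length
        assert sites[0].pvalue == pytest.approx(-math.expm1(-(L - 8 + 1) * 0.25**8), rel=1e-9)


class TestConsensusFilter:
    def test_published_exclusions_and_retentions(self, published_sites):
        kept = consensus_filter(published_sites, min_sources=5, alpha=0.05)
        kept_pairs = {(t.gene, t.mirna) for t in kept}
        assert ("SP1", "hsa-mir-24") not in kept_pairs          # p = 0.2725
        assert ("HBEGF", "hsa-mir-379") in kept_pairs           # p = 0.0223
        assert ("SP1", "hsa-mir-155") not in kept_pairs         # p = 0.0764
        assert len(kept) == 12

    def test_empty_input_gives_empty_output(self):
        assert consensus_filter([], min_sources=5, alpha=0.05) == []

    def test_subset_stable_and_idempotent(self, published_sites):
        kept = consensus_filter(published_sites, min_sources=5, alpha=0.05)
        assert all(t in published_sites for t in kept)
        order = [published_sites.index(t) for t in kept]
        assert order == sorted(order)
        assert consensus_filter(kept, min_sources=5, alpha=0.05) == kept

    def test_source_threshold_applies(self, published_sites):
        assert consensus_filter(published_sites, min_sources=6, alpha=0.05) == []
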