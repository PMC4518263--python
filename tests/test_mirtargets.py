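"""Seed/alignment scanners vs naive oracles; promoter rule; bootstrap."""

import numpy as np
import pytest

from ernakit.core import GenomicInterval, reverse_complement
from ernakit.mirtargets import (
    MATCH_SCORE,
    MISMATCH_SCORE,
    SEED_WEIGHT,
    SeedFamily,
    WOBBLE_SCORE,
    alignment_site_scan,
    build_promoter,
    build_utr3,
    confirm_mir_region,
    count_promoter_unique_matches,
    promoter_unique_filter,
    seed_site_scan,
    shuffle_bootstrap,
    shuffle_sequence,
)

from conftest import make_gene

LET7 = SeedFamily("let-7", "GAGGUAG", ("UGAGGUAGUAGGUUGUAUAGUU",))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestConfirmMirRegion:
    def test_mature_exact_match(self):
        seq = "AAAA" + "TGAGGTAGTAGGTTGTATAGTT" + "CCCC"
        assert confirm_mir_region(seq, LET7) == (4, "sense")

    def test_seed_only_match(self):
        seq = "TTTT" + "GAGGTAG" + "TTTT"
        assert confirm_mir_region(seq, LET7) == (4, "sense")

    def test_absent(self, rng):
        rng2 = np.random.default_rng(5)
        for _ in range(20):
            seq = random_seq(rng2, 60)
            got = confirm_mir_region(seq, LET7)
            # brute-force both-strand search as the oracle
            expected = None
            pats = ["TGAGGTAGTAGGTTGTATAGTT", "GAGGTAG"]
            hits = []
            for pat in pats:
                for orient, probe in (("sense", pat), ("antisense", reverse_complement(pat))):
                    p = seq.find(probe)
                    if p != -1:
                        hits.append((p, orient))
            if hits:
                expected = min(hits, key=lambda h: (h[0], h[1] != "sense"))
            assert got == expected

    def test_reverse_strand_match_reports_orientation(self):
        seq = "CCCC" + reverse_complement("GAGGTAG") + "CCCC"
        assert confirm_mir_region(seq, LET7) == (4, "antisense")


class TestPromoterUtr:
    def test_promoter_window_plus_strand(self):
        g = make_gene("g", "chr1", 50000, 56000, "+", 55000)
        assert build_promoter(g, [g]) == [GenomicInterval("chr1", 49000, 50200, "+")]

    def test_promoter_neighbor_subtracted(self):
        g = make_gene("g", "chr1", 50000, 56000, "+", 55000)
        other = make_gene("o", "chr1", 48000, 49100, "+")
        assert build_promoter(g, [g, other]) == [GenomicInterval("chr1", 49100, 50200, "+")]

    def test_promoter_minus_strand_mirror(self):
        g = make_gene("g", "chr1", 54000, 60000, "-", 55000)
        assert build_promoter(g, [g]) == [GenomicInterval("chr1", 59800, 61000, "-")]

    def test_utr3_plus(self):
        g = make_gene("g", "chr1", 50000, 60000, "+", 59000)
        assert build_utr3(g) == GenomicInterval("chr1", 59000, 60000, "+")

    def test_utr3_minus(self):
        g = make_gene("g", "chr1", 50000, 60000, "-", 51000)
        assert build_utr3(g) == GenomicInterval("chr1", 50000, 51000, "-")

    @pytest.mark.parametrize("coding_end", [None, 60000])
    def test_utr3_absent(self, coding_end):
        g = make_gene("g", "chr1", 50000, 60000, "+", coding_end)
        assert build_utr3(g) is None


def naive_seed_sites(seq, family):
    """Exhaustive substring-enumeration oracle for one strand."""
    rc7 = reverse_complement(family.seed7)
    rc6a = rc7[1:] + "A"
    sites = []
    for i in range(len(seq)):
        if seq[i:i + 7] == rc7:
            if seq[i + 7:i + 8] == "A":
                sites.append((i, "8mer"))
            else:
                sites.append((i, "7mer-m8"))
        if seq[i:i + 7] == rc6a and (i == 0 or seq[i - 1] != rc7[0]):
            sites.append((i, "7mer-A1"))
    return sorted(sites)


class TestSeedSiteScan:
    def test_8mer_example(self):
        # the embedded 7mer-A1 pattern is part of the 8mer and not reported twice
        sites = seed_site_scan("TTTCTACCTCATTT", LET7, scan_antisense=False)
        assert [(s.position, s.site_type) for s in sites] == [(3, "8mer")]

    def test_7mer_m8_without_a(self):
        sites = seed_site_scan("TTTCTACCTCGTTT", LET7, scan_antisense=False)
        assert [(s.position, s.site_type) for s in sites] == [(3, "7mer-m8")]

    def test_7mer_a1(self):
        sites = seed_site_scan("TTTGTACCTCATTT", LET7, scan_antisense=False)
        assert [(s.position, s.site_type) for s in sites] == [(4, "7mer-A1")]

    def test_matches_naive_oracle_on_random_sequences(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            seed = "".join(rng.choice(list("ACGT"), size=7))
            fam = SeedFamily("f", seed)
            # seed-enriched alphabet so matches actually occur
            seq = "".join(rng.choice(list("ACGT"), size=150))
            rc7 = reverse_complement(seed)
            for _ in range(3):
                p = int(rng.integers(0, 140))
                seq = seq[:p] + rc7 + ("A" if rng.random() < 0.5 else "G") + seq[p + 8:]
            got = [
                (s.position, s.site_type)
                for s in seed_site_scan(seq, fam, scan_antisense=False)
            ]
            assert got == naive_seed_sites(seq, fam)

    def test_antisense_strand_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            seed = "".join(rng.choice(list("ACGT"), size=7))
            fam = SeedFamily("f", seed)
            seq = "".join(rng.choice(list("ACGT"), size=120))
            p = int(rng.integers(0, 112))
            seq = seq[:p] + reverse_complement(seed) + "A" + seq[p + 8:]
            sense_only = seed_site_scan(seq, fam, scan_antisense=False)
            # scanning the reverse complement on its antisense strand must
            # reproduce the sense sites at mirrored coordinates
            rc = reverse_complement(seq)
            both_rc = seed_site_scan(rc, fam, scan_antisense=True)
            anti = [
                (len(seq) - s.position - (8 if s.site_type == "8mer" else 7), s.site_type)
                for s in both_rc
                if s.strand_scanned == "antisense"
            ]
            assert {(s.position, s.site_type) for s in sense_only} <= set(anti) | {
                (s.position, s.site_type) for s in both_rc if s.strand_scanned == "sense"
            }


def naive_alignment_scores(seq, mature):
    """All-window scorer in plain Python."""
    wc = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    wob = {("G", "T"), ("T", "G")}
    m = len(mature)
    rev = mature[::-1]
    weights = [1.0] * m
    for k in range(1, 8):
        weights[k] = SEED_WEIGHT
    rev_w = weights[::-1]
    out = []
    for i in range(len(seq) - m + 1):
        score = 0.0
        for k in range(m):
            pair = (rev[k], seq[i + k])
            s = MATCH_SCORE if pair in wc else WOBBLE_SCORE if pair in wob else MISMATCH_SCORE
            score += s * rev_w[k]
        out.append(score)
    return out


class TestAlignmentSiteScan:
    def test_perfect_complement_scores_145(self):
        mature = "TGAGGTAGTAGGTTGTATAGTT"  # 22 nt
        target = reverse_complement(mature)
        sites = alignment_site_scan(target, mature, threshold=80, scan_antisense=False)
        assert len(sites) == 1
        assert sites[0].score == pytest.approx(22 * 5 + 7 * 5)  # 145

    def test_one_seed_mismatch_costs_sixteen(self):
        mature = "TGAGGTAGTAGGTTGTATAGTT"
        target = list(reverse_complement(mature))
        # miRNA position 4 (inside the weighted seed) sits at target index
        # len-1-3 on the sense target; break that pairing to a mismatch
        idx = len(target) - 1 - 3
        orig = target[idx]
        target[idx] = {"A": "C", "C": "A", "G": "A", "T": "C"}[orig]
        sites = alignment_site_scan("".join(target), mature, threshold=80,
                                    scan_antisense=False)
        assert sites[0].score == pytest.approx(145 - SEED_WEIGHT * (MATCH_SCORE - MISMATCH_SCORE))

    def test_matches_naive_all_window_scorer(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            mature = "".join(rng.choice(list("ACGT"), size=int(rng.integers(16, 24))))
            seq = "".join(rng.choice(list("ACGT"), size=90))
            # plant one near-perfect site
            p = int(rng.integers(0, 90 - len(mature)))
            seq = seq[:p] + reverse_complement(mature) + seq[p + len(mature):]
            threshold = 60.0
            got = {
                s.position: s.score
                for s in alignment_site_scan(seq, mature, threshold, scan_antisense=False)
            }
            oracle = {
                i: sc
                for i, sc in enumerate(naive_alignment_scores(seq, mature))
                if sc >= threshold
            }
            assert got == pytest.approx(oracle)

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError):
            alignment_site_scan("ACGT" * 20, "ACGTACGTACGT")


class TestPromoterUniqueFilter:
    def test_rule_table(self):
        site = seed_site_scan("TTTCTACCTCATTT", LET7)[0]
        assert promoter_unique_filter([site], []) is True
        assert promoter_unique_filter([site], [site]) is False
        assert promoter_unique_filter([], []) is False

    def test_monotone_in_utr_sites(self):
        site = seed_site_scan("TTTCTACCTCATTT", LET7)[0]
        retained_before = promoter_unique_filter([site], [])
        retained_after = promoter_unique_filter([site], [site])
        assert retained_before and not retained_after


class TestShuffleBootstrap:
    def test_formula_all_shuffles_reach_observed(self):
        p, obs, _ = shuffle_bootstrap("ACGTACGTACGT", lambda s: 0.0, B=100, rng_seed=1)
        assert p == 1.0

    def test_formula_no_shuffle_reaches_observed(self):
        seq = "ACGTACGTACGT"
        p, obs, _ = shuffle_bootstrap(
            seq, lambda s: 1.0 if s == seq else 0.0, B=100, rng_seed=1
        )
        assert p == pytest.approx(1 / 101)

    def test_deterministic_under_seed(self):
        stat = lambda s: float(s.count("AC"))
        a = shuffle_bootstrap("ACGTACGTAAACCC", stat, B=50, rng_seed=4)
        b = shuffle_bootstrap("ACGTACGTAAACCC", stat, B=50, rng_seed=4)
        assert a[0] == b[0] and (a[2] == b[2]).all()

    def test_shuffle_preserves_composition(self, rng):
        seq = "AAACCCGGGTTTACGT"
        out = shuffle_sequence(seq, np.random.default_rng(3))
        assert sorted(out) == sorted(seq)

    def test_dinucleotide_shuffle_preserves_dinucleotides(self):
        seq = "ACGTACGTTTGGACCA"
        out = shuffle_sequence(seq, np.random.default_rng(3), dinucleotide=True)
        count = lambda s: sorted(s[i:i + 2] for i in range(len(s) - 1))
        assert count(out) == count(seq)
        assert out[0] == seq[0]

    def test_null_statistic_gives_p_one(self):
        p, _, _ = shuffle_bootstrap("ACGT" * 10, lambda s: 0.0, B=20, rng_seed=0)
        assert p == 1.0


class TestCountPromoterUniqueMatches:
    def test_counts_confirmed_families_with_promoter_only_sites(self):
        prom = "TTT" + reverse_complement(LET7.seed7) + "A" + "TTT"
        utr_clean = "T" * 30
        erna = "CCC" + LET7.seed7.replace("U", "T") + "CCC"
        n = count_promoter_unique_matches(
            erna, [LET7], {"g": prom}, {"g": utr_clean}, mode="seed"
        )
        assert n == 1
        # a 3'UTR site removes the match
        utr_hit = "TTT" + reverse_complement(LET7.seed7) + "ATT"
        n2 = count_promoter_unique_matches(
            erna, [LET7], {"g": prom}, {"g": utr_hit}, mode="seed"
        )
        assert n2 == 0
        # unconfirmed eRNA contributes nothing
        n3 = count_promoter_unique_matches(
            "T" * 40, [LET7], {"g": prom}, {"g": utr_clean}, mode="seed"
        )
        assert n3 == 0
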