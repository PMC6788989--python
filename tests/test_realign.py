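"""Pair-HMM realignment: parameter estimation, anchor/window construction,
forward algorithm against a path-enumeration oracle, allelotyping, and the
strand-bias filter against an exact hypergeometric oracle."""

import math
from fractions import Fraction

import numpy as np
import pytest

from phasecall.candidates import CandidateSite
from phasecall.formats import AlignedRead
from phasecall.realign import (NEG_INF, AlleleCall, PairHmmParams,
                               RealignmentWindow, allelotype,
                               allelotype_cluster, anchor_is_valid,
                               banded_forward_prob, cluster_sites,
                               estimate_hmm_params, find_window, forward_prob,
                               is_nonrepetitive_kmer, strand_bias_filter)
from phasecall.simulate import random_reference


def _site(pos, ref, alt):
    return CandidateSite("c", pos, ref, alt, 1, 1, 1, 1, 0, 4,
                         np.zeros(3), 0.5)


def _read(pos, seq, cigar=None, name="r", strand="+"):
    return AlignedRead(name, "c", pos, strand, 60,
                       cigar or [("M", len(seq))], seq)


# ---------------------------------------------------------------------------
# parameter estimation

class TestEstimateParams:
    def test_opening_rates_from_counts(self):
        # 90 aligned positions, 5 insertion openings, 5 deletion openings
        # over 100 alignment events -> both opening rates 0.05
        ref = "ACGT" * 40
        cigar = []
        for _ in range(5):
            cigar += [("M", 9), ("I", 1), ("M", 9), ("D", 1)]
        seq_len = 5 * 19
        read = AlignedRead("r", "c", 0, "+", 60, cigar,
                           (ref * 2)[:seq_len])
        params = estimate_hmm_params([read], ref, ref_offset=0)
        assert params.match_to_ins == pytest.approx(0.05)
        assert params.match_to_del == pytest.approx(0.05)

    def test_extension_rate_from_lengths(self):
        # all insertions length 2 -> extension probability (2-1)/2 = 0.5
        ref = "ACGTACGTACGTACGTACGT"
        cigar = [("M", 5), ("I", 2), ("M", 5), ("I", 2), ("M", 5)]
        read = AlignedRead("r", "c", 0, "+", 60, cigar, "A" * 19)
        params = estimate_hmm_params([read], ref)
        assert params.ins_extend == pytest.approx(0.5)

    def test_no_usable_alignments(self):
        with pytest.raises(ValueError):
            estimate_hmm_params([], "ACGT" * 10)

    def test_recovers_simulator_rates(self, read_sample_sim):
        """Rates estimated from >= 500 simulated reads match the generative
        0.11/0.04/0.01 within 20% relative."""
        cfg, ref, reads, _ = read_sample_sim
        assert len(reads) >= 500
        params = estimate_hmm_params(reads, ref)
        assert params.match_to_ins == pytest.approx(0.11, rel=0.2)
        assert params.match_to_del == pytest.approx(0.04, rel=0.2)
        assert params.sub_rate == pytest.approx(0.01, rel=0.2)
        assert params.ins_extend == pytest.approx(1 / 3, rel=0.2)
        assert params.del_extend == pytest.approx(1 / 3, rel=0.2)


# ---------------------------------------------------------------------------
# forward algorithm vs. path enumeration

def oracle_forward(query, hap, params):
    """Sum over every explicit state path (virtual match start, match end)
    of transition x emission products.  Exponential; lengths <= 4 only."""
    t_mm, t_mi, t_md, t_im, t_ii, t_dm, t_dd, sub = params.as_tuple()
    trans = {
        ("M", "M"): t_mm, ("M", "I"): t_mi, ("M", "D"): t_md,
        ("I", "M"): t_im, ("I", "I"): t_ii,
        ("D", "M"): t_dm, ("D", "D"): t_dd,
    }

    def em(qc, hc):
        return (1.0 - sub) if (qc == hc and qc in "ACGT") else sub / 3.0

    total = 0.0

    def rec(i, j, state, p):
        nonlocal total
        if i == len(query) and j == len(hap) and state == "M":
            total += p
            return
        for nxt in ("M", "I", "D"):
            t = trans.get((state, nxt))
            if t is None:
                continue
            if nxt == "M" and i < len(query) and j < len(hap):
                rec(i + 1, j + 1, "M", p * t * em(query[i], hap[j]))
            elif nxt == "I" and i < len(query):
                rec(i + 1, j, "I", p * t * 0.25)
            elif nxt == "D" and j < len(hap):
                rec(i, j + 1, "D", p * t)

    rec(0, 0, "M", 1.0)
    return total


def _random_params(rng):
    return PairHmmParams(
        match_to_ins=float(rng.uniform(0.01, 0.2)),
        match_to_del=float(rng.uniform(0.01, 0.2)),
        ins_extend=float(rng.uniform(0.05, 0.6)),
        del_extend=float(rng.uniform(0.05, 0.6)),
        sub_rate=float(rng.uniform(0.001, 0.2)))


class TestForward:
    def test_identity_near_deterministic_params(self):
        params = PairHmmParams(1e-9, 1e-9, 1e-9, 1e-9, 1e-9)
        lp = forward_prob("ACGTA", "ACGTA", params)
        assert lp == pytest.approx(5 * math.log1p(-1e-9), abs=1e-6)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        bases = "ACGT"
        for _ in range(40):
            params = _random_params(rng)
            m, n = rng.integers(1, 5), rng.integers(1, 5)
            q = "".join(rng.choice(list(bases), size=m))
            h = "".join(rng.choice(list(bases), size=n))
            expected = oracle_forward(q, h, params)
            got = math.exp(forward_prob(q, h, params))
            assert got == pytest.approx(expected, rel=1e-10)

    def test_emission_normalization_over_queries(self):
        """Summing P(query|hap) over all 4^m queries equals the pure
        transition mass of all m-emission paths (emissions sum to one)."""
        rng = np.random.default_rng(7)
        params = _random_params(rng)
        hap = "ACG"
        for m in (1, 2, 3):
            total = 0.0
            for idx in range(4 ** m):
                q = "".join("ACGT"[(idx >> (2 * k)) & 3] for k in range(m))
                total += math.exp(forward_prob(q, hap, params))
            mass = oracle_forward("N" * 0 + "x" * 0, "", params) if False else None
            # transition mass: oracle with emissions forced to 1
            flat = _TransitionMass(params)
            assert total == pytest.approx(flat.mass(m, len(hap)), rel=1e-9)

    def test_n_bases_always_mismatch(self):
        # against a haplotype containing no C, an N base and a C base are
        # emission-equivalent (both always take the sub/3 mismatch term)
        params = PairHmmParams(0.05, 0.05, 0.3, 0.3, 0.01)
        hap = "AGGTAGTA"
        lp_n = forward_prob("AGNTAGTA", hap, params)
        lp_c = forward_prob("AGCTAGTA", hap, params)
        assert lp_n == pytest.approx(lp_c, rel=1e-12)
        assert forward_prob("N", "A", params) == pytest.approx(
            math.log(params.match_to_match * params.sub_rate / 3.0), rel=1e-12)


class _TransitionMass:
    """Total transition probability of all paths with m query and n hap
    consumptions, ending in match (emissions summed out to 1)."""

    def __init__(self, params):
        self.t = params.as_tuple()

    def mass(self, m, n):
        t_mm, t_mi, t_md, t_im, t_ii, t_dm, t_dd, _ = self.t
        from functools import lru_cache

        @lru_cache(maxsize=None)
        def f(i, j, state):
            # mass of completing from (i, j, state) to (m, n) ending in M
            if i == m and j == n and state == "M":
                base = 1.0
            else:
                base = 0.0
            out = base
            if state == "M":
                if i < m and j < n:
                    out += t_mm * f(i + 1, j + 1, "M")
                if i < m:
                    out += t_mi * f(i + 1, j, "I")
                if j < n:
                    out += t_md * f(i, j + 1, "D")
            elif state == "I":
                if i < m and j < n:
                    out += t_im * f(i + 1, j + 1, "M")
                if i < m:
                    out += t_ii * f(i + 1, j, "I")
            else:
                if i < m and j < n:
                    out += t_dm * f(i + 1, j + 1, "M")
                if j < n:
                    out += t_dd * f(i, j + 1, "D")
            return out

        return f(0, 0, "M")


class TestBandedForward:
    def test_full_band_is_exact(self):
        rng = np.random.default_rng(0)
        params = _random_params(rng)
        q = "".join(rng.choice(list("ACGT"), size=30))
        h = "".join(rng.choice(list("ACGT"), size=33))
        assert banded_forward_prob(q, h, params, band=40) == forward_prob(q, h, params)

    def test_band_20_close_to_full_on_read_like_pairs(self):
        """On 100 random 30-60 bp windows whose query is a CLR-errored copy
        of the haplotype (the pairs realignment actually sees), the default
        band loses <= 0.01 log10 units versus the full recursion."""
        rng = np.random.default_rng(1)
        params = PairHmmParams.default()

        def clr_copy(h):
            out = []
            for ch in h:
                while rng.random() < 0.11:          # insertion run
                    out.append(str(rng.choice(list("ACGT"))))
                if rng.random() < 0.04:             # deletion
                    continue
                if rng.random() < 0.01:             # substitution
                    ch = str(rng.choice([b for b in "ACGT" if b != ch]))
                out.append(ch)
            return "".join(out)

        for _ in range(100):
            n = int(rng.integers(30, 61))
            h = "".join(rng.choice(list("ACGT"), size=n))
            q = clr_copy(h)
            if not q:
                continue
            full = forward_prob(q, h, params)
            band = banded_forward_prob(q, h, params, band=20)
            assert abs(band - full) / math.log(10) <= 0.01

    def test_band_monotone_toward_full(self):
        rng = np.random.default_rng(2)
        params = PairHmmParams.default()
        q = "".join(rng.choice(list("ACGT"), size=40))
        h = "".join(rng.choice(list("ACGT"), size=52))
        full = forward_prob(q, h, params)
        vals = [banded_forward_prob(q, h, params, band=b)
                for b in (2, 5, 10, 20, 60)]
        assert all(vals[i] <= vals[i + 1] + 1e-12 for i in range(len(vals) - 1))
        assert vals[-1] == full

    def test_narrow_band_excludes_all_paths_sentinel(self):
        # a large alignment shift between short query and long haplotype
        # leaves no complete path inside a width-1 band: log(0) sentinel
        q = "ACGTA"
        h = "T" * 40 + "ACGTA"
        params = PairHmmParams.default()
        assert banded_forward_prob(q, h, params, band=1) == NEG_INF
        assert banded_forward_prob(q, h, params, band=50) > NEG_INF

    def test_band_must_be_positive(self):
        with pytest.raises(ValueError):
            banded_forward_prob("ACG", "ACG", PairHmmParams.default(), band=0)


# ---------------------------------------------------------------------------
# anchors and windows

class TestAnchors:
    def test_nonrepetitive_rule(self):
        assert is_nonrepetitive_kmer("ACGTAC")
        assert not is_nonrepetitive_kmer("AAAAAA")   # period 1
        assert not is_nonrepetitive_kmer("ACACAC")   # period 2
        assert not is_nonrepetitive_kmer("AAGAAG")   # only 2 distinct bases
        assert is_nonrepetitive_kmer("AAGAAC")

    def test_uniqueness_within_span(self):
        ref = "ACGTTG" + "A" * 20 + "ACGTTG" + "C" * 20
        assert not anchor_is_valid(ref, 0, 0, 6, 0, len(ref))
        assert anchor_is_valid(ref, 0, 0, 6, 0, 20)


def _brute_force_window(ref, read_seq, read_pos, site_pos, k, max_dist):
    """Independent scan over all anchor placements for an exactly-matching
    read: innermost valid (left, right) anchor pair."""
    left = None
    for a in range(site_pos - k, site_pos - max_dist - 1, -1):
        if a < read_pos or a + k > read_pos + len(read_seq):
            continue
        kmer = ref[a:a + k]
        span = ref[max(0, site_pos - max_dist - k): site_pos + max_dist + k + 1]
        if (is_nonrepetitive_kmer(kmer) and span.count(kmer) == 1
                and read_seq[a - read_pos:a - read_pos + k] == kmer):
            left = a
            break
    right = None
    for b in range(site_pos + 1, site_pos + max_dist - k + 1):
        if b < read_pos or b + k > read_pos + len(read_seq):
            continue
        kmer = ref[b:b + k]
        span = ref[max(0, site_pos - max_dist - k): site_pos + max_dist + k + 1]
        if (is_nonrepetitive_kmer(kmer) and span.count(kmer) == 1
                and read_seq[b - read_pos:b - read_pos + k] == kmer):
            right = b
            break
    if left is None or right is None:
        return None
    return left, right + 6


class TestFindWindow:
    def test_innermost_anchors_on_clean_reference(self):
        ref = random_reference(200, seed=123)
        read = _read(0, ref)
        site = _site(50, ref[50], "A" if ref[50] != "A" else "C")
        w = find_window(read, ref, site, k=6, max_dist=200)
        assert w is not None
        expected = _brute_force_window(ref, ref, 0, 50, 6, 200)
        assert (w.start, w.end) == expected
        # immediately-valid anchors give the tight window [44, 57)
        if expected == (44, 57):
            assert w.query_seq == ref[44:57]

    def test_matches_brute_force_on_many_sites(self):
        ref = random_reference(2000, seed=9)
        read = _read(0, ref)
        for pos in range(100, 1900, 137):
            site = _site(pos, ref[pos], "A" if ref[pos] != "A" else "C")
            w = find_window(read, ref, site, k=6, max_dist=200)
            expected = _brute_force_window(ref, ref, 0, pos, 6, 200)
            got = None if w is None else (w.start, w.end)
            assert got == expected

    def test_homopolymer_forces_anchor_outside(self):
        base = random_reference(300, seed=77)
        ref = base[:100] + "AAAAAAAA" + base[108:]
        site_pos = 104  # inside the homopolymer
        read = _read(0, ref)
        site = _site(site_pos, ref[site_pos], "C")
        w = find_window(read, ref, site, k=6, max_dist=200)
        assert w is not None
        # the window strictly contains the full homopolymer run: no anchor
        # k-mer lies wholly inside it
        assert w.start < 100 and w.end > 108
        assert not (w.start >= 100 and w.start + 6 <= 108)
        assert not (w.end - 6 >= 100 and w.end <= 108)

    def test_two_close_sites_share_window(self):
        ref = random_reference(300, seed=5)
        read = _read(0, ref)
        s1 = _site(150, ref[150], "A" if ref[150] != "A" else "C")
        s2 = _site(154, ref[154], "A" if ref[154] != "A" else "C")
        w = find_window(read, ref, [s1, s2], k=6)
        assert w is not None
        assert w.start + 6 <= 150 and w.end - 6 >= 155
        assert len(w.sites) == 2

    def test_no_window_when_read_lacks_flank(self):
        ref = random_reference(300, seed=11)
        read = _read(48, ref[48:60])  # only 2 bases left of the site
        site = _site(50, ref[50], "A" if ref[50] != "A" else "C")
        assert find_window(read, ref, site, k=6) is None

    def test_window_haplotype_substitution(self):
        ref = random_reference(200, seed=3)
        read = _read(0, ref)
        alt = "A" if ref[50] != "A" else "C"
        w = find_window(read, ref, _site(50, ref[50], alt), k=6)
        hap_ref = w.haplotype([0])
        hap_alt = w.haplotype([1])
        assert hap_ref == w.ref_hap
        assert hap_alt[50 - w.start] == alt
        assert sum(a != b for a, b in zip(hap_ref, hap_alt)) == 1


class TestClusterSites:
    def test_gap_grouping_and_cap_split(self):
        sites = [_site(p, "A", "C") for p in (10, 14, 18, 22, 60)]
        clusters = cluster_sites(sites, gap=10, cap=3)
        lens = [len(c) for c in clusters]
        assert sum(lens) == 5
        assert max(lens) <= 3
        assert [s.pos for s in clusters[-1]] == [60]


# ---------------------------------------------------------------------------
# allelotyping

def _window_for(ref, site, read, k=6):
    w = find_window(read, ref, site, k=k)
    assert w is not None
    return w


class TestAllelotype:
    def setup_method(self):
        self.ref = random_reference(400, seed=21)
        self.params = PairHmmParams.default()
        self.pos = 200
        self.ref_base = self.ref[self.pos]
        self.alt_base = "A" if self.ref_base != "A" else "C"
        self.site = _site(self.pos, self.ref_base, self.alt_base)

    def test_read_with_alt_base_calls_alt(self):
        seq = self.ref[:self.pos] + self.alt_base + self.ref[self.pos + 1:]
        read = _read(0, seq)
        w = _window_for(self.ref, self.site, read)
        call = allelotype(read, w, self.params)
        assert call is not None and call.allele == "alt"
        assert call.quality > 7.0

    def test_read_with_ref_base_calls_ref(self):
        read = _read(0, self.ref)
        w = _window_for(self.ref, self.site, read)
        call = allelotype(read, w, self.params)
        assert call is not None and call.allele == "ref"

    def test_equidistant_read_discarded(self):
        # a third base at the SNV mismatches ref and alt haplotypes equally:
        # p_ref == p_alt, quality -10 log10(1/2) ~= 3.01 < 7 -> discarded
        third = next(b for b in "ACGT" if b not in (self.ref_base, self.alt_base))
        seq = self.ref[:self.pos] + third + self.ref[self.pos + 1:]
        read = _read(0, seq)
        w = _window_for(self.ref, self.site, read)
        assert allelotype(read, w, self.params) is None

    def test_quality_formula_on_99_to_1_ratio(self):
        from phasecall.realign import _phred_from_logs
        q = _phred_from_logs(math.log(99.0), math.log(1.0))
        assert q == pytest.approx(20.0, abs=1e-9)
        q_tie = _phred_from_logs(0.0, 0.0)
        assert q_tie == pytest.approx(-10 * math.log10(0.5), abs=1e-9)

    def test_swapping_alleles_swaps_label_preserves_quality(self):
        seq = self.ref[:self.pos] + self.alt_base + self.ref[self.pos + 1:]
        read = _read(0, seq)
        w = _window_for(self.ref, self.site, read)
        call = allelotype(read, w, self.params)
        # a window whose reference haplotype carries the alt base and whose
        # "alt" is the true reference base: the roles swap exactly
        swapped_site = _site(self.pos, self.alt_base, self.ref_base)
        w2 = RealignmentWindow(w.chrom, w.start, w.end, [swapped_site],
                               w.query_start, w.query_end, w.query_seq,
                               w.haplotype([1]))
        call2 = allelotype(read, w2, self.params)
        assert call.allele == "alt" and call2.allele == "ref"
        assert call.quality == pytest.approx(call2.quality, rel=1e-12)


class TestAllelotypeCluster:
    def setup_method(self):
        self.ref = random_reference(400, seed=33)
        self.params = PairHmmParams.default()
        p1, p2 = 200, 204
        self.alt1 = "A" if self.ref[p1] != "A" else "C"
        self.alt2 = "A" if self.ref[p2] != "A" else "C"
        self.s1 = _site(p1, self.ref[p1], self.alt1)
        self.s2 = _site(p2, self.ref[p2], self.alt2)

    def test_ref_read_calls_ref_at_both(self):
        read = _read(0, self.ref)
        w = find_window(read, self.ref, [self.s1, self.s2])
        calls = allelotype_cluster(read, w, self.params)
        assert [c.allele for c in calls] == ["ref", "ref"]

    def test_marginal_equals_brute_force_over_four_haplotypes(self):
        seq = (self.ref[:200] + self.alt1 + self.ref[201:204]
               + self.ref[204] + self.ref[205:])
        read = _read(0, seq)
        w = find_window(read, self.ref, [self.s1, self.s2])
        calls = allelotype_cluster(read, w, self.params, band=500)
        # brute force: full forward against each of the 4 local haplotypes
        lps = {}
        for a1 in (0, 1):
            for a2 in (0, 1):
                lps[(a1, a2)] = forward_prob(w.query_seq,
                                             w.haplotype([a1, a2]), self.params)
        def lse(vals):
            mx = max(vals)
            return mx + math.log(sum(math.exp(v - mx) for v in vals))
        for s_idx in (0, 1):
            ref_lp = lse([lp for (g, lp) in lps.items() if g[s_idx] == 0])
            alt_lp = lse([lp for (g, lp) in lps.items() if g[s_idx] == 1])
            expect_allele = "ref" if ref_lp >= alt_lp else "alt"
            expect_q = -10 * (min(ref_lp, alt_lp) - lse([ref_lp, alt_lp])) / math.log(10)
            call = calls[s_idx]
            if expect_q < 7.0:
                assert call is None
            else:
                assert call.allele == expect_allele
                assert call.quality == pytest.approx(expect_q, rel=1e-9)

    def test_single_site_cluster_degenerates_to_allelotype(self):
        read = _read(0, self.ref)
        w = find_window(read, self.ref, [self.s1])
        single = allelotype(read, w, self.params)
        (clustered,) = allelotype_cluster(read, w, self.params)
        assert clustered.allele == single.allele
        assert clustered.quality == pytest.approx(single.quality, rel=1e-12)


# ---------------------------------------------------------------------------
# strand bias

def _calls(site, n_ref_fwd, n_ref_rev, n_alt_fwd, n_alt_rev):
    out = []
    for allele, strand, n in [("ref", "+", n_ref_fwd), ("ref", "-", n_ref_rev),
                              ("alt", "+", n_alt_fwd), ("alt", "-", n_alt_rev)]:
        out += [AlleleCall("r", site, allele, 20.0, strand) for _ in range(n)]
    return out


def oracle_fisher_two_tailed(a, b, c, d):
    """Exact two-tailed Fisher p: sum of hypergeometric probabilities of all
    tables with the same margins no more probable than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                         math.comb(n, c1)))

    obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= obs:
            total += pmf(x)
    return float(total)


class TestStrandBias:
    def setup_method(self):
        self.site = _site(0, "A", "G")

    def test_balanced_table_keeps(self):
        assert strand_bias_filter(self.site, _calls(self.site, 10, 10, 10, 10))

    def test_biased_table_filtered_and_matches_oracle(self):
        calls = _calls(self.site, 20, 20, 15, 0)
        p = oracle_fisher_two_tailed(20, 20, 15, 0)
        assert p < 0.01
        assert not strand_bias_filter(self.site, calls)

    def test_empty_table_keeps(self):
        assert strand_bias_filter(self.site, [])

    def test_cutoff_is_strict_inequality(self):
        from scipy.stats import fisher_exact
        calls = _calls(self.site, 12, 4, 3, 9)
        _, p = fisher_exact([[12, 4], [3, 9]], alternative="two-sided")
        assert strand_bias_filter(self.site, calls, alpha=p)        # p < p false
        assert not strand_bias_filter(self.site, calls, alpha=p * 1.001)

    def test_scipy_matches_hypergeometric_oracle(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(4)
        tables = [(20, 20, 15, 0), (10, 10, 10, 10), (5, 0, 0, 5), (3, 7, 8, 2)]
        tables += [tuple(int(x) for x in rng.integers(0, 25, size=4))
                   for _ in range(40)]
        for a, b, c, d in tables:
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert abs(p - oracle_fisher_two_tailed(a, b, c, d)) < 1e-12
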