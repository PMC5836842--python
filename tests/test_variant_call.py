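import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from ampliseq.panel import CallerConfig
from ampliseq.reads import AlignedRead, code_base
from ampliseq.variant_call import (PileupColumn, build_pileup, call_pileup,
                                   call_site, left_align_del, left_align_ins,
                                   recurrent_artifact_filter, strand_bias_test,
                                   VariantCall)


def make_read(rid, start, seq, strand="+", cigar=None):
    cigar = cigar or [("M", len(seq))]
    qlen = sum(n for op, n in cigar if op in "MI")
    return AlignedRead(rid, start, strand, seq, np.full(qlen, 30, dtype=np.int16), cigar)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric tail enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    kmin, kmax = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(kmin, kmax + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestLeftAlignment:
    def test_insertion_in_run_shifts_left(self):
        ref = "GGAAAAC"
        anchor, ins = left_align_ins(ref, 5, "A")  # ins A after last run A
        assert (anchor, ins) == (1, "A")

    def test_deletion_in_run_shifts_left(self):
        ref = "GGAAAAC"
        assert left_align_del(ref, 4, 1) == 1

    def test_non_repeat_indel_stays(self):
        ref = "GACTG"
        assert left_align_ins(ref, 2, "T") == (2, "T")
        assert left_align_del(ref, 1, 2) == 1


class TestBuildPileup:
    def test_uniform_reference_column(self, panel):
        seq = panel.reference.sequence
        reads = [make_read(f"r{i}", 500, seq[500:600]) for i in range(10)]
        pileup = build_pileup(reads, panel)
        col = pileup.column(550)
        assert col.sub_counts == {seq[550]: [10, 0]}
        assert col.depth == 10

    def test_strand_split_counts(self, panel):
        seq = panel.reference.sequence
        pos = 700
        ref_base = seq[pos]
        alt = "T" if ref_base != "T" else "G"
        reads = []
        for i, (has_alt, strand) in enumerate(
                [(True, "+")] * 3 + [(True, "-")] * 3 + [(False, "+")] * 2 + [(False, "-")] * 2):
            s = seq[650:750]
            if has_alt:
                s = s[:50] + alt + s[51:]
            reads.append(make_read(f"r{i}", 650, s, strand))
        pileup = build_pileup(reads, panel)
        col = pileup.column(pos)
        assert col.sub_counts[alt] == [3, 3]
        assert col.sub_counts[ref_base] == [2, 2]

    def test_counts_match_naive_recount(self, panel, rng):
        """Pileup equals a per-read brute-force recount on random reads."""
        seq = panel.reference.sequence
        reads = []
        for i in range(50):
            start = int(rng.integers(100, 8000))
            length = int(rng.integers(80, 250))
            bases = list(seq[start:start + length])
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, length))
                bases[p] = "ACGT"[rng.integers(0, 4)]
            reads.append(make_read(f"r{i:02d}", start, "".join(bases),
                                   "+" if rng.random() < 0.5 else "-"))
        pileup = build_pileup(reads, panel)
        # naive recount at 40 random positions
        for pos in rng.integers(100, 8200, size=40):
            pos = int(pos)
            counts = {}
            for r in reads:
                if r.ref_start <= pos < r.ref_end:
                    base = r.seq[pos - r.ref_start]
                    sidx = 0 if r.strand == "+" else 1
                    counts.setdefault(base, [0, 0])[sidx] += 1
            col = pileup.column(pos)
            assert col.sub_counts == counts

    def test_read_order_permutation_invariant(self, panel, sim_sample, config):
        reads, _ = sim_sample
        sample = reads[:400]
        calls_fwd = call_pileup(build_pileup(sample, panel, config), config)
        calls_rev = call_pileup(build_pileup(sample[::-1], panel, config), config)
        key = lambda c: (c.pos, c.ref, c.alt, frozenset(c.filters))
        assert sorted(map(key, calls_fwd)) == sorted(map(key, calls_rev))


def column(ref_base, alt, ref_f, ref_r, alt_f, alt_r):
    return PileupColumn(
        pos=100, ref_base=ref_base,
        sub_counts={ref_base: [ref_f, ref_r], alt: [alt_f, alt_r]},
        depth_fwd=ref_f + alt_f, depth_rev=ref_r + alt_r, ref_context=ref_base)


class TestCallSite:
    def test_one_strand_below_depth_flagged(self, config):
        col = column("C", "T", 7, 50, 7, 50)  # fwd depth 14, rev 100
        calls = call_site(col, config)
        (call,) = calls
        assert "low_depth" in call.filters and not call.is_pass

    def test_vaf_just_below_threshold_flagged(self, config):
        col = column("C", "T", 41, 40, 10, 9)  # vaf 19/100
        (call,) = call_site(col, config)
        assert call.vaf == pytest.approx(0.19)
        assert call.filters == {"low_vaf"}

    def test_balanced_het_passes(self, config):
        col = column("C", "T", 25, 25, 25, 25)
        (call,) = call_site(col, config)
        assert call.is_pass and call.vaf == pytest.approx(0.5)

    def test_multiallelic_ordered_by_count_then_allele(self, config):
        col = PileupColumn(
            pos=10, ref_base="A",
            sub_counts={"A": [30, 30], "C": [10, 10], "G": [10, 10], "T": [15, 15]},
            depth_fwd=65, depth_rev=65, ref_context="A")
        calls = call_site(col, config)
        assert [c.alt for c in calls] == ["T", "C", "G"]


class TestStrandBias:
    def test_one_sided_alt_flagged(self, config):
        p, flagged = strand_bias_test(50, 50, 20, 0, config)
        assert flagged
        assert p == pytest.approx(fisher_two_sided_oracle(50, 50, 20, 0), rel=1e-6)

    def test_symmetric_table_not_flagged(self, config):
        p, flagged = strand_bias_test(50, 50, 10, 10, config)
        assert p == pytest.approx(1.0)
        assert not flagged

    def test_small_table_above_threshold_not_flagged(self, config):
        p, flagged = strand_bias_test(5, 5, 1, 0, config)
        assert not flagged
        assert p > config.strand_bias_p

    def test_degenerate_margin_gives_p_one(self, config):
        p, flagged = strand_bias_test(0, 0, 10, 0, config)
        assert (p, flagged) == (1.0, False)

    @settings(max_examples=80, derandomize=True)
    @given(a=st.integers(0, 12), b=st.integers(0, 12),
           c=st.integers(0, 12), d=st.integers(0, 12))
    def test_p_matches_enumeration_oracle(self, config, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p, _ = strand_bias_test(a, b, c, d, config)
        assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-6, abs=1e-12)


def fake_call(pos, ref, alt, vaf, depth=100, sample=None, filters=()):
    alt_n = int(round(vaf * depth))
    return VariantCall(pos, ref, alt, depth // 2, depth - depth // 2,
                       alt_n // 2, alt_n - alt_n // 2, set(filters), sample=sample)


class TestRecurrentArtifactFilter:
    def test_recurrent_low_vaf_blacklisted(self, config):
        calls = {f"S{i}": [fake_call(500, "CT", "C", 0.10, filters=["low_vaf"])]
                 for i in range(9)}
        calls["S9"] = []
        blacklist, filtered = recurrent_artifact_filter(calls, config)
        assert (500, "CT", "C") in blacklist
        assert all("recurrent_artifact" in c.filters
                   for cs in filtered.values() for c in cs)

    def test_true_variant_not_blacklisted(self, config):
        calls = {f"S{i}": [] for i in range(10)}
        calls["S0"] = [fake_call(600, "C", "T", 0.5)]
        calls["S1"] = [fake_call(600, "C", "T", 0.5)]
        blacklist, _ = recurrent_artifact_filter(calls, config)
        assert blacklist == set()

    def test_fewer_than_three_samples_skipped_with_warning(self, config):
        calls = {"S0": [fake_call(1, "CT", "C", 0.1)], "S1": []}
        with pytest.warns(UserWarning, match="fewer than 3"):
            blacklist, _ = recurrent_artifact_filter(calls, config)
        assert blacklist == set()

    def test_static_blacklist_unioned(self, config):
        calls = {f"S{i}": [] for i in range(4)}
        blacklist, _ = recurrent_artifact_filter(calls, config,
                                                 static_blacklist={(7, "A", "AT")})
        assert (7, "A", "AT") in blacklist


class TestMonotonicity:
    def test_raising_min_vaf_never_adds_pass_calls(self, panel, sim_sample):
        reads, _ = sim_sample
        strict = CallerConfig(min_vaf=0.35)
        loose = CallerConfig(min_vaf=0.20)
        pileup = build_pileup(reads, panel, loose)
        pass_loose = {c.key for c in call_pileup(pileup, loose) if c.is_pass}
        pass_strict = {c.key for c in call_pileup(pileup, strict) if c.is_pass}
        assert pass_strict <= pass_loose
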