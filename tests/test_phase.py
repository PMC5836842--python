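import pytest

from ampliseq.errors import PhaseInconsistencyError
from ampliseq.phase import (CIS, TRANS, UNKNOWN, PhaseEvidence,
                            assemble_genotype, classify_phase,
                            collect_phase_evidence, read_allele_support)
from ampliseq.variant_call import VariantCall


def call_at(pos, ref, alt, name=None, vaf=0.5):
    depth = 200
    alt_n = int(vaf * depth)
    c = VariantCall(pos, ref, alt, 100, 100, alt_n // 2, alt_n - alt_n // 2)
    c.name = name
    return c


class TestClassifyPhase:
    def test_cis_pattern(self):
        ev = PhaseEvidence(both_alt=40, alt1_only=1, alt2_only=0, both_ref=45)
        assert classify_phase(ev) == CIS

    def test_trans_pattern(self):
        ev = PhaseEvidence(both_alt=1, alt1_only=30, alt2_only=28, both_ref=0)
        assert classify_phase(ev) == TRANS

    def test_all_zero_unknown(self):
        assert classify_phase(PhaseEvidence()) == UNKNOWN

    def test_contradiction_rate_blocks_cis(self):
        ev = PhaseEvidence(both_alt=40, alt1_only=20, alt2_only=0, both_ref=40)
        assert classify_phase(ev) == UNKNOWN


class TestCollectEvidence:
    def test_different_amplicons_no_covering_reads(self, panel, sim_sample):
        reads, _ = sim_sample
        c1 = call_at(2933, "C", "T")       # A12 insert
        c2 = call_at(5407, "GT", "G")      # A21 insert
        ev = collect_phase_evidence(reads, c1, c2, panel.reference.sequence)
        assert ev.total == 0

    def test_tallies_match_per_read_inspection(self, panel, placements, sim_sample):
        """Evidence equals a naive per-read haplotype inspection."""
        reads, _ = sim_sample
        ref_seq = panel.reference.sequence
        c1 = call_at(*placements["L467F"], name="L467F")
        c2 = call_at(*placements["F508del"], name="F508del")
        ev = collect_phase_evidence(reads, c1, c2, ref_seq)

        def oracle_snv(read, pos, ref, alt):
            qpos, rpos = 0, read.ref_start
            for op, n in read.cigar:
                if op == "M":
                    if rpos <= pos < rpos + n:
                        ch = read.seq[qpos + pos - rpos]
                        return "alt" if ch == alt else ("ref" if ch == ref else "other")
                    qpos += n
                    rpos += n
                elif op == "I":
                    qpos += n
                else:
                    rpos += n
            return None

        def oracle_del(read, anchor, length):
            if not (read.ref_start <= anchor and anchor + length + 1 <= read.ref_end):
                return None
            rpos = read.ref_start
            for op, n in read.cigar:
                if op == "D":
                    if rpos == anchor + 1 and n == length:
                        return "alt"
                    if anchor < rpos + n and rpos <= anchor + length:
                        return "other"
                if op in "MD":
                    rpos += n
            return "ref"

        counts = {"aa": 0, "ar": 0, "ra": 0, "rr": 0}
        for r in reads:
            s1 = oracle_snv(r, c1.pos, c1.ref, c1.alt)
            s2 = oracle_del(r, c2.pos, len(c2.ref) - 1)
            if s1 == "alt" and s2 == "alt":
                counts["aa"] += 1
            elif s1 == "alt" and s2 == "ref":
                counts["ar"] += 1
            elif s1 == "ref" and s2 == "alt":
                counts["ra"] += 1
            elif s1 == "ref" and s2 == "ref":
                counts["rr"] += 1
        assert (ev.both_alt, ev.alt1_only, ev.alt2_only, ev.both_ref) == (
            counts["aa"], counts["ar"], counts["ra"], counts["rr"])

    def test_planted_cis_pair_classified_cis(self, panel, placements, sim_sample):
        reads, _ = sim_sample
        ref_seq = panel.reference.sequence
        ev = collect_phase_evidence(
            reads, call_at(*placements["L467F"]), call_at(*placements["F508del"]), ref_seq)
        assert classify_phase(ev) == CIS
        assert ev.both_alt > 20 and ev.both_ref > 20


class TestAssembleGenotype:
    def setup_method(self):
        from ampliseq import fixtures
        cat = fixtures.default_catalog()
        self.cdna = {e.name: e.cdna_name for e in cat}
        self.status = {e.name: e.status for e in cat}

    def _assemble(self, calls, phases, **kw):
        return assemble_genotype(calls, phases, cdna_of=self.cdna,
                                 status_of=self.status, **kw)

    def test_cis_pair_plus_trans_singleton_formats_as_published(self):
        calls = [call_at(3000, "GCTT", "G", "F508del"),
                 call_at(2933, "C", "T", "L467F"),
                 call_at(5407, "GT", "G", "2143delT")]
        phases = {frozenset(("F508del", "L467F")): CIS,
                  frozenset(("F508del", "2143delT")): TRANS,
                  frozenset(("L467F", "2143delT")): TRANS}
        record = self._assemble(calls, phases)
        assert record.resolved
        assert record.hgvs == "c.[2012delT];[1521_1523delCTT;1399C>T]"

    def test_three_mutually_trans_variants_inconsistent(self):
        calls = [call_at(10, "A", "C", "x"), call_at(20, "A", "C", "y"),
                 call_at(30, "A", "C", "z")]
        phases = {frozenset(p): TRANS
                  for p in (("x", "y"), ("y", "z"), ("x", "z"))}
        with pytest.raises(PhaseInconsistencyError):
            self._assemble(calls, phases)

    def test_cis_and_trans_for_same_pair_inconsistent(self):
        calls = [call_at(10, "A", "C", "x"), call_at(20, "A", "C", "y"),
                 call_at(30, "A", "C", "z")]
        phases = {frozenset(("x", "y")): CIS, frozenset(("y", "z")): CIS,
                  frozenset(("x", "z")): TRANS}
        with pytest.raises(PhaseInconsistencyError):
            self._assemble(calls, phases)

    def test_external_cnv_fills_second_slot_with_unknown_phase(self):
        calls = [call_at(1006, "G", "A", "E92K")]
        record = self._assemble(calls, {}, external_cnv=["ex2,3del"])
        assert record.hgvs == "c.[274G>A](;)[54-5940_273+10250del21kb]"

    def test_homozygous_variant_fills_both_slots(self):
        record = self._assemble([call_at(1006, "G", "A", "E92K", vaf=0.97)], {})
        assert record.resolved
        assert record.hgvs == "c.[274G>A];[274G>A]"

    def test_assembly_invariant_to_call_order(self):
        calls = [call_at(3000, "GCTT", "G", "F508del"),
                 call_at(2933, "C", "T", "L467F"),
                 call_at(5407, "GT", "G", "2143delT")]
        phases = {frozenset(("F508del", "L467F")): CIS,
                  frozenset(("F508del", "2143delT")): TRANS,
                  frozenset(("L467F", "2143delT")): TRANS}
        a = self._assemble(calls, phases)
        b = self._assemble(calls[::-1], phases)
        assert a.hgvs == b.hgvs and a.allele_lists == b.allele_lists
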