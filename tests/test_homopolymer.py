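import numpy as np
import pytest

from ampliseq.fixtures import planted_hp_site
from ampliseq.homopolymer import (LengthSpectrum, call_homopolymer_variant,
                                  length_spectrum, observed_run_length,
                                  offset_discriminable)
from ampliseq.panel import CallerConfig, HomopolymerSite


def spectrum_from_counts(site, counts):
    spec = LengthSpectrum(site)
    for length, n in counts.items():
        spec.counts[length] = [n - n // 2, n // 2]
        spec.total += n
    return spec


SITE = HomopolymerSite(100, 107, "A")  # an (A)7 run


class TestSpectrum:
    def test_frequency_arithmetic(self):
        spec = spectrum_from_counts(SITE, {7: 80, 8: 4, 6: 10, 5: 6})
        assert spec.total == 100
        assert spec.freq(8) == pytest.approx(0.04)

    def test_all_reference_length(self):
        spec = spectrum_from_counts(SITE, {7: 100})
        assert spec.freq(8) == 0.0

    def test_matches_stringwalk_oracle_on_simulated_reads(self, panel, sim_sample):
        """Spectrum equals a cigar-walking per-read recount."""
        reads, _ = sim_sample
        site = planted_hp_site(panel)
        informative = [r for r in reads if r.amplicon_id == "A16"][:50]
        spec = length_spectrum(informative, site)

        def oracle_run_length(read):
            # independent reconstruction: walk the cigar, build the aligned
            # string between the two flank columns, take the longest A-run
            left, right = site.start - 1, site.end
            if read.ref_start > left or read.ref_end <= right:
                return None
            qpos = 0
            rpos = read.ref_start
            out = []
            for op, n in read.cigar:
                if op == "M":
                    for k in range(n):
                        if left <= rpos <= right:
                            out.append(read.seq[qpos])
                        qpos += 1
                        rpos += 1
                elif op == "I":
                    if left <= rpos - 1 < right:
                        out.append(read.seq[qpos:qpos + n])
                    qpos += n
                else:
                    rpos += n
            segment = "".join(out)
            best = run = 0
            for ch in segment:
                run = run + 1 if ch == site.base else 0
                best = max(best, run)
            return best

        expected = {}
        total = 0
        for r in informative:
            length = oracle_run_length(r)
            assert length == observed_run_length(r, site)
            if length is not None:
                expected[length] = expected.get(length, 0) + 1
                total += 1
        assert {k: spec.count(k) for k in sorted(spec.counts)} == dict(sorted(expected.items()))
        assert spec.total == total

    def test_non_spanning_reads_excluded(self, panel):
        site = planted_hp_site(panel)
        from ampliseq.reads import AlignedRead
        # read ends inside the run: not informative
        seq = panel.reference.sequence[site.start - 10:site.start + 3]
        read = AlignedRead("r", site.start - 10, "+", seq,
                           np.full(len(seq), 30, dtype=np.int16), [("M", len(seq))])
        assert observed_run_length(read, site) is None
        assert length_spectrum([read], site).total == 0


class TestCarrierCall:
    def test_published_minimum_carrier_called(self, config, panel):
        spec = spectrum_from_counts(SITE, {7: 336, 8: 64})  # freq(8)=0.16
        res = call_homopolymer_variant(spec, config, panel.reference.sequence[:200])
        assert res.status == "carrier"
        (call,) = res.calls
        assert call.kind == "ins" and call.alt.endswith("A")
        assert call.annotations["hp_freq"] == pytest.approx(0.16)

    def test_published_noncarrier_maximum_not_called(self, config):
        spec = spectrum_from_counts(SITE, {7: 368, 8: 32})  # freq(8)=0.08
        res = call_homopolymer_variant(spec, config)
        assert res.status == "reference"

    def test_zero_frequency_not_called(self, config):
        spec = spectrum_from_counts(SITE, {7: 400})
        assert call_homopolymer_variant(spec, config).status == "reference"

    def test_insufficient_depth_no_call(self, config):
        spec = spectrum_from_counts(SITE, {7: 20, 8: 5})
        res = call_homopolymer_variant(spec, config)
        assert res.status == "no_call"

    def test_minus_one_baseline_stutter_not_called(self, config):
        """The pervasive 15% deletion stutter never reaches significance at
        its own baseline rate, so sitting above the 10% threshold alone does
        not produce a deletion carrier."""
        spec = spectrum_from_counts(SITE, {7: 340, 6: 60})  # freq(6)=0.15
        res = call_homopolymer_variant(spec, config)
        assert res.calls == []
        assert 6 in res.non_discriminable
        assert not offset_discriminable(-1, 10_000, config)

    def test_strong_deletion_excess_is_callable(self, config, panel):
        """A genuine deletion carrier stands out even against 15% stutter."""
        spec = spectrum_from_counts(SITE, {7: 200, 6: 200})  # freq(6)=0.5
        res = call_homopolymer_variant(spec, config, panel.reference.sequence[:200])
        assert res.status == "carrier"
        assert res.calls[0].kind == "del"

    def test_power_degrades_at_depth_50(self, config):
        """The same 14% signal calls at depth 500 but not at depth 50."""
        assert offset_discriminable(1, 500, config)
        assert not offset_discriminable(1, 50, config)
        weak = spectrum_from_counts(SITE, {7: 43, 8: 7})      # 14% at depth 50
        res = call_homopolymer_variant(weak, config)
        assert res.calls == [] and 8 in res.non_discriminable
        strong = spectrum_from_counts(SITE, {7: 430, 8: 70})  # 14% at depth 500
        res2 = call_homopolymer_variant(strong, config)
        assert res2.status == "carrier"


class TestSeparationInvariant:
    def test_carriers_and_noncarriers_separate_at_depth_200(self, panel, placements):
        from ampliseq.panel import Panel
        from ampliseq.simulate import PlantedVariant, SimGenotype, SimProfile, simulate_reads
        site = planted_hp_site(panel)
        sub = Panel(panel.reference, [panel.get("A16")])
        carrier_freqs, noncarrier_freqs = [], []
        for seed in range(12):
            profile = SimProfile(reads_per_amplicon=220)
            gt = SimGenotype([PlantedVariant("2184insA", *placements["2184insA"])])
            reads, _ = simulate_reads(sub, gt, profile, seed=seed)
            carrier_freqs.append(length_spectrum(reads, site).freq(8))
            reads0, _ = simulate_reads(sub, SimGenotype([]), profile, seed=1000 + seed)
            noncarrier_freqs.append(length_spectrum(reads0, site).freq(8))
        assert min(carrier_freqs) > 0.10
        assert max(noncarrier_freqs) < 0.10
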