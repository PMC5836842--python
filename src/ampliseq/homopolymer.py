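"""Allele-length spectra and carrier discrimination at homopolymer runs.

Flow-based sequencing miscounts mononucleotide run lengths, so a length
variant inside a run (e.g. a single-A duplication in an (A)7 tract) cannot be
trusted to the generic indel path: every sample shows a background of
run-length stutter.  Instead, the observed run-length spectrum is tallied
from reads that fully span the run plus one anchored flank on each side, and
a carrier is called when the frequency of a non-reference length clears the
``hp_carrier_threshold`` (default 0.10 — the midpoint of the gap between the
observed 8% non-carrier maximum and the 16% carrier minimum).

Because stutter is a *rate*, not an anomaly, clearing the frequency
threshold is not by itself evidence of a carrier: at moderate depth the 4%
(+1) background fluctuates past 10% often enough to matter across many
sites and samples.  A carrier call therefore also requires the observed
count to be statistically inconsistent with the offset's baseline stutter
rate (one-sided exact binomial test at ``hp_stutter_alpha``).  Under the
default priors the pervasive -1 offset (15% background) can never reach
significance at its own baseline, mirroring the fact that the +1
duplication allele is the one the frequency rule resolves in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import binom

from .panel import CallerConfig, HomopolymerSite
from .reads import AlignedRead, code_base
from .variant_call import FILTER_LOW_DEPTH, VariantCall


@dataclass
class LengthSpectrum:
    site: HomopolymerSite
    counts: dict = field(default_factory=dict)  # run length -> [fwd, rev]
    total: int = 0

    def count(self, length: int) -> int:
        return sum(self.counts.get(length, (0, 0)))

    def freq(self, length: int) -> float:
        return self.count(length) / self.total if self.total else 0.0

    def strand_counts(self, length: int) -> tuple[int, int]:
        f, r = self.counts.get(length, (0, 0))
        return int(f), int(r)


@dataclass
class HpCallResult:
    spectrum: LengthSpectrum
    calls: list = field(default_factory=list)           # carrier VariantCalls
    non_discriminable: list = field(default_factory=list)  # lengths skipped
    flags: set = field(default_factory=set)

    @property
    def status(self) -> str:
        if FILTER_LOW_DEPTH in self.flags:
            return "no_call"
        return "carrier" if self.calls else "reference"


def observed_run_length(read: AlignedRead, site: HomopolymerSite) -> int | None:
    """Run length of ``site.base`` between the anchored flanks, or None.

    A read is informative only when it spans the run plus one base on each
    side with countable (unmasked, undeleted is not required — deletions
    shorten the run) flanks.
    """
    left, right = site.start - 1, site.end  # flank positions
    if read.ref_start > left or read.ref_end <= right:
        return None
    codes = read.projected_codes()
    off = read.ref_start
    if codes[left - off] == 0 or codes[right - off] == 0:
        return None
    ins = {a: s for a, s in read.insertions()}
    chars = []
    for pos in range(left, right + 1):
        code = int(codes[pos - off])
        if code == 0:
            return None  # masked interior
        if 1 <= code <= 4:
            chars.append(code_base(code))
        if pos < right and pos in ins:
            chars.append(ins[pos])
    segment = "".join(chars)
    best = run = 0
    for ch in segment:
        run = run + 1 if ch == site.base else 0
        best = max(best, run)
    return best


def length_spectrum(reads: list[AlignedRead], site: HomopolymerSite) -> LengthSpectrum:
    spectrum = LengthSpectrum(site)
    for read in reads:
        length = observed_run_length(read, site)
        if length is None:
            continue
        pair = spectrum.counts.setdefault(length, [0, 0])
        pair[0 if read.strand == "+" else 1] += 1
        spectrum.total += 1
    return spectrum


def stutter_excess_p(count: int, depth: int, offset: int,
                     config: CallerConfig) -> float:
    """One-sided exact binomial p for an excess over the stutter prior."""
    rate = float(config.hp_stutter_rates.get(offset, 0.0))
    if depth <= 0:
        return 1.0
    return float(binom.sf(count - 1, depth, rate))


def offset_discriminable(offset: int, depth: int, config: CallerConfig) -> bool:
    """Can a frequency at the carrier threshold reach significance here?

    False for the -1 offset at any depth under the default priors (its 15%
    baseline exceeds the 10% threshold) and for any offset at depths too
    low for the threshold count to stand out from the stutter background.
    """
    k = math.ceil(config.hp_carrier_threshold * depth)
    return stutter_excess_p(k, depth, offset, config) < config.hp_stutter_alpha


def call_homopolymer_variant(
    spectrum: LengthSpectrum,
    config: CallerConfig,
    ref_seq: str | None = None,
    sample: str | None = None,
) -> HpCallResult:
    """Carrier discrimination by allele-length frequency.

    Requires spectrum depth of at least ``2 * min_strand_depth``; emits one
    anchored insertion/deletion call per non-reference length whose frequency
    clears the threshold and whose count is significantly above the stutter
    background for that offset.
    """
    result = HpCallResult(spectrum)
    site = spectrum.site
    if spectrum.total < 2 * config.min_strand_depth:
        result.flags.add(FILTER_LOW_DEPTH)
        return result
    anchor = site.start - 1
    anchor_base = ref_seq[anchor] if ref_seq else "N"
    for length in sorted(spectrum.counts):
        if length == site.ref_run_length:
            continue
        freq = spectrum.freq(length)
        if freq < config.hp_carrier_threshold:
            continue
        offset = length - site.ref_run_length
        excess_p = stutter_excess_p(spectrum.count(length), spectrum.total,
                                    offset, config)
        if excess_p >= config.hp_stutter_alpha:
            result.non_discriminable.append(length)
            continue
        af, ar = spectrum.strand_counts(length)
        if offset > 0:
            ref_allele, alt_allele = anchor_base, anchor_base + site.base * offset
        else:
            ref_allele, alt_allele = anchor_base + site.base * (-offset), anchor_base
        result.calls.append(VariantCall(
            pos=anchor, ref=ref_allele, alt=alt_allele,
            fwd_depth=sum(v[0] for v in spectrum.counts.values()),
            rev_depth=sum(v[1] for v in spectrum.counts.values()),
            alt_fwd=af, alt_rev=ar, filters=set(), sample=sample, hp_call=True,
            annotations={"hp_freq": freq, "hp_length": length,
                         "hp_excess_p": excess_p},
        ))
    return result


def hp_calls_for_sample(
    reads: list[AlignedRead],
    sites: list[HomopolymerSite],
    config: CallerConfig,
    ref_seq: str,
    sample: str | None = None,
) -> tuple[list[VariantCall], dict[HomopolymerSite, HpCallResult]]:
    calls, results = [], {}
    for site in sites:
        spectrum = length_spectrum(reads, site)
        res = call_homopolymer_variant(spectrum, config, ref_seq, sample)
        results[site] = res
        calls.extend(res.calls)
    return calls, results
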