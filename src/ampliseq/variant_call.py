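"""Pileup construction and threshold-based variant calling.

The caller is deliberately model-free, mirroring the published protocol: an
alternate allele is PASS iff the site is covered by at least
``min_strand_depth`` usable reads on *each* strand, the allele fraction is at
least ``min_vaf``, the allele shows no significant strand bias (two-sided
Fisher exact, plus a 5x strand-ratio band), and the site is not owned by the
homopolymer caller.  Sub-threshold alleles are still emitted, flagged — the
cross-sample recurrent-artifact filter needs them.

Usable depth excludes masked (primer) bases and respects a deterministic
per-strand depth cap applied in read-id order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .panel import CallerConfig, HomopolymerSite, Panel, find_homopolymers
from .reads import AlignedRead, base_code, code_base

FILTER_LOW_DEPTH = "low_depth"
FILTER_LOW_VAF = "low_vaf"
FILTER_STRAND_BIAS = "strand_bias"
FILTER_RECURRENT = "recurrent_artifact"
FILTER_HP_ADJACENT = "hp_adjacent"


def left_align_ins(ref: str, anchor: int, ins: str) -> tuple[int, str]:
    """Shift an insertion (after ``anchor``) to its leftmost equivalent."""
    while anchor >= 0 and ins[-1] == ref[anchor]:
        ins = ref[anchor] + ins[:-1]
        anchor -= 1
    return anchor, ins


def left_align_del(ref: str, anchor: int, length: int) -> int:
    """Shift a deletion of ``ref[anchor+1:anchor+1+length]`` leftmost."""
    while anchor >= 1 and anchor + length < len(ref) and ref[anchor] == ref[anchor + length]:
        anchor -= 1
    return anchor


@dataclass
class VariantCall:
    pos: int            # 0-based anchor position
    ref: str            # VCF-style alleles (indels carry the anchor base)
    alt: str
    fwd_depth: int
    rev_depth: int
    alt_fwd: int
    alt_rev: int
    filters: set[str] = field(default_factory=set)
    p_strand_bias: float = 1.0
    sample: str | None = None
    name: str | None = None      # catalog name once annotated
    hp_call: bool = False        # emitted by the homopolymer caller
    annotations: dict = field(default_factory=dict)

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "snv"
        return "del" if len(self.ref) > len(self.alt) else "ins"

    @property
    def depth(self) -> int:
        return self.fwd_depth + self.rev_depth

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def is_pass(self) -> bool:
        return not self.filters

    @property
    def key(self) -> tuple:
        return (self.pos, self.ref, self.alt)


@dataclass
class PileupColumn:
    """Per-position allele counts split by strand.

    ``sub_counts`` includes the reference base; indels are keyed on this
    column as their left-aligned anchor.  ``ref_context`` carries the
    downstream reference bases needed to spell deletion alleles.
    """

    pos: int
    ref_base: str
    sub_counts: dict = field(default_factory=dict)   # base -> [fwd, rev]
    ins_counts: dict = field(default_factory=dict)   # inserted seq -> [fwd, rev]
    del_counts: dict = field(default_factory=dict)   # length -> [fwd, rev]
    depth_fwd: int = 0
    depth_rev: int = 0
    ref_context: str = ""

    @property
    def depth(self) -> int:
        return self.depth_fwd + self.depth_rev


class Pileup:
    """Strand-split base counts over the reference, post-mask, post-cap."""

    def __init__(self, ref_seq: str, config: CallerConfig | None = None):
        self.ref_seq = ref_seq
        self.config = config or CallerConfig()
        L = len(ref_seq)
        self.counts = np.zeros((2, 6, L), dtype=np.int32)  # [strand][code][pos]
        self.ins_counts: dict[tuple[int, str], list[int]] = {}
        self.del_counts: dict[tuple[int, int], list[int]] = {}

    # strand index: 0 = forward, 1 = reverse
    def add_reads(self, reads: list[AlignedRead]) -> None:
        cap = self.config.max_depth
        depth_seen = np.zeros((2, len(self.ref_seq)), dtype=np.int32)
        for read in sorted(reads, key=lambda r: r.id):
            s = 0 if read.strand == "+" else 1
            rs, re_ = read.ref_span
            codes = read.projected_codes()
            allowed = depth_seen[s, rs:re_] < cap
            sel = (codes > 0) & allowed
            if sel.any():
                np.add.at(self.counts[s], (codes[sel], np.nonzero(sel)[0] + rs), 1)
                depth_seen[s, rs:re_] += sel
            for anchor, ins in read.insertions():
                if rs <= anchor < re_ and sel[anchor - rs]:
                    a, seq = left_align_ins(self.ref_seq, anchor, ins)
                    self.ins_counts.setdefault((a, seq), [0, 0])[s] += 1
            for anchor, length in read.deletions():
                if rs <= anchor < re_ and sel[anchor - rs]:
                    a = left_align_del(self.ref_seq, anchor, length)
                    self.del_counts.setdefault((a, length), [0, 0])[s] += 1

    def depth_at(self, pos: int) -> tuple[int, int]:
        col = self.counts[:, 1:6, pos].sum(axis=1)
        return int(col[0]), int(col[1])

    def column(self, pos: int) -> PileupColumn:
        ref_base = self.ref_seq[pos]
        subs = {}
        for code in range(1, 5):
            f, r = int(self.counts[0, code, pos]), int(self.counts[1, code, pos])
            if f or r:
                subs[code_base(code)] = [f, r]
        ins = {seq: list(c) for (a, seq), c in self.ins_counts.items() if a == pos}
        dels = {length: list(c) for (a, length), c in self.del_counts.items() if a == pos}
        df, dr = self.depth_at(pos)
        max_del = max(dels, default=0)
        return PileupColumn(
            pos=pos, ref_base=ref_base, sub_counts=subs, ins_counts=ins,
            del_counts=dels, depth_fwd=df, depth_rev=dr,
            ref_context=self.ref_seq[pos:pos + max_del + 1],
        )

    def candidate_positions(self) -> list[int]:
        """Positions with an emittable non-reference allele."""
        cfg = self.config
        ref_codes = np.frombuffer(self.ref_seq.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        for b in "ACGT":
            lut[ord(b)] = base_code(b)
        ref_codes = lut[ref_codes]
        totals = self.counts.sum(axis=0)  # [code][pos]
        alt_any = np.zeros(len(self.ref_seq), dtype=bool)
        for code in range(1, 5):
            alt_any |= (totals[code] >= cfg.min_emit_count) & (ref_codes != code)
        pos = set(np.nonzero(alt_any)[0].tolist())
        pos.update(a for (a, _), c in self.ins_counts.items() if sum(c) >= cfg.min_emit_count)
        pos.update(a for (a, _), c in self.del_counts.items() if sum(c) >= cfg.min_emit_count)
        return sorted(pos)


def build_pileup(reads: list[AlignedRead], panel: Panel,
                 config: CallerConfig | None = None) -> Pileup:
    pileup = Pileup(panel.reference.sequence, config)
    pileup.add_reads(reads)
    return pileup


def strand_bias_test(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int,
                     config: CallerConfig) -> tuple[float, bool]:
    """Two-sided Fisher exact on the ref/alt x strand table.

    The flag requires both significance and an alt strand ratio outside
    ``[1/strand_bias_ratio, strand_bias_ratio]``; a degenerate table (any
    zero margin) yields p=1 and no flag.
    """
    if (ref_fwd + ref_rev == 0 or alt_fwd + alt_rev == 0
            or ref_fwd + alt_fwd == 0 or ref_rev + alt_rev == 0):
        return 1.0, False
    _, p = fisher_exact([[ref_fwd, ref_rev], [alt_fwd, alt_rev]], alternative="two-sided")
    r = config.strand_bias_ratio
    if alt_rev == 0:
        ratio = float("inf")
    else:
        ratio = alt_fwd / alt_rev
    skewed = ratio > r or ratio < 1.0 / r
    return float(p), bool(p < config.strand_bias_p and skewed)


def call_site(column: PileupColumn, config: CallerConfig,
              hp_windows: list[tuple[int, int]] | None = None,
              sample: str | None = None) -> list[VariantCall]:
    """Emit every allele with >= ``min_emit_count`` supporting reads.

    PASS requires per-strand depth, VAF and strand-balance thresholds;
    sub-threshold alleles carry the corresponding failure flags.  Indels
    anchored inside a homopolymer window are flagged ``hp_adjacent`` — the
    length-spectrum caller owns those sites.
    """
    hp_windows = hp_windows or []
    df, dr = column.depth_fwd, column.depth_rev
    total = df + dr
    ref_f, ref_r = column.sub_counts.get(column.ref_base, [0, 0])
    calls = []

    def consider(ref_allele: str, alt_allele: str, af: int, ar: int,
                 is_indel: bool):
        if af + ar < config.min_emit_count:
            return
        filters = set()
        if df < config.min_strand_depth or dr < config.min_strand_depth:
            filters.add(FILTER_LOW_DEPTH)
        vaf = (af + ar) / total if total else 0.0
        if vaf < config.min_vaf:
            filters.add(FILTER_LOW_VAF)
        if is_indel:
            rf, rr = df - af, dr - ar
        else:
            rf, rr = ref_f, ref_r
        p, flagged = strand_bias_test(max(rf, 0), max(rr, 0), af, ar, config)
        if flagged:
            filters.add(FILTER_STRAND_BIAS)
        if is_indel and any(ws <= column.pos < we for ws, we in hp_windows):
            filters.add(FILTER_HP_ADJACENT)
        calls.append(VariantCall(
            pos=column.pos, ref=ref_allele, alt=alt_allele,
            fwd_depth=df, rev_depth=dr, alt_fwd=af, alt_rev=ar,
            filters=filters, p_strand_bias=p, sample=sample,
        ))

    for base, (af, ar) in column.sub_counts.items():
        if base != column.ref_base:
            consider(column.ref_base, base, af, ar, is_indel=False)
    for seq, (af, ar) in column.ins_counts.items():
        consider(column.ref_base, column.ref_base + seq, af, ar, is_indel=True)
    for length, (af, ar) in column.del_counts.items():
        ref_allele = column.ref_context[:length + 1]
        if len(ref_allele) == length + 1:
            consider(ref_allele, column.ref_base, af, ar, is_indel=True)

    calls.sort(key=lambda c: (-c.alt_count, c.alt))
    return calls


def call_pileup(pileup: Pileup, config: CallerConfig | None = None,
                hp_sites: list[HomopolymerSite] | None = None,
                sample: str | None = None) -> list[VariantCall]:
    """Run :func:`call_site` over every candidate column of a pileup."""
    config = config or pileup.config
    if hp_sites is None:
        hp_sites = find_homopolymers(pileup.ref_seq, config.hp_min_length)
    hp_windows = [s.window() for s in hp_sites]
    calls = []
    for pos in pileup.candidate_positions():
        calls.extend(call_site(pileup.column(pos), config, hp_windows, sample))
    return calls


def recurrent_artifact_filter(
    calls_by_sample: dict[str, list[VariantCall]],
    config: CallerConfig,
    static_blacklist: set[tuple] | None = None,
) -> tuple[set[tuple], dict[str, list[VariantCall]]]:
    """Blacklist alleles recurring across the cohort at sub-threshold VAF.

    An allele key ``(pos, ref, alt)`` is blacklisted when it is observed
    (under any flag) in at least ``recurrence_fraction`` of samples with a
    median VAF below ``min_vaf``, or when it is an indel flagged
    homopolymer-adjacent in that many samples.  A user-supplied static
    blacklist is unioned in.  With fewer than 3 samples the filter is a
    no-op (warned).
    """
    blacklist = set(static_blacklist or ())
    n = len(calls_by_sample)
    if n < 3:
        warnings.warn("recurrent-artifact filter skipped: fewer than 3 samples")
    else:
        seen: dict[tuple, list[float]] = {}
        hp_seen: dict[tuple, int] = {}
        for calls in calls_by_sample.values():
            for c in calls:
                seen.setdefault(c.key, []).append(c.vaf)
                if c.kind != "snv" and FILTER_HP_ADJACENT in c.filters:
                    hp_seen[c.key] = hp_seen.get(c.key, 0) + 1
        threshold = config.recurrence_fraction * n
        for key, vafs in seen.items():
            if len(vafs) >= threshold and float(np.median(vafs)) < config.min_vaf:
                blacklist.add(key)
        for key, count in hp_seen.items():
            if count >= threshold:
                blacklist.add(key)
    for calls in calls_by_sample.values():
        for c in calls:
            if c.key in blacklist:
                c.filters.add(FILTER_RECURRENT)
    return blacklist, calls_by_sample
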