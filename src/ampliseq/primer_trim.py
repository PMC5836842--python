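"""Post-alignment primer masking.

Primer oligos are genomic sequence: they anchor alignments (which helps indel
detection near read ends), but their bases are synthesized, always matching
the reference, so letting them feed pileups dilutes the variant allele
fraction at any site that sits under a primer of an overlapping amplicon —
the mechanism behind the missed-variant failure this stage repairs.  Bases in
the read's own amplicon's primer intervals are therefore *masked* (flagged
non-countable) rather than clipped: the alignment span is retained.

Reads that cannot be assigned to an amplicon are conservatively masked
against every primer interval they overlap.
"""

from __future__ import annotations

from .panel import Panel
from .reads import AlignedRead

UNASSIGNED = None


def assign_amplicon(read: AlignedRead, panel: Panel) -> str | None:
    """Assign a read to the amplicon with maximal span overlap.

    Ties break toward the amplicon whose start is closest to the read start,
    then by lexicographic id.  Returns ``None`` when no amplicon overlaps.
    """
    rs, re_ = read.ref_span
    best = None
    best_key = None
    for amp in panel.amplicons:
        overlap = min(re_, amp.end) - max(rs, amp.start)
        if overlap <= 0:
            continue
        key = (-overlap, abs(amp.start - rs), amp.id)
        if best_key is None or key < best_key:
            best, best_key = amp, key
    return best.id if best else None


def mask_primers(read: AlignedRead, panel: Panel) -> AlignedRead:
    """Mask primer-derived bases in place and return the read.

    For an assigned read only its own amplicon's primer intervals are masked;
    unassigned reads are masked against the union of all overlapping primer
    intervals.  Masking is idempotent.
    """
    amp_id = read.amplicon_id or assign_amplicon(read, panel)
    rs, re_ = read.ref_span
    if amp_id is not None:
        read.amplicon_id = amp_id
        intervals = panel.get(amp_id).primer_intervals
    else:
        intervals = panel.primer_union()
    clipped = [
        (max(s, rs), min(e, re_))
        for s, e in intervals
        if max(s, rs) < min(e, re_)
    ]
    if clipped:
        read.add_mask(clipped)
    return read


def mask_all(reads: list[AlignedRead], panel: Panel) -> list[AlignedRead]:
    for read in reads:
        mask_primers(read, panel)
    return reads
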