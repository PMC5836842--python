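"""File-format plumbing: FASTQ, SAM, VCF and the TSV side tables.

SAM dialect: reads are stored in reference-forward orientation (flag 16 for
reverse-strand reads), with masked reference intervals recorded in the
``XM:Z`` tag as comma-separated ``start-end`` half-open intervals; the
masked bases additionally have base quality 0 so third-party pileup tools
ignore them too.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam

from .panel import Panel, PanelReference
from .reads import AlignedRead, ReadRecord
from .variant_call import VariantCall

_CIGAR_OP = {"M": 0, "I": 1, "D": 2}
_OP_CIGAR = {0: "M", 1: "I", 2: "D"}


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq(records: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = "".join(chr(int(q) + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    out = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            quals = np.array(entry.get_quality_array() or [], dtype=np.int16)
            out.append(ReadRecord(entry.name, entry.sequence or "", quals))
    return out


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _sam_header(reference: PanelReference) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.name, "LN": reference.length}],
    })


def write_sam(reads: list[AlignedRead], reference: PanelReference, path: str | Path) -> None:
    header = _sam_header(reference)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.id
            seg.flag = 16 if read.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = read.ref_start
            seg.mapping_quality = 60
            seg.cigartuples = [(_CIGAR_OP[op], n) for op, n in read.cigar]
            seg.query_sequence = read.seq
            quals = read.quals.copy()
            if read.mask:
                qpos = rpos = 0
                masked_q = []
                for op, n in read.cigar:
                    if op == "M":
                        for k in range(n):
                            pos = read.ref_start + rpos + k
                            masked = any(s <= pos < e for s, e in read.mask)
                            masked_q.append(0 if masked else int(quals[qpos + k]))
                        qpos += n
                        rpos += n
                    elif op == "I":
                        masked_q.extend(int(q) for q in quals[qpos:qpos + n])
                        qpos += n
                    else:
                        rpos += n
                quals = np.array(masked_q, dtype=np.int16)
                seg.set_tag("XM", ",".join(f"{s}-{e}" for s, e in read.mask))
            seg.query_qualities = [int(q) for q in quals]
            if read.amplicon_id:
                seg.set_tag("XA", read.amplicon_id)
            fh.write(seg)


def read_sam(path: str | Path) -> list[AlignedRead]:
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            seq = seg.query_sequence or ""
            quals = np.array(seg.query_qualities or [0] * len(seq), dtype=np.int16)
            cigar = []
            qtrim_start = 0
            qtrim_end = len(seq)
            for i, (op, n) in enumerate(seg.cigartuples):
                if op in (4, 5):  # soft/hard clips: drop clipped bases
                    if op == 4 and i == 0:
                        qtrim_start = n
                    elif op == 4:
                        qtrim_end -= n
                    continue
                if op not in _OP_CIGAR:
                    raise ValueError(f"unsupported CIGAR op {op} in {seg.query_name}")
                cigar.append((_OP_CIGAR[op], n))
            mask = []
            if seg.has_tag("XM"):
                for chunk in str(seg.get_tag("XM")).split(","):
                    s, e = chunk.split("-")
                    mask.append((int(s), int(e)))
            read = AlignedRead(
                id=seg.query_name,
                ref_start=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                seq=seq[qtrim_start:qtrim_end],
                quals=quals[qtrim_start:qtrim_end],
                cigar=cigar,
                mask=mask,
                amplicon_id=str(seg.get_tag("XA")) if seg.has_tag("XA") else None,
            )
            out.append(read)
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_FILTERS = {
    "low_depth": "fewer than the required usable reads on one or both strands",
    "low_vaf": "variant allele fraction below threshold",
    "strand_bias": "significant strand bias of the alternate allele",
    "recurrent_artifact": "recurrent cross-sample sub-threshold artifact",
    "hp_adjacent": "indel inside a homopolymer window (called separately)",
}


def write_vcf(calls: list[VariantCall], reference: PanelReference,
              path: str | Path, sample: str | None = None) -> None:
    """Write calls as VCF 4.2, ordered by position then alt allele."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={reference.name},length={reference.length}>",
        '##INFO=<ID=DPF,Number=1,Type=Integer,Description="Usable forward-strand depth">',
        '##INFO=<ID=DPR,Number=1,Type=Integer,Description="Usable reverse-strand depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">',
        '##INFO=<ID=SB,Number=1,Type=Float,Description="Strand-bias Fisher p-value">',
        '##INFO=<ID=HP,Number=0,Type=Flag,Description="Called by the homopolymer length-spectrum caller">',
    ]
    for name, desc in _VCF_FILTERS.items():
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(calls, key=lambda c: (c.pos, c.alt)):
        filt = "PASS" if c.is_pass else ";".join(sorted(c.filters))
        info = f"DPF={c.fwd_depth};DPR={c.rev_depth};AF={c.vaf:.4f};SB={c.p_strand_bias:.3g}"
        if c.hp_call:
            info += ";HP"
        lines.append("\t".join([
            reference.name, str(c.pos + 1), c.name or ".", c.ref, c.alt,
            ".", filt, info,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_blacklist(blacklist: set, path: str | Path) -> None:
    lines = ["#pos\tref\talt"]
    for pos, ref, alt in sorted(blacklist):
        lines.append(f"{pos}\t{ref}\t{alt}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_spectra(results: dict, path: str | Path) -> None:
    """Per-site homopolymer length-spectrum TSV."""
    lines = ["#site_start\tsite_end\tbase\tlength\tcount\tfreq"]
    for site, res in sorted(results.items(), key=lambda kv: kv[0].start):
        spec = res.spectrum
        for length in sorted(spec.counts):
            lines.append(
                f"{site.start}\t{site.end}\t{site.base}\t{length}"
                f"\t{spec.count(length)}\t{spec.freq(length):.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_genotypes(records: list, path: str | Path) -> None:
    lines = ["#sample\tallele1\tallele2\tresolved\thgvs"]
    for rec in records:
        alleles = rec.allele_lists
        a1 = ";".join(alleles[0]) if alleles else ""
        a2 = ";".join(alleles[1]) if len(alleles) > 1 else ""
        lines.append(f"{rec.sample}\t{a1}\t{a2}\t{int(rec.resolved)}\t{rec.hgvs}")
    Path(path).write_text("\n".join(lines) + "\n")
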