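"""Read containers shared across the pipeline stages.

``AlignedRead`` holds a gapped alignment against the panel reference in a
form convenient for pileup work: a per-reference-position base-code array
plus explicit insertion events.  Reads produced by the simulator and reads
parsed from SAM both normalize to this container.

Base codes: 0 = absent/masked, 1..4 = A/C/G/T, 5 = deleted base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

A, C, G, T, DEL = 1, 2, 3, 4, 5

_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_BASE_OF_CODE = {1: "A", 2: "C", 3: "G", 4: "T"}

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def encode_bases(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def base_code(base: str) -> int:
    return int(_CODE_LUT[ord(base)])


def code_base(code: int) -> str:
    return _BASE_OF_CODE[code]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A raw (unaligned) read as it appears in FASTQ."""

    id: str
    bases: str
    qualities: np.ndarray  # Phred integers, one per base

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id!r}: bases/qualities length mismatch")

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if len(self.qualities) else 0.0


@dataclass
class AlignedRead:
    """A mapped read with reference span, strand and gap-aware base map.

    ``cigar`` uses ops 'M' (alignment match/mismatch), 'I', 'D' against
    ``seq``/``quals`` in reference-forward orientation.  ``mask`` lists
    reference intervals whose bases must not contribute to pileups (set by
    the primer-masking stage).
    """

    id: str
    ref_start: int
    strand: str  # '+' or '-'
    seq: str
    quals: np.ndarray
    cigar: list[tuple[str, int]]
    mask: list[tuple[int, int]] = field(default_factory=list)
    amplicon_id: str | None = None
    _proj: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        qlen = sum(n for op, n in self.cigar if op in "MI")
        if qlen != len(self.seq) or len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.id!r}: cigar/seq/qual inconsistency")
        if self.strand not in "+-":
            raise ValueError(f"read {self.id!r}: bad strand {self.strand!r}")

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def ref_span(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quals)) if len(self.quals) else 0.0

    # -- projection onto reference coordinates --------------------------------

    def _project(self):
        if self._proj is not None:
            return self._proj
        ref_len = self.ref_end - self.ref_start
        codes = np.zeros(ref_len, dtype=np.uint8)
        quals = np.zeros(ref_len, dtype=np.int16)
        insertions: list[tuple[int, str]] = []
        deletions: list[tuple[int, int]] = []  # (anchor, length)
        qpos = rpos = 0
        for op, n in self.cigar:
            if op == "M":
                codes[rpos:rpos + n] = encode_bases(self.seq[qpos:qpos + n])
                quals[rpos:rpos + n] = self.quals[qpos:qpos + n]
                qpos += n
                rpos += n
            elif op == "D":
                codes[rpos:rpos + n] = DEL
                deletions.append((self.ref_start + rpos - 1, n))
                rpos += n
            elif op == "I":
                insertions.append((self.ref_start + rpos - 1, self.seq[qpos:qpos + n]))
                qpos += n
            else:  # pragma: no cover - guarded at construction
                raise ValueError(f"unsupported cigar op {op!r}")
        self._proj = (codes, quals, insertions, deletions)
        return self._proj

    def projected_codes(self, apply_mask: bool = True) -> np.ndarray:
        """Base codes over ``ref_span``; masked positions forced to 0."""
        codes = self._project()[0]
        if apply_mask and self.mask:
            codes = codes.copy()
            for s, e in self.mask:
                s = max(s, self.ref_start) - self.ref_start
                e = min(e, self.ref_end) - self.ref_start
                if s < e:
                    codes[s:e] = 0
        return codes

    def insertions(self, apply_mask: bool = True) -> list[tuple[int, str]]:
        ins = self._project()[2]
        if apply_mask and self.mask:
            ins = [(a, s) for a, s in ins if not self._masked(a)]
        return ins

    def deletions(self, apply_mask: bool = True) -> list[tuple[int, int]]:
        dels = self._project()[3]
        if apply_mask and self.mask:
            dels = [(a, n) for a, n in dels if not self._masked(a)]
        return dels

    def _masked(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.mask)

    def base_at(self, pos: int, apply_mask: bool = True) -> int:
        """Base code at a reference position (0 if outside span or masked)."""
        if not (self.ref_start <= pos < self.ref_end):
            return 0
        return int(self.projected_codes(apply_mask)[pos - self.ref_start])

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    def add_mask(self, intervals: list[tuple[int, int]]) -> None:
        """Merge additional masked reference intervals (idempotent)."""
        ivs = sorted(set(self.mask) | set(intervals))
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.mask = [tuple(m) for m in merged]

    def masked_base_count(self) -> int:
        n = 0
        for s, e in self.mask:
            n += max(0, min(e, self.ref_end) - max(s, self.ref_start))
        return n

    def to_read_record(self) -> ReadRecord:
        """FASTQ view of this read (sequencer orientation)."""
        if self.strand == "-":
            return ReadRecord(self.id, revcomp(self.seq), self.quals[::-1].copy())
        return ReadRecord(self.id, self.seq, self.quals.copy())
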