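"""Read-level QC: mean-quality and length filtering.

The filter keeps a read iff the arithmetic mean of its Phred scores is at
least ``min_mean_quality`` (default 25) and its length is at least
``min_read_length`` (default 75 bp); both comparisons are inclusive, matching
the Prinseq convention of averaging Phred scores rather than error
probabilities.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Iterator

from .panel import CallerConfig
from .reads import AlignedRead, ReadRecord


@dataclass
class FilterStats:
    kept: int = 0
    discarded: int = 0
    malformed: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.discarded + self.malformed

    @property
    def kept_fraction(self) -> float:
        return self.kept / self.total if self.total else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kept_fraction"] = self.kept_fraction
        return d


def passes_filter(record, config: CallerConfig) -> bool:
    """Inclusive boundary check on length and mean Phred quality."""
    length = len(record.bases) if isinstance(record, ReadRecord) else len(record.seq)
    return (length >= config.min_read_length
            and record.mean_quality >= config.min_mean_quality)


def filter_reads(
    reads: Iterable[ReadRecord | AlignedRead],
    config: CallerConfig,
    stats: FilterStats | None = None,
) -> Iterator[ReadRecord | AlignedRead]:
    """Stream the reads that pass QC; malformed records are dropped and
    counted separately (a ``ReadRecord`` with mismatched bases/qualities
    cannot be constructed, so malformed input surfaces as ``ValueError``
    from upstream parsing and is tallied by the caller via ``count_malformed``).
    """
    stats = stats if stats is not None else FilterStats()
    for rec in reads:
        if passes_filter(rec, config):
            stats.kept += 1
            yield rec
        else:
            stats.discarded += 1


def filter_read_list(reads, config: CallerConfig):
    """Eager variant of :func:`filter_reads`; returns (kept, stats)."""
    stats = FilterStats()
    kept = list(filter_reads(reads, config, stats))
    return kept, stats
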