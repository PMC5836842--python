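"""Panel geometry, variant catalog, homopolymer sites and caller configuration.

A *panel* is a single reference sequence (here, a synthetic stand-in for the
~9 kb CFTR target region) tiled by PCR amplicons.  Each amplicon carries a
forward and a reverse primer; only the *insert* between the two primers is
template-derived and trustworthy for variant calling — primer bases are
synthesized oligo sequence and always match the reference, which is why they
must be masked after alignment (see :mod:`ampliseq.primer_trim`).

Coordinates are 0-based half-open throughout the package; VCF output is
1-based as usual.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml
from Bio import SeqIO

from .errors import ConfigError, PanelError

_VALID_BASES = frozenset("ACGT")

#: default amplicon length bounds (bp)
AMPLICON_MIN_LEN = 172
AMPLICON_MAX_LEN = 328


@dataclass(frozen=True)
class PanelReference:
    """A single uppercase nucleotide reference sequence."""

    name: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise PanelError(f"reference {self.name!r} contains non-ACGT symbols: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Amplicon:
    """Full amplicon span plus primer lengths; the insert is derived."""

    id: str
    start: int
    end: int
    fwd_primer_len: int
    rev_primer_len: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise PanelError(f"amplicon {self.id!r}: invalid span [{self.start},{self.end})")
        if self.fwd_primer_len < 0 or self.rev_primer_len < 0:
            raise PanelError(f"amplicon {self.id!r}: negative primer length")
        if self.insert_start >= self.insert_end:
            raise PanelError(f"amplicon {self.id!r}: empty insert")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def insert_start(self) -> int:
        return self.start + self.fwd_primer_len

    @property
    def insert_end(self) -> int:
        return self.end - self.rev_primer_len

    @property
    def insert(self) -> tuple[int, int]:
        return (self.insert_start, self.insert_end)

    @property
    def primer_intervals(self) -> list[tuple[int, int]]:
        """Reference intervals occupied by this amplicon's two primers."""
        out = []
        if self.fwd_primer_len:
            out.append((self.start, self.insert_start))
        if self.rev_primer_len:
            out.append((self.insert_end, self.end))
        return out

    def contains_in_insert(self, pos: int) -> bool:
        return self.insert_start <= pos < self.insert_end


@dataclass
class Panel:
    """Reference plus validated amplicon set with a derived overlap graph."""

    reference: PanelReference
    amplicons: list[Amplicon]
    min_amplicon_len: int = AMPLICON_MIN_LEN
    max_amplicon_len: int = AMPLICON_MAX_LEN

    def __post_init__(self):
        seen = set()
        for amp in self.amplicons:
            if amp.id in seen:
                raise PanelError(f"duplicate amplicon id {amp.id!r}")
            seen.add(amp.id)
            if amp.end > self.reference.length:
                raise PanelError(
                    f"amplicon {amp.id!r} end {amp.end} exceeds reference length "
                    f"{self.reference.length}"
                )
            if not (self.min_amplicon_len <= amp.length <= self.max_amplicon_len):
                raise PanelError(
                    f"amplicon {amp.id!r} length {amp.length} outside "
                    f"[{self.min_amplicon_len},{self.max_amplicon_len}]"
                )
        self.amplicons = sorted(self.amplicons, key=lambda a: (a.start, a.id))

    @property
    def overlap_edges(self) -> list[tuple[str, str]]:
        """Pairs of amplicon ids whose full spans overlap."""
        edges = []
        amps = self.amplicons
        for i, a in enumerate(amps):
            for b in amps[i + 1:]:
                if b.start >= a.end:
                    break
                edges.append((a.id, b.id))
        return edges

    def get(self, amp_id: str) -> Amplicon:
        for a in self.amplicons:
            if a.id == amp_id:
                return a
        raise KeyError(amp_id)

    def amplicons_covering(self, pos: int) -> list[Amplicon]:
        return [a for a in self.amplicons if a.start <= pos < a.end]

    def inserts_covering(self, pos: int) -> list[Amplicon]:
        return [a for a in self.amplicons if a.contains_in_insert(pos)]

    def primer_union(self) -> list[tuple[int, int]]:
        """Merged list of all primer intervals on the reference."""
        ivs = sorted(iv for a in self.amplicons for iv in a.primer_intervals)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [tuple(m) for m in merged]


@dataclass(frozen=True)
class CatalogEntry:
    """One variant of the disease-gene catalog.

    ``name`` is the short label used in genotype tables (e.g. ``F508del``);
    ``cdna_name``/``protein_name`` are HGVS-style.  ``mutation_class`` encodes
    the functional class I-V ('none' for unclassed/VUS/benign entries); class
    IV-V variants confer residual channel function and define the mild
    phenotype group.  ``position``/``ref``/``alt`` locate the variant on the
    panel reference when it is placeable there (empty for CNVs and variants
    outside the synthetic fixture).
    """

    name: str
    cdna_name: str
    protein_name: str
    mutation_class: str  # I, II, III, IV, V, none
    status: str  # pathogenic, likely_pathogenic, VUS, benign
    position: int | None = None
    ref: str | None = None
    alt: str | None = None

    _CLASSES = frozenset({"I", "II", "III", "IV", "V", "none"})
    _STATUSES = frozenset({"pathogenic", "likely_pathogenic", "VUS", "benign"})

    def __post_init__(self):
        if self.mutation_class not in self._CLASSES:
            raise PanelError(f"{self.name}: bad mutation class {self.mutation_class!r}")
        if self.status not in self._STATUSES:
            raise PanelError(f"{self.name}: bad status {self.status!r}")

    @property
    def is_causative(self) -> bool:
        return self.status in ("pathogenic", "likely_pathogenic")

    @property
    def is_mild_class(self) -> bool:
        return self.mutation_class in ("IV", "V")

    @property
    def is_severe_class(self) -> bool:
        return self.mutation_class in ("I", "II", "III")


@dataclass(frozen=True)
class HomopolymerSite:
    """A maximal single-nucleotide run on the reference."""

    start: int
    end: int
    base: str

    @property
    def ref_run_length(self) -> int:
        return self.end - self.start

    def window(self, pad: int = 1) -> tuple[int, int]:
        """Reference interval owned by the homopolymer caller (run +- pad)."""
        return (self.start - pad, self.end + pad)


@dataclass
class CallerConfig:
    """All pipeline thresholds.

    Defaults encode the published protocol: mean read quality >= 25 and length
    >= 75 bp for the QC filter; a site is callable when covered by at least 15
    reads on each strand with a mutant allele fraction of at least 20%, under a
    per-strand depth cap of 10,000; homopolymer carriers are discriminated at a
    10% allele-length frequency (midpoint of the observed 8% non-carrier
    maximum and 16% carrier minimum); consensus pathogenicity requires 5 of 7
    in-silico votes.
    """

    min_mean_quality: float = 25.0
    min_read_length: int = 75
    min_strand_depth: int = 15
    min_vaf: float = 0.20
    max_depth: int = 10000
    strand_bias_p: float = 0.01
    hp_min_length: int = 5
    hp_carrier_threshold: float = 0.10
    recurrence_fraction: float = 0.75
    consensus_votes_required: int = 5
    consensus_votes_total: int = 7
    # secondary knobs (not part of the published protocol)
    min_emit_count: int = 2          # min alt reads for a sub-threshold record
    strand_bias_ratio: float = 5.0   # alt strand ratio band [1/r, r]
    phase_min_reads: int = 5
    phase_max_contradiction: float = 0.10
    common_af_threshold: float = 0.05
    # platform stutter priors per length offset; a carrier call must be
    # statistically inconsistent with its offset's prior (one-sided exact
    # binomial at hp_stutter_alpha) in addition to clearing the threshold
    hp_stutter_rates: dict = field(
        default_factory=lambda: {-2: 0.06, -1: 0.15, 1: 0.04}
    )
    hp_stutter_alpha: float = 1e-6

    def __post_init__(self):
        positive = [
            "min_mean_quality", "min_read_length", "min_strand_depth",
            "max_depth", "strand_bias_p", "hp_min_length",
            "hp_carrier_threshold", "recurrence_fraction",
            "consensus_votes_required", "consensus_votes_total",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 < self.min_vaf < 1.0):
            raise ConfigError("min_vaf must lie in (0,1)")
        if self.consensus_votes_required > self.consensus_votes_total:
            raise ConfigError("consensus_votes_required exceeds total")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["hp_stutter_rates"] = {int(k): float(v) for k, v in d["hp_stutter_rates"].items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CallerConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "hp_stutter_rates" in raw:
            raw["hp_stutter_rates"] = {int(k): float(v) for k, v in raw["hp_stutter_rates"].items()}
        return cls(**raw)

    def replace(self, **kw) -> "CallerConfig":
        return replace(self, **kw)


def find_homopolymers(reference: PanelReference | str, min_len: int) -> list[HomopolymerSite]:
    """All maximal runs of a single base with length >= ``min_len``.

    Returned sorted by start position.  ``min_len`` must be >= 2.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = reference.sequence if isinstance(reference, PanelReference) else reference
    sites = []
    for m in re.finditer(r"(A+|C+|G+|T+)", seq):
        if m.end() - m.start() >= min_len:
            sites.append(HomopolymerSite(m.start(), m.end(), m.group()[0]))
    return sites


def load_reference(reference_file: str | Path) -> PanelReference:
    """Read the first record of a FASTA file as the panel reference."""
    path = Path(reference_file)
    if not path.exists():
        raise PanelError(f"reference file not found: {path}")
    try:
        rec = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise PanelError(f"no FASTA record in {path}") from None
    return PanelReference(rec.id, str(rec.seq).upper())


def load_panel(panel_file: str | Path, reference_file: str | Path) -> Panel:
    """Load a BED-derived panel file against its FASTA reference.

    Panel columns (tab-separated, ``#`` comments allowed):
    ``chrom  start  end  id  fwd_primer_len  rev_primer_len``.
    """
    ref = load_reference(reference_file)
    path = Path(panel_file)
    if not path.exists():
        raise PanelError(f"panel file not found: {path}")
    amplicons = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise PanelError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        chrom, start, end, amp_id, fwd, rev = parts
        if chrom != ref.name:
            raise PanelError(f"{path}:{lineno}: chrom {chrom!r} does not match reference {ref.name!r}")
        try:
            amp = Amplicon(amp_id, int(start), int(end), int(fwd), int(rev))
        except ValueError as exc:
            raise PanelError(f"{path}:{lineno}: {exc}") from None
        amplicons.append(amp)
    if not amplicons:
        raise PanelError(f"{path}: no amplicons")
    return Panel(ref, amplicons)


def write_panel(panel: Panel, panel_file: str | Path) -> None:
    lines = ["#chrom\tstart\tend\tid\tfwd_primer_len\trev_primer_len"]
    for a in panel.amplicons:
        lines.append(f"{panel.reference.name}\t{a.start}\t{a.end}\t{a.id}\t{a.fwd_primer_len}\t{a.rev_primer_len}")
    Path(panel_file).write_text("\n".join(lines) + "\n")


def write_reference(reference: PanelReference, fasta_file: str | Path) -> None:
    seq = reference.sequence
    chunks = [seq[i:i + 70] for i in range(0, len(seq), 70)]
    Path(fasta_file).write_text(f">{reference.name}\n" + "\n".join(chunks) + "\n")


def load_catalog(catalog_file: str | Path) -> list[CatalogEntry]:
    """Read the variant catalog TSV (name, cdna, protein, class, status[, pos, ref, alt])."""
    path = Path(catalog_file)
    if not path.exists():
        raise PanelError(f"catalog file not found: {path}")
    entries = []
    names = set()
    lines = path.read_text().splitlines()
    header = lines[0].lstrip("#").split("\t")
    idx = {c: i for i, c in enumerate(header)}
    required = {"name", "cdna_name", "protein_name", "mutation_class", "status"}
    if not required <= set(idx):
        raise PanelError(f"{path}: missing catalog columns {sorted(required - set(idx))}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        get = lambda c: parts[idx[c]].strip() if c in idx and idx[c] < len(parts) else ""
        name = get("name")
        if name in names:
            raise PanelError(f"{path}:{lineno}: duplicate variant name {name!r}")
        names.add(name)
        pos = get("position")
        entries.append(
            CatalogEntry(
                name=name,
                cdna_name=get("cdna_name"),
                protein_name=get("protein_name"),
                mutation_class=get("mutation_class") or "none",
                status=get("status"),
                position=int(pos) if pos else None,
                ref=get("ref") or None,
                alt=get("alt") or None,
            )
        )
    return entries


def validate_catalog_against_panel(panel: Panel, catalog: list[CatalogEntry]) -> None:
    """Every placed catalog variant must fall inside at least one insert."""
    for entry in catalog:
        if entry.position is None:
            continue
        if not panel.inserts_covering(entry.position):
            raise PanelError(
                f"catalog variant {entry.name} at {entry.position} is not covered "
                "by any amplicon insert"
            )
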