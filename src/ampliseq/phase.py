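"""Read-backed cis/trans classification and complex-allele assembly.

Two variants co-covered by the same amplicon's reads are classified from the
four haplotype-support categories among co-covering reads: both-alt,
alt1-only, alt2-only, both-ref.  A cis verdict requires enough both-alt reads
and near-absent singleton categories; trans the converse.  Variants on
non-overlapping amplicons are never resolved by reads — their relative phase
is reported unknown, printed with the ``(;)`` HGVS convention.

Assembly builds a phase graph (cis edges merge variants into complex
alleles, trans edges force separation); a diploid genotype must 2-color the
trans graph, so any odd cycle is reported as an inconsistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import PhaseInconsistencyError
from .reads import AlignedRead, base_code
from .variant_call import VariantCall, left_align_del, left_align_ins

CIS, TRANS, UNKNOWN = "cis", "trans", "unknown"


@dataclass
class PhaseEvidence:
    both_alt: int = 0
    alt1_only: int = 0
    alt2_only: int = 0
    both_ref: int = 0

    @property
    def total(self) -> int:
        return self.both_alt + self.alt1_only + self.alt2_only + self.both_ref


def read_allele_support(read: AlignedRead, call: VariantCall, ref_seq: str) -> str | None:
    """'alt', 'ref', or None/'other' for one read at one call site."""
    pos = call.pos
    if not (read.ref_start <= pos < read.ref_end - (len(call.ref) - 1)):
        return None
    code = read.base_at(pos)
    if code == 0:
        return None
    kind = call.kind
    if kind == "snv":
        if code == base_code(call.alt):
            return "alt"
        if code == base_code(call.ref):
            return "ref"
        return "other"
    if kind == "ins":
        want = call.alt[len(call.ref):]
        for anchor, seq in read.insertions():
            a, s = left_align_ins(ref_seq, anchor, seq)
            if a == pos:
                return "alt" if s == want else "other"
        return "ref"
    # deletion
    want_len = len(call.ref) - len(call.alt)
    for anchor, length in read.deletions():
        a = left_align_del(ref_seq, anchor, length)
        if a == pos:
            return "alt" if length == want_len else "other"
    return "ref"


def collect_phase_evidence(
    reads: list[AlignedRead],
    call1: VariantCall,
    call2: VariantCall,
    ref_seq: str,
) -> PhaseEvidence:
    """Tally haplotype-support categories from co-covering reads only."""
    ev = PhaseEvidence()
    for read in reads:
        s1 = read_allele_support(read, call1, ref_seq)
        s2 = read_allele_support(read, call2, ref_seq)
        if s1 == "alt" and s2 == "alt":
            ev.both_alt += 1
        elif s1 == "alt" and s2 == "ref":
            ev.alt1_only += 1
        elif s1 == "ref" and s2 == "alt":
            ev.alt2_only += 1
        elif s1 == "ref" and s2 == "ref":
            ev.both_ref += 1
    return ev


def classify_phase(
    evidence: PhaseEvidence,
    min_reads: int = 5,
    max_contradiction: float = 0.1,
) -> str:
    total = evidence.total
    if total == 0:
        return UNKNOWN
    limit = max_contradiction * total
    if (evidence.both_alt >= min_reads
            and evidence.alt1_only < limit and evidence.alt2_only < limit):
        return CIS
    if (evidence.alt1_only >= min_reads and evidence.alt2_only >= min_reads
            and evidence.both_alt < limit):
        return TRANS
    return UNKNOWN


@dataclass
class GenotypeRecord:
    """Per-sample diploid genotype: complex-allele groups and slot layout.

    ``groups`` are cis components (ordered variant-name lists); ``resolved``
    is true when trans evidence pins every group to one of the two allele
    slots, in which case ``slots`` holds the two allele lists.  ``hgvs``
    is the formatted genotype string.
    """

    sample: str
    groups: list = field(default_factory=list)
    resolved: bool = False
    slots: tuple = ((), ())
    pair_phase: dict = field(default_factory=dict)
    hgvs: str = ""

    @property
    def allele_lists(self) -> list[list[str]]:
        """Variant groups interpreted as alleles (slots when resolved)."""
        if self.resolved:
            return [list(self.slots[0]), list(self.slots[1])]
        return [list(g) for g in self.groups]


def _format_hgvs(groups: list[list[str]], resolved: bool,
                 cdna_of: dict[str, str] | None) -> str:
    def pretty(name: str) -> str:
        if cdna_of and name in cdna_of and cdna_of[name]:
            return cdna_of[name].removeprefix("c.")
        return name

    parts = ["[" + ";".join(pretty(v) for v in g) + "]" for g in groups]
    sep = ";" if resolved else "(;)"
    return "c." + sep.join(parts)


def assemble_genotype(
    calls: list[VariantCall],
    pair_phases: dict[frozenset, str],
    external_cnv: list[str] | None = None,
    sample: str = "",
    cdna_of: dict[str, str] | None = None,
    status_of: dict[str, str] | None = None,
    hom_threshold: float = 0.8,
) -> GenotypeRecord:
    """Assemble per-sample calls plus pairwise phases into a genotype.

    ``pair_phases`` maps ``frozenset({label_a, label_b})`` to cis/trans/
    unknown, where labels are call names (or position keys).  Homozygous
    calls (VAF >= ``hom_threshold``) occupy both slots.  Externally supplied
    CNV alleles fill a slot with unknown phase.
    """
    labels = []
    hom = set()
    for c in sorted(calls, key=lambda c: (c.pos, c.alt)):
        label = c.name or f"{c.pos}:{c.ref}>{c.alt}"
        if label in labels:
            continue
        labels.append(label)
        if c.vaf >= hom_threshold:
            hom.add(label)

    parent = {v: v for v in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    trans_edges = []
    for pair, phase in pair_phases.items():
        a, b = sorted(pair)
        if a not in parent or b not in parent:
            continue
        if phase == CIS:
            parent[find(a)] = find(b)
        elif phase == TRANS:
            trans_edges.append((a, b))

    comp_of = {v: find(v) for v in labels}
    groups_by_root: dict[str, list[str]] = {}
    for v in labels:
        groups_by_root.setdefault(comp_of[v], []).append(v)

    # trans edge inside a cis component -> contradiction
    for a, b in trans_edges:
        if comp_of[a] == comp_of[b]:
            raise PhaseInconsistencyError(
                f"variants {a} and {b} are both cis-linked and trans-separated",
                conflict=[a, b])

    # 2-color the component-level trans graph
    adj: dict[str, set[str]] = {r: set() for r in groups_by_root}
    for a, b in trans_edges:
        adj[comp_of[a]].add(comp_of[b])
        adj[comp_of[b]].add(comp_of[a])
    color: dict[str, int] = {}
    for root in groups_by_root:
        if root in color or not adj[root]:
            continue
        stack = [(root, 0)]
        while stack:
            node, col = stack.pop()
            if node in color:
                if color[node] != col:
                    cycle = sorted(v for r in (node,) for v in groups_by_root[r])
                    raise PhaseInconsistencyError(
                        "phase graph is not 2-colorable (more than two alleles "
                        f"implied around {cycle})", conflict=cycle)
                continue
            color[node] = col
            for nb in adj[node]:
                stack.append((nb, 1 - col))

    _status_rank = {"pathogenic": 0, "likely_pathogenic": 1, "VUS": 2, "benign": 3}

    def order_group(group):
        # causative variants lead their complex allele, as genotype tables print
        def rank(v):
            status = (status_of or {}).get(v, "")
            return (_status_rank.get(status, 4), labels.index(v))
        return sorted(group, key=rank)

    groups = [order_group(groups_by_root[r]) for r in groups_by_root]
    groups.sort(key=lambda g: (len(g), g[0]))

    cnv = list(external_cnv or [])
    colored_roots = set(color)
    all_roots = set(groups_by_root)
    resolved = False
    slots: tuple = ((), ())

    if colored_roots == all_roots and all_roots and len(set(color.values())) <= 2 and not cnv:
        slot0 = [v for r, c in color.items() if c == 0 for v in order_group(groups_by_root[r])]
        slot1 = [v for r, c in color.items() if c == 1 for v in order_group(groups_by_root[r])]
        if slot0 and slot1:
            resolved = True
            slot0, slot1 = sorted((slot0, slot1), key=lambda s: (len(s), s))
            slots = (tuple(slot0), tuple(slot1))
    elif len(groups) == 1 and not cnv:
        only = groups[0]
        if all(v in hom for v in only):
            resolved = True
            slots = (tuple(only), tuple(only))

    out_groups = [list(g) for g in groups] + [[name] for name in cnv]
    if resolved:
        out_groups = [list(slots[0]), list(slots[1])]

    record = GenotypeRecord(
        sample=sample,
        groups=out_groups,
        resolved=resolved,
        slots=slots if resolved else ((), ()),
        pair_phase={tuple(sorted(k)): v for k, v in pair_phases.items()},
    )
    record.hgvs = _format_hgvs(out_groups, resolved, cdna_of)
    return record
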