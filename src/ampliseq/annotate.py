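"""Catalog annotation, consensus in-silico pathogenicity, severity classes.

Missense variants are scored by a fixed panel of seven prediction tools; a
variant's pathogenicity is *asserted* when at least five of the seven vote
damaging (unavailable verdicts count toward the denominator, not the
threshold).  In-frame indels use a two-tool panel where both must agree.
The continuous consensus score (damaging votes / panel size) is kept
alongside the binary assertion.

Severity follows the residual-function class rule: a genotype is *mild* when
at least one allele carries a class IV-V causative variant and *severe* when
every classed causative variant on both alleles is class I-III.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import CallerConfig, CatalogEntry
from .phase import GenotypeRecord

MISSENSE_TOOLS = ("SIFT", "PolyPhen-2", "PROVEAN", "Phd-SNP", "PANTHER", "SNP&GO", "OGMET")
INFRAME_TOOLS = ("PROVEAN", "DDIG-in")

DAMAGING, BENIGN, UNAVAILABLE = "damaging", "benign", "unavailable"

MILD, SEVERE, UNCLASSIFIED = "mild", "severe", "unclassified"


@dataclass
class PredictionVotes:
    variant: str
    votes: dict  # tool -> verdict
    panel: tuple = MISSENSE_TOOLS

    def __post_init__(self):
        bad = {v for v in self.votes.values() if v not in (DAMAGING, BENIGN, UNAVAILABLE)}
        if bad:
            raise ValueError(f"{self.variant}: invalid verdicts {sorted(bad)}")
        extra = set(self.votes) - set(self.panel)
        if extra:
            raise ValueError(f"{self.variant}: votes from tools outside the panel: {sorted(extra)}")


@dataclass
class ConsensusResult:
    variant: str
    damaging: int
    total: int
    consensus: str | None  # 'asserted_damaging' | 'not_asserted' | None
    score: float
    undefined: bool = False


def votes_from_table(df, variant: str) -> PredictionVotes:
    """Build a vote set from the long-format votes table for one variant."""
    sub = df[df["variant"] == variant]
    votes = dict(zip(sub["tool"], sub["verdict"]))
    panel = INFRAME_TOOLS if set(votes) <= set(INFRAME_TOOLS) and votes else MISSENSE_TOOLS
    return PredictionVotes(variant, votes, panel)


def consensus_vote(votes: PredictionVotes, config: CallerConfig) -> ConsensusResult:
    """Apply the voting rule; unavailable verdicts never count as damaging."""
    total = (config.consensus_votes_total if votes.panel == MISSENSE_TOOLS
             else len(votes.panel))
    informative = [v for v in votes.votes.values() if v != UNAVAILABLE]
    damaging = sum(1 for v in votes.votes.values() if v == DAMAGING)
    score = damaging / total
    if not informative:
        return ConsensusResult(votes.variant, damaging, total, None, score, undefined=True)
    if votes.panel == INFRAME_TOOLS:
        asserted = damaging == len(votes.panel)  # both tools must agree
    else:
        asserted = damaging >= config.consensus_votes_required
    verdict = "asserted_damaging" if asserted else "not_asserted"
    return ConsensusResult(votes.variant, damaging, total, verdict, score)


@dataclass
class AnnotatedVariant:
    name: str
    entry: CatalogEntry | None
    consensus: ConsensusResult | None = None
    population_freq: float | None = None
    common_polymorphism: bool = False
    freq_unknown: bool = False

    @property
    def causative_candidate(self) -> bool:
        return not self.common_polymorphism


def annotate_common_polymorphisms(
    names: list[str],
    catalog: list[CatalogEntry],
    population_freq: dict,
    threshold: float = 0.05,
) -> list[AnnotatedVariant]:
    """Split calls into causative candidates and common-polymorphism tags.

    Variants above the population-frequency threshold are excluded from the
    causative candidate set but retained as annotations (e.g. a common
    benign missense tracked as a complex-allele member); variants missing
    from the frequency map are retained and flagged.
    """
    by_name = {e.name: e for e in catalog}
    out = []
    for name in names:
        entry = by_name.get(name)
        av = AnnotatedVariant(name, entry)
        if name in population_freq:
            av.population_freq = float(population_freq[name])
            av.common_polymorphism = av.population_freq > threshold
        else:
            av.freq_unknown = True
        out.append(av)
    return out


def annotate_calls(calls, catalog: list[CatalogEntry]):
    """Attach catalog names to calls matching a placed catalog variant."""
    by_key = {(e.position, e.ref, e.alt): e for e in catalog if e.position is not None}
    for c in calls:
        entry = by_key.get((c.pos, c.ref, c.alt))
        if entry is not None:
            c.name = entry.name
    return calls


def classify_severity(
    genotype: GenotypeRecord | list,
    catalog: list[CatalogEntry],
) -> str:
    """Mild / severe / unclassified from the allele-slot class content.

    Accepts a ``GenotypeRecord`` or a plain list of allele variant-name
    lists.  Mild: any allele carries a class IV-V causative variant.
    Severe: at least two alleles each anchored by a classed causative
    variant, all of class I-III.  Anything else (empty slot, unclassed
    causative content) is unclassified.
    """
    alleles = genotype.allele_lists if isinstance(genotype, GenotypeRecord) else [
        list(a) for a in genotype]
    by_name = {e.name: e for e in catalog}

    classed: list[list[CatalogEntry]] = []
    for allele in alleles:
        entries = [by_name[v] for v in allele if v in by_name]
        classed.append([e for e in entries if e.is_causative and e.mutation_class != "none"])

    if any(e.is_mild_class for group in classed for e in group):
        return MILD
    anchored = [group for group in classed if group]
    if len(anchored) >= 2 and all(e.is_severe_class for g in anchored for e in g):
        return SEVERE
    return UNCLASSIFIED


@dataclass
class SeverityTally:
    mild: int = 0
    severe: int = 0
    unclassified: int = 0
    labels: list = field(default_factory=list)
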