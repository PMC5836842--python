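"""Synthetic diploid amplicon-read generator.

Reads are full-amplicon (two-step amplicon PCR produces no fragmentation), so
every read carries its amplicon's primers and spans its whole insert — which
is what makes same-amplicon variant pairs always phaseable.  Three error
processes are modelled:

* per-base substitution noise at ``base_error_rate``;
* Phred quality noise (per-read mean ~ N(quality_mean, quality_read_sd),
  per-base ~ N(read mean, quality_base_sd));
* homopolymer stutter: at every reference run of >= 5 identical bases the
  observed run length is the template's run length plus an offset drawn from
  ``hp_length_noise`` (default -2:6%, -1:15%, 0:75%, +1:4%, tuned so a
  non-carrier (A)7 site shows the (A)8 allele near 4%).

Repeat-allele amplification bias: at a homopolymer site carrying a planted
length variant, the fraction of reads drawn from the mutant allele is sampled
once per sample from ``allelic_imbalance_range`` (default 0.25-0.75), which
spreads heterozygous carrier frequencies over the wide observed band while
leaving non-repeat variants balanced at 0.5.

A read's bases inside its *own* primer intervals always show the reference:
primers are synthesized oligos, so template variants under a primer site are
overwritten in that amplicon's product (the false-negative mechanism that
post-alignment primer masking repairs).

Alignments are emitted by construction (truth placement); no aligner runs.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError
from .panel import HomopolymerSite, Panel, find_homopolymers
from .reads import AlignedRead

STUTTER_MIN_RUN = 5  # runs shorter than this do not stutter


@dataclass(frozen=True)
class PlantedVariant:
    """A variant to simulate, VCF-style (indels anchored on the prior base).

    ``haplotype`` is 0 or 1 for heterozygous placements, 2 for homozygous.
    """

    name: str
    pos: int
    ref: str
    alt: str
    haplotype: int = 0

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "snv"
        return "del" if len(self.ref) > len(self.alt) else "ins"

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)


@dataclass
class SimGenotype:
    """Per-sample set of planted variants."""

    variants: list[PlantedVariant] = field(default_factory=list)

    def validate(self, panel: Panel) -> None:
        for v in self.variants:
            if not any(panel.inserts_covering(p) for p in range(v.pos, v.end)) \
                    and not panel.amplicons_covering(v.pos):
                raise SimulationError(f"variant {v.name} at {v.pos} outside all amplicons")
            if panel.reference.sequence[v.pos:v.end] != v.ref:
                raise SimulationError(f"variant {v.name}: ref allele mismatch at {v.pos}")


@dataclass
class SimProfile:
    """Sequencing-noise and depth profile."""

    reads_per_amplicon: float = 200.0
    depth_factors: dict = field(default_factory=dict)  # amplicon id -> multiplier
    strand_fraction: float = 0.5
    base_error_rate: float = 0.002
    quality_mean: float = 30.0
    quality_read_sd: float = 3.0
    quality_base_sd: float = 4.0
    hp_length_noise: dict = field(
        default_factory=lambda: {-2: 0.06, -1: 0.15, 0: 0.75, 1: 0.04}
    )
    allelic_imbalance_range: tuple = (0.25, 0.75)
    # fraction of cohort samples whose runs resolve cleanly (+1 stutter
    # suppressed); models run-to-run flow resolution variability and gives the
    # bimodal non-carrier (A)8 distribution with modes at 0 and ~4%
    hp_clean_fraction: float = 0.5

    def __post_init__(self):
        total = sum(self.hp_length_noise.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"hp_length_noise probabilities sum to {total}, not 1")
        if not (0.0 < self.strand_fraction < 1.0):
            raise ConfigError("strand_fraction must lie in (0,1)")
        lo, hi = self.allelic_imbalance_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("allelic_imbalance_range must lie inside (0,1)")


@dataclass(frozen=True)
class NoiseEdit:
    """A recurrent sequencing artifact injected at read level with some VAF."""

    pos: int
    ref: str
    alt: str
    prob: float


def stable_sample_stream(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample RNG derived from the global seed by hashing the sample id."""
    digest = hashlib.sha256(sample_id.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2 ** 31)
    return np.random.default_rng([int(seed) % (2 ** 31), sub])


def _apply_edits(seq: str, start: int, end: int, edits) -> tuple[str, list]:
    """Rebuild an amplicon read from reference ``seq[start:end]`` plus edits.

    ``edits`` are sorted, non-overlapping (pos, ref, alt) triples in absolute
    reference coordinates; indels carry the anchor base in both alleles.
    """
    parts: list[str] = []
    cigar: list[tuple[str, int]] = []

    def push(op: str, n: int):
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    cur = start
    for pos, ref_a, alt_a in edits:
        if pos < cur or pos + len(ref_a) > end:
            continue  # overlapping a prior edit or sticking out of the read
        if len(ref_a) == len(alt_a) == 1:  # substitution
            parts.append(seq[cur:pos])
            parts.append(alt_a)
            push("M", pos - cur + 1)
            cur = pos + 1
        elif len(ref_a) > len(alt_a):  # deletion (anchored)
            parts.append(seq[cur:pos + 1])
            push("M", pos + 1 - cur)
            push("D", len(ref_a) - len(alt_a))
            cur = pos + len(ref_a)
        else:  # insertion (anchored)
            parts.append(seq[cur:pos + 1])
            parts.append(alt_a[len(ref_a):])
            push("M", pos + 1 - cur)
            push("I", len(alt_a) - len(ref_a))
            cur = pos + 1
    parts.append(seq[cur:end])
    push("M", end - cur)
    return "".join(parts), cigar


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos < e for s, e in intervals)


def simulate_reads(
    panel: Panel,
    genotype: SimGenotype,
    profile: SimProfile,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
    noise_edits: list[NoiseEdit] | None = None,
    hp_plus_scale: float = 1.0,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Simulate one sample; returns truth-placed reads and a truth table.

    ``hp_plus_scale`` rescales the +1 stutter probability (cohort simulation
    uses it to model samples whose runs resolve cleanly).
    """
    genotype.validate(panel)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref_seq = panel.reference.sequence
    noise_edits = noise_edits or []

    hp_sites = find_homopolymers(panel.reference, STUTTER_MIN_RUN)
    hp_windows = {site: site.window() for site in hp_sites}

    # stutter offset distribution, optionally with +1 suppressed
    noise = dict(profile.hp_length_noise)
    if hp_plus_scale != 1.0 and 1 in noise:
        moved = noise[1] * (1.0 - hp_plus_scale)
        noise[1] -= moved
        noise[0] = noise.get(0, 0.0) + moved
    offsets = np.array(sorted(noise), dtype=int)
    offset_p = np.array([noise[o] for o in offsets], dtype=float)

    # split planted variants into repeat-length variants (owned by their run)
    # and ordinary ones
    hp_variant_of_site: dict[HomopolymerSite, PlantedVariant] = {}
    plain_variants: list[PlantedVariant] = []
    for v in genotype.variants:
        owner = None
        if v.kind != "snv":
            run_base = (v.alt[1:] or v.ref[1:])[:1]
            for site, (ws, we) in hp_windows.items():
                if ws <= v.pos < we and site.base == run_base:
                    owner = site
                    break
        if owner is not None:
            if owner in hp_variant_of_site:
                raise SimulationError(f"two length variants at one run: {v.name}")
            hp_variant_of_site[owner] = v
        else:
            plain_variants.append(v)

    # per-sample mutant-allele sampling fraction at each carried repeat site
    lo, hi = profile.allelic_imbalance_range
    hp_fraction = {
        site: (1.0 if var.haplotype == 2 else float(rng.uniform(lo, hi)))
        for site, var in hp_variant_of_site.items()
    }

    reads: list[AlignedRead] = []
    truth_rows = []

    for amp in panel.amplicons:
        mean = profile.reads_per_amplicon * profile.depth_factors.get(amp.id, 1.0)
        n_reads = int(rng.poisson(mean))
        if n_reads == 0:
            continue
        primer_ivs = amp.primer_intervals
        # template variants visible in this amplicon's product (own primer
        # positions are overwritten by the synthesized primer)
        amp_variants = [
            v for v in plain_variants
            if amp.start <= v.pos and v.end <= amp.end
            and not _in_intervals(v.pos, primer_ivs)
        ]
        amp_runs = [
            site for site in hp_sites
            if amp.start < site.start - 1 and site.end + 1 < amp.end
            and not _in_intervals(site.start, primer_ivs)
        ]
        amp_noise = [e for e in noise_edits if amp.insert_start <= e.pos < amp.insert_end]

        haps = rng.integers(0, 2, size=n_reads)
        strands = rng.random(n_reads) < profile.strand_fraction
        read_mus = rng.normal(profile.quality_mean, profile.quality_read_sd, size=n_reads)
        run_offsets = {
            site: offsets[rng.choice(len(offsets), size=n_reads, p=offset_p)]
            for site in amp_runs
        }
        run_mutant = {
            site: rng.random(n_reads) < hp_fraction[site]
            for site in amp_runs if site in hp_fraction
        }
        noise_hits = {e: rng.random(n_reads) < e.prob for e in amp_noise}

        for i in range(n_reads):
            edits = []
            for v in amp_variants:
                if v.haplotype == 2 or v.haplotype == haps[i]:
                    edits.append((v.pos, v.ref, v.alt))
            for site in amp_runs:
                delta = 0
                var = hp_variant_of_site.get(site)
                if var is not None and site in run_mutant and run_mutant[site][i]:
                    delta = len(var.alt) - len(var.ref)
                delta += int(run_offsets[site][i])
                delta = max(delta, -(site.ref_run_length - 1))
                if delta > 0:
                    anchor = site.start - 1
                    edits.append((anchor, ref_seq[anchor], ref_seq[anchor] + site.base * delta))
                elif delta < 0:
                    anchor = site.start - 1
                    edits.append((anchor, ref_seq[anchor] + site.base * (-delta), ref_seq[anchor]))
            for e in amp_noise:
                if noise_hits[e][i]:
                    edits.append((e.pos, e.ref, e.alt))
            edits.sort(key=lambda t: t[0])

            seq, cigar = _apply_edits(ref_seq, amp.start, amp.end, edits)

            n_err = rng.binomial(len(seq), profile.base_error_rate)
            if n_err:
                pos_err = rng.integers(0, len(seq), size=n_err)
                chars = list(seq)
                for p in pos_err:
                    choices = [b for b in "ACGT" if b != chars[p]]
                    chars[p] = choices[rng.integers(0, 3)]
                seq = "".join(chars)

            quals = np.clip(
                np.rint(rng.normal(read_mus[i], profile.quality_base_sd, size=len(seq))),
                2, 41,
            ).astype(np.int16)

            reads.append(AlignedRead(
                id=f"{sample_id}:{amp.id}:{i:05d}",
                ref_start=amp.start,
                strand="+" if strands[i] else "-",
                seq=seq,
                quals=quals,
                cigar=cigar,
            ))

    for v in genotype.variants:
        site = next((s for s, var in hp_variant_of_site.items() if var is v), None)
        if site is not None:
            f = hp_fraction[site]
            expected = f * noise.get(0, 0.0) + (1.0 - f) * noise.get(
                len(v.alt) - len(v.ref), 0.0)
        else:
            f = 0.5 if v.haplotype != 2 else 1.0
            expected = f
        truth_rows.append({
            "sample": sample_id, "name": v.name, "pos": v.pos, "ref": v.ref,
            "alt": v.alt, "kind": v.kind, "category": "hp_variant" if site else "variant",
            "haplotype": v.haplotype, "hp_fraction": f if site else np.nan,
            "expected_vaf": expected,
        })
    for e in noise_edits:
        truth_rows.append({
            "sample": sample_id, "name": f"artifact_{e.pos}", "pos": e.pos,
            "ref": e.ref, "alt": e.alt,
            "kind": "del" if len(e.ref) > len(e.alt) else "ins",
            "category": "artifact", "haplotype": -1, "hp_fraction": np.nan,
            "expected_vaf": e.prob,
        })
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "name", "pos", "ref", "alt", "kind", "category",
                 "haplotype", "hp_fraction", "expected_vaf"],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortScenario:
    """What to plant across a simulated cohort.

    ``carriers`` maps a planted variant (by fixture name or explicit triple)
    to the sample indices carrying it heterozygously.  ``n_shared_snvs``
    additional het SNVs are planted in *every* sample at cohort-chosen
    positions; ``with_phase_pairs`` adds one cis and one trans same-amplicon
    SNV pair per sample.  ``n_artifacts`` recurrent low-VAF single-base
    deletions are injected in a fraction of samples.
    """

    n_samples: int = 20
    profile: SimProfile = field(default_factory=SimProfile)
    n_shared_snvs: int = 6
    with_phase_pairs: bool = True
    carriers: dict = field(default_factory=dict)  # name -> list[int]
    n_artifacts: int = 37
    artifact_sample_fraction: float = 0.85
    artifact_vaf_range: tuple = (0.05, 0.15)

    def validate(self):
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        for name, samples in self.carriers.items():
            if len(samples) > self.n_samples:
                raise ConfigError(f"carrier count for {name} exceeds n_samples")
            if any(s >= self.n_samples for s in samples):
                raise ConfigError(f"carrier index for {name} out of range")


@dataclass
class CohortSim:
    samples: dict  # sample_id -> list[AlignedRead]
    truth: pd.DataFrame
    artifact_positions: list[int]
    snv_positions: list[int]
    phase_pairs: list[tuple]  # (name_a, name_b, relation)


def _candidate_positions(panel: Panel, rng, n: int, taken: set[int],
                         indel_safe: bool = False) -> list[int]:
    seq = panel.reference.sequence
    hp_windows = [s.window(2) for s in find_homopolymers(panel.reference, 4)]
    primer_ivs = panel.primer_union()
    pool = []
    for amp in panel.amplicons:
        pool.extend(range(amp.insert_start + 2, amp.insert_end - 2))
    pool = sorted(set(pool))
    rng.shuffle(pool)
    chosen = []
    for p in pool:
        if len(chosen) == n:
            break
        if any(abs(p - q) < 4 for q in taken) or any(abs(p - q) < 4 for q in chosen):
            continue
        if _in_intervals(p, hp_windows) or _in_intervals(p, primer_ivs):
            continue
        if indel_safe and (seq[p - 1] == seq[p] or seq[p + 1] == seq[p]):
            continue
        chosen.append(p)
    if len(chosen) < n:
        raise SimulationError("panel too small for requested placements")
    return chosen


def simulate_cohort(
    panel: Panel,
    scenario: CohortScenario,
    seed: int,
    catalog=None,
) -> CohortSim:
    """Simulate a cohort with shared variants and recurrent artifacts.

    Per-sample randomness comes from streams derived by hashing sample ids,
    so any subset of samples reproduces independently of the others.
    """
    scenario.validate()
    cohort_rng = np.random.default_rng([int(seed) % (2 ** 31), 0xC0])
    seq = panel.reference.sequence

    placed = {e.name: (e.position, e.ref, e.alt)
              for e in (catalog or []) if e.position is not None}
    taken = {p for p, _, _ in placed.values()}

    snv_pos = _candidate_positions(panel, cohort_rng, scenario.n_shared_snvs, taken)
    taken |= set(snv_pos)

    pair_defs: list[tuple] = []
    if scenario.with_phase_pairs:
        # two same-amplicon SNV pairs: one cis, one trans
        for relation, amp in (("cis", panel.amplicons[6]), ("trans", panel.amplicons[24])):
            p1 = amp.insert_start + 30
            p2 = amp.insert_start + 110
            while p1 in taken or _near_hp(panel, p1):
                p1 += 1
            while p2 in taken or _near_hp(panel, p2):
                p2 += 1
            pair_defs.append((relation, p1, p2))
            taken |= {p1, p2}

    art_pos = _candidate_positions(panel, cohort_rng, scenario.n_artifacts, taken,
                                   indel_safe=True)
    n_art_samples = math.ceil(scenario.artifact_sample_fraction * scenario.n_samples)
    art_samples = {
        p: set(cohort_rng.choice(scenario.n_samples, size=n_art_samples, replace=False).tolist())
        for p in art_pos
    }

    clean = cohort_rng.random(scenario.n_samples) < scenario.profile.hp_clean_fraction

    samples = {}
    truths = []
    phase_pairs_named = []
    for s in range(scenario.n_samples):
        sample_id = f"S{s + 1:03d}"
        rng = stable_sample_stream(seed, sample_id)
        variants = []
        for p in snv_pos:
            variants.append(PlantedVariant(
                f"snv_{p}", p, seq[p], _det_alt(seq[p]),
                haplotype=int(rng.integers(0, 2))))
        for relation, p1, p2 in pair_defs:
            h1 = int(rng.integers(0, 2))
            h2 = h1 if relation == "cis" else 1 - h1
            variants.append(PlantedVariant(f"{relation}_a_{p1}", p1, seq[p1], _det_alt(seq[p1]), h1))
            variants.append(PlantedVariant(f"{relation}_b_{p2}", p2, seq[p2], _det_alt(seq[p2]), h2))
            if s == 0:
                phase_pairs_named.append((f"{relation}_a_{p1}", f"{relation}_b_{p2}", relation))
        for name, carrier_samples in scenario.carriers.items():
            if s in carrier_samples:
                if name not in placed:
                    raise ConfigError(f"carrier variant {name!r} has no placement")
                p, ref, alt = placed[name]
                variants.append(PlantedVariant(name, p, ref, alt, haplotype=int(rng.integers(0, 2))))

        noise = []
        for p in art_pos:
            if s in art_samples[p]:
                v = float(rng.uniform(*scenario.artifact_vaf_range))
                noise.append(NoiseEdit(p - 1, seq[p - 1:p + 1], seq[p - 1], v))

        reads, truth = simulate_reads(
            panel, SimGenotype(variants), scenario.profile, rng, sample_id,
            noise_edits=noise,
            hp_plus_scale=0.05 if clean[s] else 1.0,
        )
        samples[sample_id] = reads
        truths.append(truth)

    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame()
    return CohortSim(samples, truth, art_pos, snv_pos, phase_pairs_named)


def _near_hp(panel: Panel, pos: int) -> bool:
    return any(s.window(2)[0] <= pos < s.window(2)[1]
               for s in find_homopolymers(panel.reference, 4))


def _det_alt(base: str) -> str:
    # deterministic transversion-ish alt, keeps cohort truth stable
    return {"A": "C", "C": "T", "G": "A", "T": "G"}[base]
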