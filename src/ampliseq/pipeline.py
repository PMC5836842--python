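"""End-to-end orchestration: QC -> mask -> call -> homopolymer -> artifact
filter -> phase -> annotate -> genotype, with a run manifest for
reproducibility auditing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from . import __version__
from .annotate import annotate_calls
from .errors import PipelineError
from .homopolymer import hp_calls_for_sample
from .panel import CallerConfig, CatalogEntry, Panel, find_homopolymers
from .phase import (classify_phase, collect_phase_evidence, assemble_genotype)
from .preprocess import filter_read_list
from .primer_trim import mask_all
from .reads import AlignedRead
from .variant_call import build_pileup, call_pileup, recurrent_artifact_filter

log = logging.getLogger("ampliseq")


@dataclass
class SampleResult:
    sample: str
    calls: list = field(default_factory=list)      # generic + hp calls
    hp_results: dict = field(default_factory=dict)
    genotype: object = None
    qc_stats: object = None
    counts: dict = field(default_factory=dict)

    @property
    def pass_calls(self):
        return [c for c in self.calls if c.is_pass]


@dataclass
class CohortResult:
    samples: dict = field(default_factory=dict)    # sample -> SampleResult
    blacklist: set = field(default_factory=set)
    manifest: dict = field(default_factory=dict)


def call_sample(
    reads: list[AlignedRead],
    panel: Panel,
    config: CallerConfig,
    sample: str,
    qc: bool = True,
) -> SampleResult:
    """QC, mask and call one sample (no cross-sample stages)."""
    result = SampleResult(sample)
    result.counts["input_reads"] = len(reads)
    if qc:
        reads, stats = filter_read_list(reads, config)
        result.qc_stats = stats
        result.counts["qc_kept"] = stats.kept
    mask_all(reads, panel)
    hp_sites = find_homopolymers(panel.reference, config.hp_min_length)
    pileup = build_pileup(reads, panel, config)
    calls = call_pileup(pileup, config, hp_sites, sample)
    hp_calls, hp_results = hp_calls_for_sample(
        reads, hp_sites, config, panel.reference.sequence, sample)
    result.calls = calls + hp_calls
    result.hp_results = hp_results
    result.counts["generic_calls"] = len(calls)
    result.counts["hp_calls"] = len(hp_calls)
    result._reads = reads  # kept for the phasing stage
    return result


def phase_sample(
    result: SampleResult,
    panel: Panel,
    config: CallerConfig,
    catalog: list[CatalogEntry] | None = None,
    external_cnv: list[str] | None = None,
):
    """Phase PASS calls and assemble the sample genotype."""
    calls = result.pass_calls
    if catalog:
        annotate_calls(calls, catalog)
    reads = getattr(result, "_reads", [])
    ref_seq = panel.reference.sequence
    phases = {}
    for c1, c2 in combinations(calls, 2):
        ev = collect_phase_evidence(reads, c1, c2, ref_seq)
        label1 = c1.name or f"{c1.pos}:{c1.ref}>{c1.alt}"
        label2 = c2.name or f"{c2.pos}:{c2.ref}>{c2.alt}"
        phases[frozenset((label1, label2))] = classify_phase(
            ev, config.phase_min_reads, config.phase_max_contradiction)
    cdna_of = {e.name: e.cdna_name for e in catalog or []}
    status_of = {e.name: e.status for e in catalog or []}
    genotype = assemble_genotype(
        calls, phases, external_cnv, sample=result.sample,
        cdna_of=cdna_of, status_of=status_of)
    result.genotype = genotype
    return genotype


def run_cohort(
    samples: dict[str, list[AlignedRead]],
    panel: Panel,
    config: CallerConfig | None = None,
    catalog: list[CatalogEntry] | None = None,
    external_cnv: dict[str, list[str]] | None = None,
    qc: bool = True,
    phase: bool = True,
    seed: int | None = None,
) -> CohortResult:
    """The full multi-sample pipeline over in-memory reads."""
    config = config or CallerConfig()
    out = CohortResult()
    for sample_id, reads in samples.items():
        try:
            out.samples[sample_id] = call_sample(reads, panel, config, sample_id, qc)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise PipelineError("call", sample_id, str(exc)) from exc
    calls_by_sample = {
        s: [c for c in r.calls if not c.hp_call] for s, r in out.samples.items()}
    out.blacklist, _ = recurrent_artifact_filter(calls_by_sample, config)
    if phase:
        for sample_id, result in out.samples.items():
            try:
                phase_sample(result, panel, config, catalog,
                             (external_cnv or {}).get(sample_id))
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("phase", sample_id, str(exc)) from exc
    out.manifest = build_manifest(config, out, seed)
    return out


def non_hp_blacklist(blacklist: set, panel: Panel, config: CallerConfig) -> set:
    """Blacklist entries outside homopolymer windows (planted-artifact view)."""
    windows = [s.window() for s in find_homopolymers(panel.reference, config.hp_min_length)]
    return {
        key for key in blacklist
        if not any(ws <= key[0] < we for ws, we in windows)
    }


def build_manifest(config: CallerConfig, cohort: CohortResult,
                   seed: int | None = None,
                   input_digests: dict | None = None) -> dict:
    return {
        "tool": "ampliseq",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "inputs": input_digests or {},
        "stages": {
            s: r.counts for s, r in cohort.samples.items()
        },
        "blacklist_size": len(cohort.blacklist),
    }


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
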