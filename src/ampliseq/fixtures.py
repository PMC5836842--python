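"""Built-in study fixtures: synthetic panel, catalog, and cohort tables.

The panel reference is a synthetic ~9 kb sequence — NOT the true CFTR locus —
tiled by 33 overlapping amplicons (lengths 172-328 bp, 20 bp primers, 44 bp
overlap between neighbours so that every internal primer interval is covered
by the neighbouring amplicon's insert).  A handful of catalog variants are
planted at fixed positions so the simulator, caller, phaser and annotator can
be exercised end to end:

* ``E92K``     - SNV inside the forward primer of amplicon A05 (and inside the
                 insert of A04): the primer-masking showcase.
* ``L467F``    - SNV in the A12 insert, 68 bp upstream of F508del (cis-phaseable).
* ``F508del``  - 3 bp deletion in the A12 insert.
* ``2184insA`` - single-A duplication in a planted (A)7 homopolymer in A16.
* ``2143delT`` - 1 bp deletion in the A21 insert.

The genotype table is transcribed from the study's published cohort table;
per-patient phenotype numerics are synthetic but constrained to the published
aggregates (marginal counts, group means, the three complex-allele carrier
weights 36/44/48 kg and the two high-FVC/FEV patients).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import PanelError
from .panel import (Amplicon, CatalogEntry, HomopolymerSite, Panel,
                    PanelReference, find_homopolymers, load_catalog)

REFERENCE_NAME = "panel_ref"
_REF_SEED = 7042018  # fixed: the fixture is a constant, not a simulation
_MARGIN = 60
_PRIMER_LEN = 20
_OVERLAP = 44
N_AMPLICONS = 33


def _data_path(name: str):
    return resources.files("ampliseq.data").joinpath(name)


def _amplicon_lengths() -> list[int]:
    # one short amplicon plus 32 in the 300-328 range; bounds match the
    # published 172-328 bp panel design
    return [172] + [300 + (7 * i) % 29 for i in range(1, N_AMPLICONS)]


def build_reference_and_panel() -> tuple[Panel, dict[str, tuple[int, str, str]]]:
    """Construct the synthetic reference, amplicons and variant placements.

    Returns the panel and a map ``name -> (vcf_like_pos, ref_allele,
    alt_allele)`` in 0-based coordinates with indels anchored on the base
    before the event.
    """
    lengths = _amplicon_lengths()
    starts = [_MARGIN]
    for length in lengths[:-1]:
        starts.append(starts[-1] + length - _OVERLAP)
    ref_len = starts[-1] + lengths[-1] + _MARGIN

    rng = np.random.default_rng(_REF_SEED)
    seq = rng.choice(list("ACGT"), size=ref_len)

    amps = [
        Amplicon(f"A{i + 1:02d}", s, s + L, _PRIMER_LEN, _PRIMER_LEN)
        for i, (s, L) in enumerate(zip(starts, lengths))
    ]

    def plant(pos: int, bases: str):
        seq[pos:pos + len(bases)] = list(bases)

    # E92K-like SNV inside A05's forward primer / A04's insert
    pos_e92k = amps[4].start + 8
    plant(pos_e92k - 1, "TGC")  # G flanked by non-G so no run forms

    # L467F-like SNV and F508del-like CTT deletion on the same amplicon
    pos_l467f = amps[11].insert_start + 12
    plant(pos_l467f - 1, "ACG")
    pos_f508 = amps[11].insert_start + 80
    plant(pos_f508 - 1, "GCTTAG")  # delete CTT; left-aligned (G before C)

    # (A)7 homopolymer carrying the single-A duplication site
    pos_hp = amps[15].insert_start + 100
    plant(pos_hp - 2, "TG" + "A" * 7 + "CT")

    # single-T deletion site with non-T flanks (left-aligned as planted)
    pos_del_t = amps[20].insert_start + 50
    plant(pos_del_t - 1, "GTC")

    reference = PanelReference(REFERENCE_NAME, "".join(seq))
    panel = Panel(reference, amps)

    s = reference.sequence
    placements = {
        "E92K": (pos_e92k, "G", "A"),
        "L467F": (pos_l467f, "C", "T"),
        "F508del": (pos_f508 - 1, s[pos_f508 - 1:pos_f508 + 3], s[pos_f508 - 1]),
        "2184insA": (pos_hp - 1, s[pos_hp - 1], s[pos_hp - 1] + "A"),
        "2143delT": (pos_del_t - 1, s[pos_del_t - 1:pos_del_t + 1], s[pos_del_t - 1]),
    }
    _validate_placements(panel, placements)
    return panel, placements


def _validate_placements(panel: Panel, placements: dict) -> None:
    seq = panel.reference.sequence
    hp_windows = [site.window() for site in find_homopolymers(seq, 5)]
    for name, (pos, ref, alt) in placements.items():
        if seq[pos:pos + len(ref)] != ref:
            raise PanelError(f"planted {name}: reference mismatch at {pos}")
        if not panel.inserts_covering(pos) and name != "E92K":
            raise PanelError(f"planted {name} at {pos} outside all inserts")
        if name not in ("2184insA",) and any(s <= pos < e for s, e in hp_windows):
            raise PanelError(f"planted {name} at {pos} collides with a homopolymer window")


def default_panel() -> Panel:
    return build_reference_and_panel()[0]


def default_catalog() -> list[CatalogEntry]:
    """Catalog TSV entries with fixture placements filled in."""
    entries = load_catalog(_data_path("catalog.tsv"))
    _, placements = build_reference_and_panel()
    out = []
    for e in entries:
        if e.name in placements:
            pos, ref, alt = placements[e.name]
            e = replace(e, position=pos, ref=ref, alt=alt)
        out.append(e)
    return out


def planted_hp_site(panel: Panel | None = None) -> HomopolymerSite:
    """The planted (A)7 site carrying the 2184insA fixture variant."""
    panel = panel or default_panel()
    _, placements = build_reference_and_panel()
    anchor = placements["2184insA"][0]
    for site in find_homopolymers(panel.reference, 5):
        if site.start == anchor + 1 and site.base == "A":
            return site
    raise PanelError("planted (A)7 site not found")  # pragma: no cover


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def load_table2() -> pd.DataFrame:
    """The transcribed published genotype table (one row per genotype)."""
    return pd.read_csv(_data_path("table2_genotypes.tsv"), sep="\t", dtype={"row": int, "n": int})


def load_votes() -> pd.DataFrame:
    return pd.read_csv(_data_path("prediction_votes.tsv"), sep="\t")


def load_popfreq() -> dict[str, float]:
    df = pd.read_csv(_data_path("population_freqs.tsv"), sep="\t")
    return dict(zip(df["variant"], df["maf"]))


def load_hp_example() -> pd.DataFrame:
    """Per-sample (A)8 allele frequencies for the worked example.

    The four carrier frequencies are the published ones (16/18/21/42%);
    the 80 non-carrier values are synthetic, bounded at 8% with modes at
    0 and 4% as described for the cohort.
    """
    return pd.read_csv(_data_path("hp_a8_freqs_synthetic.tsv"), sep="\t")


def split_allele(allele: str) -> list[str]:
    """Split an allele-slot string into variant names ('(;)' = unknown phase)."""
    parts = []
    for chunk in allele.split("(;)"):
        parts.extend(v for v in chunk.split(";") if v)
    return parts


def patient_variants(row) -> list[str]:
    return split_allele(row["allele1"]) + split_allele(row["allele2"])


def build_cohort_table(seed: int = 20180213) -> pd.DataFrame:
    """Expand the genotype table into an 84-patient phenotype table.

    Genotypes and the printed M/S and pancreatic labels are transcribed;
    numeric phenotype fields are synthetic draws constrained to the published
    aggregates: the three R668C complex-allele carriers weigh 36/44/48 kg, the
    two R1070Q carriers have FVC 107/109% and FEV 90/111%, diabetes occurs
    only in severe patients (10 cases), S. aureus is enriched in the mild
    group (11 of 12 positives), and group means/ranges track the published
    cohort table.
    """
    table2 = load_table2()
    rng = np.random.default_rng(seed)

    rows = []
    for _, g in table2.iterrows():
        for _ in range(int(g["n"])):
            rows.append({
                "row": int(g["row"]),
                "allele1": g["allele1"],
                "allele2": g["allele2"],
                "phenotype": g["phenotype"],
                "pancreatic": g["pancreatic"],
            })
    df = pd.DataFrame(rows)
    df.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(len(df))])

    n = len(df)
    df["sex"] = ["M" if i < 40 else "F" for i in range(n)]
    df["age"] = np.clip(19 + rng.exponential(7, size=n).astype(int), 19, 47)
    df["height"] = np.clip(np.round(rng.normal(168, 8, size=n)), 142, 187)
    df["weight"] = np.round(np.clip(rng.normal(52.5, 5.0, size=n), 33, 75), 1)
    df["fvc"] = np.round(np.clip(rng.normal(67, 20, size=n), 28, 120))
    df["fev"] = np.round(np.clip(rng.normal(47, 18, size=n), 15, 111))

    # published anchor values
    r668c_rows = df.index[df["allele1"].str.contains("R668C")].tolist()
    for idx, w in zip(r668c_rows, (36.0, 44.0, 48.0)):
        df.loc[idx, "weight"] = w
    r1070q_rows = df.index[
        df["allele1"].str.contains("R1070Q") | df["allele2"].str.contains("R1070Q")
    ].tolist()
    for idx, (fvc, fev) in zip(r1070q_rows, ((107, 90), (109, 111))):
        df.loc[idx, "fvc"] = fvc
        df.loc[idx, "fev"] = fev

    severe_idx = df.index[df["phenotype"] == "S"].tolist()
    mild_idx = df.index[df["phenotype"] == "M"].tolist()
    df["diabetes"] = False
    df.loc[severe_idx[:10], "diabetes"] = True

    df["s_aureus"] = False
    df.loc[mild_idx[:11], "s_aureus"] = True
    df.loc[severe_idx[:1], "s_aureus"] = True
    for col, count in (("p_aeruginosa", 41), ("achromobacter", 7),
                       ("stenotrophomonas", 1), ("e_coli", 1), ("b_cepacia", 22)):
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=count, replace=False)] = True
        df[col] = flags
    return df
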