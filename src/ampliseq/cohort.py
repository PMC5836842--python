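"""Cohort genotype-phenotype statistics.

Works on a per-patient table (one row per patient) whose genotype columns
``allele1``/``allele2`` hold ``;``-joined (cis) and ``(;)``-joined
(unknown-phase) variant names, plus phenotype fields: pancreatic status,
diabetes, weight/height, FVC/FEV percent-predicted, and bacterial flora
flags.

Statistical conventions: association tests are two-sided Fisher exact;
group means are reported with z-based 95% confidence intervals
(mean +- 1.96 s/sqrt(n), sample SD) — the convention consistent with the
published intervals (a t-based CI for n=3 would be markedly wider); the
two-group location test is Welch's t by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import classify_severity
from .errors import AmpliseqError
from .fixtures import split_allele
from .panel import CatalogEntry

Z95 = 1.96


@dataclass
class CohortSummary:
    n: int = 0
    severity: dict = field(default_factory=dict)
    pancreatic: dict = field(default_factory=dict)
    variant_carriers: dict = field(default_factory=dict)
    genotype_counts: dict = field(default_factory=dict)
    multi_variant_patients: int = 0
    per_patient_severity: list = field(default_factory=list)

    def carriers(self, variant: str) -> int:
        return self.variant_carriers.get(variant, 0)

    def genotype_count(self, allele_a: str, allele_b: str) -> int:
        return self.genotype_counts.get(tuple(sorted((allele_a, allele_b))), 0)


def patient_alleles(row) -> list[list[str]]:
    return [split_allele(row["allele1"]), split_allele(row["allele2"])]


def tally_cohort(patients: pd.DataFrame, catalog: list[CatalogEntry]) -> CohortSummary:
    """Severity, pancreatic, carrier, exact-genotype and complexity tallies.

    Severity labels are recomputed from the catalog's mutation classes, not
    read from the table.  'Carrying' a variant means it appears in either
    allele; the exact-genotype count keys on the unordered pair of printed
    allele strings; ``multi_variant_patients`` counts patients with more
    than two pathogenic / likely-pathogenic / VUS variants.
    """
    if patients["patient_id"].duplicated().any():
        dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise AmpliseqError(f"duplicate patient ids: {dupes}")
    by_name = {e.name: e for e in catalog}
    summary = CohortSummary(n=len(patients))
    for _, row in patients.iterrows():
        alleles = patient_alleles(row)
        severity = classify_severity(alleles, catalog)
        summary.per_patient_severity.append(severity)
        summary.severity[severity] = summary.severity.get(severity, 0) + 1
        panc = row.get("pancreatic", "unknown")
        summary.pancreatic[panc] = summary.pancreatic.get(panc, 0) + 1
        variants = [v for allele in alleles for v in allele]
        for v in set(variants):
            summary.variant_carriers[v] = summary.variant_carriers.get(v, 0) + 1
        key = tuple(sorted((row["allele1"], row["allele2"])))
        summary.genotype_counts[key] = summary.genotype_counts.get(key, 0) + 1
        relevant = sum(
            1 for v in variants
            if v in by_name and by_name[v].status in ("pathogenic", "likely_pathogenic", "VUS")
        )
        if relevant > 2:
            summary.multi_variant_patients += 1
    return summary


def _as_binary(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    values = sorted(series.dropna().unique())
    if len(values) != 2:
        raise AmpliseqError(f"field is not binary: {values}")
    return series == values[0]


def fisher_association(
    patients: pd.DataFrame,
    group_by: str,
    outcome: str,
) -> tuple[np.ndarray, float]:
    """Two-sided Fisher exact test between two binary patient fields.

    Returns the 2x2 table (rows: group_by true/false, columns: outcome
    true/false) and the exact p-value; a degenerate margin yields p = 1.
    """
    g = _as_binary(patients[group_by])
    o = _as_binary(patients[outcome])
    table = np.array([
        [int((g & o).sum()), int((g & ~o).sum())],
        [int((~g & o).sum()), int((~g & ~o).sum())],
    ])
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        return table, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


@dataclass
class GroupComparison:
    n: int
    mean: float
    mean_rounded: int
    ci_low: float | None
    ci_high: float | None
    complement_mean: float | None
    p_value: float | None
    ci_undefined: bool = False


def group_comparison(
    patients: pd.DataFrame,
    subset: pd.Series | np.ndarray,
    metric: str,
    equal_var: bool = False,
) -> GroupComparison:
    """Subset mean with z-based 95% CI and a t-test against the complement.

    ``subset`` is a boolean mask over the table rows.  The CI uses the
    sample SD; with n = 1 the CI is undefined and flagged.  The t-test is
    Welch's by default (``equal_var=True`` switches to pooled variance).
    """
    mask = np.asarray(subset, dtype=bool)
    values = patients.loc[mask, metric].dropna().to_numpy(dtype=float)
    other = patients.loc[~mask, metric].dropna().to_numpy(dtype=float)
    if len(values) == 0:
        raise AmpliseqError("empty subset")
    mean = float(np.mean(values))
    n = len(values)
    if n > 1:
        s = float(np.std(values, ddof=1))
        half = Z95 * s / np.sqrt(n)
        ci_low, ci_high, undefined = mean - half, mean + half, False
    else:
        ci_low = ci_high = None
        undefined = True
    if len(other) > 1 and n > 1:
        if np.std(values) == 0 and np.std(other) == 0 and np.mean(values) == np.mean(other):
            p = 1.0
        else:
            _, p = stats.ttest_ind(values, other, equal_var=equal_var)
            p = float(p)
    else:
        p = None
    return GroupComparison(
        n=n, mean=mean, mean_rounded=int(round(mean)),
        ci_low=ci_low, ci_high=ci_high,
        complement_mean=float(np.mean(other)) if len(other) else None,
        p_value=p, ci_undefined=undefined,
    )


def carrier_mask(patients: pd.DataFrame, variant: str) -> pd.Series:
    """Boolean mask of patients carrying ``variant`` in either allele."""
    return patients.apply(
        lambda row: variant in split_allele(row["allele1"]) + split_allele(row["allele2"]),
        axis=1,
    )


def severity_mask(patients: pd.DataFrame, catalog: list[CatalogEntry]) -> pd.Series:
    """Boolean mask: True for mild (class IV-V carrying) patients."""
    return patients.apply(
        lambda row: classify_severity(patient_alleles(row), catalog) == "mild", axis=1)
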