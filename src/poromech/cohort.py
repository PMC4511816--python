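"""Detection-yield and genotype-phenotype cross-tabulation.

Summarises a cohort of index patients — each with a set of mutated
mevalonate-pathway genes (possibly empty, i.e. genetically unexplained)
and clinical phenotype attributes — into the per-arm detection yield and a
clinical-characteristics-by-gene cross-tab.  A patient carrying mutations
in two genes contributes to both gene columns of the cross-tab (column
totals then exceed the patient count) but is counted once in the yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import percent
from .datamodel import CAUSAL_GENES, CohortRecord


@dataclass
class YieldSummary:
    per_arm: dict[str, tuple[int, int, int]]  # arm -> (carriers, n, percent)
    total_carriers: int
    total_patients: int
    total_percent: int


def detection_yield(cohort: list[CohortRecord]) -> YieldSummary:
    """Carrier counts and integer percentages per cohort arm, plus total."""
    if not cohort:
        raise ValueError("empty cohort")
    per_arm: dict[str, tuple[int, int, int]] = {}
    for arm in ("familial", "sporadic"):
        records = [r for r in cohort if r.cohort_arm == arm]
        if not records:
            continue
        carriers = sum(r.is_carrier for r in records)
        per_arm[arm] = (carriers, len(records), percent(carriers, len(records)))
    total_carriers = sum(r.is_carrier for r in cohort)
    return YieldSummary(
        per_arm=per_arm,
        total_carriers=total_carriers,
        total_patients=len(cohort),
        total_percent=percent(total_carriers, len(cohort)),
    )


@dataclass
class CrossTab:
    """Phenotype x gene-group contingency table.

    ``columns`` are the causal genes plus ``unknown``; ``table`` rows are
    ``(section, category)`` pairs.  ``column_totals`` count patients per
    gene column with dual-gene patients counted in each of their columns;
    ``footnotes`` records those dual-gene patients.
    """

    table: pd.DataFrame
    column_totals: dict[str, int]
    footnotes: list[str] = field(default_factory=list)


_SECTIONS = [
    ("sex", lambda r: [r.sex] if r.sex else []),
    ("lesion_count", lambda r: [r.lesion_count_category]
        if r.lesion_count_category else []),
    ("onset", lambda r: [r.onset_category] if r.onset_category else []),
    ("pk_variant", lambda r: sorted(r.pk_variants)),
    ("comorbidity", lambda r: sorted(r.comorbidity)),
]


def genotype_phenotype_crosstab(cohort: list[CohortRecord]) -> CrossTab:
    """Cross-tabulate phenotype categories against mutated-gene groups."""
    columns = list(CAUSAL_GENES) + ["unknown"]
    counts: dict[tuple[str, str], dict[str, int]] = {}
    column_totals = {c: 0 for c in columns}
    footnotes: list[str] = []

    for r in cohort:
        genes = sorted(r.genes_mutated) or ["unknown"]
        for g in genes:
            if g not in columns:
                raise ValueError(f"gene {g!r} outside the causal-gene columns")
            column_totals[g] += 1
        if len(genes) > 1:
            footnotes.append(
                f"patient {r.patient_id} counted in {' and '.join(genes)} columns"
            )
        for section, extractor in _SECTIONS:
            for category in extractor(r):
                row = counts.setdefault((section, category), dict.fromkeys(columns, 0))
                for g in genes:
                    row[g] += 1

    index = pd.MultiIndex.from_tuples(
        sorted(counts), names=["section", "category"]
    )
    table = pd.DataFrame(
        [counts[key] for key in sorted(counts)], index=index, columns=columns
    )
    return CrossTab(table=table, column_totals=column_totals, footnotes=footnotes)


def recurrent_allele_share(
    cohort: list[CohortRecord],
    carriers_by_allele: dict[str, set[str]],
    alleles: list[str],
    gene: str,
) -> tuple[int, int, int]:
    """Share of a gene's patients explained by a list of recurrent alleles.

    ``carriers_by_allele`` maps each cDNA allele to the patient ids carrying
    it.  Returns (carrier count, gene patient count, integer percent);
    the denominator is every cohort patient with any mutation in ``gene``.
    """
    gene_patients = {r.patient_id for r in cohort if gene in r.genes_mutated}
    if not gene_patients:
        raise ValueError(f"no patients with a {gene} mutation")
    carriers: set[str] = set()
    for allele in alleles:
        carriers |= carriers_by_allele.get(allele, set()) & gene_patients
    return (
        len(carriers),
        len(gene_patients),
        percent(len(carriers), len(gene_patients)),
    )
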