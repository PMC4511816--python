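"""Deterministic cohort and mutation-list fixtures from the published counts.

The study deposits no raw data; its printed per-gene carrier counts,
mutation spectrum and clinical cross-tab are treated as inputs and encoded
here as deterministic fixture builders.  Where the supplementary tables are
not public (the per-mutation list, the allelic-signal table) the fixtures
are synthetic stand-ins constructed to match every printed marginal count;
they are labelled as such.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datamodel import AlleleSignalSet, CohortRecord, MechanismLabel, VariantType
from .simulate import SimulationConfig, gen_allele_signals

#: Per-arm carrier counts as printed: gene -> (familial, sporadic) counts of
#: patients carrying a mutation in that gene only.  One familial patient
#: carries both an MVK and an MVD mutation and is listed separately.
SINGLE_GENE_COUNTS = {
    "MVD": (30, 31),
    "PMVK": (3, 6),
    "FDPS": (2, 2),
    "MVK": (24, 14),
}
DUAL_GENE_FAMILIAL = ("MVK", "MVD")  # the F-28-like dual-mutation patient
N_FAMILIAL = 61
N_SPORADIC = 73

#: Giant-plaque phenotype count among MVK index patients, and the
#: denominator convention of the results text (single-gene MVK patients).
PPT_MVK_COUNT = 19

#: The two recurrent MVD alleles and the number of unrelated patients
#: carrying either of them.
RECURRENT_MVD_ALLELES = ("c.746T>C", "c.875A>G")
RECURRENT_MVD_CARRIERS = 50


def results_cohort() -> tuple[list[CohortRecord], dict[str, set[str]]]:
    """Build the 134-index-patient cohort from the printed per-gene counts.

    Returns the cohort records plus a carriers-by-allele map for the two
    recurrent MVD alleles (synthetic patient-to-allele assignment honouring
    the printed carrier total).  Phenotype attributes are filled only where
    a printed count pins them down (the giant-plaque phenotype under MVK).
    """
    cohort: list[CohortRecord] = []
    counters = {"familial": 0, "sporadic": 0}

    def new_patient(arm: str, genes: frozenset, sex: str = "male",
                    pk_variants: frozenset = frozenset()) -> CohortRecord:
        counters[arm] += 1
        prefix = "F" if arm == "familial" else "S"
        rec = CohortRecord(
            patient_id=f"{prefix}-{counters[arm]}",
            cohort_arm=arm, sex=sex, genes_mutated=genes,
            pk_variants=pk_variants,
        )
        cohort.append(rec)
        return rec

    mvk_single: list[CohortRecord] = []
    mvd_patients: list[CohortRecord] = []
    for gene, (n_fam, n_spo) in SINGLE_GENE_COUNTS.items():
        for arm, n in (("familial", n_fam), ("sporadic", n_spo)):
            for _ in range(n):
                rec = new_patient(arm, frozenset({gene}))
                if gene == "MVK":
                    mvk_single.append(rec)
                if gene == "MVD":
                    mvd_patients.append(rec)

    dual = new_patient(
        "familial", frozenset(DUAL_GENE_FAMILIAL), sex="female"
    )
    mvd_patients.append(dual)

    # giant-plaque phenotype on 19 of the single-gene MVK patients
    for rec in mvk_single[:PPT_MVK_COUNT]:
        rec.pk_variants = frozenset({"giant-plaque PPt"})

    while counters["familial"] < N_FAMILIAL:
        new_patient("familial", frozenset())
    while counters["sporadic"] < N_SPORADIC:
        new_patient("sporadic", frozenset())

    # recurrent-allele assignment: 50 of the 62 MVD patients carry one of
    # the two recurrent alleles (the dual patient carries the common one)
    carriers_by_allele: dict[str, set[str]] = {a: set() for a in RECURRENT_MVD_ALLELES}
    carriers = [dual] + [r for r in mvd_patients if r is not dual]
    carriers = carriers[:RECURRENT_MVD_CARRIERS]
    for i, rec in enumerate(carriers):
        allele = RECURRENT_MVD_ALLELES[0] if i < 40 else RECURRENT_MVD_ALLELES[1]
        carriers_by_allele[allele].add(rec.patient_id)
    return cohort, carriers_by_allele


def single_gene_mvk_count(cohort: list[CohortRecord]) -> int:
    """The results-text PPt denominator: patients mutated in MVK alone."""
    return sum(1 for r in cohort if r.genes_mutated == frozenset({"MVK"}))


# ---------------------------------------------------------------------------
# mutation-spectrum fixture

def _synthetic_missense(gene: str, n: int, start_pos: int) -> list[tuple]:
    rows = []
    for i in range(n):
        pos = start_pos + 3 * i
        rows.append((gene, f"c.{pos}G>A", f"p.Ala{pos // 3}Thr", False))
    return rows


def spectrum_mutations() -> list[tuple[str, str, Optional[str], bool]]:
    """The 51-mutation list as (gene, cdna, protein, large_deletion).

    Alleles named in the main text are used verbatim; the remainder are
    synthetic stand-ins chosen so the per-gene and per-type counts match
    the printed spectrum: 30 missense, 2 start-codon, 5 nonsense, 7
    frameshift indels, 4 splice-site changes and 3 large deletions across
    28 MVK, 13 MVD, 6 PMVK and 4 FDPS mutations.
    """
    muts: list[tuple[str, str, Optional[str], bool]] = []

    # MVK: 15 missense, 2 start codon, 3 nonsense, 4 frameshift,
    # 2 splicing, 2 large deletions = 28
    muts += [("MVK", "c.235G>A", "p.Asp79Asn", False),
             ("MVK", "c.1093T>A", "p.Ser365Thr", False)]
    muts += _synthetic_missense("MVK", 13, 301)
    muts += [("MVK", "c.1A>G", "p.Met1?", False),
             ("MVK", "c.2T>C", "p.Met1?", False)]
    muts += [("MVK", "c.417C>A", "p.Tyr139Ter", False),
             ("MVK", "c.600G>A", "p.Trp200Ter", False),
             ("MVK", "c.901C>T", "p.Arg301Ter", False)]
    muts += [("MVK", "c.395delT", "p.Leu132ArgfsTer26", False),
             ("MVK", "c.500delA", "p.Lys167ArgfsTer10", False),
             ("MVK", "c.700_701insT", "p.Gly234ValfsTer5", False),
             ("MVK", "c.810dupC", "p.Ile271HisfsTer8", False)]
    muts += [("MVK", "c.371+2T>A", None, False),
             ("MVK", "c.768+1G>T", None, False)]
    muts += [("MVK", "c.(?_-1)_(283+1_284-1)del", None, True),
             ("MVK", "c.(463+1_464-1)_(*1_?)del", None, True)]

    # MVD: 11 missense, 1 nonsense, 1 frameshift = 13
    muts += [("MVD", "c.746T>C", "p.Phe249Ser", False),
             ("MVD", "c.875A>G", "p.Asn292Ser", False),
             ("MVD", "c.302C>G", "p.Pro101Arg", False),
             ("MVD", "c.683G>A", "p.Arg228Gln", False)]
    muts += _synthetic_missense("MVD", 7, 401)
    muts += [("MVD", "c.520C>T", "p.Gln174Ter", False),
             ("MVD", "c.930delC", "p.Phe311SerfsTer12", False)]

    # PMVK: 3 missense, 1 nonsense, 2 frameshift = 6
    muts += _synthetic_missense("PMVK", 3, 121)
    muts += [("PMVK", "c.412C>T", "p.Arg138Ter", False),
             ("PMVK", "c.200delG", "p.Gly67AlafsTer3", False),
             ("PMVK", "c.310_311delCT", "p.Leu104ValfsTer7", False)]

    # FDPS: 1 missense, 2 splicing, 1 large deletion = 4
    muts += _synthetic_missense("FDPS", 1, 211)
    muts += [("FDPS", "c.684+1G>A", None, False),
             ("FDPS", "c.885+2T>C", None, False),
             ("FDPS", "c.(?_-1)_(174+1_175-1)del", None, True)]
    assert len(muts) == 51
    return muts


# ---------------------------------------------------------------------------
# synthetic stand-in for the 13-tissue-pair allelic-signal table

#: (patient, site, germline mutation, germline type, true mechanism) for the
#: 13 lesional/normal tissue pairs: two gene-conversion lesions, one
#: RNA-editing lesion without AEI, eight lesions with wild-allele
#: silencing, and two without detectable mechanism.
STUDY_TISSUE_PAIRS: list[tuple[str, str, str, VariantType, MechanismLabel]] = [
    ("F-31", "buttock", "c.395delT", VariantType.frameshift_indel,
     MechanismLabel.gene_conversion),
    ("F-43b", "left thigh", "c.1093T>A", VariantType.missense,
     MechanismLabel.gene_conversion),
    ("F-38", "left forearm", "c.1093T>A", VariantType.missense,
     MechanismLabel.rna_editing),
    ("F-42", "trunk", "c.371+2T>A", VariantType.splicing,
     MechanismLabel.epigenetic_silencing_unknown),
    ("S-36", "arm", "c.684+1G>A", VariantType.splicing,
     MechanismLabel.epigenetic_silencing_unknown),
    ("F-43a", "left forearm", "c.1093T>A", VariantType.missense,
     MechanismLabel.epigenetic_silencing_unknown),
    ("F-12", "leg", "c.746T>C", VariantType.missense,
     MechanismLabel.epigenetic_silencing_unknown),
    ("S-07", "chest", "c.746T>C", VariantType.missense,
     MechanismLabel.epigenetic_silencing_unknown),
    ("F-05", "back", "c.875A>G", VariantType.missense,
     MechanismLabel.epigenetic_silencing_unknown),
    ("S-41", "forearm", "c.235G>A", VariantType.missense,
     MechanismLabel.epigenetic_silencing_unknown),
    ("F-19", "thigh", "c.417C>A", VariantType.nonsense,
     MechanismLabel.epigenetic_silencing_unknown),
    ("S-11", "abdomen", "c.875A>G", VariantType.missense,
     MechanismLabel.none),
    ("F-51", "shoulder", "c.746T>C", VariantType.missense,
     MechanismLabel.none),
]


def study_signal_sets(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> tuple[list[AlleleSignalSet], list[dict]]:
    """Synthetic stand-in for the study's 13-tissue-pair signal table.

    Generates one allele-signal set per tissue pair under its reported
    mechanism (the supplementary table itself is not public).  Ten of the
    thirteen lesions carry a true wild-allele expression reduction.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    sets, truths = [], []
    for patient, site, mutation, vtype, mechanism in STUDY_TISSUE_PAIRS:
        s, truth = gen_allele_signals(
            mechanism, vtype, config, rng=rng,
            patient_id=patient, mutation=mutation, tissue_site=site,
        )
        sets.append(s)
        truths.append(truth)
    return sets, truths
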