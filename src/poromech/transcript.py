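"""RNA-editing detection and cis/trans phasing.

An RNA-editing event is a base change seen in a lesion's cDNA but in
neither the lesion's genomic DNA nor the neighbouring normal skin's cDNA
(nor blood gDNA when assayed) — a post-transcriptional change rather than
a germline or somatic DNA mutation.  Phase relative to the germline
mutation is resolved either from allele-specific amplicon reads or, for
two germline variants in one gene, from offspring genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .datamodel import EditingEvent, Phase

Variant = tuple[int, str, str]  # (cdna position, ref, alt)


@dataclass
class TissueVariantSets:
    """Observed variant sets per (tissue, molecule).

    Keys are ``(tissue, molecule)`` such as ``("LT", "cDNA")``; values are
    sets of ``(position, ref, alt)``.  ``support`` optionally carries
    allele-specific read counts per variant.
    """

    sets: dict[tuple[str, str], set[Variant]]
    support: dict[tuple[str, str], dict[Variant, int]] = field(
        default_factory=dict
    )

    def get(self, tissue: str, molecule: str) -> Optional[set[Variant]]:
        return self.sets.get((tissue, molecule))


@dataclass
class EditingDetection:
    status: str  # "ok" | "no_call"
    events: list[EditingEvent]
    message: str = ""


def detect_rna_editing(sets: TissueVariantSets) -> EditingDetection:
    """Call cDNA-only variants in lesional tissue as RNA-editing events.

    Requires the LT gDNA set — without it a somatic DNA mutation cannot be
    excluded, so the result is a no-call rather than an empty list.
    Germline variants (present in any gDNA) are never events.
    """
    lt_cdna = sets.get("LT", "cDNA")
    lt_gdna = sets.get("LT", "gDNA")
    if lt_cdna is None:
        return EditingDetection("no_call", [], "missing LT cDNA set")
    if lt_gdna is None:
        return EditingDetection(
            "no_call", [], "missing LT gDNA set: cannot exclude somatic DNA mutation"
        )
    nns_cdna = sets.get("NNS", "cDNA") or set()
    blood_gdna = sets.get("blood", "gDNA")

    events = []
    for variant in sorted(lt_cdna):
        if variant in lt_gdna or variant in nns_cdna:
            continue
        if blood_gdna is not None and variant in blood_gdna:
            continue
        pos, ref, alt = variant
        present = frozenset(
            key for key, vs in sets.sets.items() if variant in vs
        )
        events.append(
            EditingEvent(cdna_pos=pos, ref=ref, alt=alt, present_in=present)
        )
    return EditingDetection("ok", events)


#: Minimum allele-specific observations in a single germline-allele group
#: required for a cis call; below this, phase stays unknown.
MIN_PHASE_SUPPORT = 3


def phase_by_reads(
    event: EditingEvent,
    allele_specific_groups: dict[str, list[bool]],
) -> Phase:
    """Phase an event against the germline mutation from partitioned reads.

    ``allele_specific_groups`` maps the germline allele group — ``"wild"``
    or ``"mutant"`` — to per-read/per-amplicon booleans recording whether
    the event allele was observed.  ``cis_with_wild`` requires the event
    allele in the wild group only (and at least
    :data:`MIN_PHASE_SUPPORT` supporting observations), symmetrically for
    ``cis_with_mutant``; anything mixed or under-supported is unknown.
    """
    wild = allele_specific_groups.get("wild", [])
    mutant = allele_specific_groups.get("mutant", [])
    wild_hits = sum(wild)
    mutant_hits = sum(mutant)
    if wild_hits and not mutant_hits and wild_hits >= MIN_PHASE_SUPPORT:
        return Phase.cis_with_wild
    if mutant_hits and not wild_hits and mutant_hits >= MIN_PHASE_SUPPORT:
        return Phase.cis_with_mutant
    return Phase.unknown


def phase_by_offspring(
    proband_variants: tuple[str, str],
    offspring_genotypes: list[set[str]],
) -> str:
    """Phase two heterozygous variants in one gene from offspring genotypes.

    Assuming no intragenic recombination, an offspring inherits one of the
    proband's two haplotypes intact: carrying exactly one of the two
    variants proves *trans*; carrying both, or neither, proves *cis*.
    Offspring jointly demanding both configurations are non-Mendelian under
    the no-recombination assumption and raise an error.  With no offspring
    data the phase is unknown.
    """
    v1, v2 = proband_variants
    if v1 == v2:
        raise ValueError("proband variants must be distinct")
    votes = set()
    for genotype in offspring_genotypes:
        carried = {v for v in (v1, v2) if v in genotype}
        if len(carried) == 1:
            votes.add("trans")
        else:  # both or neither: one intact proband haplotype either way
            votes.add("cis")
    if not votes:
        return "unknown"
    if len(votes) > 1:
        raise ValueError(
            "offspring genotypes are inconsistent with Mendelian "
            "transmission of two intact haplotypes"
        )
    return votes.pop()
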