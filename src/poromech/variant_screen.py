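"""Rare-variant screening cascade for the mevalonate-pathway gene panel.

The screen takes already-called, already-annotated variants and applies the
study's prioritisation rules:

* read-pair consensus correction (a pre-alignment error-reduction step for
  overlapping mate pairs from the same cluster);
* removal of benign polymorphisms — variants recorded in dbSNP *and* with a
  reference-population minor allele frequency >= 1%;
* retention of predicted-deleterious variants — SIFT < 0.05, PolyPhen-2
  > 0.85 or MutationTaster > 0.85 for protein-changing point substitutions,
  while truncating / splicing / start-codon / large-deletion variants are
  deleterious by type;
* exclusion of anything observed in healthy controls;
* pedigree co-segregation and mutation-spectrum summarisation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from ._util import percent
from .datamodel import (
    DELETERIOUS_BY_TYPE,
    Pedigree,
    VariantRecord,
    VariantType,
)


@dataclass
class FilterConfig:
    """Thresholds of the rarity / deleteriousness filter.

    Boundary strictness mirrors the printed rules exactly: a variant is a
    benign polymorphism at MAF exactly 1% (``>=``), while all three score
    thresholds are strict (``<`` for SIFT, ``>`` for PolyPhen-2 and
    MutationTaster).
    """

    maf_threshold: float = 0.01
    sift_threshold: float = 0.05
    pp2_threshold: float = 0.85
    mt_threshold: float = 0.85
    control_exclusion: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "sift_threshold", "pp2_threshold",
                     "mt_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


# ---------------------------------------------------------------------------
# read-pair consensus

#: Quality difference required to resolve a mate-pair mismatch.
CONSENSUS_QUALITY_GAP = 10
#: Quality assigned to masked (irresolvable) positions.
MASKED_QUALITY = 2


def consensus_read_pair(
    read1: str,
    qual1: list[int],
    read2: str,
    qual2: list[int],
    offset: int = 0,
) -> tuple[str, list[int]]:
    """Merge two same-cluster mates into one corrected read.

    ``offset`` places ``read2``'s first base at position ``offset`` of
    ``read1`` (caller-supplied alignment).  Agreeing positions keep the base
    with the higher quality; disagreeing positions take the higher-quality
    base when the quality gap is at least :data:`CONSENSUS_QUALITY_GAP`,
    otherwise ``N`` at quality :data:`MASKED_QUALITY`.  Non-overlapping
    tails pass through unchanged.
    """
    if len(read1) != len(qual1) or len(read2) != len(qual2):
        raise ValueError("read and quality lengths differ")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    overlap = min(len(read1), offset + len(read2)) - offset
    if overlap > len(read1) or overlap > len(read2):
        raise ValueError("overlap window longer than a read")
    if overlap <= 0:
        raise ValueError("reads do not overlap at this offset")

    bases: list[str] = []
    quals: list[int] = []
    # read1 head
    bases.extend(read1[:offset])
    quals.extend(qual1[:offset])
    for i in range(overlap):
        b1, q1 = read1[offset + i], qual1[offset + i]
        b2, q2 = read2[i], qual2[i]
        if b1 == b2:
            bases.append(b1)
            quals.append(max(q1, q2))
        elif abs(q1 - q2) >= CONSENSUS_QUALITY_GAP:
            bases.append(b1 if q1 > q2 else b2)
            quals.append(max(q1, q2))
        else:
            bases.append("N")
            quals.append(MASKED_QUALITY)
    # tails
    if offset + len(read2) > len(read1):
        bases.extend(read2[overlap:])
        quals.extend(qual2[overlap:])
    else:
        bases.extend(read1[offset + overlap:])
        quals.extend(qual1[offset + overlap:])
    return "".join(bases), quals


# ---------------------------------------------------------------------------
# HGVS mutation-type classification

class ClassificationError(ValueError):
    """Raised for a cDNA description outside the supported HGVS subset."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"cannot classify HGVS description: {token!r}")


_POS = r"(?:[-*]?\d+(?:[+-]\d+)?)"
_SUBST_RE = re.compile(
    rf"^c\.(?P<pos>{_POS})(?P<ref>[ACGTN])>(?P<alt>[ACGTN])$"
)
_INDEL_RE = re.compile(
    rf"^c\.(?P<start>{_POS})(?:_(?P<end>{_POS}))?"
    r"(?P<kind>delins|del|dup|ins)(?P<bases>[ACGTN]*)$"
)
_POS_RE = re.compile(r"^(?P<base>[-*]?\d+)(?P<off>[+-]\d+)?$")

_PROT_SUBST_RE = re.compile(
    r"^p\.\(?(?P<ref>[A-Z][a-z]{2}|\*)(?P<pos>\d+)"
    r"(?P<alt>[A-Z][a-z]{2}|\*|\?|=)\)?$"
)


def _parse_pos(token: str) -> tuple[int, int, bool]:
    """Return (anchor, intron offset, is_coding) for one HGVS c. position."""
    m = _POS_RE.match(token)
    if m is None:
        raise ClassificationError(token)
    base = m.group("base")
    off = int(m.group("off") or 0)
    is_coding = not (base.startswith("*") or base.startswith("-"))
    anchor = int(base.lstrip("*"))
    return anchor, off, is_coding


def classify_mutation_type(
    cdna_hgvs: str,
    protein_hgvs: Optional[str] = None,
    large_deletion: bool = False,
) -> VariantType:
    """Classify one variant into the mutation-spectrum categories.

    Precedence: large deletion > splicing (intronic offset +-1/2, the
    canonical splice dinucleotides) > start codon (c.1-c.3 or p.Met1) >
    nonsense > frameshift > in-frame indel > missense > synonymous.
    """
    if large_deletion:
        return VariantType.large_deletion

    positions: list[tuple[int, int, bool]] = []
    kind = None
    net_change = 0

    m = _SUBST_RE.match(cdna_hgvs)
    if m:
        kind = "subst"
        positions.append(_parse_pos(m.group("pos")))
    else:
        m = _INDEL_RE.match(cdna_hgvs)
        if m is None:
            raise ClassificationError(cdna_hgvs)
        kind = m.group("kind")
        start = _parse_pos(m.group("start"))
        end = _parse_pos(m.group("end")) if m.group("end") else start
        positions.extend([start, end])
        bases = m.group("bases")
        if kind == "ins" and not bases:
            raise ClassificationError(cdna_hgvs)
        span = (end[0] - start[0] + 1) if (start[2] and end[2]) else len(bases) or 1
        if bases and kind in ("del", "dup"):
            span = len(bases)
        if kind == "del":
            net_change = -span
        elif kind == "dup":
            net_change = span
        elif kind == "ins":
            net_change = len(bases)
        elif kind == "delins":
            net_change = len(bases) - span

    # splicing: canonical intronic dinucleotide positions
    if any(abs(off) in (1, 2) and off != 0 for _, off, _ in positions):
        return VariantType.splicing

    prot = _parse_protein(protein_hgvs)

    # start codon
    if prot is not None and prot[0] == "Met" and prot[1] == 1:
        return VariantType.start_codon
    if any(is_coding and off == 0 and 1 <= anchor <= 3
           for anchor, off, is_coding in positions) and kind == "subst":
        if prot is None or prot[1] == 1:
            return VariantType.start_codon

    # nonsense
    if prot is not None and prot[2] in ("Ter", "*"):
        return VariantType.nonsense

    # frameshift / in-frame indels
    if protein_hgvs and "fs" in protein_hgvs:
        return VariantType.frameshift_indel
    if kind in ("del", "dup", "ins", "delins"):
        if net_change % 3 != 0:
            return VariantType.frameshift_indel
        return VariantType.inframe_indel

    # point substitutions: protein consequence decides
    if prot is not None:
        ref_aa, _, alt_aa = prot
        if alt_aa == "=" or alt_aa == ref_aa:
            return VariantType.synonymous
        if alt_aa == "?":
            return VariantType.other
        return VariantType.missense
    return VariantType.other


def _parse_protein(protein_hgvs: Optional[str]):
    if not protein_hgvs:
        return None
    if protein_hgvs in ("p.=", "p.(=)"):
        return ("=", 0, "=")
    if "fs" in protein_hgvs:
        return None  # handled by the frameshift rule
    m = _PROT_SUBST_RE.match(protein_hgvs)
    if m is None:
        return None
    return (m.group("ref"), int(m.group("pos")), m.group("alt"))


def ensure_vtype(v: VariantRecord, large_deletion: bool = False) -> VariantType:
    """Return the record's mutation type, classifying it if unset."""
    if v.vtype is not None:
        return v.vtype
    vtype = classify_mutation_type(
        v.cdna_hgvs, v.protein_hgvs, large_deletion=large_deletion
    )
    v.vtype = vtype
    return vtype


# ---------------------------------------------------------------------------
# filter rules

def is_benign_polymorphism(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Benign iff recorded in dbSNP AND population MAF >= threshold.

    A dbSNP-recorded variant with low or unknown MAF is *not* benign under
    this rule (the conjunction matters: plenty of pathogenic alleles have
    dbSNP identifiers).
    """
    return (
        v.dbsnp_id is not None
        and v.ref_maf is not None
        and v.ref_maf >= cfg.maf_threshold
    )


def is_predicted_deleterious(v: VariantRecord, cfg: FilterConfig) -> bool:
    """Score rule for protein-changing point variants (OR of three tools)."""
    return (
        (v.sift is not None and v.sift < cfg.sift_threshold)
        or (v.pp2 is not None and v.pp2 > cfg.pp2_threshold)
        or (v.mt is not None and v.mt > cfg.mt_threshold)
    )


def screen_cascade(
    variants: list[VariantRecord],
    controls: dict,
    cfg: Optional[FilterConfig] = None,
) -> tuple[list[VariantRecord], list[dict]]:
    """Apply the full prioritisation cascade, preserving input order.

    ``controls`` maps a mutation key — ``(gene, cdna_hgvs)`` — to True when
    the allele was observed in healthy controls.  Returns the candidate list
    and an exclusion log (one row per removed variant with the rule and
    reason).
    """
    cfg = cfg or FilterConfig()
    candidates: list[VariantRecord] = []
    exclusion_log: list[dict] = []

    def exclude(v: VariantRecord, rule: str, reason: str) -> None:
        exclusion_log.append(
            {
                "sample_id": v.sample_id,
                "gene": v.gene,
                "cdna_hgvs": v.cdna_hgvs,
                "rule": rule,
                "reason": reason,
            }
        )

    for v in variants:
        if is_benign_polymorphism(v, cfg):
            exclude(v, "benign_polymorphism", "population frequency")
            continue
        vtype = ensure_vtype(v)
        by_type = vtype in DELETERIOUS_BY_TYPE
        if not by_type and not is_predicted_deleterious(v, cfg):
            exclude(v, "deleteriousness", "no deleterious prediction")
            continue
        if cfg.control_exclusion and controls.get(v.mutation_key, False):
            exclude(v, "controls", "observed in controls")
            continue
        candidates.append(v)
    return candidates, exclusion_log


# ---------------------------------------------------------------------------
# co-segregation

def cosegregation_check(
    ped: Pedigree,
    mutation: str,
    mode: str = "strict",
    onset_age: float = 30.0,
) -> tuple[bool, list[str]]:
    """Check perfect co-segregation of one mutation with affection status.

    ``strict``: every affected member must carry, every unaffected member
    must not.  ``age_aware``: an unaffected carrier younger than
    ``onset_age`` (not yet through the risk window) is not a violation.
    Members with unknown status or genotype are ignored.
    """
    if mode not in ("strict", "age_aware"):
        raise ValueError(f"unknown mode {mode!r}")
    genotypes = ped.genotypes.get(mutation)
    if not genotypes or all(g is None for g in genotypes.values()):
        raise ValueError(f"no genotyped members for mutation {mutation!r}")
    violators: list[str] = []
    for member in ped.members:
        carrier = genotypes.get(member.member_id)
        if carrier is None or member.affected is None:
            continue
        if member.affected and not carrier:
            violators.append(member.member_id)
        elif not member.affected and carrier:
            if (
                mode == "age_aware"
                and member.age_at_exam is not None
                and member.age_at_exam <= onset_age
            ):
                continue
            violators.append(member.member_id)
    return (not violators), violators


# ---------------------------------------------------------------------------
# mutation spectrum

def summarize_mutation_spectrum(
    variants: Iterable[VariantRecord],
) -> pd.DataFrame:
    """Count distinct mutations per type, with integer percentages.

    The denominator is the number of distinct mutations (gene + cDNA
    change), not the number of carriers.  Percentages round half away from
    zero; with an empty input they are reported missing.
    """
    seen: dict[tuple[str, str], VariantType] = {}
    for v in variants:
        seen.setdefault(v.mutation_key, ensure_vtype(v))
    total = len(seen)
    rows = []
    for vtype in VariantType:
        count = sum(1 for t in seen.values() if t == vtype)
        rows.append(
            {
                "vtype": vtype.value,
                "count": count,
                "percent": percent(count, total) if total else None,
            }
        )
    return pd.DataFrame(rows, columns=["vtype", "count", "percent"])
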