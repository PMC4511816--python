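"""Shared domain types for the porokeratosis second-hit pipeline.

The pipeline analyses an autosomal-dominant skin disease in which every
patient carries a germline heterozygous mutation in one of the mevalonate
pathway genes, and each skin lesion additionally silences or removes the
remaining wild-type allele ("second hit").  The types here carry the data
from annotated variant tables through copy-number probes, allele-signal
(SNaPshot-style) measurements and promoter methylation, up to a mechanism
label per lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: The 12-gene mevalonate-pathway screening panel.  Configurable at call
#: sites; this is the default universe for gene symbols.
PANEL_GENES = (
    "ACAT1", "ACAT2", "HMGCS1", "HMGCS2", "HMGCR", "MVK",
    "PMVK", "MVD", "IDI1", "IDI2", "FDPS", "GGPS1",
)

#: Genes in which causal mutations are actually found; columns of the
#: genotype-phenotype cross-tab.
CAUSAL_GENES = ("MVK", "PMVK", "MVD", "FDPS")


class VariantType(str, Enum):
    """Mutation-type categories used for the mutation spectrum."""

    missense = "missense"
    start_codon = "start_codon"
    nonsense = "nonsense"
    frameshift_indel = "frameshift_indel"
    inframe_indel = "inframe_indel"
    splicing = "splicing"
    large_deletion = "large_deletion"
    synonymous = "synonymous"
    other = "other"


#: Types that are deleterious regardless of in-silico scores (the score
#: thresholds apply to non-synonymous point substitutions only).
TRUNCATING_TYPES = frozenset(
    {
        VariantType.nonsense,
        VariantType.frameshift_indel,
        VariantType.splicing,
    }
)
DELETERIOUS_BY_TYPE = TRUNCATING_TYPES | {
    VariantType.start_codon,
    VariantType.large_deletion,
}


class MechanismLabel(str, Enum):
    """Second-hit mechanism call for one lesion."""

    cnv_loss = "cnv_loss"
    gene_conversion = "gene_conversion"
    rna_editing = "rna_editing"
    epigenetic_silencing_unknown = "epigenetic_silencing_unknown"
    none = "none"


class Direction(str, Enum):
    """Direction of an allelic-expression-imbalance shift."""

    wild_reduced = "wild_reduced"
    mutant_reduced = "mutant_reduced"
    none = "none"


class Phase(str, Enum):
    """Phase of a somatic/editing event relative to the germline mutation."""

    cis_with_wild = "cis_with_wild"
    cis_with_mutant = "cis_with_mutant"
    unknown = "unknown"


def _check_unit(value: Optional[float], name: str) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass
class VariantRecord:
    """One annotated sequence variant observed in one sample.

    ``ref_maf`` is the minor-allele frequency in the matched reference
    population; ``sift``, ``pp2`` and ``mt`` are the SIFT, PolyPhen-2 and
    MutationTaster scores supplied by upstream annotation (never computed
    here).
    """

    sample_id: str
    gene: str
    cdna_hgvs: str
    protein_hgvs: Optional[str] = None
    vtype: Optional[VariantType] = None
    dbsnp_id: Optional[str] = None
    ref_maf: Optional[float] = None
    sift: Optional[float] = None
    pp2: Optional[float] = None
    mt: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cdna_hgvs:
            raise ValueError("cdna_hgvs must be non-empty")
        for name in ("ref_maf", "sift", "pp2", "mt"):
            _check_unit(getattr(self, name), name)

    @property
    def mutation_key(self) -> tuple[str, str]:
        """Identity of the mutation itself (gene, cDNA change)."""
        return (self.gene, self.cdna_hgvs)


@dataclass
class PedigreeMember:
    member_id: str
    sex: str  # "1"/"male", "2"/"female", "0" unknown
    affected: Optional[bool]
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    age_at_exam: Optional[float] = None


@dataclass
class Pedigree:
    """A family with per-mutation carrier genotypes.

    ``genotypes[mutation][member_id]`` is True (carrier), False
    (non-carrier) or None (unknown).
    """

    family_id: str
    members: list[PedigreeMember]
    genotypes: dict[str, dict[str, Optional[bool]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {m.member_id for m in self.members}
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in ids:
                    raise ValueError(
                        f"member {m.member_id}: parent {parent!r} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            m.member_id: [p for p in (m.father_id, m.mother_id) if p is not None]
            for m in self.members
        }
        WHITE, GREY, BLACK = 0, 1, 2
        color = {mid: WHITE for mid in parents}

        def visit(mid: str, stack: list[str]) -> None:
            color[mid] = GREY
            stack.append(mid)
            for p in parents[mid]:
                if color[p] == GREY:
                    cycle = stack[stack.index(p):] + [p]
                    raise ValueError(f"cyclic parentage: {' -> '.join(cycle)}")
                if color[p] == WHITE:
                    visit(p, stack)
            stack.pop()
            color[mid] = BLACK

        for mid in parents:
            if color[mid] == WHITE:
                visit(mid, [])

    def member(self, member_id: str) -> PedigreeMember:
        for m in self.members:
            if m.member_id == member_id:
                return m
        raise KeyError(member_id)

    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    def children_of(self, member_id: str) -> list[PedigreeMember]:
        return [
            m for m in self.members
            if member_id in (m.father_id, m.mother_id)
        ]


@dataclass
class Probe:
    probe_id: str
    position: int  # genomic coordinate (bp) of the probe target site
    region_label: str  # "promoter" or "exon-<k>"
    variant_tag: str = "A"  # A/B for alternative probes on the same region


@dataclass
class ProbeTrack:
    """Ordered copy-ratio probes over one gene's promoter and exons."""

    gene: str
    probes: list[Probe]
    ratios: dict[str, dict[str, float]]  # sample -> probe_id -> copy ratio

    def __post_init__(self) -> None:
        positions = [p.position for p in self.probes]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("probe positions must be strictly increasing")
        probe_ids = {p.probe_id for p in self.probes}
        for sample, by_probe in self.ratios.items():
            missing = probe_ids - set(by_probe)
            if missing:
                raise ValueError(
                    f"sample {sample}: missing ratios for probes {sorted(missing)}"
                )
            for pid, r in by_probe.items():
                if r < 0:
                    raise ValueError(f"negative copy ratio for {sample}/{pid}")

    def probe_index(self, probe_id: str) -> int:
        for i, p in enumerate(self.probes):
            if p.probe_id == probe_id:
                return i
        raise KeyError(probe_id)


@dataclass
class SignalMeasurement:
    tissue: str  # blood | NNS | LT
    molecule: str  # gDNA | cDNA
    replicate: int  # >= 1
    mutant_signal: float
    wild_signal: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if self.mutant_signal < 0 or self.wild_signal < 0:
            raise ValueError("signals must be non-negative")
        if self.mutant_signal == 0 and self.wild_signal == 0:
            raise ValueError("measurement with both signals zero")


@dataclass
class AlleleSignalSet:
    """Mutant/wild allele signals for one patient x mutation across tissues.

    Emulates SNaPshot primer-extension peak data: a fluorescence signal per
    allele, per tissue (blood / neighbouring normal skin / lesion), per
    molecule (gDNA / cDNA) and per replicate.
    """

    patient_id: str
    mutation: str  # cdna_hgvs
    measurements: list[SignalMeasurement]
    tissue_site: str = ""

    def __post_init__(self) -> None:
        if not any(
            m.tissue == "blood" and m.molecule == "gDNA" for m in self.measurements
        ):
            raise ValueError("at least one blood gDNA measurement is required")

    def stratum(self, tissue: str, molecule: str) -> list[SignalMeasurement]:
        return [
            m for m in self.measurements
            if m.tissue == tissue and m.molecule == molecule
        ]


@dataclass
class BreakpointInterval:
    """Half-open genomic interval bounding one breakpoint.

    ``left``/``right`` are genomic positions (bp); an unbounded side is None.
    """

    left: Optional[int]
    right: Optional[int]

    @property
    def unbounded(self) -> bool:
        return self.left is None or self.right is None

    @property
    def width(self) -> Optional[int]:
        if self.unbounded:
            return None
        return self.right - self.left


@dataclass
class DeletedSegment:
    first_probe: str
    last_probe: str
    left_interval: BreakpointInterval
    right_interval: BreakpointInterval
    deep: bool = False  # homozygous-loss flag (ratio ~ 0)


@dataclass
class CnvCall:
    gene: str
    sample: str
    state_per_probe: dict[str, str]  # probe_id -> loss|normal|gain|indeterminate
    deleted_segments: list[DeletedSegment]
    junction_size: Optional[int] = None

    @property
    def has_loss(self) -> bool:
        return bool(self.deleted_segments)

    @property
    def has_gain(self) -> bool:
        return any(s == "gain" for s in self.state_per_probe.values())

    @property
    def has_change(self) -> bool:
        return self.has_loss or self.has_gain


@dataclass
class AeiResult:
    """Outcome of one allelic-expression-imbalance test (LT vs NNS)."""

    patient_id: str
    mutation: str
    molecule: str  # cDNA or gDNA
    lt_ratios: list[float]
    nns_ratios: list[float]
    p_value: Optional[float]
    significant: bool
    direction: Direction
    alpha: float = 0.01
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class EditingEvent:
    """A candidate RNA-editing event: a cDNA-only base change."""

    cdna_pos: int
    ref: str
    alt: str
    present_in: frozenset = frozenset()  # of (tissue, molecule) pairs
    phase_vs_germline: Phase = Phase.unknown

    @property
    def description(self) -> str:
        return f"c.{self.cdna_pos}{self.ref}>{self.alt}"


@dataclass
class TissuePairEvidence:
    """Evidence bundle for one lesion, consumed by the mechanism classifier."""

    patient_id: str
    mutation: str
    aei_cdna: AeiResult
    aei_gdna: Optional[AeiResult] = None
    gdna_shift: bool = False
    gdna_shift_estimate: Optional[float] = None
    cnv: Optional[CnvCall] = None
    methylation_detected: Optional[bool] = None  # None = not assayed/insufficient
    editing_events: list[EditingEvent] = field(default_factory=list)
    germline_vtype: Optional[VariantType] = None

    def __post_init__(self) -> None:
        for res in (self.aei_cdna, self.aei_gdna):
            if res is not None and (
                res.patient_id != self.patient_id or res.mutation != self.mutation
            ):
                raise ValueError(
                    "evidence elements refer to different patient/mutation"
                )


@dataclass
class MechanismCall:
    label: MechanismLabel
    nns_mutant_reduction: bool = False
    advisory: tuple[str, ...] = ()


#: Phenotype category vocabularies for the cohort table.
LESION_COUNT_CATEGORIES = ("0-10", "10-100", "100-500", ">500")
ONSET_CATEGORIES = ("at birth", "0-20", "20-40", "40-60", ">60")
PK_VARIANTS = (
    "DSAP/DSP", "SFP", "PM", "HPM", "giant-plaque PPt",
    "genital PK", "porokeratoma", "LP",
)


@dataclass
class CohortRecord:
    """Per-index-patient genotype and phenotype attributes."""

    patient_id: str
    cohort_arm: str  # familial | sporadic
    sex: str  # male | female
    genes_mutated: frozenset = frozenset()  # empty set = genetically unknown
    lesion_count_category: Optional[str] = None
    lesion_diameter_min_mm: Optional[float] = None
    lesion_diameter_max_mm: Optional[float] = None
    onset_category: Optional[str] = None
    pk_variants: frozenset = frozenset()
    comorbidity: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.cohort_arm not in ("familial", "sporadic"):
            raise ValueError(f"unknown cohort arm {self.cohort_arm!r}")
        if self.lesion_count_category is not None and (
            self.lesion_count_category not in LESION_COUNT_CATEGORIES
        ):
            raise ValueError(
                f"lesion count category {self.lesion_count_category!r} not in "
                f"{LESION_COUNT_CATEGORIES}"
            )
        if self.onset_category is not None and (
            self.onset_category not in ONSET_CATEGORIES
        ):
            raise ValueError(
                f"onset category {self.onset_category!r} not in {ONSET_CATEGORIES}"
            )
        for v in self.pk_variants:
            if v not in PK_VARIANTS:
                raise ValueError(f"PK variant label {v!r} not in {PK_VARIANTS}")

    @property
    def is_carrier(self) -> bool:
        return bool(self.genes_mutated)
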