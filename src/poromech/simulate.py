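"""Synthetic-data generators with known ground truth.

Every input class of the pipeline can be generated here under a stated
world: a two-arm cohort (61 familial / 73 sporadic index patients) over a
four-causal-gene panel, SNaPshot-like allele-signal sets under known
second-hit mechanisms, MLPA-style probe tracks with planted heterozygous
deletions, junction reads over planted deletions, autosomal-dominant
pedigrees, and tissue-wise cDNA/gDNA variant sets with planted RNA-editing
events.  All generators are pure functions of (config, seed); truth labels
are returned separately (and written to ``*.truth.tsv`` sidecars) so the
pipelines under test can never read them from their own inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datamodel import (
    AlleleSignalSet,
    CohortRecord,
    MechanismLabel,
    Pedigree,
    PedigreeMember,
    Probe,
    ProbeTrack,
    SignalMeasurement,
    TRUNCATING_TYPES,
    VariantRecord,
    VariantType,
)
from .transcript import TissueVariantSets

RngLike = Union[int, np.random.Generator]


def _rng(seed_or_rng: RngLike) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _default_gene_weights() -> dict[str, float]:
    # marginal carrier fractions matching the observed cohort
    # (62, 39, 9 and 4 of 134 patients; the remainder genetically unknown)
    return {"MVD": 0.46, "MVK": 0.29, "PMVK": 0.07, "FDPS": 0.03}


def _default_mechanism_mix() -> dict[str, float]:
    # lesion mechanism proportions: wild-allele silencing dominates,
    # conversion is a minor fraction, editing is a single-case phenomenon
    return {
        MechanismLabel.epigenetic_silencing_unknown.value: 0.60,
        MechanismLabel.gene_conversion.value: 0.15,
        MechanismLabel.cnv_loss.value: 0.05,
        MechanismLabel.rna_editing.value: 0.05,
        MechanismLabel.none.value: 0.15,
    }


@dataclass
class SimulationConfig:
    seed: int = 0
    n_familial: int = 61
    n_sporadic: int = 73
    gene_carrier_weights: dict[str, float] = field(
        default_factory=_default_gene_weights
    )
    noise_cv: float = 0.10
    replicates_per_stratum: int = 3
    mechanism_mix: dict[str, float] = field(
        default_factory=_default_mechanism_mix
    )
    probe_noise_sd: float = 0.05
    deletion_specs: list[tuple[str, str, str]] = field(default_factory=list)
    dual_gene_p: float = 0.0075  # ~1 dual-gene patient per 134
    benign_background_mean: float = 1.5  # benign polymorphisms per patient
    base_intensity: float = 5000.0
    allele_bias: float = 1.0  # constant per-allele assay factor
    nmd_factor: float = 0.3  # mutant-transcript survival under NMD

    def __post_init__(self) -> None:
        if self.n_familial < 1 or self.n_sporadic < 1:
            raise ValueError("cohort arm counts must be >= 1")
        if self.noise_cv < 0 or self.probe_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.replicates_per_stratum < 1:
            raise ValueError("replicates_per_stratum must be >= 1")
        for gene, w in self.gene_carrier_weights.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"carrier weight for {gene} outside [0, 1]")
        if sum(self.gene_carrier_weights.values()) > 1.0 + 1e-9:
            raise ValueError("gene carrier weights must sum to <= 1")
        if not (0.0 <= self.dual_gene_p <= 1.0):
            raise ValueError("dual_gene_p must lie in [0, 1]")
        if self.benign_background_mean < 0:
            raise ValueError("benign_background_mean must be >= 0")
        total = sum(self.mechanism_mix.values())
        if self.mechanism_mix and abs(total - 1.0) > 1e-9:
            raise ValueError("mechanism_mix proportions must sum to 1")


# ---------------------------------------------------------------------------
# cohort + variant tables

#: Per-gene phenotype tables, calibrated to the observed cohort: the
#: giant-plaque phenotype occurs only under MVK, solar facial PK only under
#: MVD, genital PK and porokeratoma only under PMVK, and FDPS lesions are
#: numerous and small.
_PHENO_TABLES: dict[str, dict] = {
    "MVK": {
        "pk_variants": [("DSAP/DSP",), ("giant-plaque PPt",), ("PM",), ("LP",)],
        "pk_weights": [0.50, 0.42, 0.05, 0.03],
        "lesion_count": (["0-10", "10-100", "100-500", ">500"],
                         [0.10, 0.51, 0.13, 0.26]),
        "onset": (["at birth", "0-20", "20-40", "40-60", ">60"],
                  [0.0, 0.59, 0.31, 0.08, 0.02]),
        "diameter_mm": (2, 200),
    },
    "PMVK": {
        "pk_variants": [("genital PK",), ("porokeratoma",), ("PM",), ("HPM",)],
        "pk_weights": [0.31, 0.38, 0.23, 0.08],
        "lesion_count": (["0-10", "10-100", "100-500", ">500"],
                         [0.44, 0.56, 0.0, 0.0]),
        "onset": (["at birth", "0-20", "20-40", "40-60", ">60"],
                  [0.0, 0.45, 0.33, 0.11, 0.11]),
        "diameter_mm": (5, 50),
    },
    "MVD": {
        "pk_variants": [("DSAP/DSP",), ("SFP",), ("PM",), ("HPM",), ("LP",)],
        "pk_weights": [0.74, 0.10, 0.12, 0.01, 0.03],
        "lesion_count": (["0-10", "10-100", "100-500", ">500"],
                         [0.0, 0.21, 0.63, 0.16]),
        "onset": (["at birth", "0-20", "20-40", "40-60", ">60"],
                  [0.0, 0.32, 0.45, 0.20, 0.03]),
        "diameter_mm": (1, 20),
    },
    "FDPS": {
        "pk_variants": [("DSAP/DSP",), ("HPM",)],
        "pk_weights": [0.8, 0.2],
        "lesion_count": ([">500"], [1.0]),
        "onset": (["0-20", "20-40", "40-60"], [0.25, 0.5, 0.25]),
        "diameter_mm": (1, 10),
    },
    "unknown": {
        "pk_variants": [("DSAP/DSP",), ("PM",), ("LP",)],
        "pk_weights": [0.5, 0.26, 0.24],
        "lesion_count": (["0-10", "10-100", "100-500", ">500"],
                         [0.29, 0.24, 0.24, 0.23]),
        "onset": (["at birth", "0-20", "20-40", "40-60", ">60"],
                  [0.14, 0.48, 0.43 - 0.14, 0.09, 0.0]),
        "diameter_mm": (1, 20),
    },
}

#: Pathogenic allele pools per gene; the two recurrent MVD alleles carry
#: most of that gene's weight.
_ALLELE_POOLS: dict[str, list[tuple[str, Optional[str], float]]] = {
    "MVD": [
        ("c.746T>C", "p.Phe249Ser", 0.55),
        ("c.875A>G", "p.Asn292Ser", 0.26),
        ("c.302C>G", "p.Pro101Arg", 0.10),
        ("c.683G>A", "p.Arg228Gln", 0.09),
    ],
    "MVK": [
        ("c.395delT", "p.Leu132Terfs", 0.2),
        ("c.371+2T>A", None, 0.2),
        ("c.1093T>A", "p.Ser365Thr", 0.2),
        ("c.235G>A", "p.Asp79Asn", 0.2),
        ("c.417C>A", "p.Tyr139Ter", 0.2),
    ],
    "PMVK": [
        ("c.329A>G", "p.Tyr110Cys", 0.5),
        ("c.412C>T", "p.Arg138Ter", 0.5),
    ],
    "FDPS": [
        ("c.684+1G>A", None, 0.5),
        ("c.601A>G", "p.Met201Val", 0.5),
    ],
}


def gen_cohort(
    config: SimulationConfig,
    rng: Optional[RngLike] = None,
) -> tuple[list[CohortRecord], list[VariantRecord], pd.DataFrame]:
    """Generate a two-arm cohort with per-gene phenotype tables and variants.

    Every patient is assigned 0-2 mutated genes by independent per-gene
    Bernoulli draws on ``gene_carrier_weights`` (over-draws truncated to
    two at random).  Pathogenic variants receive deleterious score
    profiles; each patient additionally carries benign background
    polymorphisms with dbSNP ids, common MAFs and benign scores.  The
    truth table records which variants are planted pathogenic.
    """
    rng = _rng(config.seed if rng is None else rng)
    genes = list(config.gene_carrier_weights)
    cohort: list[CohortRecord] = []
    variants: list[VariantRecord] = []
    truth_rows: list[dict] = []

    arms = [("familial", "F", config.n_familial),
            ("sporadic", "S", config.n_sporadic)]
    for arm, prefix, n in arms:
        for i in range(1, n + 1):
            pid = f"{prefix}-{i}"
            # genes are nearly mutually exclusive in this disease: one
            # categorical draw per patient (remainder = unexplained), with a
            # rare independent second gene
            weights = np.asarray([config.gene_carrier_weights[g] for g in genes])
            u = rng.random()
            drawn: list[str] = []
            cumulative = np.cumsum(weights)
            for g, edge in zip(genes, cumulative):
                if u < edge:
                    drawn.append(g)
                    break
            if drawn and genes and rng.random() < config.dual_gene_p:
                others = [g for g in genes if g != drawn[0]]
                if others:
                    w2 = np.asarray(
                        [config.gene_carrier_weights[g] for g in others]
                    )
                    drawn.append(
                        str(np.asarray(others, dtype=object)[
                            rng.choice(len(others), p=w2 / w2.sum())
                        ])
                    )
            pheno_gene = drawn[0] if drawn else "unknown"
            table = _PHENO_TABLES[pheno_gene]
            variants_labels = list(
                table["pk_variants"][
                    rng.choice(len(table["pk_variants"]),
                               p=np.asarray(table["pk_weights"])
                               / sum(table["pk_weights"]))
                ]
            )
            counts, count_w = table["lesion_count"]
            onsets, onset_w = table["onset"]
            dmin, dmax = table["diameter_mm"]
            cohort.append(
                CohortRecord(
                    patient_id=pid,
                    cohort_arm=arm,
                    sex="male" if rng.random() < 92 / 134 else "female",
                    genes_mutated=frozenset(drawn),
                    lesion_count_category=str(
                        np.asarray(counts, dtype=object)[
                            rng.choice(len(counts),
                                       p=np.asarray(count_w) / sum(count_w))
                        ]
                    ),
                    lesion_diameter_min_mm=float(dmin),
                    lesion_diameter_max_mm=float(dmax),
                    onset_category=str(
                        np.asarray(onsets, dtype=object)[
                            rng.choice(len(onsets),
                                       p=np.asarray(onset_w) / sum(onset_w))
                        ]
                    ),
                    pk_variants=frozenset(variants_labels),
                )
            )
            for gene in drawn:
                pool = _ALLELE_POOLS[gene]
                weights = np.asarray([w for _, _, w in pool])
                cdna, prot, _ = pool[rng.choice(len(pool), p=weights / weights.sum())]
                variants.append(
                    VariantRecord(
                        sample_id=pid, gene=gene, cdna_hgvs=cdna,
                        protein_hgvs=prot,
                        sift=float(rng.uniform(0.0, 0.04)),
                        pp2=float(rng.uniform(0.86, 1.0)),
                        mt=float(rng.uniform(0.86, 1.0)),
                    )
                )
                truth_rows.append(
                    {"patient_id": pid, "gene": gene, "cdna_hgvs": cdna,
                     "pathogenic": True}
                )
            # benign background polymorphisms
            for k in range(rng.poisson(config.benign_background_mean)):
                gene = genes[int(rng.integers(len(genes)))]
                pos = int(rng.integers(100, 900))
                cdna = f"c.{pos}G>A"
                variants.append(
                    VariantRecord(
                        sample_id=pid, gene=gene, cdna_hgvs=cdna,
                        protein_hgvs=f"p.Val{pos // 3 + 1}Met",
                        dbsnp_id=f"rs{int(rng.integers(10**6, 10**7))}",
                        ref_maf=float(rng.uniform(0.01, 0.4)),
                        sift=float(rng.uniform(0.2, 1.0)),
                        pp2=float(rng.uniform(0.0, 0.5)),
                        mt=float(rng.uniform(0.0, 0.5)),
                    )
                )
                truth_rows.append(
                    {"patient_id": pid, "gene": gene, "cdna_hgvs": cdna,
                     "pathogenic": False}
                )
    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "gene", "cdna_hgvs", "pathogenic"]
    )
    return cohort, variants, truth


# ---------------------------------------------------------------------------
# allele-signal sets

#: Target LT (gDNA, cDNA) normalised mutant/wild ratios per mechanism.
_SCENARIO_RATIOS: dict[str, tuple[float, float]] = {
    MechanismLabel.none.value: (1.0, 1.0),
    MechanismLabel.rna_editing.value: (1.0, 1.0),
    MechanismLabel.gene_conversion.value: (3.0, 10.0),
    MechanismLabel.epigenetic_silencing_unknown.value: (1.0, 5.0),
    # one-copy wild-allele loss in two-thirds of lesion cells shifts both
    # molecules to the same 3:1 ratio
    MechanismLabel.cnv_loss.value: (3.0, 3.0),
}


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def gen_allele_signals(
    mechanism: Union[str, MechanismLabel],
    germline_vtype: Union[str, VariantType],
    config: SimulationConfig,
    rng: Optional[RngLike] = None,
    patient_id: str = "SIM-1",
    mutation: str = "c.395delT",
    tissue_site: str = "",
) -> tuple[AlleleSignalSet, dict]:
    """Simulate one patient's SNaPshot signal set under a known mechanism.

    Signals are ``base_intensity x allele fraction x lognormal(1, cv)`` per
    replicate, with the mutant allele additionally scaled by a constant
    assay bias (cancelled by blood normalisation).  Truncating germline
    alleles get NMD-like mutant reduction in NNS (and blood) cDNA.  With
    ``noise_cv = 0`` the normalised ratios hit the scenario means exactly.
    """
    mechanism = MechanismLabel(mechanism)
    germline_vtype = VariantType(germline_vtype)
    if mechanism.value not in _SCENARIO_RATIOS:
        raise ValueError(f"no signal scenario for mechanism {mechanism}")
    rng = _rng(config.seed if rng is None else rng)

    gdna_lt, cdna_lt = _SCENARIO_RATIOS[mechanism.value]
    targets = {
        ("blood", "gDNA"): 1.0,
        ("NNS", "gDNA"): 1.0,
        ("LT", "gDNA"): gdna_lt,
        ("NNS", "cDNA"): 1.0,
        ("LT", "cDNA"): cdna_lt,
    }
    if germline_vtype in TRUNCATING_TYPES:
        targets[("NNS", "cDNA")] *= config.nmd_factor

    measurements = []
    for (tissue, molecule), ratio in targets.items():
        mutant_frac = ratio / (1.0 + ratio)
        wild_frac = 1.0 / (1.0 + ratio)
        n = config.replicates_per_stratum
        mut_noise = _lognormal_factor(rng, config.noise_cv, n)
        wild_noise = _lognormal_factor(rng, config.noise_cv, n)
        for rep in range(1, n + 1):
            measurements.append(
                SignalMeasurement(
                    tissue=tissue, molecule=molecule, replicate=rep,
                    mutant_signal=config.base_intensity * config.allele_bias
                    * mutant_frac * mut_noise[rep - 1],
                    wild_signal=config.base_intensity * wild_frac
                    * wild_noise[rep - 1],
                )
            )
    truth = {
        "patient_id": patient_id,
        "mutation": mutation,
        "mechanism": mechanism.value,
        "germline_vtype": germline_vtype.value,
        "lt_gdna_ratio": gdna_lt,
        "lt_cdna_ratio": cdna_lt,
        "nns_cdna_ratio": targets[("NNS", "cDNA")],
    }
    return (
        AlleleSignalSet(
            patient_id=patient_id, mutation=mutation,
            measurements=measurements, tissue_site=tissue_site,
        ),
        truth,
    )


# ---------------------------------------------------------------------------
# probe tracks

def default_probe_layout(gene: str = "MVK", n_exons: int = 11) -> list[Probe]:
    """Promoter probes PA/PB followed by one probe per exon (E01..)."""
    probes = [
        Probe("PA", 1_000, "promoter", "A"),
        Probe("PB", 1_600, "promoter", "B"),
    ]
    for k in range(1, n_exons + 1):
        probes.append(
            Probe(f"E{k:02d}", 2_000 + 1_500 * k, f"exon-{k}", "A")
        )
    return probes


def gen_probe_track(
    gene_model: Optional[tuple[str, list[Probe]]] = None,
    deletion_spec: Optional[tuple[str, str]] = None,
    config: Optional[SimulationConfig] = None,
    rng: Optional[RngLike] = None,
    sample: str = "SIM-1",
) -> tuple[ProbeTrack, dict]:
    """Simulate one sample's probe copy ratios, optionally with a deletion.

    Deleted probes have expected ratio 0.5 (heterozygous loss), all others
    1.0, plus Gaussian noise truncated at zero.
    """
    config = config or SimulationConfig()
    rng = _rng(config.seed if rng is None else rng)
    gene, probes = gene_model or ("MVK", default_probe_layout())
    probe_ids = [p.probe_id for p in probes]
    deleted: set[str] = set()
    if deletion_spec is not None:
        first, last = deletion_spec
        if first not in probe_ids or last not in probe_ids:
            raise ValueError(
                f"deletion spec ({first}, {last}) names probes outside the track"
            )
        i, j = probe_ids.index(first), probe_ids.index(last)
        if j < i:
            raise ValueError("deletion spec probes out of order")
        deleted = set(probe_ids[i:j + 1])
    ratios = {}
    for p in probes:
        expected = 0.5 if p.probe_id in deleted else 1.0
        noise = rng.normal(0.0, config.probe_noise_sd) if config.probe_noise_sd else 0.0
        ratios[p.probe_id] = max(0.0, expected + noise)
    track = ProbeTrack(gene=gene, probes=probes, ratios={sample: ratios})
    truth = {
        "sample": sample,
        "gene": gene,
        "deleted_probes": sorted(deleted, key=probe_ids.index),
        "deletion_spec": deletion_spec,
    }
    return track, truth


# ---------------------------------------------------------------------------
# junction sequences

def gen_junction_sequence(
    reference_length: int,
    deletion_interval: tuple[int, int],
    read_length: int,
    rng: RngLike = 0,
) -> tuple[str, str, int]:
    """Random reference plus a junction read spanning a planted deletion.

    ``deletion_interval`` is 0-based half-open on the reference.  The read
    concatenates the flank ends across the deleted interval (half on each
    side); the truth size is the interval length.  A zero-length interval
    yields a contiguous reference window.
    """
    rng = _rng(rng)
    start, end = deletion_interval
    if not (0 <= start <= end <= reference_length):
        raise ValueError("deletion interval outside the reference")
    half = read_length // 2
    if start < half or end + (read_length - half) > reference_length:
        raise ValueError("read does not fit around the deletion interval")
    reference = "".join(
        rng.choice(np.array(list("ACGT")), size=reference_length)
    )
    read = reference[start - half:start] + reference[end:end + read_length - half]
    return reference, read, end - start


# ---------------------------------------------------------------------------
# pedigrees

def gen_pedigree(
    n_generations: int,
    mutation: str,
    penetrance: float = 1.0,
    rng: RngLike = 0,
    children_per_couple: int = 2,
) -> tuple[Pedigree, dict]:
    """Simulate autosomal-dominant transmission through a family.

    The founder carrier transmits the mutation to each child with
    probability 1/2; affection status is carrier AND a penetrance draw.
    Non-carriers are never affected (no phenocopies).
    """
    if n_generations < 1:
        raise ValueError("need at least one generation")
    if not (0.0 <= penetrance <= 1.0):
        raise ValueError("penetrance must lie in [0, 1]")
    rng = _rng(rng)
    members: list[PedigreeMember] = []
    genotypes: dict[str, Optional[bool]] = {}
    counter = 0

    def add(sex, carrier, father=None, mother=None):
        nonlocal counter
        counter += 1
        mid = f"II{counter:03d}"
        affected = bool(carrier and rng.random() < penetrance)
        members.append(
            PedigreeMember(
                member_id=mid, sex=sex, affected=affected,
                father_id=father, mother_id=mother,
                age_at_exam=float(rng.integers(20, 80)),
            )
        )
        genotypes[mid] = carrier
        return mid

    founder = add("1", True)
    spouse = add("2", False)
    couples = [(founder, spouse)]
    for _ in range(1, n_generations):
        next_couples = []
        for father, mother in couples:
            father_carrier = genotypes[father]
            mother_carrier = genotypes[mother]
            for _ in range(children_per_couple):
                inherit = (
                    (father_carrier and rng.random() < 0.5)
                    or (mother_carrier and rng.random() < 0.5)
                )
                sex = "1" if rng.random() < 0.5 else "2"
                child = add(sex, inherit)
                child_spouse = add("2" if sex == "1" else "1", False)
                next_couples.append(
                    (child, child_spouse) if sex == "1"
                    else (child_spouse, child)
                )
        couples = next_couples
    ped = Pedigree(
        family_id="SIMFAM",
        members=members,
        genotypes={mutation: dict(genotypes)},
    )
    truth = {
        "carriers": sorted(m for m, g in genotypes.items() if g),
        "penetrance": penetrance,
    }
    return ped, truth


# ---------------------------------------------------------------------------
# tissue-wise cDNA/gDNA variant sets

GERMLINE_VARIANT = (1093, "T", "A")
EDITING_VARIANT = (1003, "G", "A")


def gen_cdna_variant_sets(
    editing: bool,
    dropout_p: float = 0.0,
    rng: RngLike = 0,
    phase_support: int = 5,
) -> tuple[TissueVariantSets, dict]:
    """Simulate tissue-wise variant sets, optionally with an editing event.

    The germline heterozygous variant appears in every tissue and molecule;
    with ``editing`` the planted event appears in LT cDNA only, phased cis
    with the wild germline allele.  Each observation independently drops
    out with probability ``dropout_p``.  The truth carries the planted
    event and the allele-specific read groups for phasing.
    """
    if not (0.0 <= dropout_p <= 1.0):
        raise ValueError("dropout_p must lie in [0, 1]")
    rng = _rng(rng)
    keys = [
        ("blood", "gDNA"), ("LT", "gDNA"), ("NNS", "gDNA"),
        ("LT", "cDNA"), ("NNS", "cDNA"),
    ]
    sets: dict[tuple[str, str], set] = {}
    for key in keys:
        observed = set()
        if rng.random() >= dropout_p:
            observed.add(GERMLINE_VARIANT)
        if editing and key == ("LT", "cDNA") and rng.random() >= dropout_p:
            observed.add(EDITING_VARIANT)
        sets[key] = observed
    phase_groups = {
        "wild": [True] * phase_support,  # event allele rides the wild haplotype
        "mutant": [False] * phase_support,
    }
    truth = {
        "editing": editing,
        "event": EDITING_VARIANT if editing else None,
        "phase": "cis_with_wild" if editing else None,
        "phase_groups": phase_groups if editing else None,
        "germline": GERMLINE_VARIANT,
    }
    return TissueVariantSets(sets=sets), truth
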