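"""Readers and writers for every external table format.

All tabular formats share one TSV dialect: UTF-8, tab-separated, ``#``
prefixed comment lines, and ``.`` for missing values (the VCF convention).
Every reader/writer pair round-trips exactly.  Variant tables can also be
exchanged as minimal VCF v4.2 with annotations in INFO keys, handled by
pysam.

Internally all genomic intervals are 0-based half-open; HGVS and VCF
coordinates are 1-based and converted at this boundary.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import pysam

from .datamodel import (
    AlleleSignalSet,
    CohortRecord,
    Pedigree,
    PedigreeMember,
    Probe,
    ProbeTrack,
    SignalMeasurement,
    VariantRecord,
    VariantType,
)

MISSING = "."


class TableFormatError(ValueError):
    """File-level format violation (e.g. missing mandatory column)."""


class RecordError(ValueError):
    """Record-level violation; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


# ---------------------------------------------------------------------------
# generic TSV helpers

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False,
        na_values=[], encoding="utf-8",
    )


def _write_tsv(df: pd.DataFrame, path, header_comments: Iterable[str] = ()) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _opt(value: str) -> Optional[str]:
    return None if value in (MISSING, "") else value


def _opt_float(value: str) -> Optional[float]:
    v = _opt(value)
    return None if v is None else float(v)


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(float(value))  # plain float repr even for numpy scalars
    return str(value)


# ---------------------------------------------------------------------------
# variant tables

VARIANT_COLUMNS = [
    "sample_id", "gene", "cdna_hgvs", "protein_hgvs", "vtype",
    "dbsnp_id", "ref_maf", "sift", "pp2", "mt",
]
_MANDATORY_VARIANT_COLUMNS = ["sample_id", "gene", "cdna_hgvs"]


def read_variant_table(path, format: str = "tsv") -> list[VariantRecord]:
    """Read annotated variants from TSV or minimal VCF.

    One :class:`VariantRecord` per sample-variant pair.  Unknown TSV columns
    are preserved in ``record.metadata``.
    """
    if format == "tsv":
        return _read_variant_tsv(path)
    if format == "vcf":
        return _read_variant_vcf(path)
    raise ValueError(f"unknown variant table format {format!r}")


def _read_variant_tsv(path) -> list[VariantRecord]:
    df = _read_tsv(path)
    missing = [c for c in _MANDATORY_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing mandatory column(s) {missing}"
        )
    extra_cols = [c for c in df.columns if c not in VARIANT_COLUMNS]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        cdna = row["cdna_hgvs"]
        if not cdna.startswith("c."):
            raise RecordError(f"malformed HGVS cDNA string {cdna!r}", line=i)
        vtype = _opt(row.get("vtype", MISSING))
        records.append(
            VariantRecord(
                sample_id=row["sample_id"],
                gene=row["gene"],
                cdna_hgvs=cdna,
                protein_hgvs=_opt(row.get("protein_hgvs", MISSING)),
                vtype=VariantType(vtype) if vtype else None,
                dbsnp_id=_opt(row.get("dbsnp_id", MISSING)),
                ref_maf=_opt_float(row.get("ref_maf", MISSING)),
                sift=_opt_float(row.get("sift", MISSING)),
                pp2=_opt_float(row.get("pp2", MISSING)),
                mt=_opt_float(row.get("mt", MISSING)),
                metadata={c: row[c] for c in extra_cols if row[c] != MISSING},
            )
        )
    return records


def write_variant_table(records: list[VariantRecord], path, format: str = "tsv") -> None:
    if format == "vcf":
        _write_variant_vcf(records, path)
        return
    extra_cols = sorted({k for r in records for k in r.metadata})
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "gene": r.gene,
            "cdna_hgvs": r.cdna_hgvs,
            "protein_hgvs": _fmt(r.protein_hgvs),
            "vtype": _fmt(r.vtype.value if r.vtype else None),
            "dbsnp_id": _fmt(r.dbsnp_id),
            "ref_maf": _fmt(r.ref_maf),
            "sift": _fmt(r.sift),
            "pp2": _fmt(r.pp2),
            "mt": _fmt(r.mt),
        }
        row.update({c: r.metadata.get(c, MISSING) for c in extra_cols})
        rows.append(row)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS + extra_cols)
    _write_tsv(df, path)


_SUBST_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")

_VCF_INFO_FIELDS = [
    ("SAMPLE", "String", "Sample identifier"),
    ("GENE", "String", "Gene symbol"),
    ("CDNA", "String", "HGVS cDNA description"),
    ("PHGVS", "String", "HGVS protein description"),
    ("VTYPE", "String", "Classified mutation type"),
    ("DBSNP", "String", "dbSNP identifier"),
    ("MAF", "Float", "Reference-population minor allele frequency"),
    ("SIFT", "Float", "SIFT score"),
    ("PP2", "Float", "PolyPhen-2 score"),
    ("MT", "Float", "MutationTaster score"),
]


def _write_variant_vcf(records: list[VariantRecord], path) -> None:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for gene in sorted({r.gene for r in records}) or ["NA"]:
        header.contigs.add(gene, length=2_000_000)
    for name, typ, desc in _VCF_INFO_FIELDS:
        header.info.add(name, 1, typ, desc)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            m = _SUBST_RE.match(r.cdna_hgvs)
            if m:
                pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
            else:
                pos, ref, alt = 1, "N", "<COMPLEX>"
            rec = vcf.new_record(
                contig=r.gene, start=pos - 1, stop=pos, alleles=(ref, alt),
            )
            if r.dbsnp_id:
                rec.id = r.dbsnp_id
            rec.info["SAMPLE"] = r.sample_id
            rec.info["GENE"] = r.gene
            rec.info["CDNA"] = r.cdna_hgvs
            if r.protein_hgvs is not None:
                rec.info["PHGVS"] = r.protein_hgvs
            if r.vtype is not None:
                rec.info["VTYPE"] = r.vtype.value
            if r.dbsnp_id is not None:
                rec.info["DBSNP"] = r.dbsnp_id
            for key, attr in (("MAF", "ref_maf"), ("SIFT", "sift"),
                              ("PP2", "pp2"), ("MT", "mt")):
                val = getattr(r, attr)
                if val is not None:
                    rec.info[key] = val
            vcf.write(rec)


def _read_variant_vcf(path) -> list[VariantRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info

            def get(key):
                return info.get(key) if key in info else None

            vtype = get("VTYPE")
            # pysam returns Float INFO as float32; round-trip through repr of
            # the original double is preserved to float precision we accept
            records.append(
                VariantRecord(
                    sample_id=get("SAMPLE"),
                    gene=get("GENE") or rec.chrom,
                    cdna_hgvs=get("CDNA"),
                    protein_hgvs=get("PHGVS"),
                    vtype=VariantType(vtype) if vtype else None,
                    dbsnp_id=get("DBSNP") or (rec.id or None),
                    ref_maf=_round_f32(get("MAF")),
                    sift=_round_f32(get("SIFT")),
                    pp2=_round_f32(get("PP2")),
                    mt=_round_f32(get("MT")),
                )
            )
    return records


def _round_f32(value) -> Optional[float]:
    # htslib stores INFO floats as 32-bit; recover the shortest double
    if value is None:
        return None
    return float(f"{float(value):.6g}")


# ---------------------------------------------------------------------------
# pedigrees (PED 6-column core + one genotype column per mutation)

def read_pedigree(path) -> Pedigree:
    """Read a PED-like family file.

    Columns: family, member, father, mother (``0`` = founder), sex,
    affected (1 unaffected / 2 affected / 0 unknown), then one ``0/1/NA``
    carrier column per mutation, named in the header comment line.
    """
    path = Path(path)
    header_cols: Optional[list[str]] = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header_cols = line.lstrip("#").split("\t")
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise TableFormatError(f"{path}: empty pedigree file")
    n_extra = len(rows[0]) - 6
    if n_extra < 0:
        raise TableFormatError(f"{path}: fewer than 6 PED columns")
    if header_cols is not None:
        mutation_names = header_cols[6:]
    else:
        mutation_names = [f"mutation_{i + 1}" for i in range(n_extra)]

    family_id = rows[0][0]
    members = []
    genotypes: dict[str, dict[str, Optional[bool]]] = {
        m: {} for m in mutation_names
    }
    aff_map = {"2": True, "1": False, "0": None, "-9": None}
    for row in rows:
        fam, member, father, mother, sex, affected = row[:6]
        members.append(
            PedigreeMember(
                member_id=member,
                sex=sex,
                affected=aff_map.get(affected),
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
            )
        )
        for name, value in zip(mutation_names, row[6:]):
            genotypes[name][member] = {
                "1": True, "0": False, "NA": None, MISSING: None,
            }[value]
    return Pedigree(family_id=family_id, members=members, genotypes=genotypes)


def write_pedigree(ped: Pedigree, path) -> None:
    mutation_names = sorted(ped.genotypes)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "#" + "\t".join(
                ["family", "member", "father", "mother", "sex", "affected"]
                + mutation_names
            ) + "\n"
        )
        for m in ped.members:
            aff = {True: "2", False: "1", None: "0"}[m.affected]
            cells = [
                ped.family_id, m.member_id, m.father_id or "0",
                m.mother_id or "0", m.sex, aff,
            ]
            for name in mutation_names:
                g = ped.genotypes[name].get(m.member_id)
                cells.append({True: "1", False: "0", None: "NA"}[g])
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# probe tracks

def read_probe_track(path) -> ProbeTrack:
    path = Path(path)
    gene = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#gene="):
                gene = line.strip().split("=", 1)[1]
    if gene is None:
        raise TableFormatError(f"{path}: missing '#gene=' directive")
    df = _read_tsv(path)
    meta_cols = ["probe_id", "position", "region_label", "variant_tag"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    probes = [
        Probe(
            probe_id=row["probe_id"],
            position=int(row["position"]),
            region_label=row["region_label"],
            variant_tag=row["variant_tag"],
        )
        for _, row in df.iterrows()
    ]
    ratios = {
        s: {row["probe_id"]: float(row[s]) for _, row in df.iterrows()}
        for s in samples
    }
    return ProbeTrack(gene=gene, probes=probes, ratios=ratios)


def write_probe_track(track: ProbeTrack, path) -> None:
    samples = sorted(track.ratios)
    rows = []
    for p in track.probes:
        row = {
            "probe_id": p.probe_id,
            "position": p.position,
            "region_label": p.region_label,
            "variant_tag": p.variant_tag,
        }
        row.update({s: repr(float(track.ratios[s][p.probe_id])) for s in samples})
        rows.append(row)
    df = pd.DataFrame(rows)
    _write_tsv(df, path, header_comments=[f"gene={track.gene}"])


# ---------------------------------------------------------------------------
# allele-signal sets

SIGNAL_COLUMNS = [
    "patient_id", "mutation", "tissue_site", "tissue", "molecule",
    "replicate", "mutant_signal", "wild_signal",
]


def read_allele_signals(path) -> list[AlleleSignalSet]:
    """Read SNaPshot-style allele signals; one set per patient x mutation."""
    df = _read_tsv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    sets = []
    for (pid, mut), grp in df.groupby(["patient_id", "mutation"], sort=False):
        site = _opt(grp["tissue_site"].iloc[0]) or ""
        measurements = [
            SignalMeasurement(
                tissue=row["tissue"],
                molecule=row["molecule"],
                replicate=int(row["replicate"]),
                mutant_signal=float(row["mutant_signal"]),
                wild_signal=float(row["wild_signal"]),
            )
            for _, row in grp.iterrows()
        ]
        sets.append(
            AlleleSignalSet(
                patient_id=pid, mutation=mut,
                measurements=measurements, tissue_site=site,
            )
        )
    return sets


def write_allele_signals(sets: list[AlleleSignalSet], path) -> None:
    rows = []
    for s in sets:
        for m in s.measurements:
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "mutation": s.mutation,
                    "tissue_site": s.tissue_site or MISSING,
                    "tissue": m.tissue,
                    "molecule": m.molecule,
                    "replicate": m.replicate,
                    "mutant_signal": repr(float(m.mutant_signal)),
                    "wild_signal": repr(float(m.wild_signal)),
                }
            )
    _write_tsv(pd.DataFrame(rows, columns=SIGNAL_COLUMNS), path)


# ---------------------------------------------------------------------------
# methylation tables (per-CpG bisulfite fractions)

METHYLATION_COLUMNS = ["gene", "cpg_position", "meth_fraction", "coverage"]


def read_methylation_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in METHYLATION_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    out = df.copy()
    out["cpg_position"] = out["cpg_position"].astype(int)
    out["meth_fraction"] = out["meth_fraction"].astype(float)
    out["coverage"] = out["coverage"].astype(int)
    if ((out["meth_fraction"] < 0) | (out["meth_fraction"] > 1)).any():
        raise TableFormatError(f"{path}: methylated fraction outside [0, 1]")
    if (out["coverage"] < 0).any():
        raise TableFormatError(f"{path}: negative coverage")
    return out


def write_methylation_table(df: pd.DataFrame, path) -> None:
    out = df[METHYLATION_COLUMNS].copy()
    out["meth_fraction"] = out["meth_fraction"].map(repr)
    _write_tsv(out, path)


# ---------------------------------------------------------------------------
# tissue variant sets (for RNA-editing detection)

TISSUE_VARIANT_COLUMNS = ["tissue", "molecule", "position", "ref", "alt", "support"]


def read_tissue_variants(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in TISSUE_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    out = df.copy()
    out["position"] = out["position"].astype(int)
    out["support"] = out["support"].replace(MISSING, "-1").astype(int)
    return out


def write_tissue_variants(df: pd.DataFrame, path) -> None:
    _write_tsv(df[TISSUE_VARIANT_COLUMNS].astype(str), path)


# ---------------------------------------------------------------------------
# cohort tables

COHORT_COLUMNS = [
    "patient_id", "cohort_arm", "sex", "genes_mutated",
    "lesion_count_category", "lesion_diameter_min_mm",
    "lesion_diameter_max_mm", "onset_category", "pk_variants", "comorbidity",
]


def _join_set(values: frozenset) -> str:
    return ",".join(sorted(values)) if values else MISSING


def _split_set(value: str) -> frozenset:
    v = _opt(value)
    return frozenset(v.split(",")) if v else frozenset()


def read_cohort_table(path) -> list[CohortRecord]:
    df = _read_tsv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    return [
        CohortRecord(
            patient_id=row["patient_id"],
            cohort_arm=row["cohort_arm"],
            sex=row["sex"],
            genes_mutated=_split_set(row["genes_mutated"]),
            lesion_count_category=_opt(row["lesion_count_category"]),
            lesion_diameter_min_mm=_opt_float(row["lesion_diameter_min_mm"]),
            lesion_diameter_max_mm=_opt_float(row["lesion_diameter_max_mm"]),
            onset_category=_opt(row["onset_category"]),
            pk_variants=_split_set(row["pk_variants"]),
            comorbidity=_split_set(row["comorbidity"]),
        )
        for _, row in df.iterrows()
    ]


def write_cohort_table(records: list[CohortRecord], path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "cohort_arm": r.cohort_arm,
            "sex": r.sex,
            "genes_mutated": _join_set(r.genes_mutated),
            "lesion_count_category": _fmt(r.lesion_count_category),
            "lesion_diameter_min_mm": _fmt(r.lesion_diameter_min_mm),
            "lesion_diameter_max_mm": _fmt(r.lesion_diameter_max_mm),
            "onset_category": _fmt(r.onset_category),
            "pk_variants": _join_set(r.pk_variants),
            "comorbidity": _join_set(r.comorbidity),
        }
        for r in records
    ]
    _write_tsv(pd.DataFrame(rows, columns=COHORT_COLUMNS), path)


# ---------------------------------------------------------------------------
# run manifests

def write_manifest(out_dir, **params) -> Path:
    """Write a JSON parameter manifest beside a pipeline run's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, **params}
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
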