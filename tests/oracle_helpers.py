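"""Independent brute-force oracles shared by unit and acceptance tests.

Deliberately re-derives every rule from scratch rather than calling the
implementation under test.
"""

from poromech.datamodel import DELETERIOUS_BY_TYPE, VariantRecord
from poromech.variant_screen import classify_mutation_type


def cascade_oracle(variants, controls, cfg):
    """Exhaustive per-variant re-evaluation of the three screening rules."""
    out = []
    for v in variants:
        benign = (v.dbsnp_id is not None and v.ref_maf is not None
                  and v.ref_maf >= cfg.maf_threshold)
        if benign:
            continue
        vtype = classify_mutation_type(v.cdna_hgvs, v.protein_hgvs)
        if vtype not in DELETERIOUS_BY_TYPE:
            score_hit = (
                (v.sift is not None and v.sift < cfg.sift_threshold)
                or (v.pp2 is not None and v.pp2 > cfg.pp2_threshold)
                or (v.mt is not None and v.mt > cfg.mt_threshold)
            )
            if not score_hit:
                continue
        if cfg.control_exclusion and controls.get((v.gene, v.cdna_hgvs), False):
            continue
        out.append(v)
    return out


def random_variants(rng, n):
    """Random annotated variants plus a random control-observation table."""
    variants, controls = [], {}
    cdna_pool = [
        ("c.746T>C", "p.Phe249Ser"), ("c.302C>G", "p.Pro101Arg"),
        ("c.395delT", None), ("c.371+2T>A", None), ("c.2T>C", "p.Met1?"),
        ("c.412C>T", "p.Arg138Ter"), ("c.100_102del", None),
        ("c.300G>A", "p.Lys100Lys"), ("c.500A>G", None),
    ]
    for i in range(n):
        cdna, prot = cdna_pool[rng.integers(len(cdna_pool))]
        v = VariantRecord(
            sample_id=f"S{i}",
            gene=["MVK", "MVD", "PMVK", "FDPS"][rng.integers(4)],
            cdna_hgvs=cdna, protein_hgvs=prot,
            dbsnp_id=f"rs{i}" if rng.random() < 0.5 else None,
            ref_maf=float(rng.uniform(0, 0.2)) if rng.random() < 0.7 else None,
            sift=float(rng.uniform(0, 1)) if rng.random() < 0.8 else None,
            pp2=float(rng.uniform(0, 1)) if rng.random() < 0.8 else None,
            mt=float(rng.uniform(0, 1)) if rng.random() < 0.8 else None,
        )
        variants.append(v)
        if rng.random() < 0.3:
            controls[v.mutation_key] = True
    return variants, controls
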